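"""Statistics over monosynaptic input-count matrices.

Per-subject region counts from rabies tracing are converted to input
proportions; regions are compared across molecular subtypes with per-region
one-way ANOVAs (Benjamini-Hochberg FDR across regions, Tukey HSD post hoc),
group structure is summarized by PCA with Fisher-combined per-PC t-tests
and a 1/(1+distance) similarity index validated by permutation, and subtype
identity is decoded from standardized proportions with a linear SVM
(one-vs-one multiclass) under leave-one-subject-out cross-validation with a
label-permutation null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from sklearn.decomposition import PCA
from sklearn.svm import SVC
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .core import InputCountMatrix, ValidationError

log = logging.getLogger(__name__)


def proportions(counts: InputCountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Per-subject proportion of total inputs assigned to each region."""
    df = counts.counts if isinstance(counts, InputCountMatrix) else pd.DataFrame(counts)
    totals = df.sum(axis=1)
    zero = totals == 0
    if zero.any():
        log.info("excluding %d zero-total subjects: %s",
                 int(zero.sum()), list(df.index[zero]))
        df = df.loc[~zero]
        totals = totals[~zero]
    return df.div(totals, axis=0)


def region_anova(
    props: pd.DataFrame, subtype: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-region one-way ANOVA across subtypes.

    Returns a table with F, raw p, eta-squared effect size, BH-adjusted p,
    and Tukey HSD pairwise results where the adjusted p clears ``alpha``.
    Regions without any variance are flagged with NaN statistics.
    """
    subtype = pd.Series(subtype).reindex(props.index)
    groups = subtype.unique()
    if len(groups) < 2:
        raise ValidationError("ANOVA needs at least 2 subtypes")
    if (subtype.value_counts() < 2).any():
        raise ValidationError("every subtype needs at least 2 subjects")
    rows = []
    for region in props.columns:
        samples = [props.loc[subtype == g, region].to_numpy() for g in groups]
        allv = np.concatenate(samples)
        if np.allclose(allv, allv[0]):
            rows.append(dict(region=region, F=np.nan, p=np.nan,
                             eta_sq=np.nan, flagged=True))
            continue
        F, p = stats.f_oneway(*samples)
        gm = allv.mean()
        ss_between = sum(len(s) * (s.mean() - gm) ** 2 for s in samples)
        ss_total = ((allv - gm) ** 2).sum()
        rows.append(dict(region=region, F=float(F), p=float(p),
                         eta_sq=float(ss_between / ss_total), flagged=False))
    table = pd.DataFrame(rows).set_index("region")
    ok = table["p"].notna()
    table["p_adj"] = np.nan
    if ok.any():
        _, adj, _, _ = multipletests(table.loc[ok, "p"], method="fdr_bh")
        table.loc[ok, "p_adj"] = adj
    tukey = {}
    for region in table.index[(table["p_adj"] < alpha).fillna(False)]:
        res = pairwise_tukeyhsd(
            props[region].to_numpy(), subtype.to_numpy(), alpha=alpha
        )
        tukey[region] = pd.DataFrame(
            res.summary().data[1:], columns=res.summary().data[0]
        )
    table.attrs["tukey"] = tukey
    return table


def _standardize(props: pd.DataFrame) -> np.ndarray:
    X = props.to_numpy(dtype=float)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


@dataclass
class ConnectivityPCA:
    scores: pd.DataFrame  # subjects x PCs
    explained_variance_ratio: np.ndarray
    fisher_p: pd.DataFrame  # group-pair matrix of combined p-values
    similarity: pd.DataFrame  # group-pair similarity indices
    permutation_p: pd.DataFrame  # group-pair permutation p-values
    dendrogram: np.ndarray  # scipy linkage matrix on group mean PC vectors
    groups: list[str]


def connectivity_pca_similarity(
    props: pd.DataFrame,
    subtype: pd.Series,
    n_pcs: int = 3,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> ConnectivityPCA:
    """PCA of z-scored proportions with pairwise group comparisons.

    Per group pair: two-sample t-tests on each retained PC combined with
    Fisher's method; the mean cross-group Euclidean distance in PC space
    mapped to a similarity index 1/(1 + distance); and a permutation test
    that reassigns subjects to groups. Average-linkage hierarchical
    clustering of the group mean PC vectors gives the dendrogram.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    subtype = pd.Series(subtype).reindex(props.index)
    X = _standardize(props)
    n_pcs = min(n_pcs, min(X.shape) - 1) or 1
    pca = PCA(n_components=n_pcs)
    S = pca.fit_transform(X)
    scores = pd.DataFrame(
        S, index=props.index, columns=[f"PC{i+1}" for i in range(n_pcs)]
    )
    groups = list(pd.unique(subtype))
    k = len(groups)
    fisher = pd.DataFrame(np.ones((k, k)), index=groups, columns=groups)
    sim = pd.DataFrame(np.ones((k, k)), index=groups, columns=groups)
    perm = pd.DataFrame(np.ones((k, k)), index=groups, columns=groups)
    for i in range(k):
        for j in range(i + 1, k):
            a = S[(subtype == groups[i]).to_numpy()]
            b = S[(subtype == groups[j]).to_numpy()]
            if min(len(a), len(b)) < 2:
                log.info("group of size 1 in pair (%s, %s): t-tests skipped",
                         groups[i], groups[j])
                fp = np.nan
            else:
                ps = [
                    stats.ttest_ind(a[:, c], b[:, c]).pvalue
                    for c in range(n_pcs)
                ]
                fp = stats.combine_pvalues(ps, method="fisher").pvalue
            d = _mean_cross_distance(a, b)
            null = np.empty(n_perm)
            pool = np.vstack([a, b])
            na = len(a)
            for t in range(n_perm):
                idx = rng.permutation(len(pool))
                null[t] = _mean_cross_distance(pool[idx[:na]], pool[idx[na:]])
            pp = (1 + int((null >= d - 1e-12).sum())) / (1 + n_perm)
            fisher.iloc[i, j] = fisher.iloc[j, i] = fp
            sim.iloc[i, j] = sim.iloc[j, i] = similarity_index(d)
            perm.iloc[i, j] = perm.iloc[j, i] = pp
    means = np.vstack([S[(subtype == g).to_numpy()].mean(axis=0) for g in groups])
    Z = linkage(means, method="average", metric="euclidean") if k > 1 else np.empty((0, 4))
    return ConnectivityPCA(
        scores=scores,
        explained_variance_ratio=pca.explained_variance_ratio_,
        fisher_p=fisher,
        similarity=sim,
        permutation_p=perm,
        dendrogram=Z,
        groups=groups,
    )


def _mean_cross_distance(a: np.ndarray, b: np.ndarray) -> float:
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    return float(d.mean())


def similarity_index(distance: float) -> float:
    """Map a mean cross-group distance to (0, 1]: 1/(1 + distance)."""
    if distance < 0:
        raise ValidationError("distance must be nonnegative")
    return 1.0 / (1.0 + distance)


@dataclass
class DecoderReport:
    loocv_accuracy: float
    bootstrap_accuracies: np.ndarray
    null_accuracies: np.ndarray
    permutation_p: float
    significant: bool
    confusion: pd.DataFrame  # rows: true class, columns: predicted


def subtype_decoder(
    props: pd.DataFrame,
    subtype: pd.Series,
    n_boot: int = 1000,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    C: float = 1.0,
) -> DecoderReport:
    """Decode molecular subtype from standardized input proportions.

    A linear SVM (native one-vs-one multiclass scheme) is scored by
    leave-one-subject-out CV; a bootstrap (resample subjects with
    replacement, test on the full dataset) yields an accuracy distribution,
    and a label-permutation null yields the p-value (add-one convention).
    Significance requires the observed accuracy to exceed the null's 95th
    percentile.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    subtype = pd.Series(subtype).reindex(props.index)
    y = subtype.to_numpy()
    classes = pd.unique(subtype)
    if len(classes) < 2:
        raise ValidationError("decoder needs at least 2 subtypes")
    if (subtype.value_counts() < 2).any():
        log.info("a class has a single sample; its LOOCV fold is degenerate")
    X = _standardize(props)

    def _loocv(labels: np.ndarray) -> tuple[float, pd.DataFrame]:
        preds = np.empty(len(labels), dtype=object)
        for i in range(len(labels)):
            mask = np.ones(len(labels), dtype=bool)
            mask[i] = False
            if len(np.unique(labels[mask])) < 2:
                preds[i] = "__degenerate__"
                continue
            clf = SVC(kernel="linear", C=C).fit(X[mask], labels[mask])
            preds[i] = clf.predict(X[i : i + 1])[0]
        acc = float((preds == labels).mean())
        conf = pd.crosstab(
            pd.Series(labels, name="true"), pd.Series(preds, name="predicted")
        ).reindex(index=classes, columns=classes, fill_value=0)
        return acc, conf

    observed, confusion = _loocv(y)

    boot = np.empty(n_boot)
    n = len(y)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if len(np.unique(y[idx])) < 2:
            boot[b] = np.nan
            continue
        clf = SVC(kernel="linear", C=C).fit(X[idx], y[idx])
        boot[b] = float((clf.predict(X) == y).mean())

    null = np.empty(n_perm)
    for t in range(n_perm):
        null[t], _ = _loocv(rng.permutation(y))
    p = (1 + int((null >= observed - 1e-12).sum())) / (1 + n_perm)
    return DecoderReport(
        loocv_accuracy=observed,
        bootstrap_accuracies=boot,
        null_accuracies=null,
        permutation_p=float(p),
        significant=bool(observed > np.percentile(null, 95)),
        confusion=confusion,
    )
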