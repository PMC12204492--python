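"""Functional clustering and anatomical-topography tests.

Neurons are clustered on their trial-averaged responses concatenated across
four behavioral epochs (CS-success, CS-failure, shock, avoidance run):
PCA to 80% variance, k-means over k = 1..20 with multiple restarts, elbow
selection, and silhouette validation. Spatial organization of clusters or of
continuous per-neuron coefficients (PC or coding-direction loadings) is
tested by binning positions along the AP/ML/DV axes into eight bins and
comparing the spread of relative bin concentrations against a
value-shuffle null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .core import TrialTensor, ValidationError

log = logging.getLogger(__name__)

EPOCHS = ("cs_success", "cs_failure", "shock", "avrun")


@dataclass
class ClusterModel:
    k: int
    assignments: np.ndarray  # neuron -> cluster id
    pc_space: np.ndarray  # neurons x retained PCs
    elbow_curve: np.ndarray  # within-cluster inertia for k = 1..k_max
    k_range: np.ndarray
    silhouette: float
    replicates: int


@dataclass
class SpatialTestResult:
    axis: str  # AP | ML | DV
    bin_edges: np.ndarray
    relative_concentration: np.ndarray
    raw_bin_means: np.ndarray
    statistic: float  # SD of the relative concentrations
    p_value: float
    corrected_p: float | None = None


def epoch_feature_matrix(tensors: dict[str, TrialTensor]) -> np.ndarray:
    """Concatenate trial-averaged responses across the four epochs into one
    row per neuron."""
    missing = [e for e in EPOCHS if e not in tensors]
    if missing:
        raise ValidationError(f"missing epochs: {missing}")
    n = tensors[EPOCHS[0]].n_neurons
    parts = []
    for e in EPOCHS:
        t = tensors[e]
        if t.n_neurons != n:
            raise ValidationError("all epoch tensors must share neurons")
        parts.append(t.data.mean(axis=1))
    return np.concatenate(parts, axis=1)


def functional_clusters(
    features: np.ndarray,
    k_range: range = range(1, 21),
    variance_target: float = 0.8,
    replicates: int = 5,
    seed: int | None = 0,
) -> ClusterModel:
    """PCA-reduced k-means with elbow-based model selection.

    The retained PCs explain at least ``variance_target`` of the feature
    variance; for each k the best of ``replicates`` restarts is kept and the
    chosen k maximizes the discrete second difference of the inertia curve
    (the elbow). Silhouette score validates the selected partition.
    """
    X = np.asarray(features, dtype=float)
    ks = np.asarray(list(k_range))
    if X.shape[0] < ks.max():
        raise ValidationError("need at least max(k_range) neurons")
    pca = PCA()
    Z = pca.fit_transform(X)
    npc = int(
        np.searchsorted(
            np.cumsum(pca.explained_variance_ratio_), variance_target - 1e-12
        )
        + 1
    )
    Z = Z[:, :npc]
    inertia, models = [], {}
    for k in ks:
        km = KMeans(n_clusters=int(k), n_init=replicates, random_state=seed)
        km.fit(Z)
        if len(np.unique(km.labels_)) < k:
            log.info("empty cluster at k=%d; re-running with fresh restarts", k)
            km = KMeans(
                n_clusters=int(k), n_init=replicates,
                random_state=None if seed is None else seed + 1,
            ).fit(Z)
        inertia.append(km.inertia_)
        models[int(k)] = km
    inertia = np.asarray(inertia)
    best_k = int(ks[0])
    if inertia[0] > 0:
        tiny = inertia <= 1e-12 * inertia[0]
        if tiny.any():
            # perfectly separated data: smallest k with zero within-cluster
            # distance is the inflection
            best_k = int(ks[np.argmax(tiny)])
        elif ks.size >= 3:
            # knee of the elbow curve: the point of maximum distance below
            # the chord of the log-inertia curve; log scaling keeps the
            # steep early drops from masking where the relative
            # improvement collapses
            li = np.log(inertia)
            chord = li[0] + (ks - ks[0]) * (li[-1] - li[0]) / (ks[-1] - ks[0])
            best_k = int(ks[np.argmin(li - chord)])
    labels = models[best_k].labels_
    sil = (
        float(silhouette_score(Z, labels))
        if 1 < best_k < X.shape[0]
        else 0.0
    )
    return ClusterModel(
        k=best_k,
        assignments=labels,
        pc_space=Z,
        elbow_curve=inertia,
        k_range=ks,
        silhouette=sil,
        replicates=replicates,
    )


def cluster_profiles(
    model: ClusterModel, tensors: dict[str, TrialTensor]
) -> dict:
    """Per-cluster mean epoch traces plus a display-ready normalized matrix.

    Rows are min-max normalized to [0, 1] per neuron (constant rows map to
    0.5) and sorted within cluster by correlation with the cluster mean.
    """
    feats = epoch_feature_matrix(tensors)
    norm = np.empty_like(feats)
    for i, row in enumerate(feats):
        rng_ = row.max() - row.min()
        if rng_ == 0:
            norm[i] = 0.5
            log.info("constant neuron %d normalized to 0.5", i)
        else:
            norm[i] = (row - row.min()) / rng_
    means = {}
    order = []
    for c in np.unique(model.assignments):
        members = np.nonzero(model.assignments == c)[0]
        cmean = feats[members].mean(axis=0)
        means[int(c)] = cmean
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.array(
                [np.corrcoef(feats[m], cmean)[0, 1] for m in members]
            )
        corr = np.nan_to_num(corr, nan=-np.inf)
        order.extend(members[np.argsort(-corr)])
    return {
        "cluster_means": means,
        "normalized": norm,
        "heatmap_order": np.asarray(order),
    }


def spatial_concentration_test(
    values: np.ndarray,
    coords: np.ndarray,
    axis: str = "AP",
    n_bins: int = 8,
    n_shuffle: int = 10000,
    seed: int | np.random.Generator | None = None,
    rng: np.random.Generator | None = None,
) -> SpatialTestResult:
    """Shuffle test for anatomical concentration of a per-neuron quantity.

    Neurons are binned along one anatomical axis (equal-width bins); per bin
    the mean value is computed and normalized by the summed absolute bin
    means into relative concentrations. The statistic is the SD of that
    vector; the null shuffles values across neurons, and the p-value is the
    add-one fraction of shuffles with an SD at least as large. Cluster
    membership is tested by passing an indicator vector.
    """
    values = np.asarray(values, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[:, {"AP": 0, "ML": 1, "DV": 2}[axis]]
    finite = np.isfinite(coords) & np.isfinite(values)
    values, coords = values[finite], coords[finite]
    if values.size < n_bins:
        raise ValidationError(f"need at least {n_bins} neurons with coordinates")
    rng = rng or (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    edges = np.histogram_bin_edges(coords, bins=n_bins)
    which = np.clip(np.digitize(coords, edges[1:-1]), 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    empty = counts == 0
    if empty.any():
        log.info("%d empty spatial bins retained with zero concentration",
                 int(empty.sum()))

    binmat = np.zeros((n_bins, values.size))
    binmat[which, np.arange(values.size)] = 1.0
    safe_counts = np.where(counts == 0, 1, counts)

    def _concentration(v: np.ndarray) -> np.ndarray:
        means = (binmat @ v) / safe_counts
        means[empty] = 0.0
        denom = np.abs(means).sum()
        return means / denom if denom > 0 else means

    obs_means = (binmat @ values) / safe_counts
    obs_means[empty] = 0.0
    conc = _concentration(values)
    stat = float(conc.std())

    shuf = rng.permuted(
        np.broadcast_to(values, (n_shuffle, values.size)).copy(), axis=1
    )
    means = (shuf @ binmat.T) / safe_counts
    means[:, empty] = 0.0
    denom = np.abs(means).sum(axis=1)
    denom[denom == 0] = 1.0
    null_stat = (means / denom[:, None]).std(axis=1)
    p = (1 + int((null_stat >= stat - 1e-15).sum())) / (1 + n_shuffle)
    return SpatialTestResult(
        axis=axis,
        bin_edges=edges,
        relative_concentration=conc,
        raw_bin_means=obs_means,
        statistic=stat,
        p_value=float(p),
    )


def correct_spatial_family(
    results: list[SpatialTestResult], method: str = "holm"
) -> list[SpatialTestResult]:
    """Holm-Bonferroni correction across a family of spatial tests run
    together (e.g. the three anatomical axes)."""
    ps = [r.p_value for r in results]
    _, corrected, _, _ = multipletests(ps, method=method)
    for r, cp in zip(results, corrected):
        r.corrected_p = float(cp)
    return results
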