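"""Pseudo-population outcome decoding with linear SVMs.

Single-trial activity is denoised by reconstruction from the top PCs of the
trial-averaged embedding, pseudo-trials are assembled by randomly pairing
trials within outcome class across neurons, and a linear-kernel max-margin
classifier is scored by stratified leave-one-out cross-validation (one trial
held out per class per fold). Chance level is estimated from label-shuffled
reruns of the identical procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core import TrialTensor, ValidationError
from .geometry import PopulationEmbedding, project_single_trials, trial_averaged_pca

#: classification periods, seconds relative to the alignment event
DECODE_PERIODS = {"window_cs": (0.0, 2.0), "window_preavrun": (-1.4, 0.0)}


@dataclass
class DecodeResult:
    mode: str  # window_cs | window_preavrun | timecourse
    n_neurons: int
    accuracies: np.ndarray  # bootstraps, or bootstraps x time
    null_accuracies: np.ndarray | None = None
    p_value: float | None = None

    @property
    def mean_accuracy(self) -> float | np.ndarray:
        return self.accuracies.mean(axis=0)


def reconstruct_from_pcs(
    embedding: PopulationEmbedding,
    tensor: TrialTensor,
    variance_target: float = 0.8,
) -> np.ndarray:
    """Denoise single-trial activity by reconstruction from the PCs that
    explain at least ``variance_target`` of the trial-averaged variance."""
    k = embedding.n_pcs_for_variance(variance_target)
    k = min(k, embedding.components.shape[1])
    proj = project_single_trials(embedding, tensor, n_pcs=k)
    comp = embedding.components[:, :k]
    return (
        np.einsum("tjk,nk->ntj", proj, comp)
        + embedding.row_means[:, None, None]
    )


def build_pseudopopulation(
    embedding: PopulationEmbedding | None,
    tensor_s: TrialTensor,
    tensor_f: TrialTensor,
    period_s: tuple[float, float],
    n_neurons: int | None = None,
    seed: int | np.random.Generator | None = None,
    variance_target: float = 0.8,
    timepoint: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble pseudo-trial feature vectors and outcome labels.

    Per class, the pseudo-trial count is the smaller condition's trial
    count; each neuron contributes an independently drawn (without
    replacement) trial ordering, emulating pairing of trials across animals.
    Features concatenate the period's timepoints per neuron; with
    ``timepoint`` set, a single 1-per-neuron bin is used instead.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if tensor_s.n_trials == 0 or tensor_f.n_trials == 0:
        raise ValidationError("each outcome class needs at least one trial")
    if embedding is None:
        embedding = trial_averaged_pca(tensor_s, tensor_f)
    recon_s = reconstruct_from_pcs(embedding, tensor_s, variance_target)
    recon_f = reconstruct_from_pcs(embedding, tensor_f, variance_target)
    n = recon_s.shape[0]
    if n_neurons is None:
        n_neurons = n
    if n_neurons > n:
        raise ValidationError(f"requested {n_neurons} neurons, pool has {n}")
    cells = rng.choice(n, size=n_neurons, replace=False)
    if timepoint is None:
        cols = tensor_s.window_slice(period_s)
    else:
        cols = np.array([timepoint])
    n_tr = min(recon_s.shape[1], recon_f.shape[1])

    def _assemble(recon: np.ndarray) -> np.ndarray:
        feats = np.empty((n_tr, n_neurons * cols.size))
        for j, c in enumerate(cells):
            order = rng.permutation(recon.shape[1])[:n_tr]
            feats[:, j * cols.size : (j + 1) * cols.size] = recon[c][
                np.ix_(order, cols)
            ]
        return feats

    X = np.vstack([_assemble(recon_s), _assemble(recon_f)])
    y = np.array(["success"] * n_tr + ["failure"] * n_tr)
    return X, y


def loo_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    C: float = 1.0,
    standardize: bool = True,
) -> float:
    """Stratified leave-one-out accuracy of a linear-kernel SVM.

    Each fold holds out one trial per class; features are standardized with
    statistics fit on the training folds only.
    """
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValidationError("need both outcome classes to decode")
    by_class = [np.nonzero(y == c)[0] for c in classes]
    n_folds = min(len(ix) for ix in by_class)
    if n_folds < 2:
        raise ValidationError("each class needs at least 2 trials for LOO folds")
    correct = total = 0
    for f in range(n_folds):
        test = np.array([ix[f] for ix in by_class])
        train = np.ones(y.size, dtype=bool)
        train[test] = False
        if standardize:
            clf = make_pipeline(StandardScaler(), SVC(kernel="linear", C=C))
        else:
            clf = SVC(kernel="linear", C=C)
        clf.fit(X[train], y[train])
        correct += int((clf.predict(X[test]) == y[test]).sum())
        total += test.size
    return correct / total


def decode_window(
    tensor_s: TrialTensor,
    tensor_f: TrialTensor,
    embedding: PopulationEmbedding | None = None,
    mode: str = "window_cs",
    period_s: tuple[float, float] | None = None,
    n_neurons: int | None = None,
    n_boot: int = 100,
    seed: int | np.random.Generator | None = None,
    variance_target: float = 0.8,
) -> DecodeResult:
    """Windowed outcome decoding: per bootstrap, pseudo-trials are
    regenerated and the stratified-LOO accuracy recorded."""
    period = period_s if period_s is not None else DECODE_PERIODS[mode]
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if embedding is None:
        embedding = trial_averaged_pca(tensor_s, tensor_f)
    acc = np.empty(n_boot)
    for b in range(n_boot):
        X, y = build_pseudopopulation(
            embedding, tensor_s, tensor_f, period, n_neurons, rng,
            variance_target,
        )
        acc[b] = loo_accuracy(X, y)
    return DecodeResult(
        mode=mode,
        n_neurons=n_neurons or tensor_s.n_neurons,
        accuracies=acc,
    )


def decode_timecourse(
    tensor_s: TrialTensor,
    tensor_f: TrialTensor,
    embedding: PopulationEmbedding | None = None,
    n_neurons: int = 200,
    n_boot: int = 100,
    seed: int | np.random.Generator | None = None,
    variance_target: float = 0.8,
) -> DecodeResult:
    """Instantaneous decoding: one classifier per time bin, features are a
    single bin per neuron."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if embedding is None:
        embedding = trial_averaged_pca(tensor_s, tensor_f)
    T = tensor_s.n_timepoints
    acc = np.empty((n_boot, T))
    for b in range(n_boot):
        for t in range(T):
            X, y = build_pseudopopulation(
                embedding, tensor_s, tensor_f, tensor_s.window_s,
                n_neurons, rng, variance_target, timepoint=t,
            )
            acc[b, t] = loo_accuracy(X, y)
    return DecodeResult(mode="timecourse", n_neurons=n_neurons, accuracies=acc)


def shuffle_null(
    tensor_s: TrialTensor,
    tensor_f: TrialTensor,
    observed: float | None = None,
    mode: str = "window_cs",
    period_s: tuple[float, float] | None = None,
    n_neurons: int | None = None,
    n_shuffle: int = 1000,
    seed: int | np.random.Generator | None = None,
    variance_target: float = 0.8,
) -> tuple[np.ndarray, float]:
    """Label-shuffle null distribution for windowed decoding.

    Per shuffle the per-trial outcome labels are randomly reassigned and the
    *entire* procedure — trial-averaged PCA, PC reconstruction, pseudo-trial
    assembly, stratified-LOO SVM — is re-run on the relabeled trials. This
    matched null absorbs the optimism that reconstruction and pseudo-trial
    resampling introduce (both reuse trial averages across folds), so the
    p-value — add-one convention ``(1 + #{null >= observed}) /
    (1 + n_shuffle)`` — is calibrated. When ``observed`` is omitted it is
    computed with the identical procedure on the true labels.
    """
    _checked = (tensor_s.n_trials >= 2) and (tensor_f.n_trials >= 2)
    if not _checked:
        raise ValidationError("shuffle null needs >= 2 trials per class")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    period = period_s if period_s is not None else DECODE_PERIODS[mode]
    data = np.concatenate([tensor_s.data, tensor_f.data], axis=1)
    n_s = tensor_s.n_trials

    def _one(labels_s_first: np.ndarray) -> float:
        ds = data[:, labels_s_first, :]
        df = data[:, ~labels_s_first, :]
        ts = TrialTensor(
            data=ds, align_event=tensor_s.align_event,
            window_s=tensor_s.window_s,
            outcome=np.array(["success"] * ds.shape[1]),
            frame_rate_hz=tensor_s.frame_rate_hz,
        )
        tf = TrialTensor(
            data=df, align_event=tensor_s.align_event,
            window_s=tensor_s.window_s,
            outcome=np.array(["failure"] * df.shape[1]),
            frame_rate_hz=tensor_s.frame_rate_hz,
        )
        emb = trial_averaged_pca(ts, tf)
        X, y = build_pseudopopulation(
            emb, ts, tf, period, n_neurons, rng, variance_target
        )
        return loo_accuracy(X, y)

    true_mask = np.zeros(data.shape[1], dtype=bool)
    true_mask[:n_s] = True
    if observed is None:
        observed = _one(true_mask)
    null = np.empty(n_shuffle)
    for k in range(n_shuffle):
        null[k] = _one(rng.permutation(true_mask))
    p = (1 + int((null >= observed - 1e-12).sum())) / (1 + n_shuffle)
    return null, float(p)
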