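"""Population trajectory geometry.

Trial-averaged activity of the pooled pseudo-population is embedded with
PCA on the success/failure-concatenated matrix (neurons x 2t); single trials
are projected into that subspace. Outcome separation is quantified two ways:
a bootstrapped Mahalanobis distance between success and failure trajectories
(z-scored to a pre-event baseline, with a conservative pointwise
significance rule), and a coding direction — the unit vector along the
difference of condition means in a post-cue window — with residual PCs
capturing outcome-independent variance orthogonal to it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.covariance import ledoit_wolf
from sklearn.decomposition import PCA

from .core import TrialTensor, ValidationError

log = logging.getLogger(__name__)

#: baseline periods for distance z-scoring, by alignment event
DIVERGENCE_BASELINES = {"cs_onset": (-2.0, 0.0), "avrun_onset": (-3.0, -2.0)}


@dataclass
class PopulationEmbedding:
    components: np.ndarray  # neurons x n_pcs, unit columns
    explained_variance_ratio: np.ndarray
    concat_means: np.ndarray  # neurons x 2t trial-averaged concatenation
    row_means: np.ndarray  # per-neuron centering offsets
    align_event: str
    window_s: tuple[float, float]

    @property
    def n_neurons(self) -> int:
        return self.components.shape[0]

    def n_pcs_for_variance(self, variance_target: float) -> int:
        cum = np.cumsum(self.explained_variance_ratio)
        return int(np.searchsorted(cum, variance_target - 1e-12) + 1)


@dataclass
class CodingDirection:
    cd: np.ndarray  # unit vector over neurons (zero vector when degenerate)
    window_s: tuple[float, float]
    projections_success: np.ndarray  # trials x time
    projections_failure: np.ndarray
    is_zero: bool = False


@dataclass
class ResidualPCs:
    components: np.ndarray  # neurons x k, each orthogonal to the CD
    explained_variance_ratio: np.ndarray
    projections_success: np.ndarray  # trials x time x k
    projections_failure: np.ndarray


@dataclass
class DivergenceResult:
    times: np.ndarray
    z_distance: np.ndarray  # bootstraps x time
    mean_z: np.ndarray
    significant: np.ndarray  # boolean mask per timepoint
    baseline_window: tuple[float, float]


def _check_paired(a: TrialTensor, b: TrialTensor) -> None:
    if a.n_neurons != b.n_neurons:
        raise ValidationError("tensors must share the same neurons")
    if a.n_timepoints != b.n_timepoints or a.window_s != b.window_s:
        raise ValidationError("tensors must share the same time window")


def trial_averaged_pca(
    tensor_s: TrialTensor,
    tensor_f: TrialTensor,
    n_pcs: int | None = None,
) -> PopulationEmbedding:
    """PCA of the success/failure trial-averaged concatenation.

    Each tensor is averaged over trials, the two condition means are
    concatenated along time into a neurons x 2t matrix, rows are
    mean-centered, and PCA is run over the time samples.
    """
    _check_paired(tensor_s, tensor_f)
    if tensor_s.n_trials < 1 or tensor_f.n_trials < 1:
        raise ValidationError("each condition needs at least one trial")
    concat = np.concatenate(
        [tensor_s.data.mean(axis=1), tensor_f.data.mean(axis=1)], axis=1
    )
    n = concat.shape[0]
    max_pcs = min(n, concat.shape[1])
    if n_pcs is not None and n_pcs > max_pcs:
        raise ValidationError(f"requested {n_pcs} PCs but rank is at most {max_pcs}")
    pca = PCA(n_components=n_pcs or min(max_pcs, concat.shape[1] - 1))
    pca.fit(concat.T)  # samples = time points, features = neurons
    return PopulationEmbedding(
        components=pca.components_.T,
        explained_variance_ratio=pca.explained_variance_ratio_,
        concat_means=concat,
        row_means=concat.mean(axis=1),
        align_event=tensor_s.align_event,
        window_s=tensor_s.window_s,
    )


def project_single_trials(
    embedding: PopulationEmbedding,
    tensor: TrialTensor,
    n_pcs: int | None = None,
    variance_target: float = 0.8,
) -> np.ndarray:
    """Project single-trial activity onto the trial-averaged PC subspace.

    Returns trials x time x k trajectories, with k either explicit or the
    number of PCs needed to reach ``variance_target`` explained variance.
    """
    if embedding.n_neurons != tensor.n_neurons:
        raise ValidationError("embedding and tensor neuron counts differ")
    k = n_pcs if n_pcs is not None else embedding.n_pcs_for_variance(variance_target)
    k = min(k, embedding.components.shape[1])
    comp = embedding.components[:, :k]
    centered = tensor.data - embedding.row_means[:, None, None]
    return np.einsum("ntj,nk->tjk", centered, comp)


def mahalanobis(a: np.ndarray, b: np.ndarray, cov: np.ndarray) -> float:
    """sqrt((a-b)^T cov^{-1} (a-b)) by direct linear solve."""
    d = np.asarray(a, float) - np.asarray(b, float)
    return float(np.sqrt(d @ np.linalg.solve(cov, d)))


def _pooled_cov(ps: np.ndarray, pf: np.ndarray) -> np.ndarray:
    """Pooled within-condition covariance of single-trial projections at one
    timepoint, with Ledoit-Wolf shrinkage when trials are scarce or the
    plain estimate is singular."""
    demeaned = np.vstack([ps - ps.mean(0), pf - pf.mean(0)])
    k = demeaned.shape[1]
    cov = demeaned.T @ demeaned / max(demeaned.shape[0] - 2, 1)
    if demeaned.shape[0] - 2 < k or np.linalg.matrix_rank(cov) < k:
        cov, _ = ledoit_wolf(demeaned, assume_centered=True)
        log.info("shrinkage covariance applied (trials < dimension)")
    return cov


def trajectory_divergence(
    tensor_s: TrialTensor,
    tensor_f: TrialTensor,
    n_boot: int = 100,
    variance_target: float = 0.8,
    subsample_frac: float = 0.8,
    baseline_window: tuple[float, float] | None = None,
    z_thresh: float = 1.65,
    sig_frac: float = 0.05,
    seed: int | np.random.Generator | None = None,
) -> DivergenceResult:
    """Bootstrapped Mahalanobis divergence between outcome trajectories.

    Per bootstrap a random neuron subset is drawn, PCA is refit on its
    trial-averaged data to the variance target, single trials (equalized to
    the smaller condition's count) are projected, and the per-timepoint
    Mahalanobis distance between condition clouds is z-scored against the
    pre-event baseline period. A timepoint is significant when fewer than
    ``sig_frac`` of bootstraps stay below ``z_thresh``.
    """
    _check_paired(tensor_s, tensor_f)
    if min(tensor_s.n_trials, tensor_f.n_trials) < 2:
        raise ValidationError("divergence needs at least 2 trials per condition")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if baseline_window is None:
        baseline_window = DIVERGENCE_BASELINES.get(
            tensor_s.align_event, (tensor_s.window_s[0], 0.0)
        )
    base_idx = tensor_s.window_slice(baseline_window)
    n = tensor_s.n_neurons
    n_sub = max(2, int(round(subsample_frac * n)))
    n_tr = min(tensor_s.n_trials, tensor_f.n_trials)
    T = tensor_s.n_timepoints
    zed = np.empty((n_boot, T))
    for b in range(n_boot):
        idx = rng.choice(n, size=n_sub, replace=False)
        ts = _subset_neurons(tensor_s, idx)
        tf = _subset_neurons(tensor_f, idx)
        ts = _subset_trials(ts, rng.choice(ts.n_trials, n_tr, replace=False))
        tf = _subset_trials(tf, rng.choice(tf.n_trials, n_tr, replace=False))
        emb = trial_averaged_pca(ts, tf)
        ps = project_single_trials(emb, ts, variance_target=variance_target)
        pf = project_single_trials(emb, tf, variance_target=variance_target)
        dist = np.empty(T)
        for t in range(T):
            cov = _pooled_cov(ps[:, t, :], pf[:, t, :])
            dist[t] = mahalanobis(ps[:, t, :].mean(0), pf[:, t, :].mean(0), cov)
        mu, sd = dist[base_idx].mean(), dist[base_idx].std()
        zed[b] = (dist - mu) / (sd if sd > 0 else 1.0)
    below = (zed < z_thresh).mean(axis=0)
    return DivergenceResult(
        times=tensor_s.times,
        z_distance=zed,
        mean_z=zed.mean(axis=0),
        significant=below < sig_frac,
        baseline_window=baseline_window,
    )


def _subset_neurons(t: TrialTensor, idx: np.ndarray) -> TrialTensor:
    return TrialTensor(
        data=t.data[idx],
        align_event=t.align_event,
        window_s=t.window_s,
        outcome=t.outcome,
        frame_rate_hz=t.frame_rate_hz,
        event_frames=t.event_frames,
        trial_index=t.trial_index,
    )


def _subset_trials(t: TrialTensor, idx: np.ndarray) -> TrialTensor:
    return TrialTensor(
        data=t.data[:, idx, :],
        align_event=t.align_event,
        window_s=t.window_s,
        outcome=t.outcome[idx],
        frame_rate_hz=t.frame_rate_hz,
        event_frames=None if t.event_frames is None else t.event_frames[idx],
        trial_index=None if t.trial_index is None else t.trial_index[idx],
    )


def coding_direction(
    tensor_s: TrialTensor,
    tensor_f: TrialTensor,
    window_s: tuple[float, float] = (0.0, 3.0),
) -> CodingDirection:
    """Unit vector along the difference of condition means in a window.

    d = mean(success) - mean(failure) per neuron over the window; the coding
    direction is d normalized to unit length, and projections are its dot
    product with single-trial activity, so the in-window success projection
    exceeds the failure projection by construction.
    """
    _check_paired(tensor_s, tensor_f)
    win = tensor_s.window_slice(window_s)
    mean_s = tensor_s.data[:, :, win].mean(axis=(1, 2))
    mean_f = tensor_f.data[:, :, win].mean(axis=(1, 2))
    d = mean_s - mean_f
    norm = np.linalg.norm(d)
    if norm == 0:
        z = np.zeros_like(d)
        return CodingDirection(
            cd=z,
            window_s=window_s,
            projections_success=np.zeros(tensor_s.data.shape[1:]),
            projections_failure=np.zeros(tensor_f.data.shape[1:]),
            is_zero=True,
        )
    cd = d / norm
    return CodingDirection(
        cd=cd,
        window_s=window_s,
        projections_success=np.einsum("n,ntj->tj", cd, tensor_s.data),
        projections_failure=np.einsum("n,ntj->tj", cd, tensor_f.data),
    )


def residual_pcs(
    cd: CodingDirection,
    tensor_s: TrialTensor,
    tensor_f: TrialTensor,
    variance_target: float = 0.85,
) -> ResidualPCs:
    """PCs of trial-averaged activity orthogonal to the coding direction.

    The CD component is projected out of the concatenated condition means;
    PCA on the residual returns components (all orthogonal to the CD) up to
    the variance target, onto which single trials are projected.
    """
    _check_paired(tensor_s, tensor_f)
    concat = np.concatenate(
        [tensor_s.data.mean(axis=1), tensor_f.data.mean(axis=1)], axis=1
    )
    v = cd.cd
    resid = concat - np.outer(v, v @ concat)
    pca = PCA(n_components=min(resid.shape[0], resid.shape[1] - 1))
    pca.fit(resid.T)
    k = int(
        np.searchsorted(
            np.cumsum(pca.explained_variance_ratio_), variance_target - 1e-12
        )
        + 1
    )
    comp = pca.components_[:k].T
    mean = resid.mean(axis=1)

    def _proj(t: TrialTensor) -> np.ndarray:
        X = t.data - np.einsum("n,mtj,m->ntj", v, t.data, v)
        return np.einsum("ntj,nk->tjk", X - mean[:, None, None], comp)

    return ResidualPCs(
        components=comp,
        explained_variance_ratio=pca.explained_variance_ratio_[:k],
        projections_success=_proj(tensor_s),
        projections_failure=_proj(tensor_f),
    )
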