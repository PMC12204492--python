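"""Task-modulation statistics: auROC against a circular-permutation null.

Each neuron's response discriminability for a task variable (CS, avoidance
run, pre-run ramp, shock) is summarized as the area under the ROC curve
comparing response-window fluorescence against a pre-event baseline
distribution. Significance comes from surrogate sessions built by circularly
shifting the whole session trace, which preserves autocorrelation while
destroying event alignment: a neuron is *activated* when its observed auROC
exceeds the upper null percentile and *suppressed* when it falls below the
lower one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .core import TrialTensor, ValidationError

#: variable -> (alignment event, baseline window, response window), seconds
VARIABLE_WINDOWS: dict[str, tuple[str, tuple[float, float], tuple[float, float]]] = {
    "cs": ("cs_onset", (-2.0, 0.0), (0.0, 2.0)),
    "avrun": ("avrun_onset", (-2.0, 0.0), (0.0, 2.0)),
    "shock": ("shock_onset", (-2.0, 0.0), (0.0, 2.0)),
    "pre_avrun": ("avrun_onset", (-3.0, -2.0), (-2.0, 0.0)),
}


@dataclass
class ModulationResult:
    neuron_id: str
    variable: str
    auroc: float
    null_pcts: tuple[float, float]
    mod_class: str  # activated | suppressed | unmodulated


def auroc(baseline: np.ndarray, response: np.ndarray) -> float:
    """Area under the empirical ROC curve for response vs baseline.

    Equals ``P(response > baseline) + 0.5 * P(response == baseline)`` over
    all cross-pairs (the rank-sum statistic U / (n1*n2) with half-credit
    ties): 1 when every response value exceeds every baseline value, 0 in the
    opposite case, 0.5 when the distributions are indistinguishable.
    """
    b = np.asarray(baseline, dtype=float).ravel()
    r = np.asarray(response, dtype=float).ravel()
    if b.size == 0 or r.size == 0:
        raise ValidationError("auroc needs nonempty baseline and response samples")
    ranks = rankdata(np.concatenate([b, r]))
    u = ranks[b.size :].sum() - r.size * (r.size + 1) / 2.0
    return float(u / (b.size * r.size))


def _auroc_stat(
    data: np.ndarray, base_idx: np.ndarray, resp_idx: np.ndarray
) -> np.ndarray:
    """Per-neuron mean auROC over response-window timepoints.

    ``data`` is neurons x trials x timepoints. The baseline sample pools the
    baseline-window values across trials; at each response timepoint the
    across-trial values are compared against that pooled baseline and the
    resulting per-timepoint auROCs are averaged.
    """
    n, ntr, _ = data.shape
    base = data[:, :, base_idx].reshape(n, -1)  # n x m
    m = base.shape[1]
    resp = data[:, :, resp_idx].transpose(0, 2, 1)  # n x Tr x ntr
    tr = resp.shape[1]
    comb = np.concatenate(
        [np.broadcast_to(base[:, None, :], (n, tr, m)), resp], axis=2
    )
    ranks = rankdata(comb, axis=2)
    u = ranks[:, :, m:].sum(axis=2) - ntr * (ntr + 1) / 2.0
    return (u / (m * ntr)).mean(axis=1)


def variable_auroc(tensor: TrialTensor, variable: str) -> np.ndarray:
    """Observed per-neuron auROC statistic for one task variable."""
    if variable not in VARIABLE_WINDOWS:
        raise ValidationError(f"unknown task variable {variable!r}")
    align, base_w, resp_w = VARIABLE_WINDOWS[variable]
    if tensor.align_event != align:
        raise ValidationError(
            f"variable {variable!r} needs a tensor aligned to {align!r}, "
            f"got {tensor.align_event!r}"
        )
    if tensor.n_trials < 2:
        raise ValidationError("auROC statistic needs at least 2 trials")
    return _auroc_stat(
        tensor.data, tensor.window_slice(base_w), tensor.window_slice(resp_w)
    )


def circular_null_classify(
    traces_z: np.ndarray,
    tensor: TrialTensor,
    variable: str,
    neuron_ids: list[str] | None = None,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
) -> list[ModulationResult]:
    """Classify neurons as activated / suppressed / unmodulated.

    For each permutation one uniform circular offset is applied to the whole
    session trace, the trial tensor is re-sliced at the original event frames
    and the auROC statistic recomputed, giving a per-neuron null
    distribution. Classification compares the observed statistic against the
    two-sided ``alpha`` percentiles (97.5th / 2.5th at the default 0.05).
    """
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} gives unstable null percentiles", stacklevel=2
        )
    if tensor.event_frames is None:
        raise ValidationError("tensor lacks event_frames; rebuild with preprocess")
    _, base_w, resp_w = VARIABLE_WINDOWS[variable]
    base_idx = tensor.window_slice(base_w)
    resp_idx = tensor.window_slice(resp_w)
    observed = variable_auroc(tensor, variable)

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    traces_z = np.asarray(traces_z, dtype=float)
    n_frames = traces_z.shape[1]
    pre, _ = tensor.window_s
    offs = int(round(pre * tensor.frame_rate_hz)) + np.arange(tensor.n_timepoints)
    idx0 = tensor.event_frames[:, None] + offs[None, :]  # trials x T

    shifts = rng.integers(1, n_frames, size=n_perm)
    null = np.empty((n_perm, traces_z.shape[0]))
    for k, s in enumerate(shifts):
        idx = (idx0 - s) % n_frames
        null[k] = _auroc_stat(traces_z[:, idx], base_idx, resp_idx)

    lo = np.percentile(null, 100 * alpha / 2, axis=0)
    hi = np.percentile(null, 100 * (1 - alpha / 2), axis=0)
    if neuron_ids is None:
        neuron_ids = [f"n{i:04d}" for i in range(traces_z.shape[0])]
    out = []
    for i, nid in enumerate(neuron_ids):
        if observed[i] > hi[i]:
            cls = "activated"
        elif observed[i] < lo[i]:
            cls = "suppressed"
        else:
            cls = "unmodulated"
        out.append(
            ModulationResult(
                neuron_id=nid,
                variable=variable,
                auroc=float(observed[i]),
                null_pcts=(float(lo[i]), float(hi[i])),
                mod_class=cls,
            )
        )
    return out


def class_fractions(results: list[ModulationResult]) -> dict[str, float]:
    """Fraction of neurons per modulation class (summary comparable to
    population-percentage reports)."""
    n = len(results)
    out = {"activated": 0.0, "suppressed": 0.0, "unmodulated": 0.0}
    for r in results:
        out[r.mod_class] += 1.0
    return {k: v / n for k, v in out.items()} if n else out
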