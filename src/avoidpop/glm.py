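"""Encoding models: kernel-convolved event regressors fit by OLS.

Behavioral events (cue onsets split by outcome, shock, avoidance-run onset
and an anticipatory run regressor) are turned into binary impulse trains,
convolved with a calcium-indicator kernel (linear rise over 0.15 s, e-fold
decay of 0.8 s, 1.5 s support, peak normalized to 1) and optionally shifted
by up to 2 s to absorb neural-behavioral lags. Each unit — a neuron, or a
bulk photometry signal treated as a single "virtual neuron" — is fit by
ordinary least squares; model quality is assessed with leave-one-trial-out
cross-validation and each predictor's influence with a zeroed-predictor
nested comparison (drop in R² relative to the full model, plus an
F statistic).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import EventTable, ValidationError

log = logging.getLogger(__name__)

DEFAULT_PREDICTORS = (
    "cs_success",
    "cs_failure",
    "shock",
    "avrun_onset",
    "avrun_anticipatory",
)

#: +1: regressor may be delayed (forward shift); -1: advanced (backward)
SHIFT_SIGN = {
    "cs_success": +1,
    "cs_failure": +1,
    "shock": +1,
    "avrun_onset": +1,
    "avrun_anticipatory": -1,
}

#: anticipatory run regressor leads the run onset by this much before any
#: additional backward shift
ANTICIPATORY_LEAD_S = 1.0

MAX_SHIFT_S = 2.0


@dataclass
class KernelSpec:
    """Calcium-indicator impulse response parameters."""

    frame_rate_hz: float
    rise_s: float = 0.15
    decay_s: float = 0.8
    duration_s: float = 1.5
    values: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.values = gcamp_kernel(
            self.frame_rate_hz, self.rise_s, self.decay_s, self.duration_s
        )


def gcamp_kernel(
    frame_rate_hz: float,
    rise_s: float = 0.15,
    decay_s: float = 0.8,
    duration_s: float = 1.5,
) -> np.ndarray:
    """Sampled indicator kernel: linear rise to the peak, exponential decay,
    truncated at ``duration_s`` and normalized to a peak of 1."""
    if duration_s < rise_s:
        raise ValidationError("kernel duration must be at least the rise time")
    n = int(round(duration_s * frame_rate_hz))
    if n < 2:
        raise ValidationError("kernel needs at least 2 samples; raise the frame rate")
    t = np.arange(n) / frame_rate_hz
    k = np.where(t <= rise_s, t / rise_s, np.exp(-(t - rise_s) / decay_s))
    return k / k.max()


def event_frames(
    events: EventTable, predictor: str, frame_rate_hz: float
) -> np.ndarray:
    """Session frame indices at which a predictor's impulses occur."""
    df = events.df
    if predictor == "cs_success":
        t = df.loc[df["outcome"] == "success", "cs_onset_s"].to_numpy(float)
    elif predictor == "cs_failure":
        t = df.loc[df["outcome"] == "failure", "cs_onset_s"].to_numpy(float)
    elif predictor == "shock":
        t = df["shock_onset_s"].to_numpy(float)
    elif predictor == "avrun_onset":
        t = df["avrun_onset_s"].to_numpy(float)
    elif predictor == "avrun_anticipatory":
        t = df["avrun_onset_s"].to_numpy(float) - ANTICIPATORY_LEAD_S
    else:
        raise ValidationError(f"unknown predictor {predictor!r}")
    t = t[np.isfinite(t)]
    return np.round(t * frame_rate_hz).astype(int)


@dataclass
class DesignMatrix:
    """Trial-concatenated design with an intercept column."""

    X: np.ndarray  # samples x columns
    columns: list[str]  # parallel to X columns; last is "intercept"
    trial_slices: list[slice]  # rows belonging to each trial
    frame_slices: list[tuple[int, int]]  # session frame range per trial
    frame_rate_hz: float
    shifts_s: dict[str, float]

    @property
    def n_trials(self) -> int:
        return len(self.trial_slices)

    def slice_trace(self, trace: np.ndarray) -> np.ndarray:
        """Concatenate the session trace over the same trial windows."""
        return np.concatenate([trace[a:b] for a, b in self.frame_slices])

    def column(self, name: str) -> int:
        return self.columns.index(name)


def build_design_matrix(
    events: EventTable,
    frame_rate_hz: float,
    n_frames: int,
    kernel: np.ndarray | None = None,
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS,
    shifts_s: dict[str, float] | None = None,
    trial_window_s: tuple[float, float] = (-2.0, 14.0),
) -> DesignMatrix:
    """Kernel-convolved, shifted, trial-concatenated design matrix.

    Each predictor's binary impulse train on the session timeline is
    convolved with the indicator kernel, shifted by ``shifts_s`` (forward for
    event onsets, backward for the anticipatory-run regressor; at most 2 s),
    then sliced into per-trial windows around the CS onset and concatenated.
    Predictors with no events in the session are dropped with a log entry.
    """
    if kernel is None:
        kernel = gcamp_kernel(frame_rate_hz)
    shifts_s = dict(shifts_s or {})
    cols, names = [], []
    for name in predictors:
        frames = event_frames(events, name, frame_rate_hz)
        frames = frames[(frames >= 0) & (frames < n_frames)]
        if frames.size == 0:
            log.info("predictor %r has no events; column dropped", name)
            continue
        shift = shifts_s.get(name, 0.0)
        if abs(shift) > MAX_SHIFT_S + 1e-9:
            raise ValidationError(f"shift for {name!r} exceeds {MAX_SHIFT_S} s")
        train = np.zeros(n_frames)
        np.add.at(train, frames, 1.0)
        conv = np.convolve(train, kernel)[:n_frames]
        k = int(round(SHIFT_SIGN[name] * abs(shift) * frame_rate_hz))
        if k > 0:
            conv = np.concatenate([np.zeros(k), conv[:-k]])
        elif k < 0:
            conv = np.concatenate([conv[-k:], np.zeros(-k)])
        cols.append(conv)
        names.append(name)
    if not cols:
        raise ValidationError("no predictor has any event in this session")

    pre, post = trial_window_s
    frame_slices = []
    for t in events.df["cs_onset_s"].to_numpy(float):
        a = max(0, int(round((t + pre) * frame_rate_hz)))
        b = min(n_frames, int(round((t + post) * frame_rate_hz)))
        frame_slices.append((a, b))
    trial_slices, pos = [], 0
    for a, b in frame_slices:
        trial_slices.append(slice(pos, pos + (b - a)))
        pos += b - a
    X = np.column_stack(
        [np.concatenate([c[a:b] for a, b in frame_slices]) for c in cols]
        + [np.ones(pos)]
    )
    return DesignMatrix(
        X=X,
        columns=names + ["intercept"],
        trial_slices=trial_slices,
        frame_slices=frame_slices,
        frame_rate_hz=frame_rate_hz,
        shifts_s={n: shifts_s.get(n, 0.0) for n in names},
    )


@dataclass
class GlmFit:
    betas: dict[str, float]
    r2_full: float
    design: DesignMatrix
    y: np.ndarray
    r2_cv: float | None = None
    mse_cv: float | None = None
    contributions: dict[str, tuple[float, float]] = field(default_factory=dict)
    predictions: list[np.ndarray] | None = None

    @property
    def beta_vector(self) -> np.ndarray:
        return np.array([self.betas[c] for c in self.design.columns])


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    sst = ((y - y.mean()) ** 2).sum()
    if sst == 0:
        return 0.0
    return float(1.0 - ((y - yhat) ** 2).sum() / sst)


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    _, r = np.linalg.qr(X)
    d = np.abs(np.diag(r))
    tol = d.max() * max(X.shape) * np.finfo(float).eps
    return [names[i] for i in np.nonzero(d <= tol)[0]]


def fit_glm(design: DesignMatrix, trace: np.ndarray) -> GlmFit:
    """OLS fit of the concatenated trace on the design matrix.

    ``trace`` may be the full session trace (it is sliced to the design's
    trial windows) or already concatenated.
    """
    trace = np.asarray(trace, dtype=float)
    y = trace if trace.size == design.X.shape[0] else design.slice_trace(trace)
    if not np.isfinite(y).all():
        raise ValidationError("trace contains non-finite samples")
    X = design.X
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValidationError(
            f"design matrix is rank deficient; collinear columns: "
            f"{_collinear_columns(X, design.columns)}"
        )
    yhat = X @ beta
    return GlmFit(
        betas=dict(zip(design.columns, beta.astype(float))),
        r2_full=_r2(y, yhat),
        design=design,
        y=y,
    )


def loo_cv(design: DesignMatrix, trace: np.ndarray) -> GlmFit:
    """Fit plus leave-one-trial-out cross-validation.

    Each trial is sequentially held out, the model refit on the remaining
    trials, and the held-out trial predicted; ``r2_cv`` compares the
    concatenated predictions with the observations and ``mse_cv`` averages
    the per-fold mean squared errors.
    """
    fit = fit_glm(design, trace)
    n_trials = design.n_trials
    if n_trials < 3:
        raise ValidationError("leave-one-out CV needs at least 3 trials")
    if design.X.shape[0] * (n_trials - 1) / n_trials < design.X.shape[1]:
        log.warning("fewer samples than predictors in folds; CV unstable")
    y = fit.y
    preds, mses = [], []
    for k, sl in enumerate(design.trial_slices):
        train = np.ones(y.size, dtype=bool)
        train[sl] = False
        beta, _, _, _ = np.linalg.lstsq(design.X[train], y[train], rcond=None)
        p = design.X[sl] @ beta
        preds.append(p)
        mses.append(float(((y[sl] - p) ** 2).mean()))
    concat = np.concatenate(preds)
    fit.r2_cv = _r2(y, concat)
    fit.mse_cv = float(np.mean(mses))
    fit.predictions = preds
    return fit


def predictor_contribution(
    fit: GlmFit, predictor: str
) -> tuple[float, float]:
    """Zeroed-predictor contribution: the predictor's columns are zeroed
    without re-estimating the model and the resulting drop in R², normalized
    by the full model's R², is returned in percent together with the nested
    F statistic."""
    if predictor not in fit.design.columns:
        raise ValidationError(f"predictor {predictor!r} not in design")
    if fit.r2_full <= 0:
        raise ValidationError("full-model R² <= 0; contribution undefined")
    X = fit.design.X
    beta = fit.beta_vector
    j = fit.design.column(predictor)
    Xz = X.copy()
    Xz[:, j] = 0.0
    y = fit.y
    yhat_full = X @ beta
    yhat_zero = Xz @ beta
    # a zeroed model that predicts worse than the mean has explained none of
    # the variance, so its R2 is floored at 0 (keeps the drop within 100%)
    r2_zero = max(_r2(y, yhat_zero), 0.0)
    drop_pct = 100.0 * (fit.r2_full - r2_zero) / fit.r2_full
    sse_full = ((y - yhat_full) ** 2).sum()
    sse_zero = ((y - yhat_zero) ** 2).sum()
    n, p = X.shape
    q = 1
    f_stat = ((sse_zero - sse_full) / q) / (sse_full / (n - p))
    fit.contributions[predictor] = (float(drop_pct), float(f_stat))
    return float(drop_pct), float(f_stat)


def optimize_shifts(
    events: EventTable,
    frame_rate_hz: float,
    n_frames: int,
    trace: np.ndarray,
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS,
    max_shift_s: float = MAX_SHIFT_S,
    **design_kw,
) -> dict[str, float]:
    """Per-predictor temporal shift chosen on a frame-resolution grid.

    A single pass of coordinate ascent: predictors are visited in order and
    each one's shift (0 to ``max_shift_s``, direction fixed by its class) is
    set to the value maximizing training R² with the other shifts held
    fixed.
    """
    shifts = {p: 0.0 for p in predictors}
    grid = np.arange(0, max_shift_s + 1e-9, 1.0 / frame_rate_hz)
    for p in predictors:
        best, best_r2 = 0.0, -np.inf
        for s in grid:
            trial = dict(shifts)
            trial[p] = SHIFT_SIGN.get(p, 1) * s
            try:
                d = build_design_matrix(
                    events, frame_rate_hz, n_frames, shifts_s=trial,
                    predictors=predictors, **design_kw,
                )
                r2 = fit_glm(d, trace).r2_full
            except ValidationError:
                continue
            if r2 > best_r2:
                best, best_r2 = trial[p], r2
        shifts[p] = best
    return shifts


def derived_indices(fits: dict[str, GlmFit]):
    """Cue-outcome and action indices per unit.

    cue_outcome = β(CS-success) − β(CS-failure); action = β(anticipatory
    run) + β(run onset). Units lacking one of the betas are excluded with a
    log entry.
    """
    import pandas as pd

    rows = []
    for uid, fit in fits.items():
        b = fit.betas
        try:
            rows.append(
                {
                    "unit": uid,
                    "cue_outcome_beta": b["cs_success"] - b["cs_failure"],
                    "action_beta": b["avrun_anticipatory"] + b["avrun_onset"],
                    "anticipatory_beta": b["avrun_anticipatory"],
                    "onset_beta": b["avrun_onset"],
                }
            )
        except KeyError as e:
            log.info("unit %s excluded from indices: missing beta %s", uid, e)
    return pd.DataFrame(rows).set_index("unit")


def group_index_tests(index_values: np.ndarray) -> dict:
    """Mean ± SEM of a derived index over a group of units, with one-sample
    t and Wilcoxon signed-rank tests against zero."""
    x = np.asarray(index_values, dtype=float)
    x = x[np.isfinite(x)]
    out = {
        "n": int(x.size),
        "mean": float(x.mean()),
        "sem": float(stats.sem(x)) if x.size > 1 else np.nan,
    }
    if x.size > 1:
        out["t_p"] = float(stats.ttest_1samp(x, 0.0).pvalue)
        out["wilcoxon_p"] = (
            float(stats.wilcoxon(x).pvalue) if np.any(x != 0) else 1.0
        )
    else:
        out["t_p"] = out["wilcoxon_p"] = np.nan
    return out
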