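"""Trace, photometry and behavior preprocessing.

Raw fluorescence is neuropil-corrected, converted to ΔF/F against a sliding
low-percentile baseline, concatenated across trials and z-scored over the
whole session. Photometry is corrected with the 405-nm isosbestic channel.
Behavior tracks yield smoothed speed, avoidance-run onsets, freezing and
flight calls. Event-aligned slicing produces :class:`~avoidpop.core.TrialTensor`
objects for all downstream statistics.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .core import (
    BehaviorTrack,
    SessionBundle,
    TrialTensor,
    ValidationError,
)

log = logging.getLogger(__name__)

#: success trials with avoidance latency below this are excluded so that
#: CS-evoked and run-evoked signals stay distinguishable
FAST_AVOID_EXCLUDE_S = 4.0

AVRUN_SPEED_CMS = 5.0
FREEZE_SPEED_CMS = 0.25
FREEZE_MIN_S = 0.5
FLIGHT_SPEED_CMS = 50.0
SPEED_SMOOTH_FRAMES = 15  # 0.5 s at 30 Hz


def neuropil_correct(F: np.ndarray, F_neu: np.ndarray, r: float = 0.7) -> np.ndarray:
    """Subtract the scaled neuropil signal: ``F - r * F_neu``."""
    F = np.asarray(F, dtype=float)
    F_neu = np.asarray(F_neu, dtype=float)
    if F.shape != F_neu.shape:
        raise ValidationError(f"F shape {F.shape} != F_neuropil shape {F_neu.shape}")
    if not 0.0 <= r <= 1.0:
        raise ValidationError("neuropil factor r must lie in [0, 1]")
    return F - r * F_neu


def sliding_dff(
    trace: np.ndarray,
    frame_rate_hz: float,
    window_s: float = 25.0,
    pct: float = 10.0,
) -> np.ndarray:
    """ΔF/F against a sliding-percentile baseline.

    The baseline F0(t) is the ``pct``-th percentile (linear interpolation
    between order statistics) of the trace inside a window of ``window_s``
    seconds centered on each frame and truncated at the recording edges.
    """
    trace = np.asarray(trace, dtype=float)
    n = trace.size
    if n < 2:
        raise ValidationError("trace too short for a sliding baseline")
    w = min(int(round(window_s * frame_rate_hz)), n)
    if w < 1:
        raise ValidationError("window shorter than one frame")
    half = w // 2
    f0 = np.empty(n)
    # interior frames share a full-width window; vectorize them
    starts = np.arange(n) - half
    ends = starts + w
    interior = (starts >= 0) & (ends <= n)
    if interior.any():
        from numpy.lib.stride_tricks import sliding_window_view

        views = sliding_window_view(trace, w)
        f0[interior] = np.percentile(views, pct, axis=1)[starts[interior]]
    for i in np.nonzero(~interior)[0]:
        f0[i] = np.percentile(trace[max(0, starts[i]) : min(n, ends[i])], pct)
    bad = np.nonzero(f0 <= 0)[0]
    if bad.size:
        raise ValidationError(
            f"nonpositive sliding baseline first at frame {bad[0]} "
            "(ΔF/F needs a strictly positive F0)"
        )
    return (trace - f0) / f0


def normalize_session(
    dff_per_trial: list[np.ndarray] | np.ndarray,
    dropped_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Concatenate trial traces, interpolate dropped frames, z-score.

    z-scoring runs over the entire session-length trace so that a unit on the
    output is one session standard deviation.
    """
    if isinstance(dff_per_trial, np.ndarray) and dff_per_trial.ndim == 1:
        x = dff_per_trial.astype(float).copy()
    else:
        x = np.concatenate([np.asarray(t, dtype=float) for t in dff_per_trial])
    if dropped_mask is not None:
        mask = np.asarray(dropped_mask, dtype=bool)
        if mask.shape != x.shape:
            raise ValidationError("dropped mask length must match concatenated trace")
        if mask.all():
            raise ValidationError("cannot interpolate: every frame is masked")
        idx = np.arange(x.size)
        x[mask] = np.interp(idx[mask], idx[~mask], x[~mask])
    if x.size < 2 or not np.isfinite(x).all():
        raise ValidationError("need at least 2 finite samples to z-score")
    sd = x.std()
    if sd == 0:
        raise ValidationError("zero-variance trace cannot be z-scored")
    return (x - x.mean()) / sd


def zscore_session(session: SessionBundle, neuropil_r: float = 0.7) -> np.ndarray:
    """Full trace pipeline for one session: neuropil correction, sliding
    ΔF/F, dropped-frame interpolation and session-length z-scoring.

    Returns a neurons x frames matrix in z-units.
    """
    F = session.traces
    if session.neuropil is not None:
        F = neuropil_correct(F, session.neuropil, neuropil_r)
    out = np.empty_like(F)
    for i in range(F.shape[0]):
        dff = sliding_dff(F[i], session.frame_rate_hz)
        out[i] = normalize_session(dff, session.dropped_frame_mask)
    return out


def isosbestic_correct(sig465: np.ndarray, sig405: np.ndarray) -> np.ndarray:
    """Remove motion/bleaching artifacts using the 405-nm reference.

    The 405 channel is fit to the 465 channel with an affine least-squares
    model; the fit is subtracted from the 465 signal and the residual divided
    by the fit, returning ΔF/F in percent.
    """
    s465 = np.asarray(sig465, dtype=float)
    s405 = np.asarray(sig405, dtype=float)
    if s465.shape != s405.shape:
        raise ValidationError("channel lengths differ")
    if np.ptp(s405) == 0:
        raise ValidationError("405-nm channel is constant; affine fit is degenerate")
    slope, intercept = np.polyfit(s405, s465, 1)
    fit = slope * s405 + intercept
    if (fit <= 0).any():
        raise ValidationError("fitted 405 baseline crosses zero; cannot form ΔF/F")
    return 100.0 * (s465 - fit) / fit


def smooth_detrend(sig: np.ndarray, frame_rate_hz: float, smooth_s: float = 0.1) -> np.ndarray:
    """Gaussian smoothing (default 100 ms SD) then linear detrend, applied to
    each photometry channel before the isosbestic regression. The channel
    mean is retained so the subsequent ΔF/F denominator stays positive."""
    sig = np.asarray(sig, dtype=float)
    out = gaussian_filter1d(sig, smooth_s * frame_rate_hz)
    t = np.arange(out.size)
    slope, intercept = np.polyfit(t, out, 1)
    return out - (slope * t + intercept) + out.mean()


def speed_trace(track: BehaviorTrack) -> np.ndarray:
    """Smoothed speed (cm/s) from the tracked body point.

    Velocity is the Gaussian-filtered central-difference derivative of the
    trajectory over a 15-frame (0.5 s at 30 Hz) support.
    """
    if track.n_frames < SPEED_SMOOTH_FRAMES + 1:
        raise ValidationError(
            f"behavior track needs more than {SPEED_SMOOTH_FRAMES} frames"
        )
    # sigma chosen so the +-3 sigma support spans ~15 frames
    sigma = SPEED_SMOOTH_FRAMES / 6.0
    vx = np.gradient(track.xy[:, 0]) * track.frame_rate_hz
    vy = np.gradient(track.xy[:, 1]) * track.frame_rate_hz
    speed = np.hypot(vx, vy)
    return gaussian_filter1d(speed, sigma)


def _bouts(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open [start, end) frame intervals."""
    edges = np.diff(mask.astype(int))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    ends = list(np.nonzero(edges == -1)[0] + 1)
    if mask.size and mask[0]:
        starts.insert(0, 0)
    if mask.size and mask[-1]:
        ends.append(mask.size)
    return list(zip(starts, ends))


def kinematics(
    track: BehaviorTrack,
    cs_windows_s: list[tuple[float, float]] | None = None,
) -> dict:
    """Speed and behavioral event calls from one track.

    Returns a dict with ``speed`` (cm/s per frame), ``freezing_bouts``
    (list of half-open frame intervals with speed < 0.25 cm/s lasting
    >= 0.5 s), ``flight_frames`` (speed > 50 cm/s), and, when CS windows are
    given, ``avrun_onsets_s``: per window, the first time speed reaches
    5 cm/s, or NaN when it never does.
    """
    speed = speed_trace(track)
    fps = track.frame_rate_hz
    min_frames = int(round(FREEZE_MIN_S * fps))
    freezing = [
        (a, b) for a, b in _bouts(speed < FREEZE_SPEED_CMS) if b - a >= min_frames
    ]
    flight = np.nonzero(speed > FLIGHT_SPEED_CMS)[0]
    out = {"speed": speed, "freezing_bouts": freezing, "flight_frames": flight}
    if cs_windows_s is not None:
        onsets = []
        for start_s, end_s in cs_windows_s:
            a = int(np.ceil(start_s * fps))
            # one frame of slack: a run terminating the CS can quantize to
            # the frame just past the offset
            b = min(int(np.floor(end_s * fps)) + 2, speed.size)
            seg = speed[a:b]
            hits = np.nonzero(seg >= AVRUN_SPEED_CMS)[0]
            onsets.append((a + hits[0]) / fps if hits.size else np.nan)
        out["avrun_onsets_s"] = np.asarray(onsets)
    return out


def build_trial_tensor(
    session: SessionBundle,
    traces_z: np.ndarray,
    align_event: str = "cs_onset",
    window_s: tuple[float, float] = (-2.0, 3.0),
    exclude_fast_avoid_s: float = FAST_AVOID_EXCLUDE_S,
) -> TrialTensor:
    """Slice the z-scored session trace around each trial's alignment event.

    Success trials with avoidance latency shorter than ``exclude_fast_avoid_s``
    are dropped, as are trials whose event is missing (e.g. aligning to the
    avoidance run on failure trials) or whose window falls outside the
    recording.
    """
    col = {
        "cs_onset": "cs_onset_s",
        "avrun_onset": "avrun_onset_s",
        "shock_onset": "shock_onset_s",
    }.get(align_event)
    if col is None:
        raise ValidationError(f"unknown alignment event {align_event!r}")
    ev = session.events.df
    times = ev[col].to_numpy(dtype=float)
    outcomes = ev["outcome"].to_numpy()
    latency = ev["avrun_onset_s"].to_numpy(dtype=float) - ev["cs_onset_s"].to_numpy(
        dtype=float
    )

    rate = session.frame_rate_hz
    pre, post = window_s
    width = int(round((post - pre) * rate))
    keep, frames = [], []
    for i, t in enumerate(times):
        if not np.isfinite(t):
            continue
        if (
            outcomes[i] == "success"
            and np.isfinite(latency[i])
            and latency[i] < exclude_fast_avoid_s
        ):
            continue
        f = int(round(t * rate))
        a = f + int(round(pre * rate))
        if a < 0 or a + width > session.n_frames:
            log.info(
                "trial %d dropped: window outside recording (%s)", i, align_event
            )
            continue
        keep.append(i)
        frames.append(f)
    if not keep:
        raise ValidationError(f"no trials survive alignment to {align_event}")
    frames = np.asarray(frames)
    offs = int(round(pre * rate)) + np.arange(width)
    data = traces_z[:, frames[:, None] + offs[None, :]]
    return TrialTensor(
        data=data,
        align_event=align_event,
        window_s=window_s,
        outcome=outcomes[keep],
        frame_rate_hz=rate,
        event_frames=frames,
        trial_index=ev["trial_index"].to_numpy()[keep],
    )
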