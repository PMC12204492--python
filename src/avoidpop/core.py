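"""Shared data containers for avoidance-population analysis.

Conventions used throughout the package:

* timestamps are seconds from session start;
* frame indices are 0-based;
* time windows are half-open ``[start, end)`` and expressed relative to an
  alignment event, so a window of ``(-2, 3)`` covers 2 s before to 3 s after.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SUBTYPES = ("Glp1r", "Chat", "Lhx2", "Met", "Tshz2", "Foxp2", "Calcr", "none")

#: maximum conditioned-stimulus duration: an avoidance run within 10 s
#: terminates the tone, so success trials can never exceed it.
CS_MAX_S = 10.0

EVENT_COLUMNS = (
    "trial_index",
    "cs_onset_s",
    "cs_offset_s",
    "outcome",
    "shock_onset_s",
    "avrun_onset_s",
)


class ValidationError(ValueError):
    """A container violated one of its structural invariants."""


class FormatError(ValueError):
    """An on-disk bundle is missing a required part."""


@dataclass
class EventTable:
    """Per-trial task events for a signaled active-avoidance session.

    One row per trial with the conditioned-stimulus (CS) onset/offset, the
    trial outcome (``success`` when the animal shuttled during the CS,
    ``failure`` otherwise), the shock onset on failure trials and the
    avoidance-run onset on success trials.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.df).copy()
        for col in EVENT_COLUMNS:
            if col not in df.columns:
                if col in ("shock_onset_s", "avrun_onset_s"):
                    df[col] = np.nan
                else:
                    raise FormatError(f"event table lacks required column {col!r}")
        self.df = df.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        df = self.df
        if not df["outcome"].isin(["success", "failure"]).all():
            bad = sorted(set(df["outcome"]) - {"success", "failure"})
            raise ValidationError(f"unknown outcome labels {bad}")
        if not (df["cs_offset_s"] > df["cs_onset_s"]).all():
            raise ValidationError("cs_offset_s must exceed cs_onset_s on every trial")
        fail = df["outcome"] == "failure"
        if fail.any() and df.loc[fail, "shock_onset_s"].isna().any():
            raise ValidationError("failure trials must carry shock_onset_s")
        succ = df["outcome"] == "success"
        dur = df.loc[succ, "cs_offset_s"] - df.loc[succ, "cs_onset_s"]
        if (dur > CS_MAX_S + 1e-9).any():
            raise ValidationError(
                f"success trials must terminate the CS within {CS_MAX_S} s"
            )

    @property
    def n_trials(self) -> int:
        return len(self.df)

    @property
    def outcomes(self) -> np.ndarray:
        return self.df["outcome"].to_numpy()

    def times(self, column: str) -> np.ndarray:
        return self.df[column].to_numpy(dtype=float)


@dataclass
class BehaviorTrack:
    """Tracked body-point trajectory in real-world centimetres."""

    xy: np.ndarray  # frames x 2, cm
    frame_rate_hz: float = 30.0
    bodypoint: str = "center"

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValidationError("behavior xy must be a frames x 2 array")
        if not np.isfinite(self.xy).all():
            raise ValidationError("behavior coordinates must be finite")
        if self.frame_rate_hz <= 0:
            raise ValidationError("behavior frame rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.xy.shape[0]


@dataclass
class NeuronRecord:
    """Anatomical location, molecular subtype and accumulated statistics."""

    neuron_id: str
    ap_mm: float = np.nan
    ml_mm: float = np.nan
    dv_mm: float = np.nan
    subtype: str = "none"
    stats: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.subtype not in SUBTYPES:
            raise ValidationError(
                f"subtype {self.subtype!r} not in controlled vocabulary {SUBTYPES}"
            )


@dataclass
class SessionBundle:
    """One animal-session: traces, events, behavior and neuron metadata."""

    traces: np.ndarray  # neurons x frames, arbitrary fluorescence units
    frame_rate_hz: float
    events: EventTable
    neuropil: np.ndarray | None = None
    behavior: BehaviorTrack | None = None
    neurons: list[NeuronRecord] = field(default_factory=list)
    animal_id: str = "animal0"
    session_id: str = "session0"
    dropped_frame_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        if self.traces.ndim != 2:
            raise ValidationError("traces must be a neurons x frames matrix")
        if self.frame_rate_hz <= 0:
            raise ValidationError("frame_rate_hz must be positive")
        if self.neuropil is not None:
            self.neuropil = np.asarray(self.neuropil, dtype=float)
            if self.neuropil.shape != self.traces.shape:
                raise ValidationError(
                    "neuropil shape "
                    f"{self.neuropil.shape} != traces shape {self.traces.shape}"
                )
        if self.dropped_frame_mask is not None:
            self.dropped_frame_mask = np.asarray(self.dropped_frame_mask, dtype=bool)
            if self.dropped_frame_mask.shape != (self.n_frames,):
                raise ValidationError("dropped_frame_mask length must equal frames")
        if not self.neurons:
            self.neurons = [NeuronRecord(f"n{i:04d}") for i in range(self.n_neurons)]
        if len(self.neurons) != self.n_neurons:
            raise ValidationError(
                f"{len(self.neurons)} neuron records for {self.n_neurons} trace rows"
            )
        dur = self.duration_s
        for col in ("cs_onset_s", "cs_offset_s", "shock_onset_s", "avrun_onset_s"):
            t = self.events.times(col)
            t = t[np.isfinite(t)]
            if t.size and ((t < 0).any() or (t > dur + 1e-9).any()):
                raise ValidationError(
                    f"event column {col!r} has timestamps outside [0, {dur:.3f}] s"
                )

    @property
    def n_neurons(self) -> int:
        return self.traces.shape[0]

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz


@dataclass
class TrialTensor:
    """Event-aligned trial data: neurons x trials x timepoints, z-units.

    ``event_frames`` keeps the session frame index of the alignment event for
    every retained trial so that surrogate tensors can be re-sliced from a
    circularly shifted session trace.
    """

    data: np.ndarray  # neurons x trials x timepoints
    align_event: str  # cs_onset | avrun_onset | shock_onset
    window_s: tuple[float, float]
    outcome: np.ndarray  # per-trial {success, failure}
    frame_rate_hz: float
    event_frames: np.ndarray | None = None
    trial_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.outcome = np.asarray(self.outcome)
        if self.data.ndim != 3:
            raise ValidationError("tensor data must be neurons x trials x time")
        pre, post = self.window_s
        expected = int(round((post - pre) * self.frame_rate_hz))
        if self.data.shape[2] != expected:
            raise ValidationError(
                f"tensor has {self.data.shape[2]} timepoints, window implies {expected}"
            )
        if len(self.outcome) != self.n_trials:
            raise ValidationError("outcome vector length must equal trials")

    @property
    def n_neurons(self) -> int:
        return self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Timepoint centres in seconds relative to the alignment event."""
        pre, _ = self.window_s
        return pre + np.arange(self.n_timepoints) / self.frame_rate_hz

    def select(self, outcome: str) -> "TrialTensor":
        """Subset to trials with the given outcome label."""
        keep = self.outcome == outcome
        return TrialTensor(
            data=self.data[:, keep, :],
            align_event=self.align_event,
            window_s=self.window_s,
            outcome=self.outcome[keep],
            frame_rate_hz=self.frame_rate_hz,
            event_frames=None if self.event_frames is None else self.event_frames[keep],
            trial_index=None if self.trial_index is None else self.trial_index[keep],
        )

    def window_slice(self, window_s: tuple[float, float]) -> np.ndarray:
        """Integer timepoint indices covering a sub-window [start, end)."""
        pre, _ = self.window_s
        a = int(round((window_s[0] - pre) * self.frame_rate_hz))
        b = int(round((window_s[1] - pre) * self.frame_rate_hz))
        if a < 0 or b > self.n_timepoints or a >= b:
            raise ValidationError(
                f"sub-window {window_s} outside tensor window {self.window_s}"
            )
        return np.arange(a, b)


@dataclass
class PhotometryRecording:
    """Two-channel bulk fluorescence from one fiber: 465 nm signal, 405 nm
    isosbestic reference, plus the session's event table."""

    sig465: np.ndarray
    sig405: np.ndarray
    frame_rate_hz: float
    events: EventTable
    region: str = "unknown"
    animal_id: str = "animal0"

    def __post_init__(self) -> None:
        self.sig465 = np.asarray(self.sig465, dtype=float)
        self.sig405 = np.asarray(self.sig405, dtype=float)
        if self.sig465.shape != self.sig405.shape or self.sig465.ndim != 1:
            raise ValidationError("photometry channels must be equal-length vectors")


@dataclass
class InputCountMatrix:
    """Presynaptic input counts: subjects x brain regions, with a molecular
    subtype label per subject (starter-population identity)."""

    counts: pd.DataFrame  # index: subject ids, columns: region names
    subtype: pd.Series  # index: subject ids

    def __post_init__(self) -> None:
        self.counts = pd.DataFrame(self.counts)
        self.subtype = pd.Series(self.subtype).reindex(self.counts.index)
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("input counts must be nonnegative")
        if self.subtype.isna().any():
            raise ValidationError("every subject needs a subtype label")

    @property
    def regions(self) -> list[str]:
        return list(self.counts.columns)
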