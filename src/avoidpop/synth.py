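"""Synthetic session, photometry and input-count generators.

The generator emulates a two-way signaled active-avoidance experiment: each
trial is a 10-s tone (CS) preceded by a random 25-40 s inter-trial interval;
on success trials the animal shuttles 4-10 s after CS onset (terminating the
tone), on failure trials a foot-shock arrives at CS+10 s and the animal
escapes within 2 s. Neurons are drawn from a dictionary of response motifs
(CS-activated with an outcome bias, CS-suppressed, pre-run ramping,
run-onset, shock-responsive, ...) whose event-locked responses are
indicator-kernel convolved impulse trains; traces add white noise and a slow
random-walk baseline and are mapped to raw fluorescence units. Anatomical
coordinates cluster per motif, photometry signals are weighted event
mixtures sharing a motion artifact with the 405-nm channel, and rabies
input-count matrices follow subject-level Dirichlet-multinomial sampling
around subtype-specific region profiles.

All planted quantities are returned in a :class:`GroundTruth` record for
recovery tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (
    BehaviorTrack,
    EventTable,
    InputCountMatrix,
    NeuronRecord,
    PhotometryRecording,
    SessionBundle,
    ValidationError,
)
from .glm import ANTICIPATORY_LEAD_S, gcamp_kernel

EVENT_TYPES = (
    "cs_success",
    "cs_failure",
    "shock",
    "avrun_onset",
    "avrun_anticipatory",
    "safe_entry",
)

#: fluorescence model: F = F0_UNITS * (1 + GAIN * s), with s the signal in
#: z-like units; keeps the sliding-percentile baseline strictly positive
F0_UNITS = 100.0
GAIN = 0.05

BEHAVIOR_FPS = 30.0
RUN_BASE_SPEED = 0.5  # cm/s between runs
RUN_PEAK_SPEED = 40.0  # cm/s during a shuttle run
RUN_ACCEL = 45.0  # cm/s^2; linear speed ramp so smoothing keeps the
#                   5 cm/s crossing exactly at the planted onset

DEFAULT_REGIONS = (
    "CA1", "CA2", "CA3", "ProS", "SuM", "VMH", "LPO",
    "LHA", "PH", "VMPO", "TU", "PeF", "MPO", "AHN",
)


@dataclass
class MotifSpec:
    """One planted response motif: event amplitudes (z-units), temporal
    persistence, and a Gaussian anatomical locus."""

    name: str
    event_weights: dict[str, float]
    persistence: str = "transient"  # transient | sustained
    sign: str = "+"
    spatial_center: tuple[float, float, float] = (0.5, 0.4, 3.0)  # AP, ML, DV mm
    spatial_sd: float = 0.12

    def __post_init__(self) -> None:
        bad = set(self.event_weights) - set(EVENT_TYPES)
        if bad:
            raise ValidationError(f"unknown event types in motif weights: {bad}")
        if not all(np.isfinite(v) for v in self.event_weights.values()):
            raise ValidationError("motif amplitudes must be finite")
        if self.spatial_sd <= 0:
            raise ValidationError("spatial_sd must be positive")
        if self.persistence not in ("transient", "sustained"):
            raise ValidationError("persistence must be transient or sustained")

    def amplitude(self, event: str) -> float:
        return float(self.event_weights.get(event, 0.0))


def default_motifs() -> tuple[list[MotifSpec], np.ndarray]:
    """Ten-motif dictionary covering the response phenomenology seen in
    functional clusters of this task, with mixing proportions matching
    realistic cluster sizes."""
    m = [
        MotifSpec("cs_sustained_success", {"cs_success": 2.2, "cs_failure": 0.7},
                  "sustained", "+", (0.85, 0.35, 2.6)),
        MotifSpec("cs_sustained_failure", {"cs_success": 0.7, "cs_failure": 2.2},
                  "sustained", "+", (0.70, 0.50, 2.9)),
        MotifSpec("cs_transient", {"cs_success": 1.8, "cs_failure": 1.8},
                  "transient", "+", (0.55, 0.30, 3.1)),
        MotifSpec("cs_suppressed", {"cs_success": -1.5, "cs_failure": -1.5},
                  "sustained", "-", (0.40, 0.45, 2.7)),
        MotifSpec("unmodulated", {},
                  "transient", "+", (0.50, 0.40, 3.0), 0.35),
        MotifSpec("shock_responsive", {"shock": 3.0},
                  "transient", "+", (0.25, 0.35, 3.3)),
        MotifSpec("pre_run_ramp", {"avrun_anticipatory": 2.0},
                  "transient", "+", (0.95, 0.40, 2.8)),
        MotifSpec("run_onset", {"avrun_onset": 2.0},
                  "transient", "+", (0.15, 0.50, 3.5)),
        MotifSpec("safe_entry", {"safe_entry": 1.8},
                  "transient", "+", (0.30, 0.25, 2.5)),
        MotifSpec("cs_and_run", {"cs_success": 1.2, "avrun_onset": 1.5},
                  "sustained", "+", (0.65, 0.55, 3.4)),
    ]
    counts = np.array([181, 106, 82, 81, 429, 246, 83, 150, 151, 145], float)
    return m, counts / counts.sum()


@dataclass
class SimConfig:
    """Study-condition parameters for synthetic sessions."""

    n_neurons: int = 40
    n_trials: int = 30
    n_sessions: int = 1
    frame_rate_hz: float = 5.0
    p_success: float = 0.5
    iti_range_s: tuple[float, float] = (25.0, 40.0)
    cs_max_s: float = 10.0
    noise_sd: float = 1.0  # z-units per frame
    baseline_drift_sd: float = 0.01  # random-walk step per frame, z-units
    motifs: list[MotifSpec] | None = None
    mixing: np.ndarray | None = None
    seed: int = 0
    pad_s: float = 20.0  # quiet time before the first ITI and after the last trial
    behavior_noise_cm: float = 0.02

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_success <= 1.0:
            raise ValidationError("p_success must be a probability")
        if min(self.n_neurons, self.n_trials, self.n_sessions) < 1:
            raise ValidationError("n_neurons, n_trials, n_sessions must be >= 1")
        if self.motifs is None:
            self.motifs, self.mixing = default_motifs()
        if self.mixing is None:
            self.mixing = np.full(len(self.motifs), 1.0 / len(self.motifs))
        self.mixing = np.asarray(self.mixing, dtype=float)
        if len(self.mixing) != len(self.motifs):
            raise ValidationError("mixing proportions must match motif count")
        if abs(self.mixing.sum() - 1.0) > 1e-9:
            raise ValidationError("mixing proportions must sum to 1")


@dataclass
class GroundTruth:
    """Planted parameters for recovery tests.

    Avoidance latencies are a modeling choice (uniform on [4, 10) s for
    success trials); the task only fixes the 10-s ceiling and the downstream
    <4 s exclusion rule.
    """

    motif_names: np.ndarray  # per neuron
    amplitudes: pd.DataFrame  # neurons x event types, z-units
    outcomes: np.ndarray  # per trial
    avrun_latency_s: np.ndarray  # per trial; NaN on failures
    signal: np.ndarray  # neurons x frames, noiseless z-scale signal s
    event_trains: dict[str, np.ndarray]  # kernel-convolved regressors


def _simulate_trials(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the trial timeline: ITIs, outcomes, latencies, shocks."""
    outcomes = np.where(
        rng.random(cfg.n_trials) < cfg.p_success, "success", "failure"
    )
    if cfg.p_success in (0.0, 1.0):
        warnings.warn(
            "p_success of 0 or 1 yields single-class sessions; outcome "
            "decoders will fail on these data",
            stacklevel=3,
        )
    rows, t = [], cfg.pad_s
    for i, outc in enumerate(outcomes):
        t += rng.uniform(*cfg.iti_range_s)
        onset = t
        if outc == "success":
            lat = rng.uniform(4.0, cfg.cs_max_s)
            rows.append(
                dict(
                    trial_index=i,
                    cs_onset_s=onset,
                    cs_offset_s=onset + lat,
                    outcome=outc,
                    shock_onset_s=np.nan,
                    avrun_onset_s=onset + lat,
                )
            )
            t = onset + lat + 3.0  # short post-run dwell in the safe chamber
        else:
            esc = rng.uniform(0.5, 2.0)
            rows.append(
                dict(
                    trial_index=i,
                    cs_onset_s=onset,
                    cs_offset_s=onset + cfg.cs_max_s,
                    outcome=outc,
                    shock_onset_s=onset + cfg.cs_max_s,
                    avrun_onset_s=np.nan,
                )
            )
            t = onset + cfg.cs_max_s + esc + 3.0
    return pd.DataFrame(rows)


def _event_times(df: pd.DataFrame) -> dict[str, np.ndarray]:
    succ = df["outcome"] == "success"
    fail = ~succ
    av = df.loc[succ, "avrun_onset_s"].to_numpy(float)
    return {
        "cs_success": df.loc[succ, "cs_onset_s"].to_numpy(float),
        "cs_failure": df.loc[fail, "cs_onset_s"].to_numpy(float),
        "shock": df.loc[fail, "shock_onset_s"].to_numpy(float),
        "avrun_onset": av,
        "avrun_anticipatory": av - ANTICIPATORY_LEAD_S,
        "safe_entry": av + 1.5,  # shuttle run lasts about 1.5 s
    }


def _convolved_trains(
    df: pd.DataFrame, n_frames: int, rate: float, persistence: str
) -> dict[str, np.ndarray]:
    """Kernel-convolved regressor per event type.

    Transient events are onset impulses. Sustained responses to the CS are
    boxcars over the tone (normalized so the plateau is 1); non-CS events
    stay transient regardless of persistence.
    """
    kern = gcamp_kernel(rate)
    out = {}
    times = _event_times(df)
    for ev, t in times.items():
        t = t[np.isfinite(t)]
        train = np.zeros(n_frames)
        if persistence == "sustained" and ev in ("cs_success", "cs_failure"):
            sub = df[df["outcome"] == ("success" if ev == "cs_success" else "failure")]
            for on, off in zip(sub["cs_onset_s"], sub["cs_offset_s"]):
                a, b = int(round(on * rate)), int(round(off * rate))
                train[a : min(b, n_frames)] = 1.0
            conv = np.convolve(train, kern)[:n_frames] / kern.sum()
        else:
            idx = np.round(t * rate).astype(int)
            idx = idx[(idx >= 0) & (idx < n_frames)]
            np.add.at(train, idx, 1.0)
            conv = np.convolve(train, kern)[:n_frames]
        out[ev] = conv
    return out


def _behavior_track(
    cfg: SimConfig, df: pd.DataFrame, duration_s: float, rng: np.random.Generator
) -> BehaviorTrack:
    """Speed profile with linear run ramps crossing 5 cm/s exactly at the
    planted run onsets, integrated into an alternating shuttle trajectory."""
    fps = BEHAVIOR_FPS
    n = int(np.ceil(duration_s * fps))
    t = np.arange(n) / fps
    speed = np.full(n, RUN_BASE_SPEED)
    run_times = []
    av = df["avrun_onset_s"].to_numpy(float)
    shocks = df["shock_onset_s"].to_numpy(float)
    run_times.extend(av[np.isfinite(av)])
    run_times.extend(shocks[np.isfinite(shocks)] + 0.3)  # escape run after shock
    from .preprocess import AVRUN_SPEED_CMS

    lead = (AVRUN_SPEED_CMS - RUN_BASE_SPEED) / RUN_ACCEL
    ramp = (RUN_PEAK_SPEED - RUN_BASE_SPEED) / RUN_ACCEL
    for t0 in run_times:
        start = t0 - lead
        up = (t >= start) & (t < start + ramp)
        speed[up] = RUN_BASE_SPEED + RUN_ACCEL * (t[up] - start)
        hold = (t >= start + ramp) & (t < start + ramp + 0.7)
        speed[hold] = RUN_PEAK_SPEED
        down = (t >= start + ramp + 0.7) & (t < start + 2 * ramp + 0.7)
        speed[down] = RUN_PEAK_SPEED - RUN_ACCEL * (t[down] - (start + ramp + 0.7))
    # alternate shuttle direction on successive runs
    direction = np.ones(n)
    for k, t0 in enumerate(sorted(run_times)):
        if k % 2 == 0:
            direction[t >= t0] = -1 if k % 4 == 0 else 1
    x = np.cumsum(speed * direction) / fps
    y = np.zeros(n)
    xy = np.column_stack([x, y])
    if cfg.behavior_noise_cm > 0:
        xy = xy + rng.normal(0, cfg.behavior_noise_cm, xy.shape)
    return BehaviorTrack(xy=xy, frame_rate_hz=fps)


def generate_session(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[SessionBundle, GroundTruth]:
    """One synthetic animal-session with planted ground truth."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    df = _simulate_trials(cfg, rng)
    duration = float(df["cs_offset_s"].max()) + cfg.pad_s
    rate = cfg.frame_rate_hz
    n_frames = int(np.ceil(duration * rate))

    trains = {
        pers: _convolved_trains(df, n_frames, rate, pers)
        for pers in ("transient", "sustained")
    }
    motif_idx = rng.choice(len(cfg.motifs), size=cfg.n_neurons, p=cfg.mixing)
    amp = np.zeros((cfg.n_neurons, len(EVENT_TYPES)))
    signal = np.zeros((cfg.n_neurons, n_frames))
    neurons = []
    for i, mi in enumerate(motif_idx):
        motif = cfg.motifs[mi]
        for j, ev in enumerate(EVENT_TYPES):
            a = motif.amplitude(ev)
            amp[i, j] = a
            if a != 0.0:
                signal[i] += a * trains[motif.persistence][ev]
        ap, ml, dv = rng.normal(motif.spatial_center, motif.spatial_sd)
        neurons.append(
            NeuronRecord(neuron_id=f"n{i:04d}", ap_mm=ap, ml_mm=ml, dv_mm=dv)
        )

    s = signal.copy()
    if cfg.noise_sd > 0:
        s = s + rng.normal(0, cfg.noise_sd, s.shape)
    if cfg.baseline_drift_sd > 0:
        s = s + np.cumsum(
            rng.normal(0, cfg.baseline_drift_sd, s.shape), axis=1
        )
    traces = F0_UNITS * (1.0 + GAIN * s)

    behavior = _behavior_track(cfg, df, duration, rng)
    events = EventTable(df)
    bundle = SessionBundle(
        traces=traces,
        frame_rate_hz=rate,
        events=events,
        behavior=behavior,
        neurons=neurons,
        animal_id=f"sim{cfg.seed}",
        session_id="s0",
    )
    lat = np.where(
        df["outcome"] == "success",
        (df["avrun_onset_s"] - df["cs_onset_s"]).to_numpy(float),
        np.nan,
    )
    truth = GroundTruth(
        motif_names=np.array([cfg.motifs[m].name for m in motif_idx]),
        amplitudes=pd.DataFrame(
            amp, columns=list(EVENT_TYPES),
            index=[n.neuron_id for n in neurons],
        ),
        outcomes=df["outcome"].to_numpy(),
        avrun_latency_s=lat.astype(float),
        signal=signal,
        event_trains=trains["transient"],
    )
    return bundle, truth


def dff_from_raw(traces: np.ndarray) -> np.ndarray:
    """Invert the generator's fluorescence map, returning the signal scale
    (z-like units) in which planted amplitudes are expressed."""
    return (np.asarray(traces, float) / F0_UNITS - 1.0) / GAIN


def generate_cohort(
    cfg: SimConfig, n_sessions: int | None = None
) -> list[tuple[SessionBundle, GroundTruth]]:
    """Independent sessions sharing the motif dictionary; per-session RNG
    streams are spawned deterministically from the config seed."""
    n = cfg.n_sessions if n_sessions is None else n_sessions
    seqs = np.random.SeedSequence(cfg.seed).spawn(n)
    out = []
    for k, sq in enumerate(seqs):
        bundle, truth = generate_session(cfg, np.random.default_rng(sq))
        bundle.session_id = f"s{k}"
        out.append((bundle, truth))
    return out


def generate_photometry(
    cfg: SimConfig,
    region_weights: dict[str, float],
    region: str = "unknown",
    artifact_sd: float = 0.5,
    artifact_gain_405: float = 0.8,
    channel_noise_sd: float = 0.05,
    rng: np.random.Generator | None = None,
) -> tuple[PhotometryRecording, GroundTruth]:
    """Bulk two-channel recording: the 465-nm channel carries the
    kernel-convolved event mixture plus a shared low-frequency motion
    artifact; the 405-nm channel carries only the (gain-scaled) artifact, so
    isosbestic regression is testable."""
    from scipy.ndimage import gaussian_filter1d

    if not all(np.isfinite(v) for v in region_weights.values()):
        raise ValidationError("region weights must be finite")
    bad = set(region_weights) - set(EVENT_TYPES)
    if bad:
        raise ValidationError(f"unknown event types in region weights: {bad}")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    cfg30 = replace(cfg, frame_rate_hz=BEHAVIOR_FPS)
    df = _simulate_trials(cfg30, rng)
    duration = float(df["cs_offset_s"].max()) + cfg.pad_s
    n = int(np.ceil(duration * BEHAVIOR_FPS))
    trains = _convolved_trains(df, n, BEHAVIOR_FPS, "transient")
    sig = np.zeros(n)
    for ev, w in region_weights.items():
        sig += w * trains[ev]
    artifact = np.zeros(n)
    if artifact_sd > 0:
        artifact = gaussian_filter1d(rng.normal(0, 1, n), 0.5 * BEHAVIOR_FPS)
        artifact *= artifact_sd / max(artifact.std(), 1e-12)
    s465 = F0_UNITS * (
        1 + GAIN * (sig + artifact + rng.normal(0, channel_noise_sd, n))
    )
    s405 = F0_UNITS * (
        1
        + GAIN
        * (artifact_gain_405 * artifact + rng.normal(0, channel_noise_sd, n))
    )
    rec = PhotometryRecording(
        sig465=s465,
        sig405=s405,
        frame_rate_hz=BEHAVIOR_FPS,
        events=EventTable(df),
        region=region,
        animal_id=f"sim{cfg.seed}",
    )
    amp = pd.DataFrame(
        [[region_weights.get(e, 0.0) for e in EVENT_TYPES]],
        columns=list(EVENT_TYPES),
        index=["bulk"],
    )
    truth = GroundTruth(
        motif_names=np.array(["bulk"]),
        amplitudes=amp,
        outcomes=df["outcome"].to_numpy(),
        avrun_latency_s=np.where(
            df["outcome"] == "success",
            (df["avrun_onset_s"] - df["cs_onset_s"]).to_numpy(float),
            np.nan,
        ),
        signal=sig[None, :],
        event_trains=trains,
    )
    return rec, truth


def generate_input_counts(
    n_subjects_per_subtype: int,
    region_profiles: dict[str, np.ndarray],
    concentration: float = 50.0,
    total_cells: int = 5000,
    regions: tuple[str, ...] = DEFAULT_REGIONS,
    seed: int | np.random.Generator | None = 0,
) -> InputCountMatrix:
    """Subjects x regions presynaptic count matrix.

    Per subject, region proportions are Dirichlet(concentration x profile)
    draws around the subject's subtype profile and counts are multinomial
    with ``total_cells`` trials. An infinite concentration is the
    deterministic limit: proportions equal the profile and counts are its
    rounded multiples.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n_regions = len(regions)
    for st, prof in region_profiles.items():
        if len(np.asarray(prof)) != n_regions:
            raise ValidationError(
                f"profile for {st!r} has {len(np.asarray(prof))} entries, "
                f"expected {n_regions} regions"
            )
    if concentration <= 0:
        raise ValidationError("concentration must be positive")
    rows, subs, ids = [], [], []
    for st, prof in region_profiles.items():
        prof = np.asarray(prof, dtype=float)
        prof = prof / prof.sum()
        for k in range(n_subjects_per_subtype):
            if np.isinf(concentration):
                counts = np.round(total_cells * prof).astype(int)
            else:
                p = rng.dirichlet(concentration * prof)
                counts = rng.multinomial(total_cells, p)
            rows.append(counts)
            subs.append(st)
            ids.append(f"{st}_{k}")
    counts = pd.DataFrame(rows, index=ids, columns=list(regions))
    return InputCountMatrix(counts=counts, subtype=pd.Series(subs, index=ids))
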