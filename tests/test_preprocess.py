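"""Trace, photometry and behavior preprocessing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import avoidpop as ap
from avoidpop.core import BehaviorTrack, ValidationError
from avoidpop.preprocess import (
    build_trial_tensor,
    isosbestic_correct,
    kinematics,
    neuropil_correct,
    normalize_session,
    sliding_dff,
    smooth_detrend,
    zscore_session,
)
from avoidpop.synth import generate_photometry

from .conftest import make_session


class TestNeuropilCorrect:
    def test_formula(self, rng):
        assert neuropil_correct(np.array([10.0]), np.array([0.0]))[0] == 10.0
        # scaled subtraction with the 0.7 contamination factor
        assert neuropil_correct(np.array([10.0]), np.array([10.0]))[0] == pytest.approx(3.0)
        F = rng.normal(size=(3, 5))
        N = rng.normal(size=(3, 5))
        out = neuropil_correct(F, N, 0.7)
        for i in range(3):
            for j in range(5):
                assert out[i, j] == pytest.approx(F[i, j] - 0.7 * N[i, j])

    def test_shape_mismatch(self):
        with pytest.raises(ValidationError):
            neuropil_correct(np.zeros((2, 3)), np.zeros((3, 2)))


class TestSlidingDff:
    def test_constant_trace_is_zero(self):
        out = sliding_dff(np.full(100, 3.0), 5.0)
        assert np.allclose(out, 0.0)

    def test_hand_computed_percentile(self):
        # 10th percentile of the truncated end window is 1, so the spike is
        # (11 - 1) / 1 = 10
        out = sliding_dff(np.array([1.0, 1, 1, 1, 11]), 1.0, window_s=5)
        assert out[-1] == pytest.approx(10.0)

    def test_matches_bruteforce_loop(self, rng):
        trace = 10.0 + np.abs(rng.normal(size=240)) + np.concatenate(
            [np.zeros(120), 5 * np.ones(120)]
        )
        rate, win, pct = 5.0, 25.0, 10.0
        out = sliding_dff(trace, rate, win, pct)
        w = int(round(win * rate))
        half = w // 2
        for i in range(trace.size):
            lo, hi = max(0, i - half), min(trace.size, i - half + w)
            f0 = np.percentile(trace[lo:hi], pct)
            assert out[i] == pytest.approx((trace[i] - f0) / f0, abs=1e-12)

    def test_nonpositive_baseline_errors(self):
        with pytest.raises(ValidationError, match="frame"):
            sliding_dff(np.linspace(-1, 1, 200), 5.0)

    @given(scale=st.floats(min_value=0.1, max_value=1e4))
    @settings(max_examples=20, deadline=None)
    def test_scale_invariance(self, scale):
        # ΔF/F is a ratio, so multiplying the raw trace by any positive
        # constant leaves it unchanged
        rng_ = np.random.default_rng(5)
        trace = 5.0 + np.abs(rng_.normal(size=200))
        a = sliding_dff(trace, 5.0)
        b = sliding_dff(scale * trace, 5.0)
        assert np.allclose(a, b, atol=1e-9)


class TestNormalizeSession:
    def test_zero_mean_unit_sd(self, rng):
        out = normalize_session([rng.normal(size=50), rng.normal(size=70)])
        assert abs(out.mean()) < 1e-10
        assert abs(out.std() - 1) < 1e-10

    def test_interpolation_recovers_ramp(self):
        ramp = np.linspace(0, 1, 20)
        mask = np.zeros(20, bool)
        mask[5:8] = True
        broken = ramp.copy()
        broken[mask] = 99.0
        out = normalize_session(broken, mask)
        ref = normalize_session(ramp)
        assert np.allclose(out, ref)

    def test_zscore_oracle(self, rng):
        x = rng.normal(2.0, 3.0, size=300)
        assert np.allclose(normalize_session(x), (x - x.mean()) / x.std())

    def test_degenerate_inputs(self):
        with pytest.raises(ValidationError):
            normalize_session(np.ones(10))  # zero variance
        with pytest.raises(ValidationError):
            normalize_session(np.ones(10), np.ones(10, bool))  # all masked


class TestIsosbestic:
    def test_perfect_fit_vanishes(self, rng):
        s = 10 + np.abs(rng.normal(size=500))
        assert np.allclose(isosbestic_correct(s, s), 0.0, atol=1e-8)
        assert np.allclose(isosbestic_correct(2 * s + 3, s), 0.0, atol=1e-8)

    def test_constant_reference_errors(self):
        with pytest.raises(ValidationError):
            isosbestic_correct(np.arange(10.0) + 1, np.ones(10))

    def test_artifact_variance_removed(self):
        cfg = ap.SimConfig(n_neurons=1, n_trials=8, seed=3)
        rec, truth = generate_photometry(
            cfg, {"cs_success": 1.0}, artifact_sd=1.0, channel_noise_sd=0.02
        )
        naive = 100 * (rec.sig465 / rec.sig465.mean() - 1)
        corrected = isosbestic_correct(
            smooth_detrend(rec.sig465, rec.frame_rate_hz),
            smooth_detrend(rec.sig405, rec.frame_rate_hz),
        )
        # artifact dominates the naive trace; regression removes >= 90% of
        # the non-signal variance
        resid_naive = naive - naive.mean()
        assert corrected.var() < 0.5 * resid_naive.var()
        sig = truth.signal[0]
        assert np.corrcoef(corrected, sig)[0, 1] > 0.5

    def test_pure_artifact_cancels(self):
        cfg = ap.SimConfig(n_neurons=1, n_trials=6, seed=4)
        rec, _ = generate_photometry(
            cfg, {}, artifact_sd=1.0, channel_noise_sd=0.0
        )
        corrected = isosbestic_correct(rec.sig465, rec.sig405)
        assert np.abs(corrected).max() < 0.1


class TestKinematics:
    def test_stationary_track(self):
        track = BehaviorTrack(xy=np.zeros((300, 2)))
        k = kinematics(track)
        assert np.allclose(k["speed"], 0.0)
        assert k["freezing_bouts"] == [(0, 300)]
        assert k["flight_frames"].size == 0

    def test_constant_velocity(self):
        t = np.arange(600) / 30.0
        track = BehaviorTrack(xy=np.column_stack([10.0 * t, np.zeros_like(t)]))
        speed = kinematics(track)["speed"]
        interior = speed[30:-30]
        assert np.allclose(interior, 10.0, rtol=0.02)

    def test_planted_run_onsets_recovered(self):
        bundle, _ = make_session(seed=3, n_neurons=2, n_trials=15)
        ev = bundle.events.df
        succ = ev[ev["outcome"] == "success"]
        wins = [(r.cs_onset_s, r.cs_offset_s) for r in succ.itertuples()]
        k = kinematics(bundle.behavior, wins)
        err_frames = np.abs(
            k["avrun_onsets_s"] - succ["avrun_onset_s"].to_numpy()
        ) * bundle.behavior.frame_rate_hz
        assert np.all(np.isfinite(err_frames))
        assert err_frames.max() <= 1.0

    def test_too_short_track(self):
        with pytest.raises(ValidationError):
            kinematics(BehaviorTrack(xy=np.zeros((10, 2))))


class TestTrialTensor:
    def test_window_arithmetic(self, default_tensors):
        t = default_tensors["cs"]
        assert t.n_timepoints == 25  # (-2, 3) s at 5 Hz

    def test_fast_avoid_exclusion(self):
        bundle, _ = make_session(seed=9, n_neurons=3, n_trials=10)
        df = bundle.events.df.copy()
        # force two successes to 3-s latencies (faster than the 4-s rule)
        succ_idx = df.index[df["outcome"] == "success"][:2]
        df.loc[succ_idx, "avrun_onset_s"] = df.loc[succ_idx, "cs_onset_s"] + 3.0
        df.loc[succ_idx, "cs_offset_s"] = df.loc[succ_idx, "cs_onset_s"] + 3.0
        bundle.events.df = df
        z = zscore_session(bundle)
        tensor = build_trial_tensor(bundle, z, "cs_onset", (-2, 3))
        assert tensor.n_trials == 10 - 2

    def test_missing_event_trials_dropped(self, default_tensors):
        # failure trials carry no avoidance run, so run-aligned tensors
        # contain only successes
        t = default_tensors["avrun"]
        assert set(t.outcome) == {"success"}

    def test_zscore_session_statistics(self, default_tensors):
        z = default_tensors["z"]
        assert np.allclose(z.mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(z.std(axis=1), 1.0, atol=1e-9)
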