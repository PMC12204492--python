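"""Indicator-kernel GLM encoding models."""

import numpy as np
import pytest

import avoidpop as ap
from avoidpop.core import EventTable, ValidationError
from avoidpop.glm import (
    build_design_matrix,
    derived_indices,
    fit_glm,
    gcamp_kernel,
    group_index_tests,
    loo_cv,
    optimize_shifts,
    predictor_contribution,
)
from avoidpop.synth import dff_from_raw

from .conftest import make_session

ALL_EVENTS = {
    "cs_success": 2.0,
    "cs_failure": 1.0,
    "shock": 1.5,
    "avrun_onset": 0.8,
    "avrun_anticipatory": 0.5,
}


def _noiseless_session(seed=5, weights=ALL_EVENTS, n_trials=12):
    motifs = [ap.MotifSpec("m", dict(weights))]
    bundle, truth = make_session(
        seed=seed, n_neurons=1, n_trials=n_trials, motifs=motifs,
        mixing=[1.0], noise_sd=0.0, baseline_drift_sd=0.0,
    )
    return bundle, truth


class TestKernel:
    def test_shape_and_landmarks(self):
        k = gcamp_kernel(20.0)
        assert k.size == 30  # 1.5 s at 20 Hz
        assert k.max() == 1.0
        assert k[3] == 1.0  # peak at the 0.15-s rise time
        # one decay constant past the peak: e^-1
        assert k[int(round(0.95 * 20))] == pytest.approx(np.exp(-1))

    def test_peak_normalized_at_coarse_rate(self):
        k = gcamp_kernel(5.0)
        assert k.max() == 1.0
        assert np.all(k >= 0)

    def test_invalid_duration(self):
        with pytest.raises(ValidationError):
            gcamp_kernel(20.0, rise_s=1.0, duration_s=0.5)


class TestDesignMatrix:
    def test_single_impulse_places_kernel(self):
        df = dict(trial_index=[0], cs_onset_s=[10.0], cs_offset_s=[16.0],
                  outcome=["success"], shock_onset_s=[np.nan],
                  avrun_onset_s=[16.0])
        ev = EventTable(__import__("pandas").DataFrame(df))
        d = build_design_matrix(ev, 5.0, 200, trial_window_s=(-2.0, 10.0))
        kernel = gcamp_kernel(5.0)
        col = d.X[:, d.column("cs_success")]
        onset_row = int(round(2.0 * 5))  # CS onset is 2 s into the window
        assert np.allclose(col[onset_row : onset_row + kernel.size], kernel)
        assert np.allclose(col[:onset_row], 0.0)

    def test_shift_delays_column(self):
        df = dict(trial_index=[0], cs_onset_s=[10.0], cs_offset_s=[16.0],
                  outcome=["success"], shock_onset_s=[np.nan],
                  avrun_onset_s=[16.0])
        ev = EventTable(__import__("pandas").DataFrame(df))
        d0 = build_design_matrix(ev, 20.0, 600, trial_window_s=(-2.0, 10.0))
        d1 = build_design_matrix(
            ev, 20.0, 600, shifts_s={"cs_success": 0.5},
            trial_window_s=(-2.0, 10.0),
        )
        a = d0.X[:, d0.column("cs_success")]
        b = d1.X[:, d1.column("cs_success")]
        assert np.allclose(b[10:], a[:-10])

    def test_overlapping_events_superpose(self):
        import pandas as pd

        df = pd.DataFrame(dict(
            trial_index=[0, 1], cs_onset_s=[10.0, 10.6],
            cs_offset_s=[16.0, 16.6], outcome=["success", "success"],
            shock_onset_s=[np.nan, np.nan], avrun_onset_s=[16.0, 16.6],
        ))
        ev = EventTable(df)
        rate, n = 20.0, 800
        kernel = gcamp_kernel(rate)
        d = build_design_matrix(ev, rate, n, trial_window_s=(-1.0, 30.0))
        # convolution linearity: session-timeline column equals the sum of
        # two kernel copies
        full = np.zeros(n)
        for t in (10.0, 10.6):
            i = int(round(t * rate))
            full[i : i + kernel.size] += kernel
        rebuilt = d.slice_trace(full)
        assert np.allclose(d.X[:, d.column("cs_success")], rebuilt)

    def test_empty_predictor_dropped(self):
        import pandas as pd

        df = pd.DataFrame(dict(
            trial_index=[0], cs_onset_s=[10.0], cs_offset_s=[16.0],
            outcome=["success"], shock_onset_s=[np.nan], avrun_onset_s=[16.0],
        ))
        d = build_design_matrix(EventTable(df), 5.0, 300)
        assert "cs_failure" not in d.columns  # no failure trials
        assert "shock" not in d.columns


class TestFitAndCv:
    def test_noiseless_recovery_exact(self):
        bundle, truth = _noiseless_session()
        s = dff_from_raw(bundle.traces)
        d = build_design_matrix(bundle.events, bundle.frame_rate_hz,
                                bundle.n_frames)
        fit = fit_glm(d, s[0])
        for name, amp in ALL_EVENTS.items():
            assert fit.betas[name] == pytest.approx(amp, abs=1e-6)
        assert fit.r2_full == pytest.approx(1.0, abs=1e-9)

    def test_residuals_orthogonal_to_design(self, rng):
        bundle, _ = make_session(seed=11, n_neurons=1, n_trials=10)
        s = dff_from_raw(bundle.traces)
        d = build_design_matrix(bundle.events, bundle.frame_rate_hz,
                                bundle.n_frames)
        fit = fit_glm(d, s[0])
        resid = fit.y - d.X @ fit.beta_vector
        assert np.abs(d.X.T @ resid).max() < 1e-6

    def test_pure_noise_betas_near_zero(self, rng):
        bundle, _ = _noiseless_session(seed=13, n_trials=30)
        d = build_design_matrix(bundle.events, bundle.frame_rate_hz,
                                bundle.n_frames)
        y = rng.normal(size=bundle.n_frames)
        fit = loo_cv(d, y)
        # beta sampling noise scales as 1/sqrt(sum k^2 x n_events)
        assert max(abs(v) for k, v in fit.betas.items()
                   if k != "intercept") < 0.5
        assert fit.r2_cv <= 0.05

    def test_loo_fold_count_and_noiseless_cv(self):
        bundle, _ = _noiseless_session()
        s = dff_from_raw(bundle.traces)
        d = build_design_matrix(bundle.events, bundle.frame_rate_hz,
                                bundle.n_frames)
        fit = loo_cv(d, s[0])
        assert len(fit.predictions) == d.n_trials == 12
        assert fit.r2_cv > 0.999


class TestContribution:
    def test_sole_predictor_is_everything(self):
        bundle, _ = _noiseless_session(weights={"cs_success": 1.5})
        s = dff_from_raw(bundle.traces)
        d = build_design_matrix(
            bundle.events, bundle.frame_rate_hz, bundle.n_frames,
            predictors=("cs_success",),
        )
        fit = fit_glm(d, s[0])
        drop, f_stat = predictor_contribution(fit, "cs_success")
        assert drop == pytest.approx(100.0, abs=1e-6)
        assert f_stat > 1e3

    def test_zero_beta_zero_drop(self):
        bundle, _ = _noiseless_session(weights={"cs_success": 1.5})
        s = dff_from_raw(bundle.traces)
        d = build_design_matrix(bundle.events, bundle.frame_rate_hz,
                                bundle.n_frames)
        fit = fit_glm(d, s[0])
        drop, _ = predictor_contribution(fit, "shock")
        assert drop == pytest.approx(0.0, abs=1e-6)

    def test_equal_orthogonal_predictors_split_evenly(self, rng):
        n = 2000
        x1 = np.zeros(n)
        x2 = np.zeros(n)
        x1[::40] = 1.0
        x2[20::40] = 1.0
        y = x1 + x2
        from avoidpop.glm import DesignMatrix, GlmFit

        d = DesignMatrix(
            X=np.column_stack([x1, x2, np.ones(n)]),
            columns=["a", "b", "intercept"],
            trial_slices=[slice(0, n)], frame_slices=[(0, n)],
            frame_rate_hz=5.0, shifts_s={},
        )
        fit = fit_glm(d, y)
        da, _ = predictor_contribution(fit, "a")
        db, _ = predictor_contribution(fit, "b")
        assert da == pytest.approx(db, rel=1e-6)
        # the shared SST denominator inflates both drops slightly above the
        # ideal 50/50 split
        assert da == pytest.approx(50.0, abs=5.0)


class TestShiftsAndIndices:
    def test_optimizer_finds_planted_lag(self):
        bundle, _ = _noiseless_session(weights={"cs_success": 2.0})
        s = dff_from_raw(bundle.traces)
        # delay the response by 0.6 s
        lag = int(round(0.6 * bundle.frame_rate_hz))
        y = np.concatenate([np.zeros(lag), s[0][:-lag]])
        shifts = optimize_shifts(
            bundle.events, bundle.frame_rate_hz, bundle.n_frames, y,
            predictors=("cs_success",),
        )
        assert shifts["cs_success"] == pytest.approx(0.6, abs=1e-9)

    def test_derived_index_arithmetic(self):
        bundle, _ = _noiseless_session()
        s = dff_from_raw(bundle.traces)
        d = build_design_matrix(bundle.events, bundle.frame_rate_hz,
                                bundle.n_frames)
        fit = fit_glm(d, s[0])
        idx = derived_indices({"u": fit})
        assert idx.loc["u", "cue_outcome_beta"] == pytest.approx(
            ALL_EVENTS["cs_success"] - ALL_EVENTS["cs_failure"], abs=1e-6
        )
        assert idx.loc["u", "action_beta"] == pytest.approx(
            ALL_EVENTS["avrun_anticipatory"] + ALL_EVENTS["avrun_onset"],
            abs=1e-6,
        )

    def test_group_tests_detect_positive_bias(self, rng):
        res = group_index_tests(rng.normal(1.0, 0.5, size=40))
        assert res["t_p"] < 1e-6
        assert res["mean"] > 0.5


class TestPhotometryVirtualNeuron:
    def test_bulk_signal_follows_single_neuron_path(self):
        cfg = ap.SimConfig(n_neurons=1, n_trials=15, seed=17)
        rec, truth = ap.generate_photometry(
            cfg, {"cs_success": 2.0, "cs_failure": 0.5},
            artifact_sd=0.0, channel_noise_sd=0.0,
        )
        # artifact-free: 465 dF/F is the planted signal up to an affine map;
        # fit the bulk trace exactly like a single neuron
        trace = (rec.sig465 / rec.sig465.mean() - 1.0) * 100
        d = build_design_matrix(rec.events, rec.frame_rate_hz,
                                rec.sig465.size)
        fit = fit_glm(d, trace)
        idx = derived_indices({"mouse0": fit})
        assert idx.loc["mouse0", "cue_outcome_beta"] > 0
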