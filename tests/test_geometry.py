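"""Population PCA, trajectory divergence and coding direction."""

import numpy as np
import pytest

from avoidpop.core import TrialTensor
from avoidpop.geometry import (
    coding_direction,
    mahalanobis,
    project_single_trials,
    residual_pcs,
    trajectory_divergence,
    trial_averaged_pca,
)


def _tensor(data, align="cs_onset", window=(-2.0, 3.0), rate=5.0,
            outcome="success"):
    data = np.asarray(data, float)
    return TrialTensor(
        data=data,
        align_event=align,
        window_s=window,
        outcome=np.array([outcome] * data.shape[1]),
        frame_rate_hz=rate,
    )


def _two_group_tensors(rng, n=20, trials=8, T=25, diverge_from=10, amp=2.0,
                       noise=0.05):
    """Anti-correlated neuron groups; conditions separate after a planted
    divergence time."""
    base = np.sin(np.linspace(0, np.pi, T))
    pattern = np.concatenate([np.ones(n // 2), -np.ones(n - n // 2)])
    bump = np.zeros(T)
    bump[diverge_from:] = amp
    ds = pattern[:, None, None] * (base + bump)[None, None, :] + rng.normal(
        0, noise, (n, trials, T)
    )
    df = pattern[:, None, None] * (base - bump)[None, None, :] + rng.normal(
        0, noise, (n, trials, T)
    )
    return _tensor(ds), _tensor(df, outcome="failure")


class TestTrialAveragedPca:
    def test_rank1_population(self, rng):
        ts, tf = _two_group_tensors(rng, noise=0.0)
        emb = trial_averaged_pca(ts, tf)
        assert emb.explained_variance_ratio[0] >= 0.95

    def test_variance_ratio_properties(self, rng):
        ds = rng.normal(size=(15, 6, 25))
        df = rng.normal(size=(15, 5, 25))
        emb = trial_averaged_pca(_tensor(ds), _tensor(df, outcome="failure"))
        evr = emb.explained_variance_ratio
        assert evr.sum() <= 1 + 1e-9
        assert np.all(np.diff(evr) <= 1e-12)
        assert np.allclose(np.linalg.norm(emb.components, axis=0), 1.0)

    def test_projecting_trial_average_recovers_scores(self, rng):
        ds = rng.normal(size=(12, 7, 25))
        ts = _tensor(ds)
        tf = _tensor(rng.normal(size=(12, 7, 25)), outcome="failure")
        emb = trial_averaged_pca(ts, tf)
        avg = _tensor(ts.data.mean(axis=1, keepdims=True))
        proj = project_single_trials(emb, avg, n_pcs=3)[0]
        centered = ts.data.mean(axis=1) - emb.row_means[:, None]
        expected = centered.T @ emb.components[:, :3]
        assert np.allclose(proj, expected, atol=1e-10)


class TestMahalanobis:
    def test_matches_direct_solve(self, rng):
        for _ in range(100):
            k = rng.integers(2, 6)
            a, b = rng.normal(size=k), rng.normal(size=k)
            A = rng.normal(size=(k, k))
            cov = A @ A.T + 0.5 * np.eye(k)
            expected = np.sqrt((a - b) @ np.linalg.inv(cov) @ (a - b))
            assert mahalanobis(a, b, cov) == pytest.approx(expected, abs=1e-8)

    def test_identity_covariance_is_euclidean(self, rng):
        a, b = rng.normal(size=4), rng.normal(size=4)
        assert mahalanobis(a, b, np.eye(4)) == pytest.approx(
            np.linalg.norm(a - b)
        )


class TestTrajectoryDivergence:
    def test_identical_conditions_flat(self, rng):
        d = rng.normal(size=(20, 8, 25))
        ts = _tensor(d)
        tf = _tensor(d.copy(), outcome="failure")
        res = trajectory_divergence(ts, tf, n_boot=10, seed=0)
        # distances are numerically ~0 everywhere; z-scoring cannot create
        # structure and nothing is flagged
        assert not res.significant.any()

    def test_planted_divergence_localized(self, rng):
        ts, tf = _two_group_tensors(rng, diverge_from=10, amp=3.0, noise=0.3)
        res = trajectory_divergence(ts, tf, n_boot=20, seed=1)
        pre = res.significant[: 8]
        post = res.significant[14:]
        assert not pre.any()
        assert post.mean() > 0.5


class TestCodingDirection:
    def test_hand_computed_direction(self):
        # 2 neurons, meanS = (1, 0), meanF = (0, 1) over the window
        T = 25
        ds = np.zeros((2, 3, T))
        df = np.zeros((2, 3, T))
        ds[0], df[1] = 1.0, 1.0
        cd = coding_direction(_tensor(ds), _tensor(df, outcome="failure"))
        assert cd.cd == pytest.approx([1 / np.sqrt(2), -1 / np.sqrt(2)])

    def test_degenerate_difference_flagged(self, rng):
        d = rng.normal(size=(10, 4, 25))
        cd = coding_direction(_tensor(d), _tensor(d.copy(), outcome="failure"))
        assert cd.is_zero
        assert np.allclose(cd.cd, 0.0)
        assert np.allclose(cd.projections_success, 0.0)

    def test_construction_property(self, rng):
        ds = rng.normal(size=(15, 6, 25))
        df = rng.normal(size=(15, 6, 25))
        ts, tf = _tensor(ds), _tensor(df, outcome="failure")
        cd = coding_direction(ts, tf)
        win = ts.window_slice(cd.window_s)
        assert np.linalg.norm(cd.cd) == pytest.approx(1.0, abs=1e-10)
        assert (
            cd.projections_success[:, win].mean()
            >= cd.projections_failure[:, win].mean()
        )

    def test_neuron_permutation_invariance(self, rng):
        ds = rng.normal(size=(12, 5, 25))
        df = rng.normal(size=(12, 5, 25))
        perm = rng.permutation(12)
        a = coding_direction(_tensor(ds), _tensor(df, outcome="failure"))
        b = coding_direction(
            _tensor(ds[perm]), _tensor(df[perm], outcome="failure")
        )
        assert np.allclose(a.projections_success, b.projections_success)


class TestResidualPcs:
    def test_orthogonality_to_cd(self, rng):
        ds = rng.normal(size=(15, 6, 25))
        df = rng.normal(size=(15, 6, 25))
        ts, tf = _tensor(ds), _tensor(df, outcome="failure")
        cd = coding_direction(ts, tf)
        rp = residual_pcs(cd, ts, tf)
        assert np.abs(rp.components.T @ cd.cd).max() < 1e-8

    def test_rank1_along_cd_leaves_nothing(self):
        T = 25
        v = np.array([3.0, -4.0]) / 5.0
        ds = np.einsum("n,t->nt", v, np.linspace(1, 2, T))[:, None, :]
        df = np.einsum("n,t->nt", -v, np.linspace(1, 2, T))[:, None, :]
        ts, tf = _tensor(ds), _tensor(df, outcome="failure")
        cd = coding_direction(ts, tf)
        rp = residual_pcs(cd, ts, tf)
        assert np.allclose(rp.projections_success, 0.0, atol=1e-8)

    def test_recovers_outcome_independent_axis(self, rng):
        # planted two-factor design: an outcome axis (condition difference)
        # plus a shared time-varying axis orthogonal to it
        n, T = 30, 25
        u = rng.normal(size=n)
        u /= np.linalg.norm(u)
        w = rng.normal(size=n)
        w -= (w @ u) * u
        w /= np.linalg.norm(w)
        time_course = np.sin(np.linspace(0, 2 * np.pi, T))
        ds = (np.outer(u, np.ones(T)) + np.outer(w, time_course))[:, None, :]
        df = (np.outer(-u, np.ones(T)) + np.outer(w, time_course))[:, None, :]
        ts, tf = _tensor(ds), _tensor(df, outcome="failure")
        cd = coding_direction(ts, tf)
        rp = residual_pcs(cd, ts, tf)
        assert abs(rp.components[:, 0] @ w) > 0.95
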