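"""Diffusional HMM: emission model, likelihood oracle, EM behavior, AIC,
and the model scan."""

import numpy as np
import pytest

import spt
from spt.hmm import (
    DiffusionModel,
    _Packed,
    aic,
    fit,
    loglik,
    model_scan,
    posterior,
    step_variance,
)
from spt.simulate import SimulationConfig, simulate_dataset
from spt.trajectory_io import Dataset

from conftest import make_cell, make_traj


def make_model(D, A, sigma=0.03, R=0.1, dt=0.005):
    A = np.asarray(A, dtype=float)
    K = len(D)
    from spt.hmm import _stationary

    return DiffusionModel(K=K, D=np.asarray(D, float), A=A, pi=_stationary(A),
                          sigma_loc=sigma, R=R, frame_interval=dt)


def enumeration_loglik(traj, model):
    """Independent oracle: exhaustive sum over all hidden state paths.

    The state of displacement i is the state at its first frame; the chain
    advances span_i frames between displacement i and i+1 (operator
    A^span_i); displacement i is an isotropic bivariate Gaussian with
    per-dimension variance v(D_k, span_i).
    """
    import itertools

    xy, frames = traj.xy, traj.frames
    d = np.diff(xy, axis=0)
    spans = np.diff(frames)
    M, K = len(d), model.K
    Apow = {int(s): np.linalg.matrix_power(model.A, int(s)) for s in set(spans)}
    total = 0.0
    for path in itertools.product(range(K), repeat=M):
        p = model.pi[path[0]]
        for i in range(M - 1):
            p *= Apow[int(spans[i])][path[i], path[i + 1]]
        for i, k in enumerate(path):
            v = step_variance(model.D[k], int(spans[i]), model.sigma_loc,
                              model.R, model.frame_interval)
            p *= np.exp(-(d[i] ** 2).sum() / (2 * v)) / (2 * np.pi * v)
        total += p
    return np.log(total)


class TestStepVariance:
    def test_pure_noise_limit(self):
        assert step_variance(0.0, 1, 0.03, 0.1, 0.005) == pytest.approx(2 * 0.03**2)

    def test_worked_example(self):
        v = step_variance(1.0, 1, 0.03, 0.1, 0.005)
        assert v == pytest.approx(2 * 1 * 0.005 * 0.8 + 2 * 0.0009, abs=1e-15)
        assert v == pytest.approx(0.0098)

    def test_ideal_brownian_limit(self):
        for n in (1, 2, 4):
            assert step_variance(2.0, n, 0.0, 0.0, 0.005) == pytest.approx(
                2 * 2.0 * n * 0.005
            )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            step_variance(1.0, 0, 0.03, 0.1, 0.005)
        with pytest.raises(ValueError):
            step_variance(1.0, 1, 0.03, 0.1, 0.0)


class TestLoglik:
    def test_single_state_closed_form(self, rng):
        """K=1: forward likelihood equals the iid Gaussian step sum."""
        xy = np.cumsum(rng.normal(0, 0.1, size=(20, 2)), axis=0)
        tr = make_traj("t0", np.arange(20), xy)
        ds = Dataset(trajectories=[tr], cells=[make_cell()])
        model = make_model([1.0], [[1.0]])
        d = np.diff(xy, axis=0)
        v = step_variance(1.0, 1, 0.03, 0.1, 0.005)
        expected = float(
            (-np.log(2 * np.pi * v) - (d**2).sum(axis=1) / (2 * v)).sum()
        )
        assert loglik(ds, model) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("K", [2, 3])
    def test_matches_exhaustive_enumeration(self, K, rng):
        """Forward algorithm equals brute-force path enumeration, including
        across detection gaps."""
        frames = np.array([0, 1, 3, 4, 5, 8, 9])
        xy = np.cumsum(rng.normal(0, 0.15, size=(len(frames), 2)), axis=0)
        tr = make_traj("t0", frames, xy)
        ds = Dataset(trajectories=[tr], cells=[make_cell()])
        rng2 = np.random.default_rng(K)
        A = rng2.dirichlet(np.ones(K) * 3, size=K)
        model = make_model(np.linspace(0.05, 2.0, K), A)
        assert loglik(ds, model) == pytest.approx(
            enumeration_loglik(tr, model), rel=1e-10
        )

    def test_duplicating_trajectories_doubles_loglik(self, small_dataset):
        model = make_model([0.05, 1.0], [[0.95, 0.05], [0.1, 0.9]])
        base = loglik(small_dataset, model)
        doubled = Dataset(
            trajectories=small_dataset.trajectories
            + [
                make_traj(f"d{t.traj_id}", t.frames, t.xy)
                for t in small_dataset.trajectories
            ],
            cells=small_dataset.cells,
        )
        assert loglik(doubled, model) == pytest.approx(2 * base, rel=1e-12)

    def test_rigid_motion_invariance(self, small_dataset):
        model = make_model([0.05, 1.0], [[0.95, 0.05], [0.1, 0.9]])
        base = loglik(small_dataset, model)
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = Dataset(
            trajectories=[
                make_traj(t.traj_id, t.frames, t.xy @ R.T + [5.0, -3.0])
                for t in small_dataset.trajectories
            ],
            cells=small_dataset.cells,
        )
        assert loglik(moved, model) == pytest.approx(base, rel=1e-12)

    def test_short_trajectory_skipped_with_warning(self, small_dataset):
        ds = Dataset(
            trajectories=small_dataset.trajectories
            + [make_traj("single", [0], [[1.0, 1.0]])],
            cells=small_dataset.cells,
        )
        model = make_model([1.0], [[1.0]])
        with pytest.warns(UserWarning, match="single"):
            ll = loglik(ds, model)
        assert ll == pytest.approx(loglik(small_dataset, model))


class TestPosterior:
    def test_marginal_consistency(self, rng):
        """Pairwise transition expectations are consistent with the node
        marginals: summed xi row/column masses equal summed gammas."""
        frames = np.array([0, 1, 2, 4, 5])
        xy = np.cumsum(rng.normal(0, 0.1, size=(5, 2)), axis=0)
        tr = make_traj("t0", frames, xy)
        ds = Dataset(trajectories=[tr], cells=[make_cell()])
        model = make_model([0.05, 1.0], [[0.9, 0.1], [0.2, 0.8]])
        post = posterior(ds, model)
        g = post.gamma["t0"][:-1]  # per-displacement gammas
        xi_total = sum(x.sum(axis=1) for x in post.xi_sum.values())
        np.testing.assert_allclose(xi_total, g[:-1].sum(axis=0), atol=1e-10)
        xi_total_in = sum(x.sum(axis=0) for x in post.xi_sum.values())
        np.testing.assert_allclose(xi_total_in, g[1:].sum(axis=0), atol=1e-10)

    def test_rows_sum_to_one(self, small_dataset):
        model = make_model([0.05, 1.0], [[0.9, 0.1], [0.2, 0.8]])
        post = posterior(small_dataset, model)
        for g in post.gamma.values():
            np.testing.assert_allclose(g.sum(axis=1), 1.0, atol=1e-10)


class TestFit:
    def test_single_state_equals_msd_estimator(self):
        cfg = SimulationConfig(K=1, D=(1.0,), rates=((0.0,),), loc_sd=0.0,
                               pulse_duration=0.0, confine=False, p_gap=0.0,
                               n_traj=300, seed=1)
        ds, _ = simulate_dataset(cfg)
        d2 = np.concatenate(
            [(np.diff(t.xy, axis=0) ** 2).sum(axis=1) for t in ds.trajectories]
        )
        msd_D = d2.mean() / (4 * cfg.frame_interval)
        m = fit(ds, 1, n_starts=2, seed=0, sigma_loc=0.0)
        assert m.D[0] == pytest.approx(msd_D, rel=1e-10)

    def test_two_state_recovery_small(self):
        cfg = SimulationConfig(seed=4, confine=False, n_traj=400)
        ds, _ = simulate_dataset(cfg)
        ds = spt.filter_trajectories(ds)
        m = fit(ds, 2, n_starts=3, seed=1, sigma_loc=0.03, tol=1e-7, max_iter=200)
        assert m.D[0] == pytest.approx(0.1, rel=0.25)
        assert m.D[1] == pytest.approx(3.0, rel=0.1)
        assert m.pi[0] == pytest.approx(0.3, abs=0.06)

    def test_model_invariants_after_fit(self):
        cfg = SimulationConfig(seed=5, confine=False, n_traj=150)
        ds, _ = simulate_dataset(cfg)
        m = fit(ds, 2, n_starts=2, seed=2, sigma_loc=0.03, max_iter=100, tol=1e-7)
        np.testing.assert_allclose(m.A.sum(axis=1), 1.0, atol=1e-10)
        np.testing.assert_allclose(m.pi @ m.A, m.pi, atol=1e-8)
        assert m.D[0] <= m.D[1]

    def test_em_monotone_likelihood(self):
        from spt.hmm import _em_single

        cfg = SimulationConfig(seed=6, confine=False, n_traj=100)
        ds, _ = simulate_dataset(cfg)
        packed = _Packed(ds)
        *_, hist = _em_single(packed, 2, np.random.default_rng(0),
                              sigma_loc=0.03, tol=1e-9, max_iter=80)
        diffs = np.diff(hist)
        assert np.all(diffs >= -1e-7 * np.abs(hist[:-1]))

    def test_em_fixed_point(self):
        """Refitting from the fitted parameters leaves them (essentially)
        unchanged: the fit is a stationary point of EM."""
        from spt.hmm import _forward_backward, _expected_transition_counts, \
            _mstep_transitions, _stationary

        cfg = SimulationConfig(seed=7, confine=False, n_traj=200)
        ds, _ = simulate_dataset(cfg)
        m = fit(ds, 2, n_starts=2, seed=3, sigma_loc=0.03, tol=1e-10, max_iter=400)
        packed = _Packed(ds)
        _, gamma, xi_sum, gamma0 = _forward_backward(
            packed, m.D, m.A, m.pi, m.sigma_loc, m.R
        )
        counts = _expected_transition_counts(m.A, xi_sum)
        A2 = _mstep_transitions(counts, gamma0.sum(axis=0), m.A)
        np.testing.assert_allclose(A2, m.A, atol=2e-5)
        np.testing.assert_allclose(_stationary(A2), m.pi, atol=2e-4)

    def test_invalid_K(self, small_dataset):
        with pytest.raises(ValueError):
            fit(small_dataset, 0)


class TestAic:
    def test_arithmetic(self):
        m = make_model([0.1, 1.0], [[0.9, 0.1], [0.2, 0.8]])
        m.logL = -1000.0
        m.n_params = 2 + 2  # sigma fixed
        assert aic(m) == pytest.approx(2008.0)

    def test_nested_difference(self):
        a = make_model([1.0], [[1.0]])
        a.logL, a.n_params = -500.0, 1
        b = make_model([0.1, 1.0], [[0.9, 0.1], [0.2, 0.8]])
        b.logL, b.n_params = -480.0, 4
        assert aic(b) - aic(a) == pytest.approx(2 * 3 - 2 * 20)

    def test_prefers_true_model_size(self):
        cfg = SimulationConfig(seed=8, confine=False, n_traj=300)
        ds, _ = simulate_dataset(cfg)
        ds = spt.filter_trajectories(ds)
        m1 = fit(ds, 1, n_starts=2, seed=0, sigma_loc=0.03)
        m2 = fit(ds, 2, n_starts=3, seed=0, sigma_loc=0.03, tol=1e-7, max_iter=200)
        assert m2.aic < m1.aic


class TestModelScan:
    def test_singleton_range(self):
        cfg = SimulationConfig(K=1, D=(1.0,), rates=((0.0,),), n_traj=60, seed=9)
        ds, _ = simulate_dataset(cfg)
        models = model_scan(ds, [1], n_starts=2, seed=0, sigma_loc=0.03)
        assert len(models) == 1 and models[0].K == 1

    def test_occupancy_weighted_mean_D_conserved(self):
        """Total diffusive mass sum(pi_k D_k) is stable across model sizes."""
        cfg = SimulationConfig(seed=10, confine=False, n_traj=300)
        ds, _ = simulate_dataset(cfg)
        ds = spt.filter_trajectories(ds)
        models = model_scan(ds, [1, 2, 3], n_starts=3, seed=0, sigma_loc=0.03,
                            tol=1e-7, max_iter=200)
        mass = [float(m.pi @ m.D) for m in models]
        assert max(mass) - min(mass) <= 0.05 * max(mass)

    def test_extra_states_split_clusters(self):
        """Fitting K above the true state count splits existing clusters
        instead of inventing occupied states at new D scales."""
        cfg = SimulationConfig(
            K=3, D=(0.05, 0.5, 3.0),
            rates=((0.0, 2.0, 1.0), (1.5, 0.0, 1.5), (1.0, 2.0, 0.0)),
            seed=11, confine=False, n_traj=400,
        )
        ds, _ = simulate_dataset(cfg)
        ds = spt.filter_trajectories(ds)
        m = fit(ds, 4, n_starts=3, seed=1, sigma_loc=0.03, tol=1e-7, max_iter=200)
        # compare on the observable scale: emission variance of each occupied
        # fitted state must sit within a factor 2 of a true state's variance
        def var(D):
            return step_variance(D, 1, 0.03, m.R, m.frame_interval)

        true_v = np.array([var(d) for d in cfg.D])
        for k in range(m.K):
            if m.pi[k] > 0.05:
                ratio = var(m.D[k]) / true_v
                assert np.any((ratio > 0.5) & (ratio < 2.0)), (m.D[k], m.pi[k])

    def test_scan_table_shape(self):
        cfg = SimulationConfig(K=1, D=(1.0,), rates=((0.0,),), n_traj=60, seed=12)
        ds, _ = simulate_dataset(cfg)
        models = model_scan(ds, [1, 2], n_starts=2, seed=0, sigma_loc=0.03,
                            max_iter=60, tol=1e-6)
        table = spt.hmm.scan_table(models)
        assert list(table["K"]) == [1, 2, 2]


def test_per_point_loc_sd_used_as_fixed_noise(rng):
    """With per-point uncertainties present, the emission noise term comes
    from them rather than from a fitted global sigma."""
    xy = np.cumsum(rng.normal(0, 0.2, size=(30, 2)), axis=0)
    tr = make_traj("t0", np.arange(30), xy, loc_sd=0.04)
    ds = Dataset(trajectories=[tr], cells=[make_cell()])
    packed = _Packed(ds)
    assert packed.has_point_sd
    model_ref = make_model([1.0], [[1.0]], sigma=0.04)
    ll_fixed = loglik(ds, model_ref)
    # same dataset without per-point sd and global sigma 0.04 must agree
    tr2 = make_traj("t0", np.arange(30), xy, loc_sd=None)
    ds2 = Dataset(trajectories=[tr2], cells=[make_cell()])
    assert loglik(ds2, model_ref) == pytest.approx(ll_fixed, rel=1e-12)
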