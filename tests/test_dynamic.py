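"""Sliding-window machinery, graphical lasso, CV penalty selection,
state clustering and matching."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

from dynconn.dynamic import (
    BrainState,
    RegularizationGrid,
    StateAssignment,
    WindowConfig,
    build_taper,
    cluster_group_states,
    cluster_subject_states,
    glasso_objective,
    graphical_lasso_fit,
    match_states,
    per_state_dc,
    precision_to_partial_corr,
    select_lambda_cv,
    select_num_states,
    subject_partial_windows,
    window_length_from_frequency,
    windowed_covariances,
)
from dynconn.errors import DegenerateInputError, InvalidArgumentError
from dynconn.static import ConnectivityMatrix, NodeTimeSeries


def _ts(data, tr=0.645):
    return NodeTimeSeries(subject_id="s", data=np.asarray(data, float), tr=tr)


class TestWindowArithmetic:
    def test_study_window_length(self):
        assert window_length_from_frequency(0.645, 0.009) == 172

    def test_round_trip_two_second_tr(self):
        assert window_length_from_frequency(2.0, 0.01) == 50

    def test_nyquist_violation(self):
        with pytest.raises(InvalidArgumentError):
            window_length_from_frequency(1.0, 1.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.integers(min_value=2, max_value=400),
        st.integers(min_value=2, max_value=400),
        st.integers(min_value=1, max_value=20),
        st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_window_count_formula(self, t, wl, stride, seed):
        if t < wl:
            return
        rng = np.random.default_rng(seed)
        ts = _ts(rng.standard_normal((3, t)))
        covs = windowed_covariances(ts, WindowConfig(window_len=wl, stride=stride))
        assert len(covs) == (t - wl) // stride + 1


class TestTaper:
    def test_delta_kernel_limit_is_uniform(self):
        taper = build_taper(WindowConfig(window_len=20, taper_sigma=1e-3))
        assert np.allclose(taper, 1 / 20, atol=1e-12)

    def test_symmetric_and_normalized(self):
        taper = build_taper(WindowConfig(window_len=31, taper_sigma=4.0))
        assert taper.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(taper, taper[::-1])

    def test_long_window_interior_flat_edges_tapered(self):
        taper = build_taper(WindowConfig(window_len=172, taper_sigma=3.0))
        assert np.allclose(taper[20:-20], taper[86], rtol=1e-9)
        assert taper[0] < 0.6 * taper[86]
        # direct convolution oracle
        half = 9  # ceil(3*sigma)
        x = np.arange(-half, half + 1)
        kernel = np.exp(-0.5 * (x / 3.0) ** 2)
        kernel /= kernel.sum()
        want = np.convolve(np.ones(172), kernel, mode="same")
        want /= want.sum()
        assert np.allclose(taper, want)


class TestWindowedCovariances:
    def test_study_window_count(self, rng):
        ts = _ts(rng.standard_normal((3, 884)))
        assert len(windowed_covariances(ts, WindowConfig(window_len=172))) == 713

    def test_single_window_boundary(self, rng):
        ts = _ts(rng.standard_normal((3, 172)))
        assert len(windowed_covariances(ts, WindowConfig(window_len=172))) == 1

    def test_too_short_reports_both_lengths(self, rng):
        ts = _ts(rng.standard_normal((3, 100)))
        with pytest.raises(InvalidArgumentError, match="100.*172"):
            windowed_covariances(ts, WindowConfig(window_len=172))

    def test_constant_node_flagged(self):
        data = np.vstack([np.ones(30), np.arange(30.0)])
        with pytest.raises(DegenerateInputError):
            windowed_covariances(_ts(data), WindowConfig(window_len=30))

    def test_matches_manual_weighted_covariance(self, rng):
        data = rng.standard_normal((4, 25))
        cfg = WindowConfig(window_len=25, taper_sigma=2.0)
        (cov,) = windowed_covariances(_ts(data), cfg)
        u = build_taper(cfg)
        xbar = (data * u).sum(axis=1)
        xc = data - xbar[:, None]
        want = (xc * u) @ xc.T
        assert np.allclose(cov.s, want)


def _lbfgs_glasso_oracle(s, lam):
    """Independent solver: split the off-diagonal into positive and
    negative parts and maximize the penalized log-likelihood with
    L-BFGS-B under nonnegativity bounds."""
    p = s.shape[0]
    iu = np.triu_indices(p, k=1)
    n_off = len(iu[0])

    def unpack(x):
        d = x[:p]
        u, v = x[p : p + n_off], x[p + n_off :]
        theta = np.zeros((p, p))
        theta[iu] = u - v
        theta += theta.T
        theta[np.diag_indices(p)] = d
        return theta

    def neg_obj(x):
        theta = unpack(x)
        sign, logdet = np.linalg.slogdet(theta)
        if sign <= 0:
            return 1e10
        return -(logdet - np.trace(s @ theta) - 2 * lam * (x[p:].sum()))

    x0 = np.concatenate([1.0 / np.diag(s), np.zeros(2 * n_off)])
    bounds = [(1e-8, None)] * p + [(0.0, None)] * (2 * n_off)
    res = minimize(neg_obj, x0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10})
    return unpack(res.x), -res.fun


class TestGraphicalLasso:
    def test_lambda_zero_is_inverse_covariance(self, rng):
        a = rng.standard_normal((4, 50))
        s = a @ a.T / 50
        est = graphical_lasso_fit(s, 0.0)
        assert np.allclose(est.theta, np.linalg.inv(s), atol=1e-6)

    def test_full_shrinkage_limit(self, rng):
        a = rng.standard_normal((4, 50))
        s = a @ a.T / 50
        est = graphical_lasso_fit(s, 100.0)
        off = est.theta - np.diag(np.diag(est.theta))
        assert np.allclose(off, 0.0, atol=1e-8)
        assert np.allclose(np.diag(est.theta), 1 / np.diag(s), atol=1e-6)

    def test_two_variable_closed_form_across_grid(self):
        s = np.array([[2.0, 0.8], [0.8, 1.5]])
        for lam in [0.05, 0.1, 0.3, 0.5, 0.79, 0.81, 1.0]:
            est = graphical_lasso_fit(s, lam)
            w12 = np.sign(s[0, 1]) * max(abs(s[0, 1]) - lam, 0.0)
            want = np.linalg.inv(np.array([[s[0, 0], w12], [w12, s[1, 1]]]))
            assert np.allclose(est.theta, want, atol=2e-4), lam

    def test_matches_independent_solver_on_3x3(self, rng):
        for _ in range(5):
            a = rng.standard_normal((3, 40))
            s = a @ a.T / 40
            for lam in (0.05, 0.2):
                est = graphical_lasso_fit(s, lam)
                _, obj_oracle = _lbfgs_glasso_oracle(s, lam)
                assert est.objective == pytest.approx(obj_oracle, abs=1e-4)

    def test_coordinate_perturbation_optimality(self, rng):
        a = rng.standard_normal((5, 60))
        s = a @ a.T / 60
        est = graphical_lasso_fit(s, 0.1)
        base = est.objective
        for i in range(5):
            for j in range(i + 1, 5):
                for d in (1e-4, -1e-4):
                    t2 = est.theta.copy()
                    t2[i, j] += d
                    t2[j, i] += d
                    assert glasso_objective(t2, s, 0.1) - base < 5e-8

    def test_objective_and_support_monotone_in_lambda(self, rng):
        for p in (2, 3):
            a = rng.standard_normal((p, 60))
            s = a @ a.T / 60
            prev_obj, prev_support = np.inf, None
            for lam in np.linspace(0.01, 1.0, 12):
                est = graphical_lasso_fit(s, lam)
                obj = glasso_objective(est.theta, s, 0.0) - lam * 0  # unpenalized part
                support = np.abs(np.triu(est.theta, 1)) > 1e-6
                assert est.objective <= prev_obj + 1e-7
                if prev_support is not None:
                    assert np.all(support <= prev_support)  # never grows
                prev_obj, prev_support = est.objective, support

    def test_negative_lambda_rejected(self):
        with pytest.raises(InvalidArgumentError):
            graphical_lasso_fit(np.eye(3), -0.1)


def _windows_from_series(data, wl):
    ts = _ts(data)
    return windowed_covariances(ts, WindowConfig(window_len=wl, stride=wl, taper_sigma=1e-3))


class TestLambdaCV:
    def test_singleton_grid(self, rng):
        covs = _windows_from_series(rng.standard_normal((3, 300)), 50)
        lam = select_lambda_cv(covs, RegularizationGrid(lambdas=[0.3], n_folds=3))
        assert lam == 0.3

    def test_support_recovery_f1(self):
        rng = np.random.default_rng(5)
        from dynconn.synthetic import generate_state_precisions

        (theta,) = generate_state_precisions(6, 1, 0.3, seed=5)
        sigma = np.linalg.inv(theta)
        chol = np.linalg.cholesky(sigma)
        data = (rng.standard_normal((5000, 6)) @ chol.T).T
        covs = _windows_from_series(data, 500)
        grid = RegularizationGrid(lambdas=list(np.geomspace(0.005, 0.5, 8)), n_folds=5)
        lam = select_lambda_cv(covs, grid)
        s_all = np.mean([c.s for c in covs], axis=0)
        est = graphical_lasso_fit(s_all, lam)
        # edges called on the partial-correlation scale: planted partials
        # are >= 0.35, so |rho| > 0.05 separates signal from solver dust
        rho = precision_to_partial_corr(est.theta).values
        true_edges = set(map(tuple, np.argwhere(np.triu(np.abs(theta) > 1e-10, 1))))
        got_edges = set(map(tuple, np.argwhere(np.triu(np.abs(rho) > 0.05, 1))))
        tp = len(true_edges & got_edges)
        f1 = 2 * tp / (len(true_edges) + len(got_edges)) if true_edges | got_edges else 1.0
        assert f1 > 0.8

    def test_dense_data_prefers_small_lambda(self):
        grid_vals = list(np.geomspace(0.02, 1.0, 6))
        median = np.median(grid_vals)
        wins = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            q = rng.standard_normal((4, 4)) * 0.4
            theta = q @ q.T + 2.0 * np.eye(4)  # dense precision
            chol = np.linalg.cholesky(np.linalg.inv(theta))
            data = (rng.standard_normal((800, 4)) @ chol.T).T
            covs = _windows_from_series(data, 100)
            lam = select_lambda_cv(covs, RegularizationGrid(lambdas=grid_vals, n_folds=4))
            wins += lam <= median
        assert wins >= 40

    def test_empty_grid_rejected(self):
        with pytest.raises(InvalidArgumentError):
            RegularizationGrid(lambdas=[])


class TestPartialCorrelation:
    def test_diagonal_precision_gives_identity(self):
        rho = precision_to_partial_corr(np.diag([2.0, 3.0, 4.0]))
        assert np.allclose(rho.values, np.eye(3))

    def test_hand_value(self):
        rho = precision_to_partial_corr(np.array([[2.0, -1.0], [-1.0, 2.0]]))
        assert rho.values[0, 1] == pytest.approx(0.5)

    def test_symmetric_unit_diagonal(self, rng):
        a = rng.standard_normal((5, 40))
        theta = np.linalg.inv(a @ a.T / 40 + 0.1 * np.eye(5))
        rho = precision_to_partial_corr(theta)
        assert np.allclose(np.diag(rho.values), 1.0)
        assert np.allclose(rho.values, rho.values.T)
        assert np.all(np.abs(rho.values) <= 1.0)

    def test_nonpositive_diagonal_rejected(self):
        with pytest.raises(InvalidArgumentError):
            precision_to_partial_corr(np.array([[1.0, 0.0], [0.0, -2.0]]))


def _blob_windows(rng, centers, n_per, p, noise=0.02):
    """Partial-correlation-like matrices clustered around given centers."""
    iu = np.triu_indices(p, k=1)
    out = []
    for c in centers:
        for _ in range(n_per):
            m = np.zeros((p, p))
            m[iu] = np.clip(c + noise * rng.standard_normal(len(iu[0])), -0.99, 0.99)
            m += m.T
            np.fill_diagonal(m, 1.0)
            out.append(ConnectivityMatrix(values=m, stage="partial"))
    return out


class TestStateClustering:
    def test_k1_mean_is_grand_mean(self, rng):
        wins = _blob_windows(rng, [rng.uniform(-0.5, 0.5, 10)], 12, 5)
        states, labels = cluster_group_states(wins, 1, seed=0)
        grand = np.mean([w.values for w in wins], axis=0)
        off = ~np.eye(5, dtype=bool)
        assert np.allclose(states[0].mean_matrix.values[off], grand[off], atol=1e-12)
        assert states[0].occupancy == 1.0

    def test_far_apart_states_recovered(self, rng):
        c1 = rng.uniform(0.2, 0.7, 10)
        c2 = -c1
        wins = _blob_windows(rng, [c1, c2], 30, 5)
        states, labels = cluster_group_states(wins, 2, seed=0)
        for c in (c1, c2):
            target = np.zeros((5, 5))
            target[np.triu_indices(5, 1)] = c
            target += target.T
            corrs = [np.corrcoef(
                s.mean_matrix.values[np.triu_indices(5, 1)], c)[0, 1] for s in states]
            assert max(corrs) > 0.95

    def test_seed_determinism(self, rng):
        wins = _blob_windows(rng, [np.zeros(10), np.full(10, 0.4)], 15, 5, noise=0.2)
        a = cluster_group_states(wins, 2, seed=7)
        b = cluster_group_states(wins, 2, seed=7)
        assert np.array_equal(a[1], b[1])

    def test_occupancy_sums_to_one_descending(self, rng):
        wins = _blob_windows(rng, [np.zeros(10), np.full(10, 0.4)], 20, 5, noise=0.1)
        states, _ = cluster_group_states(wins, 2, seed=1)
        occ = [s.occupancy for s in states]
        assert sum(occ) == pytest.approx(1.0, abs=1e-9)
        assert occ == sorted(occ, reverse=True)


class TestSelectNumStates:
    def test_well_separated_three_states(self, rng):
        centers = [np.full(15, v) for v in (-0.6, 0.0, 0.6)]
        windows = {
            f"s{i}": _blob_windows(rng, centers, 10, 6, noise=0.05) for i in range(4)
        }
        assert select_num_states(windows, range(2, 7), seed=0) == 3

    def test_empty_k_range(self, rng):
        with pytest.raises(InvalidArgumentError):
            select_num_states({"a": _blob_windows(rng, [np.zeros(3)], 8, 3)}, [])


class TestMatchStates:
    def _states(self, mats):
        return [
            BrainState(index=i, mean_matrix=m, occupancy=1.0 / len(mats))
            for i, m in enumerate(mats)
        ]

    def test_identity_mapping(self, rng):
        mats = _blob_windows(rng, [np.full(10, v) for v in (-0.5, 0.0, 0.5)], 1, 5)
        mapping = match_states(mats, np.array([0.5, 0.3, 0.2]), self._states(mats))
        assert mapping == {0: 0, 1: 1, 2: 2}

    def test_permutation_recovered(self, rng):
        mats = _blob_windows(rng, [np.full(10, v) for v in (-0.5, 0.0, 0.5)], 1, 5)
        perm = [2, 0, 1]
        subject = [mats[j] for j in perm]
        mapping = match_states(subject, np.array([0.2, 0.5, 0.3]), self._states(mats))
        assert mapping == {i: perm[i] for i in range(3)}

    def test_greedy_is_total(self, rng):
        group = _blob_windows(rng, [np.full(10, 0.5), np.full(10, -0.5)], 1, 5)
        orthogonal = _blob_windows(rng, [np.zeros(10)], 1, 5, noise=0.3)
        mapping = match_states(
            [group[0], orthogonal[0]], np.array([0.9, 0.1]), self._states(group)
        )
        assert set(mapping.keys()) == {0, 1}
        assert set(mapping.values()) == {0, 1}

    def test_too_many_subject_states_rejected(self, rng):
        mats = _blob_windows(rng, [np.zeros(10)], 3, 5, noise=0.1)
        with pytest.raises(InvalidArgumentError):
            match_states(mats, np.ones(3), self._states(mats[:2]))


class TestPerStateDC:
    def test_single_state_collapse_and_closed_form(self, rng):
        p = 4
        identity_partials = [
            ConnectivityMatrix(values=np.eye(p), stage="partial") for _ in range(6)
        ]
        assignment = StateAssignment(
            window_labels={"s0": np.zeros(6, dtype=int)},
            subject_to_group={"s0": {0: 0}},
        )
        dc = per_state_dc({"s0": identity_partials}, assignment)
        # all off-diagonal rho = 0 -> w = 0.5^6 -> DC = (p-1) * atanh(0.5^6)
        assert np.allclose(dc["s0"][0].values, (p - 1) * np.arctanh(0.5**6), atol=1e-12)

    def test_unvisited_state_absent(self, rng):
        wins = _blob_windows(rng, [np.zeros(3)], 5, 3)
        assignment = StateAssignment(
            window_labels={"s0": np.zeros(5, dtype=int)},
            subject_to_group={"s0": {0: 2, 1: 4}},  # local state 1 never used
        )
        dc = per_state_dc({"s0": wins}, assignment)
        assert 2 in dc["s0"] and 4 not in dc["s0"]
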