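"""GP surrogates, Pareto/hypervolume bookkeeping and the EHVI loop."""

import itertools

import numpy as np
import pytest
from scipy.stats import norm, qmc

from polycalib.bayesopt import (
    OptState,
    ehvi_select,
    feasibility_weight,
    gp_fit,
    gp_predict,
    hypervolume,
    hypervolume_improvement,
    optimize,
    pareto_front,
    select_best,
    sobol_points,
)


class TestSobol:
    def test_points_within_bounds(self):
        bounds = np.array([[0.0, 1.0]] * 5 + [[-2.0, 3.0]] * 5)
        pts = sobol_points(bounds, 15, seed=3)
        assert pts.shape == (15, 10)
        assert np.all(pts >= bounds[:, 0]) and np.all(pts <= bounds[:, 1])

    def test_deterministic_per_seed(self):
        bounds = np.array([[0.0, 1.0]] * 4)
        np.testing.assert_array_equal(
            sobol_points(bounds, 7, seed=11), sobol_points(bounds, 7, seed=11)
        )
        assert not np.array_equal(
            sobol_points(bounds, 7, seed=11), sobol_points(bounds, 7, seed=12)
        )

    def test_lower_discrepancy_than_uniform(self):
        bounds = np.array([[0.0, 1.0], [0.0, 1.0]])
        sob, uni = [], []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            sob.append(qmc.discrepancy(sobol_points(bounds, 256, seed=seed)))
            uni.append(qmc.discrepancy(rng.random((256, 2))))
        assert np.median(sob) < np.median(uni)


class TestGP:
    def test_three_point_posterior_matches_hand_coded_formula(self):
        X = np.array([[0.1], [0.5], [0.9]])
        y = np.array([1.0, -0.5, 0.3])
        model = gp_fit(X, y)
        xq = np.array([[0.3]])
        mean, var = gp_predict(model, xq)
        # direct 3x3 linear algebra with the fitted hyperparameters
        l, s2, n2, mu = (model.length_scale, model.signal_variance,
                         model.noise_variance, model.mean_const)
        ys = (y - model.y_loc) / model.y_scale
        K = s2 * np.exp(-((X - X.T) ** 2) / (2 * l * l)) + n2 * np.eye(3) + 1e-8 * s2 * np.eye(3)
        k = s2 * np.exp(-((X[:, 0] - xq[0, 0]) ** 2) / (2 * l * l))
        alpha = np.linalg.solve(K, ys - mu)
        m_ref = model.y_loc + model.y_scale * (mu + k @ alpha)
        v_ref = model.y_scale**2 * (s2 - k @ np.linalg.solve(K, k))
        assert mean == pytest.approx(m_ref, rel=1e-6)
        assert var == pytest.approx(v_ref, rel=1e-4, abs=1e-10)

    def test_near_interpolation_at_training_points(self):
        X = np.array([[0.2, 0.2], [0.8, 0.6]])
        y = np.array([3.0, -1.0])
        model = gp_fit(X, y)
        for xi, yi in zip(X, y):
            mean, var = gp_predict(model, xi)
            assert mean == pytest.approx(yi, abs=1e-4)
            assert var < 1e-4 * model.y_scale**2

    def test_constant_targets_predict_constant(self):
        X = np.random.default_rng(0).random((6, 3))
        model = gp_fit(X, np.full(6, 2.5))
        mean, var = gp_predict(model, np.array([0.1, 0.9, 0.4]))
        assert mean == 2.5
        assert var == 0.0

    def test_reverts_to_prior_far_from_data(self):
        X = np.random.default_rng(1).random((10, 2)) * 0.05
        y = np.sin(X[:, 0] * 20) + X[:, 1]
        model = gp_fit(X, y)
        mean, var = gp_predict(model, np.array([50.0, 50.0]))
        prior_mean = model.y_loc + model.y_scale * model.mean_const
        prior_var = model.y_scale**2 * model.signal_variance
        assert mean == pytest.approx(prior_mean, rel=0.01, abs=1e-9)
        assert var == pytest.approx(prior_var, rel=0.01)

    def test_length_scale_recovery_from_known_gp(self):
        """Samples from a GP with l* = 0.3 yield fits in [0.15, 0.6] mostly."""
        l_true = 0.3
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.random((60, 2))
            d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
            K = np.exp(-d2 / (2 * l_true**2)) + 1e-8 * np.eye(60)
            y = np.linalg.cholesky(K) @ rng.standard_normal(60)
            model = gp_fit(X, y)
            hits += 0.15 <= model.length_scale <= 0.6
        assert hits >= 8


class TestParetoAndHypervolume:
    def test_single_point_front(self):
        assert pareto_front(np.array([[1.0, 2.0]])).tolist() == [0]

    def test_simple_dominance(self):
        pts = np.array([[1.0, 2.0], [2.0, 1.0], [2.0, 2.0]])
        assert sorted(pareto_front(pts).tolist()) == [0, 1]

    def test_matches_all_pairs_dominance_oracle(self, rng):
        pts = rng.random((200, 6))
        feas = rng.random(200) > 0.3
        got = set(pareto_front(pts, feas).tolist())
        # O(n^2) oracle
        pool = [i for i in range(200) if feas[i]]
        expected = set()
        for i in pool:
            dominated = False
            for j in pool:
                if j != i and np.all(pts[j] <= pts[i]) and np.any(pts[j] < pts[i]):
                    dominated = True
                    break
            if not dominated:
                expected.add(i)
        assert got == expected

    def test_infeasible_points_never_enter_front(self, rng):
        pts = np.array([[0.0, 0.0], [1.0, 1.0]])
        feas = np.array([False, True])
        assert pareto_front(pts, feas).tolist() == [1]

    def test_hypervolume_examples(self):
        assert hypervolume(np.array([[1.0, 1.0]]), np.array([2.0, 2.0])) == 1.0
        # area((0,2)) = 3, area((2,0)) = 3, overlap = 1 -> union 5
        hv = hypervolume(np.array([[0.0, 2.0], [2.0, 0.0]]), np.array([3.0, 3.0]))
        assert hv == pytest.approx(5.0)

    def test_dominated_point_does_not_change_hypervolume(self):
        ref = np.array([3.0, 3.0])
        base = hypervolume(np.array([[0.0, 2.0], [2.0, 0.0]]), ref)
        more = hypervolume(np.array([[0.0, 2.0], [2.0, 0.0], [2.5, 2.5]]), ref)
        assert more == pytest.approx(base)

    def test_non_dominating_point_rejected(self):
        with pytest.raises(ValueError):
            hypervolume(np.array([[4.0, 1.0]]), np.array([3.0, 3.0]))

    def test_3d_sweep_matches_inclusion_exclusion_oracle(self, rng):
        pts = rng.random((200, 3))
        front = pts[pareto_front(pts)]
        sub = front[rng.choice(len(front), size=min(10, len(front)), replace=False)]
        sub = sub[pareto_front(sub)]
        ref = np.array([1.5, 1.5, 1.5])
        # inclusion-exclusion over all nonempty subsets
        expected = 0.0
        for k in range(1, len(sub) + 1):
            for combo in itertools.combinations(range(len(sub)), k):
                corner = sub[list(combo)].max(axis=0)
                expected += (-1) ** (k + 1) * np.prod(ref - corner)
        assert hypervolume(sub, ref) == pytest.approx(expected, rel=1e-9)

    def test_6d_monte_carlo_agrees_with_exact_on_product_front(self, rng):
        # a single point in 6-D has exactly known dominated volume
        p = rng.random(6) * 0.5
        ref = np.ones(6)
        vol, stderr = hypervolume(p[None, :], ref, mc_samples=200_000, seed=4)
        assert vol == pytest.approx(np.prod(ref - p), abs=4 * stderr + 1e-12)


def _toy_state(F, feasible=None, bounds_dim=2, energies=None):
    n = len(F)
    X = np.linspace(0.1, 0.9, n)[:, None] * np.ones((n, bounds_dim))
    state = OptState(
        bounds=np.array([[0.0, 1.0]] * bounds_dim),
        X=X,
        F=np.asarray(F, dtype=float),
        feasible=np.ones(n, dtype=bool) if feasible is None else np.asarray(feasible),
        energies=energies,
    )
    state.update_ref_point()
    state.refit()
    return state


class TestEHVI:
    def test_degenerate_posterior_improvement(self):
        front = np.array([[1.0, 1.0]])
        ref = np.array([2.0, 2.0])
        assert hypervolume_improvement(np.array([1.5, 1.5]), front, ref) == 0.0
        delta = hypervolume_improvement(np.array([0.5, 0.5]), front, ref)
        # new box [0.5,2]x[0.5,2] = 2.25 minus old 1.0 -> 1.25
        assert delta == pytest.approx(1.25)

    def test_matches_closed_form_expected_improvement_in_1d(self, rng):
        """Single-objective reduction: MC-EHVI equals analytic EI."""
        best, ref = 0.4, 1.0
        mu, sigma = 0.35, 0.1
        # closed-form EI for minimization with truncation at ref (> best)
        z = (best - mu) / sigma
        ei = (best - mu) * norm.cdf(z) + sigma * norm.pdf(z)
        draws = mu + sigma * rng.standard_normal(200_000)
        mc = np.maximum(best - np.maximum(draws, 0.0), 0.0)
        mc[draws < 0] = best  # improvement capped at the [0, best] box
        est, sem = mc.mean(), mc.std() / np.sqrt(len(mc))
        assert est == pytest.approx(ei, abs=3 * sem + 1e-4)

    def test_selection_is_deterministic_and_within_bounds(self):
        state = _toy_state([[0.8, 0.2], [0.2, 0.8], [0.6, 0.6]])
        a = ehvi_select(state, candidate_pool_size=32, mc_samples=8, seed=5)
        b = ehvi_select(state, candidate_pool_size=32, mc_samples=8, seed=5)
        np.testing.assert_array_equal(a, b)
        assert np.all(a >= 0.0) and np.all(a <= 1.0)


class TestFeasibilityWeight:
    def test_point_mass_orderings(self):
        # correct order gamma <= alpha <= beta with tiny posterior variance
        energies = np.array([
            [-282.80, -282.03, -282.85],
            [-282.81, -282.05, -282.86],
            [-282.79, -282.02, -282.84],
            [-282.80, -282.04, -282.85],
        ])
        F = np.abs(np.random.default_rng(0).random((4, 2))) + 0.1
        state = _toy_state(F, energies=energies)
        w = feasibility_weight(state, state.X[0], seed=1)
        assert w == pytest.approx(1.0, abs=0.02)
        flipped = energies[:, ::-1]  # now gamma is least stable
        state2 = _toy_state(F, energies=np.ascontiguousarray(flipped))
        w2 = feasibility_weight(state2, state2.X[0], seed=1)
        assert w2 == pytest.approx(0.0, abs=0.02)

    def test_exchangeable_posteriors_give_one_sixth(self, rng):
        # identical training data for the three energies makes their
        # posteriors exchangeable; the ordering probability is then exactly
        # the 1/6 of three i.i.d. continuous variables
        X = rng.random((12, 2)) * 0.3
        col = rng.standard_normal(12)
        energies = np.tile(col[:, None], (1, 3))
        state = OptState(
            bounds=np.array([[0.0, 1.0]] * 2), X=X,
            F=np.abs(rng.random((12, 2))) + 0.1,
            feasible=np.ones(12, dtype=bool), energies=energies,
        )
        state.update_ref_point()
        state.refit()
        # query far from the data so the (equal) posterior variances are > 0
        ws = [
            feasibility_weight(state, np.array([0.95, 0.95]),
                               mc_samples=4096, seed=s)
            for s in range(8)
        ]
        assert np.mean(ws) == pytest.approx(1 / 6, abs=0.05)


class TestOptimizeLoop:
    @staticmethod
    def _quadratic_eval(x):
        """Two smooth objectives minimized at different corners."""
        from polycalib.objectives import ObjectiveVector

        x = np.asarray(x)
        f1 = float(((x - 0.2) ** 2).sum())
        f2 = float(((x - 0.8) ** 2).sum())
        v = np.array([f1, f2, 0.0, 0.0, 0.0, 0.0])
        return ObjectiveVector(values=v[:2].repeat(1), feasible=True)

    def test_zero_iterations_returns_initial_design_only(self):
        bounds = np.array([[0.0, 1.0]] * 3)
        state = optimize(self._quadratic_eval, bounds, n_init=9, max_iter=0, seed=2)
        assert len(state.X) == 9

    def test_identical_seeds_reproduce_evaluation_sequence(self):
        bounds = np.array([[0.0, 1.0]] * 3)
        s1 = optimize(self._quadratic_eval, bounds, n_init=6, max_iter=4, seed=9)
        s2 = optimize(self._quadratic_eval, bounds, n_init=6, max_iter=4, seed=9)
        np.testing.assert_array_equal(s1.X, s2.X)

    def test_hypervolume_non_decreasing(self):
        bounds = np.array([[0.0, 1.0]] * 2)
        state = optimize(self._quadratic_eval, bounds, n_init=8, max_iter=8, seed=3)
        ref = state.ref_point
        hv = []
        for n in range(1, len(state.X) + 1):
            sub = state.F[:n]
            front = sub[pareto_front(sub)]
            front = front[np.all(front < ref, axis=1)]
            hv.append(hypervolume(front, ref) if len(front) else 0.0)
        assert np.all(np.diff(hv) >= -1e-12)

    def test_two_objective_toy_reaches_dense_scan_hypervolume(self):
        """BO front hypervolume ~ matches a dense Sobol scan reference."""
        bounds = np.array([[0.0, 1.0]] * 4)
        dense = sobol_points(bounds, 4096, seed=99)
        dense_f = np.array([self._quadratic_eval(x).values for x in dense])
        passes = 0
        for seed in range(5):
            state = optimize(
                self._quadratic_eval, bounds, n_init=10, max_iter=25, seed=seed
            )
            ref = np.maximum(dense_f.max(axis=0), state.F.max(axis=0)) * 1.1
            hv_dense = hypervolume(dense_f[pareto_front(dense_f)], ref)
            front = state.F[state.pareto]
            hv_bo = hypervolume(front, ref)
            passes += hv_bo >= 0.95 * hv_dense
        assert passes >= 4

    def test_select_best_prefers_feasible_minimax(self):
        state = _toy_state(
            [[0.9, 0.1], [0.3, 0.4], [0.05, 0.05]],
            feasible=[True, True, False],
        )
        assert select_best(state) == 1
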