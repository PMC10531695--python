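"""GS model fitters: worked fixtures, limits, dualities and invariances."""

import numpy as np
import pytest

from gsnue import models as M
from gsnue.kinship import build_gaussian_kernel, build_grm


@pytest.fixture()
def tiny_rr():
    X = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 1.0]])
    y = np.array([1.0, 0.0, -1.0])
    return X, y


class TestVarianceComponents:
    def test_h2_formula(self):
        vc = M.VarianceComponents(sigma2_a=2.0, sigma2_e=2.0)
        assert vc.h2 == 0.5
        assert M.snp_heritability(M.VarianceComponents(3.0, 0.0)) == 1.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            M.VarianceComponents(-1.0, 1.0)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            M.VarianceComponents(0.0, 0.0).h2


class TestREML:
    def test_noise_free_boundary(self, rng):
        X = rng.binomial(2, 0.4, size=(300, 400)).astype(float)
        effects = rng.normal(size=400) * 0.1
        y = (X - X.mean(axis=0)) @ effects
        G = build_grm(X)
        vc = M.estimate_variance_components(y, G)
        assert vc.h2 >= 0.95

    def test_single_seed_recovery(self):
        from gsnue.simulate import PopulationConfig, simulate_genotypes, simulate_phenotypes

        cfg = PopulationConfig(n_genotypes=350, n_markers=800, h2_low_n=0.6,
                               missing_rate=0.0, seed=21)
        G = simulate_genotypes(cfg)
        pheno, _ = simulate_phenotypes(G, cfg)
        vc = M.estimate_variance_components(
            pheno.trait("LN", G.genotype_ids), build_grm(G.dosage)
        )
        assert abs(vc.h2 - 0.6) < 0.15

    def test_identity_kinship_warns(self, rng):
        y = rng.normal(size=50)
        with pytest.warns(M.IdentifiabilityWarning):
            M.estimate_variance_components(y, np.eye(50))

    def test_zero_variance_phenotype_raises(self):
        with pytest.raises(ValueError):
            M.estimate_variance_components(np.ones(10), np.eye(10))

    def test_matches_direct_likelihood_optimizer(self, rng):
        """Independent oracle: generic 2-D REML optimization over both
        variances must agree with the spectral profile search."""
        from scipy.optimize import minimize

        n = 40
        A = rng.normal(size=(n, 10))
        K = A @ A.T / 10 + 0.5 * np.eye(n)
        L = np.linalg.cholesky(K)
        y = 2.0 + L @ rng.normal(size=n) * 1.3 + rng.normal(size=n) * 0.9
        ones = np.ones((n, 1))

        def neg_reml(params):
            s2a, s2e = np.exp(params)
            V = K * s2a + np.eye(n) * s2e
            Vi = np.linalg.inv(V)
            XtViX = (ones.T @ Vi @ ones).item()
            beta = (ones.T @ Vi @ y).item() / XtViX
            r = y - beta
            _, ld = np.linalg.slogdet(V)
            return 0.5 * (ld + np.log(XtViX) + (r @ Vi @ r).item())

        best = min(
            (minimize(neg_reml, x0, method="Nelder-Mead") for x0 in
             ([0.0, 0.0], [1.0, -1.0], [-1.0, 1.0])),
            key=lambda rr: rr.fun,
        )
        s2a_ref, s2e_ref = np.exp(best.x)
        vc = M.estimate_variance_components(y, K)
        assert vc.h2 == pytest.approx(s2a_ref / (s2a_ref + s2e_ref), abs=0.02)


class TestRRBLUP:
    def test_worked_fixture(self, tiny_rr):
        X, y = tiny_rr
        fit = M.fit_rrblup(y, X, lambda_=1.0, fit_intercept=False)
        np.testing.assert_allclose(fit.marker_effects, [0.625, -0.125], atol=1e-10)
        np.testing.assert_allclose(fit.gebv, [0.625, -0.125, -0.75], atol=1e-10)

    def test_infinite_penalty_shrinks_to_zero(self, tiny_rr):
        X, y = tiny_rr
        fit = M.fit_rrblup(y, X, lambda_=1e8)
        assert np.abs(fit.marker_effects).max() <= 1e-6

    def test_interpolation_limit(self, rng):
        X = rng.normal(size=(5, 5)) + np.eye(5) * 3
        y = rng.normal(size=5)
        fit = M.fit_rrblup(y, X, lambda_=1e-10)
        np.testing.assert_allclose(
            fit.gebv - fit.gebv.mean(), y - y.mean(), atol=1e-6
        )

    def test_dual_path_matches_explicit_mme_solve(self, rng):
        """m > n dual route vs a dense solve of the full MME (oracle)."""
        n, m, lam = 15, 40, 3.7
        X = rng.normal(size=(n, m))
        y = rng.normal(size=n)
        fit = M.fit_rrblup(y, X, lambda_=lam)  # dual path (m > n)
        A = np.zeros((m + 1, m + 1))
        A[0, 0] = n
        A[0, 1:] = A[1:, 0] = X.sum(axis=0)
        A[1:, 1:] = X.T @ X + lam * np.eye(m)
        sol = np.linalg.solve(A, np.concatenate(([y.sum()], X.T @ y)))
        assert fit.intercept == pytest.approx(sol[0], abs=1e-8)
        np.testing.assert_allclose(fit.marker_effects, sol[1:], atol=1e-8)

    def test_row_permutation_invariance(self, rng):
        X = rng.normal(size=(20, 30))
        y = rng.normal(size=20)
        perm = rng.permutation(20)
        a = M.fit_rrblup(y, X, lambda_=2.0)
        b = M.fit_rrblup(y[perm], X[perm], lambda_=2.0)
        np.testing.assert_allclose(b.gebv, a.gebv[perm], atol=1e-8)

    def test_shrinkage_monotone_in_lambda(self, rng):
        X = rng.normal(size=(25, 40))
        y = rng.normal(size=25)
        norms = [
            np.linalg.norm(M.fit_rrblup(y, X, lambda_=lam).marker_effects)
            for lam in (0.1, 1.0, 10.0, 100.0)
        ]
        assert all(a >= b for a, b in zip(norms, norms[1:]))


class TestGBLUP:
    def test_duality_with_rrblup(self, rng):
        n, m = 50, 200
        X = rng.normal(size=(n, m))
        X = X - X.mean(axis=0)  # GRM centers columns; match it exactly
        y = X @ rng.normal(size=m) * 0.1 + rng.normal(size=n)
        G = build_grm(X)
        c = G.parameters["denominator"]
        lam_marker = 5.0
        rr = M.fit_rrblup(y, X, lambda_=lam_marker)
        gb = M.fit_gblup(y, G, lambda_=lam_marker / c)
        np.testing.assert_allclose(gb.gebv, rr.gebv, atol=1e-8)

    def test_null_genetic_variance_collapses_to_mean(self, rng):
        y = rng.normal(size=12)
        G = build_grm(rng.integers(0, 3, size=(12, 40)).astype(float))
        fit = M.fit_gblup(y, G, lambda_=np.inf)
        np.testing.assert_allclose(fit.gebv, 0.0, atol=1e-12)
        assert fit.intercept == pytest.approx(y.mean())

    def test_duplicate_individuals_share_gebv(self, rng):
        X = rng.integers(0, 3, size=(10, 60)).astype(float)
        X[3] = X[0]
        y = rng.normal(size=10)
        y[3] = y[0]
        fit = M.fit_gblup(y, build_grm(X), lambda_=1.0)
        assert fit.gebv[3] == pytest.approx(fit.gebv[0], abs=1e-8)

    def test_non_psd_raises(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        with pytest.raises(ValueError, match="positive semidefinite"):
            M.fit_gblup(np.array([1.0, -1.0]), bad)


class TestLASSO:
    def test_null_model_threshold(self, rng):
        X = rng.normal(size=(30, 10))
        y = rng.normal(size=30)
        lam_max = np.abs(X.T @ (y - y.mean())).max() / 30
        fit = M.fit_lasso(y, X, lambda_=lam_max * 1.01)
        assert np.all(fit.marker_effects == 0.0)

    def test_soft_threshold_closed_form(self):
        # single standardized predictor, x'y/n = 0.5, lambda = 0.2 -> 0.3
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = 0.5 * x + np.array([1.0, 1.0, -1.0, -1.0]) * 0.7
        fit = M.fit_lasso(y, x[:, None], lambda_=0.2)
        assert fit.marker_effects[0] == pytest.approx(0.3, abs=1e-8)

    def test_unpenalized_limit_equals_ols(self, rng):
        X = rng.normal(size=(40, 5))
        y = rng.normal(size=40)
        fit = M.fit_lasso(y, X, lambda_=1e-10)
        ols = np.linalg.lstsq(
            np.column_stack([np.ones(40), X]), y, rcond=None
        )[0]
        np.testing.assert_allclose(fit.marker_effects, ols[1:], atol=1e-6)

    def test_shrinkage_monotone(self, rng):
        X = rng.normal(size=(30, 20))
        y = rng.normal(size=30)
        norms = [
            np.abs(M.fit_lasso(y, X, lambda_=lam).marker_effects).sum()
            for lam in (0.01, 0.05, 0.2, 1.0)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))


class TestBayesianRidge:
    def test_same_seed_identical_chains(self, rng):
        X = rng.normal(size=(40, 30))
        y = rng.normal(size=40)
        a = M.fit_bayesian_ridge(y, X, n_iter=300, burn_in=100, seed=7)
        b = M.fit_bayesian_ridge(y, X, n_iter=300, burn_in=100, seed=7)
        np.testing.assert_array_equal(a.gebv, b.gebv)

    def test_null_data_shrinks_effects(self, rng):
        X = rng.normal(size=(200, 500))
        y = rng.normal(size=200)
        fit = M.fit_bayesian_ridge(y, X, n_iter=600, burn_in=200, seed=3)
        # no signal: posterior-mean effects hover near zero
        assert np.abs(fit.marker_effects).mean() < 3 * y.std() / np.sqrt(200)

    def test_fixed_variance_conjugacy_small(self, rng):
        n, p = 50, 8
        X = rng.normal(size=(n, p))
        y = X @ rng.normal(size=p) + rng.normal(size=n)
        s2a, s2e = 0.5, 1.0
        fit = M.fit_bayesian_ridge(
            y, X, n_iter=6000, burn_in=1000, seed=5, fixed_variances=(s2a, s2e)
        )
        ridge = np.linalg.solve(X.T @ X + (s2e / s2a) * np.eye(p), X.T @ y)
        np.testing.assert_allclose(fit.marker_effects, ridge, atol=0.05)

    def test_sign_probabilities_reported(self, rng):
        X = rng.normal(size=(30, 20))
        y = rng.normal(size=30)
        fit = M.fit_bayesian_ridge(y, X, n_iter=300, burn_in=100, seed=1)
        sp = fit.training_meta["sign_prob"]
        assert sp.shape == (20,) and ((sp >= 0) & (sp <= 1)).all()


class TestRKHS:
    def test_identity_kernel_decouples(self, rng):
        y = rng.normal(size=10)
        lam = 2.0
        fit = M.fit_rkhs(y, np.eye(10), lambda_=lam)
        np.testing.assert_allclose(
            fit.gebv, (y - fit.intercept) / (1 + lam), atol=1e-10
        )

    def test_two_point_hand_case(self):
        K = np.array([[1.0, 0.5], [0.5, 1.0]])
        y = np.array([1.0, -1.0])
        fit = M.fit_rkhs(y, K, lambda_=1.0)
        np.testing.assert_allclose(fit.state["alpha"], [2 / 3, -2 / 3], atol=1e-12)
        np.testing.assert_allclose(fit.gebv, [1 / 3, -1 / 3], atol=1e-12)

    def test_interpolation_limit(self, rng):
        A = rng.normal(size=(8, 8))
        K = A @ A.T + 5 * np.eye(8)
        y = rng.normal(size=8)
        fit = M.fit_rkhs(y, K, lambda_=1e-9)
        np.testing.assert_allclose(fit.intercept + fit.gebv, y, atol=1e-6)

    def test_linear_kernel_matches_gblup(self, rng):
        X = rng.normal(size=(30, 100))
        y = rng.normal(size=30)
        G = build_grm(X)
        lam = 1.3
        gb = M.fit_gblup(y, G, lambda_=lam)
        rk = M.fit_rkhs(y, G.values, lambda_=lam)
        np.testing.assert_allclose(rk.gebv, gb.gebv, atol=1e-8)


class TestSVR:
    def test_wide_tube_zero_support_vectors(self):
        y = np.array([0.0, 1.0, 2.0, 3.0])
        K = np.eye(4)
        fit = M.fit_svr(y, K, epsilon=2.0, C=1.0)
        assert fit.training_meta["n_support_vectors"] == 0
        assert fit.intercept == pytest.approx(1.5)  # midrange tie rule
        np.testing.assert_allclose(fit.gebv, 0.0, atol=1e-12)

    def test_vanishing_capacity_is_flat(self, rng):
        X = rng.normal(size=(20, 10))
        y = rng.normal(size=20)
        K = build_gaussian_kernel(X).values
        fit = M.fit_svr(y, K, epsilon=0.01, C=1e-8)
        preds = fit.intercept + fit.gebv
        assert np.ptp(preds) < 1e-5

    def test_dual_objective_matches_grid_search(self):
        """Exhaustive search over the dual box (0.05 lattice, sum-zero
        constraint) cannot beat the returned solution by more than 1e-4."""
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = np.array([0.1, 0.9, 2.2, 2.8, 4.1])
        K = 1.0 + np.outer(x, x)  # linear kernel with bias feature
        C, eps = 0.2, 0.3
        fit = M.fit_svr(y, K, epsilon=eps, C=C)
        ours = M.svr_dual_objective(K, y, fit.state["alpha"], eps)
        lattice = np.arange(-C, C + 1e-12, 0.05)
        best = -np.inf
        import itertools

        for combo in itertools.product(lattice, repeat=4):
            last = -sum(combo)
            if abs(last) > C + 1e-12:
                continue
            beta = np.array(combo + (last,))
            best = max(best, M.svr_dual_objective(K, y, beta, eps))
        assert ours >= best - 1e-4

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            M.fit_svr(np.zeros(3), np.eye(3), epsilon=-0.1)
        with pytest.raises(ValueError):
            M.fit_svr(np.zeros(3), np.eye(3), C=0.0)


class TestBoosting:
    def test_constant_learner_geometric_shrinkage(self):
        y = np.full(6, 2.0)
        fit = M.fit_boosting(y, np.zeros((6, 1)), learning_rate=0.5,
                             n_rounds=2, max_depth=0)
        # residual mean shrinks geometrically: 2 * (1 - (1 - v)^M) = 1.5
        np.testing.assert_allclose(fit.gebv, 1.5, atol=1e-12)

    def test_zero_rate_stays_at_f0(self, rng):
        y = rng.normal(size=10)
        fit = M.fit_boosting(y, rng.normal(size=(10, 4)), learning_rate=0.0,
                             n_rounds=20, max_depth=1)
        np.testing.assert_allclose(fit.gebv, 0.0)

    def test_training_mse_non_increasing(self, rng):
        X = rng.normal(size=(60, 20))
        y = X[:, 0] * 2 + rng.normal(size=60)
        fit = M.fit_boosting(y, X, learning_rate=0.1, n_rounds=200, max_depth=2)
        trace = fit.training_meta["train_mse_trace"]
        assert all(a >= b - 1e-10 for a, b in zip(trace, trace[1:]))

    def test_schedule_trace_recorded(self, rng):
        from gsnue.evaluation import learning_rate_schedule

        sched, _ = learning_rate_schedule(1.0, 9900)
        y = rng.normal(size=12)
        fit = M.fit_boosting(y, rng.normal(size=(12, 3)), n_rounds=5,
                             schedule=sched, max_depth=1)
        np.testing.assert_allclose(
            fit.training_meta["learning_rate_trace"], sched[:5]
        )

    def test_invalid_config(self, rng):
        with pytest.raises(ValueError):
            M.fit_boosting(np.zeros(3), np.zeros((3, 1)), learning_rate=1.5)
        with pytest.raises(ValueError):
            M.fit_boosting(np.zeros(3), np.zeros((3, 1)), n_rounds=0)


class TestBagging:
    def test_constant_learner_matches_mean(self, rng):
        y = rng.normal(loc=5.0, size=40)
        fit = M.fit_bagging(y, rng.normal(size=(40, 5)), n_bags=100,
                            max_depth=0, seed=2)
        se = y.std() / np.sqrt(40)
        assert abs(fit.gebv.mean() - y.mean()) < 2 * se

    def test_variance_decreases_with_bags(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 8))
        y = X[:, 0] + rng.normal(size=40)
        x_test = X[:1]
        var_by_b = []
        for B in (1, 10, 50):
            preds = []
            for rep in range(30):
                fit = M.fit_bagging(y, X, n_bags=B, max_depth=2, seed=1000 + rep)
                preds.append(M.predict(fit, x_test)[0])
            var_by_b.append(np.var(preds))
        violations = sum(a < b for a, b in zip(var_by_b, var_by_b[1:]))
        assert violations <= 1

    def test_fixed_seed_reproducible(self, rng):
        X = rng.normal(size=(25, 6))
        y = rng.normal(size=25)
        a = M.fit_bagging(y, X, n_bags=20, seed=3)
        b = M.fit_bagging(y, X, n_bags=20, seed=3)
        np.testing.assert_array_equal(a.gebv, b.gebv)

    def test_invalid_bags(self):
        with pytest.raises(ValueError):
            M.fit_bagging(np.zeros(3), np.zeros((3, 1)), n_bags=0)


class TestStacking:
    def test_oracle_base_recovery(self, rng):
        n = 300
        truth = rng.normal(size=n)
        y = truth.copy()
        P = np.column_stack([truth, rng.normal(size=n), rng.normal(size=n)])
        fit = M.fit_stacking(P, y, ["truth", "noise1", "noise2"])
        assert fit.training_meta["weights"]["truth"] >= 0.9

    def test_identical_bases_degenerate(self, rng):
        base = rng.normal(size=50)
        y = base + 0.1 * rng.normal(size=50)
        P = np.column_stack([base, base, base])
        fit = M.fit_stacking(P, y, ["a", "b", "c"])
        w = fit.state["weights"]
        np.testing.assert_allclose(fit.intercept + P @ w,
                                   fit.intercept + base * w.sum(), atol=1e-10)

    def test_eps_insensitive_loss_zero_inside_tube(self, rng):
        y = rng.normal(size=30)
        P = np.column_stack([y + 0.001, y - 0.001])
        fit = M.fit_stacking(P, y, ["a", "b"], epsilon=0.5)
        assert fit.training_meta["meta_loss_eps"] == 0.0

    def test_too_few_bases(self, rng):
        with pytest.raises(ValueError):
            M.fit_stacking(rng.normal(size=(10, 1)), rng.normal(size=10), ["a"])


class TestPredict:
    def test_training_set_consistency(self, rng):
        X = rng.normal(size=(20, 15))
        y = rng.normal(size=20)
        for fit in (
            M.fit_rrblup(y, X, lambda_=1.0),
            M.fit_lasso(y, X, lambda_=0.05),
        ):
            np.testing.assert_allclose(M.predict(fit, X), fit.gebv, atol=1e-10)

    def test_duplicated_rows_identical_predictions(self, rng):
        X = rng.normal(size=(15, 10))
        y = rng.normal(size=15)
        fit = M.fit_rrblup(y, X, lambda_=2.0)
        new = np.vstack([X[2], X[2]])
        p = M.predict(fit, new)
        assert p[0] == p[1]

    def test_heldout_matrix_product_oracle(self, tiny_rr):
        X, y = tiny_rr
        fit = M.fit_rrblup(y, X, lambda_=1.0, fit_intercept=False)
        x_new = np.array([[2.0, -1.0]])
        expected = 2.0 * 0.625 + (-1.0) * (-0.125)
        assert M.predict(fit, x_new)[0] == pytest.approx(expected, abs=1e-10)

    def test_marker_mismatch_raises(self, rng):
        fit = M.fit_rrblup(rng.normal(size=10), rng.normal(size=(10, 5)), lambda_=1.0)
        with pytest.raises(ValueError, match="marker mismatch"):
            M.predict(fit, rng.normal(size=(3, 7)))


def test_serialize_fit_round_trips_scalars(tmp_path, rng):
    import json

    fit = M.fit_rrblup(rng.normal(size=12), rng.normal(size=(12, 6)), lambda_=2.0)
    M.serialize_fit(fit, tmp_path)
    payload = json.loads((tmp_path / "rrBLUP.json").read_text())
    assert payload["regularization"]["lambda"] == 2.0
    import pandas as pd

    gebv = pd.read_csv(tmp_path / "rrBLUP_gebv.tsv", sep="\t")["gebv"]
    np.testing.assert_allclose(gebv, fit.gebv, atol=1e-9)
    assert (tmp_path / "rrBLUP_effects.tsv").exists()
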