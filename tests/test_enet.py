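import numpy as np
import pytest
from scipy.optimize import minimize

from metclass import enet


def random_instance(rng, n=20, p=10):
    X = rng.normal(size=(n, p))
    y = (rng.random(n) < 0.5).astype(float)
    if y.sum() < 2 or y.sum() > n - 2:
        y[:3], y[3:6] = 1.0, 0.0
    return X, y


def lbfgs_oracle(X, y, w, alpha, lam):
    """Generic high-precision solver on the split-variable formulation."""
    n, p = X.shape
    v = w / w.sum()

    def f(z):
        b0, u, q = z[0], z[1:1 + p], z[1 + p:]
        b = u - q
        eta = b0 + X @ b
        nll = -np.sum(v * (y * eta - np.logaddexp(0.0, eta)))
        return nll + lam * ((1 - alpha) * np.sum(b ** 2) / 2
                            + alpha * np.sum(u + q))

    res = minimize(f, np.zeros(1 + 2 * p), method="L-BFGS-B",
                   bounds=[(None, None)] + [(0, None)] * (2 * p),
                   options={"maxiter": 20000, "ftol": 1e-16, "gtol": 1e-12})
    return res.fun


class TestObjective:
    def test_null_model_on_balanced_labels_is_log_two(self):
        X = np.zeros((10, 3))
        y = np.array([0., 1.] * 5)
        m = enet.EnetModel(beta0=0.0, beta=np.zeros(3), alpha=0.5, lam=1.0,
                           weights=np.ones(10), n=10, p=3)
        assert enet.enet_objective(m, X, y) == pytest.approx(np.log(2.0))

    def test_zero_lambda_equals_weighted_nll(self, rng):
        X, y = random_instance(rng)
        w = enet.class_weights(y)
        beta = rng.normal(size=10) * 0.3
        m = enet.EnetModel(beta0=0.1, beta=beta, alpha=0.5, lam=0.0,
                           weights=w, n=20, p=10)
        v = w / w.sum()
        eta = 0.1 + X @ beta
        nll = -np.sum(v * (y * eta - np.logaddexp(0.0, eta)))
        assert enet.enet_objective(m, X, y) == pytest.approx(nll, abs=1e-12)

    def test_matches_direct_formula_evaluation(self, rng):
        # independent re-implementation of the penalized criterion
        X = rng.normal(size=(5, 3))
        y = np.array([1.0, 0.0, 1.0, 0.0, 1.0])
        w = np.array([1.2, 0.8, 1.0, 1.0, 1.0])
        beta0, beta, alpha, lam = 0.3, np.array([0.5, -0.2, 0.0]), 0.5, 0.1
        m = enet.EnetModel(beta0=beta0, beta=beta, alpha=alpha, lam=lam,
                           weights=w, n=5, p=3)
        acc = 0.0
        for i in range(5):
            eta = beta0 + X[i] @ beta
            acc += w[i] * (y[i] * eta - np.log(1 + np.exp(eta)))
        expected = -acc / w.sum() + lam * (
            (1 - alpha) * np.sum(beta ** 2) / 2 + alpha * np.sum(np.abs(beta)))
        assert enet.enet_objective(m, X, y) == pytest.approx(expected, abs=1e-10)


class TestFitEnet:
    def test_oracle_equivalence(self, rng):
        for _ in range(3):
            X, y = random_instance(rng)
            w = enet.class_weights(y)
            lam = enet.lambda_path(X, y, w, 0.5)[35]
            m = enet.fit_enet(X, y, w, 0.5, lam)
            obj = enet.enet_objective(m, X, y)
            assert obj <= lbfgs_oracle(X, y, w, 0.5, lam) + 1e-6

    def test_kkt_conditions_hold(self, rng):
        X, y = random_instance(rng, n=40, p=15)
        w = enet.class_weights(y)
        for li in (5, 40, 80):
            lam = enet.lambda_path(X, y, w, 0.5)[li]
            m = enet.fit_enet(X, y, w, 0.5, lam)
            assert enet.kkt_residuals(m, X, y).max() < 1e-6

    def test_weight_invariance_under_row_duplication(self, rng):
        X, y = random_instance(rng)
        w = np.ones(20)
        lam = 0.05
        m1 = enet.fit_enet(X, y, w, 0.5, lam)
        X2 = np.vstack([X, X])
        y2 = np.concatenate([y, y])
        m2 = enet.fit_enet(X2, y2, np.full(40, 0.5), 0.5, lam)
        np.testing.assert_allclose(m1.beta, m2.beta, atol=1e-7)
        assert m1.beta0 == pytest.approx(m2.beta0, abs=1e-7)

    def test_feature_permutation_invariance(self, rng):
        X, y = random_instance(rng)
        w = enet.class_weights(y)
        lam = enet.lambda_path(X, y, w, 0.5)[30]
        m = enet.fit_enet(X, y, w, 0.5, lam)
        perm = rng.permutation(10)
        m2 = enet.fit_enet(X[:, perm], y, w, 0.5, lam)
        np.testing.assert_allclose(m2.beta, m.beta[perm], atol=1e-6)

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError):
            enet.fit_enet(X, np.ones(10), None, 0.5, 0.1)

    def test_unpenalized_covariates_always_active(self, rng):
        X, y = random_instance(rng, n=50, p=6)
        # make column 0 informative so its unpenalized coefficient is nonzero
        X[:, 0] += y
        pf = np.ones(6)
        pf[0] = 0.0
        lam = enet.lambda_path(X, y, None, 0.5, penalty_factor=pf)[0]
        m = enet.fit_enet(X, y, None, 0.5, lam, penalty_factor=pf)
        assert m.beta[0] != 0.0
        assert np.all(m.beta[1:] == 0.0)


class TestLambdaPath:
    def test_hand_derived_lambda_max_single_feature(self):
        x = np.array([1.0, -1.0, 2.0, -2.0])
        y = np.array([1.0, 0.0, 1.0, 0.0])
        w = np.ones(4)
        alpha = 0.5
        grid = enet.lambda_path(x[:, None], y, w, alpha, n_lambda=5)
        v = w / w.sum()
        ybar = np.sum(v * y)
        expected = abs(np.sum(v * x * (y - ybar))) / alpha
        assert grid[0] == pytest.approx(expected, rel=1e-12)

    def test_grid_is_strictly_decreasing_length_100(self, rng):
        X, y = random_instance(rng)
        grid = enet.lambda_path(X, y, None, 0.5)
        assert grid.size == 100
        assert np.all(np.diff(grid) < 0)

    def test_fit_at_top_of_path_has_empty_support(self, rng):
        X, y = random_instance(rng)
        w = enet.class_weights(y)
        grid = enet.lambda_path(X, y, w, 0.5)
        m = enet.fit_enet(X, y, w, 0.5, grid[0])
        assert m.support.size == 0
        v = w / w.sum()
        ybar = np.sum(v * y)
        assert m.beta0 == pytest.approx(np.log(ybar / (1 - ybar)), abs=1e-8)

    def test_alpha_zero_needs_explicit_grid(self, rng):
        X, y = random_instance(rng)
        with pytest.raises(ValueError):
            enet.lambda_path(X, y, None, 0.0)


class TestSelectLambda:
    def test_pure_noise_selects_sparse_model(self, rng):
        supports = []
        for rep in range(5):
            X, y = random_instance(rng, n=40, p=20)
            w = enet.class_weights(y)
            sel = enet.select_lambda(X, y, w, 0.5, cv=10, n_lambda=50, seed=rep)
            m = enet.fit_enet(X, y, w, 0.5, sel.lam)
            supports.append(m.support.size)
        assert np.median(supports) <= 4

    def test_separating_feature_is_selected(self, rng):
        n = 40
        y = np.array([0.0, 1.0] * (n // 2))
        X = rng.normal(size=(n, 8))
        X[:, 3] = y * 2 - 1 + rng.normal(0, 0.3, n)
        X = (X - X.mean(0)) / X.std(0)
        w = enet.class_weights(y)
        sel = enet.select_lambda(X, y, w, 0.5, cv="loo", n_lambda=50)
        m = enet.fit_enet(X, y, w, 0.5, sel.lam)
        assert 3 in m.support

    def test_selected_deviance_not_worse_than_null(self, rng):
        X, y = random_instance(rng, n=30, p=10)
        sel = enet.select_lambda(X, y, None, 0.5, cv=5, n_lambda=40)
        assert sel.mean_deviance[sel.index] <= sel.mean_deviance[0] + 1e-12

    def test_warm_path_objective_never_increases_at_own_lambda(self, rng):
        # each path point's solution must beat the previous solution on
        # its own objective (continuation sanity)
        X, y = random_instance(rng, n=30, p=12)
        w = enet.class_weights(y)
        betas, beta0s, lams = enet.fit_enet_path(X, y, w, 0.5,
                                                 enet.lambda_path(X, y, w, 0.5, 30))
        for l in range(1, 30):
            cur = enet.EnetModel(beta0s[l], betas[l], 0.5, lams[l], w, 30, 12)
            prev = enet.EnetModel(beta0s[l - 1], betas[l - 1], 0.5, lams[l],
                                  w, 30, 12)
            assert enet.enet_objective(cur, X, y) <= \
                enet.enet_objective(prev, X, y) + 1e-9


class TestClassWeights:
    def test_study_scale_group_sizes(self):
        y = np.r_[np.zeros(85), np.ones(57)]
        w = enet.class_weights(y)
        assert w[0] == pytest.approx(142 / 170)
        assert w[-1] == pytest.approx(142 / 114)
        assert w.sum() == pytest.approx(142)

    def test_balanced_labels_give_unit_weights(self):
        y = np.array([0.0, 1.0] * 10)
        np.testing.assert_allclose(enet.class_weights(y), 1.0)

    def test_class_totals_equal(self, rng):
        y = (rng.random(37) < 0.3).astype(float)
        if y.sum() in (0, 37):
            y[0] = 1 - y[0]
        w = enet.class_weights(y)
        assert w[y == 0].sum() == pytest.approx(w[y == 1].sum())

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            enet.class_weights(np.ones(5))


class TestConsensusOddsRatios:
    def _fit(self, beta):
        return enet.EnetModel(0.0, np.asarray(beta, float), 0.5, 0.1,
                              np.ones(4), 4, len(beta))

    def test_feature_missing_from_one_fit_is_excluded(self):
        fits = [self._fit([1.0, 0.5]) for _ in range(4)]
        fits.append(self._fit([1.0, 0.0]))
        recs = enet.consensus_odds_ratios(fits, ["a", "b"])
        assert [r.name for r in recs] == ["a"]

    def test_identical_coefficients_collapse_interval(self):
        fits = [self._fit([np.log(2.0)]) for _ in range(5)]
        recs = enet.consensus_odds_ratios(fits, ["a"])
        assert recs[0].odds_ratio == pytest.approx(2.0)
        assert recs[0].low == pytest.approx(2.0)
        assert recs[0].high == pytest.approx(2.0)
        pos, neg = enet.split_or_tables(recs)
        assert [r.name for r in pos] == ["a"] and neg == []

    def test_near_unity_odds_ratios_filtered(self):
        fits = [self._fit([0.05, -0.5]) for _ in range(5)]  # OR 1.05 filtered
        recs = enet.consensus_odds_ratios(fits, ["a", "b"])
        assert [r.name for r in recs] == ["b"]

    def test_single_fit_warns_and_reports_point(self):
        with pytest.warns(UserWarning, match="fewer than 2"):
            recs = enet.consensus_odds_ratios([self._fit([1.0])], ["a"])
        assert recs[0].low == recs[0].high == recs[0].odds_ratio
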