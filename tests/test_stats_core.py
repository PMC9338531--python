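import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from concordmap import stats_core
from oracles import (brute_auc, brute_bh, brute_logrank, brute_mwu,
                     brute_pearson, brute_spearman, brute_spearman_exact_p)


class TestSpearman:
    def test_perfect_and_reversed(self):
        x = [1, 2, 3, 4]
        assert stats_core.spearman_rho(x, x).estimate == pytest.approx(1.0)
        assert stats_core.spearman_rho(x, x[::-1]).estimate == pytest.approx(-1.0)

    def test_hand_rank_formula(self):
        # d^2 = 1+1+1+1+0 -> rho = 1 - 6*4/(5*24) = 0.8
        res = stats_core.spearman_rho([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res.estimate == pytest.approx(0.8, abs=1e-12)

    def test_matches_brute_force_with_ties(self, rng):
        x = rng.integers(0, 5, size=8).astype(float)
        y = rng.integers(0, 5, size=8).astype(float)
        x[0] += 0.5  # avoid fully constant vectors
        res = stats_core.spearman_rho(x, y)
        assert res.estimate == pytest.approx(brute_spearman(list(x), list(y)), abs=1e-9)

    def test_exact_small_sample_p(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        y = [2.0, 1.0, 4.0, 3.0, 6.0, 5.0]
        res = stats_core.spearman_rho(x, y)
        assert res.method == "spearman-exact"
        assert res.p_value == pytest.approx(brute_spearman_exact_p(x, y), abs=1e-9)

    def test_constant_flagged(self):
        res = stats_core.spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])
        assert "constant" in res.flags and math.isnan(res.estimate)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.integers(-500, 500), min_size=5, max_size=20, unique=True),
           st.integers(0, 2 ** 31 - 1))
    def test_monotone_transform_invariance(self, xs, seed):
        xs = [v / 10.0 for v in xs]  # distinct after exp(x/25) too
        y = np.random.default_rng(seed).normal(size=len(xs))
        base = stats_core.spearman_rho(xs, y).estimate
        warped = stats_core.spearman_rho(np.exp(np.asarray(xs) / 25.0), y).estimate
        assert warped == pytest.approx(base, abs=1e-12)


class TestPearson:
    def test_linear(self):
        x = np.arange(10.0)
        assert stats_core.pearson_r(x, 2 * x + 1).estimate == pytest.approx(1.0)

    def test_hand_formula(self, rng):
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        res = stats_core.pearson_r(x, y)
        assert res.estimate == pytest.approx(brute_pearson(list(x), list(y)), abs=1e-12)

    def test_orthogonal(self):
        assert stats_core.pearson_r([1, -1, 1, -1], [1, 1, -1, -1]).estimate == \
            pytest.approx(0.0, abs=1e-12)


class TestMannWhitney:
    def test_exact_toy(self):
        res = stats_core.mann_whitney_u([1.0, 2.0], [3.0, 4.0])
        u, p = brute_mwu([1.0, 2.0], [3.0, 4.0])
        assert res.statistic == pytest.approx(u) == 0.0
        assert res.p_value == pytest.approx(p, abs=1e-9)
        assert res.p_value == pytest.approx(2.0 / 6.0, abs=1e-9)

    def test_identical_multisets(self):
        res = stats_core.mann_whitney_u([1.0, 2.0, 3.0], [3.0, 1.0, 2.0])
        assert res.p_value == pytest.approx(1.0)

    def test_all_tied(self):
        res = stats_core.mann_whitney_u([2.0, 2.0], [2.0, 2.0, 2.0])
        assert res.p_value == 1.0 and "all-tied" in res.flags

    def test_exact_matches_enumeration(self, rng):
        a = list(rng.normal(size=5))
        b = list(rng.normal(size=6))
        res = stats_core.mann_whitney_u(a, b)
        u, p = brute_mwu(a, b)
        assert res.statistic == pytest.approx(u, abs=1e-9)
        assert res.p_value == pytest.approx(p, abs=1e-9)

    def test_power_at_one_sd_shift(self):
        rng = np.random.default_rng(0)
        hits = 0
        n_sims = 500
        for _ in range(n_sims):
            a = rng.normal(1.0, 1.0, 50)
            b = rng.normal(0.0, 1.0, 50)
            hits += stats_core.mann_whitney_u(a, b).p_value < 0.05
        assert hits / n_sims > 0.9


class TestWelch:
    def test_identical_groups(self):
        res = stats_core.welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0) and res.p_value == pytest.approx(1.0)

    def test_hand_formula(self):
        a = np.array([3.0, 4.0, 5.0, 6.0])
        b = np.array([1.0, 2.0, 2.5])
        res = stats_core.welch_t(a, b)
        se = math.sqrt(a.var(ddof=1) / 4 + b.var(ddof=1) / 3)
        assert res.statistic == pytest.approx((a.mean() - b.mean()) / se, abs=1e-12)

    def test_zero_variance_equal_means(self):
        res = stats_core.welch_t([2.0, 2.0], [2.0, 2.0, 2.0])
        assert res.p_value == 1.0

    def test_type_one_error_calibration(self):
        rng = np.random.default_rng(1)
        n_sims = 4000
        hits = sum(stats_core.welch_t(rng.normal(size=10), rng.normal(size=10)).p_value < 0.05
                   for _ in range(n_sims))
        assert hits / n_sims == pytest.approx(0.05, abs=0.012)


class TestBH:
    def test_single(self):
        assert stats_core.bh_adjust([0.04])[0] == pytest.approx(0.04)

    def test_step_up_by_hand(self):
        q = stats_core.bh_adjust([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_all_equal(self):
        q = stats_core.bh_adjust([0.2, 0.2, 0.2, 0.2])
        assert np.allclose(q, 0.2)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=25))
    def test_matches_brute_and_dominates_p(self, ps):
        q = stats_core.bh_adjust(ps)
        assert np.allclose(q, brute_bh(ps), atol=1e-12)
        assert np.all(q >= np.asarray(ps) - 1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=25),
           st.floats(0.01, 0.2))
    def test_rejections_superset_of_bonferroni(self, ps, alpha):
        q = stats_core.bh_adjust(ps)
        m = len(ps)
        bonf = {i for i, p in enumerate(ps) if p * m <= alpha}
        bh = {i for i, qq in enumerate(q) if qq <= alpha}
        assert bonf <= bh


class TestSurvival:
    def test_km_no_events(self):
        curve = stats_core.km_curve([3, 5, 7], [0, 0, 0])
        assert np.allclose(curve["survival"], 1.0)

    def test_logrank_identical_groups(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        e = [1, 1, 0, 1, 1, 1, 0, 1]
        g = [0, 0, 0, 0, 1, 1, 1, 1]
        res = stats_core.logrank(t, e, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_logrank_matches_hand_table(self):
        t = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        e = [1, 1, 1, 0, 1, 1]
        g = [0, 1, 0, 1, 1, 0]
        res = stats_core.logrank(t, e, g)
        assert res.statistic == pytest.approx(brute_logrank(t, e, g), abs=1e-10)

    def test_logrank_one_group_without_events(self):
        res = stats_core.logrank([1, 2, 3, 4], [1, 1, 0, 0], [0, 0, 1, 1])
        assert math.isfinite(res.statistic)

    def test_logrank_requires_two_groups(self):
        with pytest.raises(ValueError):
            stats_core.logrank([1, 2], [1, 1], [0, 0])


class TestCox:
    def test_negation_antisymmetry(self, rng):
        x = rng.normal(size=60)
        t = rng.exponential(1.0, 60) / np.exp(0.8 * x)
        e = np.ones(60, dtype=int)
        a = stats_core.cox_fit(pd.DataFrame({"x": x}), t, e)["x"]
        b = stats_core.cox_fit(pd.DataFrame({"x": -x}), t, e)["x"]
        assert b.estimate == pytest.approx(-a.estimate, abs=1e-6)

    def test_constant_covariate_flagged(self, rng):
        t = rng.exponential(1.0, 20)
        res = stats_core.cox_fit(pd.DataFrame({"x": np.ones(20)}), t,
                                 np.ones(20, dtype=int))["x"]
        assert "constant-covariate" in res.flags

    def test_rescaling_equivariance(self, rng):
        x = rng.normal(size=80)
        t = rng.exponential(1.0, 80) / np.exp(0.5 * x)
        e = np.ones(80, dtype=int)
        a = stats_core.cox_fit(pd.DataFrame({"x": x}), t, e)["x"]
        b = stats_core.cox_fit(pd.DataFrame({"x": 10 * x}), t, e)["x"]
        assert b.estimate == pytest.approx(a.estimate / 10.0, rel=1e-5)

    def test_parameter_recovery_and_coverage(self):
        rng = np.random.default_rng(3)
        est, cover = [], 0
        n_sims = 40
        for _ in range(n_sims):
            x = rng.normal(size=300)
            t = rng.exponential(1.0, 300) / np.exp(1.0 * x)
            res = stats_core.cox_fit(pd.DataFrame({"x": x}), t,
                                     np.ones(300, dtype=int))["x"]
            est.append(res.estimate)
            cover += res.ci_low <= 1.0 <= res.ci_high
        assert np.mean(est) == pytest.approx(1.0, abs=0.1)
        assert cover / n_sims >= 0.85


class TestLogistic:
    def test_intercept_only_closed_form(self):
        y = np.array([1, 1, 1, 0, 0], dtype=float)
        fit = stats_core.logistic_fit(np.zeros((5, 0)), y)
        assert fit.coef["(Intercept)"] == pytest.approx(math.log(3 / 2), abs=1e-6)

    def test_matches_grid_oracle(self):
        x = np.array([-1.5, -1.0, -0.5, -0.2, 0.2, 0.5, 1.0, 1.5])
        y = np.array([0, 0, 1, 0, 1, 0, 1, 1], dtype=float)
        fit = stats_core.logistic_fit(x[:, None], y)

        def nll(b0, b1):
            eta = b0 + b1 * x
            return np.sum(np.log1p(np.exp(eta)) - y * eta)

        grid = np.arange(-5, 5, 0.001)
        best = min(((nll(b0, b1), b0, b1)
                    for b0 in np.arange(-2, 2, 0.05) for b1 in grid),
                   key=lambda z: z[0])
        assert fit.coef.iloc[1] == pytest.approx(best[2], abs=1e-2)
        assert 2 * best[0] >= fit.deviance - 1e-6  # MLE deviance is minimal

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm
        X = rng.normal(size=(120, 3))
        y = (rng.random(120) < 1 / (1 + np.exp(-(0.5 + X @ [1.0, -0.5, 0.0])))).astype(float)
        fit = stats_core.logistic_fit(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert np.allclose(fit.coef.to_numpy(), ref.params, atol=1e-6)
        assert np.allclose(fit.p_values.to_numpy(), ref.pvalues, atol=1e-5)

    def test_separation_flag_and_firth_fallback(self):
        x = np.array([-2.0, -1.0, -0.5, 0.5, 1.0, 2.0])
        y = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        fit = stats_core.logistic_fit(x[:, None], y)
        assert "separation" in fit.flags
        firth = stats_core.logistic_fit(x[:, None], y, firth=True)
        assert np.isfinite(firth.coef.iloc[1]) and firth.coef.iloc[1] < 10

    def test_uninformative_feature(self, rng):
        x = rng.normal(size=200)
        y = np.r_[np.ones(100), np.zeros(100)]
        fit = stats_core.logistic_fit(x[:, None], y)
        assert abs(fit.coef.iloc[1]) < 0.5
        assert fit.p_values.iloc[1] > 0.01


class TestLassoPath:
    def _toy(self, seed=0, n=80, p=12):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        X[: n // 2, 0] += 2.0
        y = np.r_[np.ones(n // 2), np.zeros(n // 2)]
        Xz = (X - X.mean(0)) / X.std(0)
        return Xz, y

    def test_all_zero_at_lambda_max(self):
        X, y = self._toy()
        lmax = stats_core.lasso_lambda_max(X, y)
        path = stats_core.lasso_logistic_path(X, y, [lmax * 1.01])
        assert (path.iloc[0].drop("(Intercept)") == 0.0).all()

    def test_small_lambda_matches_unpenalized(self):
        X, y = self._toy(n=200, p=4)
        fit = stats_core.logistic_fit(X, y)
        path = stats_core.lasso_logistic_path(X, y, [1e-6], tol=1e-9)
        assert np.allclose(path.iloc[0].to_numpy(), fit.coef.to_numpy(), atol=1e-3)

    def test_matches_liblinear_oracle(self):
        from sklearn.linear_model import LogisticRegression
        X, y = self._toy(seed=4, n=100, p=20)
        lam = 0.05
        mine = stats_core.lasso_logistic_path(X, y, [lam], tol=1e-9).iloc[0]
        ref = LogisticRegression(l1_ratio=1.0, C=1 / (len(y) * lam),
                                 solver="liblinear", tol=1e-10,
                                 max_iter=100000).fit(X, y)
        assert np.allclose(mine.drop("(Intercept)").to_numpy(),
                           ref.coef_.ravel(), atol=5e-3)

    def test_planted_feature_dominates_at_cv_lambda(self):
        hits = 0
        n_reps = 40
        for seed in range(n_reps):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(100, 50))
            eta = 1.5 * X[:, 7]
            y = (rng.random(100) < 1 / (1 + np.exp(-eta))).astype(float)
            if y.sum() < 10 or y.sum() > 90:
                hits += 1
                continue
            Xz = (X - X.mean(0)) / X.std(0)
            lam, _ = stats_core.cv_lambda(Xz, y, seed=seed)
            coefs = stats_core.lasso_logistic_path(Xz, y, [lam]).iloc[0]
            coefs = coefs.drop("(Intercept)").to_numpy()
            hits += np.argmax(np.abs(coefs)) == 7
        assert hits / n_reps >= 0.9


class TestKmeansAuc:
    def test_kmeans_blob_recovery(self, rng):
        a = rng.normal(0, 0.2, size=(30, 2))
        b = rng.normal(5, 0.2, size=(30, 2)) + [0, 5]
        X = np.vstack([a, b])
        labels, _, inertia = stats_core.kmeans(X, 2, seed=0)
        assert len(set(labels[:30])) == 1 and len(set(labels[30:])) == 1
        assert labels[0] != labels[30]

    def test_kmeans_k_equals_n(self, rng):
        X = rng.normal(size=(6, 3))
        _, _, inertia = stats_core.kmeans(X, 6, seed=0)
        assert inertia == pytest.approx(0.0, abs=1e-9)

    def test_kmeans_inertia_monotone_in_k(self, rng):
        X = rng.normal(size=(40, 4))
        inertias = [stats_core.kmeans(X, k, seed=0)[2] for k in (2, 4, 8)]
        assert inertias[0] >= inertias[1] >= inertias[2]

    def test_auc_perfect_and_brute(self, rng):
        assert stats_core.roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]) == 1.0
        scores = list(rng.normal(size=6))
        labels = [0, 1, 0, 1, 1, 0]
        assert stats_core.roc_auc(scores, labels) == \
            pytest.approx(brute_auc(scores, labels), abs=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=4, max_size=30),
           st.integers(0, 2 ** 31 - 1))
    def test_auc_negation_symmetry(self, scores, seed):
        labels = np.random.default_rng(seed).integers(0, 2, size=len(scores))
        if len(set(labels)) < 2:
            labels[0], labels[1] = 0, 1
        a = stats_core.roc_auc(scores, labels)
        b = stats_core.roc_auc([-s for s in scores], labels)
        assert a + b == pytest.approx(1.0, abs=1e-12)
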