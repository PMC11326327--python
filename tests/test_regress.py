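"""Regression-engine oracles: cluster sandwiches, within transforms,
conditional logit closed forms."""

import numpy as np
import pandas as pd
import pytest

from sibmr import (
    Z975,
    logistic_cluster,
    ols_cluster,
    ols_fe_cluster,
    sibling_difference_logit,
    within_transform,
)


def hand_summed_sandwich(y, X, clusters, k_dof=None):
    """Independent oracle: the CR1 cluster sandwich summed cluster by
    cluster with explicit loops."""
    M = np.column_stack([np.ones(len(y)), np.asarray(X, float).ravel()])
    beta = np.linalg.solve(M.T @ M, M.T @ y)
    u = y - M @ beta
    meat = np.zeros((2, 2))
    for g in np.unique(clusters):
        idx = clusters == g
        sg = M[idx].T @ u[idx]
        meat += np.outer(sg, sg)
    n, k = M.shape
    G = len(np.unique(clusters))
    c = (G / (G - 1)) * ((n - 1) / (n - (k_dof or k)))
    bread = np.linalg.inv(M.T @ M)
    return beta, c * bread @ meat @ bread


class TestOlsCluster:
    def test_perfect_fit_zero_se(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = ols_cluster(2 * x, pd.DataFrame({"x": x}), [0, 0, 1, 1])
        assert res.coef("x") == pytest.approx(2.0, abs=1e-12)
        assert res.se["x"] == pytest.approx(0.0, abs=1e-10)

    def test_singleton_clusters_equal_hc1(self, three_cluster_fixture):
        y, X, _ = three_cluster_fixture
        import statsmodels.api as sm

        res = ols_cluster(y, X, np.arange(len(y)))
        sm_res = sm.OLS(y, sm.add_constant(X)).fit(cov_type="HC1")
        np.testing.assert_allclose(res.se.to_numpy(), sm_res.bse, atol=1e-10)

    def test_matches_hand_summed_sandwich(self, three_cluster_fixture):
        y, X, clusters = three_cluster_fixture
        res = ols_cluster(y, X, clusters)
        beta, cov = hand_summed_sandwich(y, X, clusters)
        np.testing.assert_allclose(res.params.to_numpy(), beta, atol=1e-12)
        np.testing.assert_allclose(res.cov, cov, atol=1e-12)

    def test_point_estimates_invariant_to_cluster_labels(self,
                                                         three_cluster_fixture):
        y, X, clusters = three_cluster_fixture
        a = ols_cluster(y, X, clusters)
        b = ols_cluster(y, X, np.array([5, 5, 1, 1, 9, 9]))
        np.testing.assert_allclose(a.params, b.params, atol=1e-14)
        np.testing.assert_allclose(a.se, b.se, atol=1e-14)

    def test_ci_halfwidth_is_z975_times_se(self, three_cluster_fixture):
        y, X, clusters = three_cluster_fixture
        res = ols_cluster(y, X, clusters)
        np.testing.assert_allclose(res.ci_high - res.params, Z975 * res.se,
                                   atol=1e-12)

    def test_rank_deficiency_names_columns(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
        with pytest.raises(np.linalg.LinAlgError, match="b"):
            ols_cluster(np.zeros(4), X, [0, 0, 1, 1])


class TestWithinTransform:
    def test_constant_column_zeroed_and_dropped(self):
        X = pd.DataFrame({"x": [1.0, 2, 3, 4], "c": [7.0, 7, 7, 7]})
        _, Xw, _, _ = within_transform([0, 1, 2, 3], X, [0, 0, 1, 1])
        assert list(Xw.columns) == ["x"]

    def test_sibling_pair_demeaning(self):
        y = np.array([3.0, 5.0])
        _, Xw, _, _ = within_transform(y, pd.DataFrame({"x": [1.0, 4.0]}),
                                       ["f1", "f1"])
        np.testing.assert_allclose(Xw["x"], [-1.5, 1.5])

    def test_singletons_dropped_and_counted(self):
        y = [1.0, 2, 3, 4, 9]
        X = pd.DataFrame({"x": [0.0, 1, 0, 1, 5]})
        yw, Xw, codes, n_single = within_transform(y, X, [0, 0, 1, 1, 2])
        assert n_single == 1 and len(yw) == 4

    def test_all_singletons_rejected(self):
        with pytest.raises(ValueError):
            within_transform([1.0, 2.0], pd.DataFrame({"x": [1.0, 2.0]}),
                             ["a", "b"])

    def test_fe_ols_equals_dummy_variable_ols(self):
        """4-family oracle: demeaned OLS slope equals least squares with one
        indicator per family."""
        rng = np.random.default_rng(3)
        fam = np.repeat(np.arange(4), [2, 2, 3, 3])
        x = rng.normal(size=10)
        fam_eff = np.array([0.0, 2.0, -1.0, 0.5])[fam]
        y = 1.5 * x + fam_eff + rng.normal(0, 0.3, 10)
        fe = ols_fe_cluster(y, pd.DataFrame({"x": x}), fam)
        D = np.column_stack([x, (fam[:, None] == np.arange(4)).astype(float)])
        beta_dummy = np.linalg.lstsq(D, y, rcond=None)[0][0]
        assert fe.coef("x") == pytest.approx(beta_dummy, abs=1e-10)


class TestLogisticCluster:
    def test_null_effect_intercept_is_logit_prevalence(self):
        rng = np.random.default_rng(4)
        n = 4000
        y = rng.binomial(1, 0.3, n)
        X = pd.DataFrame({"x": rng.normal(size=n)})
        res = logistic_cluster(y, X, np.arange(n))
        prev = y.mean()
        assert res.coef("const") == pytest.approx(np.log(prev / (1 - prev)),
                                                  abs=0.05)
        assert abs(res.coef("x")) < 3 * res.se["x"] + 0.05

    def test_two_by_two_table_log_odds_ratio(self):
        """Counts (a,b,c,d)=(10,20,30,40): slope = log(ad/bc) = log(2/3)."""
        y = np.concatenate([np.ones(10), np.zeros(20), np.ones(30),
                            np.zeros(40)])
        x = np.concatenate([np.ones(30), np.zeros(70)])
        res = logistic_cluster(y, pd.DataFrame({"x": x}), np.arange(100))
        assert res.coef("x") == pytest.approx(np.log(10 * 40 / (20 * 30)),
                                              abs=1e-6)

    def test_singleton_clusters_equal_hc1(self):
        """One observation per cluster collapses CR1 to HC1, i.e. the HC0
        logit sandwich scaled by n/(n-k)."""
        rng = np.random.default_rng(5)
        n = 300
        x = rng.normal(size=n)
        y = rng.binomial(1, 1 / (1 + np.exp(-0.5 * x)))
        import statsmodels.api as sm

        res = logistic_cluster(y, pd.DataFrame({"x": x}), np.arange(n))
        sm_res = sm.Logit(y, sm.add_constant(x)).fit(disp=0, cov_type="HC0")
        hc1 = sm_res.bse * np.sqrt(n / (n - 2))
        np.testing.assert_allclose(res.se.to_numpy(), hc1, rtol=1e-5)

    def test_mle_matches_statsmodels(self):
        rng = np.random.default_rng(6)
        n = 500
        X = pd.DataFrame({"x": rng.normal(size=n), "w": rng.normal(size=n)})
        y = rng.binomial(1, 1 / (1 + np.exp(-(0.3 * X["x"] - 0.6 * X["w"]))))
        import statsmodels.api as sm

        res = logistic_cluster(y, X, np.repeat(np.arange(n // 2), 2))
        sm_res = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(res.params.to_numpy(), sm_res.params,
                                   atol=1e-6)

    def test_separation_detected(self):
        x = np.linspace(-3, 3, 40)
        y = (x > 0).astype(float)
        with pytest.raises(RuntimeError, match="separation"):
            logistic_cluster(y, pd.DataFrame({"x": x}), np.arange(40))


class TestSiblingDifferenceLogit:
    @staticmethod
    def matched_pairs(n10: int, n01: int) -> tuple[np.ndarray, pd.DataFrame,
                                                   np.ndarray]:
        """1:1 sibling pairs: n10 with the exposed sibling a case, n01 with
        the unexposed sibling a case."""
        y, x, fam = [], [], []
        for i in range(n10):
            y += [1, 0]; x += [1, 0]; fam += [f"a{i}"] * 2
        for i in range(n01):
            y += [1, 0]; x += [0, 1]; fam += [f"b{i}"] * 2
        return np.array(y, float), pd.DataFrame({"x": np.array(x, float)}), \
            np.array(fam)

    def test_matched_pair_closed_form_log2(self):
        y, X, fam = self.matched_pairs(12, 6)
        res = sibling_difference_logit(y, X, fam)
        assert res.coef("x") == pytest.approx(np.log(2.0), abs=1e-6)
        assert res.n_clusters == 18

    def test_concordant_families_dropped(self):
        y, X, fam = self.matched_pairs(12, 6)
        y2 = np.concatenate([y, [1, 1, 0, 0]])
        X2 = pd.concat([X, pd.DataFrame({"x": [1.0, 0, 1, 0]})],
                       ignore_index=True)
        fam2 = np.concatenate([fam, ["c0", "c0", "c1", "c1"]])
        res = sibling_difference_logit(y2, X2, fam2)
        assert res.coef("x") == pytest.approx(np.log(2.0), abs=1e-6)
        assert res.n_dropped == 2

    def test_family_constant_covariate_conditioned_out(self):
        y, X, fam = self.matched_pairs(12, 6)
        X2 = X.copy()
        X2["famvar"] = np.repeat(np.arange(18, dtype=float), 2)
        res = sibling_difference_logit(y, X2, fam)
        assert res.coef("x") == pytest.approx(np.log(2.0), abs=1e-6)
        assert "famvar" not in res.params.index

    def test_all_concordant_rejected(self):
        y = np.array([1.0, 1, 0, 0])
        X = pd.DataFrame({"x": [1.0, 0, 1, 0]})
        with pytest.raises(ValueError, match="discordant"):
            sibling_difference_logit(y, X, ["a", "a", "b", "b"])
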