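"""Unit and property tests for the conditional-independence test engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cisel import (
    CITester,
    TargetSpec,
    TestConfig,
    dispatch,
    fisher_z_test,
    gen_glm,
    log_pval_chisq,
    lrt_test,
    perm_test,
    spearman_test,
    wald_test,
)
from cisel.ci_tests import CollinearityWarning


class TestLogPvalChisq:
    def test_zero_statistic_gives_log_one(self):
        for df in (1, 2, 5):
            assert log_pval_chisq(0.0, df) == 0.0

    @pytest.mark.parametrize("stat,df", [(-1.0, 1), (1.0, 0)])
    def test_invalid_arguments(self, stat, df):
        with pytest.raises(ValueError):
            log_pval_chisq(stat, df)

    def test_no_underflow_for_huge_statistics(self):
        lp = log_pval_chisq(1e4, 1)
        assert np.isfinite(lp) and lp < -4000

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        stat=st.floats(0, 1e4, allow_nan=False),
        df=st.integers(1, 20),
    )
    def test_is_a_log_probability(self, stat, df):
        lp = log_pval_chisq(stat, df)
        assert lp <= 0.0
        assert 0.0 <= np.exp(lp) <= 1.0


class TestFisherZ:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_partial_correlation_matches_residual_regression(self, seed):
        """Partial corr of (y, x) given Z equals the Pearson correlation of
        the residuals of y ~ Z and x ~ Z."""
        rng = np.random.default_rng(seed)
        n = 50
        X = rng.standard_normal((n, 5))
        y = X[:, 0] + rng.standard_normal(n)
        res = fisher_z_test(y, 1, (0, 2, 3), X)

        M = np.column_stack([np.ones(n), X[:, [0, 2, 3]]])
        ry = y - M @ np.linalg.lstsq(M, y, rcond=None)[0]
        rx = X[:, 1] - M @ np.linalg.lstsq(M, X[:, 1], rcond=None)[0]
        r = np.corrcoef(ry, rx)[0, 1]
        expected = np.sqrt(n - 3 - 3) * abs(np.arctanh(r))
        assert res.stat == pytest.approx(expected, abs=1e-10)

    def test_empty_cond_reduces_to_marginal_pearson(self, rng):
        n = 120
        X = rng.standard_normal((n, 3))
        y = 0.5 * X[:, 0] + rng.standard_normal(n)
        res = fisher_z_test(y, 0, (), X)
        r = np.corrcoef(y, X[:, 0])[0, 1]
        assert res.stat == pytest.approx(np.sqrt(n - 3) * abs(np.arctanh(r)), abs=1e-10)
        assert res.logp == pytest.approx(
            np.log(2) + stats.norm.logsf(res.stat), abs=1e-12
        )

    def test_exact_collinearity_underflows_with_warning(self, rng):
        X = rng.standard_normal((40, 2))
        y = 2.0 * X[:, 0]
        with pytest.warns(CollinearityWarning):
            res = fisher_z_test(y, 0, (), X)
        assert res.logp == -np.inf

    def test_insufficient_sample_size_raises(self, rng):
        X = rng.standard_normal((5, 4))
        with pytest.raises(ValueError, match="n >"):
            fisher_z_test(X[:, 3], 0, (1, 2), X)


class TestSpearman:
    def test_monotone_transform_is_perfect_rank_correlation(self, rng):
        x = rng.standard_normal(60)
        X = np.column_stack([x, rng.standard_normal(60)])
        y = np.exp(x)  # strictly monotone in x
        with pytest.warns(CollinearityWarning):
            res = spearman_test(y, 0, (), X)
        assert res.logp == -np.inf

    def test_marginal_agrees_with_direct_rank_correlation(self, rng):
        n = 150
        X = rng.standard_normal((n, 2))
        y = 0.4 * X[:, 0] + rng.standard_normal(n)
        res = spearman_test(y, 0, (), X)
        rho = stats.spearmanr(y, X[:, 0]).statistic
        assert res.stat == pytest.approx(np.sqrt(n - 3) * abs(np.arctanh(rho)), abs=1e-8)

    def test_duplicated_column_gives_identical_result(self, rng):
        n = 80
        x = np.round(rng.standard_normal(n), 1)  # induce ties -> midranks
        X = np.column_stack([x, x, rng.standard_normal(n)])
        y = 0.5 * x + rng.standard_normal(n)
        a = spearman_test(y, 0, (2,), X)
        b = spearman_test(y, 1, (2,), X)
        assert a.stat == b.stat and a.logp == b.logp


class TestLRT:
    def test_duplicate_of_conditioning_member_adds_nothing(self, rng):
        """A feature identical to one already conditioned on cannot improve
        the fit: the nested models are the same."""
        n = 200
        x = rng.standard_normal(n)
        X = np.column_stack([x, x.copy(), rng.standard_normal(n)])
        y = (rng.random(n) < 1 / (1 + np.exp(-x))).astype(float)
        t = TargetSpec(y, "binary")
        res = lrt_test(t, 1, (0,), X, "testIndLogistic")
        assert res.stat == pytest.approx(0.0, abs=1e-5)
        assert res.logp == pytest.approx(0.0, abs=1e-4)

    def test_binary_2x2_matches_g2_statistic(self):
        """Logistic LRT with one binary feature equals the G^2
        (likelihood-ratio) statistic of the 2x2 contingency table."""
        counts = {(0, 0): 30, (0, 1): 10, (1, 0): 15, (1, 1): 25}
        x, y = [], []
        for (xi, yi), c in counts.items():
            x += [xi] * c
            y += [yi] * c
        x, y = np.array(x, float), np.array(y, float)
        n = y.size
        g2 = 0.0
        for xi in (0, 1):
            for yi in (0, 1):
                obs = counts[(xi, yi)]
                exp = (x == xi).sum() * (y == yi).sum() / n
                g2 += 2 * obs * np.log(obs / exp)
        t = TargetSpec(y, "binary")
        res = lrt_test(t, 0, (), x[:, None], "testIndLogistic")
        assert res.stat == pytest.approx(g2, rel=1e-6)
        assert res.df == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_poisson_true_effect_is_detected(self, seed):
        ds = gen_glm(500, 3, family="poisson", n_active=1, beta=1.0, seed=seed)
        res = lrt_test(ds.target, int(ds.active[0]), (), ds.X, "testIndPois")
        assert res.logp < np.log(0.001)

    def test_cox_marginal_agrees_with_lifelines_llr(self, rng):
        """Dual route: our Cox LRT (closed-form Efron null) against the
        likelihood-ratio test lifelines computes internally."""
        from lifelines import CoxPHFitter
        import pandas as pd

        n = 150
        x = rng.standard_normal(n)
        T = rng.exponential(np.exp(-0.6 * x))
        C = rng.exponential(1.2, n)
        time = np.minimum(T, C)
        ev = (T <= C).astype(int)
        t = TargetSpec(np.maximum(time, 1e-9), "survival", status=ev)
        res = lrt_test(t, 0, (), x[:, None], "censIndCR")
        cph = CoxPHFitter().fit(
            pd.DataFrame({"T": t.values, "E": ev, "x": x}), "T", "E"
        )
        assert res.stat == pytest.approx(
            cph.log_likelihood_ratio_test().test_statistic, rel=1e-8
        )

    def test_quasi_poisson_deflates_significance_under_overdispersion(self):
        ds = gen_glm(400, 4, family="negbin", n_active=1, beta=0.4,
                     dispersion=1.0, seed=3)
        f = int(ds.active[0])
        pois = lrt_test(ds.target, f, (), ds.X, "testIndPois")
        qpois = lrt_test(ds.target, f, (), ds.X, "testIndQPois")
        assert qpois.logp > pois.logp  # less significant


class TestWald:
    def test_agreement_with_lrt_improves_with_n(self):
        """Under a local alternative (beta ~ 1/sqrt(n), so the statistic
        stays O(1)) the Wald and LRT statistics converge."""
        diffs = []
        for n in (100, 1000, 10000):
            ds = gen_glm(n, 3, family="binomial", n_active=1,
                         beta=8.0 / np.sqrt(n), seed=7)
            f = int(ds.active[0])
            lr = lrt_test(ds.target, f, (), ds.X, "testIndLogistic")
            wd = wald_test(ds.target, f, (), ds.X, "testIndLogistic")
            diffs.append(abs(wd.stat / max(lr.stat, 1e-12) - 1.0))
        assert diffs[2] < diffs[1] < diffs[0]
        assert diffs[2] < 0.02

    def test_constant_feature_is_rejected(self, rng):
        X = np.column_stack([np.ones(50), rng.standard_normal(50)])
        t = TargetSpec((rng.random(50) < 0.5).astype(float), "binary")
        with pytest.warns(UserWarning, match="constant"):
            tester = CITester(t, X, TestConfig("testIndLogistic", flavor="wald"))
        with pytest.raises(ValueError, match="constant"):
            tester(0, ())

    def test_gaussian_family_wald_equals_fisher_z(self, gaussian_ds):
        """For the correlation engine the Wald flavor is the same z-test."""
        f = int(gaussian_ds.active[0])
        lr = CITester(gaussian_ds.target, gaussian_ds.X, TestConfig("testIndFisher"))(f, ())
        wd = CITester(
            gaussian_ds.target, gaussian_ds.X,
            TestConfig("testIndFisher", flavor="wald"),
        )(f, ())
        assert lr.stat == wd.stat and lr.logp == wd.logp


class TestPermutation:
    def test_p_floor_and_determinism(self, gaussian_ds):
        f = int(gaussian_ds.active[0])
        a = perm_test(gaussian_ds.target, f, (), gaussian_ds.X,
                      "testIndFisher", B=99, seed=5)
        b = perm_test(gaussian_ds.target, f, (), gaussian_ds.X,
                      "testIndFisher", B=99, seed=5)
        assert a.logp == b.logp
        assert a.logp >= np.log(1.0 / 100) - 1e-12

    def test_null_pvalues_are_uniform(self):
        """KS distance of 500 null permutation p-values from U(0,1)."""
        pvals = []
        for s in range(500):
            rng = np.random.default_rng(9000 + s)
            X = rng.standard_normal((60, 1))
            y = rng.standard_normal(60)
            res = perm_test(TargetSpec(y, "continuous"), 0, (), X,
                            "testIndFisher", B=199, seed=s)
            pvals.append(np.exp(res.logp))
        ks = stats.kstest(pvals, "uniform").statistic
        assert ks < 0.1

    def test_glm_permutation_runs(self, rng):
        ds = gen_glm(80, 2, family="poisson", n_active=1, beta=0.8, seed=2)
        res = perm_test(ds.target, int(ds.active[0]), (), ds.X,
                        "testIndPois", B=39, seed=1)
        assert res.logp < np.log(0.05)


class TestDispatch:
    def test_known_names(self):
        assert dispatch("censIndCR") == "cox"
        assert dispatch("testIndFisher") == "fisher"
        assert dispatch("testIndQPois") == "qpoisson"

    def test_unknown_name_lists_supported(self):
        with pytest.raises(ValueError, match="supported tests"):
            dispatch("testIndBogus")

    def test_out_of_scope_name_is_named(self):
        with pytest.raises(ValueError, match="longitudinal"):
            dispatch("testIndGLMMReg")

    def test_incompatible_target_kind(self, null_target, rng):
        with pytest.raises(ValueError, match="requires a binary"):
            CITester(null_target, rng.standard_normal((200, 2)),
                     TestConfig("testIndLogistic"))

    def test_permutation_config_needs_positive_B(self):
        with pytest.raises(ValueError, match="B >= 1"):
            TestConfig("testIndFisher", flavor="permutation", B=0)
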