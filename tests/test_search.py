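"""Tests for the constraint-based and stepwise search algorithms."""

from itertools import combinations

import numpy as np
import pytest

from cisel import (
    AlgoConfig,
    CITester,
    NotExcluded,
    TargetSpec,
    TestCache,
    TestConfig,
    backward_selection,
    certificate_of_exclusion,
    fbed,
    forward_selection,
    gen_equivalent,
    gen_glm,
    iamb,
    mmmb,
    mmpc,
    mmpc_path,
    ses,
    univariate_screen,
)

LN05 = np.log(0.05)


def _result_fields(res):
    return (res.selected, res.stats, res.logps, res.n_tests, res.per_k_info)


class TestMMPC:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_max_k_zero_equals_univariate_filter(self, seed):
        ds = gen_glm(200, 30, n_active=3, beta=0.8, seed=seed)
        uni = univariate_screen(ds.target, ds.X)
        expected = {j for j in range(30) if uni.logps[j] < LN05}
        res = mmpc(ds.target, ds.X, AlgoConfig(max_k=0))
        assert set(res.selected) == expected

    def test_recovers_parent_set_and_matches_exhaustive_search(self):
        """On a well-separated 8-feature linear system the selected set is
        the parent set, and the dropped/kept split agrees with exhaustive
        conditional-independence search over all subsets of the selection."""
        rng = np.random.default_rng(42)
        n = 1000
        X = rng.standard_normal((n, 8))
        X[:, 5] = 0.8 * X[:, 0] + 0.6 * rng.standard_normal(n)  # child of 0
        X[:, 6] = 0.8 * X[:, 1] + 0.6 * rng.standard_normal(n)  # child of 1
        y = X[:, 0] + X[:, 1] + X[:, 2] + rng.standard_normal(n)
        t = TargetSpec(y, "continuous")
        tester = CITester(t, X, TestConfig("testIndFisher"))
        res = mmpc(t, X, AlgoConfig(max_k=7), tester=tester)
        assert sorted(res.selected) == [0, 1, 2]
        for f in range(8):
            pool = [c for c in res.selected if c != f]
            exhaustively_excluded = any(
                tester(f, Z).logp >= LN05
                for size in range(len(pool) + 1)
                for Z in combinations(pool, size)
            )
            assert (f in res.certificates) == exhaustively_excluded

    def test_cache_on_off_results_identical(self, gaussian_ds):
        t, X = gaussian_ds.target, gaussian_ds.X
        res_nc = mmpc(t, X, AlgoConfig())
        res_c = mmpc(t, X, AlgoConfig(), cache=TestCache())
        assert _result_fields(res_nc) == _result_fields(res_c)
        assert res_nc.to_json() == res_c.to_json()
        # replaying against a warm cache is also identical
        cache = TestCache()
        first = mmpc(t, X, AlgoConfig(), cache=cache)
        second = mmpc(t, X, AlgoConfig(), cache=cache)
        assert _result_fields(first) == _result_fields(second)
        assert cache.hits > 0

    def test_univariate_reuse_saves_exactly_p_tests(self, gaussian_ds):
        t, X = gaussian_ds.target, gaussian_ds.X
        uni = univariate_screen(t, X)
        full = mmpc(t, X, AlgoConfig())
        reused = mmpc(t, X, AlgoConfig(), univariate=uni)
        assert reused.selected == full.selected
        assert full.n_tests - reused.n_tests == X.shape[1]

    def test_mismatched_univariate_scores_are_recomputed(self, gaussian_ds):
        t, X = gaussian_ds.target, gaussian_ds.X
        uni = univariate_screen(t, X, test="testIndSpearman")
        res = mmpc(t, X, AlgoConfig(), test="testIndFisher", univariate=uni)
        full = mmpc(t, X, AlgoConfig(), test="testIndFisher")
        assert res.n_tests == full.n_tests

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            AlgoConfig(threshold=1.5)
        with pytest.raises(ValueError):
            AlgoConfig(max_k=-1)
        with pytest.raises(ValueError):
            AlgoConfig(K=-2)


class TestCertificates:
    def test_replay_reproduces_logp_exactly(self, gaussian_ds):
        t, X = gaussian_ds.target, gaussian_ds.X
        res = mmpc(t, X, AlgoConfig())
        fresh = CITester(t, X, TestConfig("testIndFisher"))
        dropped = sorted(res.certificates)
        assert dropped, "expected some dropped features"
        for cert in certificate_of_exclusion(res, dropped):
            replay = fresh(cert.feature, cert.cond_set)
            assert replay.logp == cert.logp
            assert replay.stat == cert.stat
            assert cert.logp >= LN05

    def test_selected_features_are_not_excluded(self, gaussian_ds):
        res = mmpc(gaussian_ds.target, gaussian_ds.X, AlgoConfig())
        [marker] = certificate_of_exclusion(res, [res.selected[0]])
        assert isinstance(marker, NotExcluded)

    def test_max_k_zero_certificates_cite_empty_subset(self, gaussian_ds):
        res = mmpc(gaussian_ds.target, gaussian_ds.X, AlgoConfig(max_k=0))
        assert res.certificates
        assert all(c.cond_set == () for c in res.certificates.values())


class TestSES:
    def test_no_equivalences_single_signature(self, gaussian_ds):
        base, sig = ses(gaussian_ds.target, gaussian_ds.X, AlgoConfig())
        assert sig.n_signatures == 1
        assert list(sig.signatures[0]) == base.selected

    def test_exact_duplicate_yields_extra_signature_with_equal_deviance(self):
        ds = gen_glm(300, 15, n_active=3, beta=1.0, seed=5)
        slot = int(ds.active[0])
        dup = gen_equivalent(ds, slot, n_copies=1, noise_sd=0.0)
        base, sig = ses(dup.target, dup.X, AlgoConfig())
        assert sig.n_signatures >= 2
        # swapping the duplicate for the original leaves the fit unchanged
        y = dup.target.values
        devs = []
        for row in sig.signatures[:2]:
            Z = np.column_stack([np.ones(dup.n), dup.X[:, list(row)]])
            resid = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
            devs.append(resid @ resid)
        assert abs(devs[0] - devs[1]) < 1e-8

    @pytest.mark.parametrize("seed", range(5))
    def test_noisy_twin_lands_in_an_equivalence_class(self, seed):
        ds = gen_glm(300, 10, n_active=2, beta=1.0, seed=seed)
        slot = int(ds.active[0])
        # correlation ~0.999 with the planted column
        twin = gen_equivalent(ds, slot, n_copies=1, noise_sd=0.045, seed=seed)
        _, sig = ses(twin.target, twin.X, AlgoConfig())
        members = {v for cls in sig.equivalence_classes for v in cls}
        assert twin.p - 1 in members or sig.n_signatures >= 2


class TestMMMB:
    def test_output_contains_mmpc_selection(self):
        for seed in range(3):
            ds = gen_glm(250, 12, n_active=3, beta=0.9, seed=seed)
            pc = mmpc(ds.target, ds.X, AlgoConfig())
            mb = mmmb(ds.target, ds.X, AlgoConfig())
            assert set(pc.selected) <= set(mb.selected)

    def test_spouse_recovery_through_common_child(self):
        """y <- A; child C = y + S; the spouse S is invisible marginally
        but becomes dependent given the child."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(500 + seed)
            n = 800
            A = rng.standard_normal(n)
            S = rng.standard_normal(n)
            y = A + rng.standard_normal(n) * 0.8
            C = y + S + 0.3 * rng.standard_normal(n)
            X = np.column_stack([A, S, C, rng.standard_normal((n, 3))])
            t = TargetSpec(y, "continuous")
            mb = mmmb(t, X, AlgoConfig())
            if 1 in mb.selected:  # the spouse
                hits += 1
        assert hits >= 8


class TestStepwise:
    def test_forward_on_orthonormal_design_ranks_by_marginal_correlation(self):
        rng = np.random.default_rng(8)
        Q, _ = np.linalg.qr(rng.standard_normal((64, 10)))
        beta = np.zeros(10)
        beta[[1, 4, 7]] = [6, 4, 2]
        y = Q @ beta + 0.2 * rng.standard_normal(64)
        t = TargetSpec(y, "continuous")
        res = forward_selection(t, Q, AlgoConfig())
        order = np.argsort(-np.abs(Q.T @ (y - y.mean())))
        assert res.selected[: len(res.selected)] == list(order[: len(res.selected)])
        assert set([1, 4, 7]) <= set(res.selected)

    def test_forward_empty_on_pure_noise(self, rng):
        X = rng.standard_normal((300, 3))
        y = rng.standard_normal(300)
        res = forward_selection(TargetSpec(y, "continuous"), X, AlgoConfig(threshold=0.01))
        assert len(res.selected) <= 1  # at most a borderline admission

    @pytest.mark.parametrize("seed", range(3))
    def test_backward_keeps_all_true_features(self, seed):
        ds = gen_glm(1000, 6, n_active=6, beta=1.0, seed=seed)
        res = backward_selection(ds.target, ds.X, AlgoConfig())
        assert sorted(res.selected) == list(range(6))

    def test_iamb_final_members_all_significant_given_rest(self, gaussian_ds):
        t, X = gaussian_ds.target, gaussian_ds.X
        res = iamb(t, X, AlgoConfig())
        tester = CITester(t, X, TestConfig("testIndFisher"))
        for s in res.selected:
            others = tuple(c for c in res.selected if c != s)
            assert tester(s, others).logp < LN05

    def test_iamb_sweeps_out_redundant_copies(self):
        ds = gen_glm(400, 8, n_active=2, beta=1.0, seed=9)
        dup = gen_equivalent(ds, int(ds.active[0]), n_copies=2, noise_sd=0.0)
        res = iamb(dup.target, dup.X, AlgoConfig())
        dup_cols = {dup.p - 1, dup.p - 2, int(ds.active[0])}
        assert len(dup_cols & set(res.selected)) <= 1


class TestFBED:
    def test_selected_non_decreasing_in_K(self, gaussian_ds):
        t, X = gaussian_ds.target, gaussian_ds.X
        sets = [
            set(fbed(t, X, AlgoConfig(K=k)).selected) for k in (0, 1, 2)
        ]
        assert sets[0] <= sets[1] <= sets[2]

    def test_n_tests_lower_bound(self, gaussian_ds):
        res = fbed(gaussian_ds.target, gaussian_ds.X, AlgoConfig())
        assert res.n_tests >= gaussian_ds.p + len(res.selected)

    def test_vector_K_reports_per_k_info(self, gaussian_ds):
        res = fbed(gaussian_ds.target, gaussian_ds.X, AlgoConfig(K=[0, 1]))
        assert [row[0] for row in res.per_k_info] == [0, 1]
        assert all(row[1] >= 0 and row[2] > 0 for row in res.per_k_info)
        table = res.info_table()
        assert list(table.columns) == ["Number of vars", "Number of tests"]
        assert list(table.index) == ["K=0", "K=1"]

    def test_res_table_lists_features_in_admission_order(self, gaussian_ds):
        res = fbed(gaussian_ds.target, gaussian_ds.X, AlgoConfig())
        table = res.res_table()
        assert list(table.columns) == ["sel", "stat", "pval"]
        assert list(table["sel"]) == res.selected

    def test_univariate_reuse_saves_exactly_p_tests(self, gaussian_ds):
        t, X = gaussian_ds.target, gaussian_ds.X
        uni = univariate_screen(t, X)
        full = fbed(t, X, AlgoConfig())
        reused = fbed(t, X, AlgoConfig(), univariate=uni)
        assert reused.selected == full.selected
        assert full.n_tests - reused.n_tests == X.shape[1]

    def test_ebic_stop_rule_recovers_planted_features(self):
        ds = gen_glm(400, 20, n_active=3, beta=1.0, seed=13)
        res = fbed(ds.target, ds.X, AlgoConfig(stop_rule="ebic", ebic_gamma=0.5))
        assert sorted(res.selected) == list(ds.active)


class TestMMPCPath:
    def test_single_cell_equals_plain_mmpc(self, gaussian_ds):
        t, X = gaussian_ds.target, gaussian_ds.X
        path = mmpc_path(t, X, [0.05], [3])
        plain = mmpc(t, X, AlgoConfig(threshold=0.05, max_k=3))
        assert path.results[(0.05, 3)].selected == plain.selected

    def test_grid_shares_cache(self, gaussian_ds):
        t, X = gaussian_ds.target, gaussian_ds.X
        path = mmpc_path(t, X, [0.05, 0.01], [2, 3])
        assert len(path.results) == 4
        assert path.tests_saved > 0

    def test_threshold_monotonicity_at_max_k_zero(self, gaussian_ds):
        t, X = gaussian_ds.target, gaussian_ds.X
        path = mmpc_path(t, X, [0.10, 0.01], [0])
        loose = set(path.results[(0.10, 0)].selected)
        strict = set(path.results[(0.01, 0)].selected)
        assert strict <= loose
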