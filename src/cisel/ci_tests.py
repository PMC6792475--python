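"""Conditional-independence tests ind(Y, X | Z) for diverse outcome types.

The engine answers one question: is feature X independent of the target Y
once the features in Z are accounted for?  For continuous targets this is
the Fisher z-test on the partial correlation (or its Spearman rank
variant); for all other outcome types it is a nested-model comparison in
the matching regression family -- logistic, multinomial, Poisson,
quasi-Poisson, negative binomial, Cox or Weibull -- as a likelihood-ratio
test, a Wald test, or a permutation test that re-randomises the X column.

Every test reports its p-value on the natural-log scale (``logp``), so
that significance comparisons remain exact far below the point where a raw
p-value would underflow to zero.  Test names follow the string identifiers
commonly used for these tests (``testIndFisher``, ``censIndCR``, ...), so
configurations are portable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .families import FitError, FitResult, fit_family
from .results import CITestResult
from .targets import TargetSpec

_LN2 = float(np.log(2.0))

#: test identifier -> (engine family, compatible target kind)
TEST_FAMILIES = {
    "testIndFisher": ("fisher", "continuous"),
    "testIndSpearman": ("spearman", "continuous"),
    "testIndLogistic": ("binary", "binary"),
    "testIndMultinom": ("nominal", "nominal"),
    "testIndPois": ("poisson", "counts"),
    "testIndQPois": ("qpoisson", "counts"),
    "testIndNB": ("negbin", "counts"),
    "censIndCR": ("cox", "survival"),
    "censIndWR": ("weibull", "survival"),
}

#: recognised identifiers from the wider test family that this package
#: deliberately does not implement
_UNSUPPORTED = {
    "testIndGLMMReg": "clustered/longitudinal targets (generalised linear mixed models)",
    "testIndGEEReg": "clustered/longitudinal targets (generalised estimating equations)",
    "testIndOrdinal": "ordinal regression targets",
    "testIndBeta": "beta-regression (percentage) targets",
    "testIndTobit": "left-censored (Tobit) targets",
    "testIndZIP": "zero-inflated Poisson targets",
    "testIndClogit": "matched case-control (conditional logistic) targets",
    "censIndER": "exponential survival regression",
}

FLAVORS = ("lrt", "wald", "permutation")


class CollinearityWarning(UserWarning):
    """Raised when a partial correlation is numerically +/-1."""


class ConvergenceWarning(UserWarning):
    """A model fit failed; the test is reported as non-significant."""


def dispatch(test_name: str) -> str:
    """Map a test identifier to its engine family.

    Unknown names raise with the list of supported identifiers; recognised
    but unimplemented names raise naming the out-of-scope capability.
    """
    if test_name in TEST_FAMILIES:
        return TEST_FAMILIES[test_name][0]
    if test_name in _UNSUPPORTED:
        raise ValueError(
            f"test {test_name!r} targets {_UNSUPPORTED[test_name]}, "
            "which this package does not support"
        )
    raise ValueError(
        f"unknown test {test_name!r}; supported tests: "
        + ", ".join(sorted(TEST_FAMILIES))
    )


def default_test_for(kind: str) -> str:
    """A sensible default test identifier for each target kind."""
    return {
        "continuous": "testIndFisher",
        "binary": "testIndLogistic",
        "nominal": "testIndMultinom",
        "counts": "testIndPois",
        "survival": "censIndCR",
    }[kind]


def log_pval_chisq(stat: float, df: int) -> float:
    """Natural-log upper-tail chi-square probability ln P(chi2_df > stat).

    Computed on the log scale, so it does not underflow even for
    statistics in the thousands (p-values below 1e-300).
    """
    if stat < 0:
        raise ValueError("chi-square statistic must be non-negative")
    if df < 1:
        raise ValueError("degrees of freedom must be a positive integer")
    lp = float(stats.chi2.logsf(stat, df))
    if np.isinf(lp) and stat > 0:
        # survival function underflowed; use the asymptotic expansion of the
        # upper incomplete gamma Q(a, z) ~ z^(a-1) e^-z / Gamma(a) * sum_k
        # prod_j (a-j) / z^k, excellent in the far tail where this happens
        from scipy.special import gammaln

        a, z = df / 2.0, stat / 2.0
        term, total = 1.0, 1.0
        for j in range(1, 60):
            term *= (a - j) / z
            if abs(term) < 1e-18:
                break
            total += term
        lp = (a - 1.0) * np.log(z) - z - float(gammaln(a)) + np.log(abs(total))
    return lp


@dataclass(frozen=True)
class TestConfig:
    """Configuration of a conditional-independence test."""

    test_name: str = "testIndFisher"
    flavor: str = "lrt"
    B: int = 999
    seed: int | None = None

    def __post_init__(self):
        dispatch(self.test_name)
        if self.flavor not in FLAVORS:
            raise ValueError(f"flavor must be one of {FLAVORS}")
        if self.flavor == "permutation" and self.B < 1:
            raise ValueError("permutation tests require B >= 1")


@dataclass
class TestCache:
    """Memo of completed tests keyed by (feature, conditioning set).

    Replaying a cached query returns a result identical to recomputation,
    so algorithm output is byte-identical with caching on or off.
    """

    store: dict = field(default_factory=dict)
    hits: int = 0
    misses: int = 0

    def get(self, key):
        res = self.store.get(key)
        if res is None:
            self.misses += 1
        else:
            self.hits += 1
        return res

    def put(self, key, result):
        self.store[key] = result


class CITester:
    """Binds a target, a feature matrix and a test configuration.

    Parameters
    ----------
    target : TargetSpec
    X : ndarray, shape (n, p)
        Numeric feature matrix.  Columns listed in ``categorical`` are
        treated as label-encoded categorical features and enter regression
        designs as reference-cell dummies (reference = smallest label).
    config : TestConfig
    cache : TestCache, optional
        Shared across runs to avoid recomputing identical tests.

    Constant (zero-variance) columns are excluded up front with a warning;
    testing one raises.
    """

    def __init__(
        self,
        target: TargetSpec,
        X: np.ndarray,
        config: TestConfig | str = "testIndFisher",
        cache: TestCache | None = None,
        categorical: set[int] | frozenset[int] = frozenset(),
    ):
        if isinstance(config, str):
            config = TestConfig(test_name=config)
        self.config = config
        self.family = dispatch(config.test_name)
        kind_needed = TEST_FAMILIES[config.test_name][1]
        if target.kind != kind_needed:
            raise ValueError(
                f"test {config.test_name!r} requires a {kind_needed} target, "
                f"got {target.kind}"
            )
        self.target = target
        self.X = np.asarray(X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != target.n:
            raise ValueError("X must be (n, p) with n matching the target")
        self.n, self.p = self.X.shape
        self.categorical = frozenset(categorical)
        if self.categorical and self.family in ("fisher", "spearman"):
            raise ValueError("correlation tests do not accept categorical features")

        sd = self.X.std(axis=0)
        self.excluded = frozenset(np.flatnonzero(sd == 0).tolist())
        if self.excluded:
            warnings.warn(
                f"excluding {len(self.excluded)} constant feature column(s): "
                f"{sorted(self.excluded)}",
                UserWarning,
                stacklevel=2,
            )

        if self.family == "spearman":
            self._work_y = stats.rankdata(target.values)
            self._work_X = np.apply_along_axis(stats.rankdata, 0, self.X)
        elif self.family == "fisher":
            self._work_y = target.values.astype(float)
            self._work_X = self.X
        else:
            self._work_y = None
            self._work_X = self.X

        self.cache = cache
        self.n_tests = 0
        self._ll_cache: dict[tuple[int, ...], FitResult] = {}

    # -- public API ---------------------------------------------------------

    @property
    def usable_features(self) -> list[int]:
        return [j for j in range(self.p) if j not in self.excluded]

    def __call__(self, feature: int, cond=()) -> CITestResult:
        """Test ind(Y, X_feature | X_cond)."""
        cond = tuple(sorted(int(c) for c in cond))
        feature = int(feature)
        if feature in cond:
            raise ValueError("feature cannot be a member of its conditioning set")
        if feature in self.excluded:
            raise ValueError(f"feature {feature} is constant")
        self.n_tests += 1
        key = (self.config.test_name, self.config.flavor, feature, cond)
        if self.cache is not None:
            hit = self.cache.get(key)
            if hit is not None:
                return hit
        res = self._compute(feature, cond)
        if self.cache is not None:
            self.cache.put(key, res)
        return res

    def test_all(self, features, cond=()) -> list[CITestResult]:
        """Test every feature in ``features`` against the same conditioning
        set; vectorised for the correlation families."""
        cond = tuple(sorted(int(c) for c in cond))
        features = [int(f) for f in features]
        if (
            self.family in ("fisher", "spearman")
            and self.config.flavor != "permutation"
        ):
            self.n_tests += len(features)
            out = {}
            cached = {}
            if self.cache is not None:
                for f in features:
                    hit = self.cache.get(
                        (self.config.test_name, self.config.flavor, f, cond)
                    )
                    if hit is not None:
                        cached[f] = hit
            todo = [f for f in features if f not in cached]
            if todo:
                stats_, logps = self._corr_batch(todo, cond)
                for f, st, lp in zip(todo, stats_, logps):
                    res = CITestResult(
                        stat=float(st), df=1, logp=float(lp),
                        feature=f, cond_set=cond,
                    )
                    out[f] = res
                    if self.cache is not None:
                        self.cache.put(
                            (self.config.test_name, self.config.flavor, f, cond), res
                        )
            out.update(cached)
            return [out[f] for f in features]
        return [self(f, cond) for f in features]

    def model_ll(self, cols) -> tuple[float, int]:
        """Log-likelihood and parameter count of the model on ``cols``
        (for information-criterion stopping rules)."""
        if self.family in ("fisher", "spearman"):
            fam = "gaussian"
        elif self.family == "qpoisson":
            raise ValueError("quasi-Poisson has no likelihood; use an LRT stop rule")
        else:
            fam = self.family
        cols = tuple(sorted(int(c) for c in cols))
        fit = self._fit_cached(cols, fam)
        return fit.ll, fit.n_params

    # -- internals ----------------------------------------------------------

    def _design(self, cols) -> np.ndarray:
        blocks = []
        for c in cols:
            col = self.X[:, c]
            if c in self.categorical:
                levels = np.unique(col)
                for lev in levels[1:]:  # reference = first sorted level
                    blocks.append((col == lev).astype(float))
            else:
                blocks.append(col)
        if not blocks:
            return np.empty((self.n, 0))
        return np.column_stack(blocks)

    def _fit_cached(self, cond: tuple[int, ...], fam: str) -> FitResult:
        key = cond
        fit = self._ll_cache.get(key)
        if fit is None:
            fit = fit_family(fam, self.target, self._design(cond))
            self._ll_cache[key] = fit
        return fit

    def _compute(self, feature, cond) -> CITestResult:
        if self.config.flavor == "permutation":
            return self._perm(feature, cond)
        if self.family in ("fisher", "spearman"):
            st, lp = self._corr_batch([feature], cond)
            return CITestResult(
                stat=float(st[0]), df=1, logp=float(lp[0]),
                feature=feature, cond_set=cond,
            )
        if self.config.flavor == "wald":
            return self._wald(feature, cond)
        return self._lrt(feature, cond)

    # correlation machinery --------------------------------------------------

    def _corr_batch(self, features, cond, columns=None):
        """Partial-correlation Fisher-z statistics for many features at one
        conditioning set.  ``columns`` overrides the feature columns (used
        by the permutation flavor)."""
        n = self.n
        dof = n - len(cond) - 3
        if dof <= 0:
            raise ValueError(
                f"need n > |cond| + 3 for the Fisher z-test (n={n}, |cond|={len(cond)})"
            )
        M = np.column_stack([np.ones(n), self._work_X[:, list(cond)]])
        Q, _ = np.linalg.qr(M)
        ry = self._work_y - Q @ (Q.T @ self._work_y)
        F = columns if columns is not None else self._work_X[:, features]
        if F.ndim == 1:
            F = F[:, None]
        ny = np.linalg.norm(ry)
        # residualise one column at a time: identical arithmetic whether a
        # feature is tested alone or in a batch, so cached/certificate
        # replays reproduce statistics bit for bit
        m = F.shape[1]
        r = np.empty(m)
        nf = np.empty(m)
        for i in range(m):
            v = F[:, i]
            rv = v - Q @ (Q.T @ v)
            nf[i] = np.linalg.norm(rv)
            r[i] = float(ry @ rv) / (max(ny, 1e-300) * max(nf[i], 1e-300))
        # features exactly in the span of cond carry no extra information
        tiny = nf <= 1e-10 * np.linalg.norm(F, axis=0)
        r = np.where(tiny, 0.0, r)
        r = np.clip(r, -1.0, 1.0)
        exact = np.abs(r) >= 1.0 - 1e-12
        if exact.any():
            warnings.warn(
                "exact collinearity with the target: p-value underflows to 0",
                CollinearityWarning,
                stacklevel=3,
            )
        z = np.sqrt(dof) * np.abs(np.arctanh(np.clip(r, -1 + 1e-16, 1 - 1e-16)))
        logp = _LN2 + stats.norm.logsf(z)
        logp = np.where(exact, -np.inf, logp)
        logp = np.minimum(logp, 0.0)
        return z, logp

    # likelihood-ratio / Wald machinery --------------------------------------

    def _nonconvergent(self, feature, cond) -> CITestResult:
        warnings.warn(
            f"fit for feature {feature} | {cond} did not converge; "
            "treating as non-significant",
            ConvergenceWarning,
            stacklevel=3,
        )
        return CITestResult(stat=0.0, df=1, logp=0.0, feature=feature, cond_set=cond)

    def _lrt(self, feature, cond) -> CITestResult:
        fam = "poisson" if self.family == "qpoisson" else self.family
        try:
            f0 = self._fit_cached(cond, fam)
            f1 = fit_family(fam, self.target, self._design(cond + (feature,)))
        except FitError:
            return self._nonconvergent(feature, cond)
        df = f1.n_params - f0.n_params
        if df < 1:
            raise ValueError(f"feature {feature} adds no parameters to the model")
        stat = max(0.0, 2.0 * (f1.ll - f0.ll))
        if self.family == "qpoisson":
            return self._qpois_result(stat, df, f1, feature, cond)
        return CITestResult(
            stat=stat, df=df, logp=log_pval_chisq(stat, df),
            feature=feature, cond_set=cond,
        )

    def _qpois_result(self, chi2_stat, df, f1, feature, cond) -> CITestResult:
        # over-dispersion: scale by the Pearson dispersion of the larger
        # model and refer to F(df, n - k1)
        phi = max(f1.pearson_chi2 / f1.df_resid, 1e-10)
        fstat = (chi2_stat / df) / phi
        logp = float(stats.f.logsf(fstat, df, f1.df_resid))
        return CITestResult(
            stat=fstat, df=df, logp=min(logp, 0.0), feature=feature, cond_set=cond
        )

    def _wald(self, feature, cond) -> CITestResult:
        fam = "poisson" if self.family == "qpoisson" else self.family
        cols = cond + (feature,)
        d_x = self._design((feature,)).shape[1]
        if d_x == 0:
            raise ValueError(f"feature {feature} is constant")
        try:
            f1 = fit_family(fam, self.target, self._design(cols), need_cov=True)
        except FitError:
            return self._nonconvergent(feature, cond)
        if f1.coef is None or f1.coef_cov is None:
            return self._nonconvergent(feature, cond)
        d_all = sum(self._design((c,)).shape[1] for c in cols)
        d_pre = d_all - d_x
        if fam == "nominal":
            C1 = self.target.n_classes - 1
            idx = np.concatenate(
                [np.arange(d_pre, d_all) + c * d_all for c in range(C1)]
            )
        else:
            idx = np.arange(d_pre, d_all)
        b = f1.coef[idx]
        V = f1.coef_cov[np.ix_(idx, idx)]
        try:
            stat = float(b @ np.linalg.solve(V, b))
        except np.linalg.LinAlgError:
            stat = float(b @ np.linalg.pinv(V) @ b)
        stat = max(stat, 0.0)
        df = idx.size
        if self.family == "qpoisson":
            phi = max(f1.pearson_chi2 / f1.df_resid, 1e-10)
            fstat = (stat / df) / phi
            logp = float(stats.f.logsf(fstat, df, f1.df_resid))
            return CITestResult(
                stat=fstat, df=df, logp=min(logp, 0.0),
                feature=feature, cond_set=cond,
            )
        return CITestResult(
            stat=stat, df=df, logp=log_pval_chisq(stat, df),
            feature=feature, cond_set=cond,
        )

    # permutation machinery ---------------------------------------------------

    def _base_stat(self, feature, cond, column=None) -> float:
        """Observed (or permuted-column) base statistic for the permutation
        flavor; the base test is the LRT variant of the configured family."""
        if column is None:
            column = self.X[:, feature]
        if self.family in ("fisher", "spearman"):
            col = stats.rankdata(column) if self.family == "spearman" else column
            st, _ = self._corr_batch([feature], cond, columns=col[:, None])
            return float(st[0])
        fam = "poisson" if self.family == "qpoisson" else self.family
        f0 = self._fit_cached(cond, fam)
        M1 = np.column_stack([self._design(cond), column]) if cond else column[:, None]
        try:
            f1 = fit_family(fam, self.target, M1)
        except FitError:
            return 0.0
        stat = max(0.0, 2.0 * (f1.ll - f0.ll))
        if self.family == "qpoisson":
            df = f1.n_params - f0.n_params
            phi = max(f1.pearson_chi2 / f1.df_resid, 1e-10)
            stat = (stat / df) / phi
        return stat

    def _perm(self, feature, cond) -> CITestResult:
        B = self.config.B
        seed = 0 if self.config.seed is None else self.config.seed
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(feature, len(cond), hash(cond) & 0x7FFFFFFF))
        )
        col = self.X[:, feature]
        observed = self._base_stat(feature, cond)
        if self.family in ("fisher", "spearman"):
            work = self._work_X[:, feature]
            P = np.column_stack([rng.permutation(work) for _ in range(B)])
            perm_stats, _ = self._corr_batch([feature] * B, cond, columns=P)
        else:
            perm_stats = np.empty(B)
            for b in range(B):
                perm_stats[b] = self._base_stat(feature, cond, rng.permutation(col))
        exceed = int((perm_stats >= observed - 1e-12).sum())
        p = (1.0 + exceed) / (B + 1.0)
        return CITestResult(
            stat=float(observed), df=1, logp=float(np.log(p)),
            feature=feature, cond_set=cond,
        )


# ---------------------------------------------------------------------------
# functional wrappers

def fisher_z_test(y, x, cond, X) -> CITestResult:
    """Fisher z-test of the partial correlation of a continuous target
    with column ``x`` of ``X`` given the columns in ``cond``."""
    t = y if isinstance(y, TargetSpec) else TargetSpec(np.asarray(y, float), "continuous")
    return CITester(t, X, TestConfig("testIndFisher"))(x, cond)


def spearman_test(y, x, cond, X) -> CITestResult:
    """Rank (Spearman) variant of :func:`fisher_z_test` using midranks."""
    t = y if isinstance(y, TargetSpec) else TargetSpec(np.asarray(y, float), "continuous")
    return CITester(t, X, TestConfig("testIndSpearman"))(x, cond)


def lrt_test(target: TargetSpec, x, cond, X, test_name: str) -> CITestResult:
    """Nested-model likelihood-ratio test in the family of ``test_name``."""
    return CITester(target, X, TestConfig(test_name, flavor="lrt"))(x, cond)


def wald_test(target: TargetSpec, x, cond, X, test_name: str) -> CITestResult:
    """Wald test on the coefficient block of ``x`` in the full fit."""
    return CITester(target, X, TestConfig(test_name, flavor="wald"))(x, cond)


def perm_test(
    target: TargetSpec, x, cond, X, test_name: str, B: int = 999, seed: int = 0
) -> CITestResult:
    """Permutation test: the ``x`` column is permuted B times and the
    base-test statistic recomputed; p = (1 + #{perm >= obs}) / (B + 1)."""
    return CITester(target, X, TestConfig(test_name, flavor="permutation", B=B, seed=seed))(x, cond)
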