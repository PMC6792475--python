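"""Regression-model backends, one per supported outcome family.

Every conditional-independence test in this package reduces to comparing
two nested fits of one of these families, so the fitting surface is kept
deliberately narrow: :func:`fit_family` takes a covariate matrix (without
an intercept column -- one is added where the family has one) and returns
the maximised log-likelihood, the parameter count and, on request, the
coefficient vector with its covariance (for Wald tests) and family-specific
residuals (for the greedy residual-pursuit algorithm).

Families
--------
gaussian    ordinary least squares (profiled error variance)
binary      logistic regression (GLM, binomial family)
poisson     Poisson log-linear regression (also the quasi-Poisson workhorse)
negbin      negative binomial (NB2) regression, shape profiled by ML
nominal     baseline-category multinomial logit
cox         Cox proportional hazards (Efron partial likelihood)
weibull     Weibull accelerated-failure-time model

Intercept-only fits are available in closed form for the gaussian, binary,
poisson and nominal families and for the Cox partial likelihood, which
keeps null-model evaluation cheap and free of optimiser noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .targets import TargetSpec

FAMILIES = ("gaussian", "binary", "poisson", "negbin", "nominal", "cox", "weibull")

FAMILY_FOR_KIND = {
    "continuous": ("gaussian",),
    "binary": ("binary",),
    "nominal": ("nominal",),
    "counts": ("poisson", "negbin"),
    "survival": ("cox", "weibull"),
}


class FitError(RuntimeError):
    """A model fit failed to converge even after the regularised retry."""


@dataclass
class FitResult:
    ll: float
    n_params: int
    converged: bool = True
    # coefficient block of the covariate columns (Wald tests); layout is
    # family specific and documented in `coef_block`
    coef: np.ndarray | None = None
    coef_cov: np.ndarray | None = None
    # family residuals (response scale; martingale for survival); for the
    # nominal family an (n, C) matrix of indicator-minus-probability rows
    resid: np.ndarray | None = None
    deviance: float | None = None
    pearson_chi2: float | None = None
    df_resid: int | None = None


def _as_matrix(M: np.ndarray | None, n: int) -> np.ndarray:
    if M is None:
        return np.empty((n, 0))
    M = np.asarray(M, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    return M


def fit_family(
    family: str,
    target: TargetSpec,
    M: np.ndarray | None,
    *,
    need_cov: bool = False,
    need_resid: bool = False,
) -> FitResult:
    """Fit one family on covariates ``M`` (n x d, no intercept column)."""
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
    M = _as_matrix(M, target.n)
    fitter = _FITTERS[family]
    return fitter(target, M, need_cov, need_resid)


# ---------------------------------------------------------------------------
# gaussian

def _fit_gaussian(target, M, need_cov, need_resid):
    y = target.values
    n = y.shape[0]
    Z = np.column_stack([np.ones(n), M])
    beta, _, rank, _ = np.linalg.lstsq(Z, y, rcond=None)
    resid = y - Z @ beta
    rss = float(resid @ resid)
    rss = max(rss, 1e-300)
    ll = -0.5 * n * (np.log(2 * np.pi * rss / n) + 1.0)
    out = FitResult(
        ll=ll,
        n_params=Z.shape[1] + 1,  # coefficients + error variance
        deviance=rss,
        df_resid=n - Z.shape[1],
    )
    if need_cov and M.shape[1]:
        sigma2 = rss / (n - Z.shape[1])
        XtX_inv = np.linalg.pinv(Z.T @ Z)
        out.coef = beta[1:]
        out.coef_cov = sigma2 * XtX_inv[1:, 1:]
    if need_resid:
        out.resid = resid
    return out


# ---------------------------------------------------------------------------
# GLM families (binary / poisson) via statsmodels

def _glm_fit(y, Z, sm_family):
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, Z, family=sm_family)
        try:
            res = model.fit(maxiter=100)
            if not np.isfinite(res.llf):
                raise ValueError("non-finite log-likelihood")
            return res, True
        except Exception:
            try:
                res = model.fit(maxiter=500, method="lbfgs")
                if np.isfinite(res.llf):
                    return res, True
            except Exception:
                pass
    return None, False


def _fit_binary(target, M, need_cov, need_resid):
    import statsmodels.api as sm

    y = target.codes.astype(float)
    n = y.shape[0]
    if M.shape[1] == 0:
        phat = y.mean()
        phat = min(max(phat, 1e-12), 1 - 1e-12)
        ll = float(y.sum() * np.log(phat) + (n - y.sum()) * np.log1p(-phat))
        mu = np.full(n, phat)
        return FitResult(
            ll=ll,
            n_params=1,
            deviance=-2.0 * ll,
            pearson_chi2=float(((y - mu) ** 2 / (mu * (1 - mu))).sum()),
            df_resid=n - 1,
            resid=(y - mu) if need_resid else None,
        )
    Z = np.column_stack([np.ones(n), M])
    res, ok = _glm_fit(y, Z, sm.families.Binomial())
    if not ok:
        raise FitError("logistic fit did not converge")
    out = FitResult(
        ll=float(res.llf),
        n_params=Z.shape[1],
        deviance=float(res.deviance),
        pearson_chi2=float(res.pearson_chi2),
        df_resid=int(res.df_resid),
    )
    if need_cov:
        cov = np.asarray(res.cov_params())
        out.coef = np.asarray(res.params)[1:]
        out.coef_cov = cov[1:, 1:]
    if need_resid:
        out.resid = y - np.asarray(res.fittedvalues)
    return out


def _fit_poisson(target, M, need_cov, need_resid):
    import statsmodels.api as sm

    y = target.values
    n = y.shape[0]
    if M.shape[1] == 0:
        mu = max(y.mean(), 1e-12)
        ll = float((y * np.log(mu) - mu - gammaln(y + 1)).sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            dev_terms = np.where(y > 0, y * np.log(y / mu) - (y - mu), mu)
        return FitResult(
            ll=ll,
            n_params=1,
            deviance=float(2.0 * dev_terms.sum()),
            pearson_chi2=float(((y - mu) ** 2 / mu).sum()),
            df_resid=n - 1,
            resid=(y - mu) if need_resid else None,
        )
    Z = np.column_stack([np.ones(n), M])
    res, ok = _glm_fit(y, Z, sm.families.Poisson())
    if not ok:
        raise FitError("Poisson fit did not converge")
    out = FitResult(
        ll=float(res.llf),
        n_params=Z.shape[1],
        deviance=float(res.deviance),
        pearson_chi2=float(res.pearson_chi2),
        df_resid=int(res.df_resid),
    )
    if need_cov:
        cov = np.asarray(res.cov_params())
        out.coef = np.asarray(res.params)[1:]
        out.coef_cov = cov[1:, 1:]
    if need_resid:
        out.resid = y - np.asarray(res.fittedvalues)
    return out


# ---------------------------------------------------------------------------
# negative binomial (NB2, shape profiled)

def _fit_negbin(target, M, need_cov, need_resid):
    from statsmodels.discrete.discrete_model import NegativeBinomial

    y = target.values
    n = y.shape[0]
    Z = np.column_stack([np.ones(n), M])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = NegativeBinomial(y, Z)
        res = None
        for kwargs in (
            {"method": "newton", "maxiter": 100},
            {"method": "bfgs", "maxiter": 500},
        ):
            try:
                cand = model.fit(disp=0, **kwargs)
                if np.isfinite(cand.llf):
                    res = cand
                    break
            except Exception:
                continue
    if res is None:
        raise FitError("negative binomial fit did not converge")
    out = FitResult(
        ll=float(res.llf),
        n_params=Z.shape[1] + 1,  # + shape parameter
        deviance=-2.0 * float(res.llf),
    )
    if need_cov and M.shape[1]:
        try:
            cov = np.asarray(res.cov_params())
            out.coef = np.asarray(res.params)[1 : Z.shape[1]]
            out.coef_cov = cov[1 : Z.shape[1], 1 : Z.shape[1]]
        except Exception:
            out.converged = False
    if need_resid:
        mu = np.exp(np.clip(Z @ np.asarray(res.params)[: Z.shape[1]], -700, 700))
        out.resid = y - mu
    return out


# ---------------------------------------------------------------------------
# nominal (multinomial logit)

def _fit_nominal(target, M, need_cov, need_resid):
    import statsmodels.api as sm

    codes = target.codes
    n = codes.shape[0]
    C = target.n_classes
    counts = np.bincount(codes, minlength=C).astype(float)
    if M.shape[1] == 0:
        probs = counts / n
        nz = counts > 0
        ll = float((counts[nz] * np.log(probs[nz])).sum())
        out = FitResult(ll=ll, n_params=C - 1, deviance=-2.0 * ll)
        if need_resid:
            ind = np.zeros((n, C))
            ind[np.arange(n), codes] = 1.0
            out.resid = ind - probs[None, :]
        return out
    Z = np.column_stack([np.ones(n), M])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MNLogit(codes, Z)
        res = None
        for kwargs in (
            {"method": "newton", "maxiter": 100},
            {"method": "bfgs", "maxiter": 500},
        ):
            try:
                cand = model.fit(disp=0, **kwargs)
                if np.isfinite(cand.llf):
                    res = cand
                    break
            except Exception:
                continue
    if res is None:
        raise FitError("multinomial fit did not converge")
    k = Z.shape[1]
    out = FitResult(
        ll=float(res.llf),
        n_params=k * (C - 1),
        deviance=-2.0 * float(res.llf),
    )
    if need_cov:
        # flat parameter order is class-major: [class1 coefs..., class2 coefs...]
        params = np.asarray(res.params)  # (k, C-1)
        cov = np.asarray(res.cov_params())
        idx = np.concatenate([np.arange(1, k) + c * k for c in range(C - 1)])
        out.coef = params[1:, :].ravel(order="F")
        out.coef_cov = cov[np.ix_(idx, idx)]
    if need_resid:
        probs = np.asarray(res.predict())
        ind = np.zeros((n, C))
        ind[np.arange(n), codes] = 1.0
        out.resid = ind - probs
    return out


# ---------------------------------------------------------------------------
# survival: Cox partial likelihood and Weibull AFT

def cox_null_loglik(time: np.ndarray, status: np.ndarray) -> float:
    """Efron partial log-likelihood of the covariate-free Cox model.

    With all relative hazards equal to one the Efron tie correction reduces
    the denominator for the l-th of d tied events to (m - l), m being the
    risk-set size, so the null partial log-likelihood is exactly
    -sum over event-time groups of sum_{l<d} log(m - l).
    """
    order = np.argsort(time, kind="stable")
    t = np.asarray(time)[order]
    s = np.asarray(status)[order]
    n = t.shape[0]
    ll = 0.0
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        d = int(s[i:j].sum())
        m = n - i
        for l in range(d):
            ll -= np.log(m - l)
        i = j
    return float(ll)


def _surv_frame(target, M):
    df = pd.DataFrame(M, columns=[f"x{i}" for i in range(M.shape[1])])
    df["time"] = target.values
    df["event"] = target.status
    return df


def _fit_cox(target, M, need_cov, need_resid):
    from lifelines import CoxPHFitter, NelsonAalenFitter

    n = target.n
    if M.shape[1] == 0:
        ll = cox_null_loglik(target.values, target.status)
        out = FitResult(ll=ll, n_params=0, deviance=-2.0 * ll)
        if need_resid:
            naf = NelsonAalenFitter().fit(target.values, target.status)
            H = np.asarray(
                naf.cumulative_hazard_at_times(target.values)
            )
            out.resid = target.status - H
        return out
    df = _surv_frame(target, M)
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for pen in (0.0, 0.1):
            try:
                cand = CoxPHFitter(penalizer=pen).fit(df, "time", "event")
                if np.isfinite(cand.log_likelihood_):
                    res = cand
                    break
            except Exception:
                continue
    if res is None:
        raise FitError("Cox fit did not converge")
    out = FitResult(
        ll=float(res.log_likelihood_),
        n_params=M.shape[1],
        deviance=-2.0 * float(res.log_likelihood_),
    )
    if need_cov:
        out.coef = np.asarray(res.params_)
        out.coef_cov = np.asarray(res.variance_matrix_)
    if need_resid:
        out.resid = np.asarray(
            res.compute_residuals(df, "martingale")["martingale"].reindex(df.index)
        )
    return out


def _fit_weibull(target, M, need_cov, need_resid):
    from lifelines import WeibullAFTFitter, WeibullFitter

    n = target.n
    if M.shape[1] == 0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            wf = WeibullFitter().fit(target.values, target.status)
        out = FitResult(
            ll=float(wf.log_likelihood_), n_params=2,
            deviance=-2.0 * float(wf.log_likelihood_),
        )
        if need_resid:
            H = (target.values / wf.lambda_) ** wf.rho_
            out.resid = target.status - H
        return out
    df = _surv_frame(target, M)
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for pen in (0.0, 0.01):
            try:
                cand = WeibullAFTFitter(penalizer=pen).fit(df, "time", "event")
                if np.isfinite(cand.log_likelihood_):
                    res = cand
                    break
            except Exception:
                continue
    if res is None:
        raise FitError("Weibull AFT fit did not converge")
    out = FitResult(
        ll=float(res.log_likelihood_),
        n_params=M.shape[1] + 2,
        deviance=-2.0 * float(res.log_likelihood_),
    )
    if need_cov:
        params = res.params_
        names = [
            ("lambda_", c) for c in params["lambda_"].index if c != "Intercept"
        ]
        out.coef = np.asarray([params[a][b] for a, b in names])
        V = res.variance_matrix_
        out.coef_cov = np.asarray(V.loc[names, names])
    if need_resid:
        H = np.asarray(
            [
                res.predict_cumulative_hazard(df.iloc[[i]], times=[df["time"].iloc[i]])
                .values[0, 0]
                for i in range(n)
            ]
        )
        out.resid = target.status - H
    return out


_FITTERS = {
    "gaussian": _fit_gaussian,
    "binary": _fit_binary,
    "poisson": _fit_poisson,
    "negbin": _fit_negbin,
    "nominal": _fit_nominal,
    "cox": _fit_cox,
    "weibull": _fit_weibull,
}
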