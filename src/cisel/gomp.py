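"""Generalised orthogonal matching pursuit (gOMP).

Classical OMP greedily selects, at each step, the feature most correlated
with the current residual of a linear model, refits, and repeats.  The
generalisation here keeps exactly that residual-pursuit structure but
defines the residual per outcome family: raw residuals for continuous
targets, response residuals (observed minus fitted mean) for logistic,
Poisson-family and multinomial models (per class, stacked, for the
multinomial), and martingale residuals for Cox and Weibull survival
models.  Features must be continuous; they are centred and scaled to unit
standard deviation for the inner-product step, while the refits use the
original scale.

Stopping is criterion-based: a step must lower the model deviance by at
least ``tol`` (default 3.84, roughly the price of one significant
parameter at the 5% level), or -- for continuous targets -- raise the
adjusted R^2 by at least ``tol`` (conventional choice 0.01).  For the
quasi-Poisson test the deviance is scaled by the estimated dispersion, so
over-dispersed data pay more per step and fewer features survive.
"""

from __future__ import annotations

import warnings

import numpy as np

from .ci_tests import TEST_FAMILIES, dispatch, default_test_for
from .families import FitError, fit_family
from .results import GompPath
from .targets import TargetSpec

_DEFAULT_TOL = {"deviance": 3.84, "ar2": 0.01}


def _gomp_family(test_name: str) -> str:
    fam = dispatch(test_name)
    if fam == "spearman":
        raise ValueError("gomp works on raw continuous scales; use testIndFisher")
    return fam


def _criterion(fam, fit, target, method, n_sel):
    if method == "ar2":
        if n_sel == 0:
            return 0.0
        n = target.n
        rss = fit.deviance
        tss = float(((target.values - target.values.mean()) ** 2).sum())
        r2 = 1.0 - rss / tss
        denom = n - n_sel - 1
        if denom <= 0:
            return 1.0
        return 1.0 - (1.0 - r2) * (n - 1) / denom
    if fam == "qpoisson":
        phi = max(fit.pearson_chi2 / max(fit.df_resid, 1), 1e-10)
        return fit.deviance / phi
    return fit.deviance


def gomp(
    target: TargetSpec,
    X: np.ndarray,
    test: str | None = None,
    tol: float | None = None,
    method: str = "deviance",
    max_steps: int | None = None,
    categorical=frozenset(),
) -> GompPath:
    """Greedy residual pursuit for one stopping tolerance.

    Returns the full path, row 0 being the constant-only model.
    """
    if categorical:
        raise ValueError("gomp accepts continuous features only")
    if method not in ("deviance", "ar2"):
        raise ValueError("method must be 'deviance' or 'ar2'")
    if test is None:
        test = default_test_for(target.kind)
    fam = _gomp_family(test)
    if target.kind != TEST_FAMILIES[test][1]:
        raise ValueError(f"test {test!r} is incompatible with a {target.kind} target")
    if method == "ar2" and fam != "fisher":
        raise ValueError("the adjusted-R2 criterion applies to continuous targets only")
    if tol is None:
        tol = _DEFAULT_TOL[method]

    X = np.asarray(X, dtype=float)
    n, p = X.shape
    fit_fam = {"fisher": "gaussian", "qpoisson": "poisson"}.get(fam, fam)

    sd = X.std(axis=0)
    usable = sd > 0
    Xs = np.zeros_like(X)
    Xs[:, usable] = (X[:, usable] - X[:, usable].mean(axis=0)) / sd[usable]

    fit = fit_family(fit_fam, target, None, need_resid=True)
    crit = _criterion(fam, fit, target, method, 0)
    null_dev = fit.deviance
    steps: list[tuple[int, float]] = [(0, crit)]
    selected: list[int] = []
    resid = fit.resid
    limit = max_steps if max_steps is not None else min(n - 2, int(usable.sum()))

    while len(selected) < limit:
        mask = usable.copy()
        mask[selected] = False
        if not mask.any():
            break
        if resid.ndim == 2:  # multinomial: one residual column per class
            scores = np.sqrt(((Xs.T @ resid) ** 2).sum(axis=1))
        else:
            scores = np.abs(Xs.T @ resid)
        scores[~mask] = -np.inf
        j = int(np.argmax(scores))  # argmax takes the lowest index on ties
        try:
            fit = fit_family(
                fit_fam, target, X[:, selected + [j]], need_resid=True
            )
        except FitError:
            warnings.warn("refit failed to converge; stopping the pursuit")
            break
        new_crit = _criterion(fam, fit, target, method, len(selected) + 1)
        if method == "deviance":
            if new_crit >= crit:
                warnings.warn(
                    "deviance did not decrease; stopping the pursuit",
                    stacklevel=2,
                )
                break
            gain = crit - new_crit
        else:
            gain = new_crit - crit
        if gain < tol:
            break
        selected.append(j)
        steps.append((j, new_crit))
        crit = new_crit
        resid = fit.resid
        if method == "deviance" and new_crit <= 1e-8 * max(null_dev, 1e-300):
            break  # features span the target exactly
    return GompPath(steps=steps, criterion="deviance" if method == "deviance" else "adjusted_r2", tol=float(tol))


def gomp_path(
    target: TargetSpec,
    X: np.ndarray,
    test: str | None = None,
    tols: list[float] = (),
    method: str = "deviance",
) -> list[GompPath]:
    """gOMP for a range of stopping values in one pass.

    The greedy selection order does not depend on the tolerance, so the
    path for the loosest tolerance is a prefix of the path for the
    strictest one; the longest path is computed once and truncated.
    """
    tols = list(tols)
    if not tols:
        raise ValueError("provide at least one stopping value")
    full = gomp(target, X, test=test, tol=min(tols), method=method)
    out = []
    vals = [v for _, v in full.steps]
    for tol in tols:
        keep = 1
        for i in range(1, len(full.steps)):
            gain = (vals[i - 1] - vals[i]) if method == "deviance" else (vals[i] - vals[i - 1])
            if gain < tol:
                break
            keep = i + 1
        out.append(
            GompPath(steps=full.steps[:keep], criterion=full.criterion, tol=float(tol))
        )
    return out
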