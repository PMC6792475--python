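"""Synthetic regression data with planted ground truth.

Generators for every supported outcome family, used by the recovery,
calibration and equivalence tests (and available from the command line for
benchmarking).  The design matrix is correlated Gaussian with exchangeable
correlation ``rho`` -- enough structure to stress collinearity without a
large parameter space -- and a chosen subset of columns (the *active set*)
drives the target through a linear predictor with known coefficients.
Near-duplicate columns can be appended to exercise equivalence detection.

All generators are fully deterministic under their seed and never touch
global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.special import expit

from .targets import TargetSpec

GLM_FAMILIES = ("gaussian", "binomial", "poisson", "negbin", "multinomial")


@dataclass
class SyntheticDataset:
    """A feature matrix with a target generated from known structure."""

    X: np.ndarray
    target: TargetSpec
    active: np.ndarray
    beta: np.ndarray
    equiv_classes: list[list[int]] = field(default_factory=list)
    params: dict[str, Any] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def _design(rng, n, p, rho):
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must lie in [0, 1)")
    Z = rng.standard_normal((n, p))
    if rho == 0.0:
        return Z
    shared = rng.standard_normal((n, 1))
    return np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * Z


def _beta_vector(beta, n_active):
    b = np.asarray(beta, dtype=float)
    if b.ndim == 0:
        b = np.full(n_active, float(b))
    if b.shape != (n_active,):
        raise ValueError("beta must be a scalar or a vector of length n_active")
    return b


def gen_glm(
    n: int,
    p: int,
    family: str = "gaussian",
    n_active: int = 5,
    beta: float | np.ndarray = 1.0,
    rho: float = 0.0,
    sigma: float = 1.0,
    dispersion: float = 0.5,
    n_classes: int = 3,
    seed: int = 0,
) -> SyntheticDataset:
    """Draw a GLM-family dataset with ``n_active`` planted features.

    ``sigma`` is the Gaussian noise standard deviation; ``dispersion`` is
    the NB2 overdispersion (Var = mu + dispersion * mu^2); multinomial
    targets share the active set across class-specific linear predictors
    whose coefficient signs are drawn per class.
    """
    if family not in GLM_FAMILIES:
        raise ValueError(f"family must be one of {GLM_FAMILIES}")
    if n_active > p:
        raise ValueError("n_active cannot exceed p")
    rng = np.random.default_rng(seed)
    X = _design(rng, n, p, rho)
    active = np.sort(rng.choice(p, size=n_active, replace=False))
    b = _beta_vector(beta, n_active)
    eta = X[:, active] @ b if n_active else np.zeros(n)

    if family == "gaussian":
        y = eta + sigma * rng.standard_normal(n)
        target = TargetSpec(y, "continuous")
    elif family == "binomial":
        y = rng.random(n) < expit(eta)
        target = TargetSpec(y.astype(float), "binary")
    elif family == "poisson":
        mu = np.exp(np.clip(eta, -30, 30))
        target = TargetSpec(rng.poisson(mu).astype(float), "counts")
    elif family == "negbin":
        if dispersion <= 0:
            raise ValueError("negbin requires dispersion > 0")
        mu = np.exp(np.clip(eta, -30, 30))
        lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
        target = TargetSpec(rng.poisson(lam).astype(float), "counts")
    else:  # multinomial
        if n_classes < 2:
            raise ValueError("multinomial requires at least 2 classes")
        signs = rng.choice([-1.0, 1.0], size=(n_classes - 1, n_active))
        logits = np.zeros((n, n_classes))
        for c in range(1, n_classes):
            logits[:, c] = X[:, active] @ (b * signs[c - 1]) if n_active else 0.0
        probs = np.exp(logits - logits.max(axis=1, keepdims=True))
        probs /= probs.sum(axis=1, keepdims=True)
        u = rng.random(n)
        y = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
        target = TargetSpec(y.astype(float), "nominal")

    return SyntheticDataset(
        X=X,
        target=target,
        active=active,
        beta=b,
        params={
            "n": n, "p": p, "family": family, "n_active": n_active,
            "rho": rho, "sigma": sigma, "dispersion": dispersion,
            "n_classes": n_classes, "seed": seed,
        },
    )


def gen_survival(
    n: int,
    p: int,
    n_active: int = 5,
    beta: float | np.ndarray = 0.5,
    censor_rate: float = 0.3,
    rho: float = 0.0,
    shape: float = 2.0,
    seed: int = 0,
) -> SyntheticDataset:
    """Weibull proportional-hazards times with independent censoring.

    The censoring-time scale is calibrated by bisection on the realised
    sample so the requested censoring fraction is met closely; status is
    coded 1 = event observed, 0 = censored.
    """
    if not 0.0 <= censor_rate < 1.0:
        raise ValueError("censor_rate must lie in [0, 1); 1 would censor everything")
    if n_active > p:
        raise ValueError("n_active cannot exceed p")
    rng = np.random.default_rng(seed)
    X = _design(rng, n, p, rho)
    active = np.sort(rng.choice(p, size=n_active, replace=False))
    b = _beta_vector(beta, n_active)
    eta = X[:, active] @ b if n_active else np.zeros(n)
    u = rng.random(n)
    T = (-np.log(u) / np.exp(np.clip(eta, -30, 30))) ** (1.0 / shape)

    if censor_rate == 0.0:
        time, status = T, np.ones(n, dtype=int)
    else:
        E = rng.exponential(1.0, n)
        lo, hi = 1e-8, 1e8
        for _ in range(200):
            mid = np.sqrt(lo * hi)
            frac = float((mid * E < T).mean())  # censored fraction
            if frac > censor_rate:
                lo = mid
            else:
                hi = mid
        C = np.sqrt(lo * hi) * E
        status = (T <= C).astype(int)
        time = np.minimum(T, C)
    time = np.maximum(time, 1e-12)
    target = TargetSpec(time, "survival", status=status)
    return SyntheticDataset(
        X=X,
        target=target,
        active=active,
        beta=b,
        params={
            "n": n, "p": p, "n_active": n_active, "censor_rate": censor_rate,
            "realized_censor_rate": float(1 - status.mean()),
            "rho": rho, "shape": shape, "seed": seed,
        },
    )


def gen_equivalent(
    base: SyntheticDataset,
    slot: int,
    n_copies: int = 1,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SyntheticDataset:
    """Append near-duplicates of one active column.

    Each copy equals the ``slot`` column plus Gaussian noise of standard
    deviation ``noise_sd`` (0 gives exact duplicates); the equivalence
    class of the slot records the copies, for checking that equivalence-
    aware search finds them interchangeable.
    """
    if slot not in base.active:
        raise ValueError("slot must be a member of the active set")
    rng = np.random.default_rng(seed)
    col = base.X[:, slot][:, None]
    copies = col + noise_sd * rng.standard_normal((base.n, n_copies))
    X = np.hstack([base.X, copies])
    new_idx = list(range(base.p, base.p + n_copies))
    equiv = [list(c) for c in base.equiv_classes] + [[slot] + new_idx]
    params = dict(base.params)
    params.update({"equiv_slot": int(slot), "n_copies": n_copies,
                   "noise_sd": noise_sd, "equiv_seed": seed})
    return SyntheticDataset(
        X=X,
        target=base.target,
        active=base.active,
        beta=base.beta,
        equiv_classes=equiv,
        params=params,
    )
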