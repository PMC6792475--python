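"""Target (outcome) specification shared by all tests and search algorithms.

A :class:`TargetSpec` couples the outcome vector with its declared
measurement type, because the choice of regression model / independence
test is driven by that type: continuous outcomes use (partial) correlation
tests, binary outcomes logistic regression, counts Poisson-family models,
nominal outcomes multinomial regression, and time-to-event outcomes Cox or
Weibull regression with a 0/1 censoring-status vector (1 = event observed,
0 = censored).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TARGET_KINDS = ("continuous", "binary", "nominal", "counts", "survival")


@dataclass(frozen=True)
class TargetSpec:
    """An outcome vector with a declared type.

    Parameters
    ----------
    values : ndarray, shape (n,)
        The outcome. For survival targets these are the observed times
        (event or censoring, whichever came first).
    kind : str
        One of ``continuous``, ``binary``, ``nominal``, ``counts``,
        ``survival``.
    status : ndarray, shape (n,), optional
        Survival only: 1 where the event was observed, 0 where censored.
    """

    values: np.ndarray
    kind: str
    status: np.ndarray | None = None
    _codes: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1:
            raise ValueError("target values must be a 1-D vector")
        if self.kind not in TARGET_KINDS:
            raise ValueError(
                f"unknown target kind {self.kind!r}; expected one of {TARGET_KINDS}"
            )
        n = values.shape[0]
        if self.kind == "survival":
            if self.status is None:
                raise ValueError("survival targets require a status vector")
            status = np.asarray(self.status, dtype=int)
            if status.shape != (n,):
                raise ValueError("status must have the same length as the times")
            if not np.isin(status, (0, 1)).all():
                raise ValueError("status must be coded 0 (censored) / 1 (event)")
            if (values <= 0).any():
                raise ValueError("survival times must be positive")
            object.__setattr__(self, "status", status)
        elif self.status is not None:
            raise ValueError("status is only meaningful for survival targets")
        if self.kind == "counts":
            if (values < 0).any() or not np.allclose(values, np.round(values)):
                raise ValueError("count targets must be non-negative integers")
        if self.kind in ("binary", "nominal"):
            levels = np.unique(values)
            if self.kind == "binary" and levels.size != 2:
                raise ValueError("binary targets must have exactly 2 distinct labels")
            if self.kind == "nominal" and levels.size < 2:
                raise ValueError("nominal targets must have at least 2 distinct labels")
            codes = np.searchsorted(levels, values)
            object.__setattr__(self, "_codes", codes.astype(int))

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def codes(self) -> np.ndarray:
        """Integer class codes 0..C-1 (binary / nominal targets only)."""
        if self._codes is None:
            raise ValueError(f"{self.kind} targets have no class codes")
        return self._codes

    @property
    def n_classes(self) -> int:
        return int(self.codes.max()) + 1
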