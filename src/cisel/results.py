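"""Result containers and their JSON / TSV serialisations.

All p-values throughout the package are carried on the natural-log scale
(``logp``), so that selection decisions can be taken far below the
double-precision underflow point of a raw p-value.  The tabular exports
mirror the shapes practitioners of this algorithm family expect: a ``res``
block with columns (sel, stat, pval) holding the selected column indices
with their admitting statistic and log p-value, an ``info`` block with the
number of selected variables and the number of tests performed, and for
equivalence-aware runs a ``signatures`` matrix whose first row is the base
selection and whose later rows are the statistically equivalent ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CITestResult:
    """Outcome of one conditional-independence test ind(Y, X | Z)."""

    stat: float
    df: int
    logp: float
    feature: int
    cond_set: tuple[int, ...]

    def __post_init__(self):
        if self.feature in self.cond_set:
            raise ValueError("tested feature cannot appear in its conditioning set")

    @property
    def pvalue(self) -> float:
        return float(np.exp(self.logp))


@dataclass(frozen=True, eq=False)
class UnivariateScores:
    """Marginal (unconditional) association of every feature with the target.

    Reusable across search algorithms as long as the test name matches.
    """

    stats: np.ndarray
    logps: np.ndarray
    test_name: str

    def __eq__(self, other):
        return (
            isinstance(other, UnivariateScores)
            and self.test_name == other.test_name
            and np.array_equal(self.stats, other.stats)
            and np.array_equal(self.logps, other.logps)
        )

    def __post_init__(self):
        object.__setattr__(self, "stats", np.asarray(self.stats, dtype=float))
        object.__setattr__(self, "logps", np.asarray(self.logps, dtype=float))
        if self.stats.shape != self.logps.shape:
            raise ValueError("stats and logps must have equal length")

    @property
    def p(self) -> int:
        return self.stats.shape[0]


@dataclass(frozen=True)
class ExclusionCertificate:
    """Why a feature was dropped: the conditioning subset that rendered it
    independent of the target, with the test outcome for that subset."""

    feature: int
    cond_set: tuple[int, ...]
    stat: float
    logp: float


@dataclass(frozen=True)
class NotExcluded:
    """Marker returned for queried features that were never dropped
    (typically because they were selected)."""

    feature: int


@dataclass
class SelectionResult:
    """Ordered selected features with per-feature statistic and log p-value.

    ``n_tests`` counts conditional-independence test evaluations (one per
    (feature, conditioning set) query; cached replays count too, so the
    counter is identical with caching on or off).
    """

    selected: list[int]
    stats: list[float]
    logps: list[float]
    n_tests: int
    algorithm: str = ""
    test_name: str = ""
    per_k_info: list[tuple[int, int, int]] | None = None
    univariate: UnivariateScores | None = None
    certificates: dict[int, ExclusionCertificate] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("selected feature list contains duplicates")
        if not (len(self.selected) == len(self.stats) == len(self.logps)):
            raise ValueError("selected/stats/logps lengths differ")

    def res_table(self) -> pd.DataFrame:
        """The (sel, stat, pval) block; pval is the natural-log p-value."""
        return pd.DataFrame(
            {"sel": self.selected, "stat": self.stats, "pval": self.logps}
        )

    def info_table(self) -> pd.DataFrame:
        """The (Number of vars, Number of tests) block; one row per K for
        the early-dropping algorithm, a single row otherwise."""
        if self.per_k_info:
            rows = {
                f"K={k}": (nsel, ntest) for (k, nsel, ntest) in self.per_k_info
            }
        else:
            rows = {"run": (len(self.selected), self.n_tests)}
        return pd.DataFrame.from_dict(
            rows, orient="index", columns=["Number of vars", "Number of tests"]
        )

    def to_json(self) -> str:
        payload: dict[str, Any] = {
            "algorithm": self.algorithm,
            "test": self.test_name,
            "res": [
                {"sel": int(s), "stat": float(st), "pval": float(lp)}
                for s, st, lp in zip(self.selected, self.stats, self.logps)
            ],
            "info": {
                "n_vars": len(self.selected),
                "n_tests": int(self.n_tests),
            },
        }
        if self.per_k_info:
            payload["info"]["per_k"] = [
                {"K": int(k), "n_vars": int(v), "n_tests": int(t)}
                for k, v, t in self.per_k_info
            ]
        return json.dumps(payload, indent=2)

    def to_tsv(self) -> str:
        return self.res_table().to_csv(sep="\t", index=False, float_format="%.6f")


@dataclass
class SignatureSet:
    """Base selection plus all statistically equivalent selections.

    ``signatures`` has one row per signature and one column per selected
    slot; row 0 is the base selection.  ``equivalence_classes[j]`` lists the
    interchangeable feature indices for slot j (the base member first).
    """

    signatures: np.ndarray
    equivalence_classes: list[list[int]]

    def __post_init__(self):
        self.signatures = np.asarray(self.signatures, dtype=int)
        if self.signatures.ndim != 2:
            raise ValueError("signatures must be a 2-D matrix")

    @property
    def n_signatures(self) -> int:
        return self.signatures.shape[0]

    def to_tsv(self) -> str:
        cols = [f"Var{j + 1}" for j in range(self.signatures.shape[1])]
        return pd.DataFrame(self.signatures, columns=cols).to_csv(
            sep="\t", index=False
        )


@dataclass
class GompPath:
    """Greedy residual-pursuit path.

    ``steps`` holds (selected index, criterion value) rows; row 0 is always
    the null model (index 0 by convention, criterion of the constant-only
    fit).  Deviance paths decrease, adjusted-R2 paths increase.
    """

    steps: list[tuple[int, float]]
    criterion: str
    tol: float

    @property
    def selected(self) -> list[int]:
        return [idx for idx, _ in self.steps[1:]]

    def res_table(self) -> pd.DataFrame:
        name = "Deviance" if self.criterion == "deviance" else "adjusted R2"
        return pd.DataFrame(self.steps, columns=["Selected Vars", name])

    def to_tsv(self) -> str:
        return self.res_table().to_csv(sep="\t", index=False, float_format="%.6f")

    def to_json(self) -> str:
        return json.dumps(
            {
                "criterion": self.criterion,
                "tol": self.tol,
                "steps": [
                    {"selected": int(i), "value": float(v)} for i, v in self.steps
                ],
            },
            indent=2,
        )
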