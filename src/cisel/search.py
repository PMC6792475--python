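"""Constraint-based and stepwise feature-selection algorithms.

All algorithms here share one engine: the conditional-independence tests of
:mod:`cisel.ci_tests`.  Significance decisions are taken on the natural-log
scale (select iff ``logp < ln(threshold)``), so nothing underflows.

Algorithms
----------
mmpc
    Max-min parents-and-children: a forward search that, before admitting
    the next candidate, tries to render every candidate independent of the
    target given small subsets of the already-selected set; candidates that
    are rendered independent are dropped permanently (with a certificate of
    the subset that excluded them).
ses
    Statistically equivalent signatures: MMPC plus detection of features
    interchangeable with a selected one, enumerated as multiple equally
    good selections ("signatures").
mmmb
    Max-min Markov blanket: MMPC on the target, then MMPC around each
    selected feature to hunt for spouses.
forward_selection / backward_selection
    Classical stepwise regression driven by the same tests.
iamb
    Forward selection followed by sweeps that remove all currently
    non-significant members at once.
fbed
    Forward selection with early dropping; the dropped pool can be
    revisited K times, and a backward phase prunes the result.  With
    ``stop_rule="ebic"`` admission/removal is by extended-BIC difference
    instead of a significance threshold.

Tie-breaking is deterministic everywhere: ties in logp go to the larger
|statistic|, then to the lower column index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from itertools import combinations, product
from typing import Sequence

import numpy as np

from .ci_tests import CITester, TestCache, TestConfig, default_test_for
from .results import (
    CITestResult,
    ExclusionCertificate,
    NotExcluded,
    SelectionResult,
    SignatureSet,
    UnivariateScores,
)
from .targets import TargetSpec


@dataclass(frozen=True)
class AlgoConfig:
    """Hyperparameters shared by the search algorithms.

    threshold : significance level alpha (compared on the log scale)
    max_k     : maximal conditioning-subset size (MMPC / SES / MMMB)
    K         : how many times FBED revisits the dropped pool (int or
                ascending sequence; results are reported per value)
    stop_rule : "lrt" (significance threshold) or "ebic" (FBED only)
    ebic_gamma: extended-BIC feature-space penalty weight in [0, 1]
    flavor/B  : test flavor ("lrt", "wald", "permutation") and permutation
                count, passed through to the test engine
    """

    threshold: float = 0.05
    max_k: int = 3
    K: int | Sequence[int] = 0
    stop_rule: str = "lrt"
    ebic_gamma: float = 0.0
    seed: int | None = None
    flavor: str = "lrt"
    B: int = 999

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie strictly between 0 and 1")
        if self.max_k < 0:
            raise ValueError("max_k must be >= 0")
        ks = self.K if isinstance(self.K, (list, tuple)) else (self.K,)
        if any(k < 0 for k in ks):
            raise ValueError("K must be >= 0")
        if self.stop_rule not in ("lrt", "ebic"):
            raise ValueError("stop_rule must be 'lrt' or 'ebic'")
        if not 0.0 <= self.ebic_gamma <= 1.0:
            raise ValueError("ebic_gamma must lie in [0, 1]")

    @property
    def log_threshold(self) -> float:
        return math.log(self.threshold)


def _make_tester(target, X, test, cfg, cache, categorical, tester):
    if tester is not None:
        return tester
    if test is None:
        test = default_test_for(target.kind)
    tc = TestConfig(test_name=test, flavor=cfg.flavor, B=cfg.B, seed=cfg.seed)
    return CITester(target, X, tc, cache=cache, categorical=categorical)


def _order_key(res: CITestResult):
    """Sort key for 'most significant first' with deterministic ties."""
    return (res.logp, -abs(res.stat), res.feature)


def univariate_screen(
    target: TargetSpec,
    X: np.ndarray,
    test: str | None = None,
    cfg: AlgoConfig | None = None,
    tester: CITester | None = None,
) -> UnivariateScores:
    """Marginal CI test of every feature (empty conditioning set).

    Constant columns are reported as non-significant (stat 0, logp 0).
    """
    cfg = cfg or AlgoConfig()
    tester = _make_tester(target, X, test, cfg, None, frozenset(), tester)
    stats = np.zeros(tester.p)
    logps = np.zeros(tester.p)
    usable = tester.usable_features
    for res in tester.test_all(usable, ()):
        stats[res.feature] = res.stat
        logps[res.feature] = res.logp
    return UnivariateScores(stats=stats, logps=logps, test_name=tester.config.test_name)


def _conditioning_subsets(others: Sequence[int], latest: int, max_k: int):
    """Subsets Z with latest in Z, Z ⊆ selected, |Z| <= max_k, by
    ascending size then lexicographic order (the classical restriction of
    the max-min search to subsets containing the newest member)."""
    others = sorted(others)
    for size in range(0, max_k):
        for extra in combinations(others, size):
            yield tuple(sorted(extra + (latest,)))


def mmpc(
    target: TargetSpec,
    X: np.ndarray,
    cfg: AlgoConfig | None = None,
    test: str | None = None,
    cache: TestCache | None = None,
    univariate: UnivariateScores | None = None,
    tester: CITester | None = None,
    categorical: frozenset[int] = frozenset(),
    candidates: Sequence[int] | None = None,
) -> SelectionResult:
    """Max-min parents-and-children selection.

    Keeps, for every candidate, the weakest association (max logp) seen
    over any tested conditioning subset of the selected set; a candidate is
    dropped for good once that weakest association crosses the threshold,
    and the next admission goes to the candidate whose weakest association
    is strongest (the max-min criterion).
    """
    cfg = cfg or AlgoConfig()
    tester = _make_tester(target, X, test, cfg, cache, categorical, tester)
    start_tests = tester.n_tests
    log_thr = cfg.log_threshold

    if candidates is None:
        alive = list(tester.usable_features)
    else:
        alive = [c for c in candidates if c not in tester.excluded]
    if univariate is not None and univariate.test_name == tester.config.test_name:
        uni = univariate
    else:
        stats_arr = np.zeros(tester.p)
        logps_arr = np.zeros(tester.p)
        for res in tester.test_all(alive, ()):
            stats_arr[res.feature] = res.stat
            logps_arr[res.feature] = res.logp
        uni = UnivariateScores(
            stats=stats_arr, logps=logps_arr, test_name=tester.config.test_name
        )
    assoc_logp = {x: float(uni.logps[x]) for x in alive}
    assoc_stat = {x: float(uni.stats[x]) for x in alive}
    cert: dict[int, tuple[int, ...]] = {x: () for x in alive}

    selected: list[int] = []
    sel_stats: list[float] = []
    sel_logps: list[float] = []
    certificates: dict[int, ExclusionCertificate] = {}

    def drop_nonsignificant():
        nonlocal alive
        for x in [x for x in alive if assoc_logp[x] >= log_thr]:
            certificates[x] = ExclusionCertificate(
                feature=x, cond_set=cert[x],
                stat=assoc_stat[x], logp=assoc_logp[x],
            )
            alive.remove(x)

    while True:
        drop_nonsignificant()
        if not alive:
            break
        best = min(alive, key=lambda x: (assoc_logp[x], -abs(assoc_stat[x]), x))
        selected.append(best)
        sel_stats.append(assoc_stat[best])
        sel_logps.append(assoc_logp[best])
        alive.remove(best)
        if not alive or cfg.max_k == 0:
            if cfg.max_k == 0:
                # only marginal associations are ever examined
                drop_nonsignificant()
                for x in list(alive):
                    selected.append(x)
                    sel_stats.append(assoc_stat[x])
                    sel_logps.append(assoc_logp[x])
                alive = []
            continue
        for Z in _conditioning_subsets(selected[:-1], best, cfg.max_k):
            live = [x for x in alive if assoc_logp[x] < log_thr]
            if not live:
                break
            for res in tester.test_all(live, Z):
                if res.logp > assoc_logp[res.feature]:
                    assoc_logp[res.feature] = res.logp
                    assoc_stat[res.feature] = res.stat
                    cert[res.feature] = Z

    # order by strength of admission for a stable, readable output
    return SelectionResult(
        selected=selected,
        stats=sel_stats,
        logps=sel_logps,
        n_tests=tester.n_tests - start_tests,
        algorithm="mmpc",
        test_name=tester.config.test_name,
        univariate=uni,
        certificates=certificates,
    )


def ses(
    target: TargetSpec,
    X: np.ndarray,
    cfg: AlgoConfig | None = None,
    test: str | None = None,
    cache: TestCache | None = None,
    univariate: UnivariateScores | None = None,
    tester: CITester | None = None,
    categorical: frozenset[int] = frozenset(),
    max_signatures: int = 1000,
) -> tuple[SelectionResult, SignatureSet]:
    """Statistically equivalent signatures.

    Runs the max-min search, then tries to swap each dropped feature x into
    the place of a selected feature s: if s was part of the subset Q that
    excluded x, and s itself becomes independent of the target given
    (Q \\ {s}) ∪ {x}, the two features are interchangeable and x joins the
    equivalence class of s.  Signatures are the Cartesian product of the
    per-slot classes (row 0 = the base selection), capped at
    ``max_signatures`` rows.
    """
    cfg = cfg or AlgoConfig()
    tester = _make_tester(target, X, test, cfg, cache, categorical, tester)
    start_tests = tester.n_tests
    base = mmpc(target, X, cfg, cache=cache, univariate=univariate, tester=tester)
    base.algorithm = "ses"
    log_thr = cfg.log_threshold

    classes = {s: [s] for s in base.selected}
    for x, c in sorted(base.certificates.items()):
        for s in base.selected:
            if s not in c.cond_set:
                continue
            swapped = tuple(sorted([q for q in c.cond_set if q != s] + [x]))
            res = tester(s, swapped)
            if res.logp >= log_thr:
                classes[s].append(x)
    base.n_tests = tester.n_tests - start_tests
    eq_classes = [sorted(set(classes[s]), key=lambda v: (v != s, v)) for s in base.selected]

    if base.selected:
        rows = []
        for combo in product(*eq_classes):
            rows.append(combo)
            if len(rows) >= max_signatures:
                break
        signatures = np.asarray(rows, dtype=int)
    else:
        signatures = np.empty((1, 0), dtype=int)
    return base, SignatureSet(signatures=signatures, equivalence_classes=eq_classes)


def mmmb(
    target: TargetSpec,
    X: np.ndarray,
    cfg: AlgoConfig | None = None,
    test: str | None = None,
    cache: TestCache | None = None,
    tester: CITester | None = None,
) -> SelectionResult:
    """Max-min Markov blanket: parents/children plus spouse recovery.

    Runs the max-min search on the target, then around each selected
    feature s (treated as a continuous target over the remaining columns);
    a neighbour u of s that the target search rejected is admitted as a
    spouse when some conditioning set containing s re-establishes its
    dependence with the target.
    """
    cfg = cfg or AlgoConfig()
    tester = _make_tester(target, X, test, cfg, cache, frozenset(), tester)
    start_tests = tester.n_tests
    pc = mmpc(target, X, cfg, cache=cache, tester=tester)
    log_thr = cfg.log_threshold
    feature_test = (
        "testIndSpearman"
        if tester.config.test_name == "testIndSpearman"
        else "testIndFisher"
    )

    selected = list(pc.selected)
    stats = list(pc.stats)
    logps = list(pc.logps)
    extra_tests = 0
    for s in pc.selected:
        s_target = TargetSpec(tester.X[:, s], "continuous")
        nb = mmpc(
            s_target,
            tester.X,
            cfg,
            test=feature_test,
            candidates=[j for j in range(tester.p) if j != s],
        )
        extra_tests += nb.n_tests
        for u in nb.selected:
            if u in selected:
                continue
            for Z in _conditioning_subsets(
                [c for c in pc.selected if c != u], s, cfg.max_k
            ):
                res = tester(u, Z)
                if res.logp < log_thr:
                    selected.append(u)
                    stats.append(res.stat)
                    logps.append(res.logp)
                    break
    return SelectionResult(
        selected=selected,
        stats=stats,
        logps=logps,
        n_tests=tester.n_tests - start_tests + extra_tests,
        algorithm="mmmb",
        test_name=tester.config.test_name,
        certificates=pc.certificates,
    )


def forward_selection(
    target: TargetSpec,
    X: np.ndarray,
    cfg: AlgoConfig | None = None,
    test: str | None = None,
    cache: TestCache | None = None,
    univariate: UnivariateScores | None = None,
    tester: CITester | None = None,
    categorical: frozenset[int] = frozenset(),
) -> SelectionResult:
    """Classical forward stepwise selection: each round admits the most
    significant candidate conditional on everything selected so far."""
    cfg = cfg or AlgoConfig()
    tester = _make_tester(target, X, test, cfg, cache, categorical, tester)
    start_tests = tester.n_tests
    log_thr = cfg.log_threshold

    selected: list[int] = []
    stats: list[float] = []
    logps: list[float] = []
    pool = list(tester.usable_features)
    first_round = True
    while pool:
        if first_round and univariate is not None and (
            univariate.test_name == tester.config.test_name
        ):
            results = [
                CITestResult(
                    stat=float(univariate.stats[f]), df=1,
                    logp=float(univariate.logps[f]), feature=f, cond_set=(),
                )
                for f in pool
            ]
        else:
            results = tester.test_all(pool, tuple(sorted(selected)))
        first_round = False
        best = min(results, key=_order_key)
        if best.logp >= log_thr:
            break
        selected.append(best.feature)
        stats.append(best.stat)
        logps.append(best.logp)
        pool.remove(best.feature)
    return SelectionResult(
        selected=selected,
        stats=stats,
        logps=logps,
        n_tests=tester.n_tests - start_tests,
        algorithm="fs",
        test_name=tester.config.test_name,
        univariate=univariate,
    )


def backward_selection(
    target: TargetSpec,
    X: np.ndarray,
    cfg: AlgoConfig | None = None,
    test: str | None = None,
    cache: TestCache | None = None,
    tester: CITester | None = None,
    categorical: frozenset[int] = frozenset(),
    start: Sequence[int] | None = None,
) -> SelectionResult:
    """Classical backward elimination: each round removes the least
    significant member until every remaining member is significant given
    the rest."""
    cfg = cfg or AlgoConfig()
    tester = _make_tester(target, X, test, cfg, cache, categorical, tester)
    start_tests = tester.n_tests
    log_thr = cfg.log_threshold

    S = list(tester.usable_features) if start is None else [
        s for s in start if s not in tester.excluded
    ]
    last: dict[int, CITestResult] = {}
    while S:
        results = [tester(s, tuple(c for c in S if c != s)) for s in S]
        last = {r.feature: r for r in results}
        worst = max(results, key=lambda r: (r.logp, -abs(r.stat), -r.feature))
        if worst.logp < log_thr:
            break
        S.remove(worst.feature)
    return SelectionResult(
        selected=S,
        stats=[last[s].stat if s in last else float("nan") for s in S],
        logps=[last[s].logp if s in last else float("nan") for s in S],
        n_tests=tester.n_tests - start_tests,
        algorithm="bs",
        test_name=tester.config.test_name,
    )


def iamb(
    target: TargetSpec,
    X: np.ndarray,
    cfg: AlgoConfig | None = None,
    test: str | None = None,
    cache: TestCache | None = None,
    tester: CITester | None = None,
    categorical: frozenset[int] = frozenset(),
) -> SelectionResult:
    """Incremental-association Markov blanket: forward selection, then
    repeated sweeps that remove *all* non-significant members at once."""
    cfg = cfg or AlgoConfig()
    tester = _make_tester(target, X, test, cfg, cache, categorical, tester)
    start_tests = tester.n_tests
    fs = forward_selection(target, X, cfg, tester=tester)
    log_thr = cfg.log_threshold

    S = list(fs.selected)
    last: dict[int, CITestResult] = {
        f: CITestResult(st, 1, lp, f, ())
        for f, st, lp in zip(fs.selected, fs.stats, fs.logps)
    }
    while S:
        results = [tester(s, tuple(c for c in S if c != s)) for s in S]
        last = {r.feature: r for r in results}
        nonsig = [r.feature for r in results if r.logp >= log_thr]
        if not nonsig:
            break
        S = [s for s in S if s not in nonsig]
    return SelectionResult(
        selected=S,
        stats=[last[s].stat for s in S],
        logps=[last[s].logp for s in S],
        n_tests=tester.n_tests - start_tests,
        algorithm="iamb",
        test_name=tester.config.test_name,
    )


# ---------------------------------------------------------------------------
# FBED

def _ebic(tester, cols, gamma, p):
    ll, k = tester.model_ll(cols)
    n = tester.n
    return -2.0 * ll + k * math.log(n) + 2.0 * gamma * k * math.log(max(p, 1))


def _fbed_backward(tester, S, cfg):
    """Backward pruning used by FBED; returns the surviving members."""
    S = list(S)
    log_thr = cfg.log_threshold
    if cfg.stop_rule == "ebic":
        p = tester.p
        while S:
            cur = _ebic(tester, S, cfg.ebic_gamma, p)
            best_drop, best_val = None, cur
            for s in S:
                tester.n_tests += 1
                val = _ebic(tester, [c for c in S if c != s], cfg.ebic_gamma, p)
                if val < best_val - 1e-12:
                    best_drop, best_val = s, val
            if best_drop is None:
                break
            S.remove(best_drop)
        return S
    while S:
        results = [tester(s, tuple(c for c in S if c != s)) for s in S]
        worst = max(results, key=lambda r: (r.logp, -abs(r.stat), -r.feature))
        if worst.logp < log_thr:
            break
        S.remove(worst.feature)
    return S


def fbed(
    target: TargetSpec,
    X: np.ndarray,
    cfg: AlgoConfig | None = None,
    test: str | None = None,
    cache: TestCache | None = None,
    univariate: UnivariateScores | None = None,
    tester: CITester | None = None,
    categorical: frozenset[int] = frozenset(),
) -> SelectionResult:
    """Forward-backward selection with early dropping.

    The forward phase tests every pool member conditional on the current
    selection, drops all non-significant ones from the pool, and admits the
    best significant one.  Once the pool empties, the dropped features are
    restored and the phase reruns, up to K extra times; a backward phase
    then prunes the selection.  ``per_k_info`` records, for each requested
    K, (K, number selected after pruning, cumulative tests).
    """
    cfg = cfg or AlgoConfig()
    tester = _make_tester(target, X, test, cfg, cache, categorical, tester)
    start_tests = tester.n_tests
    log_thr = cfg.log_threshold
    ebic_mode = cfg.stop_rule == "ebic"
    Ks = sorted(
        set(cfg.K if isinstance(cfg.K, (list, tuple)) else [cfg.K])
    )
    Kmax = Ks[-1]

    selected: list[int] = []
    adm: dict[int, CITestResult] = {}
    pool = list(tester.usable_features)
    dropped: list[int] = []
    per_k_info: list[tuple[int, int, int]] = []
    final_S: list[int] = []
    first_round = True
    k = 0

    while True:
        # one forward phase with early dropping
        while pool:
            if ebic_mode:
                p = tester.p
                cur = _ebic(tester, selected, cfg.ebic_gamma, p)
                gains = {}
                for x in pool:
                    tester.n_tests += 1
                    gains[x] = cur - _ebic(
                        tester, selected + [x], cfg.ebic_gamma, p
                    )
                keep = [x for x in pool if gains[x] > 1e-12]
                dropped.extend(x for x in pool if x not in keep)
                if not keep:
                    pool = []
                    break
                best = max(keep, key=lambda x: (gains[x], -x))
                selected.append(best)
                adm[best] = CITestResult(
                    stat=float(gains[best]), df=1, logp=float("nan"),
                    feature=best, cond_set=tuple(sorted(selected[:-1])),
                )
                pool = [x for x in keep if x != best]
            else:
                if first_round and univariate is not None and (
                    univariate.test_name == tester.config.test_name
                ):
                    results = [
                        CITestResult(
                            stat=float(univariate.stats[f]), df=1,
                            logp=float(univariate.logps[f]), feature=f, cond_set=(),
                        )
                        for f in pool
                    ]
                else:
                    results = tester.test_all(pool, tuple(sorted(selected)))
                first_round = False
                sig = [r for r in results if r.logp < log_thr]
                dropped.extend(r.feature for r in results if r.logp >= log_thr)
                if not sig:
                    pool = []
                    break
                best = min(sig, key=_order_key)
                selected.append(best.feature)
                adm[best.feature] = best
                pool = [r.feature for r in sig if r.feature != best.feature]
        # phase done: pool empty
        if k in Ks:
            survivors = _fbed_backward(tester, selected, cfg)
            per_k_info.append(
                (k, len(survivors), tester.n_tests - start_tests)
            )
            if k == Kmax:
                final_S = survivors
        if k == Kmax:
            break
        pool = list(dict.fromkeys(dropped))
        dropped = []
        k += 1

    stats = [adm[s].stat for s in final_S]
    logps = [adm[s].logp for s in final_S]
    return SelectionResult(
        selected=list(final_S),
        stats=stats,
        logps=logps,
        n_tests=tester.n_tests - start_tests,
        algorithm="fbed",
        test_name=tester.config.test_name,
        per_k_info=per_k_info,
        univariate=univariate,
    )


# ---------------------------------------------------------------------------
# hyperparameter path and certificates

@dataclass
class MMPCPath:
    """Grid of MMPC runs sharing one test cache."""

    results: dict[tuple[float, int], SelectionResult]
    cache: TestCache

    @property
    def tests_saved(self) -> int:
        return self.cache.hits


def mmpc_path(
    target: TargetSpec,
    X: np.ndarray,
    thresholds: Sequence[float],
    max_ks: Sequence[int],
    test: str | None = None,
    cfg: AlgoConfig | None = None,
) -> MMPCPath:
    """Run MMPC over a (threshold, max_k) grid with a shared test cache,
    so repeated (feature, conditioning set) queries are computed once."""
    base = cfg or AlgoConfig()
    cache = TestCache()
    if test is None:
        test = default_test_for(target.kind)
    tc = TestConfig(test_name=test, flavor=base.flavor, B=base.B, seed=base.seed)
    tester = CITester(target, X, tc, cache=cache)
    results = {}
    for thr in sorted(thresholds, reverse=True):
        for mk in sorted(max_ks):
            cell_cfg = replace(base, threshold=thr, max_k=mk)
            results[(thr, mk)] = mmpc(target, X, cell_cfg, tester=tester)
    return MMPCPath(results=results, cache=cache)


def certificate_of_exclusion(
    result: SelectionResult, features: Sequence[int]
) -> list[ExclusionCertificate | NotExcluded]:
    """For each queried feature, the conditioning subset (and test outcome)
    that caused the max-min search to drop it; selected / never-dropped
    features get an explicit :class:`NotExcluded` marker."""
    out: list[ExclusionCertificate | NotExcluded] = []
    for f in features:
        f = int(f)
        out.append(result.certificates.get(f, NotExcluded(feature=f)))
    return out
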