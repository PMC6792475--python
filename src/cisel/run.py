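"""One-shot run configuration: load data, select, serialise results."""

from __future__ import annotations

import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ci_tests import TestCache, default_test_for, dispatch
from .gomp import gomp
from .io import read_dataset
from .results import SelectionResult, UnivariateScores
from .search import (
    AlgoConfig,
    backward_selection,
    fbed,
    forward_selection,
    iamb,
    mmmb,
    mmpc,
    ses,
)

log = logging.getLogger("cisel")

ALGORITHMS = ("mmpc", "ses", "mmmb", "fs", "bs", "iamb", "fbed", "gomp")


@dataclass
class RunConfig:
    data: str
    algorithm: str = "mmpc"
    test: str | None = None
    target: str | None = None
    kind: str | None = None
    time: str | None = None
    status: str | None = None
    threshold: float = 0.05
    max_k: int = 3
    K: int = 0
    tol: float | None = None
    method: str = "deviance"
    flavor: str = "lrt"
    B: int = 999
    seed: int = 0
    out: str | None = None
    univariate_from: str | None = None
    use_cache: bool = True
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}"
            )
        if self.test is not None:
            dispatch(self.test)


def _load_univariate(path: str) -> UnivariateScores:
    payload = json.loads(Path(path).read_text())
    return UnivariateScores(
        stats=np.asarray(payload["stats"], dtype=float),
        logps=np.asarray(payload["logps"], dtype=float),
        test_name=payload["test"],
    )


def run(cfg: RunConfig):
    """Execute one selection run and write JSON/TSV outputs.

    Returns the result object (a SelectionResult, a (SelectionResult,
    SignatureSet) pair for ses, or a GompPath for gomp).
    """
    logging.basicConfig(level=cfg.log_level)
    t0 = _time.time()
    ds = read_dataset(
        cfg.data, target=cfg.target, kind=cfg.kind, time=cfg.time, status=cfg.status
    )
    test = cfg.test or default_test_for(ds.target.kind)
    if cfg.algorithm == "gomp" and ds.categorical:
        raise ValueError("gomp accepts continuous features only")

    acfg = AlgoConfig(
        threshold=cfg.threshold, max_k=cfg.max_k, K=cfg.K,
        seed=cfg.seed, flavor=cfg.flavor, B=cfg.B,
    )
    cache = TestCache() if cfg.use_cache else None
    univariate = (
        _load_univariate(cfg.univariate_from) if cfg.univariate_from else None
    )

    kw = dict(cache=cache, categorical=ds.categorical)
    sig = None
    if cfg.algorithm == "gomp":
        result = gomp(ds.target, ds.X, test=test, tol=cfg.tol, method=cfg.method)
    elif cfg.algorithm == "ses":
        result, sig = ses(ds.target, ds.X, acfg, test=test, univariate=univariate, **kw)
    elif cfg.algorithm == "mmpc":
        result = mmpc(ds.target, ds.X, acfg, test=test, univariate=univariate, **kw)
    elif cfg.algorithm == "mmmb":
        result = mmmb(ds.target, ds.X, acfg, test=test, cache=cache)
    elif cfg.algorithm == "fs":
        result = forward_selection(
            ds.target, ds.X, acfg, test=test, univariate=univariate, **kw
        )
    elif cfg.algorithm == "bs":
        result = backward_selection(ds.target, ds.X, acfg, test=test, **kw)
    elif cfg.algorithm == "iamb":
        result = iamb(ds.target, ds.X, acfg, test=test, **kw)
    else:  # fbed
        result = fbed(ds.target, ds.X, acfg, test=test, univariate=univariate, **kw)

    elapsed = _time.time() - t0
    if isinstance(result, SelectionResult):
        log.info(
            "%s/%s selected %d features in %d tests (%.2fs, seed %d)",
            cfg.algorithm, test, len(result.selected), result.n_tests,
            elapsed, cfg.seed,
        )
    else:
        log.info(
            "gomp/%s selected %d features (%.2fs)", test, len(result.selected), elapsed
        )

    if cfg.out:
        out = Path(cfg.out)
        out.parent.mkdir(parents=True, exist_ok=True)
        out.with_suffix(".json").write_text(result.to_json())
        out.with_suffix(".res.tsv").write_text(result.to_tsv())
        if sig is not None:
            out.with_suffix(".signatures.tsv").write_text(sig.to_tsv())
        if isinstance(result, SelectionResult) and result.univariate is not None:
            out.with_suffix(".univariate.json").write_text(
                json.dumps(
                    {
                        "test": result.univariate.test_name,
                        "stats": result.univariate.stats.tolist(),
                        "logps": result.univariate.logps.tolist(),
                    }
                )
            )
        meta = {
            "algorithm": cfg.algorithm, "test": test, "seed": cfg.seed,
            "threshold": cfg.threshold, "max_k": cfg.max_k, "K": cfg.K,
            "flavor": cfg.flavor, "wall_time_s": elapsed,
        }
        if isinstance(result, SelectionResult):
            meta["n_tests"] = result.n_tests
        out.with_suffix(".log.json").write_text(json.dumps(meta, indent=2))
    return (result, sig) if sig is not None else result
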