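"""Cross-validated hyperparameter assessment for the selection algorithms.

For each hyperparameter cell and each fold: select features on the
training part only, fit the matching regression model on the training
part, and score the held-out part.  Metrics follow the target type:
AUC / accuracy / F score for binary (accuracy for nominal), MSE / MAE /
proportion of variance explained for continuous, and the concordance
index for survival targets.  Folds are stratified for binary/nominal
targets and plain random otherwise, and depend only on (n, folds, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from .ci_tests import default_test_for, dispatch
from .gomp import gomp
from .search import AlgoConfig, mmpc, ses
from .targets import TargetSpec

_HIGHER_IS_BETTER = {"auc", "accuracy", "f_score", "pve", "concordance_index"}
_METRIC_KINDS = {
    "auc": ("binary",),
    "accuracy": ("binary", "nominal"),
    "f_score": ("binary",),
    "mse": ("continuous",),
    "mae": ("continuous",),
    "pve": ("continuous",),
    "concordance_index": ("survival",),
}


@dataclass
class CVReport:
    metric: str
    algorithm: str
    fold_scores: dict[tuple, list[float]]
    mean_scores: dict[tuple, float]
    best_cell: dict
    grid: list[dict] = field(default_factory=list)


def default_metric_for(kind: str) -> str:
    return {
        "continuous": "mse",
        "binary": "auc",
        "nominal": "accuracy",
        "counts": "mse",
        "survival": "concordance_index",
    }[kind]


def _subset_target(target: TargetSpec, idx) -> TargetSpec:
    if target.kind == "survival":
        return TargetSpec(target.values[idx], "survival", status=target.status[idx])
    return TargetSpec(target.values[idx], target.kind)


def _fit_predict(family, tr: TargetSpec, Xtr, Xte):
    """Fit the final model on the training fold, return held-out
    predictions on the scale the metric expects."""
    import statsmodels.api as sm

    n_tr, n_te = Xtr.shape[0], Xte.shape[0]
    Ztr = np.column_stack([np.ones(n_tr), Xtr])
    Zte = np.column_stack([np.ones(n_te), Xte])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if family == "gaussian":
            beta, *_ = np.linalg.lstsq(Ztr, tr.values, rcond=None)
            return Zte @ beta
        if family == "binary":
            res = sm.GLM(tr.codes.astype(float), Ztr, family=sm.families.Binomial()).fit()
            return res.predict(Zte)
        if family in ("poisson", "qpoisson", "negbin"):
            res = sm.GLM(tr.values, Ztr, family=sm.families.Poisson()).fit()
            return res.predict(Zte)
        if family == "nominal":
            res = sm.MNLogit(tr.codes, Ztr).fit(disp=0)
            return np.asarray(res.predict(Zte))
        if family in ("cox", "weibull"):
            from lifelines import CoxPHFitter

            if Xtr.shape[1] == 0:
                return np.zeros(n_te)
            df = pd.DataFrame(Xtr, columns=[f"x{i}" for i in range(Xtr.shape[1])])
            df["time"] = tr.values
            df["event"] = tr.status
            cph = CoxPHFitter(penalizer=0.01).fit(df, "time", "event")
            dfe = pd.DataFrame(Xte, columns=[f"x{i}" for i in range(Xte.shape[1])])
            return np.asarray(cph.predict_partial_hazard(dfe))
    raise ValueError(f"no predictor for family {family}")


def _score(metric, te: TargetSpec, pred) -> float:
    from sklearn import metrics as skm

    if metric == "auc":
        return float(skm.roc_auc_score(te.codes, pred))
    if metric == "accuracy":
        if pred.ndim == 2:
            labels = pred.argmax(axis=1)
        else:
            labels = (pred >= 0.5).astype(int)
        return float((labels == te.codes).mean())
    if metric == "f_score":
        return float(skm.f1_score(te.codes, (pred >= 0.5).astype(int)))
    if metric == "mse":
        return float(skm.mean_squared_error(te.values, pred))
    if metric == "mae":
        return float(skm.mean_absolute_error(te.values, pred))
    if metric == "pve":
        var = float(np.var(te.values))
        if var == 0:
            return 0.0
        return 1.0 - float(skm.mean_squared_error(te.values, pred)) / var
    if metric == "concordance_index":
        from lifelines.utils import concordance_index

        return float(concordance_index(te.values, -np.asarray(pred), te.status))
    raise ValueError(f"unknown metric {metric!r}")


def cross_validate(
    target: TargetSpec,
    X: np.ndarray,
    algorithm: str = "mmpc",
    hyper_grid: list[dict] | None = None,
    folds: int = 5,
    metric: str | None = None,
    seed: int = 0,
    test: str | None = None,
) -> CVReport:
    """Grid-search hyperparameters of mmpc / ses / gomp by K-fold CV."""
    if algorithm not in ("mmpc", "ses", "gomp"):
        raise ValueError("cross-validation supports mmpc, ses and gomp only")
    if metric is None:
        metric = default_metric_for(target.kind)
    if metric not in _METRIC_KINDS:
        raise ValueError(
            f"unknown metric {metric!r}; choose from {sorted(_METRIC_KINDS)}"
        )
    if target.kind not in _METRIC_KINDS[metric]:
        raise ValueError(
            f"metric {metric!r} is incompatible with a {target.kind} target"
        )
    if test is None:
        test = default_test_for(target.kind)
    family = dispatch(test)
    if family in ("fisher", "spearman"):
        family = "gaussian"
    if hyper_grid is None:
        hyper_grid = (
            [{"tol": t} for t in (2.0, 3.84, 8.0)]
            if algorithm == "gomp"
            else [{"threshold": a, "max_k": k} for a in (0.01, 0.05) for k in (2, 3)]
        )

    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if target.kind in ("binary", "nominal"):
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        split_iter = list(splitter.split(np.zeros(n), target.codes))
    else:
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
        split_iter = list(splitter.split(np.zeros(n)))

    fold_scores: dict[tuple, list[float]] = {}
    for cell in hyper_grid:
        key = tuple(sorted(cell.items()))
        scores = []
        for tr_idx, te_idx in split_iter:
            tr = _subset_target(target, tr_idx)
            te = _subset_target(target, te_idx)
            Xtr, Xte = X[tr_idx], X[te_idx]
            if algorithm == "gomp":
                path = gomp(tr, Xtr, test=test, **cell)
                sel = path.selected
            elif algorithm == "ses":
                res, _ = ses(tr, Xtr, AlgoConfig(**cell), test=test)
                sel = res.selected
            else:
                res = mmpc(tr, Xtr, AlgoConfig(**cell), test=test)
                sel = res.selected
            pred = _fit_predict(family, tr, Xtr[:, sel], Xte[:, sel])
            scores.append(_score(metric, te, pred))
        fold_scores[key] = scores

    mean_scores = {k: float(np.mean(v)) for k, v in fold_scores.items()}
    pick = max if metric in _HIGHER_IS_BETTER else min
    best_key = pick(sorted(mean_scores), key=lambda k: mean_scores[k])
    return CVReport(
        metric=metric,
        algorithm=algorithm,
        fold_scores=fold_scores,
        mean_scores=mean_scores,
        best_cell=dict(best_key),
        grid=list(hyper_grid),
    )
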