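"""Reading and writing datasets.

CSV/TSV with a header row is the interchange format.  Non-numeric columns
are detected and label-encoded (sorted label order, recorded mapping) so
they can enter regression designs as categorical features; missing values
are a hard error naming the offending rows and columns -- no silent
imputation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .simgen import SyntheticDataset
from .targets import TargetSpec


@dataclass
class LoadedDataset:
    X: np.ndarray
    target: TargetSpec
    feature_names: list[str]
    categorical: frozenset[int] = frozenset()
    encodings: dict[str, list] = field(default_factory=dict)


def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_dataset(
    path: str | Path,
    target: str | None = None,
    kind: str | None = None,
    time: str | None = None,
    status: str | None = None,
    sep: str | None = None,
) -> LoadedDataset:
    """Load a feature table plus target specification.

    Either ``target`` (+ ``kind``) names one outcome column, or ``time``
    and ``status`` name the survival pair.  All remaining columns are
    features, in file order.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep))
    if df.isna().any().any():
        bad_cols = [c for c in df.columns if df[c].isna().any()]
        bad_rows = df.index[df.isna().any(axis=1)].tolist()[:20]
        raise ValueError(
            f"missing values in columns {bad_cols} (rows {bad_rows}); "
            "impute or drop them before selection"
        )

    if time is not None or status is not None:
        if time is None or status is None:
            raise ValueError("survival targets need both time and status columns")
        for c in (time, status):
            if c not in df.columns:
                raise ValueError(f"column {c!r} not found in {path.name}")
        tvals = df[time].to_numpy(dtype=float)
        svals = df[status].to_numpy()
        tspec = TargetSpec(tvals, "survival", status=svals)
        feats = df.drop(columns=[time, status])
    else:
        if target is None or kind is None:
            raise ValueError("provide target and kind, or time and status")
        if target not in df.columns:
            raise ValueError(f"column {target!r} not found in {path.name}")
        yraw = df[target]
        if kind in ("binary", "nominal") and not pd.api.types.is_numeric_dtype(yraw):
            levels = sorted(yraw.astype(str).unique())
            yvals = yraw.astype(str).map({l: i for i, l in enumerate(levels)}).to_numpy(float)
        else:
            yvals = yraw.to_numpy(dtype=float)
        tspec = TargetSpec(yvals, kind)
        feats = df.drop(columns=[target])

    feature_names = list(feats.columns)
    cols = []
    categorical = set()
    encodings: dict[str, list] = {}
    for j, name in enumerate(feature_names):
        col = feats[name]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.to_numpy(dtype=float))
        else:
            levels = sorted(col.astype(str).unique())
            mapping = {l: i for i, l in enumerate(levels)}
            cols.append(col.astype(str).map(mapping).to_numpy(dtype=float))
            categorical.add(j)
            encodings[name] = levels
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return LoadedDataset(
        X=X,
        target=tspec,
        feature_names=feature_names,
        categorical=frozenset(categorical),
        encodings=encodings,
    )


def write_dataset(ds: SyntheticDataset, prefix: str | Path) -> dict[str, str]:
    """Write a synthetic dataset as ``<prefix>.csv`` (features + target
    columns) with a ``<prefix>.truth.tsv`` / ``<prefix>.json`` sidecar
    holding the planted ground truth and generator parameters."""
    prefix = Path(prefix)
    cols = {f"x{j}": ds.X[:, j] for j in range(ds.p)}
    if ds.target.kind == "survival":
        cols["time"] = ds.target.values
        cols["status"] = ds.target.status
    else:
        cols["y"] = ds.target.values
    data_path = prefix.with_suffix(".csv")
    pd.DataFrame(cols).to_csv(data_path, index=False)

    truth_path = prefix.with_suffix(".truth.tsv")
    pd.DataFrame(
        {"active": ds.active, "beta": ds.beta}
    ).to_csv(truth_path, sep="\t", index=False)

    manifest_path = prefix.with_suffix(".json")
    manifest = {
        "params": ds.params,
        "target_kind": ds.target.kind,
        "active": [int(a) for a in ds.active],
        "beta": [float(b) for b in ds.beta],
        "equiv_classes": [[int(v) for v in c] for c in ds.equiv_classes],
    }
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return {
        "data": str(data_path),
        "truth": str(truth_path),
        "manifest": str(manifest_path),
    }
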