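"""File I/O: delimited series tables, parameter tables, configs, surfaces.

Numeric CSV output is serialized at 12 significant digits so every
table round-trips through its reader without visible loss; on-screen
summaries round to 3 decimals.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidInputError
from .estimation import ObservedSeries
from .model import SourceEmotionSpec, TargetEmotionSpec, Trajectory, TransferModelSpec
from .strategy import QuadraticSurface

__all__ = [
    "FLOAT_FMT",
    "read_series_table",
    "write_series",
    "write_trajectory",
    "spec_to_frame",
    "spec_from_frame",
    "read_spec_csv",
    "write_spec_csv",
    "spec_to_dict",
    "spec_from_dict",
    "load_config",
    "save_config",
    "write_surface",
    "read_surface",
]

FLOAT_FMT = "%.12g"


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"input file does not exist: {path}")
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep)


def read_series_table(
    path: str | Path,
    mapping: Mapping[str, str] | None = None,
    time_col: str | None = None,
    cumulative: bool = True,
) -> ObservedSeries:
    """Read a delimited series table into an :class:`ObservedSeries`.

    ``mapping`` maps file columns to emotion labels (default: every
    non-time column under its own name); ``time_col`` defaults to the
    first column. Incremental input (``cumulative=False``) is cumulated
    after validation of non-negative increments.
    """
    df = _read_table(path)
    if df.shape[1] < 2:
        raise InvalidInputError(f"{path}: need a time column plus at least one emotion column")
    time_col = time_col if time_col is not None else df.columns[0]
    if time_col not in df.columns:
        raise InvalidInputError(f"{path}: missing time column {time_col!r}")
    if mapping is None:
        mapping = {c: c for c in df.columns if c != time_col}
    missing = [c for c in mapping if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{path}: missing mapped columns {missing}")
    cols = list(mapping)
    for col in cols:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise InvalidInputError(
                f"{path}: non-numeric cell at row {row}, column {col!r}: {df[col].iloc[row]!r}"
            )
        if numeric.isna().any():
            row = int(np.flatnonzero(numeric.isna())[0])
            raise InvalidInputError(f"{path}: empty cell at row {row}, column {col!r}")
        df[col] = numeric
    values = df[cols].to_numpy(dtype=float)
    labels = tuple(mapping[c] for c in cols)
    if not cumulative:
        if np.any(values < 0):
            k, j = np.argwhere(values < 0)[0]
            raise InvalidInputError(
                f"{path}: negative increment at row {k}, column {cols[j]!r}"
            )
        values = np.cumsum(values, axis=0)
    else:
        diffs = np.diff(values, axis=0)
        bad = np.argwhere(diffs < 0)
        if bad.size:
            k, j = bad[0]
            raise InvalidInputError(
                f"{path}: cumulative column {cols[j]!r} decreases at row {k + 1}"
            )
    times = np.arange(values.shape[0])
    return ObservedSeries(times=times, values=values, labels=labels, cumulative=True)


def write_series(series: ObservedSeries, path: str | Path) -> None:
    series.to_frame().to_csv(path, index=False, float_format=FLOAT_FMT)


def write_trajectory(traj: Trajectory, path: str | Path, shares: bool = False) -> None:
    traj.to_frame(shares=shares).to_csv(path, index=False, float_format=FLOAT_FMT)


def spec_to_frame(spec: TransferModelSpec) -> pd.DataFrame:
    """Flat parameter table: columns role, label, x0, r, K, a, b."""
    rows = [
        {"role": "source", "label": s.label, "x0": s.x0, "r": s.r, "K": s.K,
         "a": s.a, "b": s.b}
        for s in spec.sources
    ]
    rows.append({"role": "target", "label": spec.target.label, "x0": spec.target.y0,
                 "r": spec.target.r, "K": spec.target.K, "a": np.nan, "b": np.nan})
    return pd.DataFrame(rows)


def spec_from_frame(df: pd.DataFrame) -> TransferModelSpec:
    required = {"role", "label", "x0", "r", "K"}
    if not required.issubset(df.columns):
        raise InvalidInputError(f"parameter table must have columns {sorted(required)}")
    sources = []
    target = None
    for _, row in df.iterrows():
        if row["role"] == "source":
            a = row.get("a")
            b = row.get("b")
            sources.append(SourceEmotionSpec(
                label=str(row["label"]), x0=float(row["x0"]), r=float(row["r"]),
                K=float(row["K"]),
                a=None if pd.isna(a) else float(a),
                b=None if pd.isna(b) else float(b),
            ))
        elif row["role"] == "target":
            if target is not None:
                raise InvalidInputError("parameter table contains more than one target row")
            target = TargetEmotionSpec(label=str(row["label"]), y0=float(row["x0"]),
                                       r=float(row["r"]), K=float(row["K"]))
        else:
            raise InvalidInputError(f"unknown role {row['role']!r}; expected 'source' or 'target'")
    if target is None:
        raise InvalidInputError("parameter table has no target row")
    return TransferModelSpec(sources=tuple(sources), target=target)


def read_spec_csv(path: str | Path) -> TransferModelSpec:
    return spec_from_frame(_read_table(path))


def write_spec_csv(spec: TransferModelSpec, path: str | Path) -> None:
    spec_to_frame(spec).to_csv(path, index=False, float_format=FLOAT_FMT)


def spec_to_dict(spec: TransferModelSpec) -> dict:
    return {
        "sources": [
            {"label": s.label, "x0": s.x0, "r": s.r, "K": s.K, "a": s.a, "b": s.b}
            for s in spec.sources
        ],
        "target": {"label": spec.target.label, "y0": spec.target.y0,
                   "r": spec.target.r, "K": spec.target.K},
    }


def spec_from_dict(d: Mapping) -> TransferModelSpec:
    try:
        sources = tuple(
            SourceEmotionSpec(label=s["label"], x0=s["x0"], r=s["r"], K=s["K"],
                              a=s.get("a"), b=s.get("b"))
            for s in d["sources"]
        )
        t = d["target"]
        target = TargetEmotionSpec(label=t["label"], y0=t["y0"], r=t["r"], K=t["K"])
    except (KeyError, TypeError) as exc:
        raise InvalidInputError(f"malformed model config: {exc}") from exc
    return TransferModelSpec(sources=sources, target=target)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise InvalidInputError(f"config {path} must be a mapping at top level")
    return cfg


def save_config(cfg: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=False)


def write_surface(surface: QuadraticSurface, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(surface.to_dict(), fh, indent=2)


def read_surface(path: str | Path) -> QuadraticSurface:
    with open(path) as fh:
        return QuadraticSurface.from_dict(json.load(fh))
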