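"""Validated table ingestion and report serialisation.

Three CSV dialects are understood (headers required, '.' decimal,
UTF-8):

* viability:  ``cell_line,condition,time_h,replicate,well,rlu``
* cbmn:       ``slide_id,cell_line,condition,time_h,n_mono,n_bi,n_tri,
  n_tetra,n_total,n_bn_scored,n_mn``
* comet:      ``cell_id,slide_id,cell_line,condition,time_h,
  tail_dna_pct,tail_length,centroid_distance``
* trajectory: ``time_h,value[,sd,n_replicates]``

Rows violating a record invariant are rejected with line-numbered
diagnostics.  A comet table may also arrive as a single-sheet XLSX file
with the same columns.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .growth import GrowthTrajectory, RISchedule
from .indices import CometCellRecord, MNScoreRecord

__all__ = [
    "TableValidationError",
    "read_table",
    "read_viability",
    "read_cbmn",
    "read_comet",
    "read_trajectory_csv",
    "write_trajectory_csv",
    "read_schedule",
    "write_schedule",
    "write_report",
    "read_report",
]

SCHEMAS = {
    "viability": ["cell_line", "condition", "time_h", "replicate", "well", "rlu"],
    "cbmn": [
        "slide_id", "cell_line", "condition", "time_h", "n_mono", "n_bi",
        "n_tri", "n_tetra", "n_total", "n_bn_scored", "n_mn",
    ],
    "comet": [
        "cell_id", "slide_id", "cell_line", "condition", "time_h",
        "tail_dna_pct", "tail_length", "centroid_distance",
    ],
}


class TableValidationError(ValueError):
    """Raised when a table has a wrong header or invariant-violating rows.

    ``errors`` lists (line_number, message) pairs; line numbers are
    1-based file lines (header is line 1).
    """

    def __init__(self, path: str | Path, errors: list[tuple[int, str]]):
        self.path = str(path)
        self.errors = errors
        detail = "; ".join(f"line {ln}: {msg}" for ln, msg in errors[:10])
        more = "" if len(errors) <= 10 else f" (+{len(errors) - 10} more)"
        super().__init__(f"{path}: {detail}{more}")


def _load_frame(path: str | Path, schema_name: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    expected = SCHEMAS[schema_name]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise TableValidationError(
            path, [(1, f"missing required columns {missing} for schema {schema_name!r}")]
        )
    return df


def read_cbmn(path: str | Path) -> list[MNScoreRecord]:
    """Read and validate a CBMN scoring table."""
    df = _load_frame(path, "cbmn")
    records, errors = [], []
    for i, row in df.iterrows():
        line = int(i) + 2  # header is line 1
        try:
            records.append(
                MNScoreRecord(
                    slide_id=str(row["slide_id"]),
                    cell_line=str(row["cell_line"]),
                    condition=str(row["condition"]),
                    time_h=float(row["time_h"]),
                    n_mono=int(row["n_mono"]),
                    n_bi=int(row["n_bi"]),
                    n_tri=int(row["n_tri"]),
                    n_tetra=int(row["n_tetra"]),
                    n_total=int(row["n_total"]),
                    n_bn_scored=int(row["n_bn_scored"]),
                    n_mn=int(row["n_mn"]),
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append((line, str(exc)))
    if errors:
        raise TableValidationError(path, errors)
    return records


def read_comet(path: str | Path) -> list[CometCellRecord]:
    """Read and validate a per-cell comet table (CSV or simple XLSX)."""
    df = _load_frame(path, "comet")
    records, errors = [], []
    for i, row in df.iterrows():
        line = int(i) + 2
        try:
            records.append(
                CometCellRecord(
                    cell_id=str(row["cell_id"]),
                    slide_id=str(row["slide_id"]),
                    cell_line=str(row["cell_line"]),
                    condition=str(row["condition"]),
                    time_h=float(row["time_h"]),
                    tail_dna_pct=float(row["tail_dna_pct"]),
                    tail_length=float(row["tail_length"]),
                    centroid_distance=float(row["centroid_distance"]),
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append((line, str(exc)))
    if errors:
        raise TableValidationError(path, errors)
    return records


def read_viability(path: str | Path) -> pd.DataFrame:
    """Read and validate a per-well viability table."""
    df = _load_frame(path, "viability")
    errors = []
    for i, row in df.iterrows():
        line = int(i) + 2
        try:
            if float(row["rlu"]) <= 0:
                errors.append((line, f"rlu must be positive, got {row['rlu']}"))
            if float(row["time_h"]) < 0:
                errors.append((line, f"time_h must be >= 0, got {row['time_h']}"))
        except (ValueError, TypeError) as exc:
            errors.append((line, str(exc)))
    if errors:
        raise TableValidationError(path, errors)
    return df


def read_table(path: str | Path, schema_name: str):
    """Dispatch on schema name: 'viability' | 'cbmn' | 'comet'."""
    readers = {"viability": read_viability, "cbmn": read_cbmn, "comet": read_comet}
    try:
        return readers[schema_name](path)
    except KeyError:
        raise ValueError(f"unknown schema {schema_name!r}") from None


def read_trajectory_csv(path: str | Path) -> GrowthTrajectory:
    """Read a ``time_h,value[,sd,n_replicates]`` trajectory CSV."""
    df = pd.read_csv(path)
    for col in ("time_h", "value"):
        if col not in df.columns:
            raise TableValidationError(path, [(1, f"missing column {col!r}")])
    return GrowthTrajectory(
        df["time_h"].to_numpy(dtype=float), df["value"].to_numpy(dtype=float)
    )


def write_trajectory_csv(traj: GrowthTrajectory, path: str | Path) -> None:
    pd.DataFrame({"time_h": traj.times, "value": traj.values}).to_csv(
        path, index=False
    )


def read_schedule(path: str | Path) -> RISchedule:
    """Read a schedule config: one ``t_start,t_end,reduction`` row per line
    (lines starting with '#' are comments)."""
    rows = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(",")
        if len(parts) != 3:
            raise ValueError(f"{path}: malformed schedule row {raw!r}")
        rows.append(tuple(float(p) for p in parts))
    return RISchedule(rows)


def write_schedule(schedule: RISchedule, path: str | Path) -> None:
    lines = ["# t_start,t_end,reduction"]
    lines += [f"{a:g},{b:g},{f:g}" for a, b, f in schedule.segments]
    Path(path).write_text("\n".join(lines) + "\n")


def _jsonify(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_report(report: Any, path: str | Path) -> None:
    """Serialise a report (dataclass or dict tree) to JSON."""
    Path(path).write_text(json.dumps(_jsonify(report), indent=2, sort_keys=True) + "\n")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
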