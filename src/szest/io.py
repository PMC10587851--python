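"""Readers and writers for the package's CSV/JSON artifacts.

Field CSV schema: ``location_id, x_deg, y_deg, value_db`` (dB values written
with 2-decimal precision).  Cohorts are stored as a directory with a long
``fields.csv`` (added ``subject_id, eye_id, field_label, repeat_index``
columns), an ``eyes.csv`` with per-eye metadata, and a ``manifest.json``.
Left-eye field files are mirrored into right-eye convention on read and the
mirroring recorded in the returned metadata.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import pandas as pd

from .field_model import Field, Grid, make_grid
from .priors import PairedRecord, PriorTable
from .synthetic_cohort import SyntheticEye

__all__ = [
    "read_field_csv",
    "write_field_csv",
    "read_paired_records",
    "write_paired_records",
    "read_prior_table",
    "write_prior_table",
    "write_cohort",
    "read_cohort",
    "RunManifest",
]

_FIELD_COLS = ["location_id", "x_deg", "y_deg", "value_db"]


class SchemaError(ValueError):
    """A file did not match its documented schema."""


def _check_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def _validate_field_rows(df: pd.DataFrame, grid: Grid, path) -> tuple[pd.DataFrame, bool]:
    """Validate coordinates/values; mirror left-eye coordinates if needed."""
    coords = grid.coord_index()
    mirrored = False
    xs = df["x_deg"].to_numpy(dtype=float)
    ys = df["y_deg"].to_numpy(dtype=float)
    if any((x, y) not in coords for x, y in zip(xs, ys)):
        # try the left-eye (mirrored) lattice
        if all((-x, y) in coords for x, y in zip(xs, ys)):
            df = df.assign(x_deg=-df["x_deg"])
            mirrored = True
        else:
            for row, (x, y) in enumerate(zip(xs, ys), start=2):
                if (x, y) not in coords and (-x, y) not in coords:
                    raise SchemaError(
                        f"{path}: line {row}: ({x}, {y}) is not a 24-2 location"
                    )
            raise SchemaError(f"{path}: mixed left/right-eye coordinates")
    for row, v in enumerate(df["value_db"], start=2):
        if not 0.0 <= float(v) <= 40.0:
            raise SchemaError(f"{path}: line {row}: value_db {v} outside [0, 40]")
    ids = {coords[(x, y)] for x, y in zip(df["x_deg"], df["y_deg"])}
    expected = {loc.id for loc in grid.locations}
    if ids != expected:
        raise SchemaError(f"{path}: field does not cover all 52 locations exactly once")
    return df, mirrored


def read_field_csv(path, label: str = "") -> tuple[Field, dict]:
    """Read one field; returns (field, metadata).  Left-eye files are
    mirrored to the internal right-eye convention and flagged in metadata."""
    path = Path(path)
    df = pd.read_csv(path)
    _check_columns(df, _FIELD_COLS, path)
    grid = make_grid()
    df, mirrored = _validate_field_rows(df, grid, path)
    coords = grid.coord_index()
    values = {
        coords[(float(r.x_deg), float(r.y_deg))]: float(r.value_db)
        for r in df.itertuples()
    }
    return Field(values=values, label=label), {"mirrored_from_left": mirrored, "path": str(path)}


def write_field_csv(path, f: Field, grid: Grid | None = None) -> None:
    grid = grid or make_grid()
    rows = [
        {
            "location_id": loc.id,
            "x_deg": loc.x_deg,
            "y_deg": loc.y_deg,
            "value_db": round(f.values[loc.id], 2),
        }
        for loc in grid.locations
    ]
    pd.DataFrame(rows, columns=_FIELD_COLS).to_csv(path, index=False)


def write_paired_records(path, records: Sequence[PairedRecord]) -> None:
    pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "eye_id": r.eye_id,
                "location_id": r.location_id,
                "predicted_db": round(r.predicted_db, 2),
                "observed_db": round(r.observed_db, 2),
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def read_paired_records(path) -> list[PairedRecord]:
    path = Path(path)
    df = pd.read_csv(path)
    _check_columns(
        df, ["subject_id", "eye_id", "location_id", "predicted_db", "observed_db"], path
    )
    for row, r in enumerate(df.itertuples(), start=2):
        for col in ("predicted_db", "observed_db"):
            v = float(getattr(r, col))
            if not 0.0 <= v <= 40.0:
                raise SchemaError(f"{path}: line {row}: {col} {v} outside [0, 40]")
    return [
        PairedRecord(
            subject_id=str(r.subject_id),
            eye_id=str(r.eye_id),
            location_id=int(r.location_id),
            predicted_db=float(r.predicted_db),
            observed_db=float(r.observed_db),
        )
        for r in df.itertuples()
    ]


def write_prior_table(path, table: PriorTable) -> None:
    Path(path).write_text(table.to_json())


def read_prior_table(path) -> PriorTable:
    return PriorTable.from_json(Path(path).read_text())


def write_cohort(outdir, cohort: Sequence[SyntheticEye], config: dict | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid = make_grid()
    rows = []

    def add(eye: SyntheticEye, f: Field, label: str, repeat: int) -> None:
        for loc in grid.locations:
            rows.append(
                {
                    "subject_id": eye.subject_id,
                    "eye_id": eye.eye_id,
                    "field_label": label,
                    "repeat_index": repeat,
                    "location_id": loc.id,
                    "x_deg": loc.x_deg,
                    "y_deg": loc.y_deg,
                    "value_db": round(f.values[loc.id], 2),
                }
            )

    eye_rows = []
    for eye in cohort:
        add(eye, eye.true_field, "true", 0)
        for k, pf in enumerate(eye.predicted_fields):
            add(eye, pf, "predicted", k)
        eye_rows.append(
            {
                "subject_id": eye.subject_id,
                "eye_id": eye.eye_id,
                "gve_sigma": eye.gve_sigma,
                "severity_label": eye.severity_label,
                "n_scans": len(eye.predicted_fields),
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "fields.csv", index=False)
    pd.DataFrame(eye_rows).to_csv(outdir / "eyes.csv", index=False)
    (outdir / "manifest.json").write_text(json.dumps({"config": config or {}}, indent=2))


def read_cohort(indir) -> list[SyntheticEye]:
    indir = Path(indir)
    fields = pd.read_csv(indir / "fields.csv")
    eyes = pd.read_csv(indir / "eyes.csv")
    _check_columns(
        fields,
        ["subject_id", "eye_id", "field_label", "repeat_index", "location_id", "value_db"],
        indir / "fields.csv",
    )
    out = []
    for meta in eyes.itertuples():
        g = fields[fields["eye_id"] == meta.eye_id]
        true_rows = g[g["field_label"] == "true"]
        true_field = Field(
            values=dict(
                zip(true_rows["location_id"].astype(int), true_rows["value_db"].astype(float))
            ),
            label="true",
        )
        preds = []
        pg = g[g["field_label"] == "predicted"]
        for k in sorted(pg["repeat_index"].unique()):
            pk = pg[pg["repeat_index"] == k]
            preds.append(
                Field(
                    values=dict(
                        zip(pk["location_id"].astype(int), pk["value_db"].astype(float))
                    ),
                    label=f"predicted_{k}",
                )
            )
        out.append(
            SyntheticEye(
                subject_id=str(meta.subject_id),
                eye_id=str(meta.eye_id),
                true_field=true_field,
                predicted_fields=preds,
                gve_sigma=float(meta.gve_sigma),
                severity_label=str(meta.severity_label),
            )
        )
    return out


@dataclass
class RunManifest:
    """Provenance record written alongside every CLI run."""

    tool_version: str
    command: str
    config: dict
    seed: int | None
    inputs: dict = dc_field(default_factory=dict)
    outputs: list = dc_field(default_factory=list)
    timestamp: str = ""

    def write(self, path) -> None:
        self.timestamp = datetime.now(timezone.utc).isoformat()
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str))

    @staticmethod
    def digest(path) -> str:
        return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
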