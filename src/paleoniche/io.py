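"""Readers and writers for the pipeline's standard formats.

Calibration curves use the IntCal columnar dialect (comma- or whitespace-
separated ``calendar age BP, radiocarbon age BP, curve error`` with optional
header/comment lines); archaeological contexts and their dates travel as two
CSV tables keyed by context; observation tables, niche series and tuning
grids round-trip through CSV; fitted models serialize to JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .chronology import CalibrationCurve, DatedContext, DateMeasurement
from .maxent import MaxentModel


class ParseError(ValueError):
    """Malformed input file, with file and record context in the message."""


# -- calibration curves -----------------------------------------------------

def read_calibration_curve(path) -> CalibrationCurve:
    """Parse an IntCal-dialect curve file.

    Lines starting with ``#`` and non-numeric header lines are skipped; each
    data line must begin with three numeric fields (calendar age BP,
    radiocarbon age BP, one-sigma curve error); extra columns are ignored.
    Rows are sorted into increasing calendar age.
    """
    path = Path(path)
    cal, c14, err = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            parts = text.replace(",", " ").split()
            try:
                vals = [float(p) for p in parts[:3]]
            except ValueError:
                if not cal:  # tolerate a leading header line
                    continue
                raise ParseError(f"{path}:{lineno}: non-numeric data line {text!r}")
            if len(vals) < 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns, got {len(vals)}")
            cal.append(vals[0])
            c14.append(vals[1])
            err.append(vals[2])
    if not cal:
        raise ParseError(f"{path}: no data rows found")
    order = np.argsort(cal)
    arr = lambda xs: np.asarray(xs, dtype=float)[order]
    return CalibrationCurve(cal_age=arr(cal), c14_age=arr(c14), error=arr(err))


def write_calibration_curve(curve: CalibrationCurve, path) -> None:
    with open(path, "w") as fh:
        fh.write("# cal BP, 14C age BP, error\n")
        for c, a, e in zip(curve.cal_age, curve.c14_age, curve.error):
            fh.write(f"{float(c)!r},{float(a)!r},{float(e)!r}\n")


# -- archaeological contexts and dates --------------------------------------

def write_contexts(contexts: list[DatedContext], contexts_path, dates_path) -> None:
    """Write the two-table layout: contexts and their per-context dates."""
    ctx_rows = [
        {
            "locality_id": c.locality_id,
            "context_id": c.context_id,
            "longitude": c.longitude,
            "latitude": c.latitude,
        }
        for c in contexts
    ]
    date_rows = [
        {"context_id": c.context_id, "method": m.method, "age": m.age, "error": m.error}
        for c in contexts
        for m in c.measurements
    ]
    pd.DataFrame(ctx_rows).to_csv(contexts_path, index=False)
    pd.DataFrame(date_rows, columns=["context_id", "method", "age", "error"]).to_csv(
        dates_path, index=False
    )


def read_contexts(contexts_path, dates_path) -> list[DatedContext]:
    """Read contexts and attach each context's date measurements."""
    try:
        ctx = pd.read_csv(contexts_path)
        dates = pd.read_csv(dates_path)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"could not read context tables: {exc}") from exc
    for col in ("locality_id", "context_id", "longitude", "latitude"):
        if col not in ctx.columns:
            raise ParseError(f"{contexts_path}: missing column {col!r}")
    for col in ("context_id", "method", "age", "error"):
        if col not in dates.columns:
            raise ParseError(f"{dates_path}: missing column {col!r}")
    by_ctx: dict[str, list[DateMeasurement]] = {}
    for i, row in dates.iterrows():
        try:
            m = DateMeasurement(
                method=str(row["method"]), age=float(row["age"]), error=float(row["error"])
            )
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{dates_path}: record {i}: {exc}") from exc
        by_ctx.setdefault(str(row["context_id"]), []).append(m)
    return [
        DatedContext(
            locality_id=str(r["locality_id"]),
            context_id=str(r["context_id"]),
            longitude=float(r["longitude"]),
            latitude=float(r["latitude"]),
            measurements=by_ctx.get(str(r["context_id"]), []),
        )
        for _, r in ctx.iterrows()
    ]


# -- tables and models ------------------------------------------------------

def write_table(df: pd.DataFrame, path, provenance: dict | None = None) -> None:
    """CSV writer with an optional provenance header of ``# key: value`` lines."""
    with open(path, "w") as fh:
        for k, v in (provenance or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, comment="#", dtype={"context_id": str})
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"could not read table {path}: {exc}") from exc
    if "context_id" in df.columns:
        df["context_id"] = df["context_id"].fillna("")
    return df


def save_model(model: MaxentModel, path) -> None:
    Path(path).write_text(model.to_json())


def load_model(path) -> MaxentModel:
    try:
        return MaxentModel.from_json(Path(path).read_text())
    except (OSError, json.JSONDecodeError, KeyError) as exc:
        raise ParseError(f"could not load model {path}: {exc}") from exc
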