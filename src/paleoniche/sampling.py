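"""Background-point sampling and space-time predictor extraction.

An observation table is a plain :class:`pandas.DataFrame` with one record per
presence or background point and the columns

``label``      "presence" or "background"
``year_bp``    the millennium slice the record belongs to
``row, col``   grid cell indices
``lon, lat``   geographic coordinates (nominal for synthetic worlds)
``context_id`` source context key (presences only)

plus, after extraction, one column per climate variable.  Records never sit
on sea or ice cells: background points are drawn from land-valid cells only,
and presences that fall on masked cells at their assigned millennium are
excluded (with a logged count) rather than snapped to a nearby valid cell.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .grids import ClimateStack, LAND

logger = logging.getLogger(__name__)

PRESENCE = "presence"
BACKGROUND = "background"

BASE_COLUMNS = ["label", "year_bp", "row", "col", "lon", "lat", "context_id"]


class SamplingError(RuntimeError):
    """A slice cannot supply the requested number of background cells."""


def sample_background(
    stack: ClimateStack,
    n_per_slice: int = 100,
    slices: np.ndarray | None = None,
    seed: int = 0,
    replace: bool = False,
) -> pd.DataFrame:
    """Uniform background points over land-valid cells, per millennium.

    Exactly ``n_per_slice`` records per requested slice, drawn uniformly over
    that slice's land cells — without replacement by default, so a slice with
    fewer valid cells than requested raises a :class:`SamplingError` naming
    the slice.  The same cell may recur in different slices: each slice is a
    distinct environment.
    """
    years = np.asarray(slices if slices is not None else stack.years)
    rng = np.random.default_rng(seed)
    frames = []
    for year in years:
        cells = stack.land_cells(year)
        if len(cells) == 0 or (len(cells) < n_per_slice and not replace):
            raise SamplingError(
                f"slice {int(year)} BP has {len(cells)} land-valid cells, "
                f"fewer than the {n_per_slice} requested"
            )
        idx = rng.choice(len(cells), size=n_per_slice, replace=replace)
        rows, cols = cells[idx, 0], cells[idx, 1]
        lon, lat = stack.transform.to_lonlat(rows, cols)
        frames.append(
            pd.DataFrame(
                {
                    "label": BACKGROUND,
                    "year_bp": int(year),
                    "row": rows,
                    "col": cols,
                    "lon": lon,
                    "lat": lat,
                    "context_id": "",
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def presences_from_chronology(filtered: pd.DataFrame, stack: ClimateStack) -> pd.DataFrame:
    """Presence records from filtered chronology output (one per observation).

    The record's time coordinate is its assigned millennium; grid cells come
    from the stack's geographic transform.
    """
    rows, cols = stack.transform.to_rowcol(filtered["longitude"].values, filtered["latitude"].values)
    return pd.DataFrame(
        {
            "label": PRESENCE,
            "year_bp": filtered["millennium"].astype(int).values,
            "row": rows,
            "col": cols,
            "lon": filtered["longitude"].values,
            "lat": filtered["latitude"].values,
            "context_id": filtered["context_id"].values,
        }
    )


def extract_values(points: pd.DataFrame, stack: ClimateStack) -> pd.DataFrame:
    """Attach each record's cell values for every predictor at its own slice.

    Records on sea/ice cells — or outside the grid extent — at their assigned
    millennium are excluded; the count is logged and stored in
    ``result.attrs["n_excluded_masked"]``.  Raises a KeyError if a record's
    slice year is absent from the stack.
    """
    df = points.reset_index(drop=True).copy()
    n_slices, H, W = stack.shape

    for year in np.unique(df["year_bp"].values):
        stack.slice_index(year)  # raises KeyError on temporal misalignment

    rows = df["row"].to_numpy(dtype=int)
    cols = df["col"].to_numpy(dtype=int)
    tidx = np.array([stack.slice_index(y) for y in df["year_bp"].values])

    in_extent = (rows >= 0) & (rows < H) & (cols >= 0) & (cols < W)
    valid = in_extent.copy()
    valid[in_extent] = stack.mask[tidx[in_extent], rows[in_extent], cols[in_extent]] == LAND

    n_excluded = int((~valid).sum())
    if n_excluded:
        logger.info("extract_values: excluded %d record(s) on masked/out-of-extent cells", n_excluded)

    kept = df[valid].copy()
    for name, arr in stack.variables.items():
        kept[name] = np.asarray(arr)[tidx[valid], rows[valid], cols[valid]]
    kept = kept.reset_index(drop=True)
    kept.attrs["n_excluded_masked"] = n_excluded
    return kept


def split_presence_background(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    pres = table[table["label"] == PRESENCE].reset_index(drop=True)
    bg = table[table["label"] == BACKGROUND].reset_index(drop=True)
    return pres, bg
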