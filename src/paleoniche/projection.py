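"""Projection of a fitted niche model over the climate stack, thresholding,
and the per-millennium niche-size bookkeeping.

Projection evaluates the model's continuous suitability for every land-valid
cell of every millennium slice (sea and ice cells are missing).  A single
optimal threshold — the cut maximizing the sum of true-positive and
true-negative rates over the training scores — converts the continuous maps
to binary presence/absence, and the per-slice presence-cell counts times the
constant cell area give the range-area time series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .grids import ClimateStack, LAND
from .maxent import MaxentModel, predict, tss_kappa, confusion_rates, youden_threshold


class ProjectionError(KeyError):
    pass


@dataclass
class PredictionStack:
    """Continuous suitability per slice; NaN on sea/ice/missing cells."""

    suitability: np.ndarray          # (slices, rows, cols) with NaN where masked
    years: np.ndarray
    cell_area_km2: float
    transform_label: str
    model_fingerprint: str

    @property
    def n_slices(self) -> int:
        return len(self.years)

    def slice_index(self, year) -> int:
        idx = np.nonzero(self.years == year)[0]
        if idx.size == 0:
            raise KeyError(f"slice year {year} BP not in prediction stack")
        return int(idx[0])

    def to_dataset(self) -> xr.Dataset:
        ds = xr.Dataset(
            {"suitability": (("time", "y", "x"), self.suitability.astype("f8"))},
            coords={
                "time": ("time", np.asarray(self.years)),
                "y": ("y", np.arange(self.suitability.shape[1])),
                "x": ("x", np.arange(self.suitability.shape[2])),
            },
        )
        ds.attrs["cell_area_km2"] = float(self.cell_area_km2)
        ds.attrs["transform"] = self.transform_label
        ds.attrs["model_fingerprint"] = self.model_fingerprint
        return ds

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")


def project_suitability(
    model: MaxentModel, stack: ClimateStack, transform: str = "logistic"
) -> PredictionStack:
    """Per-cell, per-slice suitability of the stack under the model."""
    missing = [v for v in model.variables if v not in stack.variables]
    if missing:
        raise ProjectionError(f"stack lacks model variables: {missing}")

    T, H, W = stack.shape
    out = np.full((T, H, W), np.nan)
    for t in range(T):
        valid = stack.mask[t] == LAND
        if not valid.any():
            continue
        rows = pd.DataFrame(
            {v: np.asarray(stack.variables[v])[t][valid] for v in model.variables}
        )
        out[t][valid] = predict(model, rows, transform)

    import hashlib

    fingerprint = hashlib.sha256(model.to_json().encode()).hexdigest()[:16]
    return PredictionStack(
        suitability=out,
        years=np.asarray(stack.years),
        cell_area_km2=stack.cell_area_km2,
        transform_label=transform,
        model_fingerprint=fingerprint,
    )


def optimal_threshold(
    pres_scores: np.ndarray, bg_scores: np.ndarray
) -> tuple[float, float, float]:
    """Youden-optimal cut over observed scores; returns (threshold, kappa, TSS).

    Ties at the maximum of TPR + TNR break toward the lower threshold.  If
    every score is identical the threshold degenerates to that value with a
    warning.
    """
    pres_scores = np.asarray(pres_scores, dtype=float)
    bg_scores = np.asarray(bg_scores, dtype=float)
    if len(pres_scores) == 0 or len(bg_scores) == 0:
        raise ValueError("both score sets must be nonempty")
    allscores = np.concatenate([pres_scores, bg_scores])
    if np.allclose(allscores, allscores[0]):
        warnings.warn("all scores identical; threshold is degenerate")
        thr = float(allscores[0])
    else:
        thr = youden_threshold(pres_scores, bg_scores)
    tss, kappa = tss_kappa(*confusion_rates(pres_scores, bg_scores, thr))
    return thr, kappa, tss


def binarize_and_measure(
    pred: PredictionStack,
    threshold: float,
    observations: pd.DataFrame | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Binary presence stack and the per-millennium niche series.

    The binary stack codes presence 1, absence 0 and missing -1.  The niche
    series reports, per slice: presence-cell count, presence area (count x
    cell area), mean suitability over valid cells, and — when observations
    are supplied — the mean suitability at that slice's observation cells.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    suit = pred.suitability
    valid = ~np.isnan(suit)
    binary = np.full(suit.shape, -1, dtype=np.int8)
    binary[valid] = (suit[valid] >= threshold).astype(np.int8)

    obs_by_year: dict[int, pd.DataFrame] = {}
    if observations is not None and len(observations):
        for year, sub in observations.groupby("year_bp"):
            obs_by_year[int(year)] = sub

    rows = []
    for t, year in enumerate(pred.years):
        v = valid[t]
        count = int((binary[t] == 1).sum())
        mean_suit = float(np.nanmean(suit[t])) if v.any() else float("nan")
        obs = obs_by_year.get(int(year))
        if obs is not None:
            r = obs["row"].to_numpy(dtype=int)
            c = obs["col"].to_numpy(dtype=int)
            inb = (r >= 0) & (r < suit.shape[1]) & (c >= 0) & (c < suit.shape[2])
            vals = suit[t, r[inb], c[inb]]
            vals = vals[~np.isnan(vals)]
            mean_obs = float(vals.mean()) if len(vals) else float("nan")
            n_obs = int(len(vals))
        else:
            mean_obs, n_obs = float("nan"), 0
        rows.append(
            {
                "year_bp": int(year),
                "n_presence_cells": count,
                "area_km2": count * pred.cell_area_km2,
                "mean_suitability": mean_suit,
                "mean_suitability_obs": mean_obs,
                "n_obs": n_obs,
            }
        )
    return binary, pd.DataFrame(rows)
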