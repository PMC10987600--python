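"""Equal-area climate grids over millennial time slices.

The central container is :class:`ClimateStack`: one value grid per climate
variable per time slice, plus a per-slice cell classification (land / sea /
ice) and a constant cell area.  Cells are square on an equal-area grid, so
cell counts convert linearly to km².  A lightweight linear grid-to-geography
transform supports the longitude/latitude filters applied to archaeological
observations; real-world rasters are assumed to arrive already projected to
an equal-area CRS upstream of this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import xarray as xr

# Cell classification flags.
LAND = 0
SEA = 1
ICE = 2

#: Default cell side (km); yields the 1122.25 km² cell area used for range sizes.
DEFAULT_CELL_KM = 33.5


@dataclass(frozen=True)
class GridTransform:
    """Linear mapping between (row, col) grid indices and lon/lat degrees.

    Row 0 is the northern edge.  This is a nominal plate-carrée style mapping
    adequate for bounding-box filters on synthetic worlds; it carries no
    projection semantics.
    """

    lon_west: float = -10.0
    lat_north: float = 72.0
    dlon: float = 0.5
    dlat: float = 0.5

    def to_lonlat(self, row, col):
        row = np.asarray(row, dtype=float)
        col = np.asarray(col, dtype=float)
        lon = self.lon_west + (col + 0.5) * self.dlon
        lat = self.lat_north - (row + 0.5) * self.dlat
        return lon, lat

    def to_rowcol(self, lon, lat):
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.lon_west) / self.dlon).astype(int)
        row = np.floor((self.lat_north - lat) / self.dlat).astype(int)
        return row, col


@dataclass
class ClimateStack:
    """Per-variable grids over time slices with land/sea/ice masks.

    Parameters
    ----------
    variables
        Mapping from variable name to a float array of shape
        ``(n_slices, height, width)``.
    years
        Slice years BP, shape ``(n_slices,)``, typically decreasing from the
        oldest slice.
    mask
        Integer array ``(n_slices, height, width)`` with values ``LAND`` (0),
        ``SEA`` (1) or ``ICE`` (2).  Exactly one class per cell per slice.
    cell_area_km2
        Constant area of every grid cell.
    transform
        Grid-to-geography transform (nominal for synthetic worlds).
    """

    variables: Mapping[str, np.ndarray]
    years: np.ndarray
    mask: np.ndarray
    cell_area_km2: float = DEFAULT_CELL_KM**2
    transform: GridTransform = field(default_factory=GridTransform)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years)
        self.mask = np.asarray(self.mask)
        if self.cell_area_km2 <= 0:
            raise ValueError("cell_area_km2 must be positive")
        shape = self.mask.shape
        if len(shape) != 3:
            raise ValueError("mask must be (slices, rows, cols)")
        if shape[0] != len(self.years):
            raise ValueError("mask slices do not match years")
        for name, arr in self.variables.items():
            if np.asarray(arr).shape != shape:
                raise ValueError(f"variable {name!r} shape {arr.shape} != {shape}")
        bad = ~np.isin(self.mask, (LAND, SEA, ICE))
        if bad.any():
            raise ValueError("mask contains values other than land/sea/ice flags")

    # -- basic geometry -------------------------------------------------
    @property
    def n_slices(self) -> int:
        return len(self.years)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def variable_names(self) -> list[str]:
        return list(self.variables)

    def slice_index(self, year) -> int:
        idx = np.nonzero(self.years == year)[0]
        if idx.size == 0:
            raise KeyError(f"slice year {year} BP not in stack")
        return int(idx[0])

    def land_cells(self, year) -> np.ndarray:
        """(row, col) pairs of land-valid cells for a slice year, shape (n, 2)."""
        t = self.slice_index(year)
        rows, cols = np.nonzero(self.mask[t] == LAND)
        return np.column_stack([rows, cols])

    def values_at(self, year, rows, cols) -> dict[str, np.ndarray]:
        t = self.slice_index(year)
        return {name: np.asarray(arr)[t, rows, cols] for name, arr in self.variables.items()}

    # -- I/O -------------------------------------------------------------
    def to_dataset(self) -> xr.Dataset:
        coords = {
            "time": ("time", np.asarray(self.years)),
            "y": ("y", np.arange(self.shape[1])),
            "x": ("x", np.arange(self.shape[2])),
        }
        data = {
            name: (("time", "y", "x"), np.asarray(arr, dtype="f8"))
            for name, arr in self.variables.items()
        }
        data["mask"] = (("time", "y", "x"), self.mask.astype("i4"))
        ds = xr.Dataset(data, coords=coords)
        ds.attrs["cell_area_km2"] = float(self.cell_area_km2)
        ds.attrs["transform"] = " ".join(
            str(v)
            for v in (
                self.transform.lon_west,
                self.transform.lat_north,
                self.transform.dlon,
                self.transform.dlat,
            )
        )
        ds["time"].attrs["units"] = "years BP"
        return ds

    def to_netcdf(self, path) -> None:
        # scipy backend writes classic NetCDF3, which every reader understands
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "ClimateStack":
        if "mask" not in ds:
            raise ValueError("dataset has no 'mask' array")
        variables = {
            str(name): ds[name].values.astype(float)
            for name in ds.data_vars
            if name != "mask"
        }
        tf = GridTransform()
        if "transform" in ds.attrs:
            vals = [float(v) for v in str(ds.attrs["transform"]).split()]
            tf = GridTransform(*vals)
        return cls(
            variables=variables,
            years=ds["time"].values,
            mask=ds["mask"].values.astype(np.int8),
            cell_area_km2=float(ds.attrs.get("cell_area_km2", DEFAULT_CELL_KM**2)),
            transform=tf,
        )

    @classmethod
    def from_netcdf(cls, path) -> "ClimateStack":
        path = Path(path)
        try:
            with xr.open_dataset(path, engine="scipy") as ds:
                return cls.from_dataset(ds.load())
        except (OSError, ValueError) as exc:
            raise IOError(f"could not parse NetCDF stack {path}: {exc}") from exc
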