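"""Combining heterogeneous absolute-date evidence into context chronologies.

Each archaeological context may carry several absolute dates obtained by
different methods (radiocarbon, TL, ESR, OSL, U-series).  Radiocarbon dates
are calibrated against a calibration curve; other methods contribute Gaussian
densities from their reported mean and one-sigma error.  The per-date
densities are normalized and summed into a single distribution per context;
the year of the summed distribution's peak is the context's estimated
occupation year, and the probability mass within a ±5000-yr window of the
peak is its confidence.  Estimated years are then rounded to the nearest
millennium and passed through temporal, spatial and deduplication filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

RADIOCARBON = "radiocarbon"

#: default PDF grid: 10-yr resolution over 0–160 ka BP
DEFAULT_GRID_STEP = 10.0
DEFAULT_GRID_MAX = 160_000.0

#: half-width (years) of the confidence window around the peak
DEFAULT_CONFIDENCE_WINDOW = 5000.0


class NoDatesError(ValueError):
    """A context without any usable absolute dates cannot be estimated."""


class CalibrationRangeError(ValueError):
    """Radiocarbon age falls outside the calibration curve's support."""


@dataclass(frozen=True)
class DateMeasurement:
    """One absolute date: method, central age (years BP), one-sigma error."""

    method: str
    age: float
    error: float

    def __post_init__(self) -> None:
        if self.error <= 0:
            raise ValueError("date error must be positive")
        if self.age < 0:
            raise ValueError("date age must be non-negative (years BP)")


@dataclass(frozen=True)
class CalibrationCurve:
    """Calendar-age grid with radiocarbon-age means and curve errors."""

    cal_age: np.ndarray
    c14_age: np.ndarray
    error: np.ndarray

    def __post_init__(self) -> None:
        for name in ("cal_age", "c14_age", "error"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (len(self.cal_age) == len(self.c14_age) == len(self.error)):
            raise ValueError("calibration curve columns must have equal length")
        if np.any(np.diff(self.cal_age) <= 0):
            raise ValueError("calendar-age grid must be strictly increasing")

    def at(self, cal_years: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Interpolated radiocarbon age and curve error at calendar years."""
        mu = np.interp(cal_years, self.cal_age, self.c14_age)
        sig = np.interp(cal_years, self.cal_age, self.error)
        return mu, sig


@dataclass(frozen=True)
class DatePDF:
    """Discrete probability masses over a regular year grid (years BP)."""

    years: np.ndarray
    mass: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "years", np.asarray(self.years, dtype=float))
        object.__setattr__(self, "mass", np.asarray(self.mass, dtype=float))
        if self.years.shape != self.mass.shape:
            raise ValueError("years and mass must align")
        if np.any(self.mass < 0):
            raise ValueError("probability masses must be non-negative")
        total = self.mass.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"masses must sum to 1 (got {total!r})")


@dataclass(frozen=True)
class ChronologyResult:
    """Peak year, confidence mass, millennium bin and date count for a context."""

    year_bp: float
    confidence: float
    millennium: int
    n_dates: int
    peak_tied: bool = False


@dataclass
class DatedContext:
    """A locality/layer with coordinates and its absolute-date measurements."""

    locality_id: str
    context_id: str
    longitude: float
    latitude: float
    measurements: list[DateMeasurement] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (np.isfinite(self.longitude) and np.isfinite(self.latitude)):
            raise ValueError("context coordinates must be finite")


def default_year_grid(step: float = DEFAULT_GRID_STEP, maximum: float = DEFAULT_GRID_MAX) -> np.ndarray:
    return np.arange(0.0, maximum + step / 2, step)


def _normalize(years: np.ndarray, dens: np.ndarray) -> DatePDF:
    total = dens.sum()
    if total <= 0 or not np.isfinite(total):
        raise ValueError("degenerate density: no probability mass on the year grid")
    return DatePDF(years=years, mass=dens / total)


def calibrate_radiocarbon(
    m: DateMeasurement,
    curve: CalibrationCurve,
    grid_step: float = DEFAULT_GRID_STEP,
    grid_max: float = DEFAULT_GRID_MAX,
) -> DatePDF:
    """Calibrate one radiocarbon date against the curve.

    The unnormalized density at calendar year t is the Gaussian density of the
    measured radiocarbon age at mean curve(t) with variance
    ``error² + curve_error(t)²``; the result is normalized over the grid.
    """
    if m.method != RADIOCARBON:
        raise ValueError(f"calibrate_radiocarbon requires a radiocarbon date, got {m.method!r}")
    lo, hi = float(curve.c14_age.min()), float(curve.c14_age.max())
    pad = 5.0 * (m.error + float(curve.error.max()))
    if not (lo - pad <= m.age <= hi + pad):
        raise CalibrationRangeError(
            f"radiocarbon age {m.age} BP outside curve support [{lo}, {hi}]"
        )
    years = default_year_grid(grid_step, grid_max)
    mu, sig = curve.at(years)
    sd = np.sqrt(m.error**2 + sig**2)
    dens = stats.norm.pdf(m.age, loc=mu, scale=sd)
    return _normalize(years, dens)


def pdf_from_absolute(
    m: DateMeasurement,
    grid_step: float = DEFAULT_GRID_STEP,
    grid_max: float = DEFAULT_GRID_MAX,
) -> DatePDF:
    """Discretized normal density for a non-radiocarbon absolute date."""
    if m.method == RADIOCARBON:
        raise ValueError("radiocarbon dates must be calibrated, not used directly")
    years = default_year_grid(grid_step, grid_max)
    dens = stats.norm.pdf(years, loc=m.age, scale=m.error)
    return _normalize(years, dens)


def round_to_millennium(year_bp: float, step: float = 1000.0) -> int:
    """Nearest multiple of ``step``; exact halves round toward the older year."""
    return int(step * np.floor(year_bp / step + 0.5))


def combine_dates(
    pdfs: Sequence[DatePDF],
    window: float = DEFAULT_CONFIDENCE_WINDOW,
    slice_step: float = 1000.0,
) -> ChronologyResult:
    """Sum normalized per-date PDFs and read off peak, confidence, millennium.

    Because every per-date PDF integrates to one, the sum is an equal-weight
    mixture: dates with narrow errors produce taller peaks and therefore
    dominate the summed distribution's maximum.  Ties at the maximum break
    toward the older (larger BP) year and are flagged.
    """
    if len(pdfs) == 0:
        raise NoDatesError("cannot combine zero date PDFs")
    years = pdfs[0].years
    for p in pdfs[1:]:
        if p.years.shape != years.shape or not np.array_equal(p.years, years):
            raise ValueError("all PDFs must share one year grid")
    total = np.sum([p.mass for p in pdfs], axis=0)
    total = total / total.sum()

    peak_mass = total.max()
    at_max = np.isclose(total, peak_mass, rtol=0.0, atol=1e-15)
    peak_idx = int(np.nonzero(at_max)[0][-1])  # grid ascends in BP: last = oldest
    peak = float(years[peak_idx])
    tied = int(at_max.sum()) > 1

    in_window = np.abs(years - peak) <= window
    confidence = float(total[in_window].sum())
    return ChronologyResult(
        year_bp=peak,
        confidence=confidence,
        millennium=round_to_millennium(peak, slice_step),
        n_dates=len(pdfs),
        peak_tied=tied,
    )


def context_pdfs(
    context: DatedContext,
    curve: CalibrationCurve | None,
    grid_step: float = DEFAULT_GRID_STEP,
    grid_max: float = DEFAULT_GRID_MAX,
) -> list[DatePDF]:
    """Per-date PDFs for one context (calibrating radiocarbon dates)."""
    out = []
    for m in context.measurements:
        if m.method == RADIOCARBON:
            if curve is None:
                raise ValueError("radiocarbon dates present but no calibration curve given")
            out.append(calibrate_radiocarbon(m, curve, grid_step, grid_max))
        else:
            out.append(pdf_from_absolute(m, grid_step, grid_max))
    return out


def estimate_context_dates(
    contexts: Sequence[DatedContext],
    curve: CalibrationCurve | None = None,
    grid_step: float = DEFAULT_GRID_STEP,
    grid_max: float = DEFAULT_GRID_MAX,
    window: float = DEFAULT_CONFIDENCE_WINDOW,
    slice_step: float = 1000.0,
) -> pd.DataFrame:
    """Chronology results for many contexts as a table.

    Contexts without any absolute dates receive no estimate and are omitted
    (their count appears in the attrs of the returned frame).
    """
    rows = []
    skipped = 0
    for ctx in contexts:
        if not ctx.measurements:
            skipped += 1
            continue
        res = combine_dates(
            context_pdfs(ctx, curve, grid_step, grid_max), window=window, slice_step=slice_step
        )
        rows.append(
            {
                "locality_id": ctx.locality_id,
                "context_id": ctx.context_id,
                "longitude": ctx.longitude,
                "latitude": ctx.latitude,
                "year_bp": res.year_bp,
                "confidence": res.confidence,
                "millennium": res.millennium,
                "n_dates": res.n_dates,
                "peak_tied": res.peak_tied,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "locality_id",
            "context_id",
            "longitude",
            "latitude",
            "year_bp",
            "confidence",
            "millennium",
            "n_dates",
            "peak_tied",
        ],
    )
    df.attrs["n_without_dates"] = skipped
    return df


@dataclass(frozen=True)
class FilterSpec:
    """Temporal and spatial bounds plus dedup settings for observations."""

    year_min: float = 50_000.0
    year_max: float = 145_000.0
    lon_max: float = 70.0
    lat_min: float = 35.0
    slice_step: float = 1000.0


@dataclass(frozen=True)
class FilterReport:
    n_input: int
    n_too_young: int
    n_too_old: int
    n_east: int
    n_south: int
    n_duplicate: int
    n_retained: int

    def removed_total(self) -> int:
        return self.n_too_young + self.n_too_old + self.n_east + self.n_south + self.n_duplicate


def assign_and_filter(
    table: pd.DataFrame, bounds: FilterSpec = FilterSpec()
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the temporal window, the spatial box, then spatio-temporal dedup.

    Input is the frame from :func:`estimate_context_dates` (each row already
    carries a millennium).  Rules are applied in order and each removal is
    attributed to the first rule that fires; duplicates key on the locality's
    spatial location (longitude, latitude) together with the millennium, and
    the first-seen record of each duplicate set is retained.
    """
    df = table.copy()
    n_input = len(df)

    too_young = df["millennium"] < bounds.year_min
    n_young = int(too_young.sum())
    df = df[~too_young]

    too_old = df["millennium"] > bounds.year_max
    n_old = int(too_old.sum())
    df = df[~too_old]

    east = df["longitude"] > bounds.lon_max
    n_east = int(east.sum())
    df = df[~east]

    south = df["latitude"] < bounds.lat_min
    n_south = int(south.sum())
    df = df[~south]

    dup = df.duplicated(subset=["longitude", "latitude", "millennium"], keep="first")
    n_dup = int(dup.sum())
    df = df[~dup].reset_index(drop=True)

    report = FilterReport(
        n_input=n_input,
        n_too_young=n_young,
        n_too_old=n_old,
        n_east=n_east,
        n_south=n_south,
        n_duplicate=n_dup,
        n_retained=len(df),
    )
    return df, report
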