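"""Synthetic paleoworlds with known ground truth.

Everything downstream — date combination, background sampling, Maxent
fitting, projection and trend testing — is validated against worlds built
here, where the true niche, the true occupation years and the true masks are
known by construction.

The world model is deliberately simple but non-degenerate:

* each climate variable is a smooth spatial profile (temperature latitudinal,
  precipitation a west-east maritime gradient, productivity a function of
  both), plus a sinusoidal temporal forcing (glacial/interglacial analogue),
  plus a static smooth spatial noise field — so variables share the forcing
  and the productivity link the way real bioclim layers do, and a
  correlation filter has something to do;
* sea cells follow a fixed "bathymetry" field against a forcing-driven sea
  level (warm phase = high stand = more sea);
* ice covers the northern rows whose unforced temperature plus forcing falls
  below a freezing threshold (cold phase = larger ice sheet);
* the archaeological record is a thinned point process: proposals uniform
  over land cells, accepted with probability proportional to true habitat
  suitability times a taphonomic survival factor that decays with age and
  with northern latitude (glacial scouring analogue).

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .chronology import CalibrationCurve, DateMeasurement, DatedContext
from .grids import ClimateStack, GridTransform, ICE, LAND, SEA, DEFAULT_CELL_KM


class ConfigError(ValueError):
    """Invalid world configuration."""


class GenerationError(RuntimeError):
    """Synthetic record generation failed (e.g. no valid cells)."""


@dataclass(frozen=True)
class WorldConfig:
    """Geometry, time axis and climate forcing of a synthetic paleoworld.

    Defaults mirror the study conditions: millennial slices from 145 ka BP to
    30 ka BP on an equal-area grid of 33.5 km cells, with glacial-cycle scale
    forcing.
    """

    height: int = 40
    width: int = 60
    cell_km: float = DEFAULT_CELL_KM
    year_start: int = 145_000
    year_end: int = 30_000
    slice_step: int = 1000
    #: sinusoidal forcing period in years (precession/obliquity scale)
    forcing_period: float = 23_000.0
    forcing_phase: float = 0.0
    #: per-variable forcing amplitude (added at forcing = +1, the warm phase)
    amplitudes: Mapping[str, float] = field(
        default_factory=lambda: {"temperature": 5.0, "precipitation": 180.0}
    )
    #: temperature profile endpoints (north edge, south edge)
    temp_range: tuple[float, float] = (-12.0, 18.0)
    #: precipitation profile endpoints (east edge, west edge): oceanic west is wet
    precip_range: tuple[float, float] = (350.0, 1100.0)
    #: static spatial noise sd per variable and its smoothing length (cells)
    noise_sd: Mapping[str, float] = field(
        default_factory=lambda: {"temperature": 1.5, "precipitation": 90.0, "npp": 40.0}
    )
    noise_smooth: float = 3.0
    #: ice forms where profile+forcing temperature drops below this (°C)
    ice_temp_threshold: float = -8.0
    #: °C of extra cooling of the ice criterion at forcing −1 (0 disables)
    ice_response: float = 3.0
    #: sea-level swing (in bathymetry units) at forcing ±1
    sea_response: float = 0.12
    #: fraction of the grid under water at forcing 0
    sea_fraction: float = 0.18
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 2 or self.width < 2:
            raise ConfigError("grid must be at least 2x2")
        if self.slice_step <= 0:
            raise ConfigError("slice spacing must be positive")
        if self.cell_km <= 0:
            raise ConfigError("cell side must be positive")
        if self.year_start < self.year_end:
            raise ConfigError("year_start (older, years BP) must be >= year_end")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end - 1, -self.slice_step)

    def forcing(self, year) -> np.ndarray:
        """Dimensionless forcing in [-1, 1]; +1 is the warm phase."""
        year = np.asarray(year, dtype=float)
        return np.sin(2.0 * np.pi * (year - self.forcing_phase) / self.forcing_period)


@dataclass(frozen=True)
class TrueNiche:
    """Known Gaussian suitability surface in climate space.

    Suitability is a product of per-variable Gaussian terms
    ``exp(-w (x - opt)^2 / (2 tol^2))``, so it lies in [0, 1] with maximum 1
    at the joint optimum.  ``survival_age_scale`` and ``survival_lat_coef``
    define the taphonomic survival factor
    ``exp(-age / age_scale) * exp(-lat_coef * northness)`` with northness 1 at
    the northern grid edge.
    """

    optima: Mapping[str, float] = field(
        default_factory=lambda: {"temperature": 8.0, "precipitation": 900.0}
    )
    tolerances: Mapping[str, float] = field(
        default_factory=lambda: {"temperature": 4.0, "precipitation": 250.0}
    )
    weights: Mapping[str, float] = field(
        default_factory=lambda: {"temperature": 1.0, "precipitation": 1.0}
    )
    max_detection: float = 1.0
    survival_age_scale: float = float("inf")
    survival_lat_coef: float = 0.0

    def __post_init__(self) -> None:
        for v, tol in self.tolerances.items():
            if tol <= 0:
                raise ConfigError(f"tolerance for {v!r} must be positive")
        if not (0 < self.max_detection <= 1):
            raise ConfigError("max_detection must be in (0, 1]")

    def suitability(self, values: Mapping[str, np.ndarray]) -> np.ndarray:
        """Evaluate true suitability for per-variable value arrays."""
        out = None
        for v, opt in self.optima.items():
            x = np.asarray(values[v], dtype=float)
            z = (x - opt) / self.tolerances[v]
            term = np.exp(-0.5 * self.weights.get(v, 1.0) * z**2)
            out = term if out is None else out * term
        if out is None:
            raise ConfigError("niche defines no variables")
        return out

    def survival(self, northness, age) -> np.ndarray:
        northness = np.asarray(northness, dtype=float)
        age = np.asarray(age, dtype=float)
        s = np.exp(-self.survival_lat_coef * northness)
        if np.isfinite(self.survival_age_scale):
            s = s * np.exp(-age / self.survival_age_scale)
        return s


def _smooth_noise(rng: np.random.Generator, shape, sd: float, length: float) -> np.ndarray:
    if sd == 0:
        return np.zeros(shape)
    raw = rng.standard_normal(shape)
    sm = gaussian_filter(raw, sigma=length, mode="nearest")
    s = sm.std()
    return sm * (sd / s) if s > 0 else sm


def generate_paleoworld(config: WorldConfig) -> ClimateStack:
    """Build the climate stack for a configuration; deterministic per seed.

    Variables produced: ``temperature`` (°C), ``precipitation`` (mm/yr) and
    ``npp`` (gC/m²/yr, a saturating function of the first two).  Cells are
    classified sea (bathymetry below sea level), else ice (cold threshold),
    else land.
    """
    rng = np.random.default_rng(config.seed)
    H, W = config.height, config.width
    years = config.years
    rows = np.arange(H, dtype=float)
    northness = 1.0 - rows / (H - 1)  # 1 at north edge, 0 at south

    tn, ts = config.temp_range
    pe, pw = config.precip_range
    temp_profile = ts + (tn - ts) * northness  # (H,)
    westness = 1.0 - np.arange(W, dtype=float) / (W - 1)
    precip_profile = pe + (pw - pe) * westness  # (W,): maritime gradient

    noise_t = _smooth_noise(rng, (H, W), config.noise_sd.get("temperature", 0.0), config.noise_smooth)
    noise_p = _smooth_noise(rng, (H, W), config.noise_sd.get("precipitation", 0.0), config.noise_smooth)
    noise_n = _smooth_noise(rng, (H, W), config.noise_sd.get("npp", 0.0), config.noise_smooth)

    # static bathymetry: smooth field plus a coastal gradient along the west
    bathy = _smooth_noise(rng, (H, W), 1.0, config.noise_smooth * 1.5)
    cols = np.arange(W, dtype=float)
    bathy = bathy + 1.5 * np.exp(-cols[None, :] / (0.12 * W))  # western ocean
    sea_level0 = float(np.quantile(bathy, 1.0 - config.sea_fraction))

    amp_t = config.amplitudes.get("temperature", 0.0)
    amp_p = config.amplitudes.get("precipitation", 0.0)

    T = len(years)
    temp = np.empty((T, H, W))
    precip = np.empty((T, H, W))
    npp = np.empty((T, H, W))
    mask = np.empty((T, H, W), dtype=np.int8)

    for t, year in enumerate(years):
        f = float(config.forcing(year))
        temp[t] = temp_profile[:, None] + amp_t * f + noise_t
        precip[t] = np.maximum(precip_profile[None, :] + amp_p * f + noise_p, 0.0)
        # NPP saturates in precipitation, linear in temperature above -5 °C
        npp[t] = np.maximum(30.0 * (temp[t] + 5.0), 0.0) * precip[t] / (precip[t] + 500.0)
        npp[t] = np.maximum(npp[t] + noise_n, 0.0)

        sea = bathy > sea_level0 + config.sea_response * f  # warm = high stand
        # ice from the noise-free criterion so cold-phase extent dominates
        ice_rows = (temp_profile + amp_t * f - config.ice_response * max(-f, 0.0)
                    ) < config.ice_temp_threshold
        m = np.full((H, W), LAND, dtype=np.int8)
        m[sea] = SEA
        ice = ice_rows[:, None] & ~sea
        m[ice] = ICE
        mask[t] = m

    tf = GridTransform(dlon=config.cell_km / 111.0 * 2.0, dlat=config.cell_km / 111.0)
    return ClimateStack(
        variables={"temperature": temp, "precipitation": precip, "npp": npp},
        years=years,
        mask=mask,
        cell_area_km2=config.cell_km**2,
        transform=tf,
    )


#: one-sigma dating error (years) per method, used unless overridden
DEFAULT_DATING_MODEL: dict[str, float] = {
    "radiocarbon": 400.0,
    "TL": 3000.0,
    "ESR": 2500.0,
    "OSL": 2000.0,
    "U-series": 1500.0,
}

#: practical upper age limit for the radiocarbon method (years BP)
RADIOCARBON_LIMIT = 50_000.0


def generate_archaeological_record(
    world: ClimateStack,
    niche: TrueNiche,
    n_contexts: int,
    dating_model: Mapping[str, float] | None = None,
    seed: int = 0,
    dates_per_context: float = 2.0,
    curve: CalibrationCurve | None = None,
    max_tries: int | None = None,
) -> tuple[list[DatedContext], pd.DataFrame]:
    """Place dated archaeological contexts by thinning uniform proposals.

    Proposals pick a slice and a land cell uniformly; acceptance probability is
    true suitability × taphonomic survival × max detection.  Each accepted
    context receives at least one date measurement whose mean is the true
    slice year plus method-specific Gaussian noise (radiocarbon measurements
    are expressed in radiocarbon years through ``curve`` when given, and are
    only drawn for ages within the method's range).

    Returns the contexts and a truth table with one row per context
    (true year, cell, suitability at generation).
    """
    dating_model = dict(dating_model or DEFAULT_DATING_MODEL)
    rng = np.random.default_rng(seed)
    H = world.shape[1]

    land_by_slice = [world.land_cells(y) for y in world.years]
    if any(len(cells) == 0 for cells in land_by_slice):
        bad = [int(y) for y, c in zip(world.years, land_by_slice) if len(c) == 0]
        raise GenerationError(f"slices with no land-valid cells: {bad}")

    methods = list(dating_model)
    contexts: list[DatedContext] = []
    truth_rows = []
    tries = 0
    limit = max_tries if max_tries is not None else 4000 * max(n_contexts, 1)
    while len(contexts) < n_contexts:
        tries += 1
        if tries > limit:
            raise GenerationError(
                f"accepted only {len(contexts)}/{n_contexts} contexts in {limit} proposals; "
                "suitability × survival may be too small"
            )
        t = int(rng.integers(world.n_slices))
        year = int(world.years[t])
        cells = land_by_slice[t]
        r, c = cells[rng.integers(len(cells))]
        vals = {name: float(arr[t, r, c]) for name, arr in world.variables.items()}
        suit = float(niche.suitability(vals))
        surv = float(niche.survival(1.0 - r / (H - 1), year))
        if rng.random() >= suit * surv * niche.max_detection:
            continue

        k = len(contexts)
        n_dates = max(1, int(rng.poisson(max(dates_per_context - 1.0, 0.0))) + 1)
        measurements = []
        for _ in range(n_dates):
            ok = [m for m in methods if m != "radiocarbon" or year <= RADIOCARBON_LIMIT]
            method = ok[int(rng.integers(len(ok)))]
            sigma = float(dating_model[method])
            if method == "radiocarbon" and curve is not None:
                mean = float(np.interp(year, curve.cal_age, curve.c14_age))
            else:
                mean = float(year)
            age = mean + (rng.normal(0.0, sigma) if sigma > 0 else 0.0)
            measurements.append(
                DateMeasurement(method=method, age=max(age, 0.0), error=max(sigma, 1.0))
            )
        lon, lat = world.transform.to_lonlat(r, c)
        ctx = DatedContext(
            locality_id=f"L{k:05d}",
            context_id=f"C{k:05d}",
            longitude=float(lon),
            latitude=float(lat),
            measurements=measurements,
        )
        contexts.append(ctx)
        truth_rows.append(
            {
                "context_id": ctx.context_id,
                "true_year": year,
                "slice": t,
                "row": int(r),
                "col": int(c),
                "true_suitability": suit,
            }
        )
    return contexts, pd.DataFrame(truth_rows)


def generate_calibration_curve(
    mode: str = "identity",
    span: float = 160_000.0,
    step: float = 20.0,
    seed: int = 0,
) -> CalibrationCurve:
    """Synthetic calibration curve on a regular calendar grid.

    ``identity`` maps radiocarbon age = calendar age with zero curve error
    (useful for closed-form checks); ``wiggly`` superimposes reproducible
    multi-scale sinusoidal wiggles and a slowly varying curve error, loosely
    shaped like real calibration curves.
    """
    if span <= 0:
        raise ConfigError("span must be positive")
    cal = np.arange(0.0, span + step / 2, step)
    if mode == "identity":
        return CalibrationCurve(cal_age=cal, c14_age=cal.copy(), error=np.zeros_like(cal))
    if mode != "wiggly":
        raise ConfigError(f"unknown calibration-curve mode {mode!r}")
    rng = np.random.default_rng(seed)
    wig = np.zeros_like(cal)
    for period in (900.0, 2300.0, 7100.0):
        wig += rng.uniform(30.0, 120.0) * np.sin(2 * np.pi * cal / period + rng.uniform(0, 2 * np.pi))
    # mild systematic offset growing with age, as in real curves
    c14 = cal + 0.02 * cal * np.sin(2 * np.pi * cal / 40_000.0) / 10.0 + wig
    err = 30.0 + 0.002 * cal + 10.0 * (1 + np.sin(2 * np.pi * cal / 11_000.0))
    return CalibrationCurve(cal_age=cal, c14_age=c14, error=err)
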