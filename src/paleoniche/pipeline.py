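"""Configuration-driven orchestration of the full analysis.

``run_pipeline`` executes chronology → background sampling/extraction →
variable selection → Maxent tuning and final fit → projection/thresholding →
trend test, writing every intermediate product (observation chronologies,
background points, niche series), the metrics, the fitted model and a run
manifest (config hash, seeds, stage record counts) into an artifact
directory.  Inputs are either real files (context/date CSVs, an IntCal-style
curve, a NetCDF climate stack) or a synthetic-world specification.

Defaults reproduce the study settings: observations filtered to 50–145 ka BP
west of 70°E and north of 35°N, 100 background points per millennium over
145–50 ka, Pearson screening at |r| > 0.7, a tuning grid of RM 1–5 by
{L, LQ, LQH, H} scored by ten-fold cross-validation, logistic output,
projection over 145–30 ka, and a ±5000-yr confidence window for dates.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import chronology as chron
from . import io as pio
from . import maxent as mx
from . import projection as proj
from . import sampling
from . import synth
from . import trend as trend_mod
from . import varselect
from .grids import ClimateStack

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with study defaults."""

    # inputs: real-data paths, or None to generate a synthetic world
    contexts_path: str | None = None
    dates_path: str | None = None
    curve_path: str | None = None
    stack_path: str | None = None

    # synthetic-world spec (used when stack_path is None)
    world: synth.WorldConfig = field(default_factory=synth.WorldConfig)
    niche: synth.TrueNiche = field(default_factory=synth.TrueNiche)
    n_contexts: int = 180
    curve_mode: str = "identity"

    # chronology
    grid_step: float = chron.DEFAULT_GRID_STEP
    confidence_window: float = chron.DEFAULT_CONFIDENCE_WINDOW
    filters: chron.FilterSpec = field(default_factory=chron.FilterSpec)

    # background sampling (inclusive year range, oldest first)
    n_background_per_slice: int = 100
    background_year_max: float = 145_000.0
    background_year_min: float = 50_000.0

    # variable selection
    candidates: tuple[str, ...] = ("temperature", "precipitation", "npp")
    correlation_threshold: float = 0.7
    stability_k: int = 3

    # maxent tuning
    rm_grid: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)
    feature_classes: tuple[str, ...] = mx.FEATURE_CLASSES
    hinge_knots: int = 15
    folds: int = 10
    transform: str = "logistic"

    # projection range (years BP, inclusive; slices taken from the stack)
    projection_year_max: float = 145_000.0
    projection_year_min: float = 30_000.0

    # trend
    trend_family: str = "poisson"
    trend_k: int = 3

    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["world"] = {
            k: (dict(v) if isinstance(v, dict) else v)
            for k, v in dataclasses.asdict(self.world).items()
        }
        return d

    def config_hash(self) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def demo_config(seed: int = 0) -> PipelineConfig:
    """A desk-scale synthetic configuration that runs end to end in minutes."""
    world = synth.WorldConfig(height=26, width=40, seed=seed)
    return PipelineConfig(
        world=world,
        n_contexts=160,
        n_background_per_slice=50,
        seed=seed,
    )


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                logger.info("stage %s: start", name)
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, exc) from exc

        return wrapper

    return deco


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage; returns a dict of in-memory artifacts.

    All intermediates are written under ``outdir``; a failure in any stage
    raises :class:`PipelineStageError` naming the stage, with the artifacts
    of completed stages left on disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = {"config_hash": config.config_hash(), "seed": config.seed}
    artifacts: dict = {}

    # --- world -----------------------------------------------------------
    @_stage("world")
    def build_world():
        if config.stack_path:
            return ClimateStack.from_netcdf(config.stack_path)
        stack = synth.generate_paleoworld(config.world)
        stack.to_netcdf(outdir / "climate_stack.nc")
        return stack

    stack = build_world()
    artifacts["stack"] = stack

    # --- chronology ------------------------------------------------------
    @_stage("chronology")
    def build_chronology():
        if config.curve_path:
            curve = pio.read_calibration_curve(config.curve_path)
        else:
            curve = synth.generate_calibration_curve(config.curve_mode, seed=config.seed)
            pio.write_calibration_curve(curve, outdir / "calibration_curve.txt")
        if config.contexts_path and config.dates_path:
            contexts = pio.read_contexts(config.contexts_path, config.dates_path)
            truth = None
        else:
            contexts, truth = synth.generate_archaeological_record(
                stack,
                config.niche,
                n_contexts=config.n_contexts,
                seed=config.seed + 1,
                curve=curve,
            )
            pio.write_contexts(contexts, outdir / "contexts.csv", outdir / "dates.csv")
            pio.write_table(truth, outdir / "truth.csv", prov)
        table = chron.estimate_context_dates(
            contexts,
            curve,
            grid_step=config.grid_step,
            window=config.confidence_window,
            slice_step=config.filters.slice_step,
        )
        filtered, report = chron.assign_and_filter(table, config.filters)
        pio.write_table(filtered, outdir / "observations_dated.csv", prov)
        logger.info("chronology: %s", report)
        return curve, filtered, report, truth

    curve, filtered, filter_report, truth = build_chronology()
    artifacts.update(curve=curve, observations=filtered, filter_report=filter_report, truth=truth)

    # --- background + extraction ----------------------------------------
    @_stage("sampling_extraction")
    def build_observations():
        years = stack.years[
            (stack.years <= config.background_year_max)
            & (stack.years >= config.background_year_min)
        ]
        bg = sampling.sample_background(
            stack,
            n_per_slice=config.n_background_per_slice,
            slices=years,
            seed=config.seed + 2,
        )
        pres = sampling.presences_from_chronology(filtered, stack)
        table = pd.concat([pres, bg], ignore_index=True)
        table = sampling.extract_values(table, stack)
        pio.write_table(table, outdir / "observation_table.csv", prov)
        return table

    table = build_observations()
    artifacts["table"] = table

    # --- variable selection ----------------------------------------------
    @_stage("variable_selection")
    def select_variables():
        report = varselect.correlation_filter(
            table, config.candidates, threshold=config.correlation_threshold
        )
        stability = varselect.stability_report(table, report.retained, k=config.stability_k)
        pio.write_table(stability, outdir / "stability.csv", prov)
        pio.write_table(report.matrix.reset_index(), outdir / "correlations.csv", prov)
        return report, stability

    corr_report, stability = select_variables()
    artifacts.update(correlation=corr_report, stability=stability)

    # --- maxent tuning and final fit --------------------------------------
    @_stage("maxent")
    def fit_model():
        grid = mx.default_tuning_grid(config.rm_grid, config.feature_classes, config.hinge_knots)
        sel = mx.cross_validate_select(
            table,
            grid=grid,
            folds=config.folds,
            seed=config.seed + 3,
            variables=corr_report.retained,
        )
        pio.write_table(sel.grid, outdir / "tuning_grid.csv", prov)
        pio.save_model(sel.model, outdir / "model.json")
        contrib = mx.variable_contribution(sel.model, table, seed=config.seed + 4)
        pio.write_table(contrib, outdir / "contributions.csv", prov)
        return sel, contrib

    selection, contributions = fit_model()
    artifacts.update(selection=selection, contributions=contributions)
    model = selection.model

    # --- projection and thresholding --------------------------------------
    @_stage("projection")
    def project():
        pres, bg = sampling.split_presence_background(table)
        pres_scores = mx.predict(model, pres, config.transform)
        bg_scores = mx.predict(model, bg, config.transform)
        thr, kappa, tss = proj.optimal_threshold(pres_scores, bg_scores)

        years = stack.years[
            (stack.years <= config.projection_year_max)
            & (stack.years >= config.projection_year_min)
        ]
        sub = ClimateStack(
            variables={v: np.asarray(a)[np.isin(stack.years, years)] for v, a in stack.variables.items()},
            years=years,
            mask=stack.mask[np.isin(stack.years, years)],
            cell_area_km2=stack.cell_area_km2,
            transform=stack.transform,
        )
        pred = proj.project_suitability(model, sub, config.transform)
        pred.to_netcdf(outdir / "suitability.nc")
        binary, series = proj.binarize_and_measure(pred, thr, observations=pres)
        pio.write_table(series, outdir / "niche_series.csv", prov)
        return pred, binary, series, {"threshold": thr, "kappa": kappa, "tss": tss}

    pred, binary, series, threshold_info = project()
    artifacts.update(prediction=pred, binary=binary, series=series, threshold=threshold_info)

    # --- trend -------------------------------------------------------------
    @_stage("trend")
    def fit_trend():
        tf = trend_mod.fit_trend_ar1(series, family=config.trend_family, k=config.trend_k)
        payload = {
            "family": tf.family,
            "edf": tf.edf,
            "r2_adj": tf.r2_adj,
            "p_value": tf.p_value,
            "rho": tf.rho,
        }
        (outdir / "trend.json").write_text(json.dumps(payload, indent=1))
        return tf

    trend_fit = fit_trend()
    artifacts["trend"] = trend_fit

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_observations": int(len(filtered)),
        "n_background": int((table["label"] == "background").sum()),
        "retained_variables": corr_report.retained,
        "selected_rm": model.spec.rm,
        "selected_features": model.spec.feature_class,
        "threshold": threshold_info,
        "trend": {"p_value": trend_fit.p_value, "edf": trend_fit.edf, "rho": trend_fit.rho},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    artifacts["manifest"] = manifest
    return artifacts
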