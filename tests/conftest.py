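"""Shared fixtures: small synthetic worlds and a session-wide demo pipeline run."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from paleoniche import (
    TrueNiche,
    WorldConfig,
    generate_archaeological_record,
    generate_calibration_curve,
    generate_paleoworld,
)
from paleoniche.pipeline import demo_config, run_pipeline


@pytest.fixture(scope="session")
def small_world():
    """A 20x30 world over the full 145-30 ka axis with default forcing."""
    return generate_paleoworld(WorldConfig(height=20, width=30, seed=11))


@pytest.fixture(scope="session")
def static_world():
    """A single-slice world with no temporal forcing (for uniformity tests)."""
    cfg = WorldConfig(
        height=20,
        width=30,
        year_start=100_000,
        year_end=100_000,
        amplitudes={"temperature": 0.0, "precipitation": 0.0},
        ice_response=0.0,
        sea_response=0.0,
        seed=5,
    )
    return generate_paleoworld(cfg)


@pytest.fixture(scope="session")
def identity_curve():
    return generate_calibration_curve("identity")


@pytest.fixture(scope="session")
def demo_artifacts(tmp_path_factory):
    """One full pipeline run shared across tests (seeded, desk-scale)."""
    import time

    outdir = tmp_path_factory.mktemp("demo_run")
    t0 = time.time()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        artifacts = run_pipeline(demo_config(seed=1), outdir)
    artifacts["elapsed_seconds"] = time.time() - t0
    return artifacts, demo_config(seed=1), outdir


@pytest.fixture(scope="session")
def fitted_lq_model(static_world):
    """A small LQ Maxent fit on synthetic presences/background with known truth."""
    from paleoniche import maxent as mx
    from paleoniche import sampling

    niche = TrueNiche()
    curve = generate_calibration_curve("identity")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        contexts, truth = generate_archaeological_record(
            static_world, niche, n_contexts=250, seed=3, curve=curve
        )
    rng = np.random.default_rng(4)
    bg = sampling.sample_background(static_world, n_per_slice=500, seed=4, replace=True)
    bg = sampling.extract_values(bg, static_world)
    rows = truth[["row", "col"]].to_numpy()
    pres = pd.DataFrame(
        {
            "label": "presence",
            "year_bp": 100_000,
            "row": rows[:, 0],
            "col": rows[:, 1],
            "lon": 0.0,
            "lat": 50.0,
            "context_id": truth["context_id"],
        }
    )
    pres = sampling.extract_values(pres, static_world)
    model = mx.fit_maxent(pres, bg, mx.FeatureSpec("LQ", rm=1.0))
    table = pd.concat([pres, bg], ignore_index=True)
    return model, table, niche
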