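"""Project the fitted model over every millennium, derive the optimal
threshold, and build the niche-area time series (with a map figure).
"""

import sys
from importlib import import_module
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
cfg_mod = import_module("00_config")

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from paleoniche import io as pio
from paleoniche import maxent as mx
from paleoniche.grids import ClimateStack
from paleoniche.projection import binarize_and_measure, optimal_threshold, project_suitability
from paleoniche.sampling import split_presence_background


def main():
    cfg = cfg_mod.CONFIG
    stack = ClimateStack.from_netcdf(cfg_mod.RESULTS / "climate_stack.nc")
    table = pio.read_table(cfg_mod.RESULTS / "observation_table.csv")
    model = pio.load_model(cfg_mod.RESULTS / "model.json")

    pres, bg = split_presence_background(table)
    ps = mx.predict(model, pres, cfg.transform)
    bs = mx.predict(model, bg, cfg.transform)
    thr, kappa, tss = optimal_threshold(ps, bs)
    auc = mx.auc_score(ps, bs)
    print(f"full model: AUC={auc:.3f}, TSS={tss:.3f} at optimal threshold "
          f"{thr:.3f} (kappa={kappa:.4f})")

    pred = project_suitability(model, stack, cfg.transform)
    pred.to_netcdf(cfg_mod.RESULTS / "suitability.nc")
    binary, series = binarize_and_measure(pred, thr, observations=pres)
    pio.write_table(series, cfg_mod.RESULTS / "niche_series.csv")

    peak = series.loc[series["area_km2"].idxmax()]
    low = series.loc[series["area_km2"].idxmin()]
    print(f"projected niche area peaks at {peak['area_km2']/1e3:.0f} thousand km2 "
          f"({int(peak['year_bp'])} BP) and bottoms at {low['area_km2']/1e3:.0f} "
          f"thousand km2 ({int(low['year_bp'])} BP)")

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for ax, t, title in ((axes[0], pred.slice_index(peak["year_bp"]), "largest niche"),
                         (axes[1], pred.slice_index(low["year_bp"]), "smallest niche")):
        im = ax.imshow(pred.suitability[t], vmin=0, vmax=1, cmap="viridis")
        ax.set_title(f"{title}: {int(pred.years[t])} BP")
        ax.set_xticks([]); ax.set_yticks([])
    fig.colorbar(im, ax=axes, shrink=0.8, label="suitability")
    fig.savefig(cfg_mod.RESULTS / "suitability_maps.png", dpi=120)
    print(f"wrote {cfg_mod.RESULTS / 'suitability_maps.png'}")


if __name__ == "__main__":
    main()
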