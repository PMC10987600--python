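"""Tune and fit the Maxent niche model, then characterize the niche.

The tuning grid (RM 1-5 x {L, LQ, LQH, H}) is scored by ten-fold CV;
selection screens delta-AICc < 2, then minimum test omission, then maximum
test AUC.  The winner is refit on all data; variable contributions and the
fundamental-niche envelope at the 0.5 level follow, with recovery checked
against the generator's true optima.
"""

import sys
from importlib import import_module
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
cfg_mod = import_module("00_config")

import json

from paleoniche import io as pio
from paleoniche import maxent as mx


def main():
    cfg = cfg_mod.CONFIG
    table = pio.read_table(cfg_mod.RESULTS / "observation_table.csv")
    retained = json.loads((cfg_mod.RESULTS / "retained_variables.json").read_text())

    grid = mx.default_tuning_grid(cfg.rm_grid, cfg.feature_classes, cfg.hinge_knots)
    sel = mx.cross_validate_select(
        table, grid=grid, folds=cfg.folds, seed=cfg.seed + 3, variables=retained
    )
    pio.write_table(sel.grid, cfg_mod.RESULTS / "tuning_grid.csv")
    pio.save_model(sel.model, cfg_mod.RESULTS / "model.json")
    for line in sel.trace:
        print(line)
    win = sel.grid.sort_values("delta_aicc").iloc[0]
    print(f"winner fold metrics: mean AUC {win['mean_auc']:.3f} "
          f"(sd {win['sd_auc']:.3f}), mean omission {win['mean_omission']:.3f}")

    contrib = mx.variable_contribution(sel.model, table, seed=cfg.seed + 4)
    pio.write_table(contrib, cfg_mod.RESULTS / "contributions.csv")
    print("\nvariable contributions (%):")
    print(contrib.round(1).to_string(index=False))

    env = mx.niche_envelope(sel.model, cut=0.5)
    print("\nfundamental-niche envelope (suitability >= 0.5):")
    for v, segs in env["intervals"].items():
        txt = ", ".join(f"[{lo:.1f}, {hi:.1f}]" for lo, hi in segs) or "(empty)"
        true_opt = cfg.niche.optima.get(v)
        mark = f"  (true optimum {true_opt})" if true_opt is not None else ""
        print(f"  {v}: {txt}{mark}")
    (cfg_mod.RESULTS / "niche_envelope.json").write_text(
        json.dumps({v: segs for v, segs in env["intervals"].items()}, indent=1)
    )


if __name__ == "__main__":
    main()
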