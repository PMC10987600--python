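"""Assemble the space-time observation table: presences from the dated
record plus 100-per-millennium background points, with predictor values
extracted at each record's own slice.
"""

import sys
from importlib import import_module
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
cfg_mod = import_module("00_config")

from paleoniche import io as pio
from paleoniche.grids import ClimateStack
from paleoniche.sampling import extract_values, presences_from_chronology, sample_background


def main():
    cfg = cfg_mod.CONFIG
    stack = ClimateStack.from_netcdf(cfg_mod.RESULTS / "climate_stack.nc")
    filtered = pio.read_table(cfg_mod.RESULTS / "observations_dated.csv")

    years = stack.years[
        (stack.years <= cfg.background_year_max) & (stack.years >= cfg.background_year_min)
    ]
    bg = sample_background(stack, cfg.n_background_per_slice, slices=years, seed=cfg.seed + 2)
    pres = presences_from_chronology(filtered, stack)
    table = extract_values(pd.concat([pres, bg], ignore_index=True), stack)
    pio.write_table(table, cfg_mod.RESULTS / "observation_table.csv")

    n_pres = (table["label"] == "presence").sum()
    n_bg = (table["label"] == "background").sum()
    print(f"{n_bg} background records over {len(years)} millennia "
          f"({cfg.n_background_per_slice}/slice), {n_pres} presences "
          f"({table.attrs['n_excluded_masked']} excluded on masked cells)")


if __name__ == "__main__":
    main()
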