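"""Generate the synthetic paleoworld: 116 millennial slices of a masked,
equal-area climate grid with glacial-cycle forcing.

Writes ``results/climate_stack.nc`` and prints the mask budget so later
stages have a known, fully synthetic predictor source with ground truth.
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent))
from importlib import import_module

cfg_mod = import_module("00_config")

from paleoniche.grids import ICE, LAND, SEA
from paleoniche.synth import generate_paleoworld


def main():
    world_cfg = cfg_mod.CONFIG.world
    stack = generate_paleoworld(world_cfg)
    out = cfg_mod.RESULTS / "climate_stack.nc"
    stack.to_netcdf(out)

    land = (stack.mask == LAND).mean()
    sea = (stack.mask == SEA).mean()
    ice = (stack.mask == ICE).mean()
    f = world_cfg.forcing(stack.years)
    print(f"wrote {out}")
    print(f"{stack.n_slices} slices of {stack.shape[1]}x{stack.shape[2]} cells "
          f"({stack.cell_area_km2:.2f} km2 each)")
    print(f"mask budget: {land:.1%} land, {sea:.1%} sea, {ice:.1%} ice")
    ice_per_slice = (stack.mask == ICE).sum(axis=(1, 2))
    print(f"ice extent ranges {ice_per_slice.min()}-{ice_per_slice.max()} cells; "
          f"coldest slice {int(stack.years[np.argmin(f)])} BP, "
          f"warmest {int(stack.years[np.argmax(f)])} BP")


if __name__ == "__main__":
    main()
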