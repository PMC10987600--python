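"""Screen predictors by pairwise correlation and probe niche stability.

A greedy Pearson screen (|r| > 0.7 drops the later-priority partner) reduces
the candidate set; small penalized-spline GAMs (k = 3) of each retained
variable on years BP — separately at presences and at backgrounds — test
whether occupied environments drifted relative to available ones.
"""

import sys
from importlib import import_module
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
cfg_mod = import_module("00_config")

import json

from paleoniche import io as pio
from paleoniche.varselect import correlation_filter, stability_report


def main():
    cfg = cfg_mod.CONFIG
    table = pio.read_table(cfg_mod.RESULTS / "observation_table.csv")
    rep = correlation_filter(table, cfg.candidates, threshold=cfg.correlation_threshold)
    pio.write_table(rep.matrix.reset_index(names="variable"), cfg_mod.RESULTS / "correlations.csv")
    (cfg_mod.RESULTS / "retained_variables.json").write_text(json.dumps(rep.retained))

    print("correlation matrix:")
    print(rep.matrix.round(3).to_string())
    print("retained:", ", ".join(rep.retained))
    for v, partner, r in rep.dropped:
        print(f"dropped {v}: r={r:+.3f} with {partner}")

    stab = stability_report(table, rep.retained, k=cfg.stability_k)
    pio.write_table(stab, cfg_mod.RESULTS / "stability.csv")
    print("\nniche-stability smooths (k=3):")
    for _, row in stab.iterrows():
        print(f"  {row['variable']:>13s} @ {row['label']:<10s} "
              f"edf={row['edf']:.2f} p={row['p_value']:.3g}")


if __name__ == "__main__":
    main()
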