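"""Shared settings for the numbered analysis scripts.

Every script reads and writes under ``results/`` relative to the repository
root and uses the same seeded desk-scale configuration, so the sequence
01 → 07 reproduces one coherent analysis.  Run them in order:

    python analysis/01_build_world.py
    python analysis/02_date_contexts.py
    ...
"""

from pathlib import Path

from paleoniche.pipeline import demo_config

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)

SEED = 1
CONFIG = demo_config(seed=SEED)
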