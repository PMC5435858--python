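#!/usr/bin/env python
"""Adult vs. fetal editing activity on a dedicated simulated cohort.

Fetal quiescent neurons carry the adult neuron signature at half the
on-probability, neuronal progenitors at a quarter; one designated Q/R-like
recoding site is always edited in adult and quiescent fetal cells and never
in progenitors. Reports the AEI ordering and the Q/R-like site's levels.
Writes tables under results/fetal/.
"""

import sys
from pathlib import Path

import json

from inosinome.studies import fetal_adult_study

OUT = Path(__file__).resolve().parent.parent / "results" / "fetal"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0

res = fetal_adult_study(OUT, seed=SEED)
(OUT / "summary.json").write_text(json.dumps(res, indent=2) + "\n")

print("median AEI by cohort:")
for key in ("median_aei_adult", "median_aei_fetal_quiescent",
            "median_aei_fetal_progenitor"):
    print(f"  {key.removeprefix('median_aei_'):18s} {res[key]:.3f}")
print(f"Q/R-like site: min level {res['qr_min_level_quiescent']:.2f} across "
      f"{res['qr_n_quiescent_covered']} covered quiescent fetal cells; "
      f"max level {res['qr_max_level_progenitor']:.2f} across "
      f"{res['qr_n_progenitor_covered']} progenitors")
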