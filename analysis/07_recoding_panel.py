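#!/usr/bin/env python
"""Editing at the recoding-site panel: per-type summaries and contrasts.

Restricts the cohort's calls to recoding sites (amino-acid-changing
positions), flags sites edited in >=90% of a type's covered cells, and
tests neuron-vs-astrocyte level differences per site (rank-sum + BH).
"""

from pathlib import Path

import pandas as pd

from inosinome.calls import FilterParams
from inosinome.catalog import load_catalog, subset_recoding
from inosinome.pipeline import load_profiles
from inosinome.recoding import recoding_profile, type_contrast

ROOT = Path(__file__).resolve().parent.parent / "results" / "cohort"
if not (ROOT / "calls").exists():
    raise SystemExit("run analysis/02_call_editing.py first")

cat = load_catalog(ROOT / "catalog.tsv", "tsv")
panel = subset_recoding(cat)
profiles = load_profiles(ROOT / "calls", cat, FilterParams())
types = pd.read_csv(ROOT / "metrics.tsv", sep="\t", index_col=0)["cell_type"]

m = recoding_profile(profiles, panel, types.to_dict())
m.levels.to_csv(ROOT / "recoding_matrix.tsv", sep="\t")
m.per_type.to_csv(ROOT / "recoding_per_type.tsv", sep="\t")

nu = m.per_type[m.per_type["near_universal"]]
print(f"recoding panel: {len(panel)} sites x {m.levels.shape[1]} cells")
print(f"near-universal (edited in >=90% of covered cells): "
      f"{len(nu)} (site, type) pairs")

contrast = type_contrast(m, "neuron", "astrocyte")
contrast.to_csv(ROOT / "contrast_neuron_vs_astrocyte.tsv", sep="\t")
tested = contrast[contrast["tested"]]
sig = tested[tested["p_bh"] < 0.05]
print(f"neuron vs astrocyte: {len(tested)} sites tested, "
      f"{len(sig)} significant at BH 0.05, "
      f"median delta(neuron - astrocyte) = {tested['delta_mean'].median():+.2f}")
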