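#!/usr/bin/env python
"""Alu editing index per cell and its correlation with per-cell summaries.

The AEI pools edited and total A+G counts over covered Alu sites (a
coverage-weighted mean level). Also reports its Spearman correlation with
the per-cell mean editing level and normalized level sum.
"""

from pathlib import Path

import pandas as pd

from inosinome.aei import (aei_summary_correlations, aei_table,
                           cell_level_summaries, compute_aei)
from inosinome.calls import FilterParams
from inosinome.catalog import load_catalog
from inosinome.pipeline import load_profiles

ROOT = Path(__file__).resolve().parent.parent / "results" / "cohort"
if not (ROOT / "calls").exists():
    raise SystemExit("run analysis/02_call_editing.py first")

cat = load_catalog(ROOT / "catalog.tsv", "tsv")
profiles = load_profiles(ROOT / "calls", cat, FilterParams())
results = [r for r in (compute_aei(p, cat) for p in profiles) if r is not None]
table = aei_table(results)
types = pd.read_csv(ROOT / "metrics.tsv", sep="\t", index_col=0)["cell_type"]
table.insert(0, "cell_type", types.reindex(table.index))
table.to_csv(ROOT / "aei.tsv", sep="\t")

per_type = table.groupby("cell_type")["aei"].median().sort_values(ascending=False)
print(f"AEI defined for {len(table)} cells; median by type:")
for t, v in per_type.items():
    print(f"  {t:16s} {v:.3f}")

corr = aei_summary_correlations(results, profiles)
cell_level_summaries(profiles).to_csv(ROOT / "cell_level_summaries.tsv", sep="\t")
print(f"Spearman(AEI, mean level)     rho = {corr['rho_mean']:.2f} (p = {corr['p_mean']:.2g})")
print(f"Spearman(AEI, normalized sum) rho = {corr['rho_normsum']:.2f} (p = {corr['p_normsum']:.2g})")
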