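#!/usr/bin/env python
"""NMDS of pairwise Spearman dissimilarities between editing profiles.

Cells are compared over sites covered in both (pairwise-complete ranks),
embedded in 2-D by nonmetric MDS, and scored against the simulated type
labels with k-means + adjusted Rand index. Writes the dissimilarity matrix
and coordinates under results/cohort/.
"""

from pathlib import Path

import pandas as pd

from inosinome.calls import FilterParams, profiles_to_matrix
from inosinome.catalog import load_catalog
from inosinome.embed import (cluster_recovery, nmds, spearman_dissimilarity,
                             type_centroids)
from inosinome.pipeline import load_profiles

ROOT = Path(__file__).resolve().parent.parent / "results" / "cohort"
if not (ROOT / "calls").exists():
    raise SystemExit("run analysis/02_call_editing.py first")

cat = load_catalog(ROOT / "catalog.tsv", "tsv")
profiles = load_profiles(ROOT / "calls", cat, FilterParams())
matrix = profiles_to_matrix(profiles, cat)
types = pd.read_csv(ROOT / "metrics.tsv", sep="\t", index_col=0)["cell_type"]

dmat = spearman_dissimilarity(matrix)
emb = nmds(dmat, seed=0)
dmat.to_frame().to_csv(ROOT / "dissimilarity.tsv", sep="\t")
coords = emb.to_frame()
coords["type"] = types.reindex(coords.index)
coords.to_csv(ROOT / "embedding.tsv", sep="\t")

ari, sil = cluster_recovery(emb, types.to_dict(), seed=0)
print(f"NMDS over {len(emb.cell_ids)} cells: stress-1 = {emb.stress:.3f}, "
      f"converged = {emb.converged}")
print(f"k-means recovery of {types.nunique()} types: ARI = {ari:.2f}, "
      f"silhouette(true labels) = {sil:.2f}")
cents = type_centroids(emb, types.to_dict())
d_n = ((cents.loc['hybrid'] - cents.loc['neuron'])**2).sum()**0.5
d_a = ((cents.loc['hybrid'] - cents.loc['astrocyte'])**2).sum()**0.5
print(f"hybrid centroid distance: to neurons {d_n:.2f}, to astrocytes {d_a:.2f}")
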