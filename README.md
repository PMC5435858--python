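# inosinome

Single-cell analysis of A-to-I RNA editing ("inosinome") profiles: quantify
editing at known sites per cell from aligned reads, compute the Alu editing
index, characterize the bimodal per-cell vs. unimodal pseudobulk structure
of editing levels, and recover cell-type identity from editing profiles
alone. The package targets transcriptomics researchers working with
single-cell RNA-seq of tissues (the motivating system is human brain
cortex, where ADAR-mediated editing is essential for neuronal function) who
want editing-centric, rather than expression-centric, cell profiling.

## What it computes

ADAR enzymes deaminate adenosine to inosine in double-stranded RNA;
sequencers read inosine as guanosine, so editing appears as A→G on the
annotated strand (T→C on the forward reference for minus-strand sites).
Working from a catalog of known editing positions (REDIportal/RADAR-style),
the pileup caller counts quality-filtered bases per cell and site
(MAPQ ≥ 20, base quality ≥ 30, ≥ 10 filtered reads, duplicates included by
default) and reports the **editing level**

    level(s) = n_G(s) / (n_A(s) + n_G(s)).

Per-cell global activity is the **Alu editing index**, the coverage-weighted
mean level over covered Alu-resident sites:

    AEI = Σ_s n_G(s) / Σ_s (n_A(s) + n_G(s)),   s ∈ covered Alu sites.

Distribution shape is scored with **Sarle's bimodality coefficient**
BC = (g₁² + 1) / (g₂ + 3(n−1)²/((n−2)(n−3))) (bias-corrected skewness g₁
and excess kurtosis g₂; BC above the uniform reference 5/9 ≈ 0.555 indicates
bimodality). Cell–cell structure comes from pairwise-complete **Spearman
dissimilarities** d = 1 − ρ embedded in 2-D by **nonmetric MDS** (Kruskal
stress-1), with k-means + adjusted Rand index scoring type recovery on
simulations. A synthetic-data generator emits per-cell SAM files with known
all-or-nothing editing ground truth, cell-type signatures, ~10% pre-flagged
PCR duplicates and realistic quality structure, so every step is testable
against truth.

## Worked example

The numbered scripts under `analysis/` run the full narrative on synthetic
cohorts (each is a thin driver over the library; outputs land in
`results/`). For example:

```
$ python analysis/01_simulate_cohort.py
simulated 60 cells of 5 types over 500 catalog sites -> .../results/cohort
mean true AEI: 0.387

$ python analysis/02_call_editing.py
called 60 cells; sites per cell: median 492, range 238-500
level matrix density: 0.96

$ python analysis/04_bimodality_pseudobulk.py
100% of 50 cells exceed the bimodality threshold (BC > 0.556); median per-cell BC = 0.995
pseudobulk: BC = 0.362 (unimodal), 82% of levels < 0.2

$ python analysis/06_embedding_clusters.py
NMDS over 60 cells: stress-1 = 0.155, converged = True
k-means recovery of 5 types: ARI = 0.70, silhouette(true labels) = 0.55
hybrid centroid distance: to neurons 0.01, to astrocytes 1.07
```

Reading these numbers: individual cells edit all-or-nothing, so per-cell
levels pile up at 0 and 1 (BC ≈ 1, far above 0.556), while pooling reads
across cells — mimicking a bulk tissue — collapses the distribution to the
familiar unimodal shape with most levels below 0.2. Editing profiles alone
separate simulated cell types; "hybrid" cells, which share the neuron
editing signature, land on top of the neuron centroid (distance 0.01) and
far from astrocytes (1.07), which is why the 5-label ARI is 0.70 — the
embedding correctly refuses to split hybrids from neurons.

The same machinery is scriptable as a CLI (`inosinome simulate|call|qc|aei|
stats|embed|recoding|run`, exit codes 0/1/2 for ok/data error/config error)
or as a library (`inosinome.calls.call_cell`, `inosinome.aei.compute_aei`,
`inosinome.embed.nmds`, ...).

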