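# Methods

## Editing model and calling

A known-sites caller, not a variant discoverer: editing is quantified only
at cataloged A-to-I positions. For each catalog site the caller counts
bases from reads passing a mapping-quality filter (default ≥ 20) whose base
quality at the site passes a phred filter (default ≥ 30). Reads carrying a
deletion or splice/reference skip across the site contribute nothing.
Counts are expressed in site-strand space: at a '+' site the forward
reference A/G are the unedited/edited bases; at a '−' site forward T/C play
those roles. Bases outside the A/G dichotomy (sequencing errors, rare SNVs)
count toward coverage but not toward the level denominator, so

    level = n_G / (n_A + n_G),  coverage = n_A + n_G + n_other.

Sites with filtered coverage below the floor (default 10 reads) are
omitted; zero-G sites are retained (no minimum on edited reads or
frequency), which is what lets fully unedited positions populate the
level-0 peak. Duplicate-flagged reads (0x400) are *included* by default —
the duplicate-sensitivity analysis shows ~10% duplication moves profiles
negligibly — and excluded only in the explicit dedup mode. The coverage
floor applies to post-filter coverage, and again after pseudobulk pooling.

A second, independent implementation of the same counting contract — a
plain-text SAM parser with its own CIGAR walk (`inosinome.validation`) —
exists solely to cross-check the pileup route; tests compare the two
exactly over a grid of filter settings.

Profiles keep one call per (chrom, pos); a catalog annotating both strands
at one position would collide there, a configuration the merge logic
resolves away and the generator never produces.

## Catalogs

Internal coordinates are 1-based inclusive (GTF convention); BED I/O
converts at the boundary. Merging is a nonredundant union keyed by
(chrom, pos, strand); annotation or strand disagreements between catalogs
are resolved by an explicit precedence argument and counted. Repeat class
(ALU / OTHER_REP / NONREP) is always taken from annotation, never
recomputed. The recoding panel is the recoding-flagged subset restricted to
nonrepetitive sites, plus an explicit gene whitelist for validated
repeat-resident recoding sites (default: NARF).

## Alu editing index

AEI = Σ n_G / Σ (n_A + n_G) over a cell's covered Alu sites — pooled
counts, i.e. a coverage-weighted mean level, which equals the unweighted
mean only under equal per-site coverage (an unweighted mode exists for
comparison). The per-cell summaries correlated with AEI are the mean level
and the "normalized sum" of levels, defined here as Σ levels / n covered
sites; over the covered-site set these coincide, and both are reported
because they are conventionally quoted separately.

## Distribution statistics

Sarle's bimodality coefficient BC = (g₁² + 1) / (g₂ + 3(n−1)²/((n−2)(n−3)))
uses bias-corrected sample skewness and excess kurtosis; it is reported as
absent for n < 4 or zero variance. The uniform distribution gives the
conventional threshold 5/9 ≈ 0.5556; note the small-sample correction makes
two-point balanced samples dip below it for n ≲ 13 (at n = 8 the value is
exactly 1/2.1 ≈ 0.476), so bimodality claims are only made at adequate n.
Histograms use 50 fixed half-open bins over [0,1], last bin closed, for
bit-reproducible summaries. Pseudobulk pools base counts across cells per
site *before* re-applying the coverage floor and recomputing levels —
pooling reads, not averaging levels — which is the mechanism converting
bimodal per-cell levels into a unimodal low-level ensemble distribution.
That conversion requires a homogeneous population: in a signature-
structured cohort, consistently edited signature sites survive pooling and
the pseudobulk stays multimodal (analysis/04 documents both).

## Dissimilarity and embedding

Cell pairs are compared over the sites covered in both (pairwise-complete),
with average-rank Spearman correlation; d = 1 − ρ ∈ [0, 2]. Pairs sharing
fewer than `min_shared` sites (default 10) or with undefined ρ are imputed
with the maximum observed dissimilarity and flagged; cells with no usable
pair are dropped with a warning. The rank basis makes the matrix invariant
to any strictly monotone transform of levels.

Nonmetric MDS is delegated to scikit-learn's SMACOF with monotone
regression (`MDS(metric_mds=False)`, precomputed dissimilarities, best of
20 random starts, deterministic under the seed); Kruskal stress-1 is then
recomputed from the final configuration via isotonic regression, matching
the metaMDS convention (validated against vegan::metaMDS, which reports
stress within 3×10⁻⁴ of ours on identical input). Coordinates are centered
at the origin; orientation is arbitrary (compare up to rotation/reflection).
Cluster recovery is scored by k-means (k = number of true classes, fixed
seed) against true labels via adjusted Rand index, plus the silhouette of
the true labels. A geometric caveat: k mutually equidistant clusters have
no low-stress 2-D rank embedding (for four tight equidistant clusters the
stress-1 floor is ≈ 0.169, attained by a square); low stress in real data
reflects *heterogeneous* between-type similarity, so stress should be read
alongside ARI, not alone.

## Recoding panel

The panel matrix holds per-cell levels at recoding sites with missingness
preserved (a site uncovered in a cell is NaN, never 0 — missingness is
informative). Per-type aggregates (mean level, fraction of covered cells
edited) use covered cells only; a site is flagged "near-universal" for a
type when ≥ 90% of that type's covered cells are edited (level > 0) — the
threshold is this package's convention. Type contrasts use the two-sided
Wilcoxon rank-sum per site (exact null for combined n ≤ 30, ties
uncorrected; tie-corrected normal approximation otherwise) with
Benjamini–Hochberg correction across tested sites; the statistical test is
this package's addition to make between-type claims assertable.

## Cell QC

Cells are excluded when uniquely aligned reads < 1,000,000 or mapping rate
< 0.70 — both strictly, so boundary cells pass. The mapping rate comes from
the supplied metrics table (upstream aligner/metrics output), never
recomputed. On desk-scale synthetic cohorts the same rule shape is
exercised with rescaled thresholds.

## Synthetic-data generator

The generator emulates the statistical structure of single-cell editing
data, not its molecular detail:

- **All-or-nothing penetrance** (default): per cell and site the true level
  is 0 or 1, drawn Bernoulli with a per-type on-probability. A graded mode
  draws levels uniformly in (0.1, 0.9) instead.
- **Cell-type signatures**: each non-aliased type owns an equal share of
  the non-shared sites; `type_signature_overlap` controls the shared
  fraction. "Hybrid" cells alias the neuron signature. Fetal cohorts scale
  the neuron on-probability by `fetal_scale` (quiescent) and `fetal_scale²`
  (progenitors), with one designated Q/R-like recoding site forced always
  edited in adult and quiescent fetal cells and never in progenitors.
- **Coverage**: per-site Poisson (default mean 30) times a per-cell
  lognormal factor (σ = 0.25, unit mean) emulating depth variation.
- **Technical noise**: substitution errors at rate 10⁻³ carrying reduced
  base quality (22), a 3% fraction of low-quality (q20) and 5% of low-MAPQ
  (10) reads to exercise the q30/m20 filters, and PCR duplicates emitted as
  exact copies pre-flagged 0x400 (each read duplicated with p = 0.10,
  matching ~10% duplication).
- **Reads**: single-end, fixed 50 bp, SAM v1.6, one chromosome, sites
  spaced 200 bp so each read covers exactly one site; the library is
  unstranded and site orientation comes only from the catalog. MAPQ 255
  for unique alignments (aligner convention).

Identical config + seed gives byte-identical SAM output. Ground truth
records true levels, realized per-site depths and the implied true AEI
(Σ depth·level / Σ depth over Alu sites).

What the generator does **not** emulate: transcript structure, splicing,
intron-spanning reads, expression-level variation coupled to cell state,
rRNA contamination, paired-end layouts, or reference-genome context.
Passing tests therefore demonstrate the correctness of counting, index
arithmetic, distribution statistics and embedding logic under the stated
statistical assumptions — not robustness to alignment artifacts or
annotation errors in real data.

## Study conditions

The packaged studies (shared by the analysis drivers, the test suite and
`scripts/acceptance.py`) use: caller validation on 20 small cohorts' worth
of SAM fixtures under a 16-point filter grid; bimodality/pseudobulk at 50
cells × 500 sites, on-probability 0.15, depth 30; AEI recovery at 40 cells
× 500 all-Alu sites, rate 0.25, depth 30 (recovery is measured against
each cell's own ground-truth AEI — read-sampling error — since site-state
sampling alone spreads per-cell AEI by ≈ 0.02 s.d. around the global rate
at 500 sites); duplicate sensitivity at 12 cells × 300 sites, depth 30;
cluster recovery at 4 types × 20 cells, 200 sites, depth 20; hybrid
placement over 5 seeded runs of 3 types × 12 cells; fetal/adult at 3
cohorts × 15 cells, 300 sites, depth 30. Sizes were chosen once to give
comfortable statistical margins at minutes-scale runtime on one core.

## Known limitations

- One call per genomic position per cell (both-strand catalogs collide).
- The exact rank-sum null ignores ties (standard for the exact method);
  heavily tied small-sample contrasts are conservative.
- NMDS inherits SMACOF's local-minimum behaviour; 20 random starts make
  results stable in practice but global optimality is not guaranteed.
- Synthetic metrics tables draw mapping rates uniformly in (0.75, 0.95);
  QC failure modes are exercised with constructed tables, not simulated
  alignment pathology.
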