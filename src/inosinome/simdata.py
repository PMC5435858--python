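"""Synthetic single-cell cohorts with known editing ground truth.

The generator emulates the statistical structure of single-cell brain-cortex
editing data: a catalog of known A-to-I sites (mostly Alu-resident), cells of
several types, and per-cell aligned reads in SAM format. Editing is
"all-or-nothing" per cell and site by default — a site is either fully edited
(every true read carries the edited base) or fully unedited in a given cell —
which is what produces the bimodal per-cell level distribution that pooling
into a pseudobulk collapses to a unimodal low-level one.

Cell-type structure comes from signature sites: each non-aliased type owns a
block of catalog sites at which its cells switch sites on with probability
``p_edited``; at other types' signature sites the on-probability is the
background rate. A configurable fraction of sites is shared across all types.
"Hybrid" cells reuse the neuron signature, mirroring their intermediate
character. Fetal cohorts are adult types with on-probabilities scaled down,
plus a designated Q/R-like recoding site that is always edited in quiescent
fetal neurons (and adult cells) but never in neuronal progenitors.

Technical noise emulated: Poisson per-site coverage with a lognormal per-cell
depth factor, sequencing errors at a fixed per-base rate (with reduced base
quality), a fraction of low-base-quality and low-MAPQ reads to exercise the
q30/m20 filters, and PCR duplicates emitted as exact copies pre-flagged with
0x400 (about 10% of reads by default). Reads are single-end, fixed length,
each overlapping exactly one catalog site; the library is unstranded and
site orientation comes only from the catalog.

Everything is driven by one integer seed; identical config + seed gives
byte-identical SAM output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .catalog import ALU, NONREP, OTHER_REP, EditingSite, SiteCatalog, write_catalog

logger = logging.getLogger(__name__)

READ_LENGTH = 50
SITE_SPACING = 200  # >= 2x read length: no read spans two sites
CHROM = "chr1"
_BASES = np.array(list("ACGT"))

DEFAULT_CELL_TYPES = ("neuron", "astrocyte", "oligodendrocyte", "OPC", "hybrid")
DEFAULT_ALIASES = {"hybrid": "neuron"}


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation parameters.

    ``p_edited_by_type`` is either a single probability applied to every
    type or a mapping type -> probability; it is the chance that a cell of
    that type switches one of its signature (or shared) sites on.
    ``type_signature_overlap`` is the fraction of catalog sites whose
    on-probability is shared across all types; the remainder is partitioned
    into per-type signature blocks.
    """

    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    n_cells_per_type: int = 20
    n_sites: int = 500
    alu_fraction: float = 0.8
    other_rep_fraction: float = 0.05
    n_recoding: int = 20
    penetrance_mode: str = "all_or_nothing"
    p_edited_by_type: float | Mapping[str, float] = 0.8
    background_p: float = 0.0
    type_signature_overlap: float = 0.0
    signature_alias: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_ALIASES))
    depth_mean: float = 30.0
    depth_cell_sigma: float = 0.25
    dup_rate: float = 0.10
    seq_error_rate: float = 0.001
    base_q_edited: int = 37
    base_q_error: int = 22
    low_bq_fraction: float = 0.03
    low_bq_value: int = 20
    low_mapq_fraction: float = 0.05
    low_mapq_value: int = 10
    seed: int = 0
    # site index -> {type: forced on-probability}; used for the Q/R-like site
    forced_sites: Mapping[int, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if not 0 <= self.dup_rate < 1:
            raise ValueError("dup_rate must be in [0, 1)")
        for p in self._p_map().values():
            if not 0 <= p <= 1:
                raise ValueError("on-probabilities must be in [0, 1]")
        for p in (self.background_p, self.type_signature_overlap, self.alu_fraction,
                  self.low_bq_fraction, self.low_mapq_fraction, self.seq_error_rate):
            if not 0 <= p <= 1:
                raise ValueError("fractions must be in [0, 1]")
        if self.penetrance_mode not in ("all_or_nothing", "graded"):
            raise ValueError(f"unknown penetrance_mode {self.penetrance_mode!r}")

    def _p_map(self) -> dict[str, float]:
        if isinstance(self.p_edited_by_type, Mapping):
            missing = set(self.cell_types) - set(self.p_edited_by_type)
            if missing:
                raise ValueError(f"p_edited_by_type missing types: {sorted(missing)}")
            return dict(self.p_edited_by_type)
        return {t: float(self.p_edited_by_type) for t in self.cell_types}


@dataclass
class GroundTruth:
    """True per-cell editing states and derived quantities.

    ``levels`` holds the true pre-noise editing level per cell and site (0/1
    in all-or-nothing mode); ``depths`` the realized unique-read coverage
    used to emit reads. ``true_aei`` is the coverage-weighted true Alu level:
    sum(depth*level) / sum(depth) over Alu sites.
    """

    cell_types: dict[str, str]
    levels: pd.DataFrame
    depths: pd.DataFrame
    alu_mask: np.ndarray
    qr_site: str | None = None

    @property
    def true_aei(self) -> pd.Series:
        d = self.depths.values[:, self.alu_mask].astype(float)
        l = self.levels.values[:, self.alu_mask]
        denom = d.sum(axis=1)
        with np.errstate(invalid="ignore"):
            aei = (d * l).sum(axis=1) / denom
        return pd.Series(aei, index=self.levels.index, name="true_aei")


@dataclass
class CohortSim:
    catalog: SiteCatalog
    sam_paths: dict[str, Path]
    truth: GroundTruth
    metrics: pd.DataFrame
    outdir: Path


# ---------------------------------------------------------------------------
# catalog construction


def _build_catalog(cfg: SimConfig, rng: np.random.Generator) -> tuple[SiteCatalog, list[EditingSite]]:
    n = cfg.n_sites
    positions = 100 + SITE_SPACING * np.arange(n)
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    classes = np.full(n, NONREP, dtype=object)
    r = rng.random(n)
    classes[r < cfg.alu_fraction] = ALU
    classes[(r >= cfg.alu_fraction) & (r < cfg.alu_fraction + cfg.other_rep_fraction)] = OTHER_REP
    nonrep_idx = np.flatnonzero(classes == NONREP)
    rec_idx = set(nonrep_idx[: cfg.n_recoding].tolist())
    aa_cycle = ("Q/R", "R/G", "I/V", "K/E", "S/G", "Y/C")
    sites = []
    for i in range(n):
        rec = i in rec_idx
        sites.append(
            EditingSite(
                CHROM, int(positions[i]), str(strands[i]),
                repeat_class=str(classes[i]),
                recoding=rec,
                gene=f"GENE{i}" if rec else None,
                aa_change=aa_cycle[i % len(aa_cycle)] if rec else None,
            )
        )
    return SiteCatalog(sites), sites


def _site_probs(cfg: SimConfig, sites: list[EditingSite], rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Per-type on-probability vector over the catalog, from overlap +
    signature-block structure plus any forced sites."""
    n = len(sites)
    p_map = cfg._p_map()
    base_types = [t for t in cfg.cell_types if t not in cfg.signature_alias]
    n_shared = int(round(cfg.type_signature_overlap * n))
    shared = np.zeros(n, dtype=bool)
    shared[:n_shared] = True
    owner = np.full(n, -1)
    if base_types:
        sig_idx = np.flatnonzero(~shared)
        for j, idx in enumerate(sig_idx):
            owner[idx] = j % len(base_types)
    probs: dict[str, np.ndarray] = {}
    for t in cfg.cell_types:
        sig_type = cfg.signature_alias.get(t, t)
        k = base_types.index(sig_type) if sig_type in base_types else -2
        p = np.where(shared | (owner == k), p_map[t], cfg.background_p)
        probs[t] = p.astype(float)
    for site_i, per_type in cfg.forced_sites.items():
        for t, pv in per_type.items():
            if t in probs:
                probs[t][site_i] = pv
    return probs


# ---------------------------------------------------------------------------
# read emission


def _emit_cell_sam(
    path: Path,
    cell_id: str,
    sites: list[EditingSite],
    true_level: np.ndarray,
    depth: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
    chrom_len: int,
) -> dict[str, int]:
    """Write one cell's reads as coordinate-sorted SAM; returns read counts."""
    lines: list[tuple[int, str, str]] = []  # (start0, name, record tail)
    n_unique = 0
    n_dup = 0
    q_high = chr(cfg.base_q_edited + 33)
    qual_chr = {
        cfg.base_q_edited: q_high,
        cfg.base_q_error: chr(cfg.base_q_error + 33),
        cfg.low_bq_value: chr(cfg.low_bq_value + 33),
    }
    for i, site in enumerate(sites):
        d = int(depth[i])
        if d == 0:
            continue
        offsets = rng.integers(0, READ_LENGTH, size=d)
        edited = rng.random(d) < true_level[i]
        errors = rng.random(d) < cfg.seq_error_rate
        low_bq = rng.random(d) < cfg.low_bq_fraction
        low_mapq = rng.random(d) < cfg.low_mapq_fraction
        reverse = rng.random(d) < 0.5
        dup = rng.random(d) < cfg.dup_rate
        seqmat = _BASES[rng.integers(0, 4, size=(d, READ_LENGTH))]
        # true base at the site in forward-reference space; errors replace it
        # with a uniformly drawn different base at reduced quality
        if site.strand == "+":
            site_base = np.where(edited, "G", "A")
        else:
            site_base = np.where(edited, "C", "T")
        err_idx = np.flatnonzero(errors)
        for r in err_idx:
            site_base[r] = rng.choice(_BASES[_BASES != site_base[r]])
        for r in range(d):
            site_off = int(offsets[r])  # offset of the site within the read
            start0 = site.pos - 1 - site_off
            seqmat[r, site_off] = site_base[r]
            if errors[r]:
                qs = qual_chr[cfg.base_q_error]
            elif low_bq[r]:
                qs = qual_chr[cfg.low_bq_value]
            else:
                qs = q_high
            qual_s = q_high * site_off + qs + q_high * (READ_LENGTH - site_off - 1)
            seq_s = "".join(seqmat[r])
            mapq = cfg.low_mapq_value if low_mapq[r] else 255
            flag = 16 if reverse[r] else 0
            name = f"{cell_id}_s{i}_r{r}"
            tail = f"{flag}\t{CHROM}\t{start0 + 1}\t{mapq}\t{READ_LENGTH}M\t*\t0\t0\t{seq_s}\t{qual_s}"
            lines.append((start0, name, tail))
            n_unique += 1
            if dup[r]:
                dtail = f"{flag | 0x400}\t{CHROM}\t{start0 + 1}\t{mapq}\t{READ_LENGTH}M\t*\t0\t0\t{seq_s}\t{qual_s}"
                lines.append((start0, name + "_d", dtail))
                n_dup += 1
    lines.sort(key=lambda x: (x[0], x[1]))
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        fh.write(f"@SQ\tSN:{CHROM}\tLN:{chrom_len}\n")
        for _start, name, tail in lines:
            fh.write(f"{name}\t{tail}\n")
    return {"n_unique": n_unique, "n_dup": n_dup}


# ---------------------------------------------------------------------------
# cohort drivers


def simulate_cohort(cfg: SimConfig, outdir: str | Path) -> CohortSim:
    """Generate a full cohort: catalog TSV, one SAM per cell, ground-truth
    and metrics tables. Deterministic given ``cfg`` (including its seed)."""
    outdir = Path(outdir)
    (outdir / "sam").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    catalog, sites = _build_catalog(cfg, rng)
    probs = _site_probs(cfg, sites, rng)
    chrom_len = 100 + SITE_SPACING * cfg.n_sites + 2 * READ_LENGTH

    site_ids = [f"{s.chrom}:{s.pos}" for s in sites]
    alu_mask = np.array([s.repeat_class == ALU for s in sites])

    cell_ids: list[str] = []
    types: dict[str, str] = {}
    levels = []
    depths = []
    sam_paths: dict[str, Path] = {}
    metrics_rows = []
    for t in cfg.cell_types:
        for j in range(cfg.n_cells_per_type):
            cell_id = f"{t}_{j:03d}"
            cell_ids.append(cell_id)
            types[cell_id] = t
            on = rng.random(cfg.n_sites) < probs[t]
            if cfg.penetrance_mode == "all_or_nothing":
                lvl = on.astype(float)
            else:
                lvl = np.where(on, rng.uniform(0.1, 0.9, size=cfg.n_sites), 0.0)
            depth_factor = float(
                rng.lognormal(mean=-cfg.depth_cell_sigma**2 / 2, sigma=cfg.depth_cell_sigma)
            )
            d = rng.poisson(cfg.depth_mean * depth_factor, size=cfg.n_sites)
            sam_path = outdir / "sam" / f"{cell_id}.sam"
            counts = _emit_cell_sam(sam_path, cell_id, sites, lvl, d, cfg, rng, chrom_len)
            sam_paths[cell_id] = sam_path
            levels.append(lvl)
            depths.append(d)
            aligned = counts["n_unique"] + counts["n_dup"]
            map_rate = float(rng.uniform(0.75, 0.95))
            metrics_rows.append(
                {
                    "cell_id": cell_id,
                    "cell_type": t,
                    "total_reads": int(round(aligned / map_rate)),
                    "uniquely_aligned_reads": aligned,
                    "mapping_rate": round(map_rate, 4),
                    "dup_rate": round(counts["n_dup"] / max(aligned, 1), 4),
                }
            )

    truth = GroundTruth(
        cell_types=types,
        levels=pd.DataFrame(np.array(levels), index=cell_ids, columns=site_ids),
        depths=pd.DataFrame(np.array(depths), index=cell_ids, columns=site_ids),
        alu_mask=alu_mask,
    )
    metrics = pd.DataFrame(metrics_rows).set_index("cell_id")

    write_catalog(catalog, outdir / "catalog.tsv")
    metrics.to_csv(outdir / "metrics.tsv", sep="\t")
    tt = truth.true_aei.to_frame()
    tt.insert(0, "cell_type", [types[c] for c in tt.index])
    tt.to_csv(outdir / "ground_truth_aei.tsv", sep="\t")
    truth.levels.to_csv(outdir / "ground_truth_levels.tsv", sep="\t")
    logger.info("simulated %d cells over %d sites into %s", len(cell_ids), cfg.n_sites, outdir)
    return CohortSim(catalog, sam_paths, truth, metrics, outdir)


def simulate_fetal_adult(
    cfg: SimConfig, fetal_scale: float, outdir: str | Path
) -> CohortSim:
    """Adult cohort plus fetal_quiescent / fetal_progenitor cohorts.

    Fetal on-probabilities are the neuron rate scaled by ``fetal_scale``
    (quiescent) and ``fetal_scale**2`` (progenitors); both reuse the neuron
    signature sites. One designated Q/R-like recoding site is forced always
    edited in adult cells and quiescent fetal neurons and never edited in
    progenitors.
    """
    if not 0 < fetal_scale <= 1:
        raise ValueError("fetal_scale must be in (0, 1]")
    p_map = cfg._p_map()
    p_neuron = p_map.get("neuron", next(iter(p_map.values())))
    new_types = cfg.cell_types + ("fetal_quiescent", "fetal_progenitor")
    new_p = dict(p_map)
    new_p["fetal_quiescent"] = fetal_scale * p_neuron
    new_p["fetal_progenitor"] = fetal_scale**2 * p_neuron
    aliases = dict(cfg.signature_alias)
    aliases["fetal_quiescent"] = aliases.get("neuron", "neuron")
    aliases["fetal_progenitor"] = aliases.get("neuron", "neuron")

    # designated Q/R-like site: the first recoding site (site 0 as fallback)
    rng = np.random.default_rng(cfg.seed)
    _catalog, sites = _build_catalog(cfg, rng)
    qr_idx = next((i for i, s in enumerate(sites) if s.recoding), 0)
    forced = {int(qr_idx): {
        **{t: 1.0 for t in cfg.cell_types},
        "fetal_quiescent": 1.0,
        "fetal_progenitor": 0.0,
    }}

    cfg2 = replace(
        cfg,
        cell_types=new_types,
        p_edited_by_type=new_p,
        signature_alias=aliases,
        forced_sites=forced,
    )
    sim = simulate_cohort(cfg2, outdir)
    sim.truth.qr_site = f"{sites[qr_idx].chrom}:{sites[qr_idx].pos}"
    return sim


def synthetic_recoding_panel(path: str | Path, n_sites: int = 183, seed: int = 0) -> None:
    """Write a synthetic recoding panel in the supplementary-table layout
    (chrom, pos, strand, gene, aa_change). Stand-in for a published panel;
    positions and gene labels are invented."""
    rng = np.random.default_rng(seed)
    aa = ("Q/R", "R/G", "I/V", "K/E", "S/G", "Y/C")
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tstrand\tgene\taa_change\n")
        pos = 0
        for i in range(n_sites):
            pos += int(rng.integers(200, 5000))
            strand = "+" if rng.random() < 0.5 else "-"
            fh.write(f"chr{1 + i % 22}\t{pos}\t{strand}\tGENE{i}\t{aa[i % len(aa)]}\n")
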