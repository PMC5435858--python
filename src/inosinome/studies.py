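"""Canonical synthetic studies over the pipeline.

Each function sets up one study condition on synthetic data with known
ground truth — caller validation, bimodality vs. pseudobulk, AEI recovery,
duplicate sensitivity, cluster recovery, hybrid-cell placement, and the
fetal/adult contrast — runs the relevant pipeline steps, and returns the
measured quantities as a plain dict. The analysis drivers, the test suite
and the reproduction script all call these, so every reported number comes
from the same computation.

Cohort sizes are chosen to keep a full run in the minutes range on one core
while leaving comfortable statistical margins; the methods note documents
each study's parameters.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import numpy as np

from .aei import compute_aei
from .calls import FilterParams, call_cell, profiles_to_matrix
from .embed import cluster_recovery, nmds, spearman_dissimilarity, type_centroids
from .qc import dup_sensitivity
from .simdata import SimConfig, simulate_cohort, simulate_fetal_adult
from .stats import (BIMODALITY_THRESHOLD, bimodality_coefficient, pseudobulk,
                    summarize_levels)
from .validation import scan_counts


def _call_all(sim, params: FilterParams = FilterParams()):
    return [call_cell(p, sim.catalog, params) for p in sim.sam_paths.values()]


def caller_validation(outdir: str | Path, seed: int = 0) -> dict[str, Any]:
    """Pileup caller vs. the independent per-read scanner on >=20 small SAM
    fixtures spanning strands, duplicates and low-quality reads, under a
    grid of filter settings. Reports the fraction of (fixture, filter, site)
    count triples in exact agreement."""
    import itertools

    configs = [
        SimConfig(cell_types=("c",), signature_alias={}, n_cells_per_type=5,
                  n_sites=30, p_edited_by_type=0.3, type_signature_overlap=1.0,
                  depth_mean=15, dup_rate=0.15, low_mapq_fraction=0.2,
                  low_bq_fraction=0.2, seq_error_rate=0.01, seed=seed),
        SimConfig(cell_types=("c",), signature_alias={}, n_cells_per_type=5,
                  n_sites=25, p_edited_by_type=0.9, type_signature_overlap=1.0,
                  depth_mean=8, dup_rate=0.05, low_bq_fraction=0.5,
                  seed=seed + 1),
        SimConfig(cell_types=("c",), signature_alias={}, n_cells_per_type=10,
                  n_sites=40, p_edited_by_type=0.1, type_signature_overlap=1.0,
                  depth_mean=25, dup_rate=0.10, low_mapq_fraction=0.05,
                  seed=seed + 2),
    ]
    grid = [
        FilterParams(min_base_quality=bq, min_mapping_quality=mq,
                     min_coverage=cov, exclude_duplicates=dup)
        for bq, mq, cov, dup in itertools.product((0, 30), (0, 20), (1, 10), (False, True))
    ]
    n_compared = 0
    n_equal = 0
    n_fixtures = 0
    for i, cfg in enumerate(configs):
        sim = simulate_cohort(cfg, Path(outdir) / f"val{i}")
        for path in sim.sam_paths.values():
            n_fixtures += 1
            for params in grid:
                called = call_cell(path, sim.catalog, params).calls
                ref = scan_counts(path, sim.catalog, params)
                ref = {
                    k: v for k, v in ref.items()
                    if sum(v) >= params.min_coverage and v[1] >= params.min_variant_reads
                }
                keys = set(called) | set(ref)
                for key in keys:
                    n_compared += 1
                    c = called.get(key)
                    r = ref.get(key)
                    if c is not None and r is not None and (c.n_A, c.n_G, c.n_other) == r:
                        n_equal += 1
    return {
        "n_fixtures": n_fixtures,
        "n_site_comparisons": n_compared,
        "agreement_fraction": n_equal / n_compared,
    }


def bimodality_study(outdir: str | Path, seed: int = 0,
                     n_cells: int = 50, n_sites: int = 500,
                     p_on: float = 0.15, depth: float = 30) -> dict[str, Any]:
    """All-or-nothing cohort; per-cell bimodality vs. pseudobulk unimodality."""
    cfg = SimConfig(cell_types=("cell",), signature_alias={},
                    n_cells_per_type=n_cells, n_sites=n_sites,
                    p_edited_by_type=p_on, type_signature_overlap=1.0,
                    depth_mean=depth, seed=seed)
    sim = simulate_cohort(cfg, outdir)
    profiles = _call_all(sim)
    bcs = [bimodality_coefficient(list(p.levels().values())) for p in profiles]
    defined = [b for b in bcs if b is not None]
    bulk = pseudobulk(profiles)
    bulk_dist = summarize_levels(list(bulk.levels().values()))
    return {
        "n_cells": len(profiles),
        "frac_cells_bimodal": float(np.mean([b > BIMODALITY_THRESHOLD for b in defined])),
        "median_cell_bc": float(np.median(defined)),
        "pseudobulk_bc": bulk_dist.bimodality_coefficient,
        "pseudobulk_frac_low": bulk_dist.frac_low,
    }


def aei_recovery_study(outdir: str | Path, seed: int = 0,
                       n_cells: int = 40, n_sites: int = 500,
                       true_rate: float = 0.25, depth: float = 30) -> dict[str, Any]:
    """Recovery of per-cell and pooled AEI against ground truth on an
    all-Alu catalog with global editing rate ``true_rate``."""
    cfg = SimConfig(cell_types=("cell",), signature_alias={},
                    n_cells_per_type=n_cells, n_sites=n_sites,
                    alu_fraction=1.0, other_rep_fraction=0.0, n_recoding=0,
                    p_edited_by_type=true_rate, type_signature_overlap=1.0,
                    depth_mean=depth, seed=seed)
    sim = simulate_cohort(cfg, outdir)
    profiles = _call_all(sim)
    truth = sim.truth.true_aei
    errors = []
    num = den = 0
    t_num = t_den = 0.0
    for p in profiles:
        r = compute_aei(p, sim.catalog)
        errors.append(abs(r.aei - truth[p.cell_id]))
        num += r.num_G
        den += r.denom_AG
    d = sim.truth.depths.values[:, sim.truth.alu_mask].astype(float)
    lv = sim.truth.levels.values[:, sim.truth.alu_mask]
    t_num, t_den = (d * lv).sum(), d.sum()
    errors = np.array(errors)
    return {
        "n_cells": len(profiles),
        "true_rate": true_rate,
        "frac_cells_within_002": float(np.mean(errors <= 0.02)),
        "max_cell_abs_error": float(errors.max()),
        "pooled_aei": num / den,
        "pooled_true_aei": t_num / t_den,
        "pooled_abs_error": abs(num / den - t_num / t_den),
        "pooled_vs_nominal_error": abs(num / den - true_rate),
    }


def dup_sensitivity_study(outdir: str | Path, seed: int = 0,
                          n_cells: int = 12, n_sites: int = 300,
                          depth: float = 30) -> dict[str, Any]:
    """Raw vs. deduplicated calls per cell at ~10% duplication."""
    cfg = SimConfig(cell_types=("cell",), signature_alias={},
                    n_cells_per_type=n_cells, n_sites=n_sites,
                    p_edited_by_type=0.15, type_signature_overlap=1.0,
                    depth_mean=depth, dup_rate=0.10, seed=seed)
    sim = simulate_cohort(cfg, outdir)
    shared, rs = [], []
    for path in sim.sam_paths.values():
        raw = call_cell(path, sim.catalog, FilterParams())
        dedup = call_cell(path, sim.catalog, FilterParams(exclude_duplicates=True))
        res = dup_sensitivity(raw, dedup)
        shared.append(res.shared_site_fraction)
        rs.append(res.level_r)
    return {
        "n_cells": n_cells,
        "min_shared_fraction": float(min(shared)),
        "mean_shared_fraction": float(np.mean(shared)),
        "min_level_r": float(min(r for r in rs if r is not None)),
        "mean_level_r": float(np.mean([r for r in rs if r is not None])),
        "n_r_defined": sum(r is not None for r in rs),
    }


def cluster_recovery_study(outdir: str | Path, seed: int = 0,
                           n_cells_per_type: int = 20, n_sites: int = 200,
                           depth: float = 20) -> dict[str, Any]:
    """Four types with disjoint signatures -> NMDS + k-means recovery."""
    cfg = SimConfig(cell_types=("neuron", "astrocyte", "oligodendrocyte", "OPC"),
                    signature_alias={}, n_cells_per_type=n_cells_per_type,
                    n_sites=n_sites, p_edited_by_type=0.8,
                    type_signature_overlap=0.0, depth_mean=depth, seed=seed)
    sim = simulate_cohort(cfg, outdir)
    profiles = _call_all(sim)
    matrix = profiles_to_matrix(profiles, sim.catalog)
    dmat = spearman_dissimilarity(matrix)
    emb = nmds(dmat, seed=seed)
    ari, sil = cluster_recovery(emb, sim.truth.cell_types, seed=seed)
    return {
        "n_cells": len(profiles),
        "stress": emb.stress,
        "ari": ari,
        "silhouette": sil,
    }


def hybrid_placement_study(outdir: str | Path, seeds: list[int],
                           n_cells_per_type: int = 12, n_sites: int = 150,
                           depth: float = 15) -> dict[str, Any]:
    """Hybrid cells share the neuron signature; across seeded runs their
    centroid must sit nearer neurons than astrocytes."""
    n_nearer = 0
    for seed in seeds:
        cfg = SimConfig(cell_types=("neuron", "astrocyte", "hybrid"),
                        signature_alias={"hybrid": "neuron"},
                        n_cells_per_type=n_cells_per_type, n_sites=n_sites,
                        p_edited_by_type=0.8, type_signature_overlap=0.0,
                        depth_mean=depth, seed=seed)
        sim = simulate_cohort(cfg, Path(outdir) / f"seed{seed}")
        profiles = _call_all(sim)
        matrix = profiles_to_matrix(profiles, sim.catalog)
        emb = nmds(spearman_dissimilarity(matrix), seed=seed)
        cents = type_centroids(emb, sim.truth.cell_types)
        d_neuron = np.linalg.norm(cents.loc["hybrid"] - cents.loc["neuron"])
        d_astro = np.linalg.norm(cents.loc["hybrid"] - cents.loc["astrocyte"])
        n_nearer += int(d_neuron < d_astro)
    return {
        "n_runs": len(seeds),
        "n_hybrid_nearer_neuron": n_nearer,
        "frac_hybrid_nearer_neuron": n_nearer / len(seeds),
    }


def fetal_adult_study(outdir: str | Path, seed: int = 0, fetal_scale: float = 0.5,
                      n_cells_per_type: int = 15, n_sites: int = 300,
                      depth: float = 30) -> dict[str, Any]:
    """Adult vs. fetal cohorts: AEI ordering and the Q/R-like site."""
    cfg = SimConfig(cell_types=("neuron",), signature_alias={},
                    n_cells_per_type=n_cells_per_type, n_sites=n_sites,
                    p_edited_by_type=0.3, type_signature_overlap=1.0,
                    depth_mean=depth, seed=seed)
    sim = simulate_fetal_adult(cfg, fetal_scale, outdir)
    profiles = _call_all(sim)
    types = sim.truth.cell_types
    aei_by_type: dict[str, list[float]] = {}
    for p in profiles:
        r = compute_aei(p, sim.catalog)
        if r is not None:
            aei_by_type.setdefault(types[p.cell_id], []).append(r.aei)
    medians = {t: float(np.median(v)) for t, v in aei_by_type.items()}
    qr_chrom, qr_pos = sim.truth.qr_site.split(":")
    qr_key = (qr_chrom, int(qr_pos))
    quiescent_levels, progenitor_levels = [], []
    for p in profiles:
        call = p.calls.get(qr_key)
        if call is None or call.level is None:
            continue
        if types[p.cell_id] == "fetal_quiescent":
            quiescent_levels.append(call.level)
        elif types[p.cell_id] == "fetal_progenitor":
            progenitor_levels.append(call.level)
    return {
        "median_aei_adult": medians["neuron"],
        "median_aei_fetal_quiescent": medians["fetal_quiescent"],
        "median_aei_fetal_progenitor": medians["fetal_progenitor"],
        "qr_n_quiescent_covered": len(quiescent_levels),
        "qr_min_level_quiescent": float(min(quiescent_levels)) if quiescent_levels else None,
        "qr_n_progenitor_covered": len(progenitor_levels),
        "qr_max_level_progenitor": float(max(progenitor_levels)) if progenitor_levels else None,
    }
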