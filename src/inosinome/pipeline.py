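"""Stage-driven orchestration: simulate -> call -> qc -> aei -> stats ->
embed -> recoding, with a machine-readable run report.

Each stage writes plain TSV artifacts under the output directory so any
stage can be re-run or inspected on its own; a stage invoked without its
in-memory predecessor reloads what it needs from those files. The report
(report.json) records the configuration, seeds and per-stage summaries and
contains no timestamps, so identical inputs give identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml

from . import __version__, aei as aei_mod, embed as embed_mod
from . import qc as qc_mod, recoding as rec_mod, stats as stats_mod
from .calls import (CellProfile, FilterParams, SiteCall, call_cell,
                    profiles_to_matrix, write_level_matrix, write_profile_tsv)
from .catalog import SiteCatalog, load_catalog, subset_recoding
from .simdata import SimConfig, simulate_cohort, simulate_fetal_adult

logger = logging.getLogger(__name__)

STAGES = ("simulate", "call", "qc", "aei", "stats", "embed", "recoding")


class PipelineError(RuntimeError):
    """A stage dependency is missing; the message names the stage to run."""


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Everything one run needs: paths, filters, QC thresholds, simulation
    parameters and the master seed."""

    outdir: Path = Path("inosinome_run")
    catalog: Path | None = None
    catalog_dialect: str = "tsv"
    sam_dir: Path | None = None
    metrics: Path | None = None
    filters: FilterParams = field(default_factory=FilterParams)
    min_reads: int = qc_mod.DEFAULT_MIN_READS
    min_map_rate: float = qc_mod.DEFAULT_MIN_MAP_RATE
    sim: SimConfig = field(default_factory=SimConfig)
    fetal_scale: float | None = None
    seed: int = 0
    min_shared_sites: int = 10
    nmds_starts: int = 20

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        try:
            kwargs: dict[str, Any] = {}
            for key in ("outdir", "catalog", "sam_dir", "metrics"):
                if raw.get(key) is not None:
                    kwargs[key] = Path(raw[key])
            for key in ("catalog_dialect", "min_reads", "min_map_rate", "seed",
                        "min_shared_sites", "nmds_starts", "fetal_scale"):
                if key in raw:
                    kwargs[key] = raw[key]
            if "filters" in raw:
                kwargs["filters"] = FilterParams(**raw["filters"])
            if "sim" in raw:
                sim_kwargs = dict(raw["sim"])
                if "cell_types" in sim_kwargs:
                    sim_kwargs["cell_types"] = tuple(sim_kwargs["cell_types"])
                kwargs["sim"] = SimConfig(**sim_kwargs)
            return cls(**kwargs)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc

    def to_dict(self) -> dict[str, Any]:
        def convert(obj: Any) -> Any:
            if isinstance(obj, Path):
                return str(obj)
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {str(k): convert(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [convert(v) for v in obj]
            return obj
        return {f.name: convert(getattr(self, f.name)) for f in dataclasses.fields(self)}


@dataclass
class PipelineState:
    catalog: SiteCatalog | None = None
    profiles: list[CellProfile] | None = None
    metrics: pd.DataFrame | None = None
    cell_types: dict[str, str] | None = None
    matrix: pd.DataFrame | None = None


def _require(cond: bool, stage_needed: str, what: str) -> None:
    if not cond:
        raise PipelineError(f"{what} unavailable: run the {stage_needed!r} stage first")


def load_profiles(calls_dir: Path, cat: SiteCatalog, params: FilterParams) -> list[CellProfile]:
    profiles = []
    for path in sorted(calls_dir.glob("*.calls.tsv")):
        cell_id = path.name.removesuffix(".calls.tsv")
        prof = CellProfile(cell_id=cell_id, params=params)
        df = pd.read_csv(path, sep="\t")
        for row in df.itertuples(index=False):
            matches = [s for s in cat.at(row.chrom, row.pos) if s.strand == row.strand]
            if not matches:
                continue
            prof.calls[(row.chrom, row.pos)] = SiteCall(
                matches[0], int(row.n_A), int(row.n_G), int(row.n_other)
            )
        profiles.append(prof)
    return profiles


def run_pipeline(cfg: RunConfig, stages: Sequence[str] | None = None) -> dict[str, Any]:
    """Run the requested stages in canonical order; returns (and writes) the
    run report."""
    stages = list(stages or STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stage(s): {sorted(unknown)}")
    stages = [s for s in STAGES if s in stages]
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    state = PipelineState()
    report: dict[str, Any] = {
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "stages": {},
    }

    for stage in stages:
        summary = _STAGE_FUNCS[stage](cfg, state, outdir)
        report["stages"][stage] = summary
        logger.info("stage %s: %s", stage, summary)

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(cfg: RunConfig, state: PipelineState, outdir: Path) -> dict[str, Any]:
    simdir = outdir / "sim"
    sim_cfg = dataclasses.replace(cfg.sim, seed=cfg.seed)
    if cfg.fetal_scale is not None:
        sim = simulate_fetal_adult(sim_cfg, cfg.fetal_scale, simdir)
    else:
        sim = simulate_cohort(sim_cfg, simdir)
    state.catalog = sim.catalog
    state.metrics = sim.metrics
    state.cell_types = dict(sim.truth.cell_types)
    return {
        "n_cells": len(sim.sam_paths),
        "n_sites": len(sim.catalog),
        "cell_types": sorted(set(sim.truth.cell_types.values())),
        "outdir": str(simdir),
    }


def _get_catalog(cfg: RunConfig, state: PipelineState, outdir: Path) -> SiteCatalog:
    if state.catalog is None:
        path = cfg.catalog or (outdir / "sim" / "catalog.tsv")
        _require(Path(path).exists(), "simulate", f"catalog {path}")
        state.catalog = load_catalog(path, cfg.catalog_dialect)
    return state.catalog


def _get_metrics(cfg: RunConfig, state: PipelineState, outdir: Path) -> pd.DataFrame:
    if state.metrics is None:
        path = cfg.metrics or (outdir / "sim" / "metrics.tsv")
        _require(Path(path).exists(), "simulate", f"metrics table {path}")
        state.metrics = pd.read_csv(path, sep="\t", index_col=0)
    if state.cell_types is None and "cell_type" in state.metrics.columns:
        state.cell_types = state.metrics["cell_type"].to_dict()
    return state.metrics


def _stage_call(cfg: RunConfig, state: PipelineState, outdir: Path) -> dict[str, Any]:
    cat = _get_catalog(cfg, state, outdir)
    sam_dir = cfg.sam_dir or (outdir / "sim" / "sam")
    sam_paths = sorted(list(Path(sam_dir).glob("*.sam")) + list(Path(sam_dir).glob("*.bam")))
    _require(bool(sam_paths), "simulate", f"alignment files in {sam_dir}")
    calls_dir = outdir / "calls"
    calls_dir.mkdir(exist_ok=True)
    profiles = []
    for path in sam_paths:
        prof = call_cell(path, cat, cfg.filters)
        write_profile_tsv(prof, calls_dir / f"{prof.cell_id}.calls.tsv")
        profiles.append(prof)
    state.profiles = profiles
    state.matrix = profiles_to_matrix(profiles, cat)
    write_level_matrix(state.matrix, outdir / "levels")
    return {
        "n_cells": len(profiles),
        "mean_sites_per_cell": float(pd.Series([len(p) for p in profiles]).mean()),
    }


def _get_profiles(cfg: RunConfig, state: PipelineState, outdir: Path) -> list[CellProfile]:
    if state.profiles is None:
        cat = _get_catalog(cfg, state, outdir)
        calls_dir = outdir / "calls"
        _require(calls_dir.exists(), "call", f"call tables in {calls_dir}")
        state.profiles = load_profiles(calls_dir, cat, cfg.filters)
        _require(bool(state.profiles), "call", f"call tables in {calls_dir}")
        state.matrix = profiles_to_matrix(state.profiles, cat)
    return state.profiles


def _stage_qc(cfg: RunConfig, state: PipelineState, outdir: Path) -> dict[str, Any]:
    metrics = _get_metrics(cfg, state, outdir)
    passing, rep = qc_mod.qc_filter(metrics, cfg.min_reads, cfg.min_map_rate)
    rep.to_csv(outdir / "qc_report.tsv", sep="\t")
    return {"n_cells": len(rep), "n_pass": len(passing)}


def _stage_aei(cfg: RunConfig, state: PipelineState, outdir: Path) -> dict[str, Any]:
    cat = _get_catalog(cfg, state, outdir)
    profiles = _get_profiles(cfg, state, outdir)
    results = [r for r in (aei_mod.compute_aei(p, cat) for p in profiles) if r is not None]
    summary: dict[str, Any] = {"n_cells_with_aei": len(results)}
    if results:
        table = aei_mod.aei_table(results)
        table.to_csv(outdir / "aei.tsv", sep="\t")
        summary["mean_aei"] = float(table["aei"].mean())
        if len(results) >= 3:
            summary.update(aei_mod.aei_summary_correlations(results, profiles))
    return summary


def _stage_stats(cfg: RunConfig, state: PipelineState, outdir: Path) -> dict[str, Any]:
    profiles = _get_profiles(cfg, state, outdir)
    bc = stats_mod.per_cell_bimodality(profiles)
    bulk = stats_mod.pseudobulk(profiles)
    bulk_dist = stats_mod.summarize_levels(list(bulk.levels().values()))
    pooled = [lvl for p in profiles for lvl in p.levels().values()]
    pooled_dist = stats_mod.summarize_levels(pooled)
    rows = [{"cell_id": c, "bimodality_coefficient": v} for c, v in bc.items()]
    pd.DataFrame(rows).to_csv(outdir / "bimodality.tsv", sep="\t", index=False)
    defined = [v for v in bc.values() if v is not None]
    return {
        "n_cells": len(bc),
        "median_cell_bc": float(pd.Series(defined).median()) if defined else None,
        "frac_cells_bimodal": (
            float(pd.Series([v > stats_mod.BIMODALITY_THRESHOLD for v in defined]).mean())
            if defined else None
        ),
        "pseudobulk_bc": bulk_dist.bimodality_coefficient,
        "pseudobulk_frac_low": bulk_dist.frac_low,
        "pooled_frac_low": pooled_dist.frac_low,
    }


def _stage_embed(cfg: RunConfig, state: PipelineState, outdir: Path) -> dict[str, Any]:
    _get_profiles(cfg, state, outdir)
    _get_metrics(cfg, state, outdir)
    dmat = embed_mod.spearman_dissimilarity(state.matrix, min_shared=cfg.min_shared_sites)
    emb = embed_mod.nmds(dmat, n_starts=cfg.nmds_starts, seed=cfg.seed)
    dmat.to_frame().to_csv(outdir / "dissimilarity.tsv", sep="\t")
    coords = emb.to_frame()
    summary: dict[str, Any] = {
        "n_cells": len(emb.cell_ids),
        "stress": emb.stress,
        "converged": emb.converged,
    }
    if state.cell_types:
        coords["type"] = [state.cell_types.get(c, "") for c in emb.cell_ids]
        ari, sil = embed_mod.cluster_recovery(emb, state.cell_types, seed=cfg.seed)
        summary["ari"] = ari
        summary["silhouette"] = sil
    coords.to_csv(outdir / "embedding.tsv", sep="\t")
    return summary


def _stage_recoding(cfg: RunConfig, state: PipelineState, outdir: Path) -> dict[str, Any]:
    cat = _get_catalog(cfg, state, outdir)
    profiles = _get_profiles(cfg, state, outdir)
    _get_metrics(cfg, state, outdir)
    panel = subset_recoding(cat)
    if len(panel) == 0:
        return {"n_panel_sites": 0, "note": "catalog has no recoding sites"}
    types = state.cell_types or {p.cell_id: "all" for p in profiles}
    m = rec_mod.recoding_profile(profiles, panel, types)
    m.levels.to_csv(outdir / "recoding_matrix.tsv", sep="\t")
    m.per_type.to_csv(outdir / "recoding_per_type.tsv", sep="\t")
    summary: dict[str, Any] = {
        "n_panel_sites": len(panel),
        "n_near_universal": int(m.per_type["near_universal"].sum()),
    }
    present = sorted(set(types.values()))
    if len(present) >= 2:
        contrast = rec_mod.type_contrast(m, present[0], present[1])
        contrast.to_csv(outdir / f"contrast_{present[0]}_vs_{present[1]}.tsv", sep="\t")
        tested = contrast[contrast["tested"]]
        summary["contrast"] = {
            "types": [present[0], present[1]],
            "n_tested": int(len(tested)),
            "median_delta": float(tested["delta_mean"].median()) if len(tested) else None,
        }
    return summary


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "call": _stage_call,
    "qc": _stage_qc,
    "aei": _stage_aei,
    "stats": _stage_stats,
    "embed": _stage_embed,
    "recoding": _stage_recoding,
}
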