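"""Alu editing index (AEI) per cell.

The AEI is the coverage-weighted mean editing level over a cell's covered
Alu-resident catalog sites: pooled edited-base count divided by pooled
(A+G) count,

    AEI = sum_s n_G(s) / sum_s (n_A(s) + n_G(s)),   s over covered Alu sites.

This equals the unweighted mean of per-site levels only when every
contributing site has identical (A+G) coverage; the pooled form is the
standard index and the default here, with the unweighted mean exposed for
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .calls import CellProfile
from .catalog import ALU, SiteCatalog


@dataclass(frozen=True)
class AEIResult:
    cell_id: str
    num_G: int
    denom_AG: int
    n_alu_sites: int

    @property
    def aei(self) -> float:
        return self.num_G / self.denom_AG

    def __post_init__(self) -> None:
        if self.denom_AG < self.num_G or self.denom_AG <= 0:
            raise ValueError("invalid AEI counts")


def compute_aei(
    profile: CellProfile, cat: SiteCatalog, weighted: bool = True
) -> AEIResult | None:
    """AEI for one cell, or None if no Alu site is covered.

    With ``weighted=False`` returns an AEIResult whose counts are rescaled to
    express the unweighted mean of per-site levels (comparison mode; num/denom
    then lose their read-count meaning).
    """
    n_g = 0
    denom = 0
    n_sites = 0
    levels = []
    for (chrom, pos), call in profile.calls.items():
        if call.site.repeat_class != ALU:
            continue
        if call.n_A + call.n_G == 0:
            continue
        n_g += call.n_G
        denom += call.n_A + call.n_G
        n_sites += 1
        levels.append(call.level)
    if n_sites == 0:
        return None
    if not weighted:
        scale = 10**9
        mean_level = float(np.mean(levels))
        return AEIResult(profile.cell_id, int(round(mean_level * scale)), scale, n_sites)
    return AEIResult(profile.cell_id, n_g, denom, n_sites)


def aei_table(results: Iterable[AEIResult]) -> pd.DataFrame:
    rows = [
        {
            "cell_id": r.cell_id,
            "aei": r.aei,
            "num_G": r.num_G,
            "denom_AG": r.denom_AG,
            "n_alu_sites": r.n_alu_sites,
        }
        for r in results
    ]
    return pd.DataFrame(rows).set_index("cell_id")


def cell_level_summaries(profiles: Iterable[CellProfile]) -> pd.DataFrame:
    """Per-cell editing-level summaries: mean level and normalized sum.

    The normalized sum is the sum of per-site levels divided by the number of
    assayed (covered) sites — identical to the mean when the assayed set is
    the covered set, which is the case here; both are kept because they are
    reported as separate per-cell summaries.
    """
    rows = []
    for p in profiles:
        levels = list(p.levels().values())
        if not levels:
            continue
        rows.append(
            {
                "cell_id": p.cell_id,
                "n_sites": len(levels),
                "mean_level": float(np.mean(levels)),
                "normalized_sum": float(np.sum(levels) / len(levels)),
            }
        )
    return pd.DataFrame(rows).set_index("cell_id")


def aei_summary_correlations(
    aeis: Sequence[AEIResult], profiles: Sequence[CellProfile]
) -> dict[str, float]:
    """Spearman correlation of per-cell AEI with (a) mean editing level and
    (b) normalized sum of editing levels, over cells having both quantities.

    Returns rho_mean, p_mean, rho_normsum, p_normsum. Requires >= 3 cells
    with a defined AEI.
    """
    aei_by_cell = {r.cell_id: r.aei for r in aeis}
    summaries = cell_level_summaries(profiles)
    cells = [c for c in summaries.index if c in aei_by_cell]
    if len(cells) < 3:
        raise ValueError("need at least 3 cells with a defined AEI")
    aei_v = np.array([aei_by_cell[c] for c in cells])
    out = {}
    for name, col in (("mean", "mean_level"), ("normsum", "normalized_sum")):
        rho, p = sps.spearmanr(aei_v, summaries.loc[cells, col].values)
        out[f"rho_{name}"] = float(rho)
        out[f"p_{name}"] = float(p)
    return out
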