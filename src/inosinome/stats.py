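"""Editing-level distribution summaries and pseudobulk pooling.

Per-cell editing levels in single cells are bimodal with peaks near 0 and 1
(all-or-nothing penetrance); pooling reads across cells into a pseudobulk
collapses this to the unimodal, low-level distribution familiar from bulk
tissue. Bimodality is quantified with Sarle's bimodality coefficient

    BC = (g1^2 + 1) / (g2 + 3(n-1)^2 / ((n-2)(n-3)))

with g1 the sample skewness and g2 the sample excess kurtosis (both
bias-corrected). BC exceeds ~5/9 ≈ 0.555, the value attained by the uniform
distribution, for distributions more bimodal than uniform.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .calls import CellProfile, SiteCall

BIMODALITY_THRESHOLD = 5.0 / 9.0
N_BINS = 50


def bimodality_coefficient(values: Sequence[float]) -> float | None:
    """Sarle's BC with bias-corrected sample skewness/kurtosis.

    None for n < 4 or zero variance (the statistic is undefined there).
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 4 or np.ptp(x) == 0:
        return None
    g1 = sps.skew(x, bias=False)
    g2 = sps.kurtosis(x, fisher=True, bias=False)
    return float((g1**2 + 1) / (g2 + 3 * (n - 1) ** 2 / ((n - 2) * (n - 3))))


@dataclass(frozen=True)
class LevelDistribution:
    """Summary of a collection of editing levels in [0, 1]."""

    n: int
    histogram: np.ndarray  # 50 half-open bins over [0,1], last bin closed
    bimodality_coefficient: float | None
    frac_low: float       # fraction of levels < 0.2
    frac_extreme: float   # fraction of levels <= 0.1 or >= 0.9

    @property
    def is_bimodal(self) -> bool | None:
        if self.bimodality_coefficient is None:
            return None
        return self.bimodality_coefficient > BIMODALITY_THRESHOLD


def summarize_levels(levels: Iterable[float]) -> LevelDistribution:
    x = np.asarray(list(levels), dtype=float)
    if x.size and (x.min() < 0 or x.max() > 1):
        raise ValueError("editing levels must lie in [0, 1]")
    # fixed half-open bins [k/50, (k+1)/50), final bin closed at 1
    idx = np.minimum((x * N_BINS).astype(int), N_BINS - 1)
    hist = np.bincount(idx, minlength=N_BINS) if x.size else np.zeros(N_BINS, dtype=int)
    return LevelDistribution(
        n=int(x.size),
        histogram=hist,
        bimodality_coefficient=bimodality_coefficient(x),
        frac_low=float(np.mean(x < 0.2)) if x.size else 0.0,
        frac_extreme=float(np.mean((x <= 0.1) | (x >= 0.9))) if x.size else 0.0,
    )


def pseudobulk(
    profiles: Iterable[CellProfile], cell_id: str = "pseudobulk"
) -> CellProfile:
    """Merge cells into one ensemble profile by pooling base counts.

    Counts (n_A, n_G, n_other) are summed across cells per site *before*
    the coverage floor is re-applied and levels recomputed — pooling reads,
    not averaging levels, which is what turns bimodal per-cell levels into a
    unimodal pseudobulk distribution.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles to pool")
    if len({p.params for p in profiles}) > 1:
        raise ValueError("profiles were called with differing FilterParams")
    params = profiles[0].params
    pooled: dict[tuple[str, int], SiteCall] = {}
    for p in profiles:
        for key, call in p.calls.items():
            prev = pooled.get(key)
            if prev is None:
                pooled[key] = call
            else:
                pooled[key] = SiteCall(
                    prev.site,
                    prev.n_A + call.n_A,
                    prev.n_G + call.n_G,
                    prev.n_other + call.n_other,
                )
    pooled = {
        k: c for k, c in pooled.items() if c.coverage >= params.min_coverage
    }
    return CellProfile(cell_id=cell_id, calls=pooled, params=params)


def per_cell_bimodality(profiles: Iterable[CellProfile]) -> dict[str, float | None]:
    """Sarle BC of each cell's level distribution."""
    return {
        p.cell_id: bimodality_coefficient(list(p.levels().values()))
        for p in profiles
    }
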