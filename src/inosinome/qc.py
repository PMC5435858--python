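"""Cell-level quality filtering and the PCR-duplicate sensitivity check.

Cells with fewer than one million uniquely aligned reads or a mapping rate
below 70% are excluded; both filters are strict ("<"), so a cell sitting
exactly on a boundary passes. The mapping rate is taken from the supplied
metrics table (uniquely_aligned / total as reported by upstream alignment
metrics), never recomputed from the alignment file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calls import CellProfile

DEFAULT_MIN_READS = 1_000_000
DEFAULT_MIN_MAP_RATE = 0.70

REQUIRED_COLUMNS = ("uniquely_aligned_reads", "mapping_rate")


def qc_filter(
    metrics: pd.DataFrame,
    min_reads: int = DEFAULT_MIN_READS,
    min_map_rate: float = DEFAULT_MIN_MAP_RATE,
) -> tuple[list[str], pd.DataFrame]:
    """Apply the cell-exclusion rule to a metrics table indexed by cell id.

    Returns (passing cell ids, per-cell report with verdicts and reasons).
    Exclusion is strict: a cell fails only if reads < min_reads or rate <
    min_map_rate; equality passes.
    """
    for col in REQUIRED_COLUMNS:
        if col not in metrics.columns:
            raise ValueError(f"metrics table lacks column {col!r}")
    reads = metrics["uniquely_aligned_reads"]
    rate = metrics["mapping_rate"]
    if (reads < 0).any() or (rate < 0).any() or (rate > 1).any():
        raise ValueError("negative read counts or mapping rate outside [0, 1]")
    fail_reads = reads < min_reads
    fail_rate = rate < min_map_rate
    reasons = np.select(
        [fail_reads & fail_rate, fail_reads, fail_rate],
        ["low_reads;low_mapping_rate", "low_reads", "low_mapping_rate"],
        default="",
    )
    report = pd.DataFrame(
        {
            "uniquely_aligned_reads": reads,
            "mapping_rate": rate,
            "pass": ~(fail_reads | fail_rate),
            "reason": reasons,
        },
        index=metrics.index,
    )
    passing = report.index[report["pass"]].tolist()
    return passing, report


@dataclass(frozen=True)
class DupSensitivity:
    """Raw-vs-deduplicated agreement for one cell.

    ``shared_site_fraction`` is relative to the raw profile's site count;
    ``level_r`` is the Pearson correlation of levels over shared sites, absent
    (None) when fewer than 3 sites are shared.
    """

    cell_id: str
    shared_site_fraction: float
    level_r: float | None
    n_shared: int


def dup_sensitivity(profile_raw: CellProfile, profile_dedup: CellProfile) -> DupSensitivity:
    """Compare a cell's profile called with duplicates against the same cell
    deduplicated (identical filters otherwise)."""
    if profile_raw.cell_id != profile_dedup.cell_id:
        raise ValueError(
            f"cell_id mismatch: {profile_raw.cell_id!r} vs {profile_dedup.cell_id!r}"
        )
    raw_levels = profile_raw.levels()
    dedup_levels = profile_dedup.levels()
    shared = sorted(set(raw_levels) & set(dedup_levels))
    frac = len(shared) / len(raw_levels) if raw_levels else 0.0
    r: float | None = None
    if len(shared) >= 3:
        x = np.array([raw_levels[k] for k in shared])
        y = np.array([dedup_levels[k] for k in shared])
        if x.std() == 0 and y.std() == 0 and np.allclose(x, y):
            r = 1.0  # identical constant vectors: perfect agreement
        elif x.std() == 0 or y.std() == 0:
            r = None
        else:
            r = float(np.corrcoef(x, y)[0, 1])
            if math.isnan(r):
                r = None
    return DupSensitivity(profile_raw.cell_id, frac, r, len(shared))
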