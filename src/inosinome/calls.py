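"""Known-site editing caller.

For one cell's aligned reads, count quality-filtered bases at every catalog
position and derive per-site editing levels. The editing level at a site is
G/(A+G) over filtered reads, in the orientation of the annotated strand: at a
'-' site the forward-reference T counts as the unedited adenosine and C as
the edited base. Bases other than A/G in strand space contribute to coverage
but not to the level denominator.

Filters mirror the standard known-sites calling setup: minimum mapping
quality 20, minimum base quality 30, and a post-filter coverage floor of 10
reads; zero-G sites are retained so fully unedited positions appear with
level 0. Duplicate-flagged reads are counted unless ``exclude_duplicates``
is set — the primary analyses run with duplicates included, the dedup mode
exists for the sensitivity comparison.
"""

from __future__ import annotations

import logging
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pysam

from .catalog import EditingSite, SiteCatalog

logger = logging.getLogger(__name__)

# sam flags excluded from pileup regardless of params
_BASE_FLAG_FILTER = 0x4 | 0x100 | 0x200  # unmapped, secondary, qcfail
_DUP_FLAG = 0x400


@dataclass(frozen=True)
class FilterParams:
    """Read/base filters applied before counting.

    Defaults follow the known-sites calling convention: MAPQ>=20, base
    quality >=30, >=10 filtered reads per retained site, duplicates included,
    and no minimum on edited-read count or frequency (zero-G sites retained).
    """

    min_base_quality: int = 30
    min_mapping_quality: int = 20
    min_coverage: int = 10
    exclude_duplicates: bool = False
    min_variant_reads: int = 0
    min_variant_freq: float = 0.0

    def __post_init__(self) -> None:
        if min(self.min_base_quality, self.min_mapping_quality,
               self.min_variant_reads) < 0 or self.min_variant_freq < 0:
            raise ValueError("filter thresholds must be >= 0")
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")


@dataclass(frozen=True)
class SiteCall:
    """Filtered base counts and editing level at one site in one cell."""

    site: EditingSite
    n_A: int
    n_G: int
    n_other: int

    @property
    def coverage(self) -> int:
        return self.n_A + self.n_G + self.n_other

    @property
    def level(self) -> float | None:
        denom = self.n_A + self.n_G
        return self.n_G / denom if denom else None


@dataclass
class CellProfile:
    """Sparse per-cell map (chrom, pos) -> SiteCall plus the filters used."""

    cell_id: str
    calls: dict[tuple[str, int], SiteCall] = field(default_factory=dict)
    params: FilterParams = field(default_factory=FilterParams)

    def __len__(self) -> int:
        return len(self.calls)

    def levels(self) -> dict[tuple[str, int], float]:
        return {k: c.level for k, c in self.calls.items() if c.level is not None}


def _strand_base_counts(counts: Mapping[str, int], strand: str) -> tuple[int, int, int]:
    """Collapse forward-reference base counts into (n_A, n_G, n_other) in
    strand space."""
    if strand == "+":
        n_a, n_g = counts.get("A", 0), counts.get("G", 0)
    else:
        n_a, n_g = counts.get("T", 0), counts.get("C", 0)
    n_other = sum(counts.values()) - n_a - n_g
    return n_a, n_g, n_other


def _prepare_bam(path: str | Path, workdir: Path) -> Path:
    """Return an indexed, coordinate-sorted BAM for ``path`` (SAM or BAM)."""
    path = Path(path)
    bai = Path(str(path) + ".bai")
    if path.suffix == ".bam" and bai.exists():
        return path
    sorted_bam = workdir / (path.stem + ".sorted.bam")
    pysam.sort("-o", str(sorted_bam), str(path))
    pysam.index(str(sorted_bam))
    return sorted_bam


def call_cell(
    alignment_path: str | Path,
    cat: SiteCatalog,
    params: FilterParams | None = None,
    cell_id: str | None = None,
) -> CellProfile:
    """Count filtered bases at every catalog site covered in one cell.

    Accepts SAM or BAM; an unindexed input is sorted and indexed into a
    temporary directory. Reads failing the MAPQ filter, bases failing the
    quality filter, and reads with a deletion or reference skip spanning the
    site contribute nothing. Sites whose filtered coverage falls below
    ``min_coverage`` are omitted from the profile.
    """
    params = params or FilterParams()
    alignment_path = Path(alignment_path)
    if cell_id is None:
        cell_id = alignment_path.stem.removesuffix(".sorted")
    profile = CellProfile(cell_id=cell_id, params=params)

    flag_filter = _BASE_FLAG_FILTER | (_DUP_FLAG if params.exclude_duplicates else 0)
    with tempfile.TemporaryDirectory(prefix="inosinome_call_") as tmp:
        bam_path = _prepare_bam(alignment_path, Path(tmp))
        with pysam.AlignmentFile(str(bam_path), "rb") as bam:
            header_refs = set(bam.references)
            n_missing = 0
            for chrom in cat.chroms:
                if chrom not in header_refs:
                    n_missing += len(cat.sites_on(chrom))
                    continue
                _call_chrom(bam, chrom, cat, params, flag_filter, profile)
            if n_missing:
                logger.warning(
                    "%s: %d catalog site(s) on chromosomes absent from the alignment header",
                    alignment_path, n_missing,
                )
    return profile


def _call_chrom(
    bam: pysam.AlignmentFile,
    chrom: str,
    cat: SiteCatalog,
    params: FilterParams,
    flag_filter: int,
    profile: CellProfile,
) -> None:
    sites = cat.sites_on(chrom)
    wanted = {s.pos for s in sites}
    lo, hi = min(wanted) - 1, max(wanted)
    for col in bam.pileup(
        chrom, lo, hi,
        truncate=True,
        stepper="samtools",
        flag_filter=flag_filter,
        min_base_quality=0,
        min_mapping_quality=0,
        ignore_overlaps=False,
        ignore_orphans=False,
        max_depth=1_000_000,
    ):
        pos1 = col.reference_pos + 1
        if pos1 not in wanted:
            continue
        counts: dict[str, int] = {}
        for pr in col.pileups:
            aln = pr.alignment
            if pr.is_del or pr.is_refskip or pr.query_position is None:
                continue
            if aln.mapping_quality < params.min_mapping_quality:
                continue
            if aln.query_qualities[pr.query_position] < params.min_base_quality:
                continue
            base = aln.query_sequence[pr.query_position].upper()
            counts[base] = counts.get(base, 0) + 1
        for site in cat.at(chrom, pos1):
            n_a, n_g, n_other = _strand_base_counts(counts, site.strand)
            call = SiteCall(site, n_a, n_g, n_other)
            if call.coverage < params.min_coverage:
                continue
            if call.n_G < params.min_variant_reads:
                continue
            if params.min_variant_freq > 0:
                lvl = call.level
                if lvl is None or lvl < params.min_variant_freq:
                    continue
            profile.calls[(chrom, pos1)] = call


# ---------------------------------------------------------------------------
# Cell x site level matrix


def profiles_to_matrix(
    profiles: Iterable[CellProfile], cat: SiteCatalog
) -> pd.DataFrame:
    """Cells x sites editing-level matrix with NaN for uncovered entries.

    A level of 0.0 (covered, zero edited reads) is a real entry, distinct
    from missing. Rows follow input order; columns follow catalog order.
    Raises on a duplicate cell id or on profiles called with differing
    filters.
    """
    profiles = list(profiles)
    ids = [p.cell_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate cell_id in profiles")
    if len({p.params for p in profiles}) > 1:
        raise ValueError("profiles were called with differing FilterParams")
    cols = [f"{s.chrom}:{s.pos}" for s in cat]
    keys = [(s.chrom, s.pos) for s in cat]
    data = np.full((len(profiles), len(cols)), np.nan)
    for i, p in enumerate(profiles):
        for j, key in enumerate(keys):
            call = p.calls.get(key)
            if call is not None and call.level is not None:
                data[i, j] = call.level
    return pd.DataFrame(data, index=ids, columns=cols)


_MTX_HEADER = "%%inosinome level matrix coordinate real general"


def write_level_matrix(matrix: pd.DataFrame, prefix: str | Path) -> None:
    """Write an MTX-style triplet file plus row/column label files.

    Explicit zero levels are stored (coordinate entries are the *covered*
    cells), which is why this writer exists: missingness must survive the
    round trip.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    rows, cols = np.nonzero(~np.isnan(matrix.values))
    with open(f"{prefix}.mtx", "w") as fh:
        fh.write(_MTX_HEADER + "\n")
        fh.write(f"{matrix.shape[0]} {matrix.shape[1]} {len(rows)}\n")
        for i, j in zip(rows, cols):
            fh.write(f"{i + 1} {j + 1} {float(matrix.values[i, j])!r}\n")
    Path(f"{prefix}.rows.txt").write_text("".join(f"{r}\n" for r in matrix.index))
    Path(f"{prefix}.cols.txt").write_text("".join(f"{c}\n" for c in matrix.columns))


def read_level_matrix(prefix: str | Path) -> pd.DataFrame:
    prefix = Path(prefix)
    row_ids = Path(f"{prefix}.rows.txt").read_text().splitlines()
    col_ids = Path(f"{prefix}.cols.txt").read_text().splitlines()
    with open(f"{prefix}.mtx") as fh:
        header = fh.readline()
        if not header.startswith("%%"):
            raise ValueError(f"{prefix}.mtx: missing header")
        n_rows, n_cols, _nnz = map(int, fh.readline().split())
        data = np.full((n_rows, n_cols), np.nan)
        for line in fh:
            i, j, v = line.split()
            data[int(i) - 1, int(j) - 1] = float(v)
    return pd.DataFrame(data, index=row_ids, columns=col_ids)


def write_profile_tsv(profile: CellProfile, path: str | Path) -> None:
    """Per-cell call table: chrom, pos, strand, coverage, n_A, n_G, n_other,
    level."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tstrand\tcoverage\tn_A\tn_G\tn_other\tlevel\n")
        for (chrom, pos), c in sorted(profile.calls.items()):
            lvl = "" if c.level is None else f"{c.level:.6g}"
            fh.write(
                f"{chrom}\t{pos}\t{c.site.strand}\t{c.coverage}\t"
                f"{c.n_A}\t{c.n_G}\t{c.n_other}\t{lvl}\n"
            )
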