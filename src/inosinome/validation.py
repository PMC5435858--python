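"""Reference per-read base counter for validating the pileup caller.

Implements the same counting contract as :func:`inosinome.calls.call_cell`
by a completely different route: a plain-text SAM parser with its own CIGAR
walk, no pileup machinery and no pysam. Used in tests and validation runs as
the independent second route; agreement between the two is a correctness
check, never a substitute for either.
"""

from __future__ import annotations

import re
from pathlib import Path

from .calls import FilterParams
from .catalog import SiteCatalog

_CIGAR = re.compile(r"(\d+)([MIDNSHP=X])")

_SKIP_FLAGS = 0x4 | 0x100 | 0x200  # unmapped, secondary, qcfail
_DUP_FLAG = 0x400


def scan_counts(
    sam_path: str | Path,
    cat: SiteCatalog,
    params: FilterParams | None = None,
) -> dict[tuple[str, int], tuple[int, int, int]]:
    """Count (n_A, n_G, n_other) in site-strand space at every catalog
    position, one read at a time.

    Applies the same filters as the caller: MAPQ and base-quality minimums,
    optional duplicate exclusion, and no contribution from deletions or
    reference skips spanning a site. Returns counts for *all* touched sites;
    the coverage floor is the caller's concern, not this scanner's.
    """
    params = params or FilterParams()
    counts: dict[tuple[str, int], dict[str, int]] = {}
    sites_by_chrom: dict[str, set[int]] = {}
    for s in cat:
        sites_by_chrom.setdefault(s.chrom, set()).add(s.pos)

    with open(sam_path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            f = line.rstrip("\n").split("\t")
            flag = int(f[1])
            if flag & _SKIP_FLAGS:
                continue
            if params.exclude_duplicates and flag & _DUP_FLAG:
                continue
            chrom, pos1, mapq, cigar, seq, qual = f[2], int(f[3]), int(f[4]), f[5], f[9], f[10]
            if chrom == "*" or chrom not in sites_by_chrom:
                continue
            if mapq < params.min_mapping_quality:
                continue
            # walk the alignment; record the query index aligned to each
            # reference position consumed by M/=/X operations
            ref = pos1
            qi = 0
            for n_str, op in _CIGAR.findall(cigar):
                n = int(n_str)
                if op in "M=X":
                    site_set = sites_by_chrom[chrom]
                    for k in range(n):
                        rp = ref + k
                        if rp in site_set:
                            q = ord(qual[qi + k]) - 33
                            if q >= params.min_base_quality:
                                base = seq[qi + k].upper()
                                c = counts.setdefault((chrom, rp), {})
                                c[base] = c.get(base, 0) + 1
                    ref += n
                    qi += n
                elif op in "IS":
                    qi += n
                elif op in "DN":
                    ref += n
                # H and P consume neither sequence shown nor reference bases
                # we count at

    out: dict[tuple[str, int], tuple[int, int, int]] = {}
    for site in cat:
        c = counts.get((site.chrom, site.pos))
        if not c:
            continue
        if site.strand == "+":
            n_a, n_g = c.get("A", 0), c.get("G", 0)
        else:
            n_a, n_g = c.get("T", 0), c.get("C", 0)
        out[(site.chrom, site.pos)] = (n_a, n_g, sum(c.values()) - n_a - n_g)
    return out
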