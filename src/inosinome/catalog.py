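"""Known A-to-I editing-site catalogs.

A catalog is a nonredundant, sorted collection of genomic positions at which
A-to-I editing has been reported (REDIportal/RADAR-style). Each site carries
the annotated strand (the edited adenosine is always on that strand), a repeat
classification (Alu, other repeat, nonrepetitive) and an optional recoding
annotation (gene and amino-acid change).

Internal coordinates are 1-based inclusive, matching GTF conventions; BED
input/output converts at the boundary. Files may be gzip-compressed.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)

ALU = "ALU"
NONREP = "NONREP"
OTHER_REP = "OTHER_REP"
REPEAT_CLASSES = (ALU, NONREP, OTHER_REP)

#: Recoding sites inside repeats are normally excluded from the recoding
#: panel; genes listed here are retained anyway (the NARF exon-8 site sits in
#: an Alu yet is a validated recoding event).
DEFAULT_RECODING_WHITELIST = ("NARF",)


class CatalogError(ValueError):
    """Malformed catalog input or an unknown dialect."""


@dataclass(frozen=True, order=True)
class EditingSite:
    """One known editing position.

    ``pos`` is 1-based on the reference; ``strand`` orients the edited
    adenosine, so on '-' sites the forward reference base is T and edited
    reads show C.
    """

    chrom: str
    pos: int
    strand: str
    repeat_class: str = NONREP
    recoding: bool = False
    gene: str | None = field(default=None, compare=False)
    aa_change: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise CatalogError(f"invalid strand {self.strand!r} at {self.chrom}:{self.pos}")
        if self.repeat_class not in REPEAT_CLASSES:
            raise CatalogError(
                f"invalid repeat class {self.repeat_class!r} at {self.chrom}:{self.pos}"
            )

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.strand)


class SiteCatalog:
    """Sorted, nonredundant set of :class:`EditingSite`.

    Sites are kept sorted by (chrom, pos, strand); (chrom, pos, strand) is
    unique. Lookup by (chrom, pos) is provided for the caller, which works in
    position space.
    """

    def __init__(self, sites: Iterable[EditingSite] = ()):  # noqa: D107
        by_key: dict[tuple[str, int, str], EditingSite] = {}
        for s in sites:
            if s.key in by_key:
                raise CatalogError(f"duplicate site {s.key}")
            by_key[s.key] = s
        self._sites: list[EditingSite] = sorted(by_key.values())
        self._by_pos: dict[tuple[str, int], list[EditingSite]] = {}
        for s in self._sites:
            self._by_pos.setdefault((s.chrom, s.pos), []).append(s)

    def __len__(self) -> int:
        return len(self._sites)

    def __iter__(self) -> Iterator[EditingSite]:
        return iter(self._sites)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SiteCatalog):
            return NotImplemented
        return self._sites == list(other._sites) and all(
            (a.gene, a.aa_change) == (b.gene, b.aa_change)
            for a, b in zip(self._sites, other._sites)
        )

    def __contains__(self, key: tuple[str, int, str]) -> bool:
        return any(s.key == key for s in self._by_pos.get(key[:2], ()))

    def at(self, chrom: str, pos: int) -> list[EditingSite]:
        """Sites annotated at a (chrom, pos); at most one per strand."""
        return list(self._by_pos.get((chrom, pos), ()))

    @property
    def chroms(self) -> list[str]:
        return sorted({s.chrom for s in self._sites})

    def sites_on(self, chrom: str) -> list[EditingSite]:
        return [s for s in self._sites if s.chrom == chrom]

    def subset(self, predicate) -> "SiteCatalog":
        return SiteCatalog(s for s in self._sites if predicate(s))


# ---------------------------------------------------------------------------
# I/O

_TSV_COLUMNS = ("chrom", "pos", "strand", "repeat_class", "recoding", "gene", "aa_change")
_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _parse_bool(tok: str) -> bool:
    return tok.strip().lower() in ("1", "true", "yes", "y")


def load_catalog(path: str | Path, dialect: str) -> SiteCatalog:
    """Load a site catalog from ``path``.

    Dialects: ``bed`` (BED6, 0-based half-open starts), ``gtf`` (1-based,
    attributes ``type``/``recoding``/``gene``/``aa_change``/``ref``), ``tsv``
    (the package's 1-based 6/7-column table). Malformed lines and sites whose
    declared reference base is not A on the annotated strand are rejected and
    counted; the counts are logged.
    """
    if dialect not in ("bed", "gtf", "tsv"):
        raise CatalogError(f"unknown catalog dialect {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    sites: list[EditingSite] = []
    n_malformed = 0
    n_bad_ref = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if dialect == "tsv" and lineno == 1 and line.split("\t")[0] == "chrom":
                continue  # header row
            try:
                site = _parse_line(line, dialect)
            except _BadRefBase:
                n_bad_ref += 1
                logger.warning("%s:%d: reference base is not A on annotated strand", path, lineno)
                continue
            except Exception:
                n_malformed += 1
                logger.warning("%s:%d: malformed %s line: %r", path, lineno, dialect, line)
                continue
            sites.append(site)
    if n_malformed or n_bad_ref:
        logger.info(
            "%s: rejected %d malformed line(s), %d non-A reference site(s)",
            path, n_malformed, n_bad_ref,
        )
    # last-one-wins on duplicate keys within a single file
    dedup: dict[tuple[str, int, str], EditingSite] = {s.key: s for s in sites}
    return SiteCatalog(dedup.values())


class _BadRefBase(Exception):
    pass


def _check_ref(ref: str | None, strand: str) -> None:
    """Reference base, when declared, must be the edited adenosine: A on '+',
    T on the forward reference for '-' sites."""
    if ref is None:
        return
    expected = "A" if strand == "+" else "T"
    if ref.upper() != expected:
        raise _BadRefBase(ref)


def _parse_line(line: str, dialect: str) -> EditingSite:
    fields = line.split("\t")
    if dialect == "bed":
        chrom, start, _end = fields[0], int(fields[1]), int(fields[2])
        name = fields[3] if len(fields) > 3 and fields[3] != "." else None
        strand = fields[5] if len(fields) > 5 else "+"
        return EditingSite(chrom, start + 1, strand, gene=name)
    if dialect == "gtf":
        chrom, _src, _feat, start, end, _score, strand, _frame = fields[:8]
        if int(start) != int(end):
            raise CatalogError("editing site spans more than one base")
        attrs = dict(_GTF_ATTR.findall(fields[8])) if len(fields) > 8 else {}
        _check_ref(attrs.get("ref"), strand)
        rc = attrs.get("type", NONREP).upper()
        rc = rc if rc in REPEAT_CLASSES else (ALU if rc.startswith("ALU") else OTHER_REP)
        return EditingSite(
            chrom, int(start), strand,
            repeat_class=rc,
            recoding=_parse_bool(attrs.get("recoding", "")),
            gene=attrs.get("gene") or None,
            aa_change=attrs.get("aa_change") or None,
        )
    # tsv
    chrom, pos, strand, rc, rec = fields[:5]
    gene = fields[5] if len(fields) > 5 and fields[5] not in (".", "") else None
    aa = fields[6] if len(fields) > 6 and fields[6] not in (".", "") else None
    ref = fields[7] if len(fields) > 7 and fields[7] not in (".", "") else None
    _check_ref(ref, strand)
    return EditingSite(chrom, int(pos), strand, rc.upper(), _parse_bool(rec), gene, aa)


def write_catalog(cat: SiteCatalog, path: str | Path) -> None:
    """Write the sorted 7-column TSV dialect (round-trips losslessly)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for s in cat:
            fh.write(
                "\t".join(
                    (
                        s.chrom,
                        str(s.pos),
                        s.strand,
                        s.repeat_class,
                        "1" if s.recoding else "0",
                        s.gene or ".",
                        s.aa_change or ".",
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Set operations


def merge_catalogs(a: SiteCatalog, b: SiteCatalog, precedence: str = "a") -> SiteCatalog:
    """Nonredundant union of two catalogs.

    Where both annotate the same (chrom, pos) — including with conflicting
    strands — the ``precedence`` catalog's record wins; conflicts are counted
    and logged.
    """
    if precedence not in ("a", "b"):
        raise CatalogError(f"precedence must be 'a' or 'b', got {precedence!r}")
    primary, secondary = (a, b) if precedence == "a" else (b, a)
    merged: dict[tuple[str, int, str], tuple[str, EditingSite]] = {}
    n_conflicts = 0
    for s in secondary:
        merged[s.key] = ("secondary", s)
    for s in primary:
        prev = merged.get(s.key)
        if prev is not None and (
            prev[1].repeat_class != s.repeat_class
            or prev[1].recoding != s.recoding
            or prev[1].gene != s.gene
            or prev[1].aa_change != s.aa_change
        ):
            n_conflicts += 1
        merged[s.key] = ("primary", s)
    # strand conflicts: same position annotated on different strands by the
    # two catalogs — the precedence catalog's record(s) win
    by_pos: dict[tuple[str, int], set[str]] = {}
    for (chrom, pos, _strand), (origin, _s) in merged.items():
        by_pos.setdefault((chrom, pos), set()).add(origin)
    for (chrom, pos), origins in by_pos.items():
        strands = [k for k in merged if k[:2] == (chrom, pos)]
        if len(strands) > 1 and origins == {"primary", "secondary"}:
            n_conflicts += 1
            for k in strands:
                if merged[k][0] == "secondary":
                    del merged[k]
    merged_sites = {k: s for k, (_origin, s) in merged.items()}
    if n_conflicts:
        logger.info("merge: %d annotation conflict(s) resolved by precedence=%s",
                    n_conflicts, precedence)
    return SiteCatalog(merged_sites.values())


def subset_recoding(
    cat: SiteCatalog,
    whitelist: Iterable[str] = DEFAULT_RECODING_WHITELIST,
) -> SiteCatalog:
    """Recoding-site panel: recoding sites in nonrepetitive regions, plus
    repeat-resident recoding sites whose gene is explicitly whitelisted."""
    wl = set(whitelist)
    return cat.subset(
        lambda s: s.recoding and (s.repeat_class == NONREP or (s.gene in wl))
    )


def load_recoding_panel(path: str | Path) -> SiteCatalog:
    """Parse a recoding panel laid out as (chrom, pos, strand, gene,
    aa_change) — the supplementary-table layout — into a catalog of
    recoding sites."""
    path = Path(path)
    sites = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if lineno == 1 and f[0].lower() in ("chrom", "chromosome", "chr"):
                continue
            sites.append(
                EditingSite(
                    f[0], int(f[1]), f[2],
                    repeat_class=NONREP, recoding=True,
                    gene=f[3] if len(f) > 3 else None,
                    aa_change=f[4] if len(f) > 4 else None,
                )
            )
    return SiteCatalog(sites)
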