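import numpy as np
import pytest

from inosinome.catalog import EditingSite, SiteCatalog
from inosinome.simdata import SimConfig, simulate_cohort

CHROM_LEN = 100_000


def sam_text(reads, chrom="chr1", chrom_len=CHROM_LEN):
    """Build SAM text from (name, flag, pos1, mapq, cigar, seq, quals) tuples;
    quals is a list of phred ints or a single int applied to every base."""
    lines = [f"@HD\tVN:1.6\tSO:coordinate", f"@SQ\tSN:{chrom}\tLN:{chrom_len}"]
    for name, flag, pos1, mapq, cigar, seq, quals in sorted(reads, key=lambda r: r[2]):
        if isinstance(quals, int):
            quals = [quals] * len(seq)
        qual = "".join(chr(q + 33) for q in quals)
        lines.append(
            f"{name}\t{flag}\t{chrom}\t{pos1}\t{mapq}\t{cigar}\t*\t0\t0\t{seq}\t{qual}"
        )
    return "\n".join(lines) + "\n"


@pytest.fixture
def write_sam(tmp_path):
    def _write(reads, filename="cell.sam", **kw):
        path = tmp_path / filename
        path.write_text(sam_text(reads, **kw))
        return path

    return _write


def plus_site(pos, **kw):
    return EditingSite("chr1", pos, "+", **kw)


def minus_site(pos, **kw):
    return EditingSite("chr1", pos, "-", **kw)


def site_reads(site, n_unedited, n_edited, start=None, mapq=255, bq=37, flag=0,
               name_prefix="r"):
    """Reads of length 11 with the site at offset 5, carrying the unedited or
    edited base in forward-reference space."""
    pos1 = (start if start is not None else site.pos - 5)
    off = site.pos - pos1
    # background bases count as "other" if they ever hit a site of this strand
    un, ed, bg = ("A", "G", "T") if site.strand == "+" else ("T", "C", "G")
    reads = []
    for k in range(n_unedited + n_edited):
        base = un if k < n_unedited else ed
        seq = bg * off + base + bg * (10 - off)
        reads.append((f"{name_prefix}{site.pos}_{k}", flag, pos1, mapq, "11M", seq, bq))
    return reads


@pytest.fixture(scope="session")
def uniform_cohort(tmp_path_factory):
    """Single-type all-or-nothing cohort: 6 cells, 80 sites, on-probability
    0.15, depth 25, 10% duplicates."""
    out = tmp_path_factory.mktemp("uniform_cohort")
    cfg = SimConfig(
        cell_types=("cell",),
        signature_alias={},
        n_cells_per_type=6,
        n_sites=80,
        p_edited_by_type=0.15,
        type_signature_overlap=1.0,
        depth_mean=25,
        seed=11,
    )
    return simulate_cohort(cfg, out)


@pytest.fixture(scope="session")
def two_type_cohort(tmp_path_factory):
    """Two types with disjoint signatures, for separation/end-to-end tests."""
    out = tmp_path_factory.mktemp("two_type_cohort")
    cfg = SimConfig(
        cell_types=("neuron", "astrocyte"),
        signature_alias={},
        n_cells_per_type=8,
        n_sites=120,
        p_edited_by_type=0.8,
        type_signature_overlap=0.0,
        depth_mean=20,
        seed=5,
    )
    return simulate_cohort(cfg, out)


@pytest.fixture(scope="session")
def called_uniform(uniform_cohort):
    from inosinome.calls import call_cell

    return [call_cell(p, uniform_cohort.catalog) for p in uniform_cohort.sam_paths.values()]


@pytest.fixture(scope="session")
def called_two_type(two_type_cohort):
    from inosinome.calls import call_cell

    return [call_cell(p, two_type_cohort.catalog) for p in two_type_cohort.sam_paths.values()]


def random_catalog(rng, n, chrom="chr1"):
    """Random catalog; strand fixed by position parity so two catalogs drawn
    from the same position space never collide across strands."""
    positions = rng.choice(np.arange(1, 5000), size=n, replace=False)
    sites = [
        EditingSite(
            chrom, int(p), "+" if p % 2 else "-",
            repeat_class=["ALU", "NONREP", "OTHER_REP"][int(p) % 3],
            recoding=bool(p % 5 == 0),
            gene=f"G{p}" if p % 5 == 0 else None,
        )
        for p in positions
    ]
    return SiteCatalog(sites)
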