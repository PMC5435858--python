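import gzip

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from inosinome.catalog import (ALU, NONREP, OTHER_REP, CatalogError, EditingSite,
                               SiteCatalog, load_catalog, load_recoding_panel,
                               merge_catalogs, subset_recoding, write_catalog)
from tests.conftest import random_catalog


def test_gtf_line_maps_to_site(tmp_path):
    p = tmp_path / "c.gtf"
    p.write_text('chr1\tradar\ted\t1000\t1000\t.\t+\t.\ttype "ALU"\n')
    cat = load_catalog(p, "gtf")
    (site,) = list(cat)
    assert site == EditingSite("chr1", 1000, "+", repeat_class=ALU)


def test_bed_zero_based_start_converts(tmp_path):
    p = tmp_path / "c.bed"
    p.write_text("chr1\t999\t1000\tsite1\t0\t-\n")
    (site,) = list(load_catalog(p, "bed"))
    assert (site.chrom, site.pos, site.strand) == ("chr1", 1000, "-")


def test_tsv_round_trip_is_byte_identical(tmp_path):
    cat = random_catalog(np.random.default_rng(0), 50)
    p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    write_catalog(cat, p1)
    reloaded = load_catalog(p1, "tsv")
    assert reloaded == cat
    write_catalog(reloaded, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_gzip_transparent(tmp_path):
    p = tmp_path / "c.tsv.gz"
    with gzip.open(p, "wt") as fh:
        fh.write("chr2\t42\t+\tALU\t0\t.\t.\n")
    (site,) = list(load_catalog(p, "tsv"))
    assert (site.chrom, site.pos, site.repeat_class) == ("chr2", 42, ALU)


def test_malformed_lines_skipped_not_fatal(tmp_path):
    p = tmp_path / "c.tsv"
    p.write_text("chr1\t10\t+\tALU\t0\n" "garbage line\n" "chr1\tNaN\t+\tALU\t0\n")
    cat = load_catalog(p, "tsv")
    assert len(cat) == 1


def test_non_adenosine_reference_rejected(tmp_path):
    # declared ref base must be the edited adenosine: A on '+', T forward on '-'
    p = tmp_path / "c.tsv"
    p.write_text(
        "chr1\t10\t+\tALU\t0\t.\t.\tA\n"
        "chr1\t20\t+\tALU\t0\t.\t.\tG\n"
        "chr1\t30\t-\tALU\t0\t.\t.\tT\n"
        "chr1\t40\t-\tALU\t0\t.\t.\tA\n"
    )
    cat = load_catalog(p, "tsv")
    assert sorted(s.pos for s in cat) == [10, 30]


def test_unknown_dialect_is_config_error(tmp_path):
    p = tmp_path / "c.txt"
    p.write_text("")
    with pytest.raises(CatalogError):
        load_catalog(p, "vcf")


def test_merge_union_and_identity():
    s1, s2, s3 = (EditingSite("chr1", p, "+") for p in (10, 20, 30))
    a, b = SiteCatalog([s1, s2]), SiteCatalog([s2, s3])
    merged = merge_catalogs(a, b)
    assert {s.key for s in merged} == {s1.key, s2.key, s3.key}
    assert merge_catalogs(SiteCatalog([]), b) == b


def test_merge_three_plus_two_sharing_one_position(tmp_path):
    a = SiteCatalog([EditingSite("chr1", p, "+") for p in (1, 2, 3)])
    b = SiteCatalog([EditingSite("chr1", p, "+") for p in (3, 4)])
    assert len(merge_catalogs(a, b)) == 4


def test_merge_precedence_on_annotation_conflict():
    a = SiteCatalog([EditingSite("chr1", 10, "+", repeat_class=ALU)])
    b = SiteCatalog([EditingSite("chr1", 10, "+", repeat_class=NONREP)])
    assert next(iter(merge_catalogs(a, b, "a"))).repeat_class == ALU
    assert next(iter(merge_catalogs(a, b, "b"))).repeat_class == NONREP


def test_merge_strand_conflict_resolved_by_precedence():
    a = SiteCatalog([EditingSite("chr1", 10, "+")])
    b = SiteCatalog([EditingSite("chr1", 10, "-")])
    assert [s.strand for s in merge_catalogs(a, b, "a")] == ["+"]
    assert [s.strand for s in merge_catalogs(a, b, "b")] == ["-"]


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed_a=st.integers(0, 1000), seed_b=st.integers(0, 1000),
       n_a=st.integers(0, 60), n_b=st.integers(0, 60))
def test_merge_cardinality_matches_set_union_oracle(seed_a, seed_b, n_a, n_b):
    """|merge(a,b)| == |a| + |b| - |a n b| against a brute-force tuple-set
    oracle (strand is a function of position, so no cross-strand clashes)."""
    a = random_catalog(np.random.default_rng(seed_a), n_a)
    b = random_catalog(np.random.default_rng(seed_b), n_b)
    oracle = {s.key for s in a} | {s.key for s in b}
    merged = merge_catalogs(a, b)
    assert len(merged) == len(oracle)
    assert {s.key for s in merged} == oracle


def test_merge_idempotent():
    x = random_catalog(np.random.default_rng(3), 40)
    assert merge_catalogs(x, x) == x


def test_merge_both_ways_same_positions_with_overlap():
    rng = np.random.default_rng(9)
    a = random_catalog(rng, 100)
    b_sites = list(a)[:10] + list(random_catalog(np.random.default_rng(10), 90))
    b = SiteCatalog({s.key: s for s in b_sites}.values())
    ab, ba = merge_catalogs(a, b, "a"), merge_catalogs(b, a, "a")
    assert {s.key for s in ab} == {s.key for s in ba}


def test_subset_recoding_rules():
    sites = [
        EditingSite("chr1", 10, "+", NONREP, recoding=True, gene="GRIA2"),
        EditingSite("chr1", 20, "+", NONREP, recoding=True, gene="CYFIP2"),
        EditingSite("chr1", 30, "+", ALU, recoding=True, gene="SOMEGENE"),
        EditingSite("chr1", 40, "+", ALU, recoding=True, gene="NARF"),
        EditingSite("chr1", 50, "+", ALU, recoding=False),
    ]
    panel = subset_recoding(SiteCatalog(sites))
    genes = {s.gene for s in panel}
    # repeat-resident recoding sites are excluded unless whitelisted (NARF)
    assert genes == {"GRIA2", "CYFIP2", "NARF"}


def test_subset_recoding_counts():
    sites = [
        EditingSite("chr1", 10, "+", NONREP, recoding=True),
        EditingSite("chr1", 20, "+", NONREP, recoding=True),
        EditingSite("chr1", 30, "+", ALU),
        EditingSite("chr1", 40, "+", NONREP),
        EditingSite("chr1", 50, "+", OTHER_REP),
    ]
    assert len(subset_recoding(SiteCatalog(sites))) == 2


def test_recoding_panel_supplementary_layout(tmp_path):
    from inosinome.simdata import synthetic_recoding_panel

    p = tmp_path / "panel.tsv"
    synthetic_recoding_panel(p, n_sites=183, seed=2)
    panel = load_recoding_panel(p)
    assert len(panel) == 183
    assert all(s.recoding for s in panel)
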