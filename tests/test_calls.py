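import itertools

import numpy as np
import pandas as pd
import pytest

from inosinome.calls import (CellProfile, FilterParams, SiteCall, call_cell,
                             profiles_to_matrix, read_level_matrix,
                             write_level_matrix)
from inosinome.catalog import EditingSite, SiteCatalog
from inosinome.simdata import SimConfig, simulate_cohort
from inosinome.validation import scan_counts
from tests.conftest import minus_site, plus_site, site_reads


def test_plus_strand_counts_and_level(write_sam):
    site = plus_site(500)
    sam = write_sam(site_reads(site, n_unedited=7, n_edited=3))
    prof = call_cell(sam, SiteCatalog([site]), FilterParams())
    call = prof.calls[("chr1", 500)]
    assert (call.coverage, call.n_A, call.n_G) == (10, 7, 3)
    assert call.level == pytest.approx(0.3)


def test_minus_strand_complement(write_sam):
    # forward-reference pileup T x8, C x2 at a '-' site is A x8, G x2 in
    # strand space
    site = minus_site(500)
    sam = write_sam(site_reads(site, n_unedited=8, n_edited=2))
    call = call_cell(sam, SiteCatalog([site])).calls[("chr1", 500)]
    assert (call.n_A, call.n_G) == (8, 2)
    assert call.level == pytest.approx(0.2)


def test_coverage_floor_excludes_nine_reads(write_sam):
    site = plus_site(500)
    sam = write_sam(site_reads(site, n_unedited=6, n_edited=3))
    prof = call_cell(sam, SiteCatalog([site]), FilterParams(min_coverage=10))
    assert ("chr1", 500) not in prof.calls
    prof9 = call_cell(sam, SiteCatalog([site]), FilterParams(min_coverage=9))
    assert prof9.calls[("chr1", 500)].coverage == 9


def test_zero_edited_site_retained_with_level_zero(write_sam):
    site = plus_site(500)
    sam = write_sam(site_reads(site, n_unedited=12, n_edited=0))
    call = call_cell(sam, SiteCatalog([site])).calls[("chr1", 500)]
    assert call.level == 0.0


def test_other_bases_count_coverage_not_denominator(write_sam):
    site = plus_site(500)
    reads = site_reads(site, 8, 2)
    # two reads carrying C at the site: coverage yes, denominator no
    reads += [(f"c{k}", 0, 495, 255, "11M", "TTTTTCTTTTT", 37) for k in range(2)]
    call = call_cell(write_sam(reads), SiteCatalog([site])).calls[("chr1", 500)]
    assert (call.coverage, call.n_A, call.n_G, call.n_other) == (12, 8, 2, 2)
    assert call.level == pytest.approx(0.2)


def test_quality_and_mapq_filters(write_sam):
    site = plus_site(500)
    reads = (
        site_reads(site, 8, 2, bq=37, name_prefix="hi")
        + site_reads(site, 0, 4, bq=20, name_prefix="lowq")      # fails q30
        + site_reads(site, 0, 4, mapq=10, name_prefix="lowmq")   # fails m20
    )
    call = call_cell(write_sam(reads), SiteCatalog([site])).calls[("chr1", 500)]
    assert (call.n_A, call.n_G) == (8, 2)


def test_deletion_and_refskip_span_contribute_nothing(write_sam):
    site = plus_site(500)
    reads = site_reads(site, 8, 2)
    # 5-base deletion and an N-skip spanning the site
    reads += [("del1", 0, 493, 255, "5M5D6M", "TTTTTTTTTTT", 37),
              ("skip1", 0, 493, 255, "5M10N6M", "TTTTTTTTTTT", 37)]
    call = call_cell(write_sam(reads), SiteCatalog([site])).calls[("chr1", 500)]
    assert call.coverage == 10


def test_duplicate_reads_toggle(write_sam):
    site = plus_site(500)
    reads = site_reads(site, 8, 2)
    reads += [(f"d{k}", 0x400, 495, 255, "11M", "TTTTTGTTTTT", 37) for k in range(5)]
    cat = SiteCatalog([site])
    raw = call_cell(write_sam(reads), cat, FilterParams(exclude_duplicates=False))
    dedup = call_cell(write_sam(reads), cat, FilterParams(exclude_duplicates=True))
    assert raw.calls[("chr1", 500)].n_G == 7
    assert dedup.calls[("chr1", 500)].n_G == 2


def test_missing_chromosome_skipped_with_profile_intact(write_sam):
    s1, s2 = plus_site(500), EditingSite("chrMissing", 100, "+")
    sam = write_sam(site_reads(s1, 10, 0))
    prof = call_cell(sam, SiteCatalog([s1, s2]))
    assert list(prof.calls) == [("chr1", 500)]


# ---------------------------------------------------------------------------
# oracle equivalence


def _oracle_profile(sam_path, cat, params):
    """Assemble SiteCalls from the independent per-read scanner, applying the
    same retention rules as the caller."""
    counts = scan_counts(sam_path, cat, params)
    calls = {}
    for site in cat:
        key = (site.chrom, site.pos)
        if key not in counts:
            continue
        n_a, n_g, n_other = counts[key]
        call = SiteCall(site, n_a, n_g, n_other)
        if call.coverage < params.min_coverage or n_g < params.min_variant_reads:
            continue
        if params.min_variant_freq > 0 and (call.level is None or call.level < params.min_variant_freq):
            continue
        calls[key] = call
    return calls


_PARAM_GRID = [
    FilterParams(min_base_quality=bq, min_mapping_quality=mq,
                 min_coverage=cov, exclude_duplicates=dup)
    for bq, mq, cov, dup in itertools.product((0, 30), (0, 20), (1, 10), (False, True))
]


@pytest.fixture(scope="module")
def oracle_sams(tmp_path_factory):
    """Simulated SAM fixtures spanning strands, duplicates and low-quality
    reads; small enough for exhaustive per-read checking."""
    out = tmp_path_factory.mktemp("oracle_sams")
    configs = [
        SimConfig(cell_types=("c",), signature_alias={}, n_cells_per_type=4,
                  n_sites=30, p_edited_by_type=0.3, type_signature_overlap=1.0,
                  depth_mean=15, dup_rate=0.15, low_mapq_fraction=0.2,
                  low_bq_fraction=0.2, seq_error_rate=0.01, seed=101),
        SimConfig(cell_types=("c",), signature_alias={}, n_cells_per_type=4,
                  n_sites=25, p_edited_by_type=0.9, type_signature_overlap=1.0,
                  depth_mean=8, dup_rate=0.0, low_mapq_fraction=0.0,
                  low_bq_fraction=0.5, seed=102),
    ]
    fixtures = []
    for i, cfg in enumerate(configs):
        sim = simulate_cohort(cfg, out / f"sim{i}")
        for path in sim.sam_paths.values():
            fixtures.append((path, sim.catalog))
    return fixtures


def test_caller_matches_per_read_oracle_exactly(oracle_sams):
    """Pileup counts equal the independent per-read SAM-text scan for every
    site under every filter combination."""
    assert len(oracle_sams) >= 8
    for sam_path, cat in oracle_sams:
        for params in _PARAM_GRID:
            got = call_cell(sam_path, cat, params).calls
            expected = _oracle_profile(sam_path, cat, params)
            assert set(got) == set(expected), (sam_path, params)
            for key, call in got.items():
                exp = expected[key]
                assert (call.n_A, call.n_G, call.n_other) == (
                    exp.n_A, exp.n_G, exp.n_other), (sam_path, key, params)


def test_quality_thresholds_monotone_in_coverage(oracle_sams):
    sam_path, cat = oracle_sams[0]
    base = call_cell(sam_path, cat, FilterParams(min_coverage=1))
    for params in (FilterParams(min_base_quality=40, min_coverage=1),
                   FilterParams(min_mapping_quality=30, min_coverage=1)):
        strict = call_cell(sam_path, cat, params)
        for key, call in strict.calls.items():
            assert call.coverage <= base.calls[key].coverage


# ---------------------------------------------------------------------------
# level matrix


def _profile(cell_id, entries, params=FilterParams()):
    prof = CellProfile(cell_id=cell_id, params=params)
    for pos, (n_a, n_g) in entries.items():
        site = plus_site(pos)
        prof.calls[("chr1", pos)] = SiteCall(site, n_a, n_g, 0)
    return prof


def test_matrix_distinguishes_zero_from_missing():
    cat = SiteCatalog([plus_site(10), plus_site(20)])
    p1 = _profile("c1", {10: (10, 0)})           # covered, level 0
    p2 = _profile("c2", {20: (5, 5)})            # disjoint coverage
    m = profiles_to_matrix([p1, p2], cat)
    assert m.loc["c1", "chr1:10"] == 0.0
    assert np.isnan(m.loc["c1", "chr1:20"])
    assert m.loc["c2", "chr1:20"] == 0.5
    assert np.isnan(m.loc["c2", "chr1:10"])


def test_matrix_duplicate_cell_id_rejected():
    cat = SiteCatalog([plus_site(10)])
    with pytest.raises(ValueError):
        profiles_to_matrix([_profile("c", {10: (9, 1)}), _profile("c", {})], cat)


def test_matrix_round_trips_losslessly(tmp_path):
    rng = np.random.default_rng(4)
    cat = SiteCatalog([plus_site(int(p)) for p in range(10, 210, 10)])
    profiles = []
    for i in range(6):
        entries = {int(p): (int(rng.integers(0, 20)), int(rng.integers(1, 20)))
                   for p in rng.choice(range(10, 210, 10), size=12, replace=False)}
        profiles.append(_profile(f"c{i}", entries))
    m = profiles_to_matrix(profiles, cat)
    write_level_matrix(m, tmp_path / "lv")
    back = read_level_matrix(tmp_path / "lv")
    pd.testing.assert_frame_equal(m, back)
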