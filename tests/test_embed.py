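import numpy as np
import pandas as pd
import pytest
from scipy.spatial import procrustes

from inosinome.calls import profiles_to_matrix
from inosinome.embed import (DissimilarityMatrix, cluster_recovery, nmds,
                             spearman_dissimilarity, type_centroids)


def _dmat(d, ids=None):
    n = d.shape[0]
    ids = ids or [f"c{i}" for i in range(n)]
    return DissimilarityMatrix(ids, d, np.full((n, n), 50), np.zeros((n, n), bool))


def _rank_oracle(x, y):
    """Spearman rho from first principles (average ranks, Pearson on ranks)."""
    def ranks(v):
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r[order[i:j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return r
    rx, ry = ranks(np.asarray(x)), ranks(np.asarray(y))
    rx -= rx.mean(); ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def test_identical_profiles_have_zero_dissimilarity():
    row = np.linspace(0.1, 0.9, 12)
    m = pd.DataFrame([row, row], index=["a", "b"])
    d = spearman_dissimilarity(m, min_shared=5)
    assert d.d[0, 1] == pytest.approx(0.0)


def test_reversed_rank_order_gives_two():
    m = pd.DataFrame([[0.1, 0.2, 0.3, 0.4, 0.5],
                      [0.5, 0.4, 0.3, 0.2, 0.1]], index=["a", "b"])
    d = spearman_dissimilarity(m, min_shared=5)
    assert d.d[0, 1] == pytest.approx(2.0)


def test_pairwise_rho_matches_rank_oracle():
    rng = np.random.default_rng(17)
    x = rng.uniform(size=(6, 20))
    x[rng.uniform(size=x.shape) < 0.2] = np.nan  # pairwise-complete path
    m = pd.DataFrame(x, index=[f"c{i}" for i in range(6)])
    d = spearman_dissimilarity(m, min_shared=3)
    for i in range(6):
        for j in range(i + 1, 6):
            mask = ~np.isnan(x[i]) & ~np.isnan(x[j])
            if mask.sum() >= 3:
                rho = _rank_oracle(x[i, mask], x[j, mask])
                assert d.d[i, j] == pytest.approx(1 - rho, abs=1e-12)


def test_dissimilarity_invariant_under_monotone_transform():
    rng = np.random.default_rng(3)
    x = rng.uniform(size=(5, 30))
    m1 = pd.DataFrame(x, index=list("abcde"))
    m2 = pd.DataFrame(x**3, index=list("abcde"))  # strictly monotone on [0,1]
    d1 = spearman_dissimilarity(m1, min_shared=5)
    d2 = spearman_dissimilarity(m2, min_shared=5)
    np.testing.assert_allclose(d1.d, d2.d, atol=1e-12)


def test_sparse_pairs_imputed_and_flagged():
    rng = np.random.default_rng(6)
    x = np.full((4, 12), np.nan)
    x[0, :6] = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]
    x[1, :6] = [0.6, 0.5, 0.4, 0.3, 0.2, 0.1]
    x[2, :2] = [0.1, 0.2]          # only 2 sites shared with c0/c1
    x[2, 6:] = rng.uniform(size=6)  # but enough shared with c3
    x[3, :] = rng.uniform(size=12)
    m = pd.DataFrame(x, index=["c0", "c1", "c2", "c3"])
    d = spearman_dissimilarity(m, min_shared=5)
    assert d.imputed[0, 2] and d.imputed[1, 2]
    assert not d.imputed[0, 1] and not d.imputed[2, 3]
    assert d.d[0, 2] == pytest.approx(2.0)  # max observed (c0 vs c1) fills in


def test_cell_sharing_too_few_sites_with_all_is_dropped():
    x = np.full((3, 12), np.nan)
    x[0, :8] = np.linspace(0.1, 0.8, 8)
    x[1, :8] = np.linspace(0.8, 0.1, 8)
    x[2, 8:] = [0.1, 0.4, 0.2, 0.9]
    m = pd.DataFrame(x, index=["c0", "c1", "lonely"])
    d = spearman_dissimilarity(m, min_shared=5)
    assert d.cell_ids == ["c0", "c1"]


# ---------------------------------------------------------------------------
# NMDS


def test_three_equidistant_cells_embed_as_equilateral_triangle():
    d = np.full((3, 3), 0.7)
    np.fill_diagonal(d, 0.0)
    emb = nmds(_dmat(d), seed=0)
    assert emb.stress < 0.01
    coords = emb.coords
    dist = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
    iu = np.triu_indices(3, 1)
    assert dist[iu].max() / dist[iu].min() < 1.05
    np.testing.assert_allclose(coords.mean(axis=0), 0.0, atol=1e-9)


def test_planar_configuration_recovered():
    rng = np.random.default_rng(5)
    pts = rng.normal(size=(30, 2))
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    emb = nmds(_dmat(d), n_starts=20, max_iter=2000, tol=1e-12, seed=1)
    assert emb.stress < 0.01
    m1, m2, _ = procrustes(pts, emb.coords)
    rmsd = np.sqrt(((m1 - m2) ** 2).sum(axis=1).mean())
    assert rmsd < 1e-3


def test_embedding_reproducible_bit_for_bit():
    rng = np.random.default_rng(2)
    pts = rng.normal(size=(12, 2))
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    e1 = nmds(_dmat(d), seed=42)
    e2 = nmds(_dmat(d), seed=42)
    assert (e1.coords == e2.coords).all() and e1.stress == e2.stress


def test_too_few_cells_rejected():
    with pytest.raises(ValueError):
        nmds(_dmat(np.zeros((2, 2))))


# ---------------------------------------------------------------------------
# cluster recovery


def _blob_embedding(rng, centers, n_per, spread=0.05):
    coords, ids, labels = [], [], {}
    for t, c in centers.items():
        for i in range(n_per):
            coords.append(np.asarray(c) + rng.normal(scale=spread, size=2))
            cid = f"{t}{i}"
            ids.append(cid)
            labels[cid] = t
    from inosinome.embed import Embedding
    arr = np.array(coords)
    return Embedding(ids, arr - arr.mean(0), 0.01, 10, True, 0), labels


def test_separated_blobs_recover_perfectly():
    rng = np.random.default_rng(0)
    emb, labels = _blob_embedding(rng, {"a": (0, 0), "b": (3, 0), "c": (0, 3)}, 10)
    ari, sil = cluster_recovery(emb, labels)
    assert ari == 1.0
    assert sil > 0.8


def test_permuted_labels_score_near_zero():
    rng = np.random.default_rng(1)
    emb, labels = _blob_embedding(rng, {"a": (0, 0), "b": (3, 0)}, 20)
    cells = list(labels)
    shuffled = rng.permutation([labels[c] for c in cells])
    permuted = dict(zip(cells, shuffled))
    ari, _ = cluster_recovery(emb, permuted)
    assert abs(ari) < 0.1


def test_end_to_end_two_types_separate(two_type_cohort, called_two_type):
    """Disjoint editing signatures drive the full dissimilarity -> NMDS ->
    k-means route to perfect type recovery."""
    matrix = profiles_to_matrix(called_two_type, two_type_cohort.catalog)
    d = spearman_dissimilarity(matrix)
    emb = nmds(d, seed=0)
    ari, _ = cluster_recovery(emb, two_type_cohort.truth.cell_types, seed=0)
    assert emb.stress < 0.15
    assert ari >= 0.9
    cents = type_centroids(emb, two_type_cohort.truth.cell_types)
    assert set(cents.index) == {"neuron", "astrocyte"}
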