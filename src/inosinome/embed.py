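"""Editing-profile similarity structure: Spearman dissimilarity and NMDS.

Cells are compared by the Spearman rank correlation of their editing levels
over the sites covered (at the coverage floor) in *both* cells
(pairwise-complete). Dissimilarity is d = 1 - rho, embedded in two dimensions
by nonmetric multidimensional scaling (rank-preserving, Kruskal stress-1),
the same analysis style as vegan's metaMDS on a correlation-derived matrix.
Cluster recovery on simulations is scored with k-means + adjusted Rand index,
which turns the visual cluster claim into an assertable number.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import KMeans
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import MDS
from sklearn.metrics import adjusted_rand_score, silhouette_score

logger = logging.getLogger(__name__)


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise dissimilarities d = 1 - Spearman rho.

    ``n_shared`` counts the sites used per pair; pairs with fewer than
    ``min_shared`` sites (or an undefined rho) are imputed with the maximum
    observed dissimilarity and flagged in ``imputed``.
    """

    cell_ids: list[str]
    d: np.ndarray
    n_shared: np.ndarray
    imputed: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.cell_ids, columns=self.cell_ids)


def spearman_dissimilarity(
    matrix: pd.DataFrame, min_shared: int = 10
) -> DissimilarityMatrix:
    """Pairwise-complete Spearman dissimilarity over a cells x sites level
    matrix (NaN = site not covered in that cell).

    Ties get average ranks (standard Spearman). A cell sharing fewer than
    ``min_shared`` sites with every other cell is dropped with a warning.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 cells")
    ids = list(matrix.index)
    x = matrix.values
    n = len(ids)
    rho = np.full((n, n), np.nan)
    n_shared = np.zeros((n, n), dtype=int)
    np.fill_diagonal(rho, 1.0)
    covered = ~np.isnan(x)
    for i in range(n):
        for j in range(i + 1, n):
            mask = covered[i] & covered[j]
            m = int(mask.sum())
            n_shared[i, j] = n_shared[j, i] = m
            if m >= 2:
                with warnings.catch_warnings():
                    # constant level vectors leave rho undefined; the NaN is
                    # handled below by imputation
                    warnings.simplefilter("ignore", sps.ConstantInputWarning)
                    r = sps.spearmanr(x[i, mask], x[j, mask]).statistic
                if not np.isnan(r):
                    rho[i, j] = rho[j, i] = r

    usable = (n_shared >= min_shared) & ~np.isnan(rho)
    np.fill_diagonal(usable, True)
    # drop cells with no usable pair at all
    keep = np.array([usable[i, np.arange(n) != i].any() for i in range(n)])
    if not keep.all():
        dropped = [ids[i] for i in np.flatnonzero(~keep)]
        logger.warning(
            "dropping %d cell(s) sharing < %d sites with all others: %s",
            len(dropped), min_shared, dropped,
        )
    idx = np.flatnonzero(keep)
    ids = [ids[i] for i in idx]
    rho = rho[np.ix_(idx, idx)]
    n_shared = n_shared[np.ix_(idx, idx)]
    usable = usable[np.ix_(idx, idx)]

    d = 1.0 - rho
    imputed = ~usable
    np.fill_diagonal(imputed, False)
    observed = d[usable & ~np.eye(len(ids), dtype=bool)]
    fill = observed.max() if observed.size else 1.0
    d[imputed] = fill
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2  # exact symmetry
    if imputed.any():
        logger.info("imputed %d pair(s) with max observed dissimilarity %.4f",
                    int(imputed.sum() // 2), fill)
    return DissimilarityMatrix(ids, d, n_shared, imputed)


@dataclass
class Embedding:
    cell_ids: list[str]
    coords: np.ndarray
    stress: float  # Kruskal stress-1
    n_iter: int
    converged: bool
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.coords, index=self.cell_ids, columns=["x", "y"])


def kruskal_stress1(d: np.ndarray, coords: np.ndarray) -> float:
    """Stress-1 of a configuration against a dissimilarity matrix: isotonic
    disparities fitted to embedded distances in rank order of d."""
    iu = np.triu_indices(d.shape[0], k=1)
    dis = d[iu]
    emb = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))[iu]
    order = np.argsort(dis, kind="stable")
    dhat = np.empty_like(emb)
    dhat[order] = IsotonicRegression().fit_transform(np.arange(order.size), emb[order])
    denom = float((emb**2).sum())
    if denom == 0:
        return 0.0
    return float(np.sqrt(((emb - dhat) ** 2).sum() / denom))


def nmds(
    dmat: DissimilarityMatrix,
    k: int = 2,
    n_starts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
) -> Embedding:
    """Nonmetric MDS by SMACOF with monotone regression, best of
    ``n_starts`` random initializations; deterministic given ``seed``.

    The reported stress is Kruskal stress-1 recomputed from the final
    configuration (the metaMDS convention), and coordinates are centered at
    the origin.
    """
    if len(dmat.cell_ids) < 3:
        raise ValueError("need at least 3 cells to embed")
    model = MDS(
        n_components=k,
        metric_mds=False,
        n_init=n_starts,
        init="random",
        max_iter=max_iter,
        eps=tol,
        metric="precomputed",
        random_state=seed,
        normalized_stress=True,
    )
    coords = model.fit_transform(dmat.d)
    coords = coords - coords.mean(axis=0, keepdims=True)
    n_iter = int(getattr(model, "n_iter_", max_iter))
    return Embedding(
        cell_ids=list(dmat.cell_ids),
        coords=coords,
        stress=kruskal_stress1(dmat.d, coords),
        n_iter=n_iter,
        converged=n_iter < max_iter,
        seed=seed,
    )


def cluster_recovery(
    emb: Embedding, labels: dict[str, str] | pd.Series, seed: int = 0
) -> tuple[float, float]:
    """Score how well the embedding recovers known cell types.

    k-means with k = number of label classes, then adjusted Rand index
    against the labels; silhouette is computed on the true labels (classes
    with a single member are dropped from the silhouette with a warning).
    """
    lab = pd.Series(labels).reindex(emb.cell_ids)
    if lab.isna().any():
        raise ValueError("labels missing for some embedded cells")
    classes = lab.unique()
    if len(classes) < 2:
        raise ValueError("need at least 2 label classes")
    km = KMeans(n_clusters=len(classes), n_init=10, random_state=seed)
    pred = km.fit_predict(emb.coords)
    ari = float(adjusted_rand_score(lab.values, pred))
    counts = lab.value_counts()
    keep_classes = counts.index[counts >= 2]
    if len(keep_classes) < len(classes):
        logger.warning("silhouette: dropping singleton class(es) %s",
                       sorted(set(classes) - set(keep_classes)))
    mask = lab.isin(keep_classes).values
    if len(keep_classes) >= 2 and mask.sum() > len(keep_classes):
        sil = float(silhouette_score(emb.coords[mask], lab.values[mask]))
    else:
        sil = float("nan")
    return ari, sil


def type_centroids(emb: Embedding, labels: dict[str, str] | pd.Series) -> pd.DataFrame:
    """Mean embedded position per label class."""
    lab = pd.Series(labels).reindex(emb.cell_ids)
    df = emb.to_frame()
    df["type"] = lab.values
    return df.groupby("type")[["x", "y"]].mean()
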