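"""Similarity matrices and k-nearest-neighbor regularization structure.

Cell-line similarity comes from four sources — expression, copy number and
IC50 profiles (Pearson correlation) and mutation profiles (Jaccard) — which
are combined by a weighted average into Sim_total.  Drug similarity is the
Jaccard index on substructure fingerprints.  From any similarity matrix a
directed k-NN adjacency A is built (row i keeps the similarities of i's k
most-similar peers) together with the graph-regularization matrix

    H = (E + Ẽ) − (A + Aᵀ),

where E and Ẽ are the diagonal matrices of row and column sums of A.  H
satisfies the quadratic-form identity Σ_ij a_ij‖x_i − x_j‖² = tr(Xᵀ H X),
which is what makes it usable as a penalty pulling latent vectors of
similar entities together.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_SYM_TOL = 1e-10


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity over a set of entities."""

    values: np.ndarray
    entity_ids: list[str]
    declared_range: tuple[float, float]

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        if len(self.entity_ids) != v.shape[0]:
            raise ValueError("entity_ids length does not match matrix")
        if np.abs(v - v.T).max(initial=0.0) > _SYM_TOL:
            raise ValueError("similarity matrix is not symmetric")
        lo, hi = self.declared_range
        if v.min(initial=0.0) < lo - _SYM_TOL or v.max(initial=0.0) > hi + _SYM_TOL:
            raise ValueError(f"entries outside declared range [{lo}, {hi}]")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.entity_ids, columns=self.entity_ids)


@dataclass
class NeighborGraph:
    """Directed k-NN adjacency and its derived regularization matrix H."""

    adjacency: np.ndarray
    k: int
    reg_matrix: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        a = self.adjacency
        if np.diag(a).any():
            raise ValueError("adjacency diagonal must be zero")
        row_deg = np.diag(a.sum(axis=1))
        col_deg = np.diag(a.sum(axis=0))
        self.reg_matrix = (row_deg + col_deg) - (a + a.T)


def _default_ids(n: int) -> list[str]:
    return [str(i) for i in range(n)]


def pearson_similarity(
    features: np.ndarray, entity_ids: list[str] | None = None
) -> SimilarityMatrix:
    """Pairwise Pearson correlation between entity rows.

    Zero-variance rows correlate 0 with everything (logged) rather than
    propagating NaN; their diagonal stays 1 by convention.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 variables per entity")
    sd = x.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        logger.warning("%d zero-variance rows; their similarities set to 0", flat.size)
    centered = x - x.mean(axis=1, keepdims=True)
    denom = np.where(sd == 0, 1.0, sd) * x.shape[1]
    corr = (centered @ centered.T) / np.outer(denom, denom) * x.shape[1]
    corr[flat, :] = 0.0
    corr[:, flat] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = np.clip((corr + corr.T) / 2, -1.0, 1.0)
    return SimilarityMatrix(corr, entity_ids or _default_ids(len(corr)), (-1.0, 1.0))


def jaccard_similarity(
    features: np.ndarray, entity_ids: list[str] | None = None
) -> SimilarityMatrix:
    """Pairwise Jaccard index |i ∩ j| / |i ∪ j| between binary rows.

    Two all-zero vectors have similarity 0 — featureless entities are not
    treated as maximally similar.
    """
    x = np.asarray(features, dtype=float)
    if ((x != 0) & (x != 1)).any():
        raise ValueError("jaccard_similarity requires a binary matrix")
    inter = x @ x.T
    sizes = x.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.where(union == 0, 1, union), 0.0)
    np.fill_diagonal(sim, np.where(sizes > 0, 1.0, 0.0))
    sim = (sim + sim.T) / 2
    return SimilarityMatrix(sim, entity_ids or _default_ids(len(sim)), (0.0, 1.0))


def aggregate_cell_similarity(
    s_exp: SimilarityMatrix,
    s_cnv: SimilarityMatrix,
    s_mut: SimilarityMatrix,
    s_ic50: SimilarityMatrix,
    w_exp: float = 1.0,
    w_cnv: float = 1.0,
    w_mut: float = 1.0,
    w_ic50: float = 3.0,
) -> SimilarityMatrix:
    """Weighted average of the four cell-line similarity matrices (Sim_total).

    Default weights are the values tuned on the GDSC cohort (1, 1, 1, 3):
    the IC50-profile similarity carries triple weight.
    """
    mats = (s_exp, s_cnv, s_mut, s_ic50)
    weights = np.array([w_exp, w_cnv, w_mut, w_ic50], dtype=float)
    if (weights < 0).any():
        raise ValueError("weights must be non-negative")
    if weights.sum() == 0:
        raise ValueError("at least one weight must be positive")
    ids = mats[0].entity_ids
    for m in mats[1:]:
        if m.entity_ids != ids:
            raise ValueError("similarity matrices have mismatched entity_ids")
    total = sum(w * m.values for w, m in zip(weights, mats)) / weights.sum()
    return SimilarityMatrix(total, list(ids), (-1.0, 1.0))


def similarity_collinearity(
    mats: list[SimilarityMatrix], names: list[str] | None = None
) -> pd.DataFrame:
    """Pearson correlation between similarity matrices.

    Each matrix is vectorized to its strict upper triangle before
    correlating, so the forced 1s on the diagonal do not inflate agreement.
    Used to check the four cell-line similarities are not collinear before
    combining them linearly.
    """
    if len(mats) < 2:
        raise ValueError("need at least two matrices")
    ids = mats[0].entity_ids
    for m in mats[1:]:
        if m.entity_ids != ids:
            raise ValueError("similarity matrices have mismatched entity_ids")
    iu = np.triu_indices(len(ids), k=1)
    stacked = np.array([m.values[iu] for m in mats])
    corr = np.corrcoef(stacked)
    names = names or [f"sim_{i}" for i in range(len(mats))]
    return pd.DataFrame(corr, index=names, columns=names)


def top_k_indices(row: np.ndarray, self_idx: int, k: int) -> np.ndarray:
    """Indices of the k largest off-diagonal entries of ``row``.

    Ties at the k-th rank are broken by ascending index so runs are
    reproducible.
    """
    masked = row.copy().astype(float)
    masked[self_idx] = -np.inf
    # lexsort: primary key descending similarity, secondary ascending index
    order = np.lexsort((np.arange(len(row)), -masked))
    return order[:k]


def knn_adjacency(sim: SimilarityMatrix, k: int) -> NeighborGraph:
    """Directed k-NN adjacency: row i keeps similarities of i's top-k peers."""
    n = sim.n
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < {n}")
    a = np.zeros((n, n))
    for i in range(n):
        nbrs = top_k_indices(sim.values[i], i, k)
        a[i, nbrs] = sim.values[i, nbrs]
    return NeighborGraph(adjacency=a, k=k)


def pairwise_quadratic_form(adjacency: np.ndarray, x: np.ndarray) -> float:
    """Brute-force Σ_ij a_ij ‖x_i − x_j‖²; reference for the H identity."""
    total = 0.0
    for i in range(adjacency.shape[0]):
        for j in range(adjacency.shape[1]):
            d = x[i] - x[j]
            total += adjacency[i, j] * float(d @ d)
    return total
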