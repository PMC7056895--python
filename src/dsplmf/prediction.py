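"""Sensitivity prediction for cell lines absent from training.

A new cell line has no IC50 profile, so its IC50-based similarity to the
training set — and hence its latent vector — cannot be computed directly.
Instead a decision tree is trained to recognize "t-nearest-by-IC50"
relationships from the three omics similarities that ARE available for a
new line (expression, CNV, mutation).  The tree flags candidate neighbors
among the training cell lines; the new line's latent vector and bias are
the averages over those neighbors, after which per-drug probabilities
follow from the logistic model and a probability threshold assigns the
sensitive / resistant label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .lmf import LatentModel
from .similarity import SimilarityMatrix, top_k_indices

PAIR_FEATURES = ["sim_exp", "sim_cnv", "sim_mut"]


def topt_labels(sim_ic50: SimilarityMatrix, t: int) -> np.ndarray:
    """Per row, mark the t most-similar peers with 1, the rest 0.

    Ties at the t-th rank break by ascending index.  Each row sums to
    exactly t; the diagonal is 0.
    """
    n = sim_ic50.n
    if not 1 <= t < n:
        raise ValueError(f"t must satisfy 1 <= t < {n}")
    labels = np.zeros((n, n))
    for i in range(n):
        labels[i, top_k_indices(sim_ic50.values[i], i, t)] = 1.0
    return labels


def build_pair_features(
    s_exp: SimilarityMatrix,
    s_cnv: SimilarityMatrix,
    s_mut: SimilarityMatrix,
    labels: np.ndarray,
) -> pd.DataFrame:
    """One row per ordered cell-line pair (i != j) with the three similarity
    features and the binary neighbor label."""
    ids = s_exp.entity_ids
    if s_cnv.entity_ids != ids or s_mut.entity_ids != ids:
        raise ValueError("similarity matrices have mismatched entity_ids")
    n = len(ids)
    i_idx, j_idx = np.where(~np.eye(n, dtype=bool))
    table = pd.DataFrame(
        {
            "i": i_idx,
            "j": j_idx,
            "sim_exp": s_exp.values[i_idx, j_idx],
            "sim_cnv": s_cnv.values[i_idx, j_idx],
            "sim_mut": s_mut.values[i_idx, j_idx],
            "label": labels[i_idx, j_idx],
        }
    )
    if table["label"].sum() == 0:
        raise ValueError("degenerate pair table: no positive labels")
    return table


@dataclass
class NeighborClassifier:
    tree: DecisionTreeClassifier
    training_accuracy: float


def train_neighbor_classifier(
    table: pd.DataFrame, seed: int = 0, max_depth: int | None = None
) -> NeighborClassifier:
    """Fit the decision tree that recognizes IC50-neighborhood from omics."""
    x = table[PAIR_FEATURES].to_numpy()
    y = table["label"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("pair table contains a single class")
    tree = DecisionTreeClassifier(random_state=seed, max_depth=max_depth)
    tree.fit(x, y)
    return NeighborClassifier(tree=tree, training_accuracy=float(tree.score(x, y)))


def predict_neighbors(
    clf: NeighborClassifier,
    new_cell_features: np.ndarray,
    t: int,
    seed: int = 0,
    fallback_similarity: np.ndarray | None = None,
) -> np.ndarray:
    """Select up to t training cell lines to act as neighbors of a new line.

    ``new_cell_features`` is (n_train, 3): the new line's expression / CNV /
    mutation similarity to each training cell line.  If the tree flags fewer
    than t candidates they are all used; if more, exactly t are sampled
    uniformly without replacement under ``seed``.  If it flags none, the
    top-t training lines by ``fallback_similarity`` are used when provided,
    otherwise an error is raised (strict mode).
    """
    flagged = np.flatnonzero(clf.tree.predict(np.asarray(new_cell_features)) == 1)
    if flagged.size == 0:
        if fallback_similarity is None:
            raise ValueError(
                "classifier flagged no neighbors; provide fallback_similarity "
                "or relax strict mode"
            )
        order = np.lexsort(
            (np.arange(len(fallback_similarity)), -np.asarray(fallback_similarity))
        )
        return np.sort(order[:t])
    if flagged.size <= t:
        return flagged
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(flagged, size=t, replace=False))


def impute_latent(
    neighbors: np.ndarray, model: LatentModel
) -> tuple[np.ndarray, float]:
    """Average the neighbors' latent vectors and cell-line biases."""
    neighbors = np.asarray(neighbors)
    if neighbors.size == 0:
        raise ValueError("neighbor set is empty")
    return model.U[neighbors].mean(axis=0), float(model.bias_c[neighbors].mean())


def classify_new(
    u_new: np.ndarray,
    bias_new: float,
    model: LatentModel,
    threshold: float = 0.6,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-drug sensitivity probabilities and labels for an imputed cell line.

    The boundary counts as sensitive: label 1 iff p >= threshold.
    """
    from scipy.special import expit

    probs = expit(np.asarray(u_new) @ model.V.T + bias_new + model.bias_d)
    return probs, (probs >= threshold).astype(float)
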