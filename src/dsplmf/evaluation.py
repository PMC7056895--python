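"""Confusion metrics, AUC, repeated cross-validation and grid search.

Cross-validation treats whole cell lines as the unit: a held-out cell line
enters the fitted model only through the neighbor-imputation path, exactly
as a genuinely new cell line would.  Everything derived from IC50 — the
IC50-profile similarity, the per-drug medians, the observation matrix Q —
is rebuilt from the training fold alone, so no response information leaks
from test cell lines into the fitted model.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from . import prediction as pred
from .datasets import CellLineDataset, binarize_response
from .lmf import LatentModel, LMFHyperparams, fit, init_model
from .similarity import (
    SimilarityMatrix,
    aggregate_cell_similarity,
    jaccard_similarity,
    knn_adjacency,
    pearson_similarity,
)

logger = logging.getLogger(__name__)

METRIC_NAMES = ("accuracy", "recall", "precision", "specificity", "f1", "mcc", "auc")


@dataclass
class MetricReport:
    """Confusion-derived metrics for one pooled set of (cell, drug) pairs.

    Zero-denominator rates are reported as 0 and listed in ``degenerate``.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    recall: float
    precision: float
    specificity: float
    f1: float
    mcc: float
    auc: float | None = None
    degenerate: list[str] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in METRIC_NAMES}
        d.update(tp=self.tp, tn=self.tn, fp=self.fp, fn=self.fn, n_pairs=self.n_pairs)
        return d


def confusion_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> MetricReport:
    """Accuracy, recall, precision, specificity, F1 and MCC from 0/1 vectors."""
    y_true = np.asarray(y_true).ravel()
    y_pred = np.asarray(y_pred).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    degenerate: list[str] = []

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            degenerate.append(name)
            return 0.0
        return num / den

    mcc_den = np.sqrt(
        float(tp + fp) * float(tp + fn) * float(fp + tn) * float(fn + tn)
    )
    return MetricReport(
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        accuracy=ratio(tp + tn, tp + fp + tn + fn, "accuracy"),
        recall=ratio(tp, tp + fn, "recall"),
        precision=ratio(tp, tp + fp, "precision"),
        specificity=ratio(tn, tn + fp, "specificity"),
        f1=ratio(2 * tp, 2 * tp + fp + fn, "f1"),
        mcc=ratio(tp * tn - fp * fn, mcc_den, "mcc"),
        degenerate=degenerate,
    )


def auc_score(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC; ties share rank."""
    y_true = np.asarray(y_true).ravel()
    if len(np.unique(y_true)) < 2:
        raise ValueError("AUC undefined for single-class truth")
    return float(roc_auc_score(y_true, np.asarray(scores).ravel()))


# ---------------------------------------------------------------------------
# cross-validation


def cross_pearson(test_rows: np.ndarray, train_rows: np.ndarray) -> np.ndarray:
    """Pearson correlation of each test row against each training row."""
    def center(x):
        c = x - x.mean(axis=1, keepdims=True)
        sd = c.std(axis=1)
        return c, np.where(sd == 0, 1.0, sd)

    ct, sdt = center(np.atleast_2d(test_rows))
    cr, sdr = center(np.atleast_2d(train_rows))
    nvar = ct.shape[1]
    return (ct @ cr.T) / (np.outer(sdt, sdr) * nvar)


def cross_jaccard(test_rows: np.ndarray, train_rows: np.ndarray) -> np.ndarray:
    test_rows = np.atleast_2d(test_rows)
    inter = test_rows @ train_rows.T
    union = test_rows.sum(axis=1)[:, None] + train_rows.sum(axis=1)[None, :] - inter
    return np.where(union > 0, inter / np.where(union == 0, 1, union), 0.0)


@dataclass
class FoldResult:
    repeat: int
    fold: int
    test_cells: np.ndarray
    report: MetricReport


@dataclass
class CVSummary:
    """Per-fold reports plus aggregate means and standard deviations."""

    folds: list[FoldResult]
    mean: dict[str, float]
    std: dict[str, float]
    per_repeat: pd.DataFrame
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"repeat": f.repeat, "fold": f.fold, **f.report.to_dict()}
            for f in self.folds
        ]
        return pd.DataFrame(rows)


def _train_similarities(ds: CellLineDataset, train: np.ndarray):
    ids = [ds.cell_ids[i] for i in train]
    return (
        pearson_similarity(ds.expression[train], ids),
        pearson_similarity(ds.cnv[train], ids),
        jaccard_similarity(ds.mutation[train], ids),
        pearson_similarity(ds.ic50[train], ids),
    )


def fit_fold(
    ds: CellLineDataset, train: np.ndarray, hp: LMFHyperparams, seed: int
) -> tuple[LatentModel, pred.NeighborClassifier, tuple, np.ndarray]:
    """Fit LMF and the neighbor classifier on one training fold.

    Returns the model, the classifier, the three omics similarity matrices
    over training cell lines, and the per-drug training medians.
    """
    n_train = train.size
    s_exp, s_cnv, s_mut, s_ic50 = _train_similarities(ds, train)
    s_total = aggregate_cell_similarity(
        s_exp, s_cnv, s_mut, s_ic50, *hp.similarity_weights()
    )
    k_cell = min(hp.k, n_train - 1)
    k_drug = min(hp.k, ds.m - 1)
    hc = knn_adjacency(s_total, k_cell).reg_matrix
    s_drug = jaccard_similarity(ds.fingerprints, list(ds.drug_ids))
    hd = knn_adjacency(s_drug, k_drug).reg_matrix

    q = binarize_response(ds.ic50[train]).q
    model, _ = fit(q, hc, hd, hp)

    t_eff = min(hp.t, n_train - 1)
    labels = pred.topt_labels(s_ic50, t_eff)
    table = pred.build_pair_features(s_exp, s_cnv, s_mut, labels)
    clf = pred.train_neighbor_classifier(table, seed=seed)
    medians = np.median(ds.ic50[train], axis=0)
    return model, clf, (s_exp, s_cnv, s_mut), medians


def predict_fold(
    ds: CellLineDataset,
    train: np.ndarray,
    test: np.ndarray,
    model: LatentModel,
    clf: pred.NeighborClassifier,
    hp: LMFHyperparams,
    seed: int,
    ablation: str | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities and labels for every (test cell, drug) pair.

    ``ablation="random_latent"`` replaces the neighbor-imputed latent vector
    with a random draw, severing the link between a test cell line's omics
    and its prediction — the control for how much the neighborhood
    machinery contributes.
    """
    ce = cross_pearson(ds.expression[test], ds.expression[train])
    cc = cross_pearson(ds.cnv[test], ds.cnv[train])
    cm = cross_jaccard(ds.mutation[test], ds.mutation[train])
    t_eff = min(hp.t, train.size - 1)
    rng = np.random.default_rng(seed)
    probs = np.zeros((test.size, ds.m))
    labels = np.zeros((test.size, ds.m))
    for idx in range(test.size):
        if ablation == "random_latent":
            u_new = rng.normal(0.0, 1.0 / np.sqrt(model.L), model.L)
            b_new = 0.0
        else:
            feats = np.column_stack([ce[idx], cc[idx], cm[idx]])
            fallback = (ce[idx] + cc[idx] + cm[idx]) / 3.0
            nbrs = pred.predict_neighbors(
                clf, feats, t_eff,
                seed=int(rng.integers(2**31 - 1)),
                fallback_similarity=fallback,
            )
            u_new, b_new = pred.impute_latent(nbrs, model)
        probs[idx], labels[idx] = pred.classify_new(u_new, b_new, model, hp.threshold)
    return probs, labels


def cross_validate(
    ds: CellLineDataset,
    hp: LMFHyperparams,
    folds: int = 10,
    repeats: int = 1,
    seed: int = 0,
    ablation: str | None = None,
) -> CVSummary:
    """Repeated cell-line-level cross-validation of the full pipeline.

    Per repeat, cell lines are shuffled and split into ``folds`` nearly
    equal folds; per fold the similarities, Q and per-drug medians are
    rebuilt from the training cell lines only, the model and neighbor
    classifier are fitted, and every held-out (cell, drug) pair is pooled
    into one MetricReport.  Test-cell truth labels compare the held-out
    IC50 against the training fold's per-drug median.
    """
    if folds < 2 or ds.n < folds:
        raise ValueError("need folds >= 2 and at least one cell line per fold")
    results: list[FoldResult] = []
    for rep in range(repeats):
        rng = np.random.default_rng(seed + 1000 * rep)
        perm = rng.permutation(ds.n)
        parts = np.array_split(perm, folds)
        for f, test in enumerate(parts):
            train = np.setdiff1d(perm, test)
            fold_seed = (seed + 1000 * rep + f) % (2**31 - 1)
            hp_fold = LMFHyperparams(**{**hp.to_dict(), "seed": fold_seed})
            model, clf, _, medians = fit_fold(ds, train, hp_fold, fold_seed)
            probs, labels = predict_fold(
                ds, train, test, model, clf, hp_fold, fold_seed, ablation
            )
            y_true = (ds.ic50[test] < medians).astype(float)
            report = confusion_metrics(y_true.ravel(), labels.ravel())
            if len(np.unique(y_true)) == 2:
                report.auc = auc_score(y_true.ravel(), probs.ravel())
            else:
                report.degenerate.append("auc")
            results.append(FoldResult(rep, f, test, report))

    frame = pd.DataFrame(
        [
            {"repeat": r.repeat, **{k: getattr(r.report, k) for k in METRIC_NAMES}}
            for r in results
        ]
    )
    # pooled-per-repeat view: weight folds by pair count for accuracy-type
    # metrics; simple fold mean for the rest
    per_repeat = frame.groupby("repeat").mean(numeric_only=True)
    mean = {k: float(frame[k].mean()) for k in METRIC_NAMES}
    std = {k: float(frame[k].std(ddof=0)) for k in METRIC_NAMES}
    return CVSummary(folds=results, mean=mean, std=std, per_repeat=per_repeat, seed=seed)


def grid_search(
    ds: CellLineDataset,
    grids: dict[str, list],
    base: LMFHyperparams | None = None,
    folds: int = 10,
    repeats: int = 1,
    seed: int = 0,
) -> tuple[LMFHyperparams, pd.DataFrame]:
    """Exhaustive search maximizing Accuracy+Recall+Precision+Specificity+F1+MCC.

    ``grids`` maps hyperparameter names to candidate lists; unlisted
    parameters stay at ``base`` (or package defaults).  Returns the best
    configuration and the full score table.
    """
    if not grids or any(len(v) == 0 for v in grids.values()):
        raise ValueError("grids must be non-empty")
    base = base or LMFHyperparams()
    score_of = ("accuracy", "recall", "precision", "specificity", "f1", "mcc")
    rows = []
    best, best_score = None, -np.inf
    for combo in itertools.product(*grids.values()):
        params = dict(zip(grids.keys(), combo))
        hp = LMFHyperparams(**{**base.to_dict(), **params})
        summary = cross_validate(ds, hp, folds=folds, repeats=repeats, seed=seed)
        score = sum(summary.mean[k] for k in score_of)
        rows.append({**params, "score": score, **summary.mean})
        if score > best_score:
            best, best_score = hp, score
    return best, pd.DataFrame(rows)
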