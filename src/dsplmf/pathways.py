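"""Drug-pathway association from predicted responses.

Pathway activity is scored per cell line as the sum, over the genes of a
set, of median-centered log2 expression fold changes:

    x_ij = log2(expr_ij) - median_j'(log2(expr_ij'))
    PAS_j(PW) = sum_{g_i in PW} x_ij

The association between a drug and a pathway is the Pearson correlation
across cell lines between the pathway's activity vector and the drug's
predicted IC50 (the linear predictor of the fitted model).  A negative
correlation marks the pathway "assistant" (active pathway, sensitive cell
lines); positive marks it "resistant".
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .lmf import LatentModel

logger = logging.getLogger(__name__)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse GMT gene sets: ``name<TAB>description<TAB>gene1<TAB>gene2...``."""
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs name, description, genes")
        name, genes = parts[0], list(dict.fromkeys(parts[2:]))
        if not genes:
            raise ValueError(f"{path}:{lineno}: empty gene set {name!r}")
        sets[name] = genes
    return sets


def read_gene_sets_tsv(path: str | Path) -> dict[str, list[str]]:
    """Two-column alternative: ``set_name<TAB>gene`` per line."""
    df = pd.read_csv(path, sep="\t", header=None, names=["set", "gene"])
    return {name: list(dict.fromkeys(g)) for name, g in df.groupby("set")["gene"]}


def fold_change(expression: pd.DataFrame, log2: bool = True) -> pd.DataFrame:
    """Median-centered (per gene) log2 expression, genes x cell lines.

    With ``log2=False`` the input is raw intensity and is log2-transformed
    first; raw values must be strictly positive.
    """
    x = expression.astype(float)
    if not log2:
        bad = x.index[(x <= 0).any(axis=1)]
        if len(bad):
            raise ValueError(f"non-positive raw intensity for gene {bad[0]!r}")
        x = np.log2(x)
    return x.sub(x.median(axis=1), axis=0)


def pathway_activity(
    x: pd.DataFrame, gene_sets: dict[str, list[str]]
) -> pd.DataFrame:
    """Sum fold changes over each set's genes: PAS matrix, pathways x cells.

    Genes absent from the expression matrix are dropped with a warning;
    a set with no present gene is excluded.
    """
    rows, names = [], []
    for name, genes in gene_sets.items():
        present = [g for g in genes if g in x.index]
        if not present:
            logger.warning("gene set %s has no gene in the expression matrix", name)
            continue
        if len(present) < len(genes):
            logger.warning(
                "gene set %s: %d of %d genes absent",
                name, len(genes) - len(present), len(genes),
            )
        rows.append(x.loc[present].sum(axis=0))
        names.append(name)
    if not rows:
        raise ValueError("no gene set overlaps the expression matrix")
    return pd.DataFrame(rows, index=names)


def predicted_ic50(model: LatentModel) -> np.ndarray:
    """Model-scale predicted response: the linear predictor u_i.v_j + biases.

    This is the logit of the sensitivity probability, used as the
    continuous predicted-IC50 surrogate for correlation analyses.
    """
    return model.linear_predictor_matrix()


def drug_pathway_association(
    pas: pd.DataFrame,
    pred: np.ndarray,
    drug_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Pearson correlation of each PAS row with each predicted-IC50 column.

    Negative entries are "assistant" associations (pathway activity goes
    with sensitivity), positive entries "resistant".  Zero-variance vectors
    yield 0 with a warning.
    """
    pred = np.asarray(pred, dtype=float)
    n = pas.shape[1]
    if pred.shape[0] != n:
        raise ValueError("PAS and predictions disagree on cell-line count")
    if n < 3:
        raise ValueError("need at least 3 cell lines for a meaningful correlation")

    def zcore(mat: np.ndarray) -> np.ndarray:
        c = mat - mat.mean(axis=1, keepdims=True)
        sd = c.std(axis=1)
        flat = sd == 0
        if flat.any():
            logger.warning("%d zero-variance vectors in association", flat.sum())
        return np.where(flat[:, None], 0.0, c / np.where(flat, 1.0, sd)[:, None])

    zp = zcore(pas.to_numpy())
    zd = zcore(pred.T)
    corr = (zp @ zd.T) / n
    cols = drug_ids if drug_ids is not None else [f"D{j}" for j in range(pred.shape[1])]
    return pd.DataFrame(np.clip(corr, -1.0, 1.0), index=pas.index, columns=cols)
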