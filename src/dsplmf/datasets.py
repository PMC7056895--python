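"""Loading, validation and preprocessing of cell-line cohorts.

A cohort bundles per-cell-line omics features (gene expression, copy-number
alteration, binary single-nucleotide mutation calls), an IC50 response matrix
over a drug panel, and per-drug binary substructure fingerprints.  All
matrices are stored cell-lines-as-rows (drugs-as-rows for fingerprints)
regardless of file orientation.

Preprocessing follows the standard pipeline for pharmacogenomic panels:
cell lines with too many missing values are dropped, remaining gaps are
filled from the k nearest cell lines in expression space, and the completed
IC50 matrix is binarized against each drug's median into the sensitive /
resistant observation matrix Q.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FINGERPRINT_WIDTH = 881  # PubChem substructure fingerprint length

MatrixKind = Literal["expression", "cnv", "mutation", "ic50", "fingerprints"]


class ValidationError(ValueError):
    """A matrix violates its declared contract (e.g. non-binary entries)."""


@dataclass
class CellLineDataset:
    """Aligned omics + response matrices for one cohort.

    Attributes
    ----------
    cell_ids : list of str
        Ordered cell-line identifiers (length n).
    drug_ids : list of str
        Ordered drug identifiers (length m).
    expression : ndarray, shape (n, genes_e)
        Log-scale expression intensities; assumed complete.
    cnv : ndarray, shape (n, genes_c)
        Copy-number alteration values; NaN marks missing entries.
    mutation : ndarray, shape (n, genes_m)
        Binary mutation calls; NaN marks missing entries.
    ic50 : ndarray, shape (n, m)
        Drug response; NaN marks missing entries until imputation.
    fingerprints : ndarray, shape (m, 881)
        Binary substructure fingerprints.
    """

    cell_ids: list[str]
    drug_ids: list[str]
    expression: np.ndarray
    cnv: np.ndarray
    mutation: np.ndarray
    ic50: np.ndarray
    fingerprints: np.ndarray

    @property
    def n(self) -> int:
        return len(self.cell_ids)

    @property
    def m(self) -> int:
        return len(self.drug_ids)

    def validate(self) -> None:
        n, m = self.n, self.m
        for name in ("expression", "cnv", "mutation", "ic50"):
            mat = getattr(self, name)
            if mat.shape[0] != n:
                raise ValidationError(
                    f"{name} has {mat.shape[0]} rows, expected {n} cell lines"
                )
        if self.ic50.shape[1] != m:
            raise ValidationError(
                f"ic50 has {self.ic50.shape[1]} columns, expected {m} drugs"
            )
        if self.fingerprints.shape[0] != m:
            raise ValidationError(
                f"fingerprints has {self.fingerprints.shape[0]} rows, expected {m} drugs"
            )
        _check_binary(self.mutation, "mutation", allow_nan=True)
        _check_binary(self.fingerprints, "fingerprints", allow_nan=False)

    def is_complete(self) -> bool:
        """True once no matrix contains missing entries."""
        return not (
            np.isnan(self.ic50).any()
            or np.isnan(self.cnv).any()
            or np.isnan(self.mutation).any()
        )


@dataclass
class BinaryResponse:
    """Observation matrix Q: q_ij = 1 iff cell line i is sensitive to drug j."""

    q: np.ndarray
    degenerate_drugs: list[int]

    def __post_init__(self) -> None:
        vals = np.unique(self.q)
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError("Q must contain only 0/1 entries")


def _check_binary(mat: np.ndarray, name: str, allow_nan: bool) -> None:
    vals = mat[~np.isnan(mat)] if allow_nan else mat
    bad = vals[(vals != 0) & (vals != 1)]
    if bad.size:
        raise ValidationError(f"{name} contains non-binary value {bad.flat[0]!r}")


def load_matrix(
    path: str | Path,
    kind: MatrixKind,
    orientation: Literal["auto", "rows", "columns"] = "auto",
    fingerprint_width: int = FINGERPRINT_WIDTH,
) -> pd.DataFrame:
    """Read a delimited matrix with a header row and a label column.

    Rows of the returned frame are always the primary entities (cell lines,
    or drugs for fingerprints).  Omics files commonly come genes-as-rows;
    with ``orientation="auto"`` a feature matrix that is taller than wide
    is transposed, on the assumption that genes outnumber cell lines.
    Missing values may be encoded as empty cells or ``NA``.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA", ""])
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValidationError(f"cannot parse {path}: {exc}") from exc
    if df.index.hasnans or df.columns.hasnans:
        raise ValidationError(f"{path}: missing row or column label")
    if not all(np.issubdtype(d, np.number) for d in df.dtypes):
        bad = df.columns[[not np.issubdtype(d, np.number) for d in df.dtypes]][0]
        raise ValidationError(f"{path}: non-numeric column {bad!r}")

    feature_kind = kind in ("expression", "cnv", "mutation")
    if orientation == "columns" or (
        orientation == "auto" and feature_kind and df.shape[0] > df.shape[1]
    ):
        df = df.T

    if kind in ("mutation", "fingerprints"):
        _check_binary(df.to_numpy(dtype=float), kind, allow_nan=(kind == "mutation"))
    if kind == "fingerprints" and df.shape[1] != fingerprint_width:
        logger.warning(
            "fingerprint table has %d columns, expected %d",
            df.shape[1],
            fingerprint_width,
        )
    return df


def load_fingerprints_hex(path: str | Path, width: int = FINGERPRINT_WIDTH) -> pd.DataFrame:
    """Read one ``drug_id<TAB>hex_string`` fingerprint per line, decoded to bits."""
    rows, ids = [], []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        try:
            drug, hexstr = line.split()
            bits = np.unpackbits(np.frombuffer(bytes.fromhex(hexstr), dtype=np.uint8))
        except ValueError as exc:
            raise ValidationError(f"{path}:{lineno}: malformed fingerprint") from exc
        if bits.size < width:
            raise ValidationError(f"{path}:{lineno}: fingerprint shorter than {width} bits")
        ids.append(drug)
        rows.append(bits[:width])
    return pd.DataFrame(np.asarray(rows, dtype=float), index=ids)


def missing_fraction(ds: CellLineDataset) -> np.ndarray:
    """Per-cell-line fraction of missing entries over IC50, CNV and mutation."""
    counts = (
        np.isnan(ds.ic50).sum(axis=1)
        + np.isnan(ds.cnv).sum(axis=1)
        + np.isnan(ds.mutation).sum(axis=1)
    )
    total = ds.ic50.shape[1] + ds.cnv.shape[1] + ds.mutation.shape[1]
    return counts / total


def filter_cell_lines(ds: CellLineDataset, max_missing: float = 0.5) -> CellLineDataset:
    """Drop cell lines whose missing-value fraction exceeds ``max_missing``.

    The threshold is strict: a cell line at exactly ``max_missing`` survives.
    Survivor order is preserved.
    """
    if not 0 <= max_missing <= 1:
        raise ValueError("max_missing must be in [0, 1]")
    keep = missing_fraction(ds) <= max_missing
    if not keep.any():
        raise ValueError("filtering removed every cell line")
    idx = np.flatnonzero(keep)
    return replace(
        ds,
        cell_ids=[ds.cell_ids[i] for i in idx],
        expression=ds.expression[idx],
        cnv=ds.cnv[idx],
        mutation=ds.mutation[idx],
        ic50=ds.ic50[idx],
    )


def impute_missing_knn(ds: CellLineDataset, k_impute: int = 5) -> CellLineDataset:
    """Fill missing IC50/CNV/mutation entries from the k nearest cell lines.

    Neighborhoods use Euclidean distance on gene expression, which is assumed
    complete.  Continuous entries take the neighbor mean; binary mutation
    entries take the neighbor majority vote (ties round up to 1).  Returns
    the dataset unchanged if nothing is missing.
    """
    if ds.is_complete():
        return ds
    from scipy.spatial.distance import cdist

    dist = cdist(ds.expression, ds.expression)
    np.fill_diagonal(dist, np.inf)
    order = np.argsort(dist, axis=1, kind="stable")

    def fill(mat: np.ndarray, binary: bool, label: str) -> np.ndarray:
        out = mat.copy()
        for col in range(mat.shape[1]):
            missing = np.flatnonzero(np.isnan(mat[:, col]))
            if missing.size == 0:
                continue
            observed = ~np.isnan(mat[:, col])
            if not observed.any():
                raise ValueError(f"{label} column {col} has no observed values")
            for i in missing:
                ranked = order[i][observed[order[i]]]
                vals = mat[ranked[:k_impute], col]
                out[i, col] = (np.mean(vals) >= 0.5) * 1.0 if binary else np.mean(vals)
        return out

    return replace(
        ds,
        ic50=fill(ds.ic50, False, "ic50 drug"),
        cnv=fill(ds.cnv, False, "cnv gene"),
        mutation=fill(ds.mutation, True, "mutation gene"),
    )


def binarize_response(ic50: np.ndarray) -> BinaryResponse:
    """Threshold each drug column at its median: strictly below = sensitive (1).

    The median of an even-length column is the mean of the two middle values.
    A constant column yields an all-zero label vector and is flagged as
    degenerate.
    """
    ic50 = np.asarray(ic50, dtype=float)
    if np.isnan(ic50).any():
        raise ValueError("ic50 must be complete before binarization")
    med = np.median(ic50, axis=0)
    q = (ic50 < med).astype(float)
    degenerate = [j for j in range(ic50.shape[1]) if not q[:, j].any()]
    for j in degenerate:
        logger.warning("drug column %d has no value below its median", j)
    return BinaryResponse(q=q, degenerate_drugs=degenerate)


def from_frames(
    expression: pd.DataFrame,
    cnv: pd.DataFrame,
    mutation: pd.DataFrame,
    ic50: pd.DataFrame,
    fingerprints: pd.DataFrame,
) -> CellLineDataset:
    """Assemble a dataset from labeled frames, aligning on shared identifiers."""
    cells = [c for c in ic50.index if all(c in f.index for f in (expression, cnv, mutation))]
    if not cells:
        raise ValidationError("no cell line appears in every matrix")
    drugs = [d for d in ic50.columns if d in fingerprints.index]
    if not drugs:
        raise ValidationError("no drug appears in both ic50 and fingerprints")
    ds = CellLineDataset(
        cell_ids=list(cells),
        drug_ids=list(drugs),
        expression=expression.loc[cells].to_numpy(dtype=float),
        cnv=cnv.loc[cells].to_numpy(dtype=float),
        mutation=mutation.loc[cells].to_numpy(dtype=float),
        ic50=ic50.loc[cells, drugs].to_numpy(dtype=float),
        fingerprints=fingerprints.loc[drugs].to_numpy(dtype=float),
    )
    ds.validate()
    return ds


def save_bundle(ds: CellLineDataset, path: str | Path) -> None:
    """Persist a dataset as a single ``.npz`` bundle."""
    np.savez_compressed(
        path,
        cell_ids=np.array(ds.cell_ids),
        drug_ids=np.array(ds.drug_ids),
        expression=ds.expression,
        cnv=ds.cnv,
        mutation=ds.mutation,
        ic50=ds.ic50,
        fingerprints=ds.fingerprints,
    )


def load_bundle(path: str | Path) -> CellLineDataset:
    with np.load(path, allow_pickle=False) as z:
        ds = CellLineDataset(
            cell_ids=[str(c) for c in z["cell_ids"]],
            drug_ids=[str(d) for d in z["drug_ids"]],
            expression=z["expression"],
            cnv=z["cnv"],
            mutation=z["mutation"],
            ic50=z["ic50"],
            fingerprints=z["fingerprints"],
        )
    ds.validate()
    return ds
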