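"""Metric-space representations: Tanimoto similarity matrices and external loaders.

In metric space a molecule is described only by its similarities to the
training molecules.  For binary fingerprints A and B the Tanimoto coefficient
is Tc = c / (a + b - c), with a and b the set-bit counts and c the common set
bits; 1 - Tc is a genuine distance metric.  Graph-based similarity scores
(e.g., atom-matching methods such as NAMS) enter the pipeline only as
precomputed matrices read from file.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .featurize import FeatureMatrix

__all__ = ["SimilarityMatrix", "tanimoto", "similarity_matrix",
           "load_external_similarity"]

SYMMETRY_TOL = 1e-8


@dataclass
class SimilarityMatrix:
    """n x m similarity block with row/column molecule identifiers."""

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]
    method: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("similarity matrix shape does not match id lists")
        if self.values.size and (self.values.min() < -1e-12 or
                                 self.values.max() > 1 + 1e-12):
            raise ValueError("similarity values must lie in [0, 1]")
        self.values = np.clip(self.values, 0.0, 1.0)

    @property
    def is_square(self) -> bool:
        return self.row_ids == self.col_ids

    def block(self, row_ids: list[str], col_ids: list[str]) -> "SimilarityMatrix":
        """Sub-block in the requested id order (rows and columns)."""
        ri = {m: i for i, m in enumerate(self.row_ids)}
        ci = {m: i for i, m in enumerate(self.col_ids)}
        missing = ([m for m in row_ids if m not in ri]
                   + [m for m in col_ids if m not in ci])
        if missing:
            raise KeyError(f"ids not covered by similarity matrix: {missing[:5]}")
        rows = [ri[m] for m in row_ids]
        cols = [ci[m] for m in col_ids]
        return SimilarityMatrix(self.values[np.ix_(rows, cols)], list(row_ids),
                                list(col_ids), self.method)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto coefficient of two equal-length bit vectors.

    Two all-zero vectors score 1 by convention (identical absence of
    features); this avoids the 0/0 case while preserving symmetry.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("bit vectors must share one length")
    c = int(np.sum((a != 0) & (b != 0)))
    union = int(np.sum(a != 0)) + int(np.sum(b != 0)) - c
    return 1.0 if union == 0 else c / union


def _tanimoto_block(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    common = A @ B.T
    union = A.sum(axis=1)[:, None] + B.sum(axis=1)[None, :] - common
    out = np.ones_like(common, dtype=float)  # both-empty convention
    np.divide(common, union, out=out, where=union > 0)
    return out


def similarity_matrix(train_fp: FeatureMatrix,
                      query_fp: FeatureMatrix | None = None,
                      ) -> SimilarityMatrix:
    """Tanimoto matrix: square train x train, or rectangular query x train."""
    if not train_fp.is_binary:
        raise ValueError("similarity_matrix requires a fingerprint representation")
    if query_fp is None:
        values = _tanimoto_block(train_fp.matrix, train_fp.matrix)
        return SimilarityMatrix(values, list(train_fp.mol_ids),
                                list(train_fp.mol_ids),
                                f"tanimoto_{train_fp.representation}")
    if (query_fp.representation != train_fp.representation
            or query_fp.dim_names != train_fp.dim_names):
        raise ValueError("train and query fingerprints use different specs")
    values = _tanimoto_block(query_fp.matrix, train_fp.matrix)
    return SimilarityMatrix(values, list(query_fp.mol_ids), list(train_fp.mol_ids),
                            f"tanimoto_{train_fp.representation}")


def load_external_similarity(path, train_ids: list[str],
                             query_ids: list[str] | None = None,
                             method: str = "graph",
                             normalize: bool = False) -> SimilarityMatrix:
    """Load a precomputed similarity matrix (CSV with id header row/column).

    Rows/columns are reordered to ``query_ids x train_ids`` (square
    ``train_ids x train_ids`` when query_ids is None).  With ``normalize`` the
    matrix is divided by its maximum entry.  Square matrices asymmetric beyond
    tolerance are symmetrized by averaging with a warning.
    """
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    values = df.to_numpy(dtype=float)
    if normalize and values.size:
        vmax = values.max()
        if vmax <= 0:
            raise ValueError("cannot normalize a non-positive similarity matrix")
        values = values / vmax
    row_ids = list(df.index)
    want_rows = list(train_ids if query_ids is None else query_ids)
    missing = ([m for m in want_rows if m not in set(row_ids)]
               + [m for m in train_ids if m not in set(df.columns)])
    if missing:
        raise KeyError(f"similarity file missing ids: {sorted(set(missing))[:10]}")
    full = SimilarityMatrix(values, row_ids, list(df.columns), method)
    out = full.block(want_rows, list(train_ids))
    if query_ids is None:
        asym = np.abs(out.values - out.values.T).max() if out.values.size else 0.0
        if asym > SYMMETRY_TOL:
            warnings.warn(
                f"square similarity matrix asymmetric (max |S-S'| = {asym:.3g}); "
                "symmetrizing by averaging")
            out.values = 0.5 * (out.values + out.values.T)
        np.fill_diagonal(out.values, 1.0)
    return out
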