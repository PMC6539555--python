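"""PCA with explicit out-of-sample projection, for vector and metric spaces.

Columns are mean-centered with training statistics and rotated onto
orthonormal loadings ordered by decreasing explained variance.  Held-out
molecules are projected with the same centering and rotation — in metric
space their "feature row" is the vector of similarities to the *training*
molecules, so a query is projected via its cross-similarity row.  Models are
then built on the leading 1..k components (the incremental-PC sequence).

The solver is scikit-learn's full-SVD PCA; means, loadings and the
explained-variance spectrum are stored explicitly, with a deterministic sign
convention (largest-magnitude loading element positive) so repeated runs are
comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .featurize import FeatureMatrix
from .similarity import SimilarityMatrix

__all__ = ["PCAModel", "PCScores", "fit_pca", "project", "incremental_pc_matrices"]

_VARIANCE_EPS = 1e-12


@dataclass
class PCAModel:
    column_means: np.ndarray
    loadings: np.ndarray          # n_dims x n_components, orthonormal columns
    explained_variance: np.ndarray
    fitted_on: str

    def __post_init__(self) -> None:
        if np.any(np.diff(self.explained_variance) > 1e-9):
            raise ValueError("explained_variance must be non-increasing")

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


@dataclass
class PCScores:
    scores: np.ndarray
    mol_ids: list[str]

    def __post_init__(self) -> None:
        if self.scores.shape[0] != len(self.mol_ids):
            raise ValueError("score rows do not align with mol_ids")


def _as_rows(X) -> tuple[np.ndarray, list[str], str]:
    if isinstance(X, FeatureMatrix):
        return X.matrix, list(X.mol_ids), X.representation
    if isinstance(X, SimilarityMatrix):
        if not X.is_square:
            raise ValueError("metric-space PCA is fitted on a square matrix")
        return X.values, list(X.row_ids), X.method
    X = np.asarray(X, dtype=float)
    return X, [str(i) for i in range(X.shape[0])], "array"


def fit_pca(X, n_components: int | None = None) -> tuple[PCAModel, PCScores]:
    """Fit PCA on training rows; returns the model and the training scores.

    ``X`` is a FeatureMatrix, a square SimilarityMatrix (rows as features), or
    a plain array.  Components run up to min(n-1, n_dims); a constant matrix
    (no variance) is an error.
    """
    rows, mol_ids, tag = _as_rows(X)
    n, d = rows.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 rows")
    k_max = min(n - 1, d)
    if n_components is not None:
        if not 1 <= n_components <= k_max:
            raise ValueError(f"n_components must be in [1, {k_max}]")
        k_max = n_components
    centered = rows - rows.mean(axis=0)
    total_var = (centered ** 2).sum() / (n - 1)
    if total_var <= _VARIANCE_EPS:
        raise ValueError("matrix is constant; PCA undefined")
    pca = PCA(n_components=k_max, svd_solver="full")
    scores = pca.fit_transform(rows)
    loadings = pca.components_.T.copy()
    # sign convention: largest-|.| element of each loading is positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0),
                            np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    loadings *= flip
    scores = scores * flip
    model = PCAModel(column_means=pca.mean_.copy(), loadings=loadings,
                     explained_variance=pca.explained_variance_.copy(),
                     fitted_on=tag)
    return model, PCScores(scores, mol_ids)


def project(model: PCAModel, rows) -> PCScores:
    """Project new rows onto a fitted PCA: (rows - means) @ loadings.

    In metric space, ``rows`` must be similarities to the same training
    molecules the model was fitted on, in the same order.
    """
    if isinstance(rows, (FeatureMatrix, SimilarityMatrix)):
        values, mol_ids, _ = _as_rows_any(rows)
    else:
        values = np.atleast_2d(np.asarray(rows, dtype=float))
        mol_ids = [str(i) for i in range(values.shape[0])]
    if values.shape[1] != model.column_means.shape[0]:
        raise ValueError(
            f"row dimensionality {values.shape[1]} does not match the fitted "
            f"space ({model.column_means.shape[0]} dims)")
    return PCScores((values - model.column_means) @ model.loadings, mol_ids)


def _as_rows_any(X) -> tuple[np.ndarray, list[str], str]:
    # like _as_rows but allows rectangular similarity blocks (query x train)
    if isinstance(X, SimilarityMatrix):
        return X.values, list(X.row_ids), X.method
    return _as_rows(X)


def incremental_pc_matrices(scores: PCScores, k_max: int) -> list[np.ndarray]:
    """Read-only views of the leading 1..k_max score columns."""
    if not 1 <= k_max <= scores.scores.shape[1]:
        raise ValueError(f"k_max must be in [1, {scores.scores.shape[1]}]")
    out = []
    for k in range(1, k_max + 1):
        view = scores.scores[:, :k]
        view.flags.writeable = False
        out.append(view)
    return out
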