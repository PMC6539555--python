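"""Model building: RF importance ranking, feedforward dimension selection by
cross-validation, SVR fitting, and independent-set evaluation.

Two model families are built per representation:

* SF-models (selected features): random-forest permutation importance ranks the
  raw dimensions, and a feedforward sweep adds them most-important-first.
* OPC-models (optimized number of principal components): PCA components are
  added in variance order.  In metric space the similarity matrix and the PCA
  are refit inside every cross-validation fold from the fold's training
  molecules only, and held-out molecules enter through their cross-similarity
  rows — otherwise the fold-test molecules would leak into the components.

For each candidate dimension count k an RBF-kernel support-vector regressor is
fitted per fold and scored on the held-out fold; the k minimizing the mean CV
RMSE is selected (ties to the smallest k), the model is refitted on the whole
training set, and the independent validation set is scored once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from .featurize import FeatureMatrix
from .pca import fit_pca, project
from .similarity import SimilarityMatrix, similarity_matrix

__all__ = [
    "SVMSpec", "RankedFeatures", "SelectionCurve", "ModelEvaluation",
    "rf_rank", "feedforward_select", "fit_final", "evaluate",
    "FittedModel", "SelectedFeatureSpace", "VectorPCASpace", "MetricPCASpace",
    "default_k_schedule",
]


@dataclass(frozen=True)
class SVMSpec:
    """RBF-kernel epsilon-SVR with libsvm-style defaults (C=1, gamma=1/d)."""

    C: float = 1.0
    epsilon: float = 0.1
    gamma: str | float = "auto"  # sklearn "auto" == 1 / n_dims

    def build(self) -> SVR:
        return SVR(kernel="rbf", C=self.C, epsilon=self.epsilon, gamma=self.gamma)


@dataclass
class RankedFeatures:
    order: np.ndarray       # dimension indices, most to least important
    importance: np.ndarray  # aligned with the original dimension order

    def __post_init__(self) -> None:
        ranked = self.importance[self.order]
        if np.any(np.diff(ranked) > 1e-12):
            raise ValueError("order is not sorted by non-increasing importance")


@dataclass
class SelectionCurve:
    k_values: list[int]
    mean_cv_pve: np.ndarray
    mean_cv_rmse: np.ndarray
    chosen_k: int


@dataclass
class ModelEvaluation:
    dataset: str
    representation: str
    approach: str
    chosen_k: int
    cv_pve: float
    ivs_pve: float | None
    ivs_rmse: float


def rf_rank(X: FeatureMatrix | np.ndarray, y: np.ndarray, seed: int = 0,
            n_estimators: int = 500, n_repeats: int = 5,
            min_rows: int = 20) -> RankedFeatures:
    """Rank dimensions by random-forest permutation importance (MSE increase).

    A regression forest (one third of the dimensions tried per split) is
    fitted, then each column is permuted in turn and the mean increase in
    squared error over ``n_repeats`` shuffles is the importance.  Ties are
    broken by original dimension index, so the ranking is deterministic under
    a fixed seed.
    """
    M = X.matrix if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if M.shape[0] < min_rows:
        raise ValueError(f"rf_rank needs at least {min_rows} rows, got {M.shape[0]}")
    rf = RandomForestRegressor(n_estimators=n_estimators, max_features=1.0 / 3.0,
                               random_state=seed, n_jobs=1)
    rf.fit(M, y)
    imp = permutation_importance(rf, M, y, scoring="neg_mean_squared_error",
                                 n_repeats=n_repeats, random_state=seed,
                                 n_jobs=1).importances_mean
    order = np.lexsort((np.arange(len(imp)), -imp))
    return RankedFeatures(order=order, importance=imp)


# ---------------------------------------------------------------------------
# Dimension spaces: how the 1..k candidate dimensions are materialized for a
# fold or for the final train/IVS matrices, per modeling approach.
# ---------------------------------------------------------------------------


class SelectedFeatureSpace:
    """Vector space with RF-ranked raw dimensions (SF-models)."""

    def __init__(self, X: np.ndarray, order: np.ndarray):
        self.X = np.asarray(X, dtype=float)
        self.order = np.asarray(order, dtype=int)

    @property
    def k_cap(self) -> int:
        return len(self.order)

    def fold(self, tr: np.ndarray, te: np.ndarray, k_max: int):
        cols = self.order[:k_max]
        return self.X[np.ix_(tr, cols)], self.X[np.ix_(te, cols)]

    def fit_full(self, k_max: int) -> np.ndarray:
        self._k = k_max
        return self.X[:, self.order[:k_max]]

    def transform_query(self, X_query: np.ndarray) -> np.ndarray:
        return np.asarray(X_query, dtype=float)[:, self.order[: self._k]]


class VectorPCASpace:
    """Vector space reduced by PCA, components in variance order (OPC-models)."""

    def __init__(self, X: np.ndarray, refit_per_fold: bool = True):
        self.X = np.asarray(X, dtype=float)
        self.refit_per_fold = refit_per_fold
        self._model = None

    @property
    def k_cap(self) -> int:
        return min(self.X.shape[0] - 1, self.X.shape[1])

    def fold(self, tr: np.ndarray, te: np.ndarray, k_max: int):
        if self.refit_per_fold:
            model, scores = fit_pca(self.X[tr], n_components=min(k_max, len(tr) - 1))
            te_scores = project(model, self.X[te]).scores
            return scores.scores, te_scores
        if self._model is None:
            self._model, self._scores = fit_pca(self.X)
        S = self._scores.scores
        return S[np.ix_(tr, range(k_max))], S[np.ix_(te, range(k_max))]

    def fit_full(self, k_max: int) -> np.ndarray:
        self._full_model, scores = fit_pca(self.X, n_components=k_max)
        return scores.scores

    def transform_query(self, X_query: np.ndarray) -> np.ndarray:
        return project(self._full_model, np.asarray(X_query, dtype=float)).scores


class MetricPCASpace:
    """Metric space: PCA over similarity profiles to the training molecules.

    Built either from a fingerprint matrix (Tanimoto computed on the fly) or
    from a precomputed square similarity matrix covering all molecules (the
    route for graph-based scores).  Fold-wise, a molecule's profile is its
    similarity row restricted to the fold-train columns, and the PCA is refit
    on the fold-train square block.
    """

    def __init__(self, source: FeatureMatrix | SimilarityMatrix,
                 train_ids: list[str], refit_per_fold: bool = True):
        self.train_ids = list(train_ids)
        if isinstance(source, FeatureMatrix):
            self.square = similarity_matrix(source.rows(self.train_ids))
            self._fp = source
        else:
            if not source.is_square:
                raise ValueError("precomputed similarity source must be square")
            self.square = source.block(self.train_ids, self.train_ids)
            self._fp = None
            self._full_source = source
        self.refit_per_fold = refit_per_fold
        self._S = self.square.values

    @property
    def k_cap(self) -> int:
        return len(self.train_ids) - 1

    def fold(self, tr: np.ndarray, te: np.ndarray, k_max: int):
        if self.refit_per_fold:
            S_tr = self._S[np.ix_(tr, tr)]
            model, scores = fit_pca(S_tr, n_components=min(k_max, len(tr) - 1))
            te_scores = project(model, self._S[np.ix_(te, tr)]).scores
            return scores.scores, te_scores
        if not hasattr(self, "_lax_scores"):
            _, self._lax_scores = fit_pca(self._S)
        S = self._lax_scores.scores
        return S[np.ix_(tr, range(k_max))], S[np.ix_(te, range(k_max))]

    def fit_full(self, k_max: int) -> np.ndarray:
        self._full_model, scores = fit_pca(self._S, n_components=k_max)
        return scores.scores

    def cross_block(self, query_ids: list[str]) -> np.ndarray:
        if self._fp is not None:
            return similarity_matrix(self._fp.rows(self.train_ids),
                                     self._fp.rows(query_ids)).values
        return self._full_source.block(query_ids, self.train_ids).values

    def transform_query(self, query) -> np.ndarray:
        if isinstance(query, list):
            rows = self.cross_block(query)
        elif isinstance(query, SimilarityMatrix):
            rows = query.block(query.row_ids, self.train_ids).values
        else:
            rows = np.asarray(query, dtype=float)
        return project(self._full_model, rows).scores


def default_k_schedule(k_cap: int, dense_until: int = 30, step: int = 5,
                       ) -> list[int]:
    """1..min(dense_until, k_cap) one at a time, then every ``step`` to k_cap."""
    ks = list(range(1, min(dense_until, k_cap) + 1))
    ks += list(range(min(dense_until, k_cap) + step, k_cap + 1, step))
    return ks


def evaluate(y_true: np.ndarray, y_pred: np.ndarray,
             ) -> tuple[float | None, float]:
    """(PVE, RMSE) of predictions: PVE = 1 - SS_res/SS_tot on the given set.

    PVE is undefined (None) when y_true is constant; RMSE is still returned.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    resid = y_true - y_pred
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        return None, rmse
    return 1.0 - float(np.sum(resid ** 2)) / ss_tot, rmse


def feedforward_select(space, y: np.ndarray, k_schedule: list[int] | None = None,
                       folds: int = 5, seed: int = 0,
                       model_spec: SVMSpec = SVMSpec()) -> SelectionCurve:
    """Sweep dimension counts under N-fold CV and pick the best k.

    For each k in the schedule, an SVR is fitted per fold on the leading k
    dimensions of the fold-train block and scored on the held-out fold; the
    fold-mean PVE and RMSE are recorded and the k with the smallest mean RMSE
    (ties to the smallest k) is chosen.
    """
    y = np.asarray(y, dtype=float)
    if folds < 2:
        raise ValueError("need at least 2 CV folds")
    if k_schedule is None:
        k_schedule = default_k_schedule(space.k_cap)
    k_schedule = sorted(set(int(k) for k in k_schedule))
    if not k_schedule or k_schedule[0] < 1 or k_schedule[-1] > space.k_cap:
        raise ValueError(f"k schedule must lie within [1, {space.k_cap}]")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    pve = np.zeros((folds, len(k_schedule)))
    rmse = np.zeros((folds, len(k_schedule)))
    for f, (tr, te) in enumerate(kf.split(y)):
        if len(np.unique(y[tr])) < 2:
            raise ValueError(f"fold {f} has fewer than 2 distinct y values")
        Xtr, Xte = space.fold(tr, te, k_schedule[-1])
        for j, k in enumerate(k_schedule):
            kk = min(k, Xtr.shape[1])
            svr = model_spec.build()
            svr.fit(Xtr[:, :kk], y[tr])
            p, r = evaluate(y[te], svr.predict(Xte[:, :kk]))
            pve[f, j] = np.nan if p is None else p
            rmse[f, j] = r
    mean_pve = np.nanmean(pve, axis=0)
    mean_rmse = rmse.mean(axis=0)
    chosen = k_schedule[int(np.argmin(mean_rmse))]  # argmin takes first == smallest k
    return SelectionCurve(k_values=k_schedule, mean_cv_pve=mean_pve,
                          mean_cv_rmse=mean_rmse, chosen_k=chosen)


@dataclass
class FittedModel:
    space: object
    svr: SVR
    k: int

    def predict(self, query) -> np.ndarray:
        return self.svr.predict(self.space.transform_query(query)[:, : self.k])


def fit_final(space, y: np.ndarray, k: int,
              model_spec: SVMSpec = SVMSpec()) -> FittedModel:
    """Refit on the whole training set with the selected dimension count."""
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("cannot fit a regression model to constant y")
    X = space.fit_full(k)
    k_eff = min(k, X.shape[1])
    svr = model_spec.build()
    svr.fit(X[:, :k_eff], y)
    return FittedModel(space=space, svr=svr, k=k_eff)
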