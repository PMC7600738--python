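"""Bacterial vs. fungal origin classifiers.

Three sklearn-style estimators, all binary with "bacterium" as the positive
class:

* :class:`Map4KernelSVC` — SVM on a precomputed kernel of estimated Jaccard
  similarities between MAP4 signatures, C selected by stratified 5-fold CV
  maximizing ROC AUC, probabilities via Platt (sigmoid) scaling.
* :class:`Map4KNNClassifier` — k-nearest neighbors under the estimated
  Jaccard distance (1 - similarity), k selected the same way, unweighted
  neighbor vote.
* :class:`PhyschemSVC` — RBF-kernel SVM on standardized physico-chemical
  properties (MW, fsp3C, HBA, HBD, AlogP, TPSA, Joback boiling point), C and
  gamma selected by the same CV.

Class weights are inversely proportional to class frequency throughout.
Labels are encoded internally as bacterium = 1 so that validation ROC AUC
is always computed with "bacterium" positive. Hyperparameter selection is
an explicit stratified-CV loop (kernel and distance matrices are sliced on
both axes per fold), which keeps the search deterministic under the seed
and works with precomputed kernels inside Platt calibration.

The estimators take a signature matrix (or property matrix) as X, so they
compose with sklearn model selection; :class:`OriginModel` wraps a fitted
estimator with its training data for end-to-end prediction on SMILES.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.calibration import CalibratedClassifierCV
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .fingerprint import ENCODING_VERSION, signatures_for, similarity_matrix
from .properties import CONTINUOUS_PROPERTIES, annotate_dataset
from .records import Dataset

POSITIVE_CLASS = "bacterium"
NEGATIVE_CLASS = "fungus"

C_GRID = (0.1, 1.0, 10.0, 100.0, 1000.0)
K_GRID = (5, 7, 9, 11)
GAMMA_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)
N_FOLDS = 5

#: property columns fed to the physico-chemical SVM
PHYSCHEM_FEATURES = list(CONTINUOUS_PROPERTIES)


def kernel_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Similarity kernel between two signature stacks: entry (i, j) is the
    estimated Jaccard similarity of A_i and B_j."""
    return similarity_matrix(A, B)


def _encode_labels(y) -> np.ndarray:
    """bacterium -> 1, fungus -> 0; also accepts pre-encoded 0/1 labels."""
    y = np.asarray(y)
    if y.dtype.kind in "USO":
        known = {POSITIVE_CLASS, NEGATIVE_CLASS}
        bad = sorted(set(map(str, y)) - known)
        if bad:
            raise ValueError(f"labels must be in {sorted(known)}, found {bad}")
        return (y == POSITIVE_CLASS).astype(int)
    return y.astype(int)


def _check_two_classes(y01: np.ndarray) -> None:
    if np.unique(y01).size < 2:
        raise ValueError("training labels contain a single class")


def _cv(seed: int) -> StratifiedKFold:
    return StratifiedKFold(n_splits=N_FOLDS, shuffle=True, random_state=seed)


def _select_by_cv(
    build: Callable[[dict], object],
    grid: Sequence[dict],
    M: np.ndarray,
    y01: np.ndarray,
    seed: int,
    pairwise: bool,
) -> tuple[dict, dict]:
    """Pick the grid point with the highest mean validation ROC AUC.

    ``M`` is either a square precomputed kernel/distance matrix (sliced on
    both axes per fold) or a plain feature matrix. Ties keep the earliest
    grid entry, so selection is deterministic under the seed.
    """
    folds = list(_cv(seed).split(np.zeros_like(y01), y01))
    results = {"params": list(grid), "mean_auc": []}
    best: tuple[float, int] | None = None
    for gi, params in enumerate(grid):
        aucs = []
        for tr, te in folds:
            est = build(params)
            if pairwise:
                est.fit(M[np.ix_(tr, tr)], y01[tr])
                X_te = M[np.ix_(te, tr)]
            else:
                est.fit(M[tr], y01[tr])
                X_te = M[te]
            if hasattr(est, "decision_function"):
                score = est.decision_function(X_te)
            else:
                score = est.predict_proba(X_te)[:, 1]
            aucs.append(roc_auc_score(y01[te], score))
        mean_auc = float(np.mean(aucs))
        results["mean_auc"].append(mean_auc)
        if best is None or mean_auc > best[0]:
            best = (mean_auc, gi)
    return dict(grid[best[1]]), results


class _PositiveProbaMixin:
    """Shared prediction surface: classes_ = [bacterium, fungus], columns of
    ``predict_proba`` in that order, labels thresholded at 0.5."""

    classes_ = np.array([POSITIVE_CLASS, NEGATIVE_CLASS])

    def predict_proba(self, X) -> np.ndarray:
        inner = self._inner_proba(X)  # columns: [fungus(0), bacterium(1)]
        return np.column_stack([inner[:, 1], inner[:, 0]])

    def predict_proba_positive(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 0]

    def predict(self, X) -> np.ndarray:
        p = self.predict_proba_positive(X)
        return np.where(p >= 0.5, POSITIVE_CLASS, NEGATIVE_CLASS)


def _platt_svc(svc_params: dict, seed: int) -> CalibratedClassifierCV:
    """SVC wrapped in sigmoid (Platt) calibration fitted on internal
    cross-validated decision values."""
    return CalibratedClassifierCV(
        SVC(class_weight="balanced", random_state=seed, **svc_params),
        method="sigmoid",
        cv=_cv(seed),
        ensemble=False,
    )


class Map4KernelSVC(_PositiveProbaMixin, ClassifierMixin, BaseEstimator):
    """Precomputed-kernel SVM over MAP4 signatures.

    Parameters
    ----------
    C_grid : candidate regularization values searched by stratified
        5-fold cross-validation maximizing validation ROC AUC.
    seed : controls fold shuffling and Platt calibration.

    Attributes (after fit)
    ----------------------
    X_fit_ : training signatures retained for kernel evaluation.
    best_C_ : selected regularization constant.
    cv_results_ : per-grid-point mean validation AUC.
    """

    def __init__(self, C_grid: Sequence[float] = C_GRID, seed: int = 0):
        self.C_grid = C_grid
        self.seed = seed

    def fit(self, X: np.ndarray, y) -> "Map4KernelSVC":
        X = np.asarray(X)
        y01 = _encode_labels(y)
        _check_two_classes(y01)
        K = kernel_matrix(X, X)
        grid = [{"C": float(c)} for c in self.C_grid]
        best, self.cv_results_ = _select_by_cv(
            lambda p: SVC(
                kernel="precomputed", class_weight="balanced",
                random_state=self.seed, **p,
            ),
            grid, K, y01, self.seed, pairwise=True,
        )
        self.best_C_ = best["C"]
        self.estimator_ = _platt_svc({"kernel": "precomputed", **best}, self.seed)
        self.estimator_.fit(K, y01)
        self.X_fit_ = X
        return self

    def _inner_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "estimator_")
        return self.estimator_.predict_proba(kernel_matrix(np.asarray(X), self.X_fit_))

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "estimator_")
        K = kernel_matrix(np.asarray(X), self.X_fit_)
        return self.estimator_.calibrated_classifiers_[0].estimator.decision_function(K)


class _StableVoteKNN:
    """Unweighted k-NN vote on a precomputed distance matrix.

    Distance ties are broken deterministically by training order (stable
    argsort), unlike the library neighbor search whose tie order is
    unspecified.
    """

    def __init__(self, n_neighbors: int):
        self.n_neighbors = n_neighbors

    def fit(self, D: np.ndarray, y01: np.ndarray) -> "_StableVoteKNN":
        self.y_ = np.asarray(y01, dtype=float)
        return self

    def predict_proba(self, D: np.ndarray) -> np.ndarray:
        order = np.argsort(D, axis=1, kind="stable")[:, : self.n_neighbors]
        pos = self.y_[order].mean(axis=1)
        return np.column_stack([1.0 - pos, pos])


class Map4KNNClassifier(_PositiveProbaMixin, ClassifierMixin, BaseEstimator):
    """k-nearest-neighbor origin classifier under estimated Jaccard distance.

    The vote is unweighted: the positive probability of a query is the
    fraction of its k nearest training molecules labeled "bacterium".
    Distance ties resolve by training insertion order (= ID order).
    """

    def __init__(self, k_grid: Sequence[int] = K_GRID, seed: int = 0):
        self.k_grid = k_grid
        self.seed = seed

    def fit(self, X: np.ndarray, y) -> "Map4KNNClassifier":
        X = np.asarray(X)
        y01 = _encode_labels(y)
        _check_two_classes(y01)
        max_train = len(y01) - len(y01) // N_FOLDS  # fold training size
        grid = [{"n_neighbors": int(k)} for k in self.k_grid if k <= max_train]
        if not grid:
            raise ValueError(
                f"all k in {list(self.k_grid)} exceed the training size {len(y01)}"
            )
        D = 1.0 - kernel_matrix(X, X)
        best, self.cv_results_ = _select_by_cv(
            lambda p: _StableVoteKNN(**p), grid, D, y01, self.seed, pairwise=True
        )
        self.best_k_ = best["n_neighbors"]
        self.estimator_ = _StableVoteKNN(**best).fit(D, y01)
        self.X_fit_ = X
        return self

    def _inner_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "estimator_")
        D = 1.0 - kernel_matrix(np.asarray(X), self.X_fit_)
        return self.estimator_.predict_proba(D)


class PhyschemSVC(_PositiveProbaMixin, ClassifierMixin, BaseEstimator):
    """RBF-kernel SVM on standardized physico-chemical property vectors.

    The scaler is fitted on training data only; zero-variance columns are
    dropped with a warning before scaling.
    """

    def __init__(
        self,
        C_grid: Sequence[float] = C_GRID,
        gamma_grid: Sequence[float] = GAMMA_GRID,
        seed: int = 0,
    ):
        self.C_grid = C_grid
        self.gamma_grid = gamma_grid
        self.seed = seed

    def fit(self, X: np.ndarray, y) -> "PhyschemSVC":
        X = np.asarray(X, dtype=float)
        y01 = _encode_labels(y)
        _check_two_classes(y01)
        keep = X.std(axis=0) > 0.0
        if not keep.all():
            warnings.warn(
                f"dropping constant feature columns {np.flatnonzero(~keep).tolist()}",
                stacklevel=2,
            )
        self.feature_mask_ = keep
        self.scaler_ = StandardScaler().fit(X[:, keep])
        Xs = self.scaler_.transform(X[:, keep])
        grid = [
            {"C": float(c), "gamma": float(g)}
            for c in self.C_grid
            for g in self.gamma_grid
        ]
        best, self.cv_results_ = _select_by_cv(
            lambda p: SVC(
                kernel="rbf", class_weight="balanced", random_state=self.seed, **p
            ),
            grid, Xs, y01, self.seed, pairwise=False,
        )
        self.best_C_ = best["C"]
        self.best_gamma_ = best["gamma"]
        self.estimator_ = _platt_svc({"kernel": "rbf", **best}, self.seed)
        self.estimator_.fit(Xs, y01)
        return self

    def _prepare(self, X) -> np.ndarray:
        return self.scaler_.transform(np.asarray(X, dtype=float)[:, self.feature_mask_])

    def _inner_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "estimator_")
        return self.estimator_.predict_proba(self._prepare(X))

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "estimator_")
        inner = self.estimator_.calibrated_classifiers_[0].estimator
        return inner.decision_function(self._prepare(X))


FORMAT_VERSION = 1


@dataclass
class OriginModel:
    """A fitted origin classifier bundled with its training context.

    Carries everything prediction on raw SMILES needs: the estimator, the
    training signatures (for kernels and nearest-neighbor reporting), the
    training IDs and labels, the model kind, the seed, and the fingerprint
    encoding version (models refuse to load across incompatible encodings).
    """

    kind: str
    estimator: object
    train_ids: list[str]
    train_labels: list[str]
    train_signatures: np.ndarray
    seed: int
    hyperparameters: dict = field(default_factory=dict)
    encoding_version: str = ENCODING_VERSION
    format_version: int = FORMAT_VERSION

    def _features(self, ds: Dataset) -> np.ndarray:
        if self.kind == "physchem-svm":
            props = annotate_dataset(ds, ranks=False)
            return props[PHYSCHEM_FEATURES].to_numpy(dtype=float)
        return signatures_for(ds.smiles)

    def predict_table(self, ds: Dataset) -> pd.DataFrame:
        """Per-molecule prediction table: probabilities for both classes, a
        0.5-threshold label, and the nearest training molecule with its
        estimated Jaccard distance."""
        X = self._features(ds)
        sigs = X if self.kind != "physchem-svm" else signatures_for(ds.smiles)
        p_bact = self.estimator.predict_proba_positive(X)
        D = 1.0 - similarity_matrix(sigs, self.train_signatures)
        nn_idx = D.argmin(axis=1)
        return pd.DataFrame(
            {
                "compound_id": ds.ids,
                "smiles": ds.smiles,
                "p_fungal": 1.0 - p_bact,
                "p_bacterial": p_bact,
                "label": np.where(p_bact >= 0.5, POSITIVE_CLASS, NEGATIVE_CLASS),
                "nn_id": [self.train_ids[i] for i in nn_idx],
                "nn_jaccard_distance": D[np.arange(len(ds)), nn_idx],
            }
        )

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path: str | Path) -> "OriginModel":
        model = joblib.load(path)
        if not isinstance(model, cls):
            raise TypeError(f"{path} does not contain an OriginModel")
        if model.encoding_version != ENCODING_VERSION:
            raise ValueError(
                f"model was built with fingerprint encoding "
                f"{model.encoding_version!r}, this build uses {ENCODING_VERSION!r}"
            )
        return model


def _training_labels(train: Dataset) -> np.ndarray:
    y = np.asarray(train.origins)
    if not set(y) <= {POSITIVE_CLASS, NEGATIVE_CLASS}:
        bad = sorted(set(y) - {POSITIVE_CLASS, NEGATIVE_CLASS})
        raise ValueError(f"training origins must be labeled, found {bad}")
    return y


def train_map4_svm(
    train: Dataset, signatures: np.ndarray | None = None, seed: int = 0
) -> OriginModel:
    """Fit the MAP4 kernel SVM on a labeled, deduplicated dataset."""
    y = _training_labels(train)
    X = signatures if signatures is not None else signatures_for(train.smiles)
    est = Map4KernelSVC(seed=seed).fit(X, y)
    return OriginModel(
        kind="map4-svm",
        estimator=est,
        train_ids=train.ids,
        train_labels=y.tolist(),
        train_signatures=X,
        seed=seed,
        hyperparameters={"C": est.best_C_},
    )


def train_map4_knn(
    train: Dataset, signatures: np.ndarray | None = None, seed: int = 0
) -> OriginModel:
    """Fit the MAP4 k-NN classifier on a labeled, deduplicated dataset."""
    y = _training_labels(train)
    X = signatures if signatures is not None else signatures_for(train.smiles)
    est = Map4KNNClassifier(seed=seed).fit(X, y)
    return OriginModel(
        kind="map4-knn",
        estimator=est,
        train_ids=train.ids,
        train_labels=y.tolist(),
        train_signatures=X,
        seed=seed,
        hyperparameters={"k": est.best_k_},
    )


def train_physchem_svm(
    train: Dataset, properties: pd.DataFrame | None = None, seed: int = 0
) -> OriginModel:
    """Fit the physico-chemical RBF SVM on a labeled, deduplicated dataset."""
    y = _training_labels(train)
    props = properties if properties is not None else annotate_dataset(train, ranks=False)
    X = props[PHYSCHEM_FEATURES].to_numpy(dtype=float)
    est = PhyschemSVC(seed=seed).fit(X, y)
    return OriginModel(
        kind="physchem-svm",
        estimator=est,
        train_ids=train.ids,
        train_labels=y.tolist(),
        train_signatures=signatures_for(train.smiles),
        seed=seed,
        hyperparameters={"C": est.best_C_, "gamma": est.best_gamma_},
    )


def predict_origin(model: OriginModel, ds: Dataset) -> pd.DataFrame:
    """Predict bacterial/fungal origin for a dataset; see
    :meth:`OriginModel.predict_table`."""
    return model.predict_table(ds)
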