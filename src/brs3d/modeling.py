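"""Selectivity models: RF feature ranking and grid-searched RBF-SVM.

Two scikit-learn estimators implement the QSAR stage:

``SelectivityRegressor``
    predicts the selectivity ratio SR with epsilon-SVR (RBF kernel);
``SelectivityClassifier``
    discriminates T1- from T2-selective compounds with SVC (RBF kernel).

Both first rank the profile columns with a seeded random forest
(impurity importances), keep the top ``feature_fraction`` of them, then grid
search C and gamma with 10-fold cross-validation — scored by q2 (pooled
out-of-fold predictions) for regression and by ROC AUC of pooled out-of-fold
decision values for discrimination — and refit on the full training set.
Ties in the grid go to the smaller C, then the smaller gamma.
"""

from __future__ import annotations

import numbers

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC, SVR

__all__ = [
    "SelectivityRegressor",
    "SelectivityClassifier",
    "rank_features",
    "feature_subsets",
    "tune_and_fit",
    "predict",
    "DEFAULT_C_GRID",
    "DEFAULT_GAMMA_GRID",
    "DEFAULT_FRACTIONS",
]

DEFAULT_C_GRID = tuple(2.0 ** np.arange(-2, 11))  # 2^-2 .. 2^10
DEFAULT_GAMMA_GRID = tuple(2.0 ** np.arange(-10, 3))  # 2^-10 .. 2^2
DEFAULT_FRACTIONS = (0.01, 0.05, 0.10, 0.20, 0.40, 0.60, 0.80, 1.0)


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X)
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])


def rank_features(
    X,
    y,
    task: str = "regression",
    seed: int = 0,
    n_trees: int = 500,
) -> list:
    """Random-forest importance ranking, sorted by importance descending
    (ties broken by feature name ascending).  Returns (name, importance) pairs."""
    Xf = _as_frame(X)
    y = np.asarray(y)
    if Xf.isna().any().any():
        raise ValueError("feature table contains missing values")
    if len(Xf) < 2:
        raise ValueError("need at least 2 samples")
    if len(np.unique(y)) < 2:
        raise ValueError("response is constant; ranking undefined")
    if task == "regression":
        rf = RandomForestRegressor(n_estimators=n_trees, random_state=seed, n_jobs=1)
    elif task == "discrimination":
        rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    else:
        raise ValueError(f"unknown task {task!r}")
    rf.fit(Xf.to_numpy(), y)
    pairs = list(zip(Xf.columns, rf.feature_importances_))
    return sorted(pairs, key=lambda p: (-p[1], p[0]))


def feature_subsets(ranking: list, fractions=DEFAULT_FRACTIONS) -> dict:
    """Nested top-fraction subsets of a ranking; size = round(f * K), min 1."""
    if not ranking:
        raise ValueError("empty ranking")
    names = [name for name, _ in ranking]
    out = {}
    for f in fractions:
        if not (isinstance(f, numbers.Real) and 0 < f <= 1):
            raise ValueError(f"fraction must lie in (0, 1], got {f}")
        size = max(1, int(np.floor(len(names) * float(f) + 0.5)))
        out[float(f)] = names[:size]
    return out


def _q2(y_obs: np.ndarray, y_pred: np.ndarray) -> float:
    ss_res = float(np.sum((y_obs - y_pred) ** 2))
    ss_tot = float(np.sum((y_obs - y_obs.mean()) ** 2))
    return 1.0 - ss_res / ss_tot


def _rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the Mann-Whitney rank statistic (ties counted half)."""
    from scipy.stats import rankdata

    pos = labels.astype(bool)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    return (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


class _BaseSelectivityModel(BaseEstimator):
    """Shared RF-selection + SVM grid-search machinery."""

    _task = ""

    def __init__(
        self,
        feature_fraction: float = 1.0,
        n_trees: int = 500,
        c_grid=None,
        gamma_grid=None,
        cv: int = 10,
        epsilon: float = 0.1,
        random_state: int = 0,
    ):
        self.feature_fraction = feature_fraction
        self.n_trees = n_trees
        self.c_grid = c_grid
        self.gamma_grid = gamma_grid
        self.cv = cv
        self.epsilon = epsilon
        self.random_state = random_state

    # -- subclass hooks -----------------------------------------------------

    def _make_svm(self, c: float, gamma: float):
        raise NotImplementedError

    def _cv_metric(self, X: np.ndarray, y: np.ndarray, c: float, gamma: float, folds) -> float:
        raise NotImplementedError

    def _make_folds(self, y: np.ndarray):
        raise NotImplementedError

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y):
        Xf = _as_frame(X)
        y = np.asarray(y)
        if len(Xf) != len(y):
            raise ValueError("X and y length mismatch")
        if len(Xf) < self.cv:
            raise ValueError(f"need at least cv={self.cv} samples")
        self.ranking_ = rank_features(
            Xf, y, task=self._task, seed=self.random_state, n_trees=self.n_trees
        )
        n_keep = max(1, int(np.floor(len(self.ranking_) * self.feature_fraction + 0.5)))
        self.features_used_ = [name for name, _ in self.ranking_[:n_keep]]
        Xs = Xf[self.features_used_].to_numpy(dtype=float)

        c_grid = sorted(self.c_grid if self.c_grid is not None else DEFAULT_C_GRID)
        gamma_grid = sorted(
            self.gamma_grid if self.gamma_grid is not None else DEFAULT_GAMMA_GRID
        )
        folds = list(self._make_folds(y).split(Xs, y))
        best = None
        for c in c_grid:
            for gamma in gamma_grid:
                metric = self._cv_metric(Xs, y, c, gamma, folds)
                if best is None or metric > best[0]:
                    best = (metric, c, gamma)
        self.cv_score_, self.C_, self.gamma_ = best
        self.model_ = self._make_svm(self.C_, self.gamma_).fit(Xs, y)
        return self

    def _check_matrix(self, X) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError(f"{type(self).__name__} is not fitted")
        if isinstance(X, pd.DataFrame):
            missing = [f for f in self.features_used_ if f not in X.columns]
            if missing:
                raise KeyError(f"missing feature columns: {missing}")
            return X[self.features_used_].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.shape[1] == len(self.features_used_):
            return X
        raise ValueError(
            f"expected {len(self.features_used_)} feature columns, got {X.shape[1]}; "
            "pass a DataFrame for name-based alignment"
        )


class SelectivityRegressor(RegressorMixin, _BaseSelectivityModel):
    """epsilon-SVR on RF-selected profile features, tuned by 10-fold q2."""

    _task = "regression"

    def _make_svm(self, c, gamma):
        return SVR(kernel="rbf", C=c, gamma=gamma, epsilon=self.epsilon)

    def _make_folds(self, y):
        return KFold(n_splits=self.cv, shuffle=True, random_state=self.random_state)

    def _cv_metric(self, X, y, c, gamma, folds):
        oof = np.empty_like(y, dtype=float)
        for tr, te in folds:
            m = self._make_svm(c, gamma).fit(X[tr], y[tr])
            oof[te] = m.predict(X[te])
        return _q2(y, oof)

    def fit(self, X, y):
        y = np.asarray(y, dtype=float)
        if np.ptp(y) == 0:
            raise ValueError("constant response; regression undefined")
        return super().fit(X, y)

    def predict(self, X):
        Xm = self._check_matrix(X)
        return self.model_.predict(Xm)


class SelectivityClassifier(ClassifierMixin, _BaseSelectivityModel):
    """RBF-SVC on RF-selected profile features, tuned by 10-fold CV AUC.

    ``predict`` thresholds the continuous decision value at 0; stratified
    folds keep both classes present in every training fold.
    """

    _task = "discrimination"

    def _make_svm(self, c, gamma):
        return SVC(kernel="rbf", C=c, gamma=gamma)

    def _make_folds(self, y):
        return StratifiedKFold(
            n_splits=self.cv, shuffle=True, random_state=self.random_state
        )

    def _cv_metric(self, X, y, c, gamma, folds):
        pos = self.classes_[1]
        oof = np.empty(len(y), dtype=float)
        for tr, te in folds:
            m = self._make_svm(c, gamma).fit(X[tr], y[tr])
            oof[te] = m.decision_function(X[te])
        return _rank_auc(oof, y == pos)

    def fit(self, X, y):
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(f"need exactly 2 classes, got {len(self.classes_)}")
        return super().fit(X, y)

    def decision_function(self, X):
        Xm = self._check_matrix(X)
        return self.model_.decision_function(Xm)

    def predict(self, X):
        scores = self.decision_function(X)
        return np.where(scores > 0, self.classes_[1], self.classes_[0])


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------


def tune_and_fit(
    X,
    y,
    task: str = "regression",
    grid: tuple | None = None,
    folds: int = 10,
    seed: int = 0,
    feature_fraction: float = 1.0,
    features: list | None = None,
):
    """Grid-search C/gamma with ``folds``-fold CV and refit on all of X.

    ``features`` restricts the table to an explicit column list (skipping the
    internal RF selection); otherwise the top ``feature_fraction`` of the RF
    ranking is used.
    """
    cls = {"regression": SelectivityRegressor, "discrimination": SelectivityClassifier}
    if task not in cls:
        raise ValueError(f"unknown task {task!r}")
    kwargs = dict(cv=folds, random_state=seed, feature_fraction=feature_fraction)
    if grid is not None:
        kwargs["c_grid"], kwargs["gamma_grid"] = grid
    Xf = _as_frame(X)
    if features is not None:
        Xf = Xf[list(features)]
        kwargs["feature_fraction"] = 1.0
    return cls[task](**kwargs).fit(Xf, y)


def predict(model, X_new):
    """SR predictions (regression) or (decision score, hard label) tuples
    (discrimination), aligned to the model's feature names."""
    if isinstance(model, SelectivityClassifier):
        return model.decision_function(X_new), model.predict(X_new)
    return model.predict(X_new)
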