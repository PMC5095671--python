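"""Model assessment: q2/RMSE/r2, confusion metrics, ROC AUC, resampling,
Y-randomization, applicability domain (Williams plot) and PCA interpretation.

Conventions
-----------
* q2 = 1 - sum((y - yhat)^2) / sum((y - ybar)^2), computed on out-of-fold or
  test predictions; may be negative for models worse than the mean.
* r2 is the squared Pearson correlation of observed vs predicted.
* SE = TP/(TP+FN), SP = TN/(TN+FP), ACC = (TP+TN)/N and the Matthews
  correlation coefficient; any metric whose denominator vanishes is 0.
* Leverage h = diag(X (X'X)^-1 X') on the intercept-augmented design; the
  warning leverage is h* = 3p/n with p = number of features + 1.  Compounds
  with h > h* or |standardized residual| > 3 fall outside the domain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .dataprep import PairDataset, split_train_test
from .modeling import (
    SelectivityClassifier,
    SelectivityRegressor,
    _as_frame,
    _q2,
    tune_and_fit,
)

__all__ = [
    "RegressionMetrics",
    "ConfusionCounts",
    "ADReport",
    "regression_metrics",
    "classification_metrics",
    "roc_auc",
    "resample_validate",
    "y_randomization",
    "applicability_domain",
    "warning_leverage",
    "pca_top_features",
    "correlation_plot",
    "williams_plot",
    "y_randomization_plot",
]

IN_DOMAIN = "IN_DOMAIN"
LEVERAGE_OUTLIER = "LEVERAGE_OUTLIER"
RESPONSE_OUTLIER = "RESPONSE_OUTLIER"
BOTH = "BOTH"


@dataclass(frozen=True)
class RegressionMetrics:
    q2: float
    r2: float
    rmse: float


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn < 1:
            raise ValueError("confusion counts sum to zero")


@dataclass
class ADReport:
    """Per-compound leverage/residual diagnostics plus the domain threshold."""

    table: pd.DataFrame  # columns: set, leverage, std_residual, flag
    h_star: float
    p: int
    n_train: int


def regression_metrics(y_obs, y_pred) -> RegressionMetrics:
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_obs.shape != y_pred.shape or y_obs.ndim != 1 or len(y_obs) < 2:
        raise ValueError("need two equal-length vectors of >= 2 observations")
    if np.ptp(y_obs) == 0:
        raise ValueError("constant observations; q2 and r2 undefined")
    q2 = _q2(y_obs, y_pred)
    rmse = float(np.sqrt(np.mean((y_obs - y_pred) ** 2)))
    if np.ptp(y_pred) == 0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(y_obs, y_pred)[0, 1] ** 2)
    return RegressionMetrics(q2=float(q2), r2=r2, rmse=rmse)


def classification_metrics(c: ConfusionCounts) -> tuple:
    """(SE, SP, ACC, MCC); a vanishing denominator makes that metric 0."""
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn

    def ratio(num, den):
        return num / den if den > 0 else 0.0

    se = ratio(tp, tp + fn)
    sp = ratio(tn, tn + fp)
    acc = ratio(tp + tn, tp + tn + fp + fn)
    mcc_den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(mcc_den) if mcc_den > 0 else 0.0
    return float(se), float(sp), float(acc), float(mcc)


def roc_auc(scores, labels) -> float:
    """AUC = P(score+ > score-) + 0.5 P(tie), via the Mann-Whitney rank sum."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# Resampling and Y-randomization
# ---------------------------------------------------------------------------


def _split_xy(features: pd.DataFrame, pairs: PairDataset, task: str):
    frame = pairs.frame if task == "regression" else pairs.selective
    ids = frame["compound_id"].to_numpy()
    X = features.loc[ids]
    y = frame["sr"].to_numpy() if task == "regression" else frame["label"].to_numpy()
    split = frame["split"].to_numpy()
    return X, y, split


def resample_validate(
    features: pd.DataFrame,
    pairs: PairDataset,
    task: str = "regression",
    n_repeats: int = 100,
    test_fraction: float = 0.2,
    seed: int = 0,
    **model_kwargs,
) -> pd.DataFrame:
    """Repeat the 4:1 split + tune/fit/evaluate cycle ``n_repeats`` times.

    Returns one row per repeat with the training 10-fold CV metric and the
    test metrics; summary statistics live in ``.attrs['summary']``.
    """
    rows = []
    for rep in range(n_repeats):
        rep_seed = int((seed * 100003 + rep * 7919) % (2**31 - 1))
        ds = split_train_test(pairs, test_fraction=test_fraction, seed=rep_seed)
        X, y, split = _split_xy(features, ds, task)
        train, test = split == "TRAIN", split == "TEST"
        model = tune_and_fit(
            X[train], y[train], task=task, seed=rep_seed, **model_kwargs
        )
        if task == "regression":
            m = regression_metrics(y[test], model.predict(X[test]))
            rows.append(
                {
                    "repeat": rep,
                    "q2_cv": model.cv_score_,
                    "r2_test": m.r2,
                    "rmse_test": m.rmse,
                }
            )
        else:
            pos = model.classes_[1]
            scores = model.decision_function(X[test])
            rows.append(
                {
                    "repeat": rep,
                    "auc_cv": model.cv_score_,
                    "auc_test": roc_auc(scores, y[test] == pos),
                    "acc_test": float(np.mean(model.predict(X[test]) == y[test])),
                }
            )
    table = pd.DataFrame(rows).set_index("repeat")
    table.attrs["summary"] = {
        col: {"mean": float(table[col].mean()), "sd": float(table[col].std())}
        for col in table.columns
    }
    return table


def y_randomization(
    features: pd.DataFrame,
    pairs: PairDataset,
    task: str = "regression",
    n_shuffles: int = 500,
    seed: int = 0,
    **model_kwargs,
) -> pd.DataFrame:
    """Scramble-stability test: permute the response, refit, collect metrics.

    The true model is tuned once; shuffled models are refit at the true
    model's (C, gamma) with the descriptors untouched.  Row 'true' holds the
    unshuffled metrics; ``q2_test`` is the predictive-q2 form on the test set
    (may be negative).
    """
    if task != "regression":
        raise ValueError("Y-randomization is defined here for the regression task")
    X, y, split = _split_xy(features, pairs, task)
    train, test = split == "TRAIN", split == "TEST"
    if not test.any():
        raise ValueError("pair dataset has no TEST rows; split it first")
    Xtr = _as_frame(X[train])
    ytr = np.asarray(y[train], dtype=float)
    model = tune_and_fit(Xtr, ytr, task=task, seed=seed, **model_kwargs)
    Xte = X[test]
    yte = np.asarray(y[test], dtype=float)

    from sklearn.model_selection import KFold
    from sklearn.svm import SVR

    Xtr_m = Xtr[model.features_used_].to_numpy(dtype=float)
    Xte_m = _as_frame(Xte)[model.features_used_].to_numpy(dtype=float)
    folds = list(
        KFold(n_splits=model.cv, shuffle=True, random_state=model.random_state).split(Xtr_m)
    )

    def eval_fit(y_fit: np.ndarray, tag) -> dict:
        # refit at the true model's hyperparameters; descriptors untouched
        def svm():
            return SVR(kernel="rbf", C=model.C_, gamma=model.gamma_, epsilon=model.epsilon)

        oof = np.empty_like(y_fit)
        for tr_i, te_i in folds:
            oof[te_i] = svm().fit(Xtr_m[tr_i], y_fit[tr_i]).predict(Xtr_m[te_i])
        pred = svm().fit(Xtr_m, y_fit).predict(Xte_m)
        return {
            "shuffle": tag,
            "q2_cv": _q2(y_fit, oof),
            "q2_test": _q2(yte, pred),
            "r2_test": regression_metrics(yte, pred).r2,
        }

    rows = [eval_fit(ytr, "true")]
    rng = np.random.default_rng(seed)
    for s in range(n_shuffles):
        rows.append(eval_fit(rng.permutation(ytr), s))
    table = pd.DataFrame(rows).set_index("shuffle")
    shuffled = table.drop(index="true")
    table.attrs["summary"] = {
        "true_q2_cv": float(table.loc["true", "q2_cv"]),
        "shuffled_q2_cv_mean": float(shuffled["q2_cv"].mean()),
        "shuffled_q2_cv_max": float(shuffled["q2_cv"].max()),
        "gap": float(table.loc["true", "q2_cv"] - shuffled["q2_cv"].mean()),
    }
    return table


# ---------------------------------------------------------------------------
# Applicability domain
# ---------------------------------------------------------------------------


def warning_leverage(n_train: int, n_features: int) -> float:
    """h* = 3p/n with p = number of model variables plus one."""
    return 3.0 * (n_features + 1) / n_train


def _flag(h: float, h_star: float, resid: float) -> str:
    lev = h > h_star
    res = abs(resid) > 3.0
    if lev and res:
        return BOTH
    if lev:
        return LEVERAGE_OUTLIER
    if res:
        return RESPONSE_OUTLIER
    return IN_DOMAIN


def applicability_domain(
    X_train,
    X_test,
    resid_train,
    resid_test,
) -> ADReport:
    """Williams-plot diagnostics for the selected-feature design matrix.

    The design is augmented with a constant column; training leverages are
    the diagonal of the hat matrix H = X (X'X)^-1 X', test leverages are
    x' (X'X)^-1 x per row.  Standardized residuals divide by the training
    residual standard deviation.
    """
    Xtr = np.asarray(_as_frame(X_train), dtype=float)
    Xte = np.asarray(_as_frame(X_test), dtype=float)
    resid_train = np.asarray(resid_train, dtype=float)
    resid_test = np.asarray(resid_test, dtype=float)
    n, k = Xtr.shape
    p = k + 1
    if p >= n:
        raise ValueError(f"hat matrix saturated: p={p} >= n={n}")
    A_tr = np.hstack([np.ones((n, 1)), Xtr])
    A_te = np.hstack([np.ones((len(Xte), 1)), Xte])
    gram = A_tr.T @ A_tr
    try:
        ginv = np.linalg.inv(gram)
        if not np.all(np.isfinite(ginv)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        warnings.warn("singular design; using the pseudo-inverse for leverages")
        ginv = np.linalg.pinv(gram)
    h_tr = np.einsum("ij,jk,ik->i", A_tr, ginv, A_tr)
    h_te = np.einsum("ij,jk,ik->i", A_te, ginv, A_te)
    sd = float(np.std(resid_train, ddof=1))
    if sd == 0:
        sd = 1.0
    h_star = warning_leverage(n, k)
    rows = []
    for name, h, r in [
        ("TRAIN", h_tr, resid_train / sd),
        ("TEST", h_te, resid_test / sd),
    ]:
        for hi, ri in zip(h, r):
            rows.append(
                {
                    "set": name,
                    "leverage": float(hi),
                    "std_residual": float(ri),
                    "flag": _flag(hi, h_star, ri),
                }
            )
    return ADReport(table=pd.DataFrame(rows), h_star=h_star, p=p, n_train=n)


# ---------------------------------------------------------------------------
# PCA interpretation
# ---------------------------------------------------------------------------


def pca_top_features(X, ranking: list, top_k: int = 30):
    """Column-standardized PCA over the ``top_k`` most important features.

    Returns (loadings DataFrame, explained variance fractions, sample scores).
    Constant columns are dropped with a warning.
    """
    from sklearn.decomposition import PCA

    Xf = _as_frame(X)
    names = [name for name, _ in ranking[:top_k]]
    if len(names) < top_k:
        raise ValueError(f"ranking has fewer than top_k={top_k} features")
    if len(Xf) < 3:
        raise ValueError("need at least 3 samples")
    sub = Xf[names]
    const = [c for c in sub.columns if sub[c].nunique() <= 1]
    if const:
        warnings.warn(f"dropping constant columns: {const}")
        sub = sub.drop(columns=const)
    z = (sub - sub.mean()) / sub.std(ddof=1)
    pca = PCA()
    scores = pca.fit_transform(z.to_numpy())
    loadings = pd.DataFrame(
        pca.components_.T,
        index=sub.columns,
        columns=[f"PC{i + 1}" for i in range(pca.n_components_)],
    )
    return loadings, pca.explained_variance_ratio_, scores


# ---------------------------------------------------------------------------
# Plots (optional outputs; Agg-safe)
# ---------------------------------------------------------------------------


def _plt():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def correlation_plot(y_obs, y_pred, path, title: str = "") -> None:
    plt = _plt()
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(y_obs, y_pred, s=12, alpha=0.7)
    lim = [min(np.min(y_obs), np.min(y_pred)), max(np.max(y_obs), np.max(y_pred))]
    ax.plot(lim, lim, "r--", lw=1)
    ax.set_xlabel("experimental SR")
    ax.set_ylabel("predicted SR")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def williams_plot(report: ADReport, path, title: str = "") -> None:
    plt = _plt()
    fig, ax = plt.subplots(figsize=(5, 4))
    for name, marker in (("TRAIN", "o"), ("TEST", "^")):
        sub = report.table[report.table["set"] == name]
        ax.scatter(sub["leverage"], sub["std_residual"], s=14, marker=marker, label=name)
    ax.axvline(report.h_star, color="k", lw=1)
    ax.axhline(3, color="k", lw=1)
    ax.axhline(-3, color="k", lw=1)
    ax.set_xlabel("leverage")
    ax.set_ylabel("standardized residual")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def y_randomization_plot(table: pd.DataFrame, path, title: str = "") -> None:
    plt = _plt()
    shuffled = table.drop(index="true")
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.hist(shuffled["q2_cv"], bins=30, alpha=0.8, label="shuffled")
    ax.axvline(table.loc["true", "q2_cv"], color="r", lw=2, label="true model")
    ax.set_xlabel("10-fold CV q2")
    ax.set_ylabel("count")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
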