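"""L1 feature selection, SVM / random-forest classifiers, and evaluation.

Two feature-selection strategies are supported over the binary
corresponding-feature matrix:

* one_model — a single L1-penalised logistic regression over every column,
  with the penalty chosen by cross-validated deviance on a log-spaced grid;
* by_group — seven independent L1 fits, one per feature group, taking the
  union of features with nonzero coefficients across groups.

Classifiers (linear-kernel SVM by default, or random forest) are tuned by
stratified 3-fold cross-validation over a small grid, refit on the full
training split, and compared on held-out test data. The final model is the
one with the best test sensitivity (ties: higher AUC, then fewer features),
matching how a screening tool would be chosen when missed cases are the
costly error.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .features import FeatureKey, FeatureMatrix

logger = logging.getLogger(__name__)

COEF_TOL = 1e-8
DEFAULT_LAMBDA_GRID = np.logspace(-4, 4, 50)  # lambda = 1 / C

SVM_GRID = {"C": [0.01, 0.1, 1.0, 10.0]}
RF_GRID = {"max_depth": [None, 8], "min_samples_leaf": [1, 5]}


@dataclass
class SelectionResult:
    """Outcome of LASSO feature selection."""

    method: str  # "one_model" | "by_group"
    selected: list[FeatureKey]
    per_group: dict[int, list[FeatureKey]] | None
    lambda_grid: np.ndarray
    chosen_lambda: dict[str, float]

    @property
    def n_selected(self) -> int:
        return len(self.selected)


@dataclass
class ModelReport:
    """Test-split performance of one (selection, classifier) combination."""

    feature_selection: str
    classifier: str
    n_features: int
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    auc: float

    def to_dict(self) -> dict:
        return {
            "feature_selection": self.feature_selection,
            "classifier": self.classifier,
            "n_features": self.n_features,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "auc": self.auc,
        }


def _nonconstant_columns(X: sparse.csr_matrix) -> np.ndarray:
    n = X.shape[0]
    col_sums = np.asarray(X.sum(axis=0)).ravel()
    keep = (col_sums > 0) & (col_sums < n)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("lasso_select: dropped %d all-constant columns", n_dropped)
    return np.flatnonzero(keep)


def _l1_fit_selected(
    X: sparse.csr_matrix,
    y: np.ndarray,
    keys: list[FeatureKey],
    cv_folds: int,
    seed: int,
    lambda_grid: np.ndarray,
) -> tuple[list[FeatureKey], float]:
    """One cross-validated L1 logistic fit; returns (selected keys, lambda)."""
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    clf = LogisticRegressionCV(
        Cs=1.0 / lambda_grid,
        l1_ratios=(1.0,),  # pure L1 penalty
        solver="liblinear",
        scoring="neg_log_loss",  # minimise mean CV deviance
        cv=cv,
        max_iter=2000,
        refit=True,
        random_state=seed,  # liblinear shuffles data internally
        use_legacy_attributes=False,
    )
    clf.fit(X, y)
    coef = clf.coef_.ravel()
    sel = [keys[j] for j in np.flatnonzero(np.abs(coef) > COEF_TOL)]
    return sel, float(1.0 / float(np.atleast_1d(clf.C_)[0]))


def lasso_select(
    fm: FeatureMatrix,
    mode: str = "one_model",
    cv_folds: int = 3,
    seed: int = 0,
    lambda_grid: np.ndarray | None = None,
) -> SelectionResult:
    """Select features by L1-penalised logistic regression.

    mode="one_model" fits all columns at once; mode="by_group" fits the
    seven feature groups independently and returns the union of their
    nonzero-coefficient keys (|coef| > 1e-8).
    """
    if fm.matrix.shape[1] == 0:
        raise ValueError("empty feature matrix")
    grid = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid, dtype=float)
    X = fm.matrix.tocsr().astype(np.float64)
    y = fm.y
    keep = _nonconstant_columns(X)
    if keep.size == 0:
        raise ValueError("no informative (non-constant) columns in the feature matrix")
    keys = [fm.vocabulary.keys[j] for j in keep]
    X = X[:, keep]
    groups = np.array([k.group for k in keys])

    if mode == "one_model":
        sel, lam = _l1_fit_selected(X, y, keys, cv_folds, seed, grid)
        return SelectionResult(
            method=mode,
            selected=sorted(sel),
            per_group=None,
            lambda_grid=grid,
            chosen_lambda={"one_model": lam},
        )
    if mode == "by_group":
        per_group: dict[int, list[FeatureKey]] = {}
        lambdas: dict[str, float] = {}
        union: set[FeatureKey] = set()
        for g in sorted(set(groups)):
            cols = np.flatnonzero(groups == g)
            gkeys = [keys[j] for j in cols]
            sel, lam = _l1_fit_selected(X[:, cols], y, gkeys, cv_folds, seed, grid)
            per_group[int(g)] = sorted(sel)
            lambdas[f"group_{g}"] = lam
            union.update(sel)
        return SelectionResult(
            method=mode,
            selected=sorted(union),
            per_group=per_group,
            lambda_grid=grid,
            chosen_lambda=lambdas,
        )
    raise ValueError(f"unknown selection mode {mode!r}")


def restrict_matrix(fm: FeatureMatrix, selected: list[FeatureKey]) -> tuple[sparse.csr_matrix, list[FeatureKey]]:
    """Columns of the matrix restricted to the selected keys (kept order)."""
    cols = [fm.vocabulary.index[k] for k in selected if k in fm.vocabulary.index]
    kept = [k for k in selected if k in fm.vocabulary.index]
    return fm.matrix.tocsr()[:, cols], kept


def train_classifier(
    X: sparse.csr_matrix,
    y: np.ndarray,
    kind: str = "svm",
    cv_folds: int = 3,
    seed: int = 0,
    kernel: str = "linear",
):
    """Fit an SVM or random forest with stratified k-fold hyperparameter CV.

    Hyperparameters are chosen over a small grid (SVM: C; RF: depth and leaf
    size) by mean CV AUC, then the winner is refit on the full training
    split. Returns (fitted estimator, cv summary dict).
    """
    if X.shape[1] == 0:
        raise ValueError(
            "zero selected features: relax the LASSO penalty (smaller lambda) first"
        )
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    if kind == "svm":
        base = SVC(kernel=kernel, random_state=seed)
        grid = SVM_GRID
    elif kind in ("rf", "random_forest"):
        base = RandomForestClassifier(n_estimators=200, random_state=seed)
        grid = RF_GRID
    else:
        raise ValueError(f"unknown classifier kind {kind!r}")
    search = GridSearchCV(base, grid, scoring="roc_auc", cv=cv, refit=True)
    search.fit(X, y)
    summary = {
        "best_params": search.best_params_,
        "cv_auc": float(search.best_score_),
        "folds": cv_folds,
    }
    return search.best_estimator_, summary


def decision_scores(clf, X: sparse.csr_matrix) -> np.ndarray:
    """Continuous ranking scores (margin for SVM, P(case) for forests)."""
    if hasattr(clf, "decision_function"):
        return np.asarray(clf.decision_function(X), dtype=float)
    return np.asarray(clf.predict_proba(X)[:, 1], dtype=float)


def auc_rank(y: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the Mann-Whitney rank statistic with mid-rank tie correction.

    Equals the probability a random case outscores a random control, with
    ties counted 1/2; nan when either class is absent.
    """
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)  # mid-ranks
    r_pos = ranks[y == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def evaluate(
    clf,
    X: sparse.csr_matrix,
    y: np.ndarray,
    feature_selection: str,
    classifier: str,
    n_features: int,
) -> ModelReport:
    """Test-split confusion metrics at the classifier's native threshold.

    Accuracy=(TP+TN)/N, sensitivity=TP/(TP+FN), specificity=TN/(TN+FP),
    PPV=TP/(TP+FP), NPV=TN/(TN+FN); AUC from the rank statistic over
    decision scores. Metrics whose denominator is zero are reported as nan,
    never as 0.
    """
    y = np.asarray(y)
    pred = np.asarray(clf.predict(X)).astype(int)
    scores = decision_scores(clf, X)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    return ModelReport(
        feature_selection=feature_selection,
        classifier=classifier,
        n_features=n_features,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        accuracy=_safe_div(tp + tn, len(y)),
        sensitivity=_safe_div(tp, tp + fn),
        specificity=_safe_div(tn, tn + fp),
        ppv=_safe_div(tp, tp + fp),
        npv=_safe_div(tn, tn + fn),
        auc=auc_rank(y, scores),
    )


def select_final(reports: list[ModelReport]) -> ModelReport:
    """Best test sensitivity wins; ties broken by AUC, then fewer features."""
    if not reports:
        raise ValueError("no model reports to choose from")

    def score(r: ModelReport) -> tuple:
        sens = r.sensitivity if not math.isnan(r.sensitivity) else -math.inf
        auc = r.auc if not math.isnan(r.auc) else -math.inf
        return (sens, auc, -r.n_features)

    return max(reports, key=score)
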