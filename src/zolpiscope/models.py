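"""Leakage-safe nested-LOOCV linear SVM and SVR over selected features.

Feature selection keeps the columns with the smallest p-value (ties
included). The model pipeline is standardization -> PCA -> linear SVM/SVR,
fitted strictly inside each training fold; the inner leave-one-out loop
grid-searches the hyperparameters, the outer loop scores one held-out row
(or subject) at a time. Classification reports the AUC of the pooled
decision scores; regression reports RMSE and the predicted-actual Pearson
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.metrics import roc_auc_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR

__all__ = ["FeatureTable", "CvEvaluation", "select_features",
           "nested_loocv_svm", "nested_loocv_svr",
           "DEFAULT_C_GRID", "DEFAULT_EPS_GRID"]

DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)
DEFAULT_EPS_GRID = (0.01, 0.1, 1.0)


@dataclass
class FeatureTable:
    """Subject x condition feature rows with a classification label or a
    regression target per row."""

    features: np.ndarray            # rows x columns
    columns: list[str]
    subjects: np.ndarray            # per-row subject id
    target: np.ndarray              # class label (0/1) or outcome score

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        if np.any(~np.isfinite(self.features)):
            raise ValueError("missing values in feature columns")
        self.subjects = np.asarray(self.subjects)
        self.target = np.asarray(self.target)

    def select(self, columns: list[str]) -> "FeatureTable":
        idx = [self.columns.index(c) for c in columns]
        return FeatureTable(self.features[:, idx], list(columns),
                            self.subjects, self.target)


@dataclass
class CvEvaluation:
    predictions: np.ndarray
    actual: np.ndarray
    fold_params: list[dict]
    fold_models: list = field(default_factory=list)  # fitted outer-fold pipelines
    auc: float | None = None
    rmse: float | None = None
    correlation: float | None = None
    rmse_excluding: float | None = None
    excluded_subjects: list = field(default_factory=list)


def select_features(columns: list[str], p_values: dict[str, float]) -> list[str]:
    """Columns achieving the minimal p-value (all ties included)."""
    if not columns:
        raise ValueError("no candidate columns")
    missing = [c for c in columns if c not in p_values]
    if missing:
        raise ValueError(f"p-values missing for {missing}")
    best = min(p_values[c] for c in columns)
    return [c for c in columns if p_values[c] == best]


def _make_pipeline(model, n_components: int, n_features: int,
                   n_train: int) -> Pipeline:
    k = min(n_components, n_features, n_train - 1)
    return Pipeline([
        ("scale", StandardScaler()),
        ("pca", PCA(n_components=k, svd_solver="full")),
        ("model", model),
    ])


def _inner_grid_search(X: np.ndarray, t: np.ndarray, build, grid,
                       score) -> dict:
    """Plain LOOCV grid search; ``build(params)`` returns a fresh pipeline
    and ``score(pred, actual)`` is maximized. First grid entry wins ties."""
    best = None
    for params in grid:
        preds = np.empty(t.shape[0], dtype=float)
        ok = True
        for i in range(t.shape[0]):
            tr = np.ones(t.shape[0], dtype=bool)
            tr[i] = False
            if len(np.unique(t[tr])) < len(np.unique(t)) and t.dtype.kind in "iub":
                ok = False
                break
            est = build(params)
            est.fit(X[tr], t[tr])
            preds[i] = est.decision_function(X[i:i + 1])[0] \
                if hasattr(est, "decision_function") else est.predict(X[i:i + 1])[0]
        if not ok:
            continue
        s = score(preds, t)
        if best is None or s > best[0]:
            best = (s, params)
    if best is None:
        raise ValueError("no admissible hyperparameters (degenerate folds)")
    return best[1]


def nested_loocv_svm(table: FeatureTable, n_components: int = 2,
                     c_grid=DEFAULT_C_GRID, by_subject: bool = False,
                     seed: int = 0) -> CvEvaluation:
    """Nested-LOOCV linear SVM classification.

    The outer loop leaves out one row per fold by default (each subject
    contributes one row per condition, so a paired study of 8 subjects
    yields 16 folds); with ``by_subject=True`` it leaves out both of a
    subject's rows at once. The inner LOOCV grid-searches C by accuracy.
    AUC is computed from the decision scores pooled over outer folds.
    """
    X, tgt = table.features, table.target.astype(int)
    classes = np.unique(tgt)
    if classes.size < 2:
        raise ValueError("need two classes")
    folds = ([np.flatnonzero(table.subjects == s) for s in np.unique(table.subjects)]
             if by_subject else [np.array([i]) for i in range(X.shape[0])])
    scores = np.empty(X.shape[0])
    fold_params, fold_models = [], []

    def build(params):
        return _make_pipeline(SVC(kernel="linear", C=params["C"], random_state=seed),
                              n_components, X.shape[1], X.shape[0] - 1)

    def acc(pred, actual):
        return float(np.mean((pred > 0).astype(int) == actual))

    for test_idx in folds:
        tr = np.ones(X.shape[0], dtype=bool)
        tr[test_idx] = False
        if len(np.unique(tgt[tr])) < 2:
            raise ValueError("a class is absent from a training fold")
        params = _inner_grid_search(X[tr], tgt[tr], build,
                                    [{"C": c} for c in c_grid], acc)
        est = build(params)
        est.fit(X[tr], tgt[tr])
        scores[test_idx] = est.decision_function(X[test_idx])
        fold_params.append(params)
        fold_models.append(est)
    auc = float(roc_auc_score(tgt, scores))
    return CvEvaluation(predictions=scores, actual=tgt,
                        fold_params=fold_params, fold_models=fold_models,
                        auc=auc)


def nested_loocv_svr(table: FeatureTable, n_components: int = 1,
                     c_grid=DEFAULT_C_GRID, eps_grid=DEFAULT_EPS_GRID,
                     exclude_subjects=(), seed: int = 0) -> CvEvaluation:
    """Nested-LOOCV linear SVR outcome prediction (one subject per fold).

    Reports RMSE and the predicted-actual Pearson correlation; when
    ``exclude_subjects`` names outliers, an additional RMSE over the
    remaining subjects is reported (no automatic outlier detection).
    """
    X, tgt = table.features, table.target.astype(float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    if np.ptp(tgt) == 0:
        raise ValueError("constant target")
    preds = np.empty(X.shape[0])
    fold_params, fold_models = [], []

    def build(params):
        return _make_pipeline(SVR(kernel="linear", C=params["C"],
                                  epsilon=params["epsilon"]),
                              n_components, X.shape[1], X.shape[0] - 1)

    grid = [{"C": c, "epsilon": e} for c in c_grid for e in eps_grid]

    def neg_mse(pred, actual):
        return -float(np.mean((pred - actual) ** 2))

    for i in range(X.shape[0]):
        tr = np.ones(X.shape[0], dtype=bool)
        tr[i] = False
        params = _inner_grid_search(X[tr], tgt[tr], build, grid, neg_mse)
        est = build(params)
        est.fit(X[tr], tgt[tr])
        preds[i] = est.predict(X[i:i + 1])[0]
        fold_params.append(params)
        fold_models.append(est)
    rmse = float(np.sqrt(np.mean((preds - tgt) ** 2)))
    corr = float(np.corrcoef(preds, tgt)[0, 1]) if np.ptp(preds) > 0 else 0.0
    ev = CvEvaluation(predictions=preds, actual=tgt, fold_params=fold_params,
                      fold_models=fold_models, rmse=rmse, correlation=corr)
    if len(exclude_subjects):
        keep = ~np.isin(table.subjects, list(exclude_subjects))
        ev.rmse_excluding = float(np.sqrt(np.mean((preds[keep] - tgt[keep]) ** 2)))
        ev.excluded_subjects = list(exclude_subjects)
    return ev
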