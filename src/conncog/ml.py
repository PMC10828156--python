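"""Nested repeated cross-validation engine.

Implements the full prediction protocol: repeated nested 10-fold CV
(10 repeats, inner 5-fold hyperparameter search by MAE), train-side
standard scaling, train-side confound regression on the target,
concatenation and fold-preserving stacking with a random-forest
meta-estimator, dummy baselines and per-fold MAE/R^2/r bookkeeping.

Everything that touches training statistics (scaler, deconfounder,
hyperparameter choice) is fitted on the training subjects of the fold
only; the fold structure is shared across modalities and stacking
layers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import (
    ElasticNet,
    Lasso,
    LogisticRegression,
    Ridge,
    RidgeClassifier,
)
from sklearn.model_selection import KFold, ParameterGrid, RepeatedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC, LinearSVR

from .base import FeatureMatrix

__all__ = [
    "CVPlan",
    "ModelConfig",
    "DeconfoundSpec",
    "FoldResult",
    "PerformanceSummary",
    "make_cv_plan",
    "build_grid",
    "make_estimator",
    "deconfound_target",
    "fit_predict_concat",
    "fit_predict_stacking",
    "fit_classify",
    "summarize",
    "REGRESSORS",
    "CLASSIFIERS",
]

REGRESSORS = ("ridge", "lasso", "en", "linsvr", "rf")
CLASSIFIERS = ("linsvc", "logistic", "ridgeclf", "rfclf")

_RF_DEPTHS = [4, 6, 8, 10, 20, 40, None]


# ---------------------------------------------------------------------------
# Plans, grids, estimators
# ---------------------------------------------------------------------------

@dataclass
class CVPlan:
    """Repeated nested fold assignments shared across modalities/layers."""

    outer: list[tuple[int, int, np.ndarray, np.ndarray]]  # (repeat, fold, train, test)
    inner_k: int
    outer_k: int
    repeats: int
    seed: int
    n_subjects: int


@dataclass
class ModelConfig:
    """Algorithm name plus hyperparameter grid.

    ``hyper_grid=None`` uses the full printed grid from
    :func:`build_grid`; tests may pass a reduced grid for speed.
    """

    algorithm: str
    hyper_grid: dict | None = None
    inner_metric: str = "mae"  # "mae" for regression, "accuracy" for classification

    def grid(self) -> dict:
        return self.hyper_grid if self.hyper_grid is not None else build_grid(self.algorithm)


@dataclass
class DeconfoundSpec:
    """Which confounds are regressed out of the target (train-fitted).

    ``no_deconf`` regresses eTIV only; ``deconf`` additionally regresses
    age, sex and education.  ``none`` disables confound regression
    entirely (used by pipeline validation runs).
    """

    mode: str = "no_deconf"

    def confound_columns(self) -> list[str]:
        if self.mode == "none":
            return []
        if self.mode == "no_deconf":
            return ["etiv"]
        if self.mode == "deconf":
            return ["etiv", "age", "sex", "education"]
        raise ValueError(f"unknown deconfounding mode {self.mode!r}")


@dataclass
class FoldResult:
    repeat: int
    fold: int
    mae: float
    r2: float
    pearson_r: float
    dummy_mae: float
    dummy_r2: float
    chosen_params: dict
    n_test: int
    coef: np.ndarray | None = None  # |coefficients| or RF importances
    test_idx: np.ndarray | None = None
    y_pred: np.ndarray | None = None
    accuracy: float | None = None
    dummy_accuracy: float | None = None


@dataclass
class PerformanceSummary:
    n_folds: int
    mean_mae: float
    sd_mae: float
    mean_r2: float
    sd_r2: float
    mean_r: float
    sd_r: float
    mean_dummy_mae: float
    mean_dummy_r2: float
    pct_folds_r2_better: float  # % of folds with model R^2 strictly > dummy R^2
    pct_folds_mae_better: float
    mean_accuracy: float | None = None
    mean_dummy_accuracy: float | None = None


def make_cv_plan(
    n_subjects: int,
    outer_k: int = 10,
    repeats: int = 10,
    inner_k: int = 5,
    seed: int = 0,
) -> CVPlan:
    """Repeated outer K-fold plan; deterministic under the seed."""
    if n_subjects < outer_k:
        raise ValueError(f"need at least outer_k={outer_k} subjects, got {n_subjects}")
    rkf = RepeatedKFold(n_splits=outer_k, n_repeats=repeats, random_state=seed)
    outer = []
    for i, (train, test) in enumerate(rkf.split(np.zeros(n_subjects))):
        outer.append((i // outer_k, i % outer_k, train, test))
    return CVPlan(outer, inner_k, outer_k, repeats, seed, n_subjects)


def build_grid(algorithm: str) -> dict:
    """Printed hyperparameter grids, in enumeration order.

    linSVR: 10 log-spaced C in [1e-4, 1e1]; Lasso: 10 log-spaced lambda
    in [1e-1, 1e2]; Ridge: 10 log-spaced lambda in [1e-3, 1e5]; EN: the
    Lasso lambdas x 10 linear l1-ratios in [0.1, 1]; RF: {100, 1000}
    trees x depths {4, 6, 8, 10, 20, 40, None}.  Classifier grids mirror
    their regression counterparts.
    """
    if algorithm == "ridge":
        return {"alpha": list(np.logspace(-3, 5, 10))}
    if algorithm == "lasso":
        return {"alpha": list(np.logspace(-1, 2, 10))}
    if algorithm == "en":
        return {
            "alpha": list(np.logspace(-1, 2, 10)),
            "l1_ratio": list(np.linspace(0.1, 1.0, 10)),
        }
    if algorithm == "linsvr":
        return {"C": list(np.logspace(-4, 1, 10))}
    if algorithm in ("rf", "rfclf"):
        return {"n_estimators": [100, 1000], "max_depth": list(_RF_DEPTHS)}
    if algorithm == "linsvc":
        return {"C": list(np.logspace(-4, 1, 10))}
    if algorithm == "logistic":
        return {"C": list(np.logspace(-4, 1, 10))}
    if algorithm == "ridgeclf":
        return {"alpha": list(np.logspace(-3, 5, 10))}
    raise ValueError(f"unknown algorithm {algorithm!r}")


def make_estimator(algorithm: str, params: dict, seed: int = 0):
    """Instantiate the sklearn estimator for one grid point."""
    if algorithm == "ridge":
        return Ridge(**params)
    if algorithm == "lasso":
        return Lasso(max_iter=5000, **params)
    if algorithm == "en":
        return ElasticNet(max_iter=5000, **params)
    if algorithm == "linsvr":
        return LinearSVR(max_iter=10000, random_state=seed, **params)
    if algorithm == "rf":
        return RandomForestRegressor(random_state=seed, n_jobs=1, **params)
    if algorithm == "linsvc":
        return LinearSVC(max_iter=10000, random_state=seed, **params)
    if algorithm == "logistic":
        return LogisticRegression(max_iter=5000, random_state=seed, **params)
    if algorithm == "ridgeclf":
        return RidgeClassifier(**params)
    if algorithm == "rfclf":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    raise ValueError(f"unknown algorithm {algorithm!r}")


# ---------------------------------------------------------------------------
# Deconfounding
# ---------------------------------------------------------------------------

def deconfound_target(
    target: np.ndarray,
    confounds: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Residualize the target on [intercept, confounds], train-fitted.

    Returns the adjusted (train, test) target values.  Collinear
    confound columns are handled by least squares (minimum-norm
    solution) with a warning.
    """
    y = np.asarray(target, dtype=float)
    c = np.atleast_2d(np.asarray(confounds, dtype=float))
    if c.shape[0] != y.size:
        c = c.T
    X = np.column_stack([np.ones(y.size), c])
    Xtr = X[train_idx]
    if np.linalg.matrix_rank(Xtr) < Xtr.shape[1]:
        warnings.warn("rank-deficient confound matrix; minimum-norm fit used")
    beta, *_ = np.linalg.lstsq(Xtr, y[train_idx], rcond=None)
    return y[train_idx] - Xtr @ beta, y[test_idx] - X[test_idx] @ beta


def _adjusted_target(
    target: np.ndarray,
    deconfound: DeconfoundSpec | None,
    confounds: pd.DataFrame | None,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    if deconfound is None or deconfound.mode == "none":
        y = np.asarray(target, dtype=float)
        return y[train_idx], y[test_idx]
    cols = deconfound.confound_columns()
    if confounds is None:
        raise ValueError("deconfounding requested but no confound table given")
    missing = [c for c in cols if c not in confounds.columns]
    if missing:
        raise ValueError(f"confound table lacks columns {missing}")
    return deconfound_target(
        target, confounds[cols].to_numpy(dtype=float), train_idx, test_idx
    )


# ---------------------------------------------------------------------------
# Inner grid search
# ---------------------------------------------------------------------------

def _grid_search(
    algorithm: str,
    grid: dict,
    X: np.ndarray,
    y: np.ndarray,
    inner_k: int,
    seed: int,
    metric: str = "mae",
) -> dict:
    """Exhaustive inner-CV search; ties go to the first grid entry.

    Regression minimizes MAE; classification maximizes accuracy.
    """
    splits = list(
        KFold(n_splits=inner_k, shuffle=True, random_state=seed).split(X)
    )
    best_params: dict | None = None
    best_score = np.inf
    for params in ParameterGrid(grid):
        scores = []
        for tr, va in splits:
            est = make_estimator(algorithm, params, seed=seed)
            est.fit(X[tr], y[tr])
            pred = est.predict(X[va])
            if metric == "mae":
                scores.append(np.mean(np.abs(y[va] - pred)))
            else:  # accuracy, negated so lower is better
                scores.append(-np.mean(pred == y[va]))
        score = float(np.mean(scores))
        if score < best_score - 1e-15:  # strict improvement: first entry wins ties
            best_score = score
            best_params = dict(params)
    assert best_params is not None
    return best_params


def _extract_coef(est) -> np.ndarray | None:
    if hasattr(est, "coef_"):
        return np.ravel(est.coef_).copy()
    if hasattr(est, "feature_importances_"):
        return np.asarray(est.feature_importances_).copy()
    return None


def _regression_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float]:
    mae = float(np.mean(np.abs(y_true - y_pred)))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    if np.std(y_pred) > 0 and np.std(y_true) > 0:
        r = float(np.corrcoef(y_true, y_pred)[0, 1])
    else:
        r = 0.0
    return mae, r2, r


def _as_array(features) -> np.ndarray:
    if isinstance(features, FeatureMatrix):
        return features.values
    x = np.asarray(features, dtype=float)
    if np.isnan(x).any():
        raise ValueError("features contain NaN")
    return x


def _fold_seed(base_seed: int, repeat: int, fold: int, salt: int = 0) -> int:
    return int(
        np.random.SeedSequence([base_seed, repeat, fold, salt]).generate_state(1)[0]
        % (2**31 - 1)
    )


def _append_extra(X: np.ndarray, extra_features: pd.DataFrame | None) -> np.ndarray:
    if extra_features is None:
        return X
    extra = extra_features.loc[:, ["age", "sex", "education"]].to_numpy(dtype=float)
    if extra.shape[0] != X.shape[0]:
        raise ValueError("extra feature subject count mismatch")
    return np.hstack([X, extra])


# ---------------------------------------------------------------------------
# Concatenation approach
# ---------------------------------------------------------------------------

def fit_predict_concat(
    features,
    target: np.ndarray,
    model_config: ModelConfig,
    cv_plan: CVPlan,
    deconfound: DeconfoundSpec | None = None,
    confounds: pd.DataFrame | None = None,
    extra_features: pd.DataFrame | None = None,
    store_coefs: bool = False,
    store_predictions: bool = False,
) -> list[FoldResult]:
    """Nested CV with all features in one concatenated block.

    Per outer fold: scale (train-fitted), deconfound the target
    (train-fitted), tune hyperparameters by inner K-fold MAE, refit on
    the full outer-train set, evaluate MAE/R^2/r on the outer-test set,
    and evaluate a train-mean dummy the same way.
    """
    X_all = _append_extra(_as_array(features), extra_features)
    y_all = np.asarray(target, dtype=float)
    if X_all.shape[0] != y_all.size:
        raise ValueError("features and target subject counts disagree")
    results = []
    for repeat, fold, train_idx, test_idx in cv_plan.outer:
        seed = _fold_seed(cv_plan.seed, repeat, fold)
        y_tr, y_te = _adjusted_target(y_all, deconfound, confounds, train_idx, test_idx)
        scaler = StandardScaler().fit(X_all[train_idx])
        X_tr = scaler.transform(X_all[train_idx])
        X_te = scaler.transform(X_all[test_idx])
        params = _grid_search(
            model_config.algorithm, model_config.grid(), X_tr, y_tr,
            cv_plan.inner_k, seed,
        )
        est = make_estimator(model_config.algorithm, params, seed=seed)
        est.fit(X_tr, y_tr)
        pred = est.predict(X_te)
        mae, r2, r = _regression_metrics(y_te, pred)
        dummy_pred = np.full(y_te.size, y_tr.mean())
        dummy_mae, dummy_r2, _ = _regression_metrics(y_te, dummy_pred)
        results.append(
            FoldResult(
                repeat, fold, mae, r2, r, dummy_mae, dummy_r2, params, y_te.size,
                coef=_extract_coef(est) if store_coefs else None,
                test_idx=test_idx.copy() if store_predictions else None,
                y_pred=pred.copy() if store_predictions else None,
            )
        )
    return results


# ---------------------------------------------------------------------------
# Stacking approach
# ---------------------------------------------------------------------------

def fit_predict_stacking(
    modality_features: dict[str, np.ndarray | FeatureMatrix],
    target: np.ndarray,
    model_config: ModelConfig,
    cv_plan: CVPlan,
    deconfound: DeconfoundSpec | None = None,
    confounds: pd.DataFrame | None = None,
    extra_features: pd.DataFrame | None = None,
    meta_grid: dict | None = None,
    store_coefs: bool = False,
    structure_log: list | None = None,
) -> list[FoldResult]:
    """Two-layer stacking with fold identity preserved across layers.

    Layer 1 fits one model per modality on the outer-train subjects
    (hyperparameters tuned by inner CV) and produces out-of-fold
    cross-validated predictions for the training set plus ordinary
    predictions for the test set.  Layer 2 tunes and fits a
    random-forest meta-estimator on the stacked training predictions
    (fresh inner split) and is evaluated on the stacked test
    predictions, so no subject's test prediction ever reaches a model
    that saw it during training.

    ``extra_features`` is treated as an additional layer-1 modality
    block.  ``coef`` of each FoldResult holds the meta-estimator's
    per-modality importances (when ``store_coefs``), ordered as
    ``list(modality_features) (+ "extra")``.

    When ``structure_log`` is a list, one dict per fold is appended
    recording the absolute subject indices used to train every layer-1
    submodel and the layer-2 meta-estimator, so fold exclusivity can be
    audited externally.
    """
    blocks = {name: _as_array(f) for name, f in modality_features.items()}
    if extra_features is not None:
        blocks["extra"] = extra_features.loc[:, ["age", "sex", "education"]].to_numpy(
            dtype=float
        )
    if len(blocks) < 2:
        raise ValueError("stacking requires at least 2 modality blocks")
    y_all = np.asarray(target, dtype=float)
    n = y_all.size
    for name, X in blocks.items():
        if X.shape[0] != n:
            raise ValueError(f"modality {name!r} subject count mismatch")
    if meta_grid is None:
        meta_grid = build_grid("rf")

    results = []
    for repeat, fold, train_idx, test_idx in cv_plan.outer:
        seed = _fold_seed(cv_plan.seed, repeat, fold)
        y_tr, y_te = _adjusted_target(y_all, deconfound, confounds, train_idx, test_idx)
        Z_tr = np.empty((train_idx.size, len(blocks)))
        Z_te = np.empty((test_idx.size, len(blocks)))
        fold_log: dict | None = None
        if structure_log is not None:
            fold_log = {
                "repeat": repeat,
                "fold": fold,
                "test_idx": test_idx.copy(),
                "layer1_train": [],
                "meta_train": train_idx.copy(),
            }
        for m, (name, X) in enumerate(blocks.items()):
            scaler = StandardScaler().fit(X[train_idx])
            X_tr = scaler.transform(X[train_idx])
            X_te = scaler.transform(X[test_idx])
            params = _grid_search(
                model_config.algorithm, model_config.grid(), X_tr, y_tr,
                cv_plan.inner_k, seed,
            )
            # out-of-fold predictions over the outer-train subjects
            oof = np.empty(train_idx.size)
            for tr, va in KFold(
                n_splits=cv_plan.inner_k, shuffle=True, random_state=seed
            ).split(X_tr):
                est = make_estimator(model_config.algorithm, params, seed=seed)
                est.fit(X_tr[tr], y_tr[tr])
                oof[va] = est.predict(X_tr[va])
                if fold_log is not None:
                    fold_log["layer1_train"].append(train_idx[tr].copy())
            Z_tr[:, m] = oof
            est = make_estimator(model_config.algorithm, params, seed=seed)
            est.fit(X_tr, y_tr)
            Z_te[:, m] = est.predict(X_te)
            if fold_log is not None:
                fold_log["layer1_train"].append(train_idx.copy())
        if fold_log is not None:
            structure_log.append(fold_log)
        # layer 2: RF meta-estimator, fresh inner split on stacked rows
        meta_seed = _fold_seed(cv_plan.seed, repeat, fold, salt=1)
        meta_params = _grid_search("rf", meta_grid, Z_tr, y_tr, cv_plan.inner_k, meta_seed)
        meta = make_estimator("rf", meta_params, seed=meta_seed)
        meta.fit(Z_tr, y_tr)
        pred = meta.predict(Z_te)
        mae, r2, r = _regression_metrics(y_te, pred)
        dummy_pred = np.full(y_te.size, y_tr.mean())
        dummy_mae, dummy_r2, _ = _regression_metrics(y_te, dummy_pred)
        results.append(
            FoldResult(
                repeat, fold, mae, r2, r, dummy_mae, dummy_r2,
                {"meta": meta_params}, y_te.size,
                coef=_extract_coef(meta) if store_coefs else None,
            )
        )
    return results


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def fit_classify(
    features,
    labels: np.ndarray,
    classifier_config: ModelConfig,
    cv_plan: CVPlan,
) -> list[FoldResult]:
    """Binary classification under the same nested CV protocol.

    Inner selection uses accuracy; a majority-class dummy is evaluated
    per fold.  Folds whose training set contains a single class are
    skipped with a warning.
    """
    X_all = _as_array(features)
    y_all = np.asarray(labels)
    if set(np.unique(y_all)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    results = []
    for repeat, fold, train_idx, test_idx in cv_plan.outer:
        if np.unique(y_all[train_idx]).size < 2:
            warnings.warn(f"single-class training fold ({repeat}, {fold}) skipped")
            continue
        seed = _fold_seed(cv_plan.seed, repeat, fold)
        scaler = StandardScaler().fit(X_all[train_idx])
        X_tr = scaler.transform(X_all[train_idx])
        X_te = scaler.transform(X_all[test_idx])
        y_tr, y_te = y_all[train_idx], y_all[test_idx]
        params = _grid_search(
            classifier_config.algorithm, classifier_config.grid(), X_tr, y_tr,
            cv_plan.inner_k, seed, metric="accuracy",
        )
        est = make_estimator(classifier_config.algorithm, params, seed=seed)
        est.fit(X_tr, y_tr)
        acc = float(np.mean(est.predict(X_te) == y_te))
        majority = np.bincount(y_tr.astype(int)).argmax()
        dummy_acc = float(np.mean(y_te == majority))
        results.append(
            FoldResult(
                repeat, fold, np.nan, np.nan, np.nan, np.nan, np.nan, params,
                y_te.size, accuracy=acc, dummy_accuracy=dummy_acc,
            )
        )
    return results


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def summarize(fold_results: list[FoldResult]) -> PerformanceSummary:
    """Mean/sd metrics and the fraction of folds beating the dummy."""
    if not fold_results:
        raise ValueError("no fold results to summarize")
    mae = np.array([f.mae for f in fold_results])
    r2 = np.array([f.r2 for f in fold_results])
    r = np.array([f.pearson_r for f in fold_results])
    dmae = np.array([f.dummy_mae for f in fold_results])
    dr2 = np.array([f.dummy_r2 for f in fold_results])
    accs = [f.accuracy for f in fold_results if f.accuracy is not None]
    daccs = [f.dummy_accuracy for f in fold_results if f.dummy_accuracy is not None]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return PerformanceSummary(
            n_folds=len(fold_results),
            mean_mae=float(np.nanmean(mae)),
            sd_mae=float(np.nanstd(mae)),
            mean_r2=float(np.nanmean(r2)),
            sd_r2=float(np.nanstd(r2)),
            mean_r=float(np.nanmean(r)),
            sd_r=float(np.nanstd(r)),
            mean_dummy_mae=float(np.nanmean(dmae)),
            mean_dummy_r2=float(np.nanmean(dr2)),
            pct_folds_r2_better=float(100.0 * np.mean(r2 > dr2))
            if not np.all(np.isnan(r2))
            else float("nan"),
            pct_folds_mae_better=float(100.0 * np.mean(mae < dmae))
            if not np.all(np.isnan(mae))
            else float("nan"),
            mean_accuracy=float(np.mean(accs)) if accs else None,
            mean_dummy_accuracy=float(np.mean(daccs)) if daccs else None,
        )


def summarize_frame(frame: pd.DataFrame) -> PerformanceSummary:
    """Summarize a tidy per-fold table (round-trips through CSV)."""
    results = [
        FoldResult(
            int(row["repeat"]), int(row["fold"]), row["mae"], row["r2"],
            row["pearson_r"], row["dummy_mae"], row["dummy_r2"], {},
            int(row["n_test"]),
            accuracy=None if pd.isna(row.get("accuracy")) else float(row["accuracy"]),
            dummy_accuracy=None
            if pd.isna(row.get("dummy_accuracy"))
            else float(row["dummy_accuracy"]),
        )
        for _, row in frame.iterrows()
    ]
    return summarize(results)


def fold_results_frame(fold_results: list[FoldResult]) -> pd.DataFrame:
    """Tidy per-fold results table."""
    return pd.DataFrame(
        {
            "repeat": [f.repeat for f in fold_results],
            "fold": [f.fold for f in fold_results],
            "n_test": [f.n_test for f in fold_results],
            "mae": [f.mae for f in fold_results],
            "r2": [f.r2 for f in fold_results],
            "pearson_r": [f.pearson_r for f in fold_results],
            "dummy_mae": [f.dummy_mae for f in fold_results],
            "dummy_r2": [f.dummy_r2 for f in fold_results],
            "accuracy": [f.accuracy for f in fold_results],
            "dummy_accuracy": [f.dummy_accuracy for f in fold_results],
            "chosen_params": [repr(f.chosen_params) for f in fold_results],
        }
    )
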