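"""Model comparison and interpretation utilities.

Multimodal bonus scores, feature/modality importance aggregation,
extreme-group construction, propensity-score matching and partial
correlations.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .ml import FoldResult

__all__ = [
    "BonusScores",
    "MatchedSample",
    "multimodal_bonus",
    "feature_importance_concat",
    "modality_importance_stacking",
    "extreme_groups",
    "propensity_match",
    "partial_correlation",
]


@dataclass
class BonusScores:
    """Multimodal bonus relative to the constituent unimodal models."""

    b_all: float  # multimodal minus the average unimodal performance
    b_best: float  # multimodal minus the best unimodal performance
    basis: str = "r2"  # "r2" | "mae"


def multimodal_bonus(
    multi_perf: float, unimodal_perfs: list[float], basis: str = "r2"
) -> BonusScores:
    """Bonus of a multimodal model over its unimodal constituents.

    On the R^2 basis, ``b_all = multi - mean(unimodals)`` and
    ``b_best = multi - max(unimodals)``.  On the MAE basis signs are
    flipped (lower is better) so positive still means the multimodal
    model wins: ``b_all = mean(unimodals) - multi``,
    ``b_best = min(unimodals) - multi``.
    """
    if not unimodal_perfs:
        raise ValueError("at least one unimodal performance required")
    u = np.asarray(unimodal_perfs, dtype=float)
    if basis == "r2":
        return BonusScores(float(multi_perf - u.mean()), float(multi_perf - u.max()), basis)
    if basis == "mae":
        return BonusScores(float(u.mean() - multi_perf), float(u.min() - multi_perf), basis)
    raise ValueError(f"unknown bonus basis {basis!r}")


def feature_importance_concat(
    fold_coefs: dict[tuple[str, str], list[FoldResult] | np.ndarray],
    feature_names: dict[str, list[str]],
    top_k: int = 20,
) -> tuple[pd.DataFrame, set[str]]:
    """Top-k feature intersection across (algorithm, feature-set) runs.

    ``fold_coefs`` maps ``(algorithm, fset)`` to either a list of
    :class:`FoldResult` with stored coefficients or a
    ``(n_folds, n_features)`` array; ``feature_names[fset]`` names the
    columns.  For each configuration, coefficients are averaged across
    folds, ranked by absolute value and the top-k kept; only features
    present in every configuration's top-k survive.

    Returns a tidy table of per-configuration mean coefficients for the
    surviving features and the surviving feature-name set.
    """
    top_sets: list[set[str]] = []
    rows = []
    mean_by_config: dict[tuple[str, str], pd.Series] = {}
    for (algorithm, fset), payload in fold_coefs.items():
        if isinstance(payload, np.ndarray):
            coefs = payload
        else:
            stored = [f.coef for f in payload if f.coef is not None]
            if not stored:
                raise ValueError(f"no stored coefficients for ({algorithm}, {fset})")
            coefs = np.vstack(stored)
        names = feature_names[fset]
        if coefs.shape[1] != len(names):
            raise ValueError("coefficient width does not match feature names")
        mean_coef = pd.Series(coefs.mean(axis=0), index=names)
        mean_by_config[(algorithm, fset)] = mean_coef
        top = mean_coef.abs().sort_values(ascending=False).head(top_k).index
        top_sets.append(set(top))
    surviving = set.intersection(*top_sets) if top_sets else set()
    for (algorithm, fset), mean_coef in mean_by_config.items():
        for name in sorted(surviving):
            rows.append(
                {
                    "algorithm": algorithm,
                    "fset": fset,
                    "feature": name,
                    "mean_coef": float(mean_coef[name]),
                }
            )
    return pd.DataFrame(rows), surviving


def modality_importance_stacking(
    meta_results: dict[str, list[FoldResult]],
    modality_names: list[str],
) -> tuple[pd.DataFrame, list[tuple[str, ...]]]:
    """Rank modalities from the stacking meta-estimator's importances.

    ``meta_results`` maps a configuration label to its stacking fold
    results (with stored meta importances).  Importances are averaged
    across folds per configuration; each configuration yields a ranking
    (most important first) and the modal ranking(s) across
    configurations are returned (all of them when tied).
    """
    rows = []
    rankings: list[tuple[str, ...]] = []
    for label, folds in meta_results.items():
        stored = [f.coef for f in folds if f.coef is not None]
        if not stored:
            raise ValueError(f"no stored meta importances for {label!r}")
        imp = np.vstack(stored).mean(axis=0)
        if imp.size != len(modality_names):
            raise ValueError("importance width does not match modality names")
        order = np.argsort(imp)[::-1]
        ranking = tuple(modality_names[i] for i in order)
        rankings.append(ranking)
        for name, value in zip(modality_names, imp):
            rows.append({"config": label, "modality": name, "mean_importance": float(value)})
    counts = Counter(rankings)
    best = max(counts.values())
    modal = [r for r, c in counts.items() if c == best]
    return pd.DataFrame(rows), modal


def extreme_groups(
    target_scores: np.ndarray, quantile: float = 0.25
) -> np.ndarray:
    """Label the top/bottom quantile of a score; middle excluded.

    Returns an integer array: 1 for high performers, 0 for low
    performers, -1 for excluded middle subjects.  Ties at the cutoff are
    resolved by the stable sort order (lower original index wins).
    """
    scores = np.asarray(target_scores, dtype=float)
    n = scores.size
    if n < 8:
        raise ValueError("need at least 8 subjects for extreme groups")
    n_group = int(np.floor(n * quantile))
    order = np.argsort(scores, kind="stable")
    labels = np.full(n, -1, dtype=int)
    labels[order[:n_group]] = 0
    labels[order[n - n_group:]] = 1
    return labels


@dataclass
class MatchedSample:
    """1:1 propensity-matched high/low groups with balance diagnostics."""

    high_ids: list[int]
    low_ids: list[int]
    pairs: list[tuple[int, int]]  # (high index, low index)
    smd_before: dict[str, float]
    smd_after: dict[str, float]
    propensity_logit: np.ndarray = field(repr=False, default=None)

    @property
    def n_matched(self) -> int:
        return 2 * len(self.pairs)


def _smd(x_a: np.ndarray, x_b: np.ndarray) -> float:
    """Standardized mean difference with pooled SD (0 when both flat)."""
    pooled = np.sqrt((x_a.var(ddof=1) + x_b.var(ddof=1)) / 2) if (
        x_a.size > 1 and x_b.size > 1
    ) else 0.0
    if pooled == 0:
        return 0.0
    return float((x_a.mean() - x_b.mean()) / pooled)


def propensity_match(
    group_labels: np.ndarray,
    covariates: pd.DataFrame,
    caliper: float = 0.2,
    seed: int = 0,
) -> MatchedSample:
    """Greedy 1:1 nearest-neighbor propensity matching on the logit.

    A logistic model of group membership on the covariates provides
    propensity logits; high-group subjects are matched to the nearest
    unused low-group subject within ``caliper * sd(logit)``.  Subjects
    with label -1 are ignored.  Returns matched ids plus standardized
    mean differences before/after matching.
    """
    labels = np.asarray(group_labels)
    mask = labels >= 0
    idx = np.flatnonzero(mask)
    y = labels[idx]
    if np.unique(y).size < 2:
        raise ValueError("both groups must be non-empty")
    X = covariates.iloc[idx].to_numpy(dtype=float)
    Xs = (X - X.mean(0)) / np.where(X.std(0) > 0, X.std(0), 1.0)
    model = LogisticRegression(C=np.inf, max_iter=5000, random_state=seed)
    model.fit(Xs, y)
    p = np.clip(model.predict_proba(Xs)[:, 1], 1e-12, 1 - 1e-12)
    logit = np.log(p / (1 - p))
    sd_logit = logit.std(ddof=1)
    max_dist = caliper * sd_logit if sd_logit > 0 else np.inf

    high = np.flatnonzero(y == 1)
    low = np.flatnonzero(y == 0)
    used = set()
    pairs: list[tuple[int, int]] = []
    # match in order of high-group propensity (descending) for determinism
    for h in high[np.argsort(-logit[high], kind="stable")]:
        best, best_d = None, np.inf
        for lo in low:
            if lo in used:
                continue
            d = abs(logit[h] - logit[lo])
            if d < best_d:
                best, best_d = lo, d
        if best is not None and best_d <= max_dist:
            used.add(best)
            pairs.append((int(idx[h]), int(idx[best])))
    if not pairs:
        warnings.warn("no matches within the caliper; empty matched sample")

    cols = list(covariates.columns)
    smd_before = {
        c: _smd(X[y == 1][:, j], X[y == 0][:, j]) for j, c in enumerate(cols)
    }
    if pairs:
        hi_rows = covariates.loc[[h for h, _ in pairs]].to_numpy(dtype=float)
        lo_rows = covariates.loc[[l for _, l in pairs]].to_numpy(dtype=float)
        smd_after = {c: _smd(hi_rows[:, j], lo_rows[:, j]) for j, c in enumerate(cols)}
    else:
        smd_after = {c: 0.0 for c in cols}
    full_logit = np.full(labels.size, np.nan)
    full_logit[idx] = logit
    return MatchedSample(
        high_ids=[int(idx[h]) for h in high],
        low_ids=[int(idx[lo]) for lo in low],
        pairs=pairs,
        smd_before=smd_before,
        smd_after=smd_after,
        propensity_logit=full_logit,
    )


def partial_correlation(
    x: np.ndarray, y: np.ndarray, controls: np.ndarray | None = None
) -> tuple[float, float]:
    """Partial Pearson correlation of x and y given control variables.

    Both variables are residualized on [intercept, controls] by OLS; the
    two-sided p-value uses a t distribution with ``n - 2 - k`` degrees
    of freedom (k = number of controls).  With no controls this reduces
    to the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if controls is None or (hasattr(controls, "size") and np.asarray(controls).size == 0):
        k = 0
        rx, ry = x - x.mean(), y - y.mean()
    else:
        c = np.atleast_2d(np.asarray(controls, dtype=float))
        if c.shape[0] != n:
            c = c.T
        # drop collinear control columns
        keep = []
        for j in range(c.shape[1]):
            trial = c[:, keep + [j]]
            if np.linalg.matrix_rank(np.column_stack([np.ones(n), trial])) == len(keep) + 2:
                keep.append(j)
        if len(keep) < c.shape[1]:
            warnings.warn("dropped collinear control column(s)")
        c = c[:, keep]
        k = c.shape[1]
        Z = np.column_stack([np.ones(n), c])
        rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
        ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    # residuals that are numerically zero relative to the original scale
    # (e.g. y is itself a control) carry no information
    x_scale = max(x.std(), 1.0)
    y_scale = max(y.std(), 1.0)
    if rx.std() <= 1e-12 * x_scale or ry.std() <= 1e-12 * y_scale:
        return 0.0, 1.0
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    if df <= 0:
        return r, float("nan")
    r_ = min(max(r, -1 + 1e-15), 1 - 1e-15)
    t = r_ * np.sqrt(df / (1 - r_ * r_))
    p = float(2 * stats.t.sf(abs(t), df))
    return r, p
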