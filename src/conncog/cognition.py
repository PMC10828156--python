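"""Cognitive targets: imputation, z-scoring, PCA composites, KMO.

The 14-test battery is reduced to prediction targets: a global composite
(one-component PCA), data-driven profiles (eigenvalue > 1 components,
Varimax-rotated, regression-method scores) and a theoretical composite
(mean of z-scores).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import CognitiveBattery

__all__ = [
    "AGE_BANDS",
    "CompositeSolution",
    "impute_group_median",
    "zscore_invert",
    "varimax",
    "pca_targets",
    "kmo_index",
    "theoretical_composite",
]

#: (low, high) inclusive age bands used for group-median imputation
AGE_BANDS = [(55, 64), (65, 74), (75, 85)]


@dataclass
class CompositeSolution:
    """PCA composite solution over the standardized battery."""

    loadings: np.ndarray  # tests x components
    scores: np.ndarray  # subjects x components, mean 0 / var 1
    eigenvalues: np.ndarray  # all eigenvalues of the correlation matrix
    rotation: str  # "none" | "varimax"
    kmo: float

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def _age_band(age: float) -> int:
    for b, (lo, hi) in enumerate(AGE_BANDS):
        if lo <= age <= hi:
            return b
    # outside the configured range: nearest band
    return 0 if age < AGE_BANDS[0][0] else len(AGE_BANDS) - 1


def impute_group_median(
    battery: CognitiveBattery,
    subjects: pd.DataFrame,
    max_missing: int = 3,
) -> tuple[CognitiveBattery, list[str]]:
    """Replace missing scores by the sex x age-band median.

    Subjects with more than ``max_missing`` missing values are excluded
    (returned as the second element).  Empty cells fall back to the
    whole-sample median of the test.
    """
    scores = battery.scores.copy()
    n_missing = np.isnan(scores).sum(axis=1)
    excluded_mask = n_missing > max_missing
    excluded = subjects.loc[excluded_mask, "subject_id"].tolist()
    if excluded:
        warnings.warn(
            f"excluding {len(excluded)} subject(s) with more than "
            f"{max_missing} missing values"
        )
    keep = ~excluded_mask
    scores = scores[keep]
    demo = subjects.loc[keep].reset_index(drop=True)
    bands = demo["age"].map(_age_band).to_numpy()
    sexes = demo["sex"].to_numpy()
    for t in range(scores.shape[1]):
        col = scores[:, t]
        miss = np.isnan(col)
        if not miss.any():
            continue
        overall = np.nanmedian(col)
        for i in np.flatnonzero(miss):
            cell = (bands == bands[i]) & (sexes == sexes[i]) & ~np.isnan(col)
            col[i] = np.median(col[cell]) if cell.any() else overall
    return (
        CognitiveBattery(scores, battery.invert_flags, list(battery.test_names)),
        excluded,
    )


def zscore_invert(battery: CognitiveBattery) -> np.ndarray:
    """Column z-scores (population sd) with inverted tests sign-flipped.

    After this step, higher always means better performance.
    """
    scores = battery.scores
    if np.isnan(scores).any():
        raise ValueError("battery contains missing values; impute first")
    sd = scores.std(axis=0)  # population denominator
    if np.any(sd == 0):
        raise ValueError("zero-variance test column")
    z = (scores - scores.mean(axis=0)) / sd
    z[:, battery.invert_flags] *= -1.0
    return z


def varimax(
    loadings: np.ndarray, max_iter: int = 500, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation of a loading matrix.

    Returns the rotated loadings and the orthogonal rotation matrix.
    Identity for a single component.
    """
    L = np.asarray(loadings, dtype=float)
    p, k = L.shape
    R = np.eye(k)
    if k < 2:
        return L.copy(), R
    var_old = 0.0
    for _ in range(max_iter):
        rotated = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (rotated**3 - rotated @ np.diag((rotated**2).sum(axis=0)) / p)
        )
        R = u @ vt
        var_new = s.sum()
        if var_new <= var_old * (1 + tol):
            break
        var_old = var_new
    return L @ R, R


def _fix_signs(loadings: np.ndarray, scores: np.ndarray) -> None:
    """Flip each component so its largest-magnitude loading is positive."""
    for c in range(loadings.shape[1]):
        if loadings[np.argmax(np.abs(loadings[:, c])), c] < 0:
            loadings[:, c] *= -1.0
            scores[:, c] *= -1.0


def pca_targets(z_matrix: np.ndarray, mode: str = "global") -> CompositeSolution:
    """PCA targets on the standardized battery.

    ``global`` keeps the first component; ``profiles`` keeps components
    with eigenvalue > 1 and applies Varimax.  Scores use the regression
    method on the correlation matrix and are standardized (population
    sd).  Loadings are sign-fixed so the largest-magnitude loading of
    each component is positive.
    """
    z = np.asarray(z_matrix, dtype=float)
    n, p = z.shape
    if n <= p:
        raise ValueError("need more subjects than tests")
    corr = (z - z.mean(0)).T @ (z - z.mean(0)) / (n * np.outer(z.std(0), z.std(0)))
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    if mode == "global":
        k = 1
        rotation = "none"
    elif mode == "profiles":
        k = int(np.sum(eigval > 1.0))
        rotation = "varimax"
        if k < 2:
            warnings.warn(
                f"profiles mode retained {k} component(s) by the eigenvalue>1 rule"
            )
            k = max(k, 1)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    loadings = eigvec[:, :k] * np.sqrt(np.clip(eigval[:k], 0, None))
    if rotation == "varimax":
        loadings, _ = varimax(loadings)
    # regression-method component scores on the correlation matrix
    weights = np.linalg.pinv(corr) @ loadings
    scores = ((z - z.mean(0)) / z.std(0)) @ weights
    scores = (scores - scores.mean(0)) / scores.std(0)
    _fix_signs(loadings, scores)
    return CompositeSolution(loadings, scores, eigval, rotation, kmo_index(z))


def kmo_index(z_matrix: np.ndarray) -> float:
    """Kaiser-Meyer-Olkin sampling adequacy of the battery.

    ``KMO = sum(r^2) / (sum(r^2) + sum(p^2))`` over off-diagonal simple
    correlations r and anti-image partial correlations p.
    """
    z = np.asarray(z_matrix, dtype=float)
    if z.shape[1] < 3:
        raise ValueError("KMO requires at least 3 variables")
    corr = np.corrcoef(z, rowvar=False)
    try:
        inv = np.linalg.inv(corr)
    except np.linalg.LinAlgError:
        warnings.warn("singular correlation matrix; using regularized inverse")
        inv = np.linalg.inv(corr + 1e-8 * np.eye(corr.shape[0]))
    d = np.sqrt(np.outer(np.diag(inv), np.diag(inv)))
    partial = -inv / d
    off = ~np.eye(corr.shape[0], dtype=bool)
    r2 = np.sum(corr[off] ** 2)
    p2 = np.sum(partial[off] ** 2)
    return float(r2 / (r2 + p2))


def theoretical_composite(z_matrix: np.ndarray) -> np.ndarray:
    """Per-subject mean of the standardized (inverted) test scores."""
    z = np.asarray(z_matrix, dtype=float)
    return z.mean(axis=1)


def build_targets(
    battery: CognitiveBattery, subjects: pd.DataFrame
) -> tuple[pd.DataFrame, CompositeSolution, CompositeSolution, list[str]]:
    """Convenience wrapper: impute -> z-score -> all targets.

    Returns a tidy target table (subject_id, global, per-profile
    columns, theoretical), the global and profile solutions, and the
    excluded subject ids.
    """
    imputed, excluded = impute_group_median(battery, subjects)
    kept = subjects.loc[~subjects["subject_id"].isin(excluded)].reset_index(drop=True)
    z = zscore_invert(imputed)
    global_sol = pca_targets(z, mode="global")
    profile_sol = pca_targets(z, mode="profiles")
    table = pd.DataFrame({"subject_id": kept["subject_id"]})
    table["global"] = global_sol.scores[:, 0]
    for c in range(profile_sol.n_components):
        table[f"comp{c + 1}"] = profile_sol.scores[:, c]
    table["theoretical"] = theoretical_composite(z)
    return table, global_sol, profile_sol, excluded
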