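"""Synthetic cohort generation.

Produces cohorts with the statistical structure the downstream analysis
assumes: community-structured node time series (for FC), sparse positive
structural connectomes, regional grey-matter volumes with an age-related
decline, demographics with mild interdependence, and a cognitive test
battery whose scores depend on demographics and on a latent brain factor
planted in a known sparse set of nodes.  Every draw flows from a single
seed so cohorts are bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .base import DEFAULT_NETWORK_NAMES, Connectome, ParcellationScheme

__all__ = [
    "CohortConfig",
    "CognitiveBattery",
    "SyntheticCohort",
    "generate_parcellation",
    "generate_timeseries_panel",
    "generate_sc_matrix",
    "generate_gmv",
    "generate_battery",
    "generate_cohort",
]


@dataclass
class CognitiveBattery:
    """Raw cognitive test scores with inversion flags and missingness.

    ``scores`` holds NaN at missing entries; ``invert_flags[t]`` is True
    when a higher raw value on test ``t`` means worse performance (e.g.
    completion times, error counts).
    """

    scores: np.ndarray  # (n_subjects, n_tests), NaN = missing
    invert_flags: np.ndarray  # (n_tests,) bool
    test_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.invert_flags = np.asarray(self.invert_flags, dtype=bool)
        if self.scores.ndim != 2:
            raise ValueError("scores must be 2-D (subjects x tests)")
        if self.invert_flags.size != self.scores.shape[1]:
            raise ValueError("invert_flags length must equal the number of tests")
        if not self.test_names:
            self.test_names = [f"test{t:02d}" for t in range(self.scores.shape[1])]

    @property
    def n_tests(self) -> int:
        return self.scores.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.scores)


@dataclass
class CohortConfig:
    """Knobs for :func:`generate_cohort`.

    The cognitive target is built as

    ``y = beta_age*z(age) + beta_sex*z(sex) + beta_edu*z(edu) +
    sqrt(brain_r2)*brain_score + noise``

    where ``brain_score`` is the standardized mean of standardized GMV
    over ``n_signal_nodes`` randomly chosen nodes and the noise variance
    is set so the planted brain signal explains ``brain_r2`` of the
    target variance (in expectation).  The achieved fraction is recorded
    in the cohort's truth record.
    """

    n_subjects: int = 200
    n_nodes: int = 400
    n_networks: int = 7
    n_timepoints: int = 296  # 300 volumes minus 4 discarded
    n_tests: int = 14
    n_test_factors: int = 1
    seed: int = 0
    age_range: tuple[float, float] = (55.0, 85.0)
    beta_age: float = -0.3
    beta_sex: float = 0.05
    beta_edu: float = 0.2
    brain_r2: float = 0.2
    n_signal_nodes: int = 20
    noise_floor: float = 0.05  # minimal residual variance of the target
    community_strength: float = 0.4
    sc_density: float = 0.3
    sc_weight_scale: float = 100.0
    gmv_age_slope: float = 0.25  # fractional GMV loss across the age range
    gmv_noise: float = 0.08
    missing_rate: float = 0.02
    n_inverted_tests: int = 4
    fc_mode: str = "panel"  # "panel" | "matrix" | "none"

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be at least 2")
        if not 0 <= self.brain_r2 < 1:
            raise ValueError("brain_r2 must lie in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.noise_floor <= 0:
            raise ValueError("noise variance must be positive")
        if self.fc_mode not in ("panel", "matrix", "none"):
            raise ValueError(f"unknown fc_mode {self.fc_mode!r}")


@dataclass
class SyntheticCohort:
    """Everything :func:`generate_cohort` produces, plus the truth record."""

    config: CohortConfig
    subjects: pd.DataFrame
    parcellation: ParcellationScheme
    fc_panels: list[np.ndarray] | None
    sc: list[Connectome]
    gmv: np.ndarray
    battery: CognitiveBattery
    truth: dict


def generate_parcellation(
    n_nodes: int, n_networks: int = 7, seed: int = 0
) -> ParcellationScheme:
    """Random near-balanced partition of ``n_nodes`` into networks.

    Network sizes differ by at most one; which nodes land in which
    network is a seed-determined permutation.
    """
    if n_networks < 1 or n_nodes < n_networks:
        raise ValueError(
            f"need 1 <= n_networks <= n_nodes, got {n_networks} and {n_nodes}"
        )
    rng = np.random.default_rng(seed)
    labels = np.arange(n_nodes) % n_networks  # sizes differ by <= 1
    network_of = labels[rng.permutation(n_nodes)]
    names = (
        list(DEFAULT_NETWORK_NAMES)
        if n_networks == 7
        else [f"net{g}" for g in range(n_networks)]
    )
    centroids = rng.uniform(-70, 70, size=(n_nodes, 3))
    return ParcellationScheme(network_of, names, centroids=centroids)


def generate_timeseries_panel(
    parcellation: ParcellationScheme,
    n_timepoints: int = 296,
    community_strength: float = 0.4,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Node x time panel where same-network nodes share a latent signal.

    Each node's series is ``c * g_net + sqrt(1 - c^2) * eps`` with unit
    marginal variance, so the expected within-network correlation is
    ``c^2`` and the between-network correlation is ~0.
    """
    if n_timepoints < 30:
        raise ValueError("n_timepoints must be >= 30")
    if not 0 <= community_strength < 1:
        raise ValueError("community_strength must lie in [0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    c = community_strength
    latent = rng.standard_normal((parcellation.n_networks, n_timepoints))
    noise = rng.standard_normal((parcellation.n_nodes, n_timepoints))
    return c * latent[parcellation.network_of] + np.sqrt(1.0 - c * c) * noise


def generate_sc_matrix(
    parcellation: ParcellationScheme,
    density: float = 0.3,
    weight_scale: float = 100.0,
    seed: int = 0,
    rng: np.random.Generator | None = None,
    subject_id: str = "synthetic",
) -> Connectome:
    """Sparse symmetric non-negative streamline-count-like matrix.

    Edge presence is Bernoulli(density) per unordered pair; weights are
    gamma-distributed raw counts (the analysis pipeline applies its own
    log transform downstream).
    """
    if not 0 < density <= 1:
        raise ValueError("density must lie in (0, 1]")
    if weight_scale <= 0:
        raise ValueError("weight_scale must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = parcellation.n_nodes
    iu = np.triu_indices(n, k=1)
    present = rng.random(iu[0].size) < density
    weights = np.where(present, weight_scale * rng.gamma(2.0, 1.0, iu[0].size), 0.0)
    m = np.zeros((n, n))
    m[iu] = weights
    m += m.T
    return Connectome(subject_id, "SC", m)


def generate_gmv(
    ages: np.ndarray,
    parcellation: ParcellationScheme,
    signal_nodes: np.ndarray,
    brain_factor: np.ndarray,
    age_range: tuple[float, float] = (55.0, 85.0),
    age_slope: float = 0.25,
    noise: float = 0.08,
    signal_strength: float = 0.15,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Positive regional grey-matter volumes with age decline.

    The latent ``brain_factor`` (one value per subject) is embedded into
    the ``signal_nodes`` columns with relative amplitude
    ``signal_strength`` so downstream feature-importance tests have a
    known answer.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    ages = np.asarray(ages, dtype=float)
    n_subj, n_nodes = ages.size, parcellation.n_nodes
    base = rng.uniform(2.0, 6.0, n_nodes)  # node-specific volume scale
    lo, hi = age_range
    decline = 1.0 - age_slope * (ages - lo) / max(hi - lo, 1e-12)
    gmv = np.outer(decline, base)
    gmv *= 1.0 + noise * rng.standard_normal((n_subj, n_nodes))
    gmv[:, signal_nodes] *= 1.0 + signal_strength * brain_factor[:, None]
    return np.clip(gmv, 1e-3, None)


def generate_battery(
    factors: np.ndarray,
    n_tests: int = 14,
    loading: float = 0.7,
    invert_flags: np.ndarray | None = None,
    missing_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> CognitiveBattery:
    """Battery of test scores loading block-wise on latent factors.

    ``factors`` is ``(n_subjects, n_factors)``; tests are split into
    near-equal contiguous blocks, one block per factor.  Inverted tests
    are stored with flipped sign so that a higher raw value means worse
    performance, matching their ``invert_flags``.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    factors = np.atleast_2d(np.asarray(factors, dtype=float))
    if factors.shape[0] == 1 and factors.shape[1] > factors.shape[0]:
        factors = factors.T
    n_subj, n_factors = factors.shape
    if invert_flags is None:
        flags = np.zeros(n_tests, dtype=bool)
        flags[:: max(n_tests // 4, 1)][:4] = True
    else:
        flags = np.asarray(invert_flags, dtype=bool)
    block = np.array_split(np.arange(n_tests), n_factors)
    scores = np.empty((n_subj, n_tests))
    for f, tests in enumerate(block):
        for t in tests:
            eps = rng.standard_normal(n_subj)
            scores[:, t] = loading * factors[:, f] + np.sqrt(1 - loading**2) * eps
    scores[:, flags] *= -1.0  # higher raw value = worse performance
    if missing_rate > 0:
        miss = rng.random(scores.shape) < missing_rate
        scores[miss] = np.nan
    return CognitiveBattery(scores, flags)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort from a single seed.

    Returns subjects (demographics + latent target), the parcellation,
    per-subject node time series and/or SC connectomes, the GMV matrix,
    the cognitive battery, and a truth record with the generating
    coefficients, signal nodes and achieved brain/confound R^2.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    ss = rng.spawn(6)
    rng_demo, rng_gmv, rng_fc, rng_sc, rng_cog, rng_target = ss

    parcellation = generate_parcellation(cfg.n_nodes, cfg.n_networks, seed=cfg.seed)

    # --- demographics -------------------------------------------------
    n = cfg.n_subjects
    lo, hi = cfg.age_range
    age = rng_demo.uniform(lo, hi, n)
    sex = rng_demo.integers(0, 2, n).astype(float)
    edu_latent = (
        4.5
        + 0.6 * (sex - 0.5)
        - 0.02 * (age - (lo + hi) / 2)
        + 1.5 * rng_demo.standard_normal(n)
    )
    education = np.clip(np.round(edu_latent), 1, 8).astype(int)
    etiv = 1450.0 + 100.0 * sex + 130.0 * rng_demo.standard_normal(n)
    demtect = np.clip(
        np.round(15.5 - 0.05 * (age - 70) + 1.8 * rng_demo.standard_normal(n)), 0, 18
    ).astype(int)

    # --- brain factor planted in GMV ---------------------------------
    signal_nodes = np.sort(
        rng_gmv.choice(cfg.n_nodes, size=min(cfg.n_signal_nodes, cfg.n_nodes), replace=False)
    )
    brain_factor = rng_gmv.standard_normal(n)
    gmv = generate_gmv(
        age,
        parcellation,
        signal_nodes,
        brain_factor,
        age_range=cfg.age_range,
        age_slope=cfg.gmv_age_slope,
        noise=cfg.gmv_noise,
        rng=rng_gmv,
    )
    # observable brain score: standardized mean of z-scored signal-node GMV
    gz = (gmv - gmv.mean(0)) / np.where(gmv.std(0) > 0, gmv.std(0), 1.0)
    brain_score = _zscore(gz[:, signal_nodes].mean(axis=1))

    # --- target -------------------------------------------------------
    confound_part = (
        cfg.beta_age * _zscore(age)
        + cfg.beta_sex * _zscore(sex)
        + cfg.beta_edu * _zscore(education.astype(float))
    )
    brain_part = np.sqrt(cfg.brain_r2) * brain_score
    signal = confound_part + brain_part
    noise_var = max(1.0 - cfg.brain_r2, cfg.noise_floor)
    target = signal + np.sqrt(noise_var) * rng_target.standard_normal(n)

    # achieved R^2 of the generating pieces, by direct regression
    def _r2_of(pred: np.ndarray) -> float:
        X = np.column_stack([np.ones(n), pred])
        beta, *_ = np.linalg.lstsq(X, target, rcond=None)
        resid = target - X @ beta
        return float(1.0 - resid.var() / target.var())

    truth = {
        "planted_brain_r2": cfg.brain_r2,
        "signal_nodes": signal_nodes,
        "brain_factor": brain_factor,
        "brain_score": brain_score,
        "betas": {"age": cfg.beta_age, "sex": cfg.beta_sex, "edu": cfg.beta_edu},
        "target": target,
        "true_r2_brain": _r2_of(brain_score),
        "true_r2_confounds": _r2_of(confound_part) if np.ptp(confound_part) > 0 else 0.0,
        "true_r2_total": _r2_of(signal) if np.ptp(signal) > 0 else 0.0,
    }

    # --- battery ------------------------------------------------------
    if cfg.n_test_factors == 1:
        factors = _zscore(target)[:, None]
    else:
        extra = rng_cog.standard_normal((n, cfg.n_test_factors - 1))
        factors = np.column_stack([_zscore(target), extra])
    battery = generate_battery(
        factors,
        n_tests=cfg.n_tests,
        missing_rate=cfg.missing_rate,
        rng=rng_cog,
    )

    # --- connectivity -------------------------------------------------
    fc_panels: list[np.ndarray] | None = None
    if cfg.fc_mode != "none":
        n_t = cfg.n_timepoints if cfg.fc_mode == "panel" else max(cfg.n_timepoints, 30)
        fc_panels = [
            generate_timeseries_panel(
                parcellation, n_t, cfg.community_strength, rng=rng_fc
            )
            for _ in range(n)
        ]
    sc = [
        generate_sc_matrix(
            parcellation,
            cfg.sc_density,
            cfg.sc_weight_scale,
            rng=rng_sc,
            subject_id=f"sub-{i:04d}",
        )
        for i in range(n)
    ]

    subjects = pd.DataFrame(
        {
            "subject_id": [f"sub-{i:04d}" for i in range(n)],
            "age": age,
            "sex": sex.astype(int),
            "education": education,
            "etiv": etiv,
            "demtect": demtect,
            "target_latent": target,
        }
    )
    return SyntheticCohort(cfg, subjects, parcellation, fc_panels, sc, gmv, battery, truth)


def flag_gmv_outliers(gmv: np.ndarray, factor: float = 1.5) -> np.ndarray:
    """Subjects whose mean GMV lies outside ``factor`` x IQR of the sample.

    Implements the quality-control exclusion rule; off by default during
    synthesis, exposed for pipeline use.
    """
    mean_gmv = np.asarray(gmv, dtype=float).mean(axis=1)
    q1, q3 = np.percentile(mean_gmv, [25, 75])
    iqr = q3 - q1
    if iqr == 0:
        warnings.warn("zero IQR in mean GMV; no outliers flagged")
        return np.zeros(mean_gmv.size, dtype=bool)
    return (mean_gmv < q1 - factor * iqr) | (mean_gmv > q3 + factor * iqr)
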