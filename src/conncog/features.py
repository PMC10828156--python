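"""Connectome feature construction.

FC pipeline: Pearson correlation of node time series -> surrogate-based
edge significance filter (phase randomization, permutation p-values) ->
Fisher r-to-z -> positive (or negative) part.  SC pipeline: log
transform of streamline-count weights.  Both feed the nodal
within-/inter-network connectivity metrics and the ratio score, which
are assembled into feature sets A, B, C or the full concatenation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .base import Connectome, FeatureMatrix, ParcellationScheme

__all__ = [
    "correlation_matrix",
    "phase_randomized_surrogate",
    "edge_significance_filter",
    "fisher_z",
    "positive_part",
    "negative_part",
    "log10_sc",
    "within_network_connectivity",
    "inter_network_connectivity",
    "ratio_score",
    "NodalMetrics",
    "nodal_metrics",
    "fc_pipeline",
    "assemble_feature_set",
    "FSET_COLUMN_COUNTS",
]

R_CLIP = 1.0 - 1e-7


# ---------------------------------------------------------------------------
# FC construction
# ---------------------------------------------------------------------------

def correlation_matrix(panel: np.ndarray, subject_id: str = "subject") -> Connectome:
    """Pearson correlation matrix of a node x time panel.

    Zero-variance nodes are flagged with a warning and their
    correlations set to 0.
    """
    panel = np.asarray(panel, dtype=float)
    if panel.ndim != 2 or panel.shape[1] < 3:
        raise ValueError("panel must be 2-D with at least 3 timepoints")
    if not np.all(np.isfinite(panel)):
        raise ValueError("panel contains non-finite values")
    sd = panel.std(axis=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(f"{flat.sum()} zero-variance node(s); correlations set to 0")
        panel = panel.copy()
        # give flat rows unit variance noise-free placeholders, zero later
        panel[flat] += np.arange(panel.shape[1])
    r = np.corrcoef(panel)
    r[flat, :] = 0.0
    r[:, flat] = 0.0
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    # Connectome construction zeroes the diagonal
    return Connectome(subject_id, "FC", r - np.diag(np.diag(r)))


def phase_randomized_surrogate(
    series: np.ndarray, seed: int | None = None, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Fourier phase-randomized surrogate of a real series.

    The amplitude spectrum is preserved exactly; phases of the
    non-DC/non-Nyquist bins are replaced by uniform random phases, with
    conjugate symmetry implied by the real FFT so the output is real.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise ValueError("series must be 1-D with length >= 4")
    if np.ptp(x) == 0:
        warnings.warn("constant series; surrogate equals the input")
        return x.copy()
    if rng is None:
        rng = np.random.default_rng(seed)
    n = x.size
    spec = np.fft.rfft(x)
    phases = rng.uniform(0, 2 * np.pi, spec.size)
    phases[0] = 0.0
    if n % 2 == 0:
        phases[-1] = 0.0  # Nyquist bin must stay real
    return np.fft.irfft(np.abs(spec) * np.exp(1j * phases), n=n)


def _surrogate_panel(panel: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independently phase-randomize each node's series (destroys all
    cross-correlations, preserves each autospectrum)."""
    n, t = panel.shape
    spec = np.fft.rfft(panel, axis=1)
    phases = rng.uniform(0, 2 * np.pi, spec.shape)
    phases[:, 0] = 0.0
    if t % 2 == 0:
        phases[:, -1] = 0.0
    return np.fft.irfft(np.abs(spec) * np.exp(1j * phases), n=t, axis=1)


def edge_significance_filter(
    panel: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    subject_id: str = "subject",
) -> Connectome:
    """Zero out FC edges not significant under a surrogate null.

    For every node pair the observed |r| is compared against |r| from
    ``n_perm`` phase-randomized surrogate panels; the two-sided p-value
    uses the add-one rule ``(k + 1) / (n_perm + 1)`` and edges with
    ``p >= alpha`` are set to zero.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    observed = correlation_matrix(panel, subject_id=subject_id)
    r_obs = np.abs(observed.matrix)
    rng = np.random.default_rng(seed)
    panel = np.asarray(panel, dtype=float)
    exceed = np.zeros_like(r_obs, dtype=np.int64)
    for _ in range(n_perm):
        surr = _surrogate_panel(panel, rng)
        with np.errstate(invalid="ignore"):
            r_null = np.abs(np.corrcoef(surr))
        r_null = np.nan_to_num(r_null)
        exceed += r_null >= r_obs
    pvals = (exceed + 1) / (n_perm + 1)
    filtered = np.where(pvals < alpha, observed.matrix, 0.0)
    return Connectome(subject_id, "FC", filtered)


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def fisher_z(matrix: np.ndarray) -> np.ndarray:
    """Elementwise Fisher r-to-z (atanh); zeros map to zeros.

    Off-diagonal |r| >= 1 is clipped to ``1 - 1e-7`` with a warning.
    """
    r = np.asarray(matrix, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        warnings.warn("|r| >= 1 encountered; clipping before atanh")
        r = np.clip(r, -R_CLIP, R_CLIP)
    return np.arctanh(r)


def positive_part(matrix: np.ndarray) -> np.ndarray:
    """Keep entries > 0, zero the rest."""
    m = np.asarray(matrix, dtype=float)
    return np.where(m > 0, m, 0.0)


def negative_part(matrix: np.ndarray) -> np.ndarray:
    """Absolute values of entries < 0; everything else zero."""
    m = np.asarray(matrix, dtype=float)
    return np.where(m < 0, -m, 0.0)


def log10_sc(matrix: np.ndarray, zero_preserving: bool = True) -> np.ndarray:
    """Log-transform non-negative SC weights.

    Default maps ``w -> log10(1 + w)`` so zero stays zero; with
    ``zero_preserving=False`` the plain ``log10(w)`` is applied on the
    nonzero support only.
    """
    m = np.asarray(matrix, dtype=float)
    if np.any(m < 0):
        raise ValueError("SC weights must be non-negative")
    if zero_preserving:
        return np.log10(1.0 + m)
    out = np.zeros_like(m)
    nz = m > 0
    out[nz] = np.log10(m[nz])
    return out


# ---------------------------------------------------------------------------
# Nodal metrics
# ---------------------------------------------------------------------------

def _network_edge_count(
    matrix: np.ndarray, idx: np.ndarray, denominator: str
) -> float:
    """Edge-count denominator E_g for network g.

    ``subject_edges`` counts nonzero within-network unordered pairs in
    this subject's matrix; ``all_pairs`` counts every possible pair.
    """
    n_g = idx.size
    if denominator == "all_pairs":
        return n_g * (n_g - 1) / 2.0
    if denominator == "subject_edges":
        sub = matrix[np.ix_(idx, idx)]
        return float(np.count_nonzero(np.triu(sub, k=1)))
    raise ValueError(f"unknown denominator convention {denominator!r}")


def within_network_connectivity(
    connectome: Connectome,
    parcellation: ParcellationScheme,
    denominator: str = "subject_edges",
) -> np.ndarray:
    """Per-node sum of weights to same-network nodes, divided by the
    network's edge count E_g (0 when E_g = 0)."""
    w = connectome.matrix
    if w.shape[0] != parcellation.n_nodes:
        raise ValueError("connectome and parcellation dimensions disagree")
    values = np.zeros(parcellation.n_nodes)
    for g in range(parcellation.n_networks):
        idx = parcellation.nodes_in(g)
        e_g = _network_edge_count(w, idx, denominator)
        if e_g > 0:
            values[idx] = w[np.ix_(idx, idx)].sum(axis=1) / e_g
    return values


def inter_network_connectivity(
    connectome: Connectome,
    parcellation: ParcellationScheme,
    denominator: str = "subject_edges",
) -> np.ndarray:
    """Per-node sum of weights to nodes outside its network, divided by
    the node's own network's edge count E_g (same convention as
    :func:`within_network_connectivity`)."""
    w = connectome.matrix
    if w.shape[0] != parcellation.n_nodes:
        raise ValueError("connectome and parcellation dimensions disagree")
    values = np.zeros(parcellation.n_nodes)
    total_strength = w.sum(axis=1)
    for g in range(parcellation.n_networks):
        idx = parcellation.nodes_in(g)
        e_g = _network_edge_count(w, idx, denominator)
        if e_g > 0:
            within_sum = w[np.ix_(idx, idx)].sum(axis=1)
            values[idx] = (total_strength[idx] - within_sum) / e_g
    return values


def ratio_score(within: np.ndarray, inter: np.ndarray) -> np.ndarray:
    """Within / inter per node; 0 where the inter value is 0."""
    within = np.asarray(within, dtype=float)
    inter = np.asarray(inter, dtype=float)
    if within.shape != inter.shape:
        raise ValueError("within and inter vectors must have equal length")
    out = np.zeros_like(within)
    nz = inter != 0
    out[nz] = within[nz] / inter[nz]
    return out


@dataclass
class NodalMetrics:
    """Stacked nodal metrics for one modality across subjects.

    Each array is ``(n_subjects, n_nodes)``.
    """

    modality: str
    within: np.ndarray
    inter: np.ndarray
    ratio: np.ndarray

    def __post_init__(self) -> None:
        self.within = np.atleast_2d(np.asarray(self.within, dtype=float))
        self.inter = np.atleast_2d(np.asarray(self.inter, dtype=float))
        self.ratio = np.atleast_2d(np.asarray(self.ratio, dtype=float))
        if not (self.within.shape == self.inter.shape == self.ratio.shape):
            raise ValueError("metric arrays must share one shape")

    @property
    def n_subjects(self) -> int:
        return self.within.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.within.shape[1]


def nodal_metrics(
    connectomes: list[Connectome],
    parcellation: ParcellationScheme,
    denominator: str = "subject_edges",
) -> NodalMetrics:
    """Compute within/inter/ratio for a list of same-modality connectomes."""
    if not connectomes:
        raise ValueError("no connectomes given")
    modality = connectomes[0].modality
    within, inter = [], []
    for c in connectomes:
        if c.modality != modality:
            raise ValueError("mixed modalities in one metric batch")
        within.append(within_network_connectivity(c, parcellation, denominator))
        inter.append(inter_network_connectivity(c, parcellation, denominator))
    w = np.vstack(within)
    b = np.vstack(inter)
    r = np.vstack([ratio_score(wi, bi) for wi, bi in zip(w, b)])
    return NodalMetrics(modality, w, b, r)


def fc_pipeline(
    panel: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    subject_id: str = "subject",
    part: str = "positive",
) -> Connectome:
    """Full FC construction: correlate, filter, Fisher-z, sign-split.

    ``part`` selects the positive branch (default) or the
    negative-correlation branch used by feature set C.
    """
    filtered = edge_significance_filter(
        panel, n_perm=n_perm, alpha=alpha, seed=seed, subject_id=subject_id
    )
    z = fisher_z(filtered.matrix)
    keep = positive_part(z) if part == "positive" else negative_part(z)
    return Connectome(subject_id, "FC", keep)


# ---------------------------------------------------------------------------
# Feature-set assembly
# ---------------------------------------------------------------------------

#: column counts on a 400-node parcellation, per feature set
FSET_COLUMN_COUNTS = {"A": 2000, "B": 1200, "C": 2800, "full": 2800}

_FSET_BLOCKS = {
    # (component key, metric) in assembly order
    "A": [("fc", "within"), ("fc", "inter"), ("sc", "within"), ("sc", "inter")],
    "B": [("fc", "ratio"), ("sc", "ratio")],
    "C": [
        ("fc", "within"),
        ("fc", "inter"),
        ("fc_neg", "within"),
        ("fc_neg", "inter"),
        ("sc", "within"),
        ("sc", "inter"),
    ],
    "full": [
        ("fc", "within"),
        ("fc", "inter"),
        ("fc", "ratio"),
        ("sc", "within"),
        ("sc", "inter"),
        ("sc", "ratio"),
    ],
}


def assemble_feature_set(
    fset: str,
    parcellation: ParcellationScheme,
    subject_ids: list[str],
    fc: NodalMetrics | None = None,
    sc: NodalMetrics | None = None,
    gmv: np.ndarray | None = None,
    fc_neg: NodalMetrics | None = None,
    extra_demographics: pd.DataFrame | None = None,
) -> FeatureMatrix:
    """Assemble feature set A, B, C or the full concatenation.

    Column counts on 400 nodes: A = 2000 (FC/SC within+inter + GMV),
    B = 1200 (FC/SC ratio + GMV), C = 2800 (positive-FC, negative-FC and
    SC within+inter + GMV), full = 2800 (FC/SC within+inter+ratio +
    GMV).  ``extra_demographics`` (age, sex, education) appends 3
    columns.
    """
    if fset not in _FSET_BLOCKS:
        raise ValueError(f"unknown feature set {fset!r}")
    components = {"fc": fc, "sc": sc, "fc_neg": fc_neg}
    n_subj = len(subject_ids)
    blocks: list[np.ndarray] = []
    meta_rows: list[dict] = []

    def _add_block(values: np.ndarray, modality: str, metric: str, nodal: bool) -> None:
        if values.shape[0] != n_subj:
            raise ValueError(
                f"{modality}/{metric} has {values.shape[0]} subjects, expected {n_subj}"
            )
        blocks.append(values)
        for col in range(values.shape[1]):
            node = col if nodal else -1
            meta_rows.append(
                {
                    "name": f"{modality}_{metric}_{col:03d}" if nodal else f"{metric}",
                    "modality": modality,
                    "metric": metric,
                    "node": node,
                    "network": int(parcellation.network_of[col]) if nodal else -1,
                }
            )

    for key, metric in _FSET_BLOCKS[fset]:
        comp = components[key]
        if comp is None:
            raise ValueError(f"feature set {fset!r} requires component {key!r}")
        if comp.n_nodes != parcellation.n_nodes:
            raise ValueError("metric node count does not match parcellation")
        _add_block(getattr(comp, metric), key, metric, nodal=True)

    if gmv is None:
        raise ValueError("all feature sets require the GMV component")
    gmv = np.atleast_2d(np.asarray(gmv, dtype=float))
    _add_block(gmv, "gmv", "volume", nodal=True)

    if extra_demographics is not None:
        extra = extra_demographics.loc[:, ["age", "sex", "education"]]
        if len(extra) != n_subj:
            raise ValueError("extra demographics subject count mismatch")
        for col in extra.columns:
            blocks.append(extra[col].to_numpy(dtype=float)[:, None])
            meta_rows.append(
                {"name": col, "modality": "extra", "metric": col, "node": -1, "network": -1}
            )

    values = np.hstack(blocks)
    return FeatureMatrix(values, pd.DataFrame(meta_rows), list(subject_ids))
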