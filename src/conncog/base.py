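"""Shared domain types: parcellation, connectomes, feature matrices."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_NETWORK_NAMES = [
    "visual",
    "sensorimotor",
    "limbic",
    "frontoparietal",
    "default_mode",
    "dorsal_attention",
    "ventral_attention",
]

SYMMETRY_TOL = 1e-10


@dataclass(frozen=True)
class ParcellationScheme:
    """Assignment of cortical nodes to resting-state networks.

    Parameters
    ----------
    network_of
        Integer array of length ``n_nodes``; entry ``i`` is the network
        index of node ``i``.  Network indices must form a contiguous
        0-based range.
    network_names
        One label per network.
    centroids
        Optional ``(n_nodes, 3)`` array of node centroids in mm.
    """

    network_of: np.ndarray
    network_names: list[str] = field(default_factory=list)
    centroids: np.ndarray | None = None

    def __post_init__(self) -> None:
        net = np.asarray(self.network_of, dtype=int)
        object.__setattr__(self, "network_of", net)
        if net.ndim != 1 or net.size == 0:
            raise ValueError("network_of must be a non-empty 1-D array")
        uniq = np.unique(net)
        if uniq[0] != 0 or not np.array_equal(uniq, np.arange(uniq.size)):
            raise ValueError("network indices must form a contiguous 0-based range")
        names = list(self.network_names) or [f"net{g}" for g in range(uniq.size)]
        if len(names) != uniq.size:
            raise ValueError(
                f"{len(names)} network names given for {uniq.size} networks"
            )
        object.__setattr__(self, "network_names", names)
        if self.centroids is not None:
            c = np.asarray(self.centroids, dtype=float)
            if c.shape != (net.size, 3):
                raise ValueError("centroids must have shape (n_nodes, 3)")
            object.__setattr__(self, "centroids", c)

    @property
    def n_nodes(self) -> int:
        return self.network_of.size

    @property
    def n_networks(self) -> int:
        return len(self.network_names)

    def nodes_in(self, network: int) -> np.ndarray:
        """Indices of the nodes assigned to ``network``."""
        return np.flatnonzero(self.network_of == network)

    def sizes(self) -> np.ndarray:
        """Number of nodes per network."""
        return np.bincount(self.network_of, minlength=self.n_networks)


@dataclass
class Connectome:
    """One subject's weighted adjacency matrix with a modality tag."""

    subject_id: str
    modality: str  # "FC" | "SC"
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"connectome matrix must be square, got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise ValueError("connectome matrix contains non-finite values")
        asym = np.max(np.abs(m - m.T)) if m.size else 0.0
        if asym > SYMMETRY_TOL:
            raise ValueError(f"matrix asymmetric beyond tolerance ({asym:.3g})")
        # symmetrize by averaging and exclude the diagonal
        m = (m + m.T) / 2.0
        np.fill_diagonal(m, 0.0)
        self.matrix = m

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]


@dataclass
class FeatureMatrix:
    """Subjects x features with per-feature metadata.

    ``feature_meta`` has one row per column of ``values`` with columns
    ``name``, ``modality``, ``metric``, ``node`` and ``network``
    (``node``/``network`` are -1 for non-nodal features such as GMV-free
    demographics).
    """

    values: np.ndarray
    feature_meta: pd.DataFrame
    subject_ids: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be 2-D (subjects x features)")
        if v.shape[1] != len(self.feature_meta):
            raise ValueError("feature_meta length does not match column count")
        if v.shape[0] != len(self.subject_ids):
            raise ValueError("subject_ids length does not match row count")
        if not np.all(np.isfinite(v)):
            raise ValueError("feature matrix contains missing or non-finite values")
        self.values = v

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.subject_ids, name="subject_id"),
            columns=self.feature_meta["name"].tolist(),
        )
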