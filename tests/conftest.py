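import numpy as np
import pytest

from conncog.base import Connectome, ParcellationScheme
from conncog.synthetic import CohortConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def parc6():
    """6 nodes, 2 networks of 3 (hand-set, deterministic)."""
    return ParcellationScheme(np.array([0, 0, 0, 1, 1, 1]), ["netA", "netB"])


@pytest.fixture
def toy_connectome(parc6):
    """Hand-set symmetric weights on the 6-node parcellation."""
    m = np.array(
        [
            [0.0, 0.5, 0.0, 0.2, 0.0, 0.0],
            [0.5, 0.0, 0.3, 0.0, 0.1, 0.0],
            [0.0, 0.3, 0.0, 0.0, 0.0, 0.4],
            [0.2, 0.0, 0.0, 0.0, 0.6, 0.0],
            [0.0, 0.1, 0.0, 0.6, 0.0, 0.7],
            [0.0, 0.0, 0.4, 0.0, 0.7, 0.0],
        ]
    )
    return Connectome("toy", "FC", m)


@pytest.fixture(scope="session")
def small_cohort():
    """Shared small cohort without FC panels (fast)."""
    cfg = CohortConfig(
        n_subjects=100, n_nodes=30, seed=7, fc_mode="none", missing_rate=0.02
    )
    return generate_cohort(cfg)


def brute_force_metrics(matrix, network_of, denominator="subject_edges"):
    """Triple-loop oracle for within/inter/ratio nodal metrics."""
    n = matrix.shape[0]
    networks = np.asarray(network_of)
    within = np.zeros(n)
    inter = np.zeros(n)
    for i in range(n):
        g = networks[i]
        members = [j for j in range(n) if networks[j] == g]
        if denominator == "all_pairs":
            e_g = len(members) * (len(members) - 1) / 2
        else:
            e_g = 0
            for a in members:
                for b in members:
                    if a < b and matrix[a, b] != 0:
                        e_g += 1
        w_sum = sum(matrix[i, j] for j in members if j != i)
        b_sum = sum(matrix[i, j] for j in range(n) if networks[j] != g)
        within[i] = w_sum / e_g if e_g > 0 else 0.0
        inter[i] = b_sum / e_g if e_g > 0 else 0.0
    ratio = np.array(
        [w / b if b != 0 else 0.0 for w, b in zip(within, inter)]
    )
    return within, inter, ratio
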