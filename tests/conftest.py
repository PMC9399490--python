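import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from fcanomaly.atlas import Parcellation, Region, build_edge_index
from fcanomaly.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def toy_parcellation() -> Parcellation:
    """Four regions: two DMN, one SMN, one unlabeled (OTHER)."""
    return Parcellation(
        regions=(
            Region(0, "L_DMN_a", "L", "DMN"),
            Region(1, "R_DMN_b", "R", "DMN"),
            Region(2, "L_SMN_a", "L", "SMN"),
            Region(3, "Brainstem", "NONE", "OTHER"),
        )
    )


@pytest.fixture(scope="session")
def toy_edge_index(toy_parcellation):
    return build_edge_index(toy_parcellation)


@pytest.fixture(scope="session")
def default_cohort():
    """Default study conditions at test scale (40 regions)."""
    return simulate_cohort(SimulationConfig(seed=0, n_regions=40))


@pytest.fixture(scope="session")
def separable_cohort():
    """Strongly separable configuration: 30 shared signal edges, 8-sigma shift."""
    cfg = SimulationConfig(
        seed=11,
        n_regions=40,
        anomaly_shift=8.0,
        anomaly_rate_responder=30,
        anomaly_rate_nonresponder=30,
        signal_edge_pool=30,
    )
    return simulate_cohort(cfg)


def symmetric_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random valid FC matrix: symmetric, unit diagonal, entries in [-1, 1]."""
    m = rng.uniform(-1, 1, size=(n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 1.0)
    return m
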