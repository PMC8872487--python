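import numpy as np
import pytest

from grntrend.io import CountMatrix, PseudotimeAssignment
from grntrend.simulate import SimulationSpec, simulate


@pytest.fixture(scope="session")
def small_truth():
    """One small synthetic data set shared across tests (20 genes, 300 cells)."""
    return simulate(SimulationSpec(p=20, n=300, n_regulators=4, n_edges=8,
                                   depth_mean=500.0, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_counts():
    values = np.array([[1, 0, 2],
                       [0, 3, 1],
                       [5, 0, 0]])
    return CountMatrix(values, ["gA", "gB", "gC"], ["c1", "c2", "c3"])


@pytest.fixture
def ramp_pseudotime():
    return PseudotimeAssignment([f"c{i}" for i in range(6)],
                                np.array([3.0, 1.0, 2.0, 0.5, 5.0, 4.0]))
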