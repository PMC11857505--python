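import numpy as np
import pytest

from sfmetab.core_io import BinInfo, BinMatrix
from sfmetab.synthetic import SimulationConfig, simulate


def make_matrix(values, labels, names=None):
    """Small hand-built BinMatrix for unit tests."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    names = names or [f"B{j} [{1.0 + j:.4f}]" for j in range(p)]
    return BinMatrix(values=values, sample_ids=[f"s{i}" for i in range(n)],
                     labels=list(labels), bins=[BinInfo.from_label(c) for c in names])


@pytest.fixture(scope="session")
def default_dataset():
    """One default-configuration simulated dataset (10 OA / 14 RA, 200 bins)."""
    return simulate(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated dataset for cheap end-to-end checks."""
    return simulate(SimulationConfig(n_bins=40, n_perfect=2, n_informative=10, seed=11))
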