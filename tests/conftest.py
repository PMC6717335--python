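import numpy as np
import pytest
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def si_table():
    """Fixed similarity/value table for read-across oracle comparisons."""
    sims = np.array([0.95, 0.88, 0.82, 0.76, 0.71, 0.55])
    values = np.array([-1.2, -0.4, 0.3, 1.1, 1.6, 2.4])
    ids = [f"n{i}" for i in range(6)]
    return sims, values, ids
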