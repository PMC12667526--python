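import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from citevae.synthetic import FIXTURE_CONFIGS, SimConfig, simulate_cite_seq


@pytest.fixture(scope="session")
def tiny_pair():
    """12 cells, 30 genes, 8 ADTs, 3 clusters — for oracle-scale tests."""
    return simulate_cite_seq(FIXTURE_CONFIGS["tiny"])


@pytest.fixture(scope="session")
def small_pair():
    """A smaller-than-default dataset for fast training-behavior tests."""
    return simulate_cite_seq(
        SimConfig(n_cells=200, n_genes=80, n_adt=12, K=3, seed=7)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
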