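import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from tcspec.synthetic import make_toy_world


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def small_world():
    """A small planted world shared by pipeline-level tests (3 families)."""
    return make_toy_world(
        n_hk_families=3, l_hk=6, l_rr=7, n_interface_pairs=4,
        coupling_strength=3.0, M_per_family=150, seed=11, gibbs_burn_in=150,
    )
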