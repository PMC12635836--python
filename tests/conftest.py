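import numpy as np
import pytest
from hypothesis import settings

import gnmlab as g

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def emb60():
    """60-node hemispheric-shell embedding at cortical (100 mm) scale."""
    return g.make_embedding(60, "shell", 100.0, seed=101)


@pytest.fixture(scope="session")
def emb_small10():
    """100-node shell at 10 mm scale (eta ~ 1/mm informative regime)."""
    return g.make_embedding(100, "shell", 10.0, seed=102)


@pytest.fixture(scope="session")
def target60(emb60):
    """Distance-decayed target with planted long-range hub edges."""
    return g.plant_target(emb60, m=180, decay=0.05,
                          hub_spec={"n_hubs": 8, "long_cutoff": 90.0,
                                    "n_planted": 15}, seed=103)


@pytest.fixture(scope="session")
def random_graphs8():
    """200 random binary graphs with n <= 8 for brute-force cross-checks."""
    rng = np.random.default_rng(7)
    graphs = []
    for _ in range(200):
        n = int(rng.integers(2, 9))
        p = rng.uniform(0.1, 0.9)
        a = (rng.random((n, n)) < p).astype(np.int8)
        a = np.triu(a, 1)
        graphs.append(g.BinaryNetwork(a + a.T))
    return graphs
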