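import numpy as np
import pytest
from hypothesis import settings

import binlmm as bl

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_panel():
    """Structured two-subpopulation panel used across model tests."""
    cfg = bl.SimConfig(n_per_subpop=(100, 100), m=500, fst=0.3, seed=11,
                       prevalence_map={"tropical": 0.5, "non_tropical": 0.5})
    G, labels = bl.simulate_structured_genotypes(cfg)
    G, _ = bl.filter_monomorphic_within(G, labels)
    X = bl.compute_pcs(G, 3)
    K = bl.compute_kinship(G)
    return cfg, G, labels, X, K


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
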