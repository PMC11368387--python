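"""Shared fixtures: small simulated datasets with known truth."""

import numpy as np
import pytest

from lucidpy import FitConfig, LucidData, default_truth, simulate_lucid_data
from lucidpy.simulate import SimDesign


@pytest.fixture(scope="session")
def small_design():
    return SimDesign(n=400, p=4, m=3)


@pytest.fixture(scope="session")
def small_truth(small_design):
    """A well-separated two-cluster truth for a compact design."""
    truth = default_truth(small_design)
    truth.mu = np.vstack([np.full(small_design.m, -1.0), np.full(small_design.m, 1.0)])
    return truth


@pytest.fixture(scope="session")
def small_data(small_design, small_truth):
    return simulate_lucid_data(small_design, true_params=small_truth, seed=11)


@pytest.fixture(scope="session")
def default_data():
    """A complete dataset from the reference design at reduced n."""
    design = SimDesign(n=2000)
    return simulate_lucid_data(design, seed=7)


@pytest.fixture()
def fast_config():
    return FitConfig(K=2, max_iter=300, tol=1e-6, seed=0)


@pytest.fixture(scope="session")
def tiny_fixture():
    """A 20-row complete dataset with p=2, m=2 for oracle comparisons."""
    rng = np.random.default_rng(5)
    G = rng.standard_normal((20, 2))
    Z = rng.standard_normal((20, 2)) + np.repeat([[-1.0, -1.0], [1.0, 1.0]], 10, axis=0)
    Y = rng.standard_normal(20) + np.repeat([-1.0, 1.0], 10)
    return LucidData(G=G, Z=Z, Y=Y, mask=np.zeros((20, 2), dtype=bool))
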