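import numpy as np
import pytest

from magicgp import (
    SimulationConfig,
    epistatic_kernel,
    simulate_magic_genotypes,
    vanraden_g,
)


@pytest.fixture(scope="session")
def small_geno():
    """60 inbred mosaic lines x 400 markers (session-wide fixture)."""
    cfg = SimulationConfig(n_lines=60, n_markers=400, seed=1)
    return simulate_magic_genotypes(cfg)


@pytest.fixture(scope="session")
def kernel_pair(small_geno):
    G = vanraden_g(small_geno)
    return G, epistatic_kernel(G)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
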