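import numpy as np
import pytest

from kfnet import kernels, knn, simulate


@pytest.fixture(scope="session")
def small_genotypes():
    """20 samples x 50 variants with mild LD; no missing calls."""
    return simulate.sim_genotypes(20, 50, (0.1, 0.4), ld_rho=0.3, seed=42)


@pytest.fixture(scope="session")
def medium_genotypes():
    return simulate.sim_genotypes(300, 100, (0.05, 0.5), ld_rho=0.2, seed=7)


@pytest.fixture(scope="session")
def product_K(medium_genotypes):
    return kernels.product_kernel(medium_genotypes)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def degree1_hidden():
    return [knn.HiddenKernel(degree=1, offset=0.0, m=1)]
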