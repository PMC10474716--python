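import numpy as np
import pytest

from gspred import simulate as sim


@pytest.fixture(scope="session")
def small_genotypes():
    """300 lines x 500 markers, LD-structured, reused across read-only tests."""
    return sim.simulate_genotypes(300, 500, n_chromosomes=5, ld_rho=0.6, seed=11)


@pytest.fixture(scope="session")
def planted_trait(small_genotypes):
    """Sparse architecture (20 QTL, h2=0.5) on the small genotype panel."""
    arch, pheno = sim.simulate_trait(small_genotypes, 20, 0.5, seed=12)
    return arch, pheno


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
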