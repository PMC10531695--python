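import numpy as np
import pytest

from gsnue.qc import apply_qc
from gsnue.simulate import PopulationConfig, simulate_genotypes, simulate_phenotypes


@pytest.fixture(scope="session")
def small_pop():
    """Small simulated population shared across tests (read-only)."""
    cfg = PopulationConfig(n_genotypes=150, n_markers=400, seed=11)
    G = simulate_genotypes(cfg)
    pheno, arch = simulate_phenotypes(G, cfg)
    return cfg, G, pheno, arch


@pytest.fixture(scope="session")
def qc_pop(small_pop):
    cfg, G, pheno, arch = small_pop
    Gq, report = apply_qc(G)
    return cfg, Gq, pheno, arch, report


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
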