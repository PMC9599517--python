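import numpy as np
import pytest

from phagepan.simulate import SimConfig, simulate_pangenome


@pytest.fixture(scope="session")
def small_sim():
    """A reduced genome collection (20 genomes, 4 clades) with sequences."""
    cfg = SimConfig(
        n_genomes=20, n_clades=4, mean_orfs=30, sd_orfs=4, n_core=8,
        mean_unique=5, sd_unique=3, mean_len=22000, sd_len=1500,
        module_prevalence=4 / 20, seed=11,
    )
    genomes, truth = simulate_pangenome(cfg)
    return cfg, genomes, truth


@pytest.fixture(scope="session")
def default_sim():
    """Full-scale collection (82 genomes, 10 clades), gene tables only."""
    cfg = SimConfig(seed=5)
    genomes, truth = simulate_pangenome(cfg, make_sequences=False)
    return cfg, genomes, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
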