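import numpy as np
import pytest

from revecol import SimConfig, simulate_populations
from revecol.anipop import ani_matrix


def toy_config(seed: int = 11, **kw) -> SimConfig:
    """Small community used throughout the unit tests: same planted structure
    as the default scenario, scaled to 80 kb / 240 genes for speed."""
    base = dict(
        seed=seed,
        genome_length=80_000,
        n_genes=240,
        gene_length_mean=280,
        n_pop_specific_a=8,
        n_pop_specific_b=8,
        sweep_region_length=3000,
        depth=20.0,
        n_de_genes=12,
        de_log2fc=3.0,
    )
    base.update(kw)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def toy_community():
    return simulate_populations(toy_config())


@pytest.fixture(scope="session")
def toy_community_nosweep():
    return simulate_populations(toy_config(seed=12, sweep_region_length=0))


@pytest.fixture(scope="session")
def toy_ani(toy_community_nosweep):
    return ani_matrix(toy_community_nosweep.genomes)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
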