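import numpy as np
import pytest

from chimpop import chimera_detect as cd
from chimpop import synthetic_data as sd


@pytest.fixture(scope="session")
def sim_config():
    cfg = sd.SimulationConfig(seed=42)
    cfg.breakpoints = sd.default_breakpoints(cfg, n=8)
    return cfg


@pytest.fixture(scope="session")
def parent_pools(sim_config):
    return sd.sample_parental_alleles(sim_config)


@pytest.fixture(scope="session")
def chimera_pool(sim_config, parent_pools):
    return sd.make_chimera_pool(sim_config, *parent_pools)


@pytest.fixture(scope="session")
def primers(sim_config, parent_pools):
    return sd.design_primers(sim_config, *parent_pools)


@pytest.fixture(scope="session")
def small_population(sim_config, parent_pools, chimera_pool):
    """50-individual single-region cohort with all three genotype classes."""
    cfg = sd.SimulationConfig(seed=sim_config.seed)
    cfg.breakpoints = list(sim_config.breakpoints)
    cfg.regions = [sd.RegionConfig("testland", 50, (0.5, 0.3, 0.2))]
    return sd.simulate_population(cfg, parent_pools, chimera_pool)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_matrix(rng, n_samples=None, n_sites=None, segment_length=1000,
                  missing_rate=0.0):
    """Random small VariantMatrix for oracle comparisons."""
    from chimpop.io_formats import VariantMatrix

    n = n_samples or int(rng.integers(2, 11))
    p = n_sites or int(rng.integers(1, 51))
    positions = np.sort(rng.choice(
        np.arange(1, segment_length + 1), size=min(p, segment_length),
        replace=False))
    genotypes = rng.integers(0, 3, size=(n, positions.size)).astype(np.int8)
    if missing_rate:
        mask = rng.random(genotypes.shape) < missing_rate
        genotypes[mask] = -1
    return VariantMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        positions=positions,
        genotypes=genotypes,
        segment_length=segment_length,
    )
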