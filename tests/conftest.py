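import numpy as np
import pytest

from evokit.simulate import SimConfig, gen_genome_layout


@pytest.fixture(scope="session")
def default_cfg():
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def layout(default_cfg):
    """Full-size genome layout shared across the suite (deterministic)."""
    return gen_genome_layout(default_cfg)


@pytest.fixture(scope="session")
def small_layout():
    """Tiny layout for cheap brute-force comparisons."""
    cfg = SimConfig(seed=3, genome_length=100_000, n_genes=60, n_scars=5)
    return gen_genome_layout(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
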