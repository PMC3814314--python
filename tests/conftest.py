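import numpy as np
import pytest

from zicreg.simulate import SimulationConfig, generate


SMALL = dict(
    genome_size=1_000_000,
    n_chroms=2,
    n_genes=40,
    n_peaks_per_stage=150,
    min_gene_spacing=8_000,
    n_cnes=30,
    seed=7,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(**SMALL)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """A 1 Mb two-chromosome dataset shared by the fast tests."""
    return generate(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
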