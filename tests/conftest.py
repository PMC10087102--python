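import pytest

from svtarget.guide_model import default_guide
from svtarget.synthetic_data import SyntheticConfig, generate_transcriptome, plant_sites


@pytest.fixture(scope="session")
def guide():
    return default_guide()


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(rng_seed=11, n_genes=30, planted_sites_per_gene=1)


@pytest.fixture(scope="session")
def small_transcriptome(small_config):
    return generate_transcriptome(small_config)


@pytest.fixture(scope="session")
def planted(small_transcriptome, small_config, guide):
    genes, sequences = small_transcriptome
    sequences2, sites = plant_sites(genes, sequences, guide, small_config)
    return genes, sequences2, sites
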