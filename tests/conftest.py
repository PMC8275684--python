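import sys
from pathlib import Path

import pytest

from hmctools import SimConfig, gen_genome, gen_region_counts, gen_site_counts

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(seed=7, n_sites=2000, n_regions=300,
                     chrom_lengths={"chr1": 400_000, "chr2": 400_000})


@pytest.fixture(scope="session")
def small_genome(small_config):
    return gen_genome(small_config)


@pytest.fixture(scope="session")
def small_sites(small_config, small_genome):
    genome, _ = small_genome
    return gen_site_counts(small_config, genome)


@pytest.fixture(scope="session")
def small_regions(small_config):
    return gen_region_counts(small_config)
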