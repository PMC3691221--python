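import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from mitocomp.synthetic_data import (
    PartitionSpec,
    SimulationConfig,
    random_coalescent_tree,
    simulate_mitogenome_set,
)


@pytest.fixture(scope="session")
def small_genome_partitions():
    """A reduced five-feature genome layout used to keep alignment-heavy
    tests fast; feature sizes are real mitochondrial gene sizes."""
    return [
        PartitionSpec("ND1", 975, "CDS", 1.0, stop_class="TAG"),
        PartitionSpec("tRNA-Ile", 70, "tRNA", 0.75),
        PartitionSpec("12S", 943, "rRNA", 1.0),
        PartitionSpec("ND6", 522, "CDS", 1.25, strand="L", stop_class="TAG"),
        PartitionSpec("CR", 892, "CR", 3.0),
    ]


@pytest.fixture(scope="session")
def simulated_genomes(small_genome_partitions):
    """Four simulated genomes at ~4% mean pairwise divergence, with truth."""
    rng = np.random.default_rng(5)
    tree = random_coalescent_tree(4, rng, mean_pairwise=0.04)
    config = SimulationConfig(tree=tree, partitions=small_genome_partitions, seed=11)
    return simulate_mitogenome_set(config)
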