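import pytest

from teregkit.genome import partition_genome
from teregkit.simulate import (
    SubfamilySpec,
    ToyGenomeConfig,
    build_toy_genome,
)

SMALL_SUBFAMILIES = (
    SubfamilySpec("LTR5x", "ERVKx", "LTR", 0, 500),
    SubfamilySpec("ERVKx-int", "ERVKx", "LTR", 0, 3000),
    SubfamilySpec("AluYx", "Alu", "SINE", 60, 300),
    SubfamilySpec("L1Mx", "L1", "LINE", 20, 1200),
)


def small_config() -> ToyGenomeConfig:
    return ToyGenomeConfig(
        chrom_lengths={"chrA": 400_000, "chrB": 300_000},
        subfamilies=SMALL_SUBFAMILIES,
        n_solo={"LTR5x": 10},
        n_proviral={"LTR5x": ("ERVKx-int", 6)},
        n_genes=30,
    )


@pytest.fixture(scope="session")
def toy():
    """Default toy genome: 3 x 2 Mb, full subfamily roster, 300 genes."""
    return build_toy_genome(seed=1)


@pytest.fixture(scope="session")
def toy_partition(toy):
    return partition_genome(toy.gene_models(), toy.chrom_sizes)


@pytest.fixture(scope="session")
def small_toy():
    """Reduced toy genome (700 kb) for methylome-scale tests."""
    return build_toy_genome(small_config(), seed=2)
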