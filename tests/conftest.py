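"""Shared fixtures: a hand-built toy genome and a small simulated pangenome."""

import numpy as np
import pytest

from regulonkit.genome_model import Gene, Genome
from regulonkit.orthology import compute_ortholog_groups
from regulonkit.synthetic_data import SimConfig, simulate


def make_toy_genome() -> Genome:
    """A 1 kb genome with three genes: two co-directional, one divergent.

    Layout (0-based half-open):
      geneA  +  [100, 250)
      geneB  +  [300, 450)   (50 bp gap after geneA -> same operon at gap 200)
      geneC  -  [700, 880)   (divergent intergenic region shared with geneB)
    """
    rng = np.random.default_rng(42)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 1000))
    genes = [
        Gene("geneA", 100, 250, "+", protein="MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"),
        Gene("geneB", 300, 450, "+", protein="MSERLQLTSGQLIDRTGLSRATIYRH"),
        Gene("geneC", 700, 880, "-", protein="MADKKLVLDLSNEWQRQTGAKLSVAE"),
    ]
    return Genome(genome_id="toy", sequence=seq, genes=genes)


@pytest.fixture
def toy_genome() -> Genome:
    return make_toy_genome()


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        n_genomes=6,
        n_core_families=10,
        n_variable_families=2,
        n_specific_per_genome=1,
        n_target_families=5,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_pangenome(small_config):
    return simulate(small_config)


@pytest.fixture(scope="session")
def small_groups(small_pangenome):
    genomes, _ = small_pangenome
    return compute_ortholog_groups(genomes)
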