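import numpy as np
import pytest

from centrosat.synthetic_data import GenomeSpec, simulate_genome


@pytest.fixture(scope="session")
def default_genome():
    """One default simulated genome shared across tests (read-only)."""
    spec = GenomeSpec(rng_seed=101)
    sequences, genes, truth = simulate_genome(spec)
    return spec, sequences, truth


@pytest.fixture(scope="session")
def small_exact_genome():
    """Single noise-free chromosome: exact telomeres, exact satellite."""
    spec = GenomeSpec(n_chromosomes=1, chrom_length=200_000,
                      telomere_copies_per_end=100, telomere_mutation_rate=0.0,
                      centromere_monomer_length=153, centromere_array_length=15_300,
                      monomer_divergence=0.0, rng_seed=1)
    sequences, genes, truth = simulate_genome(spec)
    return spec, sequences, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
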