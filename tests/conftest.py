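import numpy as np
import pytest

from seqbias.core_io import MappedRead
from seqbias.synthetic import (
    SimulationConfig, exact_unique_map, simulate_genome, simulate_reads,
)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_read(read_id="r0", sequence="ACGTACGT", contig="c1", strand="+",
              pos=100, mismatches=(), unique=True, score=None):
    return MappedRead(
        read_id, contig, strand, pos, len(sequence), sequence,
        len(mismatches), list(mismatches), unique,
        float(len(sequence)) if score is None else score,
    )


@pytest.fixture(scope="session")
def mixed_sim():
    """A small simulated experiment exercising every bias channel:
    mRNA contamination, 5'-end enrichment, and intron-hosted ncRNAs."""
    config = SimulationConfig(
        seed=0, n_genes=6, exons_per_gene=7, exon_length=60,
        intron_length=450, n_reads=15_000, mrna_fraction=0.05,
        five_prime_enrichment=0.1, ncRNA_in_introns=2,
    )
    sim = simulate_genome(config)
    reads = simulate_reads(sim)
    mapped, map_report = exact_unique_map(reads, sim.genome)
    return sim, reads, mapped, map_report
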