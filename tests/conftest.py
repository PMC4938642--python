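import numpy as np
import pytest

from chromaquant import Contig, FragmentSet, Gene, Genome, SimConfig, simulate_genome


def make_genome(chr1_len=10_000, mito_len=2_000, seed=7, with_sequence=True):
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype="S1")

    def seq(n):
        return bases[rng.integers(0, 4, n)].tobytes().decode() if with_sequence else None

    return Genome(
        contigs=(Contig("chr1", chr1_len, seq(chr1_len)), Contig("mito", mito_len, seq(mito_len))),
        mito_name="mito",
    )


def fragments(*rows):
    return FragmentSet.from_records(list(rows))


@pytest.fixture
def toy_genome():
    return make_genome()


@pytest.fixture(scope="session")
def small_sim():
    """A shared small simulated dataset: ~110 kb genome, 20 genes, 3 domains."""
    cfg = SimConfig(
        seed=11,
        n_nuclear_contigs=1,
        contig_length_bp=100_000,
        mito_length_bp=10_000,
        n_genes=20,
        n_domains=3,
        chip_n_fragments=60_000,
        mnase_n_fragments=60_000,
    )
    genome, genes, domains = simulate_genome(cfg)
    return cfg, genome, genes, domains
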