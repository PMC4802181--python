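import numpy as np
import pytest

from nbconform.genome import GeneRecord, GenomicInterval, ToyGenome


@pytest.fixture
def toy_genome() -> ToyGenome:
    return ToyGenome([("chr1", 4_000_000), ("chr2", 2_000_000)])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_genes(rng, genome, n, gene_class="snRNA", length=2_000):
    """Uniformly placed genes of one class (may overlap; fine for oracles)."""
    genes = []
    for j in range(n):
        chrom, clen = genome.chromosomes[int(rng.integers(len(genome.chromosomes)))]
        start = int(rng.integers(0, clen - length))
        genes.append(
            GeneRecord(f"g{j}", GenomicInterval(chrom, start, start + length), gene_class)
        )
    return genes
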