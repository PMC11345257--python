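import numpy as np
import pytest

from lamipul import GeneRecord, GenomeAnnotation


def build_linear_genome(n_genes: int, contig: str = "c1", circular: bool = False,
                        strand: str = "+") -> GenomeAnnotation:
    """Evenly spaced single-contig genome with gene ids g000..g{n-1}."""
    genes = [
        GeneRecord(f"g{i:03d}", contig, 1 + i * 1000, i * 1000 + 900, strand,
                   protein_id=f"p{i:03d}")
        for i in range(n_genes)
    ]
    return GenomeAnnotation(genes, circular={contig: circular})


@pytest.fixture
def linear30() -> GenomeAnnotation:
    return build_linear_genome(30)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
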