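import numpy as np
import pytest

from skipscan.gene_models import GeneModel, JunctionKey
from skipscan.junction_quant import JunctionCountTable

_NT = np.array(list("ACGT"))


def random_gene(gene_id: str, n_exons: int, rng, min_exon=60, max_exon=200) -> GeneModel:
    lengths = rng.integers(min_exon, max_exon + 1, size=n_exons)
    seqs = ["".join(rng.choice(_NT, size=n)) for n in lengths]
    return GeneModel.from_exon_lengths(gene_id, list(lengths), sequences=seqs)


def make_table(sample_id: str, counts: dict[tuple[str, int, int], int]) -> JunctionCountTable:
    return JunctionCountTable.from_counts(
        sample_id, {JunctionKey(*k): v for k, v in counts.items()}
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def three_exon_gene(rng):
    return random_gene("geneA", 3, rng)


@pytest.fixture
def five_exon_gene(rng):
    return random_gene("geneB", 5, rng)
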