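import numpy as np
import pytest

from codonuse import SyntheticGenomeSpec, simulate_genome, standard_code
from codonuse.datasets import extreme_group_counts


@pytest.fixture(scope="session")
def code():
    return standard_code()


@pytest.fixture(scope="session")
def group_counts():
    """Published pooled codon counts (high, low expression extremes)."""
    return extreme_group_counts()


@pytest.fixture(scope="session")
def small_sim():
    """A small synthetic genome shared across unit tests."""
    spec = SyntheticGenomeSpec(n_genes=60, min_codons=100, max_codons=200, seed=11)
    genome, genes, truth = simulate_genome(spec)
    return spec, genome, genes, truth


def random_gene(rng, n_codons=150, gene_id="g", code=None):
    """A filter-clean random gene: ATG + uniform non-stop codons + TAA."""
    code = code or standard_code()
    internal = [c for c in code.sense_codons]
    body = [internal[i] for i in rng.integers(0, len(internal), size=n_codons - 2)]
    from codonuse import GeneRecord

    return GeneRecord(gene_id=gene_id, codons=("ATG", *body, "TAA"))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
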