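import numpy as np
import pytest

from ernakit.core import GeneModel, GenomicInterval


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_gene(gene_id, chrom, start, end, strand="+", coding_end=None):
    return GeneModel(gene_id, GenomicInterval(chrom, start, end, strand), coding_end)


@pytest.fixture
def gene_pair():
    """Two well-separated genes on one chromosome."""
    return [
        make_gene("gA", "chr1", 20000, 30000, "+", 29000),
        make_gene("gB", "chr1", 60000, 70000, "-", 61000),
    ]
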