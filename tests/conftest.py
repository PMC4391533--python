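import numpy as np
import pytest

from exonsplice.core_model import ExonExpressionSet, GeneBlock


def make_block(matrix, n1, n2, gene_id="g1"):
    """GeneBlock from a matrix whose first n1 columns are condition c1."""
    matrix = np.asarray(matrix, dtype=float)
    n_exons, n_samples = matrix.shape
    assert n_samples == n1 + n2
    return GeneBlock(
        gene_id=gene_id,
        exon_ids=tuple(f"e{i + 1}" for i in range(n_exons)),
        matrix=matrix,
        sample_ids=tuple(f"s{j + 1}" for j in range(n_samples)),
        condition=("c1",) * n1 + ("c2",) * n2,
    )


def make_dataset(blocks):
    """ExonExpressionSet from GeneBlocks sharing one sample annotation."""
    first = blocks[0]
    return ExonExpressionSet(
        gene_ids=[b.gene_id for b in blocks],
        exon_ids={b.gene_id: list(b.exon_ids) for b in blocks},
        values={b.gene_id: b.matrix for b in blocks},
        sample_ids=list(first.sample_ids),
        condition=list(first.condition),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def noisy_block(rng):
    """A 5-exon, 4+4-sample block with generic noise, no DS event."""
    return make_block(rng.normal(8.0, 0.6, size=(5, 8)), 4, 4)
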