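"""Monte Carlo permutation p-values for heuristic gene scores.

Score methods (KLAS, SI, ARH, PAC) quantify evidence for differential
splicing but carry no significance level.  Permuting the condition labels
while preserving group sizes yields a null distribution of the score; the
p-value is the fraction of relabelings scoring at least as high as the
observed labels.

Monte Carlo mode uses the add-one estimator p = (1 + #{perm >= obs}) /
(n_perm + 1), which is a valid p-value at any finite number of draws and
never returns 0.  When the number of distinct label assignments is small
enough (<= n_perm) and ``exhaustive`` is enabled, all assignments are
enumerated instead and p = #{score >= observed} / total with the observed
assignment included (so p >= 1/total).  Ties count as exceedances in both
modes, which is conservative.

Each gene draws its permutations from a seed derived by stable hash of the
master seed and the gene id, so per-gene p-values do not depend on gene
order or on which other genes are present.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Callable

import numpy as np

from .core_model import GeneBlock

__all__ = ["PermutationConfig", "permutation_pvalue", "permutation_pvalue_fast"]


@dataclass(frozen=True)
class PermutationConfig:
    n_perm: int = 1000
    seed: int = 0
    exhaustive: bool = True

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


def derive_gene_seed(master_seed: int, gene_id: str) -> int:
    """Stable, order-independent per-gene RNG seed (CRC32 of seed + id)."""
    return zlib.crc32(f"{master_seed}:{gene_id}".encode()) & 0x7FFFFFFF


def _group_indices(block: GeneBlock) -> tuple[np.ndarray, str, str]:
    conds = block.conditions
    if len(conds) != 2:
        raise ValueError(f"gene {block.gene_id}: permutation test needs exactly 2 conditions")
    c1, c2 = sorted(conds)  # same orientation convention as the score methods
    n1 = int(block.condition_mask(c1).sum())
    n2 = block.n_samples - n1
    if n1 < 2 or n2 < 2:
        raise ValueError(f"gene {block.gene_id}: each group needs >= 2 samples")
    return np.arange(block.n_samples), c1, c2


def label_assignments(
    n: int, n1: int, config: PermutationConfig, gene_seed: int
) -> tuple[np.ndarray, bool]:
    """Group-1 column indices for each assignment to score.

    Returns ``(idx, exhaustive)`` where ``idx`` has shape (k, n1).  In
    exhaustive mode the identity assignment ``0..n1-1`` is the first row
    of the full enumeration; in Monte Carlo mode the rows are ``n_perm``
    random draws (the observed assignment is handled separately by the
    add-one estimator).
    """
    total = comb(n, n1)
    if config.exhaustive and total <= config.n_perm:
        idx = np.array(list(combinations(range(n), n1)), dtype=int)
        return idx, True
    rng = np.random.default_rng(gene_seed)
    # first n1 positions of n_perm random orderings of the samples
    idx = rng.random((config.n_perm, n)).argsort(axis=1)[:, :n1]
    return idx, False


def _pvalue_from_scores(
    observed: float, permuted: np.ndarray, exhaustive: bool
) -> float:
    if exhaustive:
        # observed assignment is one of the enumerated rows
        return float((permuted >= observed).sum() / permuted.size)
    n_perm = permuted.size
    return float((1 + (permuted >= observed).sum()) / (n_perm + 1))


def permutation_pvalue(
    score_fn: Callable[[GeneBlock], float],
    block: GeneBlock,
    config: PermutationConfig,
) -> float:
    """Permutation p-value of ``score_fn`` on one gene block.

    ``score_fn`` must be deterministic and oriented so that higher scores
    mean more evidence of differential splicing.
    """
    _, c1, c2 = _group_indices(block)
    n = block.n_samples
    n1 = int(block.condition_mask(c1).sum())
    gene_seed = derive_gene_seed(config.seed, block.gene_id)
    idx, exhaustive = label_assignments(n, n1, config, gene_seed)

    def score_for(group1: np.ndarray) -> float:
        labels = np.full(n, c2, dtype=object)
        labels[group1] = c1
        relabeled = GeneBlock(
            gene_id=block.gene_id,
            exon_ids=block.exon_ids,
            matrix=block.matrix,
            sample_ids=block.sample_ids,
            condition=tuple(labels),
        )
        return float(score_fn(relabeled))

    observed = score_for(np.flatnonzero(block.condition_mask(c1)))
    permuted = np.array([score_for(row) for row in idx])
    return _pvalue_from_scores(observed, permuted, exhaustive)


def permutation_pvalue_fast(
    method: str,
    block: GeneBlock,
    config: PermutationConfig,
    q_mode: str = "quotient_linear",
) -> float:
    """Vectorized permutation p-value for mean-based score methods.

    KLAS, SI and ARH depend on the data only through per-condition exon
    means, so all relabelings can be scored in one shot: group means for
    every assignment are a single matrix product of the gene matrix with a
    sparse averaging matrix.  Methods without a mean-based kernel (PAC)
    fall back to the generic loop.  Matches :func:`permutation_pvalue`
    (same assignments, same estimator).
    """
    from . import ds_methods

    if method not in ("klas", "si", "arh"):
        if method == "pac":
            fn: Callable[[GeneBlock], float] = ds_methods.pac_score
        else:
            raise ValueError(f"no permutation scheme for method {method!r}")
        return permutation_pvalue(fn, block, config)

    _, c1, c2 = _group_indices(block)
    n = block.n_samples
    obs1 = np.flatnonzero(block.condition_mask(c1))
    n1 = obs1.size
    n2 = n - n1
    gene_seed = derive_gene_seed(config.seed, block.gene_id)
    idx, exhaustive = label_assignments(n, n1, config, gene_seed)

    # score observed + permuted assignments through the same kernel
    all_idx = np.vstack([obs1[None, :], idx])
    k = all_idx.shape[0]
    in_g1 = np.zeros((k, n), dtype=bool)
    np.put_along_axis(in_g1, all_idx, True, axis=1)
    w1 = in_g1.T.astype(float) / n1  # (samples, k) averaging weights
    w2 = (~in_g1).T.astype(float) / n2
    m1 = block.matrix @ w1  # (exons, k) per-assignment condition means
    m2 = block.matrix @ w2
    scores = ds_methods.mean_based_score_fn(method, q_mode)(m1, m2)

    observed, permuted = scores[0], scores[1:]
    if exhaustive:
        # row 0 duplicates one enumerated assignment; drop it
        return _pvalue_from_scores(observed, permuted, True)
    return _pvalue_from_scores(observed, permuted, False)
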