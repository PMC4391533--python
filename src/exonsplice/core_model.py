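"""Core domain types for exon-array differential-splicing analysis.

An exon array measures expression per exon rather than per gene.  All
containers here hold log2-scale intensities: rows are exons (grouped by
gene), columns are samples, and every sample belongs to one of exactly two
conditions.  Differential splicing (DS) then shows up as an exon-level
expression change between conditions that is not explained by a gene-level
change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "GeneBlock",
    "ExonExpressionSet",
    "ScenarioSpec",
    "TruthEntry",
    "TruthTable",
    "MethodResult",
    "validate",
]


@dataclass(frozen=True)
class GeneBlock:
    """One gene's exon-by-sample log2 expression with condition labels.

    ``matrix`` has shape (n_exons, n_samples); ``condition[j]`` labels
    column ``j``.  Exactly two distinct condition labels are supported.
    """

    gene_id: str
    exon_ids: tuple[str, ...]
    matrix: np.ndarray
    sample_ids: tuple[str, ...]
    condition: tuple[str, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2:
            raise ValueError(f"gene {self.gene_id}: matrix must be 2-D")
        if m.shape != (len(self.exon_ids), len(self.sample_ids)):
            raise ValueError(
                f"gene {self.gene_id}: matrix shape {m.shape} does not match "
                f"{len(self.exon_ids)} exons x {len(self.sample_ids)} samples"
            )
        if len(self.condition) != len(self.sample_ids):
            raise ValueError(f"gene {self.gene_id}: one condition label per sample required")

    @property
    def n_exons(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    @property
    def conditions(self) -> tuple[str, ...]:
        """Distinct condition labels in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.condition:
            seen.setdefault(c)
        return tuple(seen)

    def condition_mask(self, label: str) -> np.ndarray:
        if label not in self.condition:
            raise KeyError(f"unknown condition label {label!r} for gene {self.gene_id}")
        return np.asarray([c == label for c in self.condition], dtype=bool)

    def submatrix(self, label: str) -> np.ndarray:
        return self.matrix[:, self.condition_mask(label)]


@dataclass
class ExonExpressionSet:
    """A collection of :class:`GeneBlock` sharing one sample annotation.

    The universal input of every scoring method: per-gene exon x sample
    blocks of log2 expression plus a two-condition sample grouping.
    """

    gene_ids: list[str]
    exon_ids: dict[str, list[str]]
    values: dict[str, np.ndarray]
    sample_ids: list[str]
    condition: list[str]

    def __post_init__(self) -> None:
        for g in self.gene_ids:
            self.values[g] = np.asarray(self.values[g], dtype=float)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def conditions(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for c in self.condition:
            seen.setdefault(c)
        return tuple(seen)

    def gene_block(self, gene_id: str) -> GeneBlock:
        return GeneBlock(
            gene_id=gene_id,
            exon_ids=tuple(self.exon_ids[gene_id]),
            matrix=self.values[gene_id],
            sample_ids=tuple(self.sample_ids),
            condition=tuple(self.condition),
        )

    def iter_blocks(self) -> Iterator[GeneBlock]:
        for g in self.gene_ids:
            yield self.gene_block(g)


# Factor levels of the simulation study: expression intensity, exons per
# gene, percent of spliced samples in the affected group, and group sizes.
_EXPR_LEVELS = ("high", "low")
_ENUM_LEVELS = (10, 30)
_PCNT_LEVELS = (60, 100)
_SNUM_LEVELS = ((15, 15), (15, 5))


@dataclass(frozen=True, order=True)
class ScenarioSpec:
    """One cell of the 2x2x2x2 factorial benchmark design."""

    expr: str
    enum: int
    pcnt: int
    snum: tuple[int, int]

    def __post_init__(self) -> None:
        if self.expr not in _EXPR_LEVELS:
            raise ValueError(f"expr must be one of {_EXPR_LEVELS}, got {self.expr!r}")
        if self.enum not in _ENUM_LEVELS:
            raise ValueError(f"enum must be one of {_ENUM_LEVELS}, got {self.enum!r}")
        if self.pcnt not in _PCNT_LEVELS:
            raise ValueError(f"pcnt must be one of {_PCNT_LEVELS}, got {self.pcnt!r}")
        if tuple(self.snum) not in _SNUM_LEVELS:
            raise ValueError(f"snum must be one of {_SNUM_LEVELS}, got {self.snum!r}")


@dataclass(frozen=True)
class TruthEntry:
    """Ground-truth annotation of one simulated gene."""

    is_ds: bool
    ds_exons: tuple[int, ...] = ()
    ds_group: str | None = None
    ds_samples: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not self.is_ds and self.ds_exons:
            raise ValueError("true-negative gene must have empty ds_exons")
        if self.is_ds and len(self.ds_exons) not in (1, 2):
            raise ValueError("true-positive gene carries 1 or 2 spliced exons")


@dataclass
class TruthTable:
    """Per-gene truth labels for a simulated dataset."""

    entries: dict[str, TruthEntry]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.entries)

    def is_ds(self, gene_id: str) -> bool:
        return self.entries[gene_id].is_ds

    def labels(self, gene_ids: Sequence[str]) -> np.ndarray:
        return np.asarray([self.entries[g].is_ds for g in gene_ids], dtype=bool)

    @property
    def n_positive(self) -> int:
        return sum(e.is_ds for e in self.entries.values())

    @property
    def n_negative(self) -> int:
        return len(self.entries) - self.n_positive


@dataclass
class MethodResult:
    """Per-gene output of one scoring method on one dataset.

    ``score`` is NaN for genes a method skipped and None for methods that
    are p-value native (MIDAS, ANOSVA).  Higher scores always mean more
    evidence for differential splicing; p-values live in [0, 1].
    """

    method: str
    gene_ids: list[str]
    score: np.ndarray | None = None
    p_value: np.ndarray | None = None
    skipped: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        if self.score is not None:
            self.score = np.asarray(self.score, dtype=float)
            if self.score.shape != (n,):
                raise ValueError("score must align with gene_ids")
        if self.p_value is not None:
            self.p_value = np.asarray(self.p_value, dtype=float)
            if self.p_value.shape != (n,):
                raise ValueError("p_value must align with gene_ids")
            ok = np.isnan(self.p_value) | ((self.p_value >= 0) & (self.p_value <= 1))
            if not ok.all():
                bad = [self.gene_ids[i] for i in np.flatnonzero(~ok)]
                raise ValueError(f"p-values outside [0, 1] for genes {bad}")


def validate(dataset: ExonExpressionSet) -> list[str]:
    """Check dataset invariants, returning one message per violation.

    An empty list means the dataset is well formed: two conditions with at
    least two samples each, every gene with at least one exon, complete
    finite per-gene matrices, and consistent dimensions.
    """
    messages: list[str] = []
    n_samples = len(dataset.sample_ids)

    if len(dataset.condition) != n_samples:
        messages.append(
            f"condition labels ({len(dataset.condition)}) do not match "
            f"samples ({n_samples})"
        )
        return messages

    conds = dataset.conditions
    if len(conds) != 2:
        messages.append(f"expected exactly 2 conditions, found {len(conds)}: {list(conds)}")
    for c in conds:
        size = sum(1 for x in dataset.condition if x == c)
        if size < 2:
            messages.append(f"condition {c!r} has {size} sample(s); at least 2 required")

    for g in dataset.gene_ids:
        if g not in dataset.values or g not in dataset.exon_ids:
            messages.append(f"gene {g!r}: missing expression block or exon ids")
            continue
        m = dataset.values[g]
        if m.ndim != 2 or m.shape != (len(dataset.exon_ids[g]), n_samples):
            messages.append(
                f"gene {g!r}: matrix shape {m.shape} does not match "
                f"{len(dataset.exon_ids[g])} exons x {n_samples} samples"
            )
            continue
        if m.shape[0] < 1:
            messages.append(f"gene {g!r}: has no exons")
        bad = ~np.isfinite(m)
        if bad.any():
            e, s = np.argwhere(bad)[0]
            messages.append(
                f"gene {g!r}: non-finite value at exon {dataset.exon_ids[g][e]!r}, "
                f"sample {dataset.sample_ids[s]!r}"
            )
    return messages
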