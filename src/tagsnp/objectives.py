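"""The four selection objectives and rank-sum dominance fitness.

For a candidate tag-SNP set encoded as a binary chromosome ``c`` over a
block's SNPs, the objectives are

* ``f1`` compactness -- number of selected SNPs (minimize),
* ``f2`` tolerance -- minimum over pattern pairs of the number of selected
  SNPs distinguishing the pair (maximize; ``f2 - 1`` missing SNPs are
  tolerated when ``f2 >= 1``),
* ``f3`` dissimilarity -- average Hamming distance between pattern pairs on
  the selected SNPs (maximize),
* ``f4`` balance -- population variance of those pairwise distances
  (minimize).

All four derive from one pass over the per-pair distinguish counts
``D_ij``; complexity O(m^2 * n) per evaluation, vectorized.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np

from tagsnp.haplotype import HaplotypeBlock

__all__ = [
    "DIRECTIONS",
    "BlockEvaluator",
    "Chromosome",
    "ObjectiveVector",
    "avg_hamming",
    "compactness",
    "evaluate",
    "hamming_distances",
    "pairwise_distinguish_counts",
    "rank_sum_fitness",
    "tolerance",
    "variance_hamming",
]

#: Optimization direction of (f1, f2, f3, f4).
DIRECTIONS: tuple[str, str, str, str] = ("min", "max", "max", "min")

#: Sign vector turning a raw objective vector into minimization sense.
_MIN_SENSE_SIGN = np.array([1.0, -1.0, -1.0, 1.0])


@dataclass(frozen=True)
class Chromosome:
    """Binary selection vector over a block's SNPs; gene k selects SNP k+1."""

    genes: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.genes)
        if g.ndim != 1:
            raise ValueError(f"genes must be a vector, got shape {g.shape}")
        if g.size < 1:
            raise ValueError("chromosome must have at least one gene")
        if not np.isin(g, (0, 1)).all():
            raise ValueError("genes must all be 0 or 1")
        g = g.astype(np.uint8)
        g.setflags(write=False)
        object.__setattr__(self, "genes", g)

    @property
    def n(self) -> int:
        return self.genes.size

    @classmethod
    def from_string(cls, bits: str) -> "Chromosome":
        return cls(np.array([int(ch) for ch in bits], dtype=np.uint8))

    @classmethod
    def from_indices(cls, indices: Iterable[int], n: int) -> "Chromosome":
        """Chromosome selecting the given 0-based SNP indices."""
        genes = np.zeros(n, dtype=np.uint8)
        genes[list(indices)] = 1
        return cls(genes)

    def to_string(self) -> str:
        return "".join(str(int(g)) for g in self.genes)

    def selected_indices(self) -> np.ndarray:
        return np.flatnonzero(self.genes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Chromosome):
            return NotImplemented
        return np.array_equal(self.genes, other.genes)

    def __hash__(self) -> int:
        return hash(self.genes.tobytes())


@dataclass(frozen=True)
class ObjectiveVector:
    """One chromosome's four objective values with their directions."""

    f1: int
    f2: int
    f3: float
    f4: float
    directions: tuple[str, str, str, str] = DIRECTIONS

    def as_array(self) -> np.ndarray:
        """Raw values on the original scales."""
        return np.array([self.f1, self.f2, self.f3, self.f4], dtype=float)

    def as_min_array(self) -> np.ndarray:
        """Values with maximization objectives (f2, f3) negated."""
        return self.as_array() * _MIN_SENSE_SIGN

    @classmethod
    def from_array(cls, values: np.ndarray) -> "ObjectiveVector":
        return cls(int(values[0]), int(values[1]), float(values[2]), float(values[3]))


def _check_length(block: HaplotypeBlock, chrom: Chromosome) -> None:
    if chrom.n != block.n:
        raise ValueError(
            f"chromosome length {chrom.n} does not match block SNP count {block.n}"
        )


def pair_diff_matrix(block: HaplotypeBlock) -> np.ndarray:
    """C(m,2) x n binary matrix; row (i,j) marks SNPs where P_i, P_j differ.

    Pairs are ordered lexicographically (i, j) with i < j, 0-based.
    """
    i_idx, j_idx = np.triu_indices(block.m, k=1)
    return (block.matrix[i_idx] != block.matrix[j_idx]).astype(np.uint8)


class BlockEvaluator:
    """Precomputed pair-difference machinery for fast batch evaluation."""

    def __init__(self, block: HaplotypeBlock):
        self.block = block
        self.diffs = pair_diff_matrix(block)
        self.n_pairs = self.diffs.shape[0]

    def pair_counts(self, genes: np.ndarray) -> np.ndarray:
        """D_ij for one chromosome (1-D) or a population (2-D, row-wise)."""
        return np.asarray(genes, dtype=np.int64) @ self.diffs.T

    def objectives(self, genes: np.ndarray) -> np.ndarray:
        """Raw (f1, f2, f3, f4) rows for a population array of genes.

        f3/f4 are computed from exact integer moments of the D_ij counts so
        that chromosomes with identical moments get bitwise-identical
        values (summation-order float noise would otherwise break
        dominance comparisons between equal-objective solutions).
        """
        genes = np.atleast_2d(np.asarray(genes, dtype=np.int64))
        counts = genes @ self.diffs.T
        f1 = genes.sum(axis=1)
        f2 = counts.min(axis=1)
        f3, f4 = _count_moments(counts)
        return np.stack([f1.astype(float), f2.astype(float), f3, f4], axis=1)

    def min_objectives(self, genes: np.ndarray) -> np.ndarray:
        """Objectives in all-minimization sense (f2, f3 negated)."""
        return self.objectives(genes) * _MIN_SENSE_SIGN


def _count_moments(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean and population variance from exact integer sums (row-wise)."""
    counts = np.atleast_2d(counts).astype(np.int64)
    c = counts.shape[1]
    s1 = counts.sum(axis=1)
    s2 = (counts * counts).sum(axis=1)
    mean = s1 / c
    var = np.maximum(s2 / c - mean * mean, 0.0)
    return mean, var


def pairwise_distinguish_counts(block: HaplotypeBlock, chrom: Chromosome) -> np.ndarray:
    """D_ij: number of selected SNPs distinguishing each pattern pair.

    Entry order is lexicographic over pairs (i, j), i < j.
    """
    _check_length(block, chrom)
    return BlockEvaluator(block).pair_counts(chrom.genes)


def compactness(chrom: Chromosome) -> int:
    """f1: number of selected SNPs."""
    return int(chrom.genes.sum())


def tolerance(block: HaplotypeBlock, chrom: Chromosome) -> int:
    """f2: minimum D_ij over pattern pairs.

    A value v >= 1 means every pair is distinguished and v - 1 missing SNPs
    are tolerated; v = 0 flags a selection that is not a valid tag set (a
    legal objective value, handled by dominance rather than a constraint).
    """
    _check_length(block, chrom)
    return int(pairwise_distinguish_counts(block, chrom).min())


def hamming_distances(block: HaplotypeBlock, chrom: Chromosome) -> np.ndarray:
    """Pairwise Hamming distances on selected SNPs, pair order as D_ij.

    Computed from the selected submatrix directly; for binary alleles this
    equals :func:`pairwise_distinguish_counts` entrywise (asserted property).
    """
    _check_length(block, chrom)
    sub = block.matrix[:, chrom.genes.astype(bool)].astype(np.int64)
    i_idx, j_idx = np.triu_indices(block.m, k=1)
    return np.abs(sub[i_idx] - sub[j_idx]).sum(axis=1)


def avg_hamming(block: HaplotypeBlock, chrom: Chromosome) -> float:
    """f3: mean pairwise Hamming distance; 0 for the empty selection."""
    mean, _ = _count_moments(hamming_distances(block, chrom))
    return float(mean[0])


def variance_hamming(block: HaplotypeBlock, chrom: Chromosome) -> float:
    """f4: population variance (divisor C(m,2)) of the pairwise distances."""
    _, var = _count_moments(hamming_distances(block, chrom))
    return float(var[0])


def evaluate(block: HaplotypeBlock, chrom: Chromosome) -> ObjectiveVector:
    """Evaluate all four objectives from a single D_ij pass."""
    _check_length(block, chrom)
    counts = pairwise_distinguish_counts(block, chrom)
    mean, var = _count_moments(counts)
    return ObjectiveVector(
        f1=compactness(chrom),
        f2=int(counts.min()),
        f3=float(mean[0]),
        f4=float(var[0]),
    )


def rank_sum_fitness(objs: Sequence[ObjectiveVector]) -> list[int]:
    """Sum of per-objective competition ranks; lower is better.

    For each objective, solutions are ranked 1 (best, per the objective's
    direction) to N (worst); tied values share the minimum rank.  Used as a
    tournament comparison heuristic, not as a replacement for Pareto
    dominance.
    """
    if len(objs) == 0:
        raise ValueError("rank_sum_fitness requires a non-empty list")
    values = np.stack([o.as_min_array() for o in objs])
    return [int(f) for f in rank_sum_from_min_array(values)]


def rank_sum_from_min_array(values: np.ndarray) -> np.ndarray:
    """Rank-sum fitness for an (N, k) array already in minimization sense."""
    values = np.atleast_2d(values)
    n = values.shape[0]
    fitness = np.zeros(n, dtype=np.int64)
    for col in values.T:
        # competition ("min") rank: 1 + number of strictly better values
        fitness += 1 + (col[None, :] < col[:, None]).sum(axis=1)
    return fitness


def dominates_min(a: np.ndarray, b: np.ndarray) -> bool:
    """Pareto dominance for vectors in minimization sense."""
    return bool(np.all(a <= b) and np.any(a < b))


def dominates(a: ObjectiveVector, b: ObjectiveVector) -> bool:
    """True if ``a`` Pareto-dominates ``b`` under the stated directions."""
    return dominates_min(a.as_min_array(), b.as_min_array())
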