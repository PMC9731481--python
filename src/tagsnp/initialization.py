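"""Random and greedy (distinguishability-sorted) population initialization.

Greedy initialization treats tag SNP selection as a coverage problem: every
pattern pair must be distinguished by at least ``c`` selected SNPs.  SNPs
are considered in descending distinguishability order (ascending index on
ties) and, by default, a SNP is added only if it raises the coverage of some
still-deficient pair.  Building one chromosome per coverage level 1..c_max
yields an initial population spread across compactness levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from tagsnp.haplotype import HaplotypeBlock, distinguishability
from tagsnp.objectives import BlockEvaluator, Chromosome

__all__ = [
    "GreedyCoverResult",
    "InitializationError",
    "Population",
    "greedy_cover",
    "greedy_population",
    "random_population",
]


class InitializationError(RuntimeError):
    """Raised when greedy initialization is infeasible for a block."""


@dataclass(frozen=True)
class Population:
    """A list of equal-length chromosomes with provenance metadata."""

    members: tuple[Chromosome, ...]
    provenance: str
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.members) < 1:
            raise ValueError("population must have at least one member")
        lengths = {c.n for c in self.members}
        if len(lengths) > 1:
            raise ValueError(f"members have unequal lengths: {sorted(lengths)}")
        object.__setattr__(self, "members", tuple(self.members))

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def n(self) -> int:
        return self.members[0].n

    def as_array(self) -> np.ndarray:
        return np.stack([c.genes for c in self.members])


def random_population(n: int, size: int, seed: Optional[int] = None) -> Population:
    """Population of ``size`` chromosomes with i.i.d. Bernoulli(0.5) genes."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if size < 1:
        raise ValueError(f"size must be >= 1, got {size}")
    rng = np.random.default_rng(seed)
    genes = rng.integers(0, 2, size=(size, n), dtype=np.uint8)
    return Population(
        members=tuple(Chromosome(row) for row in genes),
        provenance="random",
        seed=seed,
    )


@dataclass(frozen=True)
class GreedyCoverResult:
    """Outcome of one greedy cover pass.

    ``saturated`` is set when the SNP supply ran out before every pair
    reached the requested coverage (best-effort chromosome returned).
    ``order`` records the SNPs considered, ``selected`` those added, both as
    0-based indices in consideration order.
    """

    chromosome: Chromosome
    coverage: int
    saturated: bool
    order: tuple[int, ...] = field(repr=False, default=())
    selected: tuple[int, ...] = ()


def greedy_cover(
    block: HaplotypeBlock,
    coverage: int,
    skip_noncontributing: bool = True,
) -> GreedyCoverResult:
    """Greedy chromosome covering every pattern pair ``coverage`` times.

    SNPs are iterated in descending distinguishability order (ascending
    index on ties).  With ``skip_noncontributing`` (default) a SNP is added
    only if some pair below target coverage is distinguished by it — true
    greedy set-cover behavior giving smaller tag sets; with the flag off,
    every SNP in sorted order is added until all pairs are covered.

    The returned chromosome satisfies ``D_ij >= min(coverage, D_ij(all-ones))``
    for every pair.
    """
    if coverage < 1:
        raise ValueError(f"coverage must be >= 1, got {coverage}")
    dist = distinguishability(block)
    # descending distinguishability, ascending index on ties
    order = np.lexsort((np.arange(block.n), -dist))
    ev = BlockEvaluator(block)
    counts = np.zeros(ev.n_pairs, dtype=np.int64)
    cap = ev.diffs.sum(axis=1)  # D_ij(all-ones): per-pair coverage ceiling
    target = np.minimum(coverage, cap)
    genes = np.zeros(block.n, dtype=np.uint8)
    considered: list[int] = []
    selected: list[int] = []
    for k in order:
        if np.all(counts >= target):
            break
        considered.append(int(k))
        contributes = bool(np.any((counts < target) & (ev.diffs[:, k] == 1)))
        if skip_noncontributing and not contributes:
            continue
        genes[k] = 1
        selected.append(int(k))
        counts += ev.diffs[:, k]
    saturated = bool(np.any(counts < coverage))
    return GreedyCoverResult(
        chromosome=Chromosome(genes),
        coverage=coverage,
        saturated=saturated,
        order=tuple(considered),
        selected=tuple(selected),
    )


def greedy_population(
    block: HaplotypeBlock,
    size: int,
    seed: Optional[int] = None,
    skip_noncontributing: bool = True,
) -> Population:
    """Greedy initial population spanning coverage levels 1..c_max.

    Members 1..min(size, c_max) are :func:`greedy_cover` chromosomes at
    coverage 1..c_max; any remaining slots are bit-flip-mutated copies
    (rate 1/n) of the coverage chromosomes, cycled in order.

    Raises
    ------
    InitializationError
        If some pattern pair is indistinguishable even with all SNPs
        selected (c_max = 0); the first offending pair is named.
    """
    if size < 1:
        raise ValueError(f"size must be >= 1, got {size}")
    ev = BlockEvaluator(block)
    cap = ev.diffs.sum(axis=1)
    c_max = int(cap.min())
    if c_max == 0:
        i_idx, j_idx = np.triu_indices(block.m, k=1)
        bad = int(np.argmin(cap))
        pi, pj = block.pattern_ids[i_idx[bad]], block.pattern_ids[j_idx[bad]]
        raise InitializationError(
            f"patterns {pi} and {pj} are identical on every SNP; "
            "no tag set can distinguish them"
        )
    base = [
        greedy_cover(block, c, skip_noncontributing=skip_noncontributing).chromosome
        for c in range(1, min(size, c_max) + 1)
    ]
    members = list(base)
    rng = np.random.default_rng(seed)
    p_m = 1.0 / block.n
    i = 0
    while len(members) < size:
        template = base[i % len(base)]
        flips = rng.random(block.n) < p_m
        members.append(Chromosome(template.genes ^ flips.astype(np.uint8)))
        i += 1
    return Population(members=tuple(members), provenance="greedy", seed=seed)
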