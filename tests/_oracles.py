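"""Independent brute-force oracles used to validate the package.

Everything here is pure-Python loop code, deliberately written without the
package's vectorized machinery, so that agreements are meaningful.
"""

from __future__ import annotations

import itertools


def pattern_pairs(m: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(m) for j in range(i + 1, m)]


def brute_distinguishability(rows: list[str]) -> list[int]:
    """Per-column count of pattern pairs with differing alleles."""
    m, n = len(rows), len(rows[0])
    out = []
    for k in range(n):
        count = 0
        for i, j in pattern_pairs(m):
            if rows[i][k] != rows[j][k]:
                count += 1
        out.append(count)
    return out


def brute_pair_counts(rows: list[str], bits) -> list[int]:
    """D_ij per pair (lexicographic i<j) for a 0/1 selection vector."""
    counts = []
    for i, j in pattern_pairs(len(rows)):
        d = 0
        for k, b in enumerate(bits):
            if b and rows[i][k] != rows[j][k]:
                d += 1
        counts.append(d)
    return counts


def brute_objectives(rows: list[str], bits) -> tuple[float, float, float, float]:
    """(f1, f2, f3, f4) computed by direct looping.

    Moments use the same exact-integer formula as the package so equal
    values are bitwise comparable (sum/c and sum-of-squares based variance).
    """
    counts = brute_pair_counts(rows, bits)
    c = len(counts)
    f1 = float(sum(bits))
    f2 = float(min(counts))
    s1 = sum(counts)
    s2 = sum(x * x for x in counts)
    f3 = s1 / c
    f4 = max(s2 / c - f3 * f3, 0.0)
    return (f1, f2, f3, f4)


def min_sense(v) -> tuple[float, float, float, float]:
    return (v[0], -v[1], -v[2], v[3])


def dominates(a, b) -> bool:
    """Pareto dominance on raw (f1, f2, f3, f4) with directions min,max,max,min."""
    sa, sb = min_sense(a), min_sense(b)
    return all(x <= y for x, y in zip(sa, sb)) and any(
        x < y for x, y in zip(sa, sb)
    )


def enumerate_objectives(rows: list[str]) -> set[tuple]:
    """All distinct objective vectors over the 2^n chromosomes."""
    n = len(rows[0])
    return {
        brute_objectives(rows, bits)
        for bits in itertools.product([0, 1], repeat=n)
    }


def enumerate_pareto(rows: list[str]) -> set[tuple]:
    """The exact Pareto front (objective space) by full enumeration."""
    vecs = enumerate_objectives(rows)
    return {v for v in vecs if not any(dominates(u, v) for u in vecs)}


def brute_greedy_cover(rows: list[str], coverage: int) -> tuple[list[int], list[int]]:
    """Replay of the greedy rule: sort SNPs by distinguishability descending
    (index ascending on ties), add only SNPs that raise a deficient pair.

    Returns (considered order, selected), both 0-based.
    """
    m, n = len(rows), len(rows[0])
    dist = brute_distinguishability(rows)
    order = sorted(range(n), key=lambda k: (-dist[k], k))
    pairs = pattern_pairs(m)
    cap = [sum(1 for k in range(n) if rows[i][k] != rows[j][k]) for i, j in pairs]
    target = [min(coverage, c) for c in cap]
    counts = [0] * len(pairs)
    considered, selected = [], []
    for k in order:
        if all(c >= t for c, t in zip(counts, target)):
            break
        considered.append(k)
        helps = any(
            counts[p] < target[p] and rows[i][k] != rows[j][k]
            for p, (i, j) in enumerate(pairs)
        )
        if not helps:
            continue
        selected.append(k)
        for p, (i, j) in enumerate(pairs):
            if rows[i][k] != rows[j][k]:
                counts[p] += 1
    return considered, selected
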