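"""Binary-encoded evolutionary search over tag SNP selections.

Four search strategies run under one contract: NSGA-II (fast nondominated
sorting + crowding distance), SPEA2 (strength/density environmental
selection), NSGA-III (Das-Dennis reference directions + niching) and MOEA/D
(Tchebycheff decomposition, steady-state neighborhood replacement).
Variation for the first three is binary tournament (Pareto dominance first,
rank-sum fitness second), uniform crossover and bit-flip mutation; MOEA/D
draws parents from each subproblem's weight-vector neighborhood and
considers one offspring per update.

Maximization objectives (f2, f3) are negated internally so every strategy
minimizes; reported objective vectors are always on the original scales.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from tagsnp.haplotype import HaplotypeBlock
from tagsnp.initialization import greedy_population, random_population
from tagsnp.objectives import (
    BlockEvaluator,
    Chromosome,
    ObjectiveVector,
    _MIN_SENSE_SIGN,
    dominates_min,
    rank_sum_from_min_array,
)

__all__ = [
    "ALGORITHMS",
    "GAConfig",
    "RunResult",
    "binary_tournament",
    "bitflip_mutation",
    "nondominated_mask",
    "run",
    "uniform_crossover",
]

ALGORITHMS = ("NSGA2", "SPEA2", "NSGA3", "MOEAD")
INITS = ("random", "greedy")


@dataclass(frozen=True)
class GAConfig:
    """Run configuration; defaults follow the standard protocol.

    ``p_m = None`` means 1/n, resolved against the block at run time.
    """

    algorithm: str = "NSGA2"
    pop_size: int = 200
    offspring_size: int = 200
    generations: int = 500
    p_c: float = 0.7
    p_m: Optional[float] = None
    neighborhood: int = 15
    init: str = "random"
    seed: int = 0

    def __post_init__(self) -> None:
        algo = self.algorithm.upper().replace("-", "").replace("/", "")
        if algo not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}"
            )
        object.__setattr__(self, "algorithm", algo)
        if self.init not in INITS:
            raise ValueError(f"init must be one of {INITS}, got {self.init!r}")
        if self.pop_size < 2:
            raise ValueError(f"pop_size must be >= 2, got {self.pop_size}")
        if self.offspring_size < 2:
            raise ValueError(
                f"offspring_size must be >= 2, got {self.offspring_size}"
            )
        if self.generations < 1:
            raise ValueError(f"generations must be >= 1, got {self.generations}")
        if not 0.0 <= self.p_c <= 1.0:
            raise ValueError(f"p_c must be in [0,1], got {self.p_c}")
        if self.p_m is not None and not 0.0 <= self.p_m <= 1.0:
            raise ValueError(f"p_m must be in [0,1], got {self.p_m}")
        if not 2 <= self.neighborhood <= self.pop_size:
            raise ValueError(
                f"neighborhood must be in [2, pop_size={self.pop_size}], "
                f"got {self.neighborhood}"
            )

    def resolve_p_m(self, n: int) -> float:
        return self.p_m if self.p_m is not None else 1.0 / n

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "pop_size": self.pop_size,
            "offspring_size": self.offspring_size,
            "generations": self.generations,
            "p_c": self.p_c,
            "p_m": self.p_m,
            "neighborhood": self.neighborhood,
            "init": self.init,
            "seed": self.seed,
        }


@dataclass
class RunResult:
    """One optimizer run: config, final nondominated front and traces."""

    config: GAConfig
    seed: int
    front: tuple[Chromosome, ...]
    front_objectives: tuple[ObjectiveVector, ...]
    traces: dict[str, list[float]]
    wall_time: float = 0.0
    generation_fronts: Optional[list[np.ndarray]] = field(default=None, repr=False)

    def front_array(self) -> np.ndarray:
        """Raw (k, 4) objective array of the final front."""
        return np.stack([o.as_array() for o in self.front_objectives])

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "seed": self.seed,
            "front": [c.to_string() for c in self.front],
            "front_objectives": [list(o.as_array()) for o in self.front_objectives],
            "traces": {k: list(map(float, v)) for k, v in self.traces.items()},
            "wall_time": self.wall_time,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunResult":
        return cls(
            config=GAConfig(**d["config"]),
            seed=d["seed"],
            front=tuple(Chromosome.from_string(s) for s in d["front"]),
            front_objectives=tuple(
                ObjectiveVector.from_array(np.asarray(o))
                for o in d["front_objectives"]
            ),
            traces={k: list(v) for k, v in d["traces"].items()},
            wall_time=d.get("wall_time", 0.0),
        )


# ---------------------------------------------------------------------------
# genetic operators
# ---------------------------------------------------------------------------

def uniform_crossover(
    parent_a: Chromosome,
    parent_b: Chromosome,
    p_c: float = 0.7,
    seed: Optional[int] = None,
) -> tuple[Chromosome, Chromosome]:
    """Uniform crossover: with probability p_c, swap each gene w.p. 0.5.

    With probability 1 - p_c the parents are returned unchanged.  At every
    position the offspring gene multiset equals the parents' multiset.
    """
    if parent_a.n != parent_b.n:
        raise ValueError(
            f"parent lengths differ: {parent_a.n} vs {parent_b.n}"
        )
    rng = np.random.default_rng(seed)
    a, b = _uniform_crossover_arrays(parent_a.genes, parent_b.genes, p_c, rng)
    return Chromosome(a), Chromosome(b)


def _uniform_crossover_arrays(
    a: np.ndarray, b: np.ndarray, p_c: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    if rng.random() >= p_c:
        return a.copy(), b.copy()
    swap = rng.random(a.size) < 0.5
    child_a = np.where(swap, b, a).astype(np.uint8)
    child_b = np.where(swap, a, b).astype(np.uint8)
    return child_a, child_b


def bitflip_mutation(
    chrom: Chromosome, p_m: float, seed: Optional[int] = None
) -> Chromosome:
    """Flip each gene independently with probability p_m (0->1, 1->0)."""
    if not 0.0 <= p_m <= 1.0:
        raise ValueError(f"p_m must be in [0,1], got {p_m}")
    rng = np.random.default_rng(seed)
    return Chromosome(_bitflip_array(chrom.genes, p_m, rng))


def _bitflip_array(genes: np.ndarray, p_m: float, rng: np.random.Generator) -> np.ndarray:
    flips = rng.random(genes.size) < p_m
    return (genes ^ flips.astype(np.uint8)).astype(np.uint8)


def binary_tournament(
    a: Chromosome,
    b: Chromosome,
    obj_a: ObjectiveVector,
    obj_b: ObjectiveVector,
    fitness_a: Optional[int] = None,
    fitness_b: Optional[int] = None,
    seed: Optional[int] = None,
) -> Chromosome:
    """Pick the better of two evaluated chromosomes.

    Pareto dominance decides first; otherwise the lower rank-sum fitness
    (computed within the caller's current population) wins; remaining ties
    are broken uniformly at random (seeded).
    """
    fa, fb = obj_a.as_min_array(), obj_b.as_min_array()
    if dominates_min(fa, fb):
        return a
    if dominates_min(fb, fa):
        return b
    if fitness_a is not None and fitness_b is not None:
        if fitness_a < fitness_b:
            return a
        if fitness_b < fitness_a:
            return b
    rng = np.random.default_rng(seed)
    return a if rng.random() < 0.5 else b


# ---------------------------------------------------------------------------
# dominance machinery
# ---------------------------------------------------------------------------

def _dominance_matrix(F: np.ndarray) -> np.ndarray:
    """Boolean (N, N) matrix: entry (i, j) true iff i dominates j (min-sense)."""
    le = np.all(F[:, None, :] <= F[None, :, :], axis=2)
    lt = np.any(F[:, None, :] < F[None, :, :], axis=2)
    return le & lt


def nondominated_mask(F: np.ndarray) -> np.ndarray:
    """Mask of rows of F (min-sense) not dominated by any other row."""
    dom = _dominance_matrix(F)
    return ~dom.any(axis=0)


def fast_nondominated_sort(F: np.ndarray) -> list[np.ndarray]:
    """Peel F (min-sense) into successive nondominated fronts."""
    n = F.shape[0]
    dom = _dominance_matrix(F)
    n_dominators = dom.sum(axis=0).astype(np.int64)
    fronts: list[np.ndarray] = []
    remaining = np.ones(n, dtype=bool)
    while remaining.any():
        current = remaining & (n_dominators == 0)
        if not current.any():  # pragma: no cover - cannot happen for finite F
            current = remaining.copy()
        fronts.append(np.flatnonzero(current))
        remaining &= ~current
        n_dominators -= dom[current].sum(axis=0)
    return fronts


def crowding_distance(F: np.ndarray) -> np.ndarray:
    """NSGA-II crowding distance; boundary solutions get +inf."""
    n, k = F.shape
    dist = np.zeros(n)
    if n <= 2:
        return np.full(n, np.inf)
    for j in range(k):
        order = np.argsort(F[:, j], kind="stable")
        col = F[order, j]
        span = col[-1] - col[0]
        dist[order[0]] = np.inf
        dist[order[-1]] = np.inf
        if span > 0:
            dist[order[1:-1]] += (col[2:] - col[:-2]) / span
    return dist


# ---------------------------------------------------------------------------
# survival strategies
# ---------------------------------------------------------------------------

def _nsga2_survival(F: np.ndarray, n_survive: int, rng: np.random.Generator) -> np.ndarray:
    survivors: list[int] = []
    for front in fast_nondominated_sort(F):
        if len(survivors) + front.size <= n_survive:
            survivors.extend(front.tolist())
            if len(survivors) == n_survive:
                break
        else:
            need = n_survive - len(survivors)
            crowd = crowding_distance(F[front])
            order = np.argsort(-crowd, kind="stable")
            survivors.extend(front[order[:need]].tolist())
            break
    return np.array(survivors, dtype=np.int64)


def _spea2_fitness(F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """SPEA2 fitness = raw strength-of-dominators + kNN density; plus distances."""
    n = F.shape[0]
    dom = _dominance_matrix(F)
    strength = dom.sum(axis=1).astype(float)
    raw = (strength[:, None] * dom).sum(axis=0)
    dists = np.sqrt(((F[:, None, :] - F[None, :, :]) ** 2).sum(axis=2))
    np.fill_diagonal(dists, np.inf)
    k = max(1, int(math.sqrt(n)))
    sigma_k = np.sort(dists, axis=1)[:, k - 1]
    density = 1.0 / (sigma_k + 2.0)
    return raw + density, dists


def _spea2_truncate(idx: np.ndarray, dists: np.ndarray, n_survive: int) -> np.ndarray:
    """Iteratively drop the member with lexicographically smallest
    sorted-distance vector to the rest (archive truncation)."""
    keep = idx.tolist()
    sub = dists[np.ix_(idx, idx)].copy()
    while len(keep) > n_survive:
        k = len(keep)
        sorted_d = np.sort(sub[:k, :k], axis=1)
        # lexicographic argmin over rows
        victim = 0
        for i in range(1, k):
            a, b = sorted_d[victim], sorted_d[i]
            diff = np.flatnonzero(a != b)
            if diff.size and b[diff[0]] < a[diff[0]]:
                victim = i
        keep.pop(victim)
        sub = np.delete(np.delete(sub, victim, axis=0), victim, axis=1)
    return np.array(keep, dtype=np.int64)


def _spea2_survival(F: np.ndarray, n_survive: int, rng: np.random.Generator) -> np.ndarray:
    fitness, dists = _spea2_fitness(F)
    nondom = np.flatnonzero(fitness < 1.0)
    if nondom.size == n_survive:
        return nondom
    if nondom.size > n_survive:
        return _spea2_truncate(nondom, dists, n_survive)
    dominated = np.flatnonzero(fitness >= 1.0)
    order = dominated[np.argsort(fitness[dominated], kind="stable")]
    need = n_survive - nondom.size
    return np.concatenate([nondom, order[:need]])


def das_dennis(n_obj: int, n_partitions: int) -> np.ndarray:
    """Das-Dennis simplex-lattice weight vectors summing to 1."""
    if n_partitions == 0:
        return np.full((1, n_obj), 1.0 / n_obj)
    out: list[list[float]] = []

    def rec(prefix: list[int], left: int, depth: int) -> None:
        if depth == n_obj - 1:
            out.append([p / n_partitions for p in prefix + [left]])
            return
        for v in range(left + 1):
            rec(prefix + [v], left - v, depth + 1)

    rec([], n_partitions, 0)
    return np.array(out)


def reference_directions(n_obj: int, min_points: int) -> np.ndarray:
    """Smallest Das-Dennis lattice with at least ``min_points`` directions."""
    p = 1
    while math.comb(p + n_obj - 1, n_obj - 1) < min_points:
        p += 1
    return das_dennis(n_obj, p)


def _nsga3_normalize(F: np.ndarray) -> np.ndarray:
    """Translate by the ideal point and scale by ASF-extreme intercepts."""
    ideal = F.min(axis=0)
    T = F - ideal
    k = F.shape[1]
    extremes = np.empty(k, dtype=np.int64)
    for j in range(k):
        w = np.full(k, 1e6)
        w[j] = 1.0
        extremes[j] = int(np.argmin(np.max(T * w, axis=1)))
    E = T[extremes]
    intercepts = T.max(axis=0).astype(float)
    try:
        if np.linalg.matrix_rank(E) == k:
            plane = np.linalg.solve(E, np.ones(k))
            cand = 1.0 / plane
            if np.all(cand > 1e-12) and np.all(np.isfinite(cand)):
                intercepts = cand
    except np.linalg.LinAlgError:  # pragma: no cover - singular fallback
        pass
    intercepts[intercepts < 1e-12] = 1.0
    return T / intercepts


def _associate(N: np.ndarray, dirs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nearest reference direction by perpendicular distance, per member."""
    norms = np.linalg.norm(dirs, axis=1)
    proj = (N @ dirs.T) / norms  # scalar projections
    proj = np.maximum(proj, 0.0)
    sq = (N ** 2).sum(axis=1, keepdims=True) - proj ** 2
    dist = np.sqrt(np.maximum(sq, 0.0))
    nearest = np.argmin(dist, axis=1)
    return nearest, dist[np.arange(N.shape[0]), nearest]


def _objective_best_indices(F: np.ndarray) -> np.ndarray:
    """One nondominated representative of each per-objective minimum.

    Among the rows attaining the minimum of objective j, the lexicographic
    minimum over the remaining objectives cannot be dominated.
    """
    k = F.shape[1]
    out = []
    for j in range(k):
        cand = np.flatnonzero(F[:, j] == F[:, j].min())
        rest = np.delete(F[cand], j, axis=1)
        order = np.lexsort(rest.T[::-1])
        out.append(int(cand[order[0]]))
    return np.unique(out)


def _nsga3_survival(
    F: np.ndarray, n_survive: int, dirs: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    fronts = fast_nondominated_sort(F)
    survivors: list[int] = []
    last: Optional[np.ndarray] = None
    for front in fronts:
        if len(survivors) + front.size <= n_survive:
            survivors.extend(front.tolist())
            if len(survivors) == n_survive:
                return np.array(survivors, dtype=np.int64)
        else:
            last = front
            break
    assert last is not None
    if not survivors:
        # the first front itself overflows: reserve one representative of
        # each per-objective best so niching cannot drop the extremes
        reserved = [
            i for i in _objective_best_indices(F) if i in set(last.tolist())
        ][: n_survive]
        survivors.extend(reserved)
        last = np.array([i for i in last if i not in set(reserved)], dtype=np.int64)
        if len(survivors) == n_survive:
            return np.array(survivors, dtype=np.int64)
    considered = np.array(survivors + last.tolist(), dtype=np.int64)
    Nrm = _nsga3_normalize(F[considered])
    nearest, dist = _associate(Nrm, dirs)
    n_prev = len(survivors)
    niche_count = np.bincount(nearest[:n_prev], minlength=dirs.shape[0])
    # members of the split front, grouped by their niche
    pool: dict[int, list[int]] = {}
    for local in range(n_prev, considered.size):
        pool.setdefault(int(nearest[local]), []).append(local)
    need = n_survive - n_prev
    active = set(pool.keys())
    chosen: list[int] = []
    while need > 0 and active:
        counts = {d: niche_count[d] for d in active}
        min_c = min(counts.values())
        cands = sorted(d for d, c in counts.items() if c == min_c)
        d = cands[int(rng.integers(len(cands)))]
        members = pool[d]
        if niche_count[d] == 0:
            pick = min(members, key=lambda i: dist[i])
        else:
            pick = members[int(rng.integers(len(members)))]
        members.remove(pick)
        chosen.append(pick)
        niche_count[d] += 1
        need -= 1
        if not members:
            active.discard(d)
    result = survivors + [int(considered[i]) for i in chosen]
    return np.array(result, dtype=np.int64)


# ---------------------------------------------------------------------------
# run driver
# ---------------------------------------------------------------------------

def _initial_population(
    block: HaplotypeBlock, config: GAConfig, seed: int
) -> np.ndarray:
    if config.init == "greedy":
        pop = greedy_population(block, config.pop_size, seed=seed)
    else:
        pop = random_population(block.n, config.pop_size, seed=seed)
    return pop.as_array()


def _mating(
    X: np.ndarray,
    F: np.ndarray,
    n_offspring: int,
    p_c: float,
    p_m: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Tournament selection + uniform crossover + bit-flip mutation."""
    pop = X.shape[0]
    ranksum = rank_sum_from_min_array(F)

    def pick() -> int:
        i, j = rng.integers(pop), rng.integers(pop)
        if dominates_min(F[i], F[j]):
            return int(i)
        if dominates_min(F[j], F[i]):
            return int(j)
        if ranksum[i] != ranksum[j]:
            return int(i) if ranksum[i] < ranksum[j] else int(j)
        return int(i) if rng.random() < 0.5 else int(j)

    children: list[np.ndarray] = []
    while len(children) < n_offspring:
        pa, pb = pick(), pick()
        ca, cb = _uniform_crossover_arrays(X[pa], X[pb], p_c, rng)
        children.append(_bitflip_array(ca, p_m, rng))
        if len(children) < n_offspring:
            children.append(_bitflip_array(cb, p_m, rng))
    return np.stack(children)


def _extract_front(X: np.ndarray, F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deduplicated nondominated subset (genes, min-sense objectives)."""
    _, unique_idx = np.unique(X, axis=0, return_index=True)
    unique_idx = np.sort(unique_idx)
    Xu, Fu = X[unique_idx], F[unique_idx]
    mask = nondominated_mask(Fu)
    return Xu[mask], Fu[mask]


def _tchebycheff(F: np.ndarray, weights: np.ndarray, z: np.ndarray,
                 scale: np.ndarray) -> np.ndarray:
    """Tchebycheff aggregation of (N,4) F rows for (N,4) weights."""
    w = np.maximum(weights, 1e-6)
    return (w * np.abs(F - z) / scale).max(axis=1)


def _moead_generation(
    X: np.ndarray,
    F: np.ndarray,
    weights: np.ndarray,
    neighbors: np.ndarray,
    z: np.ndarray,
    ev: BlockEvaluator,
    p_c: float,
    p_m: float,
    rng: np.random.Generator,
    eval_log: list[np.ndarray],
) -> np.ndarray:
    """One generation = pop_size steady-state updates; returns updated z."""
    pop = X.shape[0]
    child_F = np.empty((pop, 4))
    for i in range(pop):
        B = neighbors[i]
        pa, pb = rng.choice(B, size=2, replace=False)
        ca, _ = _uniform_crossover_arrays(X[pa], X[pb], p_c, rng)
        child = _bitflip_array(ca, p_m, rng)
        fc = ev.min_objectives(child[None, :])[0]
        child_F[i] = fc
        z = np.minimum(z, fc)
        spread = np.maximum(F.max(axis=0) - z, 1e-9)
        order = rng.permutation(B)
        g_child = _tchebycheff(fc[None, :], weights[order], z, spread)
        g_old = _tchebycheff(F[order], weights[order], z, spread)
        better = g_child <= g_old
        for j in order[better]:
            X[j] = child
            F[j] = fc
    eval_log.append(child_F)
    return z


def run(block: HaplotypeBlock, config: GAConfig) -> RunResult:
    """Execute the configured algorithm and return its nondominated front.

    Fully reproducible for a fixed config (seed included); the final front
    is deduplicated and mutually nondominated, and traces cover every
    generation.
    """
    t0 = time.perf_counter()
    master = np.random.default_rng(config.seed)
    init_seed = int(master.integers(2 ** 31))
    rng = np.random.default_rng(int(master.integers(2 ** 31)))

    ev = BlockEvaluator(block)
    p_m = config.resolve_p_m(block.n)
    X = _initial_population(block, config, init_seed)
    F = ev.min_objectives(X)

    gen_fronts: list[np.ndarray] = []  # raw-scale per-generation fronts
    eval_log: list[np.ndarray] = [F.copy()]  # every objective vector seen

    algo = config.algorithm
    if algo == "MOEAD":
        weights = reference_directions(4, config.pop_size)
        if weights.shape[0] > config.pop_size:
            pick = np.round(
                np.linspace(0, weights.shape[0] - 1, config.pop_size)
            ).astype(np.int64)
            weights = weights[pick]
        wdist = np.sqrt(((weights[:, None] - weights[None, :]) ** 2).sum(axis=2))
        T = min(config.neighborhood, config.pop_size)
        neighbors = np.argsort(wdist, axis=1, kind="stable")[:, :T]
        z = F.min(axis=0)
        for _ in range(config.generations):
            z = _moead_generation(
                X, F, weights, neighbors, z, ev, config.p_c, p_m, rng, eval_log
            )
            _, Ff = _extract_front(X, F)
            gen_fronts.append(Ff * _MIN_SENSE_SIGN)
    else:
        if algo == "NSGA3":
            dirs = reference_directions(4, config.pop_size)
            survival = lambda FF, ns, rr: _nsga3_survival(FF, ns, dirs, rr)
        elif algo == "SPEA2":
            survival = _spea2_survival
        else:
            survival = _nsga2_survival
        for _ in range(config.generations):
            children = _mating(X, F, config.offspring_size, config.p_c, p_m, rng)
            Fc = ev.min_objectives(children)
            eval_log.append(Fc)
            Xall = np.vstack([X, children])
            Fall = np.vstack([F, Fc])
            keep = survival(Fall, config.pop_size, rng)
            X, F = Xall[keep], Fall[keep]
            _, Ff = _extract_front(X, F)
            gen_fronts.append(Ff * _MIN_SENSE_SIGN)

    Xf, Ff = _extract_front(X, F)
    # prune against everything evaluated during the run: never report a
    # solution the search itself saw dominated
    seen = np.unique(np.vstack(eval_log), axis=0)
    keep = np.array([
        not np.any(
            np.all(seen <= f, axis=1) & np.any(seen < f, axis=1)
        )
        for f in Ff
    ])
    Xf, Ff = Xf[keep], Ff[keep]
    raw = Ff * _MIN_SENSE_SIGN
    order = np.lexsort(raw.T[::-1])  # sort by f1, then f2, f3, f4
    Xf, raw = Xf[order], raw[order]

    traces = _compute_traces(gen_fronts)
    result = RunResult(
        config=config,
        seed=config.seed,
        front=tuple(Chromosome(g) for g in Xf),
        front_objectives=tuple(ObjectiveVector.from_array(r) for r in raw),
        traces=traces,
        wall_time=time.perf_counter() - t0,
        generation_fronts=gen_fronts,
    )
    return result


def _compute_traces(gen_fronts: list[np.ndarray]) -> dict[str, list[float]]:
    """Per-generation quality measures with bounds pooled over the run."""
    from tagsnp import evaluation as ev_mod

    normalized, _bounds = ev_mod.normalize(gen_fronts)
    traces: dict[str, list[float]] = {
        "front_size": [],
        "range": [],
        "summin": [],
        "minsum": [],
        "max_tolerance_rate": [],
        "avg_tolerance_rate": [],
        "avg_hamming": [],
    }
    for raw, norm in zip(gen_fronts, normalized):
        max_tr, avg_tr = ev_mod.tolerance_rates(raw)
        traces["front_size"].append(float(raw.shape[0]))
        traces["range"].append(ev_mod.range_metric(norm))
        traces["summin"].append(ev_mod.summin(norm))
        traces["minsum"].append(ev_mod.minsum(norm))
        traces["max_tolerance_rate"].append(max_tr)
        traces["avg_tolerance_rate"].append(avg_tr)
        traces["avg_hamming"].append(ev_mod.avg_hamming_metric(raw))
    return traces
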