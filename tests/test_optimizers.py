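import numpy as np
import pytest

from tagsnp import (
    Chromosome,
    GAConfig,
    HaplotypeBlock,
    ObjectiveVector,
    SyntheticBlockSpec,
    generate_block,
    run,
)
from tagsnp.optimizers import (
    ALGORITHMS,
    RunResult,
    binary_tournament,
    bitflip_mutation,
    crowding_distance,
    das_dennis,
    fast_nondominated_sort,
    nondominated_mask,
    reference_directions,
    uniform_crossover,
)

from _oracles import dominates, enumerate_pareto

SMALL = dict(pop_size=20, offspring_size=20, generations=50)


def _front_set(result: RunResult) -> set:
    return {(o.f1, o.f2, o.f3, o.f4) for o in result.front_objectives}


class TestGAConfig:
    def test_defaults_follow_protocol(self):
        cfg = GAConfig()
        assert (cfg.pop_size, cfg.offspring_size, cfg.generations) == (200, 200, 500)
        assert cfg.p_c == 0.7
        assert cfg.p_m is None  # resolved to 1/n per block
        assert cfg.neighborhood == 15

    def test_p_m_resolution(self):
        assert GAConfig().resolve_p_m(1000) == pytest.approx(1e-3)
        assert GAConfig(p_m=0.5).resolve_p_m(1000) == 0.5

    @pytest.mark.parametrize("name,expected", [
        ("nsga2", "NSGA2"), ("NSGA-2", "NSGA2"), ("moea/d", "MOEAD"),
        ("spea2", "SPEA2"), ("nsga3", "NSGA3"),
    ])
    def test_algorithm_name_normalization(self, name, expected):
        assert GAConfig(algorithm=name).algorithm == expected

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError):
            GAConfig(algorithm="msops")

    @pytest.mark.parametrize("kwargs", [
        {"pop_size": 1}, {"generations": 0}, {"p_c": 1.5},
        {"p_m": -0.1}, {"neighborhood": 1}, {"init": "magic"},
        {"neighborhood": 300},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GAConfig(**kwargs)


class TestUniformCrossover:
    def test_identical_parents_unchanged(self):
        p = Chromosome.from_string("10110")
        a, b = uniform_crossover(p, p, p_c=1.0, seed=0)
        assert a == p and b == p

    def test_complementary_parents_xor(self):
        a = Chromosome.from_string("11111")
        b = Chromosome.from_string("00000")
        ca, cb = uniform_crossover(a, b, p_c=1.0, seed=1)
        assert (ca.genes ^ cb.genes).tolist() == [1] * 5

    def test_position_multiset_preserved(self):
        a = Chromosome.from_string("1100110011")
        b = Chromosome.from_string("0101010101")
        ca, cb = uniform_crossover(a, b, p_c=1.0, seed=2)
        assert ((ca.genes.astype(int) + cb.genes) == (a.genes.astype(int) + b.genes)).all()

    def test_p_c_zero_returns_copies(self):
        a = Chromosome.from_string("10101")
        b = Chromosome.from_string("01010")
        ca, cb = uniform_crossover(a, b, p_c=0.0, seed=3)
        assert ca == a and cb == b

    def test_deterministic(self):
        a = Chromosome.from_string("1100110011")
        b = Chromosome.from_string("0101010101")
        assert uniform_crossover(a, b, 0.7, seed=9) == uniform_crossover(a, b, 0.7, seed=9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            uniform_crossover(Chromosome.from_string("10"), Chromosome.from_string("101"), 0.7)


class TestBitflipMutation:
    def test_zero_rate_is_identity(self):
        c = Chromosome.from_string("10110")
        assert bitflip_mutation(c, 0.0, seed=0) == c

    def test_unit_rate_is_complement(self):
        c = Chromosome.from_string("10110")
        assert bitflip_mutation(c, 1.0, seed=0).to_string() == "01001"

    def test_expected_flip_count(self):
        n, trials = 1000, 3000
        c = Chromosome(np.zeros(n, dtype=np.uint8))
        rng_seeds = range(trials)
        total = sum(int(bitflip_mutation(c, 1 / n, seed=s).genes.sum()) for s in rng_seeds)
        assert 0.8 <= total / trials <= 1.2

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            bitflip_mutation(Chromosome.from_string("1"), 1.5)


class TestBinaryTournament:
    def _obj(self, f1, f2, f3, f4):
        return ObjectiveVector(f1=f1, f2=f2, f3=f3, f4=f4)

    def test_dominating_candidate_wins(self):
        a, b = Chromosome.from_string("100"), Chromosome.from_string("111")
        oa = self._obj(1, 1, 1.0, 0.0)  # dominates (fewer SNPs, same rest)
        ob = self._obj(3, 1, 1.0, 0.0)
        assert binary_tournament(a, b, oa, ob) == a
        assert binary_tournament(b, a, ob, oa) == a

    def test_rank_sum_breaks_nondominated_ties(self):
        a, b = Chromosome.from_string("110"), Chromosome.from_string("011")
        oa = self._obj(2, 2, 1.0, 0.5)
        ob = self._obj(1, 1, 1.0, 0.5)  # mutually nondominated with oa
        assert not dominates((2, 2, 1.0, 0.5), (1, 1, 1.0, 0.5))
        winner = binary_tournament(a, b, oa, ob, fitness_a=4, fitness_b=7)
        assert winner == a

    def test_full_tie_uses_seeded_rng(self):
        a, b = Chromosome.from_string("110"), Chromosome.from_string("011")
        o = self._obj(2, 1, 1.0, 0.5)
        picks = {binary_tournament(a, b, o, o, seed=s).to_string() for s in range(20)}
        assert picks == {"110", "011"}  # both reachable, seed-deterministic
        assert binary_tournament(a, b, o, o, seed=5) == binary_tournament(a, b, o, o, seed=5)


class TestDominanceMachinery:
    def test_nondominated_mask(self):
        F = np.array([[1, 1], [2, 2], [0, 3]], dtype=float)
        assert nondominated_mask(F).tolist() == [True, False, True]

    def test_fast_nondominated_sort_peels_layers(self):
        F = np.array([[0, 0], [1, 1], [2, 2], [0, 1]], dtype=float)
        fronts = [f.tolist() for f in fast_nondominated_sort(F)]
        assert fronts == [[0], [3], [1], [2]]

    def test_crowding_extremes_infinite(self):
        F = np.array([[0.0, 2.0], [1.0, 1.0], [2.0, 0.0]])
        d = crowding_distance(F)
        assert np.isinf(d[0]) and np.isinf(d[2])
        assert np.isfinite(d[1])

    def test_das_dennis_sums_to_one(self):
        dirs = das_dennis(4, 3)
        assert dirs.shape == (20, 4)
        assert np.allclose(dirs.sum(axis=1), 1.0)

    def test_reference_directions_cover_requested_count(self):
        dirs = reference_directions(4, 200)
        assert dirs.shape[0] >= 200


class TestRunContract:
    @pytest.mark.parametrize("algo", ALGORITHMS)
    def test_exact_front_on_worked_block(self, algo, block45, rows45):
        result = run(block45, GAConfig(algorithm=algo, seed=11, **SMALL))
        assert _front_set(result) == enumerate_pareto(rows45)

    @pytest.mark.parametrize("algo", ALGORITHMS)
    def test_deterministic(self, algo, block45):
        cfg = GAConfig(algorithm=algo, seed=21, **SMALL)
        a, b = run(block45, cfg), run(block45, cfg)
        assert [c.to_string() for c in a.front] == [c.to_string() for c in b.front]
        assert a.traces == b.traces

    @pytest.mark.parametrize("algo", ALGORITHMS)
    def test_single_generation_structure(self, algo, block45):
        cfg = GAConfig(algorithm=algo, pop_size=10, offspring_size=10,
                       generations=1, neighborhood=10, seed=0)
        result = run(block45, cfg)
        assert len(result.traces["front_size"]) == 1
        front = result.front_array()
        for i, a in enumerate(front):
            for j, b in enumerate(front):
                if i != j:
                    assert not dominates(tuple(a), tuple(b))

    @pytest.mark.parametrize("algo", ALGORITHMS)
    @pytest.mark.parametrize("init", ["random", "greedy"])
    def test_inits_reach_front(self, algo, init, block45, rows45):
        # greedy init starts from dense cover sets; a slightly larger budget
        # is needed to also discover the sparse end of the front
        cfg = GAConfig(algorithm=algo, init=init, seed=2, pop_size=20,
                       offspring_size=20, generations=80)
        assert _front_set(run(block45, cfg)) == enumerate_pareto(rows45)

    def test_trace_length_equals_generations(self, block45):
        cfg = GAConfig(pop_size=10, offspring_size=10, generations=7,
                       neighborhood=10, seed=0)
        result = run(block45, cfg)
        for key in ("front_size", "range", "summin", "minsum",
                    "max_tolerance_rate", "avg_tolerance_rate", "avg_hamming"):
            assert len(result.traces[key]) == 7

    def test_front_nondominated_on_random_block(self):
        block = generate_block(SyntheticBlockSpec(
            m=6, n=12, n_founders=3, recomb_rate=0.1, noise_rate=0.1, seed=5
        ))
        result = run(block, GAConfig(algorithm="NSGA2", pop_size=30,
                                     offspring_size=30, generations=30, seed=5))
        front = [tuple(x) for x in result.front_array()]
        for a in front:
            for b in front:
                if a != b:
                    assert not dominates(a, b)

    def test_subset_of_pareto_set_small_block(self):
        block = generate_block(SyntheticBlockSpec(
            m=5, n=8, n_founders=3, recomb_rate=0.2, noise_rate=0.2, seed=1
        ))
        pareto = enumerate_pareto(block.row_strings())
        result = run(block, GAConfig(algorithm="NSGA2", pop_size=40,
                                     offspring_size=40, generations=60, seed=1))
        assert _front_set(result) <= pareto

    @pytest.mark.parametrize("algo", ["NSGA2", "SPEA2", "NSGA3"])
    def test_elitism_best_objectives_never_worsen(self, algo):
        block = generate_block(SyntheticBlockSpec(
            m=6, n=12, n_founders=3, recomb_rate=0.1, noise_rate=0.1, seed=2
        ))
        result = run(block, GAConfig(algorithm=algo, pop_size=30,
                                     offspring_size=30, generations=40, seed=7))
        sign = np.array([1.0, -1.0, -1.0, 1.0])
        best = np.array([(f * sign).min(axis=0) for f in result.generation_fronts])
        assert (np.diff(best, axis=0) <= 1e-12).all()

    def test_reported_scales_are_original(self, block45):
        result = run(block45, GAConfig(seed=0, **SMALL))
        arr = result.front_array()
        assert (arr[:, 0] >= 0).all() and (arr[:, 1] >= 0).all()
        assert (arr[:, 2] >= 0).all() and (arr[:, 3] >= 0).all()

    def test_front_chromosomes_deduplicated(self, block45):
        result = run(block45, GAConfig(seed=0, **SMALL))
        strings = [c.to_string() for c in result.front]
        assert len(strings) == len(set(strings))

    def test_greedy_init_runs_on_structured_block(self):
        block = generate_block(SyntheticBlockSpec(
            m=8, n=30, n_founders=3, recomb_rate=0.05, noise_rate=0.1, seed=3
        ))
        result = run(block, GAConfig(algorithm="MOEAD", init="greedy",
                                     pop_size=20, offspring_size=20,
                                     generations=20, seed=3))
        assert len(result.front) >= 1


class TestRunResultSerialization:
    def test_json_round_trip(self, block45):
        result = run(block45, GAConfig(seed=4, pop_size=10, offspring_size=10,
                                       neighborhood=10, generations=5))
        again = RunResult.from_dict(result.to_dict())
        assert [c.to_string() for c in again.front] == [c.to_string() for c in result.front]
        assert again.config == result.config
        assert again.traces == result.traces
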