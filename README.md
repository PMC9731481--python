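# tagsnp

Many-objective selection of tag SNPs from haplotype blocks.

A haplotype block is an `m x n` binary matrix of distinct haplotype
patterns over `n` biallelic SNPs. A tag SNP set is a SNP subset that
distinguishes every pair of patterns. `tagsnp` searches for tag SNP sets
that jointly optimize four objectives:

1. **compactness** (`f1`, minimize) — number of selected SNPs;
2. **tolerance** (`f2`, maximize) — minimum over pattern pairs of the
   number of selected SNPs distinguishing the pair (`f2 - 1` missing SNPs
   are tolerated);
3. **dissimilarity** (`f3`, maximize) — average pairwise Hamming distance
   between patterns on the selected SNPs;
4. **balance** (`f4`, minimize) — population variance of those distances.

Search runs under four evolutionary strategies implemented from scratch —
NSGA-II, SPEA2, NSGA-III (Das–Dennis reference directions) and MOEA/D
(Tchebycheff decomposition, steady-state neighborhood replacement) — with
binary encoding, binary tournament (Pareto dominance, then rank-sum
fitness), uniform crossover and bit-flip mutation, and either random or
greedy (distinguishability-sorted, coverage-targeted) initialization.
A measure suite (Range, SumMin, MinSum, tolerance rates, average Hamming
distance, hypervolume) compares fronts under pooled min–max normalization.

## CLI

```sh
# synthesize a block (founder/recombination model, LD-like columns)
tagsnp generate --m 20 --n 200 --seed 1 --out block.txt

# run one optimizer; writes run.front.tsv (bitstring + f1..f4) and run.json
tagsnp select block.txt --algorithm moead --init greedy --pop 200 \
    --generations 500 --seed 7 --out-prefix run

# full algorithm x init x runs grid from a YAML plan
tagsnp benchmark plan.yaml

# measure suite over saved runs (pooled normalization across inputs)
tagsnp evaluate run1.json run2.json --out-prefix report
```

A benchmark plan is a YAML mapping with `block` (path) or `spec`
(generator parameters), `algorithms`, `inits`, `runs`, `base_seed`,
`outdir`, and GAConfig overrides under `config`. Default operator settings:
population 200, offspring 200, 500 generations, crossover 0.7, mutation
1/n, MOEA/D neighborhood 15.

## Python API

```python
from tagsnp import (read_block, generate_block, SyntheticBlockSpec,
                    GAConfig, run, evaluate, Chromosome)

block = generate_block(SyntheticBlockSpec(m=20, n=200, seed=1))
result = run(block, GAConfig(algorithm="NSGA3", init="greedy", seed=1))
for chrom, obj in zip(result.front, result.front_objectives):
    print(chrom.to_string(), obj.f1, obj.f2, obj.f3, obj.f4)
```

Every run is deterministic for a fixed config and seed; the reported front
is deduplicated, mutually nondominated, and additionally pruned against
every solution evaluated during the run.

## Layout

- `src/tagsnp/haplotype.py` — block model, matrix-format I/O,
  distinguishability, synthetic generator
- `src/tagsnp/objectives.py` — the four objectives, pairwise distinguish
  counts, rank-sum fitness
- `src/tagsnp/initialization.py` — random and greedy populations
- `src/tagsnp/optimizers.py` — genetic operators and the four search
  strategies under one run contract
- `src/tagsnp/evaluation.py` — normalization, front quality measures,
  summary tables
- `src/tagsnp/cli.py` — `generate` / `select` / `benchmark` / `evaluate`
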