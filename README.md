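# ibbig

Iterative binary bi-clustering of gene-set association matrices.

## The problem

Meta-analysis of transcriptomics studies is hard to do at the gene level:
different platforms measure different probes, and samples are unmatched
across studies. A robust alternative is to run gene set analysis (GSA) on
each study first and work with its *discretized* output: a sparse binary
matrix whose rows are gene sets (e.g. MSigDB C2) and whose columns are
"phenotypes" — either single-sample enrichment profiles or pairwise
covariate contrasts (Grade 1 vs Grade 3, ER+ vs ER−, ...), with a 1
marking a significant gene set–phenotype association.

`ibbig` finds *modules* (bi-clusters) in such a matrix: groups of gene
sets coordinately associated with groups of phenotypes across studies.
It needs no prior estimate of the number or size of clusters, tolerates
heavy noise, and — because discovered signal is only partially masked
between iterations — it can recover *overlapping* modules of very
different shapes.

## The score and the algorithm

For a candidate module `K` with `k` phenotypes (2 ≤ k ≤ m), each gene
set `i` gets an association probability and a Shannon entropy

    p_i = (1/k) Σ_{j∈K} w_ij,     H_i = −p log₂ p − (1−p) log₂ (1−p),

computed on a weight matrix `W` that equals the binary matrix `M` on the
first iteration. The row weight is the α-weighted geometric mean of
module size and homogeneity, and the row score is the weighted
association count, gated asymmetrically at 50%:

    W_ik = k^α (1 − H_i)^(1−α),
    S_i  = W_ik · Σ_{j∈K} w_ij   if p_i > 0.5,  else 0.

Shared *non*-associations carry no evidence (they arise from technical
causes), so rows at or below p = 0.5 contribute nothing. The module
fitness `S = Σ_i S_i` is maximised by a genetic algorithm with offspring
selection: individuals are column-membership bit vectors, parents are
drawn by linear-ranking selection, recombined by single-point crossover
and mutated, and a generation must fill a fixed share of its slots with
children that beat at least one parent; the search stops after 50
stagnant generations. After each discovered module the used fraction
`(1 − H_i)^(1−α)` of every scoring row's module-column weights is
removed, and the search repeats — homogeneous rows are consumed
entirely, heterogeneous rows leave a residue that lets weaker and
overlapping modules surface later. Modules are ranked by the weighted
score `log((k/m)·S)`; positive values mark genuine modules.

Default parameters: α = 0.3, population 100, mutation rate 0.08,
success ratio 0.6, selection pressure 1.2, stagnation 50. α tunes the
sensitivity–specificity trade-off (α = 0.5 finds weaker modules at the
cost of specificity).

## Worked example

The package ships the planted-module benchmark generator: a 400×400
binary matrix with seven overlapping modules of very different shapes
(M1 "tall": 25 phenotypes × 250 gene sets; M2 wide: 120 phenotypes),
within-module signal gradients (e.g. 90% → 40%), and 10% background
noise.

```python
from ibbig import IBBIG, make_artificial, SimulationConfig, evaluate_against_truth

matrix, truth = make_artificial(SimulationConfig(seed=7))
result = IBBIG(matrix, n_modules=8).fit(seed=7)
print(result.summary())
```

```
iBBiG extraction results
  matrix: 400 gene sets x 400 phenotypes
  params: alpha=0.3, P=100, MR=0.08, SR=0.6, SP=1.2, stagnation=50
  modules extracted: 8 (positive weighted score: 8, above background: 6)

module      k       score  weighted  genesets
M1         25     3298.49     5.329       130
M2         39     1272.30     4.821        50
M3        109     2395.56     6.481        26
M4         35      766.47     4.206        32
M5         18      324.38     2.681        41
M6         62      532.39     4.413        36
M7         46      601.09     4.236        27
M8         17      193.36     2.106        57
```

Each row is one extracted module: `k` phenotypes, fitness score `S`,
weighted score `log((k/m)·S)` and the number of gene sets assigned by
the two-component Gaussian-mixture call on the module's gene-set scores.
The first extraction (M1) is the strongest planted module — the tall
25-phenotype block with 130 confidently assigned gene sets; the wide
planted module is recovered at iteration 3 with 109 of its 120
phenotypes. Scoring the run against the generator's ground truth:

```python
report = evaluate_against_truth(result.module_set, truth)
print(report.summary())
```

```
Recovery vs ground truth (macro-averaged)

metric        phenotypes   gene sets
sensitivity       0.8826      0.6255
specificity       0.9960      0.9835
precision         0.9689      0.8577
accuracy          0.9746      0.9064
```

Phenotypes are recovered with ~99.6% specificity and ~88% sensitivity;
gene-set sensitivity is lower by design — the planted gradients leave
many gene sets below the 50% association gate, where they are invisible
to an asymmetric score.

A command-line interface mirrors the library:

```sh
ibbig simulate --out sim --seed 1           # matrix.tsv + ground_truth.json
ibbig run sim/matrix.tsv --out run --n-modules 20 --seed 1
ibbig evaluate --modules run/modules.tsv --genesets run/genesets.tsv \
      --truth sim/ground_truth.json --matrix sim/matrix.tsv --out eval
ibbig discretize pvals.tsv --out matrix.tsv          # BH-FDR + P<0.05
```

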