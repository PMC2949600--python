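# gravfield

Global and multimodal optimization with the **gravitation field algorithm
(GFA)**, plus the application it was built for: K-means clustering of
gene-expression matrices with the K-means objective minimized globally by
GFA instead of Lloyd iterations.

GFA is a population method modelled on the solar nebular disk picture of
planetary formation. Candidate solutions ("dusts") carry a *mass* — the
objective value, sign-adjusted so larger is always better. Each epoch the
box domain is divided into groups; the best dust of a group becomes its
stationary *centre dust*; every other member moves straight toward the
centre by

    pace = M · dis,          M = 0.618/10 by default,

so each move contracts its distance to the centre by exactly (1 − M).
Centres are re-elected whenever a mover strictly beats the incumbent, and
once a group has contracted (or grown overcrowded) its surrounding dusts
are *absorbed*: deleted, leaving the centre to seed the next epoch. The
archive of absorbed-group survivors is what makes top-k multimodal search
possible — a single run can return the k best distinct local optima, which
single-trajectory methods and standard GA/SA cannot.

For a group of n dusts whose apparent maximum sits a distance `l_max` from
the nearest valley inside a region of extent `l_total`, the probability of
locking onto that pseudo peak is `(l_max/l_total)^(n−1)` — it vanishes as
groups grow, which is the engine of the global-convergence argument (see
`docs/methods.md`).

The package provides:

- `gravfield.gfa_core` — the engine: dust/group types, division, motion,
  absorption, `optimize`, `multi_minima`, and the pseudo-peak probability
  calculator with an empirical simulator.
- `gravfield.evaluation` — the sphere/Rosenbrock/Rastrigin/Griewank/Ackley
  benchmark suite, MSE/STD/mean-gauss-error metrics, a seeded comparison
  harness, and textbook GA/SA baselines.
- `gravfield.gene_cluster` — expression-matrix I/O (tab-delimited/PCL),
  missing-value handling, correlation distances, GFA-driven K-means,
  per-sample one-way ANOVA F tests, and Cluster-3.0/TreeView-style CDT
  output.
- `gravfield.synthetic_data` — planted-cluster expression matrices and
  sum-of-Gaussian-bump test functions with known optima.
- `gravfield.cli` — the `gfa` command with `optimize`, `multimin`,
  `benchmark`, `cluster` and `simulate` subcommands; every run writes a
  plain-text manifest for reproduction.

## Worked example

Minimize the 2-D sphere function on [−2, 2]²:

```sh
$ gfa optimize sphere --dim 2 --epochs 50 --seed 1
best_value      3.838110509e-08
epochs_used     29
converged       True
best_position   -4.506061463e-05        -0.000190658454
```

The run stopped after 29 epochs with the population collapsed onto the
global minimum at the origin; `best_value` is the objective at the best
point ever evaluated (here ~4e-8, against a true minimum of 0).

Find the five best distinct minima of the 2-D Rastrigin function on
[−1.5, 1.5]²:

```sh
$ gfa multimin rastrigin --profile table5-scaled --top 5 --seed 2
rank    value   position
1       0.0001827623235 -0.000393496,-0.000875432
2       0.9960591508    -5.21308e-05,-0.997313
3       0.9981276105    0.00328798,0.992686
4       1.007580407     -0.991633,0.00725071
5       2.008480597     0.999821,1.00332
```

Rank 1 is the global minimum at the origin (true value 0); ranks 2–4 are
the three local minima at (0, ±1) and (−1, 0), whose true value is 1; rank
5 is the depth-2 minimum at (1, 1). Distinct minima are recovered from the
absorption archive, merged within a radius and checked to be genuine local
optima.

Cluster a synthetic 20-cluster expression matrix and write TreeView-ready
output:

```sh
gfa simulate --genes 1000 --samples 16 --clusters 20 --effect 5 \
    --seed 4 --out expr.tsv
gfa cluster --input expr.tsv --k 20 --seed 1 --out-cdt expr.cdt
```

This writes `expr.cdt` (rows grouped by cluster), an assignments table and
a per-sample F-test report with Bonferroni-adjusted p-values alongside.

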