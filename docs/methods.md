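# Methods

## The gravitation field algorithm

`gravfield` implements a population-based global and multimodal optimizer
modelled on the solar nebular disk picture of planetary formation: candidate
solutions are *dusts*, the objective is a *mass function*, and search
proceeds by dusts assembling around locally dominant dusts until only the
"planets" — the optima — remain.

A run iterates *epochs*, each consisting of:

1. **Division.** The box domain is partitioned into *groups*. Two
   strategies are provided. *Average* division cuts the box into `m`
   equal-volume grid cells, factorizing `m` into per-dimension factors as
   close to `m^(1/D)` as possible (for `D = 2` this is the factor pair of
   `m` closest to `√m`; a prime `m` falls back to an `m × 1` slicing with a
   warning). *Power-weight* division (the default) elects up to `m`
   provisional centres greedily by mass, subject to a minimum pairwise
   separation, and allots each a region whose linear extent is proportional
   to its mass share, capped at the maximum power distance (5 length units
   per dimension by default). In one dimension these regions are a
   proportional partition of the interval; in higher dimensions they are
   axis-aligned boxes around the centres, with assignment by nearest centre
   so that the whole domain remains covered.
2. **Replenishment** (optional, on by default). Each group is refilled to
   `n` dusts by uniform sampling inside its region, survivors kept. Without
   replenishment the population shrinks monotonically, which follows the
   bare description of the dynamics but starves the late epochs; the
   refilled variant preserves the group-size condition the convergence
   argument needs.
3. **Motion.** For `s` rounds, every surrounding dust steps straight toward
   its group's centre by `pace = M · dis`, where `dis` is its current
   Euclidean distance — so each move contracts that distance by exactly
   `(1 − M)`. The pace weight defaults to the golden-section value
   `M = 0.618/10`. After each round masses are re-evaluated and a group's
   centre is re-elected whenever a mover strictly exceeds it (ties keep the
   incumbent; centres never move within an epoch, which is what makes the
   per-epoch best value monotone). Each moved coordinate is, with
   probability `jitter_rate` (default 0.02, the configured mutation rate),
   resampled uniformly over the domain. This per-coordinate uniform
   mutation is what lets the algorithm recombine coordinate-wise on
   separable multimodal objectives; a whole-position resample was tried and
   cannot fix a single bad coordinate of an otherwise good dust, which
   stalls 50-D Rastrigin around the best initial basin combination.
4. **Absorption.** A group whose surrounding dusts have all contracted to
   within `absorb_distance_eps` of the centre collapses early; a group
   holding more surrounding dusts than `crowd_threshold` collapses
   immediately (a running-time safeguard); at the end of the epoch every
   group collapses. Only centres survive, with their centre flag reset, and
   every absorbed-group survivor is archived for multimodal search.

Minimization is handled by maximizing `−f`; all reported values are on the
original scale. Positions outside the box are clipped before evaluation;
non-finite objective values mark a dust invalid (worst possible mass).

Convergence is declared when the survivors sit within the absorption
distance of each other *and* the best value has not improved for
`stall_epochs` consecutive epochs (default 25). The second clause matters
because a single surviving niche trivially satisfies the first one while
late-stage refinement is still in progress.

### Why this converges, and at what rate

The engine's refinement mechanism is the interplay of three scales:

- the *niche scale*: the minimum centre separation (default 5% of the
  domain diagonal) controls how many distinct basins stay alive; dusts
  within that distance of a better centre become movers toward it, which is
  how niches merge;
- the *region scale*: power-weight boxes have per-dimension extent of order
  `width/m`, which sets the resolution of replenishment sampling around
  each centre (the `g/m` factor keeps this scale fixed as niches merge —
  a literal share-of-width allocation would hand the last surviving group
  the whole domain back and destroy late refinement);
- the *contraction scale*: each move multiplies a mover's distance to its
  centre by `(1 − M)`, so within an epoch a group shrinks by `(1 − M)^s`.

For a group of `n` dusts whose apparent maximum sits a distance `l_max`
from the nearest valley inside a region of extent `l_total`, the
probability that the group locks onto that pseudo peak — i.e. that all
`n − 1` surrounding dusts land on its side of the valley — is

    p = (l_max / l_total)^(n−1),

which vanishes as the group size grows. `pseudo_peak_probability` computes
this, and `simulate_pseudo_peak_frequency` estimates it empirically by
placing surrounding dusts uniformly and counting the locking events; the
test-suite checks the two against each other inside 99% binomial intervals
for a constructed two-bump function whose valley is solved to sit exactly
halfway. The placement event is the operational content of the statement:
full motion dynamics with discrete paces can trap a dust that starts just
beyond the valley with a mass below the pseudo peak, an idealization gap
(the "smooth motion" assumption) that no continuous objective avoids, so
the check deliberately targets the probability model rather than the
integrator.

## Benchmarks and error metrics

The five standard box-constrained benchmarks are implemented in their
textbook forms (sphere, Rosenbrock, Rastrigin, Griewank, Ackley; all have
global minimum 0). Repeated minimization runs are scored by mean squared
error against the optimum, the sample standard deviation (n − 1
denominator), and the mean gauss error — the average of `erf(|error|)`,
which maps any error scale into [0, 1]. The per-run quantity fed to the
gauss error is the absolute deviation of the best-found value from the
optimum, the same quantity MSE squares; this keeps MGE within [0, 1] and
comparable across functions. A run counts as a *failure* when its best
value never comes within the success threshold (default `1e-2`, exposed)
of the optimum within the epoch budget.

The GA and SA baselines are deliberately plain textbook implementations —
real-coded GA with tournament selection, uniform crossover, per-gene
Gaussian mutation at rate 0.02, population 50, one elite; SA with Gaussian
proposals and geometric cooling from an initial temperature drawn in
(0, 5], started uniformly within a unit ball of the optimum (a generous
protocol, flagged as such). They are comparable in spirit, not numerically
identical, to commercial toolbox versions, and no claim of equality with
published GA/SA numbers is made.

## Replication profiles and problem sizes

Two headline experiments are packaged:

- **Single-optimum profile** (`table2`): 50 dimensions on [−2, 2] per
  dimension, 200 groups × 50 dusts (10,000 dusts), `s = 10`, up to 1,000
  epochs, 500 runs. The desk-scale profile used by the test-suite and
  `scripts/acceptance.py` keeps the protocol shape at 150 groups × 8 dusts
  (1,200 dusts), `s = 5`, 300 epochs, 20 runs. The group count is kept
  high rather than the group size because the power-weight region extent —
  and with it the late-stage refinement resolution and the acceptance rate
  of single-coordinate mutations on separable objectives — scales as
  `width/m`; convergence diagnostics on 50-D Rastrigin showed the
  coordinate-fix rate collapsing for coarse regions.
- **Multi-minima profile** (`table5`): per-function domains, iteration and
  dust budgets (e.g. Rosenbrock on [−2, 2] with 10,000 dusts in 200 groups
  for 1,000 iterations); dimensionality is not part of the published
  settings and defaults to `D = 2`. The desk-scale version uses
  1,000–2,000 dusts in 40–80 groups for 150–250 epochs.

Top-k multimodal search archives every absorbed-group survivor, greedily
merges archive entries closer than the merge radius (default 1% of the
domain diagonal, better value kept), and then discards entries that fail an
axis-aligned probe test at half the merge radius — stale early-epoch
survivors sit on slopes and would otherwise masquerade as optima. Probes
that clip back onto the candidate at a domain boundary are ignored, so
boundary minima survive the filter. If fewer than `k` distinct optima
remain the result is flagged incomplete, which is the expected outcome on a
unimodal objective.

## Gene-expression clustering

The application front end clusters a genes × samples matrix into `K`
groups (20 in the replication profile) by K-means whose objective — the
mean distance of each gene to its nearest centroid — is minimized by GFA. A
dust encodes a flattened `K × S` centroid matrix; its mass is the negative
mean nearest-centroid distance; the centroid domain box is the per-sample
data range. The distance defaults to the centred Pearson correlation
distance `1 − r` (the measure used by the Cluster 3.0 lineage; an
uncentred variant and Euclidean distance are options). The original
description of this analysis names an "SMBS correlation coefficient" whose
definition we could not resolve; centred Pearson is substituted, and this
substitution is deliberate and prominent.

Initial dusts are built from prior knowledge, as the initializer allows:
each is a k-means++ draw of actual gene profiles pushed to a fixed point of
the assign-and-average map. Good centroid sets are exactly such fixed
points, and straight-line motion between independently generated centroid
sets is uninformative (their cluster orderings are arbitrary permutations
of each other), so seeding at fixed points lets GFA do what it is good at —
the global choice among basins plus box-scale refinement — rather than
asking 320-dimensional line moves to rediscover local structure.
Independent restarts with derived seeds continue until a restart fails to
improve the best objective or the restart budget (default 1,000) is spent.

Genes are assigned to the nearest centroid at the end; an empty cluster is
re-seeded at the gene farthest from its centroid and assignment repeated
once, with a warning. Missing values are handled either by dropping any
gene row containing one (listwise; the replication setting) or by
pairwise-complete distances over jointly observed entries, dropping genes
with fewer than 3 observations. The result is evaluated by a per-sample
one-way ANOVA: for each sample column, expression values are grouped by
cluster and the F statistic and p-value are reported, without
multiple-testing correction (matching the claim the profile replicates) but
with a Bonferroni column emitted alongside for honesty.

Output is a Cluster-3.0/TreeView-style CDT table (GID / ORF / NAME /
CLUSTER / GWEIGHT / samples, EWEIGHT row, rows grouped by cluster, missing
cells empty, values at 6 significant digits), an assignments table and the
F-test report.

## Synthetic data

The planted-cluster generator emulates the shape of the yeast cell-cycle
compendium the application targets: `G` gene rows (default 7,663), 16
samples, 20 clusters. Cluster mean profiles are uniform random directions
on the unit sphere in sample space scaled by `effect × noise_sd`, genes
pick clusters uniformly (multinomial sizes, so small matrices can produce
empty clusters — deliberately, to exercise the re-seeding path), observed
values add Gaussian noise, and cells go missing independently at
`missing_rate` (default 1.4e-4, chosen so a 7,680 × 16 matrix carries ~17
affected rows in expectation, the count the preprocessing step reproduces);
alternatively exactly `missing_rows` rows receive a missing cell. What the
generator does *not* model: cell-cycle periodicity, gene-gene correlation
within clusters, intensity-dependent noise, or systematic (non-random)
missingness. Tests passing on these matrices therefore demonstrate the
pipeline's mechanics and its behaviour under the stated separation, not
performance on real compendia.

The multimodal-function generator builds sums of Gaussian bumps with known
peak positions and, in one dimension, locates inter-peak valleys by
root-finding on the analytic derivative; it warns when bumps sit closer
than two widths, where valley analysis becomes unreliable.

## Numerical choices and edge cases

- Ties in centre election go to the incumbent; among non-centres, to the
  lowest-index dust. All randomness flows from one seed per run; harnesses
  derive per-run seeds as `seed + run_index`.
- Grid cells are half-open `[lo, hi)` with the top-most cell closed, so
  boundary dusts belong to exactly one cell.
- Moves toward an in-box centre cannot leave the box; mutated coordinates
  are drawn inside the domain; positions are clipped defensively anyway.
- Mass shares for power-weight division use raw masses when all are
  positive (a mass-3 centre owns three times the extent of a mass-1
  centre) and are shifted otherwise so the worst centre keeps a positive
  share; equal masses give equal regions.
- `K = 1` clustering bypasses the optimizer: the grand centroid (column
  means over observed cells) with the mean distance to it.
- Zero-variance vectors get correlation distance 1 (uncorrelated
  convention), with a warning.

## Known limitations

- The convergence guarantee is a one-dimensional argument; in higher
  dimensions the pseudo-peak model is heuristic, and 50-D Rastrigin relies
  on the mutation channel rather than the contraction dynamics alone.
- Multi-minima rank assignment is by value within each run; published
  per-rank tables may instead match minima across runs by location, so
  only the best-rank summary is comparable.
- No gradient use, no parallel execution; single-process only.
- The GA/SA baselines are qualitative reference points, not reproductions
  of any particular toolbox.
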