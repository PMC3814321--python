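# Methods

## Labeling mechanism and model assumptions

The cassette is abstracted as an integer count *n* ≥ 1 of tandem loxP units
on one chromatid; the reporter is ON iff *n* = 1. Each division, given Cre
activity, at most one sister-chromatid crossover occurs, with probability
*c*; its pairing (*i*, *j*) is uniform over the *n*² cross-alignments of
units between the two sisters, and the two products — of sizes
*i* + *n* − *j* and *j* + *n* − *i*, conserving 2*n* — segregate to the
daughters at random. In-cis recombination is impossible by construction, so
*n* never decreases below 1 and never reaches 0; the 1-unit state is
absorbing and the label is permanent and heritable. Single-crossover and
uniform pairing are the minimal assumptions reproducing the 25% first-cycle
maximum; whether several crossovers can occur in one S/G2 at very high Cre
levels is unknown and not modeled. Everything biological that modulates
recombination efficiency — Cre level, locus accessibility, S/G2 duration —
is absorbed into the single effective parameter *c* (equivalently *p*
below), which is therefore an empirical, tissue-specific quantity.

Two variants are exposed and deliberately not collapsed:

* **exact** — the multiplicity Markov chain over states {1..n_max} with the
  marginal daughter pmf as transition law. After two divisions at *c* = 1 it
  yields 29/72 ≈ 40.3%, because triple-loxP intermediates re-activate at
  only *c*/9.
* **simplified** — each daughter of an unlabeled cell is labeled with fixed
  probability *p* per division: *f*(*k*) = 1 − (1 − *p*)^*k*. At *p* = 1/4
  this gives the 25%/43.75%→"44%" headline values. It is the default for
  stage predictions and the only model used for inference, because it is
  closed-form, invertible, and accepts fractional (effective) division
  numbers; the exact variant serves as a forward cross-check and brackets
  the simplified one from below.

## Parameters that matter

| parameter | meaning | default | rationale |
|---|---|---|---|
| *c* | crossover probability per division given Cre | 1.0 | maximal-labeling reference point |
| *p* (`p_simplified`) | per-daughter activation probability per division | 0.25 | exact first-cycle value at *c* = 1; an upper bound in vivo |
| `n_max` | truncation of the multiplicity chain | 32 | truncated mass < 1e−9 for *c* = 1, k ≤ 20; excess mass is lumped onto the last state (not renormalized) so rows stay stochastic |
| `doubling_time` | culture doubling time (h) | 17 (examples) | typical unsynchronized fibroblast value |
| `t_pulse` | BrdU pulse window (h) | 4 | standard i.p. pulse protocol |
| `t_cycle`, `t_s` | cell-cycle and S-phase lengths (h) | 16, 7 | typical murine lymphocyte kinetics; both are free inputs, not estimates |
| `rho` | intra-class correlation of mouse-level fractions | 0.02 | puts simulated SEMs in the few-percentage-point range seen across 3–7-mouse cohorts |

Per-stage division counts are *inputs*: the shipped B path (proB 2, preB 2,
matureB 0) and T path (DN3 0, DN4 2, DP 0, CD4SP 0, CD8SP +1) are
illustrative defaults that reproduce the qualitative orderings (no label
before the first Cre-active division; plateaus in non-dividing stages;
CD8-lineage excess over CD4), not measured values. A Cre onset falling
inside a stage is modeled as a fraction `missed_fraction` of that stage's
divisions completing before Cre is active (default 0.5 for the
between-stages driver).

## Simulation

`simulate_population` runs synchronous generations either with paired
daughters (crossover products kept together — correct joint law for
lineage-tree statistics) or by sampling each daughter independently from the
marginal pmf via multinomial count vectors. Marginal sampling is valid for
population-level fractions because daughters' fates are exchangeable; the
tests assert the two modes agree. Paired mode switches to count vectors
with a warning beyond a configurable census (default 2×10⁶ cells).

`simulate_culture` models unsynchronized growth with per-cell exponential
inter-division times of mean `doubling_time`/ln 2, so the census doubles
every `doubling_time` hours in expectation and effective generation numbers
are naturally fractional. Divisions completing before `cre_start` use
crossover probability 0. The population labeled fraction is monotone in
time in expectation; individual trajectories can dip transiently when
unlabeled cells divide, which is visible at small censuses.

Randomness: every simulator takes one seed for a `numpy` PCG64 generator;
identical seeds reproduce outputs byte-for-byte.

## Inference

With *p* assumed, k̂ = ln(1 − f̂)/ln(1 − *p*) from the pooled labeled
fraction f̂ (mice weighted by cell counts); with *k* assumed,
p̂ = 1 − (1 − f̂)^(1/k). A pooled fraction ≥ 0.999 raises a saturation
error instead of returning an unbounded k̂. Time-course data are fitted by
binomial maximum likelihood in *p* with *t*/`doubling_time` effective
generations and a profile-likelihood CI at the χ²(1) cutoff.

**Confidence intervals.** The resampling unit is the mouse whenever ≥ 2
mice exist (means ± errors in this field are mouse-level); a single
replicate falls back to an exact binomial interval over cells. Because
cohorts have only 3–7 mice, the percentile bootstrap undercovers badly (its
interval roughly spans the per-mouse extremes, ≈ 75–80% coverage at 3
mice). We therefore use the studentized bootstrap-t interval with
hierarchical resampling — resample mice with replacement, redraw each
resampled mouse's labeled count binomially, pivot on
(θ* − θ̂)/se* — the standard small-sample bootstrap construction. Measured
coverage under the default synthetic conditions (3 mice × 10⁴ cells,
p = 0.1, ρ = 0.02) is ≈ 97% at k = 1..6. The price is occasionally wide
intervals when the three mouse-level estimates happen to sit close together.

**Two-population comparison.** The statistic is |k̂_a − k̂_b|; mouse group
labels are permuted, exhaustively when the number of arrangements is at
most `n_perm` (then the p-value is exact, a multiple of 1/arrangements) and
by Monte Carlo with the (1 + exceedances)/(1 + draws) estimator otherwise.
A structural limitation: the statistic is symmetric under a group swap, so
with *m* mice per group the attainable p-value floor is
2/C(2m, m) — with 3v3 mice that is 2/20 = 0.1, and **no effect size can
reach α = 0.05**. At least 4 mice per group (floor 2/70 ≈ 0.029) are needed
to resolve α = 0.05; at that design the test rejects a k = 2 vs k = 6
contrast in ≈ 97% of replicates. Under the null the p-values are uniform to
within their discreteness (verified by Kolmogorov–Smirnov at a 6v6 design,
where the permutation distribution has adequate resolution). With fewer
than 2 mice in a group the test degrades to a cell-level Fisher exact test
with a warning; that fallback ignores mouse-to-mouse overdispersion. A
method-of-moments beta-binomial ICC is reported per group as a
overdispersion diagnostic.

## Synthetic data: what it emulates, and what it does not

`generate_cohort` draws per-mouse true fractions from a Beta distribution
with mean 1 − (1 − p)^k and ICC ρ (degenerate at ρ = 0), per-cell Bernoulli
labels and BrdU status (BrdU positivity =
`cycling_fraction × min(1, (t_s + t_pulse)/t_cycle)`), and two-channel
log-normal intensity mixtures whose components sit 6 log-sd apart by
default (midpoint-gate misclassification ≈ 0.13%). `gate_events` thresholds
at the mixture-log-mean midpoint, an explicit value, or Otsu's threshold on
log intensities, and reports the realized misclassification when ground
truth is present. Canned scenarios mirror the study designs: B path, T
path, a circulating-vs-tissue-resident contrast (k = 2 vs 6 at p = 0.1,
3 mice × 3000 cells), and a rate-versus-history discordance scenario
(mutant neonates cycle faster at equal history; mutant adults carry more
history while cycling less).

Not modeled: spectral spillover/compensation, doublets, viability, reporter
protein maturation or dilution, cell death and selection, cell-cycle phase
structure beyond the single per-division crossover probability, and
inter-homolog mitotic recombination (orders of magnitude rarer than
sister-chromatid exchange). Passing the end-to-end tests therefore shows
the statistical machinery is self-consistent under the stated generative
assumptions — not that real cytometry data meet them. In particular, gating
false positives put a floor of roughly `misclassification/p` on the
smallest detectable history, which is why a never-divided population reads
as k̂ ≈ 0.01 rather than exactly 0.

## Numerical choices and degenerate inputs

* Exact-variant cumulative fractions require integer k (matrix recursion);
  fractional effective generations are a simplified-variant concept.
* Probability computations preserve `fractions.Fraction` inputs exactly;
  floats otherwise.
* f̂ = 0 maps to k̂ = 0 (and p̂ = 0); f̂ ≥ 0.999 raises a saturation error.
* Bootstrap resamples with zero internal spread get a 1e−12 SE floor;
  an all-identical-mice cohort falls back to a percentile interval.
* Permutation ties are counted with a 1e−12 tolerance, always including the
  observed arrangement.
* Rounding to integer percentages happens only in reporting, never
  internally (43.75% is carried exactly and *prints* as 44%).
* Problem sizes in the test suite (10⁵-cell simulations, 500 recovery
  replicates per division count, 200 power and 500 null permutation
  replicates) were chosen so Monte Carlo error is well below every margin
  being asserted while the suite stays fast.

## Known limitations

* *k* and *p* are not jointly identifiable from a single fraction; one must
  be assumed. Estimates are "effective divisions," a lower bound on true
  proliferation whenever real labeling efficiency is below the assumed *p*.
* Increments between developmental stages may reflect differential
  survival/selection as well as division; the model attributes them
  entirely to division.
* The permutation test's resolution floor at small cohorts (above) is a
  property of the design, not the implementation; experiments needing
  α = 0.05 at mouse-level inference should plan ≥ 4 mice per group.
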