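# Methods

## The experimental system being modelled

A clonal *E. coli* culture grows in rich medium and is left for four days
before each transfer, so it traverses all five phases of the batch-culture
life cycle: lag, exponential growth, stationary phase, death phase (viable
counts fall by >99%) and long-term stationary phase (LTSP).  Each passage
dilutes the aged culture 1:1,000 into fresh medium; 30 passages are run in
parallel replicate populations and a sample is frozen after every third
passage.  Whole-population (pooled) sequencing of those samples turns the
genetics of the culture into per-site allele frequencies.

Three censuses govern allele dynamics in this design and are the only ones
the simulator represents explicitly:

| census | symbol | default | unit |
|---|---|---|---|
| peak (post-growth) | N_peak | 5×10⁹ × 12.5 | cells (CFU/ml × ml) |
| trough (post-death) | N_trough | 2×10⁷ × 12.5 | cells |
| bottleneck (transfer) | N_b | N_trough / 1,000 | cells |

Lag- and stationary-phase durations are not modelled: they do not move
allele frequencies in this design.  The bottleneck size is a parameter
derived from trough density and dilution factor (≈2.5×10⁵ cells at the
defaults) rather than a hard-coded constant, because the narrative census
("the lowest cell density") and the arithmetic one differ and the
arithmetic one is the conservative choice.

## Passage-cycle model

The population is a list of lineages, each a genotype (set of mutation
identifiers) with an abundance and two cached fitness multipliers.  One
passage cycle is three steps:

1. **Growth.**  The realized fold expansion F = N_peak / N_start defines
   the number of doublings g = log₂F.  Lineage abundances are apportioned
   by a multinomial draw with weights `x_i (1+s_growth,i)^g`, i.e. a single
   weighted expansion conditional on the total — not per-generation
   Wright–Fisher steps — which keeps 10¹⁰-cell cultures tractable through
   lineage abundances.  New mutations are Poisson with mean
   `births × G × μ`; each founds a new single-cell lineage at a uniformly
   random position (an infinite-sites flag resamples occupied positions;
   by default recurrent mutation at an occupied site simply yields a new
   identifier, and identifiers sharing one (position, ref, alt) are
   aggregated when frequencies are reported, so multi-allelic sites arise
   naturally).
2. **Death phase.**  Abundances contract to N_trough by a multinomial draw
   weighted by `x_i (1+s_death,i)` — the LTSP-survival component of
   fitness, applied once per death phase.
3. **Bottleneck.**  A multinomial sample of N_total/dilution cells founds
   the next culture.  An empty sample halts that population with an
   explicit extinction flag.

Fitness is deliberately two-component because the phenotype of interest is
regime-dependent: a mutant can hold a strong advantage under 4-day
(death-phase-inclusive) passaging and a disadvantage under daily passaging.
Setting `s_growth < 0 < s_death` reproduces exactly that reversal, and
`simulate_competition(include_death_phase=False)` emulates the daily
scheme by passaging from peak density.

**Deterministic mode** replaces every draw by its expectation.  Two-lineage
competition then obeys the logistic recursion
`logit(p') = logit(p) + g ln(1+s)` exactly; the test suite verifies
agreement to better than 1e-9 relative error at every passage, and the
stochastic mode is checked against the neutral martingale property (mean
frequency conserved across ≥200 replicates, 3-standard-error band).

**Generation accounting.**  Whether "generations per passage" counts only
regrowth doublings or also the turnover implied by death-phase contraction
is a matter of convention; the census log reports both
(`g_regrowth = log₂(N_peak/N_start)` and
`g_with_death_turnover = g_regrowth + log₂(N_peak/N_trough)`).

**Randomness.**  One integer seed per run; population *i* uses an
independent substream at `seed + i × 1_000_003`.  Identical (seed, params,
scheme) give byte-identical trajectory tables.

## Desk-scale problem sizes

At the default parameters the growth phase supplies
`6.25×10¹⁰ × 4.6×10⁶ × 10⁻¹⁰ ≈ 2.9×10⁷` new lineages per passage —
faithful, but not trackable object-by-object.  Simulation-based tests and
the acceptance script therefore track a **4.6 kb genomic window at full
census sizes** (`genome_length = 4_600`, everything else at its default):
per-window mutation supply (~2.9×10⁴ per passage), drift, selection and
bottleneck dynamics are then exact for that window, and a 30-passage
population runs in a few seconds.  The registry of mutations is pruned to
standing diversity after each death phase and bottleneck (extinct
identifiers can never recur, since identifiers are monotonic).

## Synthetic sequencing layer

Each segregating site (plus a configurable number of invariant sites)
receives a Poisson(depth_mean ≈ 300) column depth.  Each read samples a
template cell from the site's true allele mix, miscalls to one of the
three other bases with probability e (symmetric, e/3 each; default
e = 0.001, a round value in the part-per-thousand range typical of
Illumina short reads after quality filtering), and lands on either strand
with probability 1/2.  The layer emulates pooled sequencing *after*
alignment-level quality control; it does not model alignment artifacts,
strand-specific error, indels, or coverage waves along the genome — so
passing end-to-end tests demonstrate correctness of the calling and
classification machinery under the stated read model, not robustness to
real-world alignment pathology.

## The strand-balanced caller

A site's alternate allele is called iff ≥`min_reads_per_strand` (default
3) supporting reads appear on each strand.  Read-level filters keep only
unique mappings with mapping quality strictly greater than 30 and mismatch
fraction strictly below 5% — strict bounds, matching the rule's wording;
when the input is an aggregated pileup those filters are assumed applied
upstream.  Frequency is alt reads over the full filtered column depth
(all A/C/G/T observations; N and ambiguous symbols are excluded from both
numerator and denominator).  No quality score is attached: the rule is a
hard threshold, and VCF QUAL is written as missing.

Detection power at true frequency f, depth D and error rate e follows a
two-stage binomial model — alt-read count A ~ Binomial(D, f′) with
f′ = f(1−e) + (1−f)e/3, forward share Binomial(A, ½) — summed exactly and
cross-checked against a ≥10⁵-replicate Monte-Carlo twin.  A Poisson-depth
variant integrates over depth.  The minimum detectable frequency is found
by bisection (power is monotone in f because e < 0.25 keeps f′ increasing
in f) to a 1e-4 tolerance; NaN marks "not achievable" (in particular any
depth < 2×min_per_strand, where the rule cannot fire).  At 300× the 50%-power
threshold computes to ≈2.4%, and the power to see a 1% allele is ≈0.04 —
the pipeline reports these numbers rather than asserting a nominal
sensitivity; a "~1%" detection claim at ~300× is only consistent with the
six-read rule if the effective depth is higher or a weaker power criterion
is meant.

## Trajectory classification

Thresholds (all configurable): *low* means max frequency ≤ 0.30 — "above
30%" is strict, so exactly 0.30 is still low; *fixed* means max ≥ 0.995,
which prints as 1.00 at two decimals; *singleton* means exactly one
sampled time point with nonzero frequency (presence floor 0, i.e. any
passing call counts — the caller's own detection limit is the de facto
floor); intermediate and high split the remainder at 0.5, with a max of
exactly 0.5 classed intermediate.  Percentages are rounded half-up to one
decimal to match printed style.

Counting convention: headline percentages (singleton / never-above-30% /
shared) are computed over **unique (position, ref, alt) alleles**, so all
three share one denominator; per-population trajectory rows are counted
alongside (a shared allele contributes one row per population — sharing is
a relation between trajectories, never a merge).  Sharing requires exact
allele identity; the same gene hit by *different* alleles in ≥2 populations
is parallel evolution and is reported per gene, ranked by population count
then allele count.  Gene labels come from a user-supplied interval map
(1-based, inclusive); unannotated positions get the placeholder "NC",
which is excluded from gene-level parallelism.

Read data cannot phase alleles, so no haplotype reconstruction is
attempted; the only joint statement made is the pigeonhole bound
`max(0, Σfᵢ − (k−1))` on cells carrying all k alleles, which the tests
verify against exhaustive enumeration over small discrete populations
(it is tight whenever it is positive).

## Phenotype analytics

* `cfu_per_ml = colonies × 10^k × (1000 / spot_volume_µl)` for a 10-µl
  spot of the 10⁻ᵏ dilution.  The volume correction is on by default (a
  convention flag restores the bare dilution-factor reading); zero
  colonies return the one-colony density as a below-detection bound,
  never zero.
* Dip metrics: replicates are geometric-mean averaged (densities are
  log-normal-ish and plotted on log scales) *before* detection — the
  documented order; peak = global max (earliest on ties), trough = global
  min strictly after the peak (earliest on ties), exit = first post-trough
  day strictly above the trough.  Monotone or flat curves return an
  explicit no-dip marker rather than an exception.
* Strain comparisons use Student's equal-variance t test on log₁₀
  densities (Welch and paired variants by flag), day by day against a
  fixed threshold (default P ≤ 0.025) with no multiple-testing correction
  across days — a documented property of the design, not an oversight.
  All statistics function at n = 2 replicates; zero-variance degenerate
  cases are handled explicitly (equal means → t = 0, p = 1) with a
  warning.
* Competition series are summarized as log₁₀(strain1/strain2) per
  replicate and passage; a below-detection denominator right-censors the
  ratio (direction flagged, value kept as a bound).  The selection
  coefficient is the least-squares slope of the natural-log ratio against
  cumulative generations; on the simulator's per-doubling scale that slope
  equals ln(1+s), so the estimate reports both `slope_per_generation` and
  `growth_advantage = exp(slope) − 1`, and parameter-recovery tests
  against deterministic simulation agree to 1e-6.

## Numerical and design notes

* Multinomial apportionment conditions each phase on its target census, so
  within-step totals are conserved exactly (up to integer rounding) and
  abundances are never negative.
* Bisection tolerance 1e-4 on frequencies; power clipped to [0, 1] against
  floating-point summation drift.
* The reporting floor for true trajectories is 0.1% (configurable) —
  deliberately below the caller's ≈1–2.4% operating range so that caller
  sensitivity is itself testable against ground truth.
* The reference genome is a single circular chromosome with a
  deterministic position→base map; only point mutations are modelled (no
  indels or structural variants), and the mpileup ingestion path ignores
  base qualities since filtering is on mapping quality.
* Known limitations: no spatial structure, cross-feeding or explicit
  stress chemistry; no per-generation Wright–Fisher mode enabled by
  default (the single weighted expansion is the supported configuration);
  no clonal-interference phasing beyond the cosegregation bound; the
  sequencing layer's error channel is symmetric and strand-neutral.
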