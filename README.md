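# ltsp — long-term serial-passage evolution analytics

`ltsp` is a Python toolkit for experimental-evolution studies in which
bacterial batch cultures are allowed to age through all five phases of the
laboratory life cycle — lag, log, stationary, death phase and long-term
stationary phase (LTSP) — before each serial passage, and whole populations
(not single clones) are sequenced to follow allele frequencies over time.

It is written for microbial-evolution researchers who need to:

* **simulate** the experiment: growth to a peak density N_peak (~5×10⁹
  CFU/ml in 12.5 ml of rich medium), death-phase contraction to a trough
  N_trough (~2×10⁷ CFU/ml), and a 1:1,000 transfer bottleneck, repeated for
  30 passages with samples saved every third passage.  Mutation supply per
  growth phase is `births × G × μ` (genome length G = 4.6×10⁶ bp, basal
  rate μ ≈ 10⁻¹⁰ per bp replicated), and per-mutation fitness is
  decomposed into a growth component and an LTSP-survival component, so a
  mutant can win 4-day passages yet lose daily ones;
* **call variants** from pooled sequencing with a strand-balanced threshold
  rule: an alternate allele is called iff it is supported by ≥3 reads on
  *each* of the forward and reverse strands (≥6 total), with multi-allelic
  sites allowed and frequency = alt reads / total column depth.  Exact and
  Monte-Carlo detection-power calculators quantify what that rule can see
  at a given depth;
* **classify allele trajectories** across sampled passages: singletons
  (one time point), alleles never above 30%, fixed alleles (≥99.5%),
  alleles shared between populations, genes hit in parallel by distinct
  mutations, and the pigeonhole cosegregation bound
  `max(0, Σfᵢ − (k−1))` on joint carriage of k majority alleles;
* **analyze phenotypes**: CFU/ml from dilution-spot plating, the
  death-phase "dip" (peak/trough/recovery folds) of multi-day growth
  curves, per-day Student t tests on log₁₀ densities, competition
  log-ratios with censoring, and selection coefficients as the
  least-squares slope of ln(mutant/wild-type) per generation.

## Worked example

```python
import numpy as np
from ltsp import *

# detection limit of the strand rule at typical pooled depths
for depth in (100, 300, 1000):
    mdf = min_detectable_frequency(depth, power_target=0.5)
    print(f"depth {depth:>5}: min detectable frequency (50% power) = {100*mdf:.2f}%")
print(f"power to detect a 1% allele at 300x: {detection_power_exact(0.01, 300):.3f}")

# seed a beneficial mutation, passage 30 times, sequence, call
params = SimulationParams(genome_length=4_600)   # 4.6 kb window, full census
state = founder_state(params)
state, mut = seed_mutant_lineage(state, 1e-4 * state.total(), growth_s=0.15)
rng = np.random.default_rng(1)
for _ in range(30):
    state = simulate_passage_cycle(state, params, rng)
true = allele_frequencies(state)[mut.allele_key]
cols = simulate_pileup(state, depth_mean=300, error_rate=0.001, rng=rng,
                       genome_length=params.genome_length)
calls = call_pileup(cols, population_id="A", passage=30)
hit = [c for c in calls
       if (c.position, c.ref_allele, c.alt_allele) == mut.allele_key][0]
print(f"seeded allele at position {mut.position}: true freq {true:.3f}, "
      f"called {hit.frequency:.3f} "
      f"({hit.alt_forward}+/{hit.alt_reverse}- of {hit.depth} reads)")
```

prints

```
depth   100: min detectable frequency (50% power) = 7.29%
depth   300: min detectable frequency (50% power) = 2.44%
power to detect a 1% allele at 300x: 0.036
seeded allele at position 1: true freq 1.000, called 0.997 (142+/165- of 308 reads)
```

The first lines make the rule's sensitivity concrete: at 300× a variant
needs roughly 2.4% population frequency before the 3-per-strand rule fires
half the time (the nominal "~1%" threshold corresponds to the regime where
expected support approaches the six-read minimum).  The last line shows a
strongly beneficial mutation (s = 0.15 per doubling) sweeping to fixation
within 30 passages and being recovered by the pooled caller with a
frequency estimate inside binomial sampling error.

## Command-line interface

The `ltsp` command exposes the same pipeline from a shell:

```bash
ltsp simulate --seed 1 --out-dir run1          # true trajectories + pileups
ltsp call --pileup run1/strand_pileup_A_P30.tsv --population A --passage 30
ltsp trajectories --calls ltsp-out/calls.csv
ltsp phenotype --growth growth.csv --competition competition.csv
ltsp power --depth 300 --target 0.5
```

Every subcommand accepts `--config` (sectioned key = value file, see
`ltsp.formats.write_config` for a template), `--seed`, `--out-dir` and
`--log-level`, and writes a `provenance.json` with the effective
configuration; identical seeds give byte-identical outputs.

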