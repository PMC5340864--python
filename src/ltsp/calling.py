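"""Pooled-population SNP calling with a strand-balanced support rule.

When whole populations (rather than single clones) are sequenced, variants
appear as allele frequencies in a pileup of reads.  The caller here is a
deterministic threshold rule: an alternate allele is called at a site when it
is supported by at least ``min_reads_per_strand`` reads on *each* of the
forward and reverse strands (default 3, i.e. at least six reads in total).
Multiple alternate alleles may be called at the same site, since each may
represent a different lineage in the population.  The reported frequency of a
call is the number of reads carrying the allele divided by the total read
depth of the column.

Read-level quality control keeps only uniquely mapping reads with mapping
quality strictly greater than 30 and a mismatch fraction strictly below 5%.
Aggregated pileups (where per-read metadata is gone) are assumed to have had
these filters applied upstream at alignment time.

The module also quantifies the caller's sensitivity: for a true population
frequency f, sequencing-error rate e and column depth D, each read carries
the alternate base with probability ``f' = f(1-e) + (1-f)e/3`` and lands on
either strand with probability 1/2, so detection power is
``P(alt_fwd >= m and alt_rev >= m)`` under that two-stage binomial model.
Both an exact summation and a Monte-Carlo twin are provided, together with a
bisection solver for the minimum detectable frequency at a target power.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")
FORWARD = "forward"
REVERSE = "reverse"

#: Sentinel returned by :func:`min_detectable_frequency` when no frequency,
#: not even f = 1, reaches the requested power (e.g. depth < 2m).
NOT_ACHIEVABLE = math.nan


@dataclass(frozen=True)
class CallerConfig:
    """Thresholds of the strand-balanced calling rule and read filters.

    ``min_mapping_quality`` and ``max_mismatch_fraction`` are strict bounds:
    a read is kept only if its mapping quality is *greater than* 30 and its
    mismatch fraction is *less than* 0.05.
    """

    min_reads_per_strand: int = 3
    min_mapping_quality: int = 30
    max_mismatch_fraction: float = 0.05
    require_unique_mapping: bool = True

    def __post_init__(self) -> None:
        if self.min_reads_per_strand < 1:
            raise ValueError("min_reads_per_strand must be >= 1")
        if self.min_mapping_quality < 0:
            raise ValueError("min_mapping_quality must be >= 0")
        if not 0.0 <= self.max_mismatch_fraction <= 1.0:
            raise ValueError("max_mismatch_fraction must be in [0, 1]")


DEFAULT_CALLER_CONFIG = CallerConfig()


@dataclass(frozen=True)
class ReadRecord:
    """A single aligned read observation at one reference position."""

    position: int
    allele: str
    strand: str
    mapping_quality: int
    mismatch_fraction: float
    is_unique_mapping: bool = True

    def __post_init__(self) -> None:
        if self.strand not in (FORWARD, REVERSE):
            raise ValueError(f"strand must be {FORWARD!r} or {REVERSE!r}")
        if self.mapping_quality < 0:
            raise ValueError("mapping_quality must be >= 0")
        if not 0.0 <= self.mismatch_fraction <= 1.0:
            raise ValueError("mismatch_fraction must be in [0, 1]")


def apply_read_filters(
    reads: Iterable[ReadRecord], config: CallerConfig = DEFAULT_CALLER_CONFIG
) -> list[ReadRecord]:
    """Keep reads passing the alignment-quality filters (strict bounds)."""
    kept = []
    for read in reads:
        if config.require_unique_mapping and not read.is_unique_mapping:
            continue
        if not read.mapping_quality > config.min_mapping_quality:
            continue
        if not read.mismatch_fraction < config.max_mismatch_fraction:
            continue
        kept.append(read)
    return kept


@dataclass
class StrandPileupColumn:
    """Per-site, per-allele forward/reverse read counts.

    ``counts`` maps an observed base to its ``(forward, reverse)`` read
    counts.  Depth counts A/C/G/T observations only; N and other ambiguous
    symbols are excluded from both numerator and denominator.
    """

    position: int
    ref_allele: str
    counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    chrom: str | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position is 1-based; must be >= 1")
        for allele, (fwd, rev) in self.counts.items():
            if fwd < 0 or rev < 0:
                raise ValueError(f"negative count for allele {allele!r}")

    @property
    def depth(self) -> int:
        return sum(
            f + r for a, (f, r) in self.counts.items() if a in VALID_BASES
        )

    def allele_depth(self, allele: str) -> int:
        fwd, rev = self.counts.get(allele, (0, 0))
        return fwd + rev

    @classmethod
    def from_reads(
        cls, position: int, ref_allele: str, reads: Iterable[ReadRecord],
        chrom: str | None = None,
    ) -> "StrandPileupColumn":
        """Tally filtered reads at one position into strand counts."""
        counts: dict[str, list[int]] = {}
        for read in reads:
            if read.position != position:
                continue
            pair = counts.setdefault(read.allele, [0, 0])
            pair[0 if read.strand == FORWARD else 1] += 1
        return cls(
            position=position,
            ref_allele=ref_allele,
            counts={a: (f, r) for a, (f, r) in counts.items()},
            chrom=chrom,
        )


@dataclass(frozen=True)
class VariantCall:
    """One alternate allele passing the strand-balanced rule at one site."""

    position: int
    ref_allele: str
    alt_allele: str
    frequency: float
    alt_forward: int
    alt_reverse: int
    depth: int
    population_id: str | None = None
    passage: int | None = None


@dataclass
class VariantCallSet:
    """Calls from one (population, passage) sequencing sample."""

    calls: list[VariantCall] = field(default_factory=list)
    population_id: str | None = None
    passage: int | None = None

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self) -> Iterator[VariantCall]:
        return iter(self.calls)

    _COLUMNS = [
        "population", "passage", "position", "ref", "alt",
        "frequency", "alt_forward", "alt_reverse", "depth",
    ]

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "population": c.population_id,
                "passage": c.passage,
                "position": c.position,
                "ref": c.ref_allele,
                "alt": c.alt_allele,
                "frequency": c.frequency,
                "alt_forward": c.alt_forward,
                "alt_reverse": c.alt_reverse,
                "depth": c.depth,
            }
            for c in self.calls
        ]
        return pd.DataFrame(rows, columns=self._COLUMNS)


def call_site(
    column: StrandPileupColumn,
    config: CallerConfig = DEFAULT_CALLER_CONFIG,
    population_id: str | None = None,
    passage: int | None = None,
) -> list[VariantCall]:
    """Apply the strand-balanced rule to one pileup column.

    Returns one :class:`VariantCall` per non-reference A/C/G/T allele with at
    least ``min_reads_per_strand`` supporting reads on each strand.  The
    reference allele is never called.  Zero-depth columns are skipped with a
    log notice.
    """
    depth = column.depth
    if depth == 0:
        logger.info("position %d: zero-depth column skipped", column.position)
        return []
    m = config.min_reads_per_strand
    calls = []
    for allele in sorted(column.counts):
        if allele == column.ref_allele or allele not in VALID_BASES:
            continue
        fwd, rev = column.counts[allele]
        if fwd >= m and rev >= m:
            calls.append(
                VariantCall(
                    position=column.position,
                    ref_allele=column.ref_allele,
                    alt_allele=allele,
                    frequency=(fwd + rev) / depth,
                    alt_forward=fwd,
                    alt_reverse=rev,
                    depth=depth,
                    population_id=population_id,
                    passage=passage,
                )
            )
    return calls


def call_pileup(
    columns: Iterable[StrandPileupColumn],
    config: CallerConfig = DEFAULT_CALLER_CONFIG,
    population_id: str | None = None,
    passage: int | None = None,
) -> VariantCallSet:
    """Call every column of a pileup; columns are processed in position order."""
    cols = list(columns)
    positions = [c.position for c in cols]
    if positions != sorted(positions):
        logger.warning("pileup columns not sorted by position; sorting")
        cols.sort(key=lambda c: c.position)
    calls: list[VariantCall] = []
    for col in cols:
        calls.extend(call_site(col, config, population_id, passage))
    return VariantCallSet(calls=calls, population_id=population_id, passage=passage)


def effective_alt_probability(true_freq: float, error_rate: float) -> float:
    """Per-read probability of observing the alternate base.

    A read sampled from a cell carrying the alternate allele reports it with
    probability 1-e; a read from a reference cell reports it as one of the
    three possible miscalls with probability e/3.
    """
    return true_freq * (1.0 - error_rate) + (1.0 - true_freq) * error_rate / 3.0


def _validate_power_args(true_freq: float, depth: int, error_rate: float) -> None:
    if not 0.0 <= true_freq <= 1.0:
        raise ValueError("true_freq must be in [0, 1]")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if not 0.0 <= error_rate < 0.25:
        raise ValueError("error_rate must be in [0, 0.25)")


def detection_power_exact(
    true_freq: float,
    depth: int,
    error_rate: float = 0.0,
    config: CallerConfig = DEFAULT_CALLER_CONFIG,
) -> float:
    """Exact probability that the strand rule fires, at fixed column depth.

    The number of alternate reads A is Binomial(depth, f'); given A, the
    forward-strand share is Binomial(A, 1/2).  Power is the sum over
    A >= 2m of ``P(A) * P(m <= alt_fwd <= A - m)``.
    """
    _validate_power_args(true_freq, depth, error_rate)
    m = config.min_reads_per_strand
    if depth < 2 * m:
        return 0.0
    p = effective_alt_probability(true_freq, error_rate)
    if p == 0.0:
        return 0.0
    a = np.arange(2 * m, depth + 1)
    pmf = stats.binom.pmf(a, depth, p)
    inner = stats.binom.cdf(a - m, a, 0.5) - stats.binom.cdf(m - 1, a, 0.5)
    power = float(np.sum(pmf * np.clip(inner, 0.0, 1.0)))
    return min(max(power, 0.0), 1.0)


def detection_power_mc(
    true_freq: float,
    depth: int,
    error_rate: float = 0.0,
    config: CallerConfig = DEFAULT_CALLER_CONFIG,
    n_reps: int = 100_000,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Monte-Carlo twin of :func:`detection_power_exact` (simulation oracle)."""
    _validate_power_args(true_freq, depth, error_rate)
    rng = np.random.default_rng(rng)
    m = config.min_reads_per_strand
    p = effective_alt_probability(true_freq, error_rate)
    alt = rng.binomial(depth, p, size=n_reps)
    fwd = rng.binomial(alt, 0.5)
    return float(np.mean((fwd >= m) & (alt - fwd >= m)))


def detection_power_poisson_depth(
    true_freq: float,
    depth_mean: float,
    error_rate: float = 0.0,
    config: CallerConfig = DEFAULT_CALLER_CONFIG,
    tail_mass: float = 1e-10,
) -> float:
    """Detection power with column depth integrated over Poisson(depth_mean)."""
    if depth_mean <= 0:
        raise ValueError("depth_mean must be > 0")
    d_max = int(stats.poisson.ppf(1.0 - tail_mass, depth_mean))
    depths = np.arange(0, d_max + 1)
    weights = stats.poisson.pmf(depths, depth_mean)
    total = 0.0
    for d, w in zip(depths, weights):
        if w == 0.0:
            continue
        total += w * detection_power_exact(true_freq, int(d), error_rate, config)
    return min(max(total, 0.0), 1.0)


def min_detectable_frequency(
    depth: int,
    power_target: float = 0.5,
    error_rate: float = 0.0,
    config: CallerConfig = DEFAULT_CALLER_CONFIG,
    tol: float = 1e-4,
) -> float:
    """Smallest true frequency detected with at least ``power_target`` power.

    Solved by bisection (power is non-decreasing in frequency).  Returns
    :data:`NOT_ACHIEVABLE` (NaN) when even f = 1 fails the target — in
    particular whenever depth < 2 * min_reads_per_strand, where the rule is
    unsatisfiable.
    """
    if not 0.0 < power_target < 1.0:
        raise ValueError("power_target must be in (0, 1)")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    m = config.min_reads_per_strand
    if depth < 2 * m:
        return NOT_ACHIEVABLE
    if detection_power_exact(1.0, depth, error_rate, config) < power_target:
        return NOT_ACHIEVABLE
    lo, hi = 0.0, 1.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if detection_power_exact(mid, depth, error_rate, config) >= power_target:
            hi = mid
        else:
            lo = mid
    return hi
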