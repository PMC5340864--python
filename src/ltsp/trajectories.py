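"""Allele-frequency trajectory assembly, classification and summaries.

A trajectory is one variant's frequency across the sampled passages of one
population.  Trajectories are keyed per population even when the same
allele appears in several populations — sharing is a relation between
trajectories, not a merge.

Classification thresholds follow the experiment's reporting conventions:
"low" means the allele never rises above 30% (a max of exactly 0.30 is
low — "above 30%" is strict), "fixed" means the maximum frequency reaches
at least 0.995 (which prints as 1.00 at two decimals), and a "singleton"
was detected at exactly one sampled time point.  Intermediate and high
split the remainder at a configurable boundary (default 0.5).

Headline summary counts are computed at the *unique-allele* level — a
distinct (position, ref, alt) — so that the singleton, never-above-30% and
shared percentages all share one denominator; the number of per-population
trajectory rows is reported alongside.

Two or more alleles simultaneously above 50% in one sample must co-occur in
at least some cells even though read data cannot phase them; the pigeonhole
bound ``max(0, sum(f) - (k - 1))`` quantifies the minimum fraction of cells
carrying all k alleles jointly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .calling import VariantCallSet

logger = logging.getLogger(__name__)

KEY_COLUMNS = ["population", "position", "ref", "alt"]
META_COLUMNS = KEY_COLUMNS + ["gene"]
ALLELE_KEY = ["position", "ref", "alt"]

#: Gene label used for positions outside any annotated interval.
NONCODING_LABEL = "NC"


@dataclass(frozen=True)
class ClassThresholds:
    """Frequency thresholds for trajectory classification."""

    low_max: float = 0.30
    fixed_min: float = 0.995
    presence_floor: float = 0.0
    cosegregation_min: float = 0.50
    high_boundary: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.low_max < self.fixed_min <= 1.0:
            raise ValueError("require 0 < low_max < fixed_min <= 1")
        if not self.low_max <= self.high_boundary < self.fixed_min:
            raise ValueError("high_boundary must lie in [low_max, fixed_min)")
        if self.presence_floor < 0:
            raise ValueError("presence_floor must be >= 0")


DEFAULT_THRESHOLDS = ClassThresholds()


def round_percent(count: float, total: float, ndigits: int = 1) -> float:
    """Percentage rounded half-up (matching printed one-decimal style)."""
    if total == 0:
        return 0.0
    quantum = Decimal(1).scaleb(-ndigits)
    return float(
        Decimal(repr(100.0 * count / total)).quantize(quantum, rounding=ROUND_HALF_UP)
    )


def passage_columns(table: pd.DataFrame) -> list[int]:
    """The sampled-passage axis of a wide trajectory table."""
    return sorted(int(c) for c in table.columns if isinstance(c, (int, np.integer)))


def build_trajectories(
    callsets: Mapping[tuple[str, int], VariantCallSet] | Iterable[VariantCallSet],
    sampled_passages: Sequence[int],
) -> pd.DataFrame:
    """Assemble per-passage call sets into a wide trajectory table.

    One row per distinct (population, position, ref, alt) with frequency 0
    at sampled passages where the allele was not called.  Conflicting
    reference alleles at one position are a format error.
    """
    if isinstance(callsets, Mapping):
        items = []
        for (pop, passage), cs in callsets.items():
            items.append((pop, passage, cs))
    else:
        items = []
        for cs in callsets:
            if cs.population_id is None or cs.passage is None:
                raise ValueError(
                    "callsets without (population, passage) metadata must be "
                    "supplied as a mapping keyed by (population, passage)"
                )
            items.append((cs.population_id, cs.passage, cs))
    sampled = sorted(int(p) for p in sampled_passages)
    sampled_set = set(sampled)
    ref_at: dict[int, str] = {}
    freqs: dict[tuple[str, int, str, str], dict[int, float]] = {}
    for pop, passage, cs in items:
        if passage not in sampled_set:
            raise ValueError(
                f"callset passage {passage} not among sampled passages {sampled}"
            )
        for call in cs:
            known = ref_at.setdefault(call.position, call.ref_allele)
            if known != call.ref_allele:
                raise ValueError(
                    f"conflicting reference alleles at position {call.position}: "
                    f"{known!r} vs {call.ref_allele!r}"
                )
            key = (pop, call.position, call.ref_allele, call.alt_allele)
            freqs.setdefault(key, {})[passage] = call.frequency
    rows = []
    for (pop, position, ref, alt), by_passage in freqs.items():
        row = {"population": pop, "position": position, "ref": ref, "alt": alt,
               "gene": None}
        for p in sampled:
            row[p] = by_passage.get(p, 0.0)
        rows.append(row)
    table = pd.DataFrame(rows, columns=META_COLUMNS + sampled)
    return table.sort_values(["population", "position", "alt"]).reset_index(drop=True)


def classify_trajectory(
    frequencies: Mapping[int, float] | Sequence[float],
    thresholds: ClassThresholds = DEFAULT_THRESHOLDS,
) -> set[str]:
    """Label one trajectory: singleton? and its magnitude class.

    Returns a subset of {"singleton", "low", "intermediate", "high",
    "fixed"}; "singleton" co-exists with the magnitude label.  An all-zero
    trajectory is a validation error (it should never have been built).
    """
    if isinstance(frequencies, Mapping):
        values = np.asarray(list(frequencies.values()), dtype=float)
    else:
        values = np.asarray(list(frequencies), dtype=float)
    if values.size == 0:
        raise ValueError("empty frequency axis")
    if np.any((values < 0) | (values > 1)):
        raise ValueError("frequencies must be in [0, 1]")
    present = values > thresholds.presence_floor
    if not present.any():
        raise ValueError("all-zero trajectory cannot be classified")
    labels: set[str] = set()
    if int(present.sum()) == 1:
        labels.add("singleton")
    peak = float(values.max())
    if peak <= thresholds.low_max:
        labels.add("low")
    elif peak >= thresholds.fixed_min:
        labels.add("fixed")
    elif peak <= thresholds.high_boundary:
        labels.add("intermediate")
    else:
        labels.add("high")
    return labels


def _allele_groups(table: pd.DataFrame) -> pd.core.groupby.DataFrameGroupBy:
    return table.groupby(ALLELE_KEY, sort=True)


@dataclass
class TrajectorySummary:
    """Headline counts of a trajectory table.

    ``n_total`` counts unique (position, ref, alt) alleles — the shared
    denominator of the singleton / never-above-30% / shared percentages;
    ``n_trajectories`` counts per-population rows.
    """

    n_total: int
    n_trajectories: int
    n_singleton: int
    pct_singleton: float
    n_low: int
    pct_low: float
    n_fixed: int
    n_shared: int
    pct_shared: float
    per_population: dict[str, dict[str, int]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_trajectories": self.n_trajectories,
            "n_singleton": self.n_singleton,
            "pct_singleton": self.pct_singleton,
            "n_low": self.n_low,
            "pct_low": self.pct_low,
            "n_fixed": self.n_fixed,
            "n_shared": self.n_shared,
            "pct_shared": self.pct_shared,
            "per_population": self.per_population,
        }

    def to_text(self) -> str:
        lines = [
            f"unique alleles:            {self.n_total}",
            f"per-population rows:       {self.n_trajectories}",
            f"singletons:                {self.n_singleton} ({self.pct_singleton}%)",
            f"never above 30%:           {self.n_low} ({self.pct_low}%)",
            f"fixed (max >= 99.5%):      {self.n_fixed}",
            f"shared (>= 2 populations): {self.n_shared} ({self.pct_shared}%)",
        ]
        for pop in sorted(self.per_population):
            c = self.per_population[pop]
            lines.append(
                f"  population {pop}: {c['n_trajectories']} trajectories, "
                f"{c['n_singleton']} singletons, {c['n_low']} low, "
                f"{c['n_fixed']} fixed"
            )
        return "\n".join(lines)


def summarize_trajectories(
    table: pd.DataFrame,
    thresholds: ClassThresholds = DEFAULT_THRESHOLDS,
) -> TrajectorySummary:
    """Count singleton / low / fixed / shared alleles and their percentages."""
    if table.empty:
        return TrajectorySummary(0, 0, 0, 0.0, 0, 0.0, 0, 0, 0.0, {})
    pcols = passage_columns(table)
    n_rows = len(table)
    n_total = 0
    n_singleton = n_low = n_fixed = n_shared = 0
    for _, group in _allele_groups(table):
        n_total += 1
        values = group[pcols].to_numpy(dtype=float)
        n_present = int((values > thresholds.presence_floor).sum())
        peak = float(values.max())
        if n_present == 1:
            n_singleton += 1
        if peak <= thresholds.low_max:
            n_low += 1
        if peak >= thresholds.fixed_min:
            n_fixed += 1
        if group["population"].nunique() >= 2:
            n_shared += 1
    per_population: dict[str, dict[str, int]] = {}
    for pop, group in table.groupby("population", sort=True):
        counts = {"n_trajectories": len(group), "n_singleton": 0, "n_low": 0,
                  "n_fixed": 0}
        for _, row in group.iterrows():
            labels = classify_trajectory(
                row[pcols].to_numpy(dtype=float), thresholds
            )
            if "singleton" in labels:
                counts["n_singleton"] += 1
            if "low" in labels:
                counts["n_low"] += 1
            if "fixed" in labels:
                counts["n_fixed"] += 1
        per_population[str(pop)] = counts
    return TrajectorySummary(
        n_total=n_total,
        n_trajectories=n_rows,
        n_singleton=n_singleton,
        pct_singleton=round_percent(n_singleton, n_total),
        n_low=n_low,
        pct_low=round_percent(n_low, n_total),
        n_fixed=n_fixed,
        n_shared=n_shared,
        pct_shared=round_percent(n_shared, n_total),
        per_population=per_population,
    )


@dataclass
class SharedAlleleReport:
    """Alleles (exact position AND alt identity) found in >= 2 populations."""

    groups: pd.DataFrame
    n_shared: int
    pct_shared: float


def detect_shared_alleles(table: pd.DataFrame) -> SharedAlleleReport:
    """Group trajectories sharing an identical (position, ref, alt) allele.

    The same position with different alt bases is *not* shared (that is
    parallel evolution at the site/gene level, handled separately).
    """
    columns = ["position", "ref", "alt", "n_populations", "populations",
               "max_freq_by_population"]
    if table.empty:
        return SharedAlleleReport(pd.DataFrame(columns=columns), 0, 0.0)
    pcols = passage_columns(table)
    rows = []
    n_total = 0
    for (position, ref, alt), group in _allele_groups(table):
        n_total += 1
        pops = sorted(group["population"].unique())
        if len(pops) < 2:
            continue
        max_by_pop = {
            str(pop): float(sub[pcols].to_numpy(dtype=float).max())
            for pop, sub in group.groupby("population")
        }
        rows.append(
            {
                "position": position, "ref": ref, "alt": alt,
                "n_populations": len(pops),
                "populations": tuple(str(p) for p in pops),
                "max_freq_by_population": max_by_pop,
            }
        )
    groups = pd.DataFrame(rows, columns=columns)
    n_shared = len(groups)
    return SharedAlleleReport(groups, n_shared, round_percent(n_shared, n_total))


@dataclass
class ParallelGeneReport:
    """Genes hit by distinct mutations, across or within populations."""

    cross_population: pd.DataFrame
    within_population: pd.DataFrame
    n_unannotated: int


_GENE_COLUMNS = ["gene", "n_populations", "n_alleles", "entries"]


def detect_parallel_genes(table: pd.DataFrame) -> ParallelGeneReport:
    """Find genes with >= 2 distinct alt alleles in >= 2 distinct populations.

    ``entries`` lists (position, alt, population, max frequency) tuples per
    gene.  Genes are ranked by population count, then allele count.
    Trajectories without a gene annotation (missing or the noncoding
    placeholder) are excluded with a notice — annotation is an input
    mapping, never inferred.
    """
    empty = pd.DataFrame(columns=_GENE_COLUMNS)
    if table.empty or "gene" not in table.columns:
        return ParallelGeneReport(empty, empty.copy(), 0)
    pcols = passage_columns(table)
    annotated = table[
        table["gene"].notna()
        & (table["gene"] != "")
        & (table["gene"] != NONCODING_LABEL)
    ]
    n_unannotated = len(table) - len(annotated)
    if n_unannotated:
        logger.info(
            "%d trajectories lack a gene annotation; excluded from "
            "parallel-gene detection", n_unannotated,
        )
    cross_rows, within_rows = [], []
    for gene, group in annotated.groupby("gene", sort=True):
        alleles = group[["position", "alt"]].drop_duplicates()
        pops = group["population"].unique()
        entries = [
            (
                int(row["position"]),
                str(row["alt"]),
                str(row["population"]),
                float(row[pcols].astype(float).max()),
            )
            for _, row in group.iterrows()
        ]
        record = {
            "gene": gene,
            "n_populations": len(pops),
            "n_alleles": len(alleles),
            "entries": entries,
        }
        if len(alleles) >= 2 and len(pops) >= 2:
            cross_rows.append(record)
        elif len(alleles) >= 2:
            within_rows.append(record)
    def _frame(rows: list[dict]) -> pd.DataFrame:
        if not rows:
            return pd.DataFrame(columns=_GENE_COLUMNS)
        return (
            pd.DataFrame(rows, columns=_GENE_COLUMNS)
            .sort_values(["n_populations", "n_alleles"], ascending=False)
            .reset_index(drop=True)
        )
    return ParallelGeneReport(_frame(cross_rows), _frame(within_rows), n_unannotated)


def cosegregation_bound(frequencies: Sequence[float]) -> float:
    """Pigeonhole lower bound on joint carriage of k alleles.

    Given marginal frequencies f_1..f_k, at least
    ``max(0, sum(f) - (k - 1))`` of cells must carry all k alleles
    simultaneously, whatever the (unknown) phasing.
    """
    values = np.asarray(list(frequencies), dtype=float)
    if values.size == 0:
        raise ValueError("frequencies must be non-empty")
    if np.any((values < 0) | (values > 1)):
        raise ValueError("frequencies must be in [0, 1]")
    return float(max(0.0, values.sum() - (values.size - 1)))


def cosegregation_report(
    table: pd.DataFrame,
    thresholds: ClassThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Per (population, passage): alleles above the cosegregation threshold.

    Samples where two or more alleles each exceed ``cosegregation_min``
    (default 50%) imply cosegregation of those alleles in at least a subset
    of cells; the joint lower bound is included per sample.
    """
    columns = ["population", "passage", "n_alleles", "alleles", "joint_lower_bound"]
    if table.empty:
        return pd.DataFrame(columns=columns)
    pcols = passage_columns(table)
    rows = []
    for pop, group in table.groupby("population", sort=True):
        for p in pcols:
            freqs = group[p].to_numpy(dtype=float)
            mask = freqs > thresholds.cosegregation_min
            if mask.sum() < 2:
                continue
            sub = group.loc[mask]
            labels = tuple(
                f"{int(r.position)}:{r.ref}>{r.alt}" for r in sub.itertuples()
            )
            rows.append(
                {
                    "population": str(pop),
                    "passage": int(p),
                    "n_alleles": int(mask.sum()),
                    "alleles": labels,
                    "joint_lower_bound": cosegregation_bound(freqs[mask]),
                }
            )
    return pd.DataFrame(rows, columns=columns)


def annotate_genes(table: pd.DataFrame, intervals: pd.DataFrame) -> pd.DataFrame:
    """Fill the gene column from an interval map (1-based, inclusive).

    ``intervals`` must have columns gene, start, end.  Positions outside
    every interval receive the noncoding placeholder label ``"NC"``.
    Overlapping intervals: the first (by table order) wins, with a notice.
    """
    for col in ("gene", "start", "end"):
        if col not in intervals.columns:
            raise ValueError("intervals require columns: gene, start, end")
    table = table.copy()
    genes = []
    for position in table["position"]:
        hits = intervals[
            (intervals["start"] <= position) & (position <= intervals["end"])
        ]
        if len(hits) > 1:
            logger.info(
                "position %d falls in %d intervals; using %r",
                position, len(hits), hits.iloc[0]["gene"],
            )
        genes.append(hits.iloc[0]["gene"] if len(hits) else NONCODING_LABEL)
    table["gene"] = genes
    return table
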