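"""Serial-passage population simulator with mutation supply and bottlenecks.

The model follows a batch-culture experiment in which *E. coli* grows in rich
medium through all five phases of its laboratory life cycle.  Each passage
cycle has three censuses that matter to allele dynamics:

1. **growth** — the culture expands from its inoculum to a peak density
   (default 5e9 CFU/ml in 12.5 ml).  Lineage abundances are apportioned in
   proportion to ``abundance * (1 + s_growth)^g`` where
   ``g = log2(realized fold expansion)`` is the number of doublings.  New
   mutations arise in proportion to the number of births times the genome
   length times the per-bp mutation rate; each founds a new single-cell
   lineage.
2. **death phase** — viable counts contract to a trough density (default
   2e7 CFU/ml), with per-lineage survival weighted by the long-term
   stationary-phase (LTSP) survival component of fitness, ``1 + s_death``.
3. **bottleneck** — a 1:1,000 dilution transfers a multinomial sample of the
   survivors into fresh medium.

Fitness is deliberately decomposed into a growth component and a death-phase
survival component, set per mutation: mutants in this system typically show
an advantage when cultures age into LTSP before passage but a disadvantage
under daily passage, and the two components let both regimes be reproduced.
Lag and stationary phase are not modelled explicitly; only the three
censuses above move allele frequencies.

A deterministic mode replaces every sampling step with its expectation,
which makes two-lineage competition follow the logistic recursion
``logit(p') = logit(p) + g * ln(1 + s)`` exactly.

The module also synthesizes the sequencing layer (strand-resolved pileup
columns at ~300x Poisson depth with symmetric base errors) and fixture
trajectory tables with a prescribed class composition, so the downstream
caller and trajectory analytics are testable without any external data.
"""

from __future__ import annotations

import copy
import logging
import math
import string
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .calling import StrandPileupColumn

logger = logging.getLogger(__name__)

BASES = "ACGT"

#: Fixed offset between per-population random substreams of one run.
POPULATION_STREAM_OFFSET = 1_000_003

PHASE_AFTER_GROWTH = "after_growth"
PHASE_AFTER_DEATH = "after_death"
PHASE_AFTER_BOTTLENECK = "after_bottleneck"


class ExtinctionError(RuntimeError):
    """Raised when a population's census reaches zero."""


@dataclass(frozen=True)
class SimulationParams:
    """Physical parameters of the serial-passage experiment.

    Defaults are the experiment's own conditions: a 4.6 Mbp genome, a basal
    mutation rate of ~1e-10 per bp replicated, peak density ~5e9 CFU/ml and
    death-phase trough ~2e7 CFU/ml in 12.5 ml of medium, passaged at 1:1,000.
    ``beneficial_fraction`` / ``beneficial_effect`` are
    distribution-of-fitness-effects knobs (default 0 → all new mutations
    neutral); a beneficial mutation receives ``beneficial_effect`` as its
    growth component and ``beneficial_death_effect`` as its death-survival
    component.
    """

    genome_length: int = 4_600_000
    mutation_rate: float = 1e-10
    peak_density: float = 5e9
    trough_density: float = 2e7
    culture_volume: float = 12.5
    dilution_factor: float = 1000.0
    beneficial_fraction: float = 0.0
    beneficial_effect: float = 0.0
    beneficial_death_effect: float = 0.0
    infinite_sites: bool = False
    reporting_floor: float = 1e-3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be > 0")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        if not self.peak_density >= self.trough_density > 0:
            raise ValueError("require peak_density >= trough_density > 0")
        if self.dilution_factor <= 1.0:
            raise ValueError("dilution_factor must be > 1")
        if self.culture_volume <= 0:
            raise ValueError("culture_volume must be > 0")
        if not 0.0 <= self.beneficial_fraction <= 1.0:
            raise ValueError("beneficial_fraction must be in [0, 1]")

    @property
    def peak_census(self) -> int:
        return int(round(self.peak_density * self.culture_volume))

    @property
    def trough_census(self) -> int:
        return int(round(self.trough_density * self.culture_volume))

    @property
    def bottleneck_census(self) -> int:
        """Cells transferred at passage (trough census / dilution factor)."""
        return int(round(self.trough_census / self.dilution_factor))


@dataclass(frozen=True)
class PassageScheme:
    """30 four-day passages, with samples saved after every third passage."""

    n_passages: int = 30
    passage_interval: int = 4
    sampling_cadence: int = 3

    def __post_init__(self) -> None:
        if self.n_passages < 1:
            raise ValueError("n_passages must be >= 1")
        if self.passage_interval < 1:
            raise ValueError("passage_interval must be >= 1")
        if not self.sampled_passages:
            raise ValueError(
                "sampling_cadence yields no sampled passages within n_passages"
            )

    @property
    def sampled_passages(self) -> tuple[int, ...]:
        if self.sampling_cadence < 1:
            return ()
        return tuple(
            range(self.sampling_cadence, self.n_passages + 1, self.sampling_cadence)
        )


@dataclass(frozen=True)
class Mutation:
    """A point mutation: unique identifier mapped to (position, ref, alt)."""

    id: int
    position: int
    ref: str
    alt: str
    growth_s: float = 0.0
    death_s: float = 0.0
    origin_passage: int = 0

    @property
    def allele_key(self) -> tuple[int, str, str]:
        return (self.position, self.ref, self.alt)


@dataclass
class Lineage:
    """A genotype (set of mutation ids) and its abundance.

    Fitness multipliers are cached at creation: products of ``1 + s`` over
    the genotype's mutations, separately for growth and death survival.
    """

    genotype: frozenset[int]
    abundance: float
    growth_fitness: float = 1.0
    death_fitness: float = 1.0


@dataclass
class PopulationState:
    """Lineage-structured population plus its mutation registry."""

    lineages: list[Lineage]
    mutations: dict[int, Mutation] = field(default_factory=dict)
    passage_index: int = 0
    phase_label: str = PHASE_AFTER_BOTTLENECK
    population_id: str = "A"
    #: next unused mutation identifier (monotonic across registry pruning)
    next_mutation_id: int = 0

    def total(self) -> float:
        return float(sum(lin.abundance for lin in self.lineages))

    def check_viable(self) -> None:
        if self.total() <= 0:
            raise ExtinctionError(
                f"population {self.population_id} extinct at passage "
                f"{self.passage_index}"
            )


class MutationSupply(NamedTuple):
    total_bp: float
    expected_mutations: float
    expected_hits_per_site: float


class Generations(NamedTuple):
    exact: float
    rounded: int


def expected_mutation_supply(
    n_cells: float, genome_length: float, mutation_rate: float
) -> MutationSupply:
    """Expected mutational input of one outgrowth.

    ``n_cells`` cells each carrying ``genome_length`` bp give
    ``n_cells * genome_length`` total bp replicated; multiplying by the
    per-bp mutation rate gives the expected mutation count, and dividing
    that by the genome length gives the expected number of independent hits
    per site.  At 1e10 cells, 4.6e6 bp and 1e-10 per bp this is 4.6e16 bp,
    4.6e6 mutations and one expected hit per genomic site — every nonlethal
    point mutation is expected to be present in the culture at least once.
    """
    if n_cells < 0 or genome_length < 0 or mutation_rate < 0:
        raise ValueError("all inputs must be >= 0")
    total_bp = n_cells * genome_length
    expected_mutations = total_bp * mutation_rate
    per_site = expected_mutations / genome_length if genome_length > 0 else 0.0
    return MutationSupply(total_bp, expected_mutations, per_site)


def generations_for_regrowth(fold_expansion: float) -> Generations:
    """Doublings needed for a given fold expansion: log2(fold).

    A 1:1,000 dilution regrown to the same density is ~10 generations; a
    1e6-fold expansion ~20; a 1:100 dilution ~7.
    """
    if fold_expansion < 1.0:
        raise ValueError("fold_expansion must be >= 1")
    exact = math.log2(fold_expansion)
    return Generations(exact, int(round(exact)))


def reference_base(position: int) -> str:
    """Deterministic reference base at a (1-based) genomic position."""
    return BASES[(position * 2654435761) % 4]


def founder_state(
    params: SimulationParams, population_id: str = "A"
) -> PopulationState:
    """A fresh culture: one unmutated lineage at the inoculation census."""
    inoculum = max(1, int(round(params.peak_census / params.dilution_factor)))
    return PopulationState(
        lineages=[Lineage(genotype=frozenset(), abundance=float(inoculum))],
        mutations={},
        passage_index=0,
        phase_label=PHASE_AFTER_BOTTLENECK,
        population_id=population_id,
    )


def seed_mutant_lineage(
    state: PopulationState,
    n_cells: float,
    growth_s: float = 0.0,
    death_s: float = 0.0,
    position: int | None = None,
    alt: str | None = None,
) -> tuple[PopulationState, Mutation]:
    """Convert ``n_cells`` of the first lineage into a new mutant lineage.

    Used to seed a tracked allele (e.g. a known beneficial mutation) into a
    founder population.  Returns the modified state and the new mutation.
    """
    state = copy.deepcopy(state)
    if not state.lineages:
        raise ValueError("cannot seed a mutant into an empty population")
    parent = state.lineages[0]
    if n_cells <= 0 or n_cells > parent.abundance:
        raise ValueError("n_cells must be in (0, parent abundance]")
    mut_id = state.next_mutation_id
    state.next_mutation_id = mut_id + 1
    if position is None:
        position = 1 + (mut_id * 997) % 4_600_000
    ref = reference_base(position)
    if alt is None:
        alt = next(b for b in BASES if b != ref)
    if alt == ref:
        raise ValueError("alt must differ from the reference base")
    mutation = Mutation(
        id=mut_id, position=position, ref=ref, alt=alt,
        growth_s=growth_s, death_s=death_s,
        origin_passage=state.passage_index,
    )
    state.mutations[mut_id] = mutation
    parent.abundance -= n_cells
    state.lineages.append(
        Lineage(
            genotype=parent.genotype | {mut_id},
            abundance=float(n_cells),
            growth_fitness=parent.growth_fitness * (1.0 + growth_s),
            death_fitness=parent.death_fitness * (1.0 + death_s),
        )
    )
    state.lineages = [lin for lin in state.lineages if lin.abundance > 0]
    return state, mutation


def _abundances(state: PopulationState) -> np.ndarray:
    return np.array([lin.abundance for lin in state.lineages], dtype=float)


def _apportion(
    target: int,
    weights: np.ndarray,
    rng: np.random.Generator,
    deterministic: bool,
) -> np.ndarray:
    """Split ``target`` cells across lineages with probabilities ~ weights."""
    total_w = float(weights.sum())
    if total_w <= 0:
        raise ExtinctionError("all lineage weights are zero")
    probs = weights / total_w
    if deterministic:
        return target * probs
    # guard the multinomial against floating-point sums slightly > 1
    probs = probs / probs.sum()
    return rng.multinomial(int(target), probs).astype(float)


def _draw_new_mutations(
    state: PopulationState,
    counts: np.ndarray,
    births: float,
    params: SimulationParams,
    rng: np.random.Generator,
    deterministic: bool,
) -> tuple[list[Lineage], np.ndarray, int]:
    """Assign de-novo mutations to single cells drawn from grown lineages."""
    expected = max(births, 0.0) * params.genome_length * params.mutation_rate
    n_new = int(round(expected)) if deterministic else int(rng.poisson(expected))
    if n_new == 0:
        return [], counts, 0
    next_id = state.next_mutation_id
    new_lineages: list[Lineage] = []
    total = counts.sum()
    parent_idx = rng.choice(len(counts), size=n_new, p=counts / total)
    positions = rng.integers(1, params.genome_length + 1, size=n_new)
    if params.infinite_sites:
        occupied = {m.position for m in state.mutations.values()}
        for k in range(n_new):
            while int(positions[k]) in occupied:
                positions[k] = rng.integers(1, params.genome_length + 1)
            occupied.add(int(positions[k]))
    # alt base: one of the 3 non-reference bases, uniformly
    alt_offsets = rng.integers(1, 4, size=n_new)
    beneficial = rng.random(size=n_new) < params.beneficial_fraction
    for k in range(n_new):
        i = int(parent_idx[k])
        if counts[i] < 1.0:
            continue
        position = int(positions[k])
        ref = reference_base(position)
        alt = BASES[(BASES.index(ref) + int(alt_offsets[k])) % 4]
        if beneficial[k]:
            growth_s = params.beneficial_effect
            death_s = params.beneficial_death_effect
        else:
            growth_s = death_s = 0.0
        mutation = Mutation(
            id=next_id, position=position, ref=ref, alt=alt,
            growth_s=growth_s, death_s=death_s,
            origin_passage=state.passage_index + 1,
        )
        state.mutations[next_id] = mutation
        next_id += 1
        parent = state.lineages[i]
        counts[i] -= 1.0
        new_lineages.append(
            Lineage(
                genotype=parent.genotype | {mutation.id},
                abundance=1.0,
                growth_fitness=parent.growth_fitness * (1.0 + growth_s),
                death_fitness=parent.death_fitness * (1.0 + death_s),
            )
        )
    state.next_mutation_id = next_id
    return new_lineages, counts, len(new_lineages)


def _rebuild(
    state: PopulationState,
    counts: np.ndarray,
    extra: list[Lineage],
    phase: str,
    passage_index: int | None = None,
) -> PopulationState:
    lineages = [
        replace(lin, abundance=float(c))
        for lin, c in zip(state.lineages, counts)
        if c > 0
    ] + extra
    return PopulationState(
        lineages=lineages,
        mutations=state.mutations,
        passage_index=state.passage_index if passage_index is None else passage_index,
        phase_label=phase,
        population_id=state.population_id,
        next_mutation_id=state.next_mutation_id,
    )


def _prune_registry(state: PopulationState) -> PopulationState:
    """Drop registry entries for mutations no surviving lineage carries.

    Extinct alleles can never reappear under the same identifier
    (``next_mutation_id`` is monotonic), so pruning keeps the registry
    proportional to standing diversity rather than cumulative supply.
    """
    alive: set[int] = set()
    for lin in state.lineages:
        alive |= lin.genotype
    if len(alive) < len(state.mutations):
        state.mutations = {i: state.mutations[i] for i in sorted(alive)}
    return state


def grow(
    state: PopulationState,
    params: SimulationParams,
    rng: np.random.Generator,
    deterministic: bool = False,
) -> tuple[PopulationState, dict]:
    """Growth to peak census with selection and de-novo mutation supply."""
    state = copy.copy(state)
    state.mutations = dict(state.mutations)
    state.lineages = list(state.lineages)
    n0 = state.total()
    state.check_viable()
    target = params.peak_census
    if target < n0:
        logger.warning(
            "population already above peak census (%g > %d); no growth", n0, target
        )
        target = int(round(n0))
    g = math.log2(target / n0) if target > n0 else 0.0
    growth_w = np.array([lin.growth_fitness for lin in state.lineages])
    weights = _abundances(state) * np.power(growth_w, g)
    counts = _apportion(target, weights, rng, deterministic)
    births = target - n0
    extra, counts, n_new = _draw_new_mutations(
        state, counts, births, params, rng, deterministic
    )
    info = {"g_regrowth": g, "n_births": births, "n_new_mutations": n_new}
    return _rebuild(state, counts, extra, PHASE_AFTER_GROWTH), info


def death_phase(
    state: PopulationState,
    params: SimulationParams,
    rng: np.random.Generator,
    deterministic: bool = False,
) -> PopulationState:
    """Contraction to the trough census, weighted by LTSP survival fitness."""
    n0 = state.total()
    state.check_viable()
    target = min(params.trough_census, int(round(n0)))
    death_w = np.array([lin.death_fitness for lin in state.lineages])
    weights = _abundances(state) * death_w
    counts = _apportion(target, weights, rng, deterministic)
    return _prune_registry(_rebuild(state, counts, [], PHASE_AFTER_DEATH))


def bottleneck(
    state: PopulationState,
    params: SimulationParams,
    rng: np.random.Generator,
    deterministic: bool = False,
    bottleneck_size: int | None = None,
) -> PopulationState:
    """1:dilution_factor transfer into fresh medium (multinomial sample)."""
    n0 = state.total()
    state.check_viable()
    if deterministic:
        counts = _abundances(state) / params.dilution_factor
    else:
        n = bottleneck_size
        if n is None:
            n = int(round(n0 / params.dilution_factor))
        if n < 1:
            raise ExtinctionError(
                f"population {state.population_id}: bottleneck sample empty"
            )
        counts = _apportion(n, _abundances(state), rng, deterministic=False)
    new = _prune_registry(
        _rebuild(
            state, counts, [], PHASE_AFTER_BOTTLENECK,
            passage_index=state.passage_index + 1,
        )
    )
    new.check_viable()
    return new


def simulate_passage_cycle(
    state: PopulationState,
    params: SimulationParams,
    rng: np.random.Generator,
    deterministic: bool = False,
    bottleneck_size: int | None = None,
) -> PopulationState:
    """One full passage: growth, death phase, then the transfer bottleneck."""
    grown, _ = grow(state, params, rng, deterministic)
    died = death_phase(grown, params, rng, deterministic)
    return bottleneck(died, params, rng, deterministic, bottleneck_size)


def allele_frequencies(state: PopulationState) -> dict[tuple[int, str, str], float]:
    """Frequency of each (position, ref, alt) allele among current cells.

    Mutation identifiers sharing the same allele key (recurrent mutation to
    the same base) are aggregated.
    """
    total = state.total()
    if total <= 0:
        return {}
    by_id: dict[int, float] = {}
    for lin in state.lineages:
        for mut_id in lin.genotype:
            by_id[mut_id] = by_id.get(mut_id, 0.0) + lin.abundance
    freqs: dict[tuple[int, str, str], float] = {}
    for mut_id, count in by_id.items():
        key = state.mutations[mut_id].allele_key
        freqs[key] = freqs.get(key, 0.0) + count / total
    return freqs


@dataclass
class ExperimentResult:
    """Output of :func:`run_experiment`.

    ``trajectories`` is the long-format true-frequency table
    (population, position, ref, alt, passage, true_freq); ``snapshots`` maps
    (population, sampled passage) to the saved after-death population state;
    ``census`` logs per-passage population sizes and mutation counts;
    ``halted`` records populations lost to extinction.
    """

    trajectories: pd.DataFrame
    snapshots: dict[tuple[str, int], PopulationState]
    census: pd.DataFrame
    halted: dict[str, int] = field(default_factory=dict)


TRAJECTORY_COLUMNS = ["population", "position", "ref", "alt", "passage", "true_freq"]

_CENSUS_COLUMNS = [
    "population", "passage", "n_start", "n_peak", "n_trough", "n_bottleneck",
    "n_new_mutations", "g_regrowth", "g_regrowth_rounded", "g_with_death_turnover",
]


def run_experiment(
    scheme: PassageScheme,
    params: SimulationParams,
    n_populations: int = 3,
    seed: int | None = None,
    deterministic: bool = False,
    population_ids: Sequence[str] | None = None,
) -> ExperimentResult:
    """Run the full passage scheme for several replicate populations.

    Samples are saved after the death phase of every ``sampling_cadence``-th
    passage, mirroring an experiment where aliquots are frozen right before
    dilution.  The trajectory table contains every allele whose true
    frequency reaches ``params.reporting_floor`` at any sampled passage,
    with zeros filled at the other sampled passages.  Fully reproducible for
    a fixed seed: population *i* uses an independent substream seeded at
    ``seed + i * POPULATION_STREAM_OFFSET``.

    The census log reports generations per passage both ways the count can
    be read: regrowth doublings only (``g_regrowth``) and including the
    turnover implied by death-phase contraction (``g_with_death_turnover``).
    """
    if n_populations < 1:
        raise ValueError("n_populations must be >= 1")
    if seed is None:
        seed = params.rng_seed
    if population_ids is None:
        letters = string.ascii_uppercase
        population_ids = [
            letters[i] if i < len(letters) else f"P{i}" for i in range(n_populations)
        ]
    snapshots: dict[tuple[str, int], PopulationState] = {}
    census_rows = []
    halted: dict[str, int] = {}
    sampled = scheme.sampled_passages
    for i in range(n_populations):
        pop_id = population_ids[i]
        rng = np.random.default_rng(seed + i * POPULATION_STREAM_OFFSET)
        state = founder_state(params, population_id=pop_id)
        for passage in range(1, scheme.n_passages + 1):
            try:
                n_start = state.total()
                grown, info = grow(state, params, rng, deterministic)
                died = death_phase(grown, params, rng, deterministic)
                if passage in sampled:
                    snapshots[(pop_id, passage)] = copy.deepcopy(died)
                state = bottleneck(died, params, rng, deterministic)
            except ExtinctionError:
                logger.warning(
                    "population %s extinct at passage %d; halting", pop_id, passage
                )
                halted[pop_id] = passage
                break
            n_peak = grown.total()
            n_trough = died.total()
            census_rows.append(
                {
                    "population": pop_id,
                    "passage": passage,
                    "n_start": n_start,
                    "n_peak": n_peak,
                    "n_trough": n_trough,
                    "n_bottleneck": state.total(),
                    "n_new_mutations": info["n_new_mutations"],
                    "g_regrowth": info["g_regrowth"],
                    "g_regrowth_rounded": int(round(info["g_regrowth"])),
                    "g_with_death_turnover": info["g_regrowth"]
                    + math.log2(n_peak / n_trough),
                }
            )
    trajectories = _true_trajectory_table(snapshots, sampled, params.reporting_floor)
    census = pd.DataFrame(census_rows, columns=_CENSUS_COLUMNS)
    return ExperimentResult(trajectories, snapshots, census, halted)


def _true_trajectory_table(
    snapshots: Mapping[tuple[str, int], PopulationState],
    sampled_passages: Sequence[int],
    reporting_floor: float,
) -> pd.DataFrame:
    rows = []
    populations = sorted({pop for pop, _ in snapshots})
    for pop in populations:
        per_passage: dict[int, dict[tuple[int, str, str], float]] = {}
        for passage in sampled_passages:
            snap = snapshots.get((pop, passage))
            per_passage[passage] = allele_frequencies(snap) if snap else {}
        reported = {
            key
            for freqs in per_passage.values()
            for key, f in freqs.items()
            if f >= reporting_floor
        }
        for key in sorted(reported):
            position, ref, alt = key
            for passage in sampled_passages:
                rows.append(
                    {
                        "population": pop,
                        "position": position,
                        "ref": ref,
                        "alt": alt,
                        "passage": passage,
                        "true_freq": per_passage[passage].get(key, 0.0),
                    }
                )
    return pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)


@dataclass(frozen=True)
class SequencingParams:
    """Pooled-sequencing emulation: mean depth, error rate, invariant sites."""

    depth_mean: float = 300.0
    error_rate: float = 0.001
    n_invariant_sites: int = 100

    def __post_init__(self) -> None:
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be > 0")
        if not 0.0 <= self.error_rate < 0.25:
            raise ValueError("error_rate must be in [0, 0.25)")
        if self.n_invariant_sites < 0:
            raise ValueError("n_invariant_sites must be >= 0")


def simulate_pileup(
    snapshot: PopulationState,
    depth_mean: float = 300.0,
    error_rate: float = 0.001,
    rng: np.random.Generator | int | None = None,
    n_invariant_sites: int = 0,
    genome_length: int = 4_600_000,
    fixed_depth: int | None = None,
) -> list[StrandPileupColumn]:
    """Emulate pooled sequencing of a population snapshot.

    Every segregating site (plus ``n_invariant_sites`` reference-only sites)
    receives a Poisson(depth_mean) column depth (or exactly ``fixed_depth``).
    Each read independently samples a template cell from the site's true
    allele mix, miscalls to one of the three other bases with probability
    ``error_rate`` (symmetric, e/3 each), and lands on the forward or
    reverse strand with probability 1/2.
    """
    if depth_mean <= 0:
        raise ValueError("depth_mean must be > 0")
    if not 0.0 <= error_rate < 0.25:
        raise ValueError("error_rate must be in [0, 0.25)")
    rng = np.random.default_rng(rng)
    freqs = allele_frequencies(snapshot)
    mixes: dict[int, dict[str, float]] = {}
    for (position, ref, alt), f in freqs.items():
        mix = mixes.setdefault(position, {"__ref__": ref})
        mix[alt] = mix.get(alt, 0.0) + f
    mutant_positions = set(mixes)
    invariant: list[int] = []
    while len(invariant) < n_invariant_sites:
        pos = int(rng.integers(1, genome_length + 1))
        if pos not in mutant_positions and pos not in invariant:
            invariant.append(pos)
    for pos in invariant:
        mixes[pos] = {"__ref__": reference_base(pos)}
    columns = []
    base_index = {b: i for i, b in enumerate(BASES)}
    for position in sorted(mixes):
        mix = dict(mixes[position])
        ref = mix.pop("__ref__")
        alt_total = sum(mix.values())
        true_probs = np.zeros(4)
        true_probs[base_index[ref]] = max(0.0, 1.0 - alt_total)
        for alt, f in mix.items():
            true_probs[base_index[alt]] += f
        # symmetric single-base error channel
        obs_probs = true_probs * (1.0 - error_rate) + (
            error_rate / 3.0
        ) * (true_probs.sum() - true_probs)
        obs_probs = obs_probs / obs_probs.sum()
        depth = fixed_depth if fixed_depth is not None else int(rng.poisson(depth_mean))
        if depth > 0:
            base_counts = rng.multinomial(depth, obs_probs)
            fwd_counts = rng.binomial(base_counts, 0.5)
        else:
            base_counts = np.zeros(4, dtype=int)
            fwd_counts = np.zeros(4, dtype=int)
        counts = {
            BASES[i]: (int(fwd_counts[i]), int(base_counts[i] - fwd_counts[i]))
            for i in range(4)
            if base_counts[i] > 0 or BASES[i] == ref
        }
        columns.append(
            StrandPileupColumn(position=position, ref_allele=ref, counts=counts)
        )
    return columns


def simulate_competition(
    growth_s: float,
    death_s: float = 0.0,
    n_passages: int = 3,
    params: SimulationParams | None = None,
    n_replicates: int = 2,
    seed: int = 0,
    deterministic: bool = False,
    initial_frequency: float = 0.5,
    include_death_phase: bool = True,
    scheme_label: str | None = None,
    strain_mutant: str = "mutant",
    strain_wt: str = "wild_type",
) -> pd.DataFrame:
    """Synthesize a head-to-head competition series between two strains.

    Two lineages (a mutant with the given fitness components and its parent)
    are passaged together; viable densities (CFU/ml) of each strain are
    recorded at inoculation (passage 0) and at the end of each passage —
    after the death phase for the 4-day scheme, or at peak density when
    ``include_death_phase`` is False (daily passage, cells transferred from
    early stationary phase).

    Returns a long table with columns
    ``scheme, replicate, passage, strain, cfu_per_ml``.
    """
    if params is None:
        params = SimulationParams()
    if scheme_label is None:
        scheme_label = "4day" if include_death_phase else "1day"
    rows = []
    for rep in range(n_replicates):
        rng = np.random.default_rng(seed + rep * POPULATION_STREAM_OFFSET)
        state = founder_state(params, population_id=f"rep{rep}")
        n_mutant = initial_frequency * state.total()
        state, mutation = seed_mutant_lineage(
            state, n_mutant, growth_s=growth_s, death_s=death_s
        )

        def record(st: PopulationState, passage: int) -> None:
            total = st.total()
            f_mut = allele_frequencies(st).get(mutation.allele_key, 0.0)
            rows.append(
                {
                    "scheme": scheme_label, "replicate": rep, "passage": passage,
                    "strain": strain_mutant,
                    "cfu_per_ml": f_mut * total / params.culture_volume,
                }
            )
            rows.append(
                {
                    "scheme": scheme_label, "replicate": rep, "passage": passage,
                    "strain": strain_wt,
                    "cfu_per_ml": (1.0 - f_mut) * total / params.culture_volume,
                }
            )

        record(state, 0)
        for passage in range(1, n_passages + 1):
            grown, _ = grow(state, params, rng, deterministic)
            end_state = (
                death_phase(grown, params, rng, deterministic)
                if include_death_phase
                else grown
            )
            record(end_state, passage)
            state = bottleneck(end_state, params, rng, deterministic)
    return pd.DataFrame(
        rows, columns=["scheme", "replicate", "passage", "strain", "cfu_per_ml"]
    )


def synthetic_trajectory_table(
    n_total: int = 213,
    n_singleton: int = 104,
    n_low: int = 183,
    n_fixed: int = 13,
    n_shared: int = 40,
    passages: Sequence[int] = tuple(range(3, 31, 3)),
    populations: Sequence[str] = ("A", "B", "C"),
    seed: int = 0,
) -> pd.DataFrame:
    """Build a trajectory table with a prescribed class composition.

    The defaults reproduce the statistical structure of the experiment's
    mutation inventory: 213 unique point mutations of which 104 are
    singletons (one time point only), 183 never rise above 30% frequency,
    13 fix, and 40 appear in more than one population.  Construction (at the
    unique-allele level):

    * shared alleles: two populations, one low-frequency time point each;
    * singletons: one population, exactly one nonzero (low) time point;
    * remaining low alleles: one population, several time points <= 30%;
    * fixed alleles: one population, rising to >= 99.5%;
    * the rest: one population, intermediate/high maxima in (30%, 99.5%).

    Returns a wide table (population, position, ref, alt, gene + one column
    per sampled passage) compatible with :mod:`ltsp.trajectories`.
    """
    n_other_low = n_low - n_singleton - n_shared
    n_mid = n_total - n_low - n_fixed
    if min(n_total, n_singleton, n_low, n_fixed, n_shared) < 0 or n_other_low < 0 or n_mid < 0:
        raise ValueError(
            "inconsistent composition: need n_low >= n_singleton + n_shared "
            "and n_total >= n_low + n_fixed"
        )
    if len(populations) < 2 and n_shared > 0:
        raise ValueError("shared alleles require at least two populations")
    rng = np.random.default_rng(seed)
    passages = list(passages)
    rows = []
    position = 0

    def new_allele() -> tuple[int, str, str]:
        nonlocal position
        position += 997  # distinct sites, deterministic spacing
        ref = reference_base(position)
        alt = str(rng.choice([b for b in BASES if b != ref]))
        return position, ref, alt

    def make_row(pop: str, key: tuple[int, str, str], freqs: dict[int, float]) -> None:
        pos, ref, alt = key
        row = {"population": pop, "position": pos, "ref": ref, "alt": alt,
               "gene": None}
        for p in passages:
            row[p] = freqs.get(p, 0.0)
        rows.append(row)

    def low_freq() -> float:
        return float(rng.uniform(0.01, 0.25))

    for _ in range(n_shared):
        key = new_allele()
        pops = rng.choice(len(populations), size=2, replace=False)
        for j in pops:
            p = int(rng.choice(passages))
            make_row(populations[int(j)], key, {p: low_freq()})
    for _ in range(n_singleton):
        key = new_allele()
        pop = populations[int(rng.integers(len(populations)))]
        p = int(rng.choice(passages))
        make_row(pop, key, {p: low_freq()})
    for _ in range(n_other_low):
        key = new_allele()
        pop = populations[int(rng.integers(len(populations)))]
        idx = rng.choice(len(passages), size=2, replace=False)
        make_row(pop, key, {passages[int(i)]: low_freq() for i in idx})
    for _ in range(n_fixed):
        key = new_allele()
        pop = populations[int(rng.integers(len(populations)))]
        i = int(rng.integers(0, len(passages) - 1))
        make_row(pop, key, {passages[i]: float(rng.uniform(0.4, 0.8)),
                            passages[i + 1]: 1.0})
    for _ in range(n_mid):
        key = new_allele()
        pop = populations[int(rng.integers(len(populations)))]
        i = int(rng.integers(0, len(passages) - 1))
        make_row(pop, key, {passages[i]: float(rng.uniform(0.05, 0.25)),
                            passages[i + 1]: float(rng.uniform(0.31, 0.97))})
    table = pd.DataFrame(
        rows, columns=["population", "position", "ref", "alt", "gene"] + passages
    )
    return table.sort_values(["population", "position", "alt"]).reset_index(drop=True)
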