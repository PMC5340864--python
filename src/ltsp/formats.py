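"""Readers and writers for the pipeline's external text formats.

Canonical interchange is a strand-pileup TSV (one row per site-allele with
forward/reverse counts).  A samtools-mpileup text dialect is accepted as a
convenience ingestion path; base qualities are ignored (filtering is on
mapping quality upstream, not base quality).  Calls are serialized as a
minimal VCF 4.2 with AF/DP/SAF/SAR INFO fields.  Coordinates are 1-based
inclusive at every interface.

The genome is modelled as a single (circular) chromosome whose label
defaults to the K-12 MG1655 reference accession; there is no multi-contig
support.

Configuration is flat key = value text with one section per module
(stdlib configparser syntax); every field has an embedded default and the
effective configuration is echoed into the provenance record of each CLI
run.
"""

from __future__ import annotations

import configparser
import dataclasses
import io
import json
import logging
import os
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO

import pandas as pd

from . import __version__
from .calling import (
    CallerConfig,
    StrandPileupColumn,
    VariantCall,
    VariantCallSet,
)
from .simulate import PassageScheme, SequencingParams, SimulationParams
from .trajectories import ClassThresholds

logger = logging.getLogger(__name__)

DEFAULT_REFERENCE_LABEL = "NC_000913.2"

STRAND_TSV_COLUMNS = ["position", "ref", "allele", "fwd_count", "rev_count"]


class MpileupParseError(ValueError):
    """Malformed pileup base string, annotated with the offending line."""


def _consume_indel(bases: str, i: int, lineno: int | None) -> int:
    """Skip a +n/-n indel subsequence starting at the sign character."""
    j = i + 1
    start = j
    while j < len(bases) and bases[j].isdigit():
        j += 1
    if j == start:
        raise MpileupParseError(
            f"line {lineno}: indel marker '{bases[i]}' not followed by a length"
        )
    length = int(bases[start:j])
    if j + length > len(bases):
        raise MpileupParseError(
            f"line {lineno}: indel sequence of length {length} overruns the "
            "base string"
        )
    return j + length


def parse_mpileup_bases(
    bases: str, ref: str, lineno: int | None = None
) -> dict[str, tuple[int, int]]:
    """Tally a pileup base string into per-allele (forward, reverse) counts.

    Dialect: '.' reference-forward, ',' reference-reverse; uppercase base
    alternate-forward, lowercase alternate-reverse; '^' consumes the
    following mapping-quality character, '$' is consumed; '+n'/'-n' indel
    subsequences are skipped; '*', '>' and '<' are excluded from counts.
    """
    ref = ref.upper()
    counts: dict[str, list[int]] = {}

    def bump(allele: str, forward: bool) -> None:
        pair = counts.setdefault(allele, [0, 0])
        pair[0 if forward else 1] += 1

    i = 0
    n = len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            if i + 1 >= n:
                raise MpileupParseError(
                    f"line {lineno}: '^' at end of base string"
                )
            i += 2
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            i = _consume_indel(bases, i, lineno)
            continue
        if c == ".":
            bump(ref, True)
        elif c == ",":
            bump(ref, False)
        elif c in "ACGTN":
            bump(c, True)
        elif c in "acgtn":
            bump(c.upper(), False)
        elif c in "*><#":
            pass  # deletions and reference skips carry no base observation
        else:
            raise MpileupParseError(
                f"line {lineno}: unexpected character {c!r} in base string"
            )
        i += 1
    return {a: (f, r) for a, (f, r) in counts.items()}


def parse_mpileup_line(line: str, lineno: int | None = None) -> StrandPileupColumn:
    """Parse one samtools-mpileup text line into a strand pileup column."""
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 5:
        raise MpileupParseError(
            f"line {lineno}: expected >= 5 tab-separated fields, got {len(fields)}"
        )
    chrom, pos_text, ref, depth_text, bases = fields[:5]
    try:
        position = int(pos_text)
        stated_depth = int(depth_text)
    except ValueError as exc:
        raise MpileupParseError(
            f"line {lineno}: non-integer position or depth"
        ) from exc
    counts = parse_mpileup_bases(bases, ref, lineno)
    parsed_depth = sum(f + r for f, r in counts.values())
    if parsed_depth > stated_depth:
        logger.warning(
            "line %s: parsed %d base observations but depth field says %d",
            lineno, parsed_depth, stated_depth,
        )
    return StrandPileupColumn(
        position=position, ref_allele=ref.upper(), counts=counts, chrom=chrom
    )


def read_mpileup(source: str | Path | TextIO) -> list[StrandPileupColumn]:
    """Read a samtools-mpileup text file into pileup columns."""
    if isinstance(source, (str, Path)):
        with open(source) as handle:
            return read_mpileup(handle)
    columns = []
    for lineno, line in enumerate(source, start=1):
        if not line.strip():
            continue
        columns.append(parse_mpileup_line(line, lineno))
    return columns


def write_strand_pileup_tsv(
    columns: Iterable[StrandPileupColumn], destination: str | Path | TextIO
) -> None:
    """Write pileup columns as the canonical strand-pileup TSV."""
    if isinstance(destination, (str, Path)):
        with open(destination, "w") as handle:
            write_strand_pileup_tsv(columns, handle)
            return
    destination.write("\t".join(STRAND_TSV_COLUMNS) + "\n")
    for col in sorted(columns, key=lambda c: c.position):
        for allele in sorted(col.counts):
            fwd, rev = col.counts[allele]
            destination.write(
                f"{col.position}\t{col.ref_allele}\t{allele}\t{fwd}\t{rev}\n"
            )


def read_strand_pileup_tsv(source: str | Path | TextIO) -> list[StrandPileupColumn]:
    """Read the strand-pileup TSV back into pileup columns."""
    df = pd.read_csv(source, sep="\t", dtype={"ref": str, "allele": str})
    missing = [c for c in STRAND_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"strand-pileup TSV missing columns: {missing}")
    columns = []
    for position, group in df.groupby("position", sort=True):
        refs = group["ref"].unique()
        if len(refs) != 1:
            raise ValueError(
                f"conflicting reference alleles at position {position}: {refs}"
            )
        counts = {
            str(row["allele"]): (int(row["fwd_count"]), int(row["rev_count"]))
            for _, row in group.iterrows()
        }
        columns.append(
            StrandPileupColumn(
                position=int(position), ref_allele=str(refs[0]), counts=counts
            )
        )
    return columns


_VCF_INFO_HEADERS = [
    '##INFO=<ID=AF,Number=A,Type=Float,Description="Alternate allele frequency '
    '(alt reads / total column depth)">',
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth at the '
    'site">',
    '##INFO=<ID=SAF,Number=A,Type=Integer,Description="Alternate-supporting '
    'reads on the forward strand">',
    '##INFO=<ID=SAR,Number=A,Type=Integer,Description="Alternate-supporting '
    'reads on the reverse strand">',
]


def write_vcf(
    calls: VariantCallSet | Sequence[VariantCall],
    destination: str | Path | TextIO | None = None,
    reference_label: str = DEFAULT_REFERENCE_LABEL,
    contig_length: int | None = None,
) -> str:
    """Serialize calls as minimal VCF 4.2 text (byte-stable for fixed input).

    One record per (site, alt).  QUAL is missing ('.') — the calling rule
    is a hard threshold with no quality model — and FILTER is PASS.
    Returns the text; also writes it when a destination is given.
    """
    if isinstance(calls, VariantCallSet):
        population_id, passage = calls.population_id, calls.passage
        records = list(calls.calls)
    else:
        population_id = passage = None
        records = list(calls)
    positions = [c.position for c in records]
    if positions != sorted(positions):
        logger.warning("calls not sorted by position; sorting before writing")
        records.sort(key=lambda c: (c.position, c.alt_allele))
    lines = ["##fileformat=VCFv4.2", f"##source=ltsp-{__version__}"]
    if contig_length is not None:
        lines.append(f"##contig=<ID={reference_label},length={contig_length}>")
    else:
        lines.append(f"##contig=<ID={reference_label}>")
    if population_id is not None:
        lines.append(f"##ltsp_population={population_id}")
    if passage is not None:
        lines.append(f"##ltsp_passage={passage}")
    lines.extend(_VCF_INFO_HEADERS)
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for call in records:
        info = (
            f"AF={call.frequency:.6g};DP={call.depth};"
            f"SAF={call.alt_forward};SAR={call.alt_reverse}"
        )
        lines.append(
            f"{reference_label}\t{call.position}\t.\t{call.ref_allele}\t"
            f"{call.alt_allele}\t.\tPASS\t{info}"
        )
    text = "\n".join(lines) + "\n"
    if destination is not None:
        if isinstance(destination, (str, Path)):
            with open(destination, "w") as handle:
                handle.write(text)
        else:
            destination.write(text)
    return text


def read_vcf(source: str | Path | TextIO) -> VariantCallSet:
    """Parse the minimal VCF dialect written by :func:`write_vcf`."""
    if isinstance(source, (str, Path)):
        with open(source) as handle:
            return read_vcf(handle)
    population_id: str | None = None
    passage: int | None = None
    calls = []
    for line in source:
        line = line.rstrip("\n")
        if not line:
            continue
        if line.startswith("##ltsp_population="):
            population_id = line.split("=", 1)[1]
            continue
        if line.startswith("##ltsp_passage="):
            passage = int(line.split("=", 1)[1])
            continue
        if line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 8:
            raise ValueError(f"malformed VCF record: {line!r}")
        info = dict(
            item.split("=", 1) for item in fields[7].split(";") if "=" in item
        )
        calls.append(
            VariantCall(
                position=int(fields[1]),
                ref_allele=fields[3],
                alt_allele=fields[4],
                frequency=float(info["AF"]),
                alt_forward=int(info["SAF"]),
                alt_reverse=int(info["SAR"]),
                depth=int(info["DP"]),
                population_id=population_id,
                passage=passage,
            )
        )
    return VariantCallSet(calls=calls, population_id=population_id, passage=passage)


def write_calls_csv(callset: VariantCallSet, path: str | Path) -> None:
    callset.to_dataframe().to_csv(path, index=False)


def read_calls_csv(path: str | Path) -> VariantCallSet:
    """Read a calls CSV (as written by :func:`write_calls_csv`)."""
    df = pd.read_csv(path, dtype={"population": str})
    calls = [
        VariantCall(
            position=int(r.position),
            ref_allele=str(r.ref),
            alt_allele=str(r.alt),
            frequency=float(r.frequency),
            alt_forward=int(r.alt_forward),
            alt_reverse=int(r.alt_reverse),
            depth=int(r.depth),
            population_id=None if pd.isna(r.population) else str(r.population),
            passage=None if pd.isna(r.passage) else int(r.passage),
        )
        for r in df.itertuples()
    ]
    pops = {c.population_id for c in calls}
    passages = {c.passage for c in calls}
    return VariantCallSet(
        calls=calls,
        population_id=pops.pop() if len(pops) == 1 else None,
        passage=passages.pop() if len(passages) == 1 else None,
    )


_PASSAGE_RE = re.compile(r"^P(\d+)$")


def write_trajectory_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a wide trajectory table; passage columns are labelled P3, P6..."""
    out = table.copy()
    out.columns = [
        f"P{c}" if isinstance(c, (int,)) or str(c).isdigit() else c
        for c in out.columns
    ]
    out.to_csv(path, index=False)


def read_trajectory_csv(path: str | Path) -> pd.DataFrame:
    """Read a wide trajectory CSV back, restoring integer passage columns."""
    df = pd.read_csv(path, dtype={"population": str, "ref": str, "alt": str})
    renames = {}
    for col in df.columns:
        match = _PASSAGE_RE.match(str(col))
        if match:
            renames[col] = int(match.group(1))
    return df.rename(columns=renames)


def read_gene_intervals(path: str | Path) -> pd.DataFrame:
    """Read a gene-annotation interval table (TSV: gene, start, end).

    Intervals are 1-based and inclusive on both ends.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    for col in ("gene", "start", "end"):
        if col not in df.columns:
            raise ValueError("gene interval file requires columns: gene, start, end")
    return df


def read_growth_csv(path: str | Path) -> pd.DataFrame:
    """Read a growth-curve CSV (strain, replicate, day, cfu_per_ml[, below_detection])."""
    df = pd.read_csv(path, dtype={"strain": str})
    for col in ("strain", "replicate", "day", "cfu_per_ml"):
        if col not in df.columns:
            raise ValueError(
                "growth CSV requires columns: strain, replicate, day, cfu_per_ml"
            )
    if "below_detection" not in df.columns:
        df["below_detection"] = False
    return df


def read_competition_csv(path: str | Path) -> pd.DataFrame:
    """Read a competition CSV (scheme, replicate, passage, strain, cfu_per_ml)."""
    df = pd.read_csv(path, dtype={"scheme": str, "strain": str})
    for col in ("scheme", "replicate", "passage", "strain", "cfu_per_ml"):
        if col not in df.columns:
            raise ValueError(
                "competition CSV requires columns: scheme, replicate, passage, "
                "strain, cfu_per_ml"
            )
    if "below_detection" not in df.columns:
        df["below_detection"] = False
    return df


@dataclass
class AnalysisConfig:
    """Bundle of every tunable the pipeline reads from a config file."""

    simulation: SimulationParams = dataclasses.field(default_factory=SimulationParams)
    scheme: PassageScheme = dataclasses.field(default_factory=PassageScheme)
    sequencing: SequencingParams = dataclasses.field(default_factory=SequencingParams)
    caller: CallerConfig = dataclasses.field(default_factory=CallerConfig)
    thresholds: ClassThresholds = dataclasses.field(default_factory=ClassThresholds)
    reference_label: str = DEFAULT_REFERENCE_LABEL

    def to_dict(self) -> dict:
        return {
            "simulation": dataclasses.asdict(self.simulation),
            "scheme": dataclasses.asdict(self.scheme),
            "sequencing": dataclasses.asdict(self.sequencing),
            "caller": dataclasses.asdict(self.caller),
            "trajectories": dataclasses.asdict(self.thresholds),
            "io": {"reference_label": self.reference_label},
        }


_SECTION_TYPES = {
    "simulation": SimulationParams,
    "scheme": PassageScheme,
    "sequencing": SequencingParams,
    "caller": CallerConfig,
    "trajectories": ClassThresholds,
}


def _coerce(value: str, target_type: type) -> object:
    if target_type is bool:
        lowered = value.strip().lower()
        if lowered in ("true", "yes", "on", "1"):
            return True
        if lowered in ("false", "no", "off", "0"):
            return False
        raise ValueError(f"not a boolean: {value!r}")
    if target_type is int:
        return int(float(value))
    if target_type is float:
        return float(value)
    return value


def load_config(path: str | Path | None = None) -> AnalysisConfig:
    """Load configuration; missing file/section/key falls back to defaults."""
    config = AnalysisConfig()
    if path is None:
        return config
    parser = configparser.ConfigParser()
    read = parser.read(path)
    if not read:
        raise FileNotFoundError(f"config file not found: {path}")
    for section, cls in _SECTION_TYPES.items():
        if not parser.has_section(section):
            continue
        field_types = {f.name: f.type for f in dataclasses.fields(cls)}
        defaults = getattr(config, "thresholds" if section == "trajectories" else section)
        kwargs = dataclasses.asdict(defaults)
        for key, raw in parser.items(section):
            if key not in kwargs:
                raise ValueError(f"unknown config key [{section}] {key}")
            kwargs[key] = _coerce(raw, type(kwargs[key]))
        rebuilt = cls(**kwargs)
        if section == "trajectories":
            config.thresholds = rebuilt
        else:
            setattr(config, section, rebuilt)
    if parser.has_section("io"):
        config.reference_label = parser.get(
            "io", "reference_label", fallback=config.reference_label
        )
    return config


def write_config(config: AnalysisConfig, path: str | Path) -> None:
    """Write every effective setting back out as sectioned key = value text."""
    parser = configparser.ConfigParser()
    for section, values in config.to_dict().items():
        parser[section] = {k: str(v) for k, v in values.items()}
    with open(path, "w") as handle:
        parser.write(handle)


def write_provenance(
    out_dir: str | Path,
    command: str,
    seed: int | None,
    config: AnalysisConfig,
    extra: dict | None = None,
) -> Path:
    """Record what produced an output directory: command, seed, config echo.

    Deliberately contains no timestamp so that repeated runs with the same
    seed produce byte-identical output trees.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record = {
        "tool": "ltsp",
        "version": __version__,
        "command": command,
        "seed": seed,
        "config": config.to_dict(),
    }
    if extra:
        record.update(extra)
    path = out_dir / "provenance.json"
    with open(path, "w") as handle:
        json.dump(record, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return path
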