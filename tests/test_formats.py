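"""IO tests: the mpileup text dialect, strand-pileup TSV and VCF round
trips (with pysam as an independent VCF reader), config handling, and the
CLI contract (determinism, empty outputs, usage errors)."""

import io
import json
from pathlib import Path

import pandas as pd
import pytest
from click.testing import CliRunner
from hypothesis import given
from hypothesis import strategies as st

from ltsp import StrandPileupColumn, VariantCall, VariantCallSet
from ltsp.cli import main
from ltsp.formats import (
    AnalysisConfig,
    MpileupParseError,
    load_config,
    parse_mpileup_line,
    read_strand_pileup_tsv,
    read_trajectory_csv,
    read_vcf,
    write_config,
    write_strand_pileup_tsv,
    write_trajectory_csv,
    write_vcf,
)


class TestMpileupParsing:
    def _parse(self, bases, ref="T", depth=None):
        depth = len(bases) if depth is None else depth
        return parse_mpileup_line(f"chr\t100\t{ref}\t{depth}\t{bases}\t IIIII")

    def test_mixed_strand_bases(self):
        col = self._parse(",.AaA")
        assert col.counts["T"] == (1, 1)
        assert col.counts["A"] == (2, 1)
        assert col.position == 100

    def test_reference_forward_only(self):
        col = self._parse(".....", ref="C")
        assert col.counts == {"C": (5, 0)}

    def test_read_start_marker_consumes_mapq_char(self):
        col = self._parse("^].,")
        assert col.counts == {"T": (1, 1)}

    def test_read_end_marker_consumed(self):
        col = self._parse(".$,")
        assert col.counts == {"T": (1, 1)}

    def test_indel_subsequences_skipped(self):
        col = self._parse(".+2AT,-1a.", ref="G")
        assert col.counts == {"G": (2, 1)}

    def test_deletion_and_refskip_symbols_excluded(self):
        col = self._parse(".*><,", ref="A")
        assert col.counts == {"A": (1, 1)}

    def test_malformed_character_reports_line(self):
        with pytest.raises(MpileupParseError, match="line 7"):
            parse_mpileup_line("chr\t5\tA\t3\t..!\tIII", lineno=7)

    def test_truncated_indel_rejected(self):
        with pytest.raises(MpileupParseError):
            self._parse(".+")

    def test_depth_mismatch_warns_but_parses(self, caplog):
        col = self._parse("..,,", depth=2)
        assert col.counts["T"] == (2, 2)


class TestStrandTsvRoundTrip:
    def test_round_trip_preserves_counts(self, tmp_path):
        columns = [
            StrandPileupColumn(10, "A", {"A": (140, 150), "G": (5, 4)}),
            StrandPileupColumn(20, "C", {"C": (160, 140)}),
        ]
        path = tmp_path / "pileup.tsv"
        write_strand_pileup_tsv(columns, path)
        restored = read_strand_pileup_tsv(path)
        assert [(c.position, c.ref_allele, c.counts) for c in restored] == [
            (c.position, c.ref_allele, c.counts) for c in columns
        ]

    def test_conflicting_reference_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "position\tref\tallele\tfwd_count\trev_count\n"
            "10\tA\tA\t5\t5\n10\tC\tC\t5\t5\n"
        )
        with pytest.raises(ValueError, match="conflicting"):
            read_strand_pileup_tsv(path)

    @given(
        data=st.dictionaries(
            st.integers(1, 10_000),
            st.tuples(
                st.sampled_from("ACGT"),
                st.dictionaries(
                    st.sampled_from("ACGT"),
                    st.tuples(st.integers(0, 500), st.integers(0, 500)),
                    min_size=1, max_size=4,
                ),
            ),
            max_size=6,
        )
    )
    def test_round_trip_on_arbitrary_valid_tables(self, data):
        columns = [
            StrandPileupColumn(pos, ref, counts)
            for pos, (ref, counts) in sorted(data.items())
        ]
        buffer = io.StringIO()
        write_strand_pileup_tsv(columns, buffer)
        buffer.seek(0)
        restored = read_strand_pileup_tsv(buffer)
        assert [(c.position, c.ref_allele, c.counts) for c in restored] == [
            (c.position, c.ref_allele, c.counts) for c in columns
        ]


def _callset():
    calls = [
        VariantCall(100, "C", "T", 0.02, 3, 3, 300, "A", 3),
        VariantCall(250, "G", "A", 0.5, 75, 80, 310, "A", 3),
        VariantCall(250, "G", "C", 0.1, 15, 16, 310, "A", 3),
    ]
    return VariantCallSet(calls=calls, population_id="A", passage=3)


class TestVcf:
    def test_single_record_info_fields(self):
        text = write_vcf(VariantCallSet([VariantCall(100, "C", "T", 0.02, 3, 3, 300)]))
        record = [l for l in text.splitlines() if not l.startswith("#")][0]
        fields = record.split("\t")
        assert fields[:5] == ["NC_000913.2", "100", ".", "C", "T"]
        assert fields[5] == "." and fields[6] == "PASS"
        assert fields[7] == "AF=0.02;DP=300;SAF=3;SAR=3"

    def test_empty_callset_header_only(self):
        text = write_vcf(VariantCallSet())
        assert all(line.startswith("#") for line in text.splitlines())

    def test_round_trip_reproduces_all_fields(self, tmp_path):
        path = tmp_path / "calls.vcf"
        write_vcf(_callset(), path)
        restored = read_vcf(path)
        assert restored.population_id == "A" and restored.passage == 3
        for original, parsed in zip(_callset(), restored):
            assert parsed.position == original.position
            assert parsed.ref_allele == original.ref_allele
            assert parsed.alt_allele == original.alt_allele
            assert parsed.frequency == pytest.approx(original.frequency, rel=1e-5)
            assert parsed.alt_forward == original.alt_forward
            assert parsed.alt_reverse == original.alt_reverse
            assert parsed.depth == original.depth

    def test_byte_stable_output(self):
        assert write_vcf(_callset()) == write_vcf(_callset())

    def test_unsorted_calls_sorted_with_warning(self, caplog):
        calls = [
            VariantCall(250, "G", "A", 0.5, 75, 80, 310),
            VariantCall(100, "C", "T", 0.02, 3, 3, 300),
        ]
        text = write_vcf(calls)
        records = [l for l in text.splitlines() if not l.startswith("#")]
        assert [r.split("\t")[1] for r in records] == ["100", "250"]

    def test_pysam_reads_our_vcf(self, tmp_path):
        pysam = pytest.importorskip("pysam")
        path = tmp_path / "calls.vcf"
        write_vcf(_callset(), path, contig_length=4_641_652)
        with pysam.VariantFile(str(path)) as vcf:
            records = list(vcf)
        assert len(records) == 3
        assert records[0].pos == 100
        assert records[0].info["AF"][0] == pytest.approx(0.02)
        assert records[0].info["DP"] == 300


class TestConfig:
    def test_defaults_without_file(self):
        config = load_config(None)
        assert config.simulation.genome_length == 4_600_000
        assert config.caller.min_reads_per_strand == 3
        assert config.scheme.sampled_passages[-1] == 30

    def test_write_then_load_round_trip(self, tmp_path):
        config = AnalysisConfig()
        path = tmp_path / "ltsp.cfg"
        write_config(config, path)
        restored = load_config(path)
        assert restored.to_dict() == config.to_dict()

    def test_partial_override(self, tmp_path):
        path = tmp_path / "ltsp.cfg"
        path.write_text("[simulation]\ngenome_length = 4600\n[caller]\n"
                        "min_reads_per_strand = 2\n")
        config = load_config(path)
        assert config.simulation.genome_length == 4_600
        assert config.simulation.peak_density == 5e9  # untouched default
        assert config.caller.min_reads_per_strand == 2

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "ltsp.cfg"
        path.write_text("[simulation]\nbogus = 1\n")
        with pytest.raises(ValueError, match="unknown config key"):
            load_config(path)

    def test_missing_file_rejected(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_config(tmp_path / "nope.cfg")


class TestTrajectoryCsv:
    def test_passage_columns_survive_round_trip(self, tmp_path):
        table = pd.DataFrame(
            [{"population": "A", "position": 10, "ref": "C", "alt": "T",
              "gene": None, 3: 0.1, 6: 0.0}],
            columns=["population", "position", "ref", "alt", "gene", 3, 6],
        )
        path = tmp_path / "traj.csv"
        write_trajectory_csv(table, path)
        header = path.read_text().splitlines()[0]
        assert header.endswith("P3,P6")
        restored = read_trajectory_csv(path)
        assert list(restored.columns)[-2:] == [3, 6]
        assert restored.iloc[0][3] == pytest.approx(0.1)


SMALL_CONFIG = """
[simulation]
genome_length = 4600
[scheme]
n_passages = 6
[sequencing]
depth_mean = 300
error_rate = 0.001
n_invariant_sites = 5
"""


class TestCli:
    def test_no_subcommand_shows_usage_nonzero(self):
        result = CliRunner().invoke(main, [])
        assert result.exit_code != 0
        assert "Usage" in result.output

    def test_unknown_flag_is_usage_error(self):
        result = CliRunner().invoke(main, ["simulate", "--bogus"])
        assert result.exit_code != 0

    def test_simulate_is_deterministic_under_fixed_seed(self, tmp_path):
        (tmp_path / "ltsp.cfg").write_text(SMALL_CONFIG)
        runner = CliRunner()
        outputs = []
        for name in ("run1", "run2"):
            result = runner.invoke(
                main,
                ["simulate", "--config", str(tmp_path / "ltsp.cfg"),
                 "--seed", "5", "--n-populations", "1",
                 "--out-dir", str(tmp_path / name)],
            )
            assert result.exit_code == 0, result.output
            tree = {
                p.name: p.read_bytes()
                for p in sorted((tmp_path / name).iterdir())
            }
            outputs.append(tree)
        assert outputs[0].keys() == outputs[1].keys()
        for name in outputs[0]:
            assert outputs[0][name] == outputs[1][name], name

    def test_call_on_reference_only_pileup_writes_empty_vcf(self, tmp_path):
        pileup = tmp_path / "pileup.tsv"
        pileup.write_text(
            "position\tref\tallele\tfwd_count\trev_count\n"
            "10\tA\tA\t150\t150\n20\tC\tC\t140\t160\n"
        )
        result = CliRunner().invoke(
            main,
            ["call", "--pileup", str(pileup), "--out-dir", str(tmp_path / "out")],
        )
        assert result.exit_code == 0, result.output
        vcf_lines = (tmp_path / "out" / "calls.vcf").read_text().splitlines()
        assert all(line.startswith("#") for line in vcf_lines)
        assert (tmp_path / "out" / "provenance.json").exists()

    def test_call_then_trajectories_pipeline(self, tmp_path):
        pileup = tmp_path / "pileup.tsv"
        pileup.write_text(
            "position\tref\tallele\tfwd_count\trev_count\n"
            "10\tA\tA\t144\t150\n10\tA\tG\t3\t3\n"
        )
        runner = CliRunner()
        result = runner.invoke(
            main,
            ["call", "--pileup", str(pileup), "--population", "A",
             "--passage", "3", "--out-dir", str(tmp_path / "calls")],
        )
        assert result.exit_code == 0, result.output
        result = runner.invoke(
            main,
            ["trajectories", "--calls", str(tmp_path / "calls" / "calls.csv"),
             "--out-dir", str(tmp_path / "traj")],
        )
        assert result.exit_code == 0, result.output
        summary = json.loads((tmp_path / "traj" / "summary.json").read_text())
        assert summary["n_total"] == 1

    def test_power_subcommand_reports_threshold(self, tmp_path):
        result = CliRunner().invoke(
            main,
            ["power", "--depth", "300", "--target", "0.5",
             "--out-dir", str(tmp_path / "power")],
        )
        assert result.exit_code == 0, result.output
        assert "min detectable frequency" in result.output
        assert (tmp_path / "power" / "power.csv").exists()

    def test_phenotype_subcommand_growth_and_competition(self, tmp_path):
        growth = tmp_path / "growth.csv"
        rows = ["strain,replicate,day,cfu_per_ml"]
        for day, value in {1: 5e9, 2: 1e9, 3: 1e8, 4: 2e7, 5: 2e8}.items():
            rows.append(f"parent,0,{day},{value}")
            rows.append(f"parent,1,{day},{value * 1.1}")
            rows.append(f"passaged,0,{day},{value * 10}")
            rows.append(f"passaged,1,{day},{value * 11}")
        growth.write_text("\n".join(rows) + "\n")
        competition = tmp_path / "competition.csv"
        comp_rows = ["scheme,replicate,passage,strain,cfu_per_ml"]
        for rep in (0, 1):
            for passage, ratio in {0: 1.0, 1: 10.0, 2: 100.0, 3: 10_000.0}.items():
                comp_rows.append(f"4day,{rep},{passage},mut,{2e7 * ratio ** 0.5}")
                comp_rows.append(f"4day,{rep},{passage},wt,{2e7 / ratio ** 0.5}")
        competition.write_text("\n".join(comp_rows) + "\n")
        result = CliRunner().invoke(
            main,
            ["phenotype", "--growth", str(growth),
             "--competition", str(competition),
             "--out-dir", str(tmp_path / "pheno")],
        )
        assert result.exit_code == 0, result.output
        out = tmp_path / "pheno"
        assert (out / "dip_metrics.csv").exists()
        assert (out / "growth_tests.csv").exists()
        results = json.loads((out / "competition_results.json").read_text())
        assert "slope_per_generation" in results
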