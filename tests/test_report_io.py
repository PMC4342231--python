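"""Report shapes, file round-trips, and CLI wiring."""

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

from delstack import io as dio
from delstack.amplicon_caller import ReferenceSeq, SnpRecord
from delstack.cli import main as cli_main
from delstack.cross_model import DetectedClass, SignificanceConfig
from delstack.report import render_interval_track, segregation_report, summarize_screening
from delstack.synteny_map import DeletionInterval, IntactnessProfile, infer_deletion_interval


class TestScreeningSummary:
    def test_per_gene_progeny_totals(self):
        tables = dio.load_tetra_crosses()
        for gene, expected in (("TaPFT1", 1237), ("TaPLDB1", 605), ("TaWRKY11", 419)):
            subset = [t for t in tables if t.gene == gene]
            assert summarize_screening(subset, gene).total_screened == expected

    def test_gene_mismatch_rejected(self):
        tables = dio.load_tetra_crosses()
        with pytest.raises(ValueError, match="mixed"):
            summarize_screening(tables, "TaPFT1")

    def test_flag_layout_of_report(self):
        tables = [t for t in dio.load_tetra_crosses() if t.gene == "TaPFT1"]
        frame = segregation_report(tables, SignificanceConfig())
        first = frame.iloc[0]  # 316 screened, AB never seen
        assert first["AB"] == "[0**]"
        assert first["A"] == "55" and first["B"] == "51"
        assert first["p_AB"] < 0.01

    def test_empty_summary(self):
        table = summarize_screening([], "TaPFT1")
        assert table.total_screened == 0 and table.rows.empty


class TestRoundTrips:
    def test_cross_tables(self, tmp_path):
        tables = dio.load_tetra_crosses()
        path = tmp_path / "crosses.csv"
        dio.write_cross_tables(tables, str(path))
        back = dio.load_cross_tables(str(path))
        assert len(back) == len(tables)
        for a, b in zip(tables, back):
            assert (a.gene, a.n, a.counts, a.cross.index) == (
                b.gene, b.n, b.counts, b.cross.index
            )

    def test_snp_table_positions_one_based_on_disk(self, tmp_path):
        records = [
            SnpRecord("scaf1", "g1", 0, "A", "C", 33.33, 90),
            SnpRecord("scaf1", "g1", 7, "A", "G", 12.5, 80),
        ]
        path = tmp_path / "snps.tsv"
        dio.write_snp_table(records, "S1", str(path))
        text = path.read_text().splitlines()
        assert text[1].split("\t")[3] == "1"  # 0-based 0 -> 1-based 1
        sample, back = dio.read_snp_table(str(path))
        assert sample == "S1"
        assert [(r.gene_id, r.ref_position, r.allele_variant) for r in back] == [
            ("g1", 0, "C"), ("g1", 7, "G"),
        ]

    def test_calls_matrix(self, tmp_path):
        from delstack.amplicon_caller import IntactnessCall

        calls = {
            "mut1": [
                IntactnessCall("g1", "A", "deleted", 3, 3),
                IntactnessCall("g1", "B", "intact", 2, 0),
            ]
        }
        path = tmp_path / "calls.tsv"
        dio.write_calls_matrix(calls, str(path))
        back = dio.read_calls_matrix(str(path))
        assert back[("mut1", "A")]["g1"] == "deleted"
        assert back[("mut1", "B")]["g1"] == "intact"

    def test_fasta_fastq(self, tmp_path):
        refs = [ReferenceSeq("r1", "ACGTACGT"), ReferenceSeq("r2", "GGGGCCCC")]
        fa = tmp_path / "refs.fa"
        dio.write_fasta(refs, str(fa))
        assert dio.read_fasta(str(fa)) == refs

    def test_hits_and_scaffolds(self, tmp_path):
        hits_path = tmp_path / "hits.tsv"
        hits_path.write_text(
            "query_gene\tsubject_arm\tidentity\talign_length\te_value\n"
            "g1\t5AL\t95.0\t400\t1e-40\n"
            "g1\t2AL\t96.0\t450\t1e-45\n"
        )
        groups = dio.load_hits_table(str(hits_path))
        assert len(groups["g1"]) == 2
        sc_path = tmp_path / "scaffolds.csv"
        sc_path.write_text("scaffold_id,length,genes\ns1,7000,g1;g2\n")
        (record,) = dio.load_scaffold_table(str(sc_path))
        assert record.length == 7000 and record.genes == {"g1", "g2"}


class TestTrackRendering:
    def test_worked_interval_row(self, panel):
        calls = {m.gene_id: "unknown" for m in panel}
        for m in panel:
            if -400 <= m.offset_kb <= 100:
                calls[m.gene_id] = "deleted"
            elif m.offset_kb in (-700, 200):
                calls[m.gene_id] = "intact"
        iv = infer_deletion_interval(IntactnessProfile("m616", "A", calls), panel)
        text = render_interval_track({("m616", "A"): iv}, panel)
        row = text.splitlines()[1]
        assert "[500,900]" in row
        assert row.count("#") == 9  # the nine markers inside the deleted run
        assert row.count("|") == 2  # both intact bounds

    def test_empty_track_is_header_only(self, panel):
        assert len(render_interval_track({}, panel).splitlines()) == 1

    def test_open_end_uses_arrow_glyph(self, panel):
        iv = DeletionInterval(
            min_size=2050.0, max_size=None, up_bound_marker="Bradi4g27607",
            down_bound_marker="none assayed", down_open=True,
            up_edge_kb=-50.0, down_edge_kb=2000.0,
        )
        text = render_interval_track({("m", "B"): iv}, panel)
        assert ">" not in text.splitlines()[0]
        # nothing lies beyond the last marker, but the label reports the open max
        assert "[2050,open]" in text.splitlines()[1]


class TestCli:
    def test_segregation_test_command(self, tmp_path):
        src = tmp_path / "crosses.csv"
        dio.write_cross_tables(dio.load_tetra_crosses(), str(src))
        out = tmp_path / "report.csv"
        runner = CliRunner()
        result = runner.invoke(
            cli_main,
            ["segregation-test", "--crosses", str(src), "--out", str(out)],
        )
        assert result.exit_code == 0, result.output
        assert out.exists()

    def test_bad_alpha_ordering_exits_3(self, tmp_path):
        src = tmp_path / "crosses.csv"
        dio.write_cross_tables(dio.load_tetra_crosses(), str(src))
        runner = CliRunner()
        result = runner.invoke(
            cli_main,
            [
                "segregation-test", "--crosses", str(src),
                "--alpha1", "0.01", "--alpha2", "0.05",
                "--out", str(tmp_path / "r.csv"),
            ],
        )
        assert result.exit_code == 3

    def test_simulate_then_call_then_infer(self, tmp_path):
        """The full shell workflow on a reduced configuration."""
        runner = CliRunner()
        sim_cfg = tmp_path / "sim.yaml"
        sim_cfg.write_text(
            "amplicon_length: 400\nread_length: 150\ncoverage: 55\nerror_rate: 0.0\n"
        )
        out_dir = tmp_path / "sim"
        result = runner.invoke(
            cli_main,
            [
                "simulate", "--config", str(sim_cfg), "--seed", "5",
                "--n-mutants", "1", "--out", str(out_dir),
            ],
        )
        assert result.exit_code == 0, result.output
        snp_dir = tmp_path / "snps"
        snp_dir.mkdir()
        for fq in sorted(out_dir.glob("*.fastq")):
            sample = fq.stem
            result = runner.invoke(
                cli_main,
                [
                    "call-snps", "--reads", str(fq),
                    "--refs", str(out_dir / "references.fa"),
                    "--sample-id", sample,
                    "--out", str(snp_dir / f"{sample}.tsv"),
                ],
            )
            assert result.exit_code == 0, result.output
        calls_path = tmp_path / "calls.tsv"
        result = runner.invoke(
            cli_main,
            [
                "call-deletions", "--snp-tables", str(snp_dir),
                "--design", str(out_dir / "design.yaml"),
                "--out", str(calls_path),
            ],
        )
        assert result.exit_code == 0, result.output
        intervals_path = tmp_path / "intervals.csv"
        result = runner.invoke(
            cli_main,
            [
                "infer-interval", "--calls", str(calls_path),
                "--out", str(intervals_path),
            ],
        )
        assert result.exit_code == 0, result.output
        with open(out_dir / "truth.yaml") as fh:
            truth = yaml.safe_load(fh)
        lines = intervals_path.read_text().splitlines()
        assert len(lines) == 1 + len(truth)  # one interval per simulated mutant

    def test_synteny_classify_command(self, tmp_path):
        hits = tmp_path / "hits.tsv"
        hits.write_text(
            "query_gene\tsubject_arm\tidentity\talign_length\te_value\n"
            "g1\t5AL\t95.0\t400\t1e-40\n"
            "g2\t4AL\t97.0\t500\t1e-50\n"
        )
        scaffolds = tmp_path / "scaffolds.csv"
        scaffolds.write_text("scaffold_id,length,genes\ns1,7000,g1\ns2,9000,g2\n")
        out = tmp_path / "synteny.csv"
        runner = CliRunner()
        result = runner.invoke(
            cli_main,
            [
                "synteny-classify", "--hits", str(hits),
                "--target-arms", "5AL,5BL,5DL",
                "--scaffolds", str(scaffolds), "--out", str(out),
            ],
        )
        assert result.exit_code == 0, result.output
        assert "7000 bp" in result.output
        rows = out.read_text().splitlines()
        assert "g1,conserved,5AL" in rows and "g2,translocated," in rows
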