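"""File formats, configuration and the end-to-end pipeline driver."""

import io as std_io
import json

import numpy as np
import pytest
from click.testing import CliRunner

from ciscompare import FrequencyMatrix, generate_background, generate_matrix, plant_motifs
from ciscompare import io as cio
from ciscompare.cli import main as cli_main
from ciscompare.config import PipelineConfig
from ciscompare.exceptions import ConfigError, FastaError, TransfacFormatError
from ciscompare.pipeline import run_pipeline

from conftest import random_matrix

TWO_RECORDS = """\
AC  M00001
XX
NA  FactorA
XX
CL  Pax6
XX
P0      A      C      G      T
01      1      2      2      0
02      2      1      2      0
03      3      0      1      1
XX
//
AC  M00002
XX
NA  FactorB
XX
P0      T      G      C      A
01      5      0      0      0
02      0      5      0      0
03      0      0      5      0
04      0      0      0      5
XX
//
"""


class TestTransfacParsing:
    def test_empty_input(self):
        assert cio.parse_transfac_flat("") == []

    def test_two_record_snippet_read_verbatim(self):
        ms = cio.parse_transfac_flat(TWO_RECORDS)
        assert [m.matrix_id for m in ms] == ["M00001", "M00002"]
        np.testing.assert_array_equal(
            ms[0].counts, [[1, 2, 2, 0], [2, 1, 2, 0], [3, 0, 1, 1]]
        )
        assert ms[0].tf_class == "Pax6"
        assert ms[1].tf_class == "FactorB"  # no CL line: falls back to the name
        # P0 header permuted T G C A: counts re-ordered to A C G T
        np.testing.assert_array_equal(
            ms[1].counts,
            [[0, 0, 0, 5], [0, 0, 5, 0], [0, 5, 0, 0], [5, 0, 0, 0]],
        )

    def test_class_override_map(self):
        ms = cio.parse_transfac_flat(TWO_RECORDS, class_overrides={"M00002": "HSF"})
        assert ms[1].tf_class == "HSF"

    def test_missing_p0_names_record(self):
        bad = "AC  M00009\nXX\nNA  X\nXX\n//\n"
        with pytest.raises(TransfacFormatError, match="M00009"):
            cio.parse_transfac_flat(bad)

    def test_ragged_row_names_line(self):
        bad = "AC  M1\nXX\nP0 A C G T\n01  1  2  3\n//\n"
        with pytest.raises(TransfacFormatError, match="line 4"):
            cio.parse_transfac_flat(bad)

    def test_negative_count_rejected(self):
        bad = "AC  M1\nXX\nP0 A C G T\n01  1  2  3  -1\n//\n"
        with pytest.raises(TransfacFormatError, match="negative"):
            cio.parse_transfac_flat(bad)

    def test_roundtrip_random_matrices(self, rng):
        matrices = [
            random_matrix(rng, int(rng.integers(2, 15)), matrix_id=f"M{i:05d}",
                          tf_class=f"class{i}")
            for i in range(5)
        ]
        buf = std_io.StringIO()
        cio.write_transfac(matrices, buf)
        back = cio.parse_transfac_flat(buf.getvalue())
        assert len(back) == len(matrices)
        for a, b in zip(matrices, back):
            assert (a.matrix_id, a.tf_class) == (b.matrix_id, b.tf_class)
            np.testing.assert_allclose(a.counts, b.counts, rtol=1e-6)

    def test_biopython_reads_written_records(self, rng, tmp_path):
        # independent cross-check of the flat dialect with Bio.motifs
        from Bio import motifs as bio_motifs

        matrices = [random_matrix(rng, 6, matrix_id="M00042")]
        path = tmp_path / "m.dat"
        cio.write_transfac(matrices, path)
        with open(path) as fh:
            parsed = bio_motifs.parse(fh, "transfac")
        assert len(parsed) == 1
        assert parsed[0].get("AC") == "M00042"
        got = np.column_stack([parsed[0].counts[b] for b in "ACGT"])
        np.testing.assert_allclose(got, matrices[0].counts, rtol=1e-6)


class TestFasta:
    def test_roundtrip(self, tmp_path):
        seqs = generate_background(3, 150, seed=1)
        path = tmp_path / "x.fa"
        cio.write_fasta(seqs, path)
        back = cio.read_fasta(path)
        assert [(r.sequence_id, r.residues) for r in back] == [
            (r.sequence_id, r.residues) for r in seqs
        ]

    def test_lowercase_uppercased_and_odd_symbols_mapped_to_n(self, tmp_path):
        path = tmp_path / "y.fa"
        path.write_text(">s1\nacgtRYacgt\n")
        (rec,) = cio.read_fasta(path)
        assert rec.residues == "ACGTNNACGT"

    def test_duplicate_ids_rejected(self, tmp_path):
        path = tmp_path / "z.fa"
        path.write_text(">a\nACGT\n>a\nTTTT\n")
        with pytest.raises(FastaError, match="duplicate"):
            cio.read_fasta(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "e.fa"
        path.write_text("")
        with pytest.raises(FastaError):
            cio.read_fasta(path)


class TestHitAndTableIO:
    def test_hits_tsv_roundtrip_uses_1based_inclusive_coords(self, rng, tmp_path):
        from ciscompare import scan_sequences

        m = random_matrix(rng, 5)
        seqs = generate_background(2, 200, seed=2)
        hits = scan_sequences(seqs, [m], 0.5)
        assert hits, "need hits for a meaningful round-trip"
        path = tmp_path / "hits.tsv"
        cio.write_hits_tsv(hits, path)
        frame = cio.hits_to_frame(hits)
        assert (frame["end"] - frame["start"] + 1 == m.length).all()
        back = cio.read_hits_tsv(path)
        assert [(h.sequence_id, h.start, h.end, h.strand) for h in back] == [
            (h.sequence_id, h.start, h.end, h.strand) for h in hits
        ]
        assert all(abs(a.score - b.score) < 1e-5 for a, b in zip(hits, back))

    def test_bed6_fields(self, tmp_path):
        from ciscompare import MotifHit

        hit = MotifHit("chr1", "M1", "Pax6", 10, 18, "-", 0.987)
        path = tmp_path / "h.bed"
        cio.write_hits_bed([hit], path)
        fields = path.read_text().strip().split("\t")
        assert fields == ["chr1", "10", "18", "M1|Pax6", "987", "-"]

    def test_presence_matrix_roundtrip(self, tmp_path):
        from ciscompare.datasets import load_pbx_meis_counts

        pm = load_pbx_meis_counts()
        path = tmp_path / "pm.tsv"
        cio.write_presence_tsv(pm, path)
        back = cio.read_presence_tsv(path)
        assert back.table.equals(pm.table)

    def test_annotation_table_roundtrip_of_packaged_fixture(self):
        from ciscompare.datasets import load_expression_annotations

        ann = load_expression_annotations()
        assert len(ann) == 8
        assert {a.species for a in ann} == {
            "Ciona intestinalis", "Branchiostoma floridae", "Mus musculus"
        }

    def test_profile_summaries_roundtrip(self, tmp_path):
        from ciscompare import calibrate_cutoffs
        from ciscompare.synthetic import sample_sites

        m = generate_matrix(8, 1.1, seed=3)
        profile = calibrate_cutoffs(
            m, sample_sites(m, 50, seed=4), generate_background(2, 1000, seed=5)
        )
        path = tmp_path / "profiles.tsv"
        cio.write_profiles_tsv([profile], path)
        summaries = cio.read_profile_summaries(path)
        assert summaries[m.matrix_id]["minSum"] == pytest.approx(profile.cutoff_min_sum)
        assert summaries[m.matrix_id]["minFN10"] == pytest.approx(profile.cutoff_min_fn10)


class TestPipelineConfig:
    def test_comparative_only_config(self, tmp_path):
        cfg = PipelineConfig(output_dir=str(tmp_path), presence_matrix="pm.tsv")
        assert cfg.cutoff_mode == "fixed"

    def test_scan_config_requires_cutoff_value(self):
        with pytest.raises(ConfigError):
            PipelineConfig(output_dir="o", fasta="f", matrices="m", cutoff_mode="fixed")

    def test_calibrated_mode_requires_profiles(self):
        with pytest.raises(ConfigError):
            PipelineConfig(output_dir="o", fasta="f", matrices="m", cutoff_mode="minSum")

    def test_unknown_mode_rejected(self):
        with pytest.raises(ConfigError):
            PipelineConfig(output_dir="o", presence_matrix="p", cutoff_mode="bogus")

    def test_yaml_roundtrip(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text(
            "fasta: seqs.fa\nmatrices: m.dat\noutput_dir: out\n"
            "cutoff:\n  mode: fixed\n  value: 0.9\n"
            "contrasts:\n  - name: c1\n    positives: [a, b]\n    negatives: [c]\n"
        )
        cfg = PipelineConfig.from_yaml(path)
        assert cfg.cutoff_value == 0.9
        assert cfg.contrasts[0].positive_ids == frozenset({"a", "b"})

    def test_unknown_keys_rejected(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("output_dir: out\npresence_matrix: p.tsv\nbogus_key: 1\n")
        with pytest.raises(ConfigError, match="bogus_key"):
            PipelineConfig.from_yaml(path)


class TestRunPipeline:
    def test_comparative_only_run_on_packaged_table(self, tmp_path):
        from ciscompare.datasets import load_sensory_vesicle_counts
        from ciscompare.comparative import GroupContrast

        pm_path = tmp_path / "table2.tsv"
        cio.write_presence_tsv(load_sensory_vesicle_counts(), pm_path)
        cfg = PipelineConfig(
            output_dir=str(tmp_path / "out"),
            presence_matrix=str(pm_path),
            contrasts=[
                GroupContrast(
                    frozenset({"1UP1.4", "4UP1.3", "2D0.8", "1CiHox3", "mb1"}),
                    frozenset({"mb2", "ma2", "ma3", "mb1RARE"}),
                    name="sensory_vesicle",
                )
            ],
        )
        result = run_pipeline(cfg)
        (contrast,) = result.contrasts
        assert contrast.common == {"GR", "HSF", "LEF1", "Pax6"}
        assert contrast.differential == {"Pax6"}
        report = (result.output_dir / "contrasts_report.txt").read_text()
        assert "Pax6" in report

    def test_no_contrasts_gives_scan_and_presence_only(self, tmp_path, rng):
        m = random_matrix(rng, 6)
        seqs = generate_background(2, 300, seed=6)
        cio.write_fasta(seqs, tmp_path / "s.fa")
        cio.write_transfac([m], tmp_path / "m.dat")
        cfg = PipelineConfig(
            output_dir=str(tmp_path / "out"),
            fasta=str(tmp_path / "s.fa"),
            matrices=str(tmp_path / "m.dat"),
            cutoff_mode="fixed",
            cutoff_value=0.8,
        )
        result = run_pipeline(cfg)
        assert result.contrasts == []
        assert (result.output_dir / "presence_matrix.tsv").exists()
        assert not (result.output_dir / "contrasts.tsv").exists()

    def test_seeded_run_is_deterministic(self, tmp_path):
        matrix = generate_matrix(8, 1.2, seed=7, tf_class="classA")
        ds = plant_motifs(generate_background(3, 500, seed=8), matrix, 3, seed=9)
        cio.write_fasta(ds.sequences, tmp_path / "s.fa")
        cio.write_transfac([matrix], tmp_path / "m.dat")
        manifests = []
        for run_dir in ("out1", "out2"):
            cfg = PipelineConfig(
                output_dir=str(tmp_path / run_dir),
                fasta=str(tmp_path / "s.fa"),
                matrices=str(tmp_path / "m.dat"),
                cutoff_mode="fixed",
                cutoff_value=0.85,
            )
            result = run_pipeline(cfg)
            manifests.append((result.output_dir / "manifest.json").read_text())
            hits = (result.output_dir / "hits.tsv").read_text()
        assert manifests[0] == manifests[1]

    def test_non_redundant_never_increases_presence_counts(self, tmp_path, rng):
        # two matrices of the same class: non_redundant keeps one
        m1 = random_matrix(rng, 6, matrix_id="M00001", tf_class="shared")
        m2 = random_matrix(rng, 6, matrix_id="M00002", tf_class="shared")
        seqs = generate_background(2, 400, seed=10)
        cio.write_fasta(seqs, tmp_path / "s.fa")
        cio.write_transfac([m1, m2], tmp_path / "m.dat")
        tables = {}
        for flag in (False, True):
            cfg = PipelineConfig(
                output_dir=str(tmp_path / f"out_{flag}"),
                fasta=str(tmp_path / "s.fa"),
                matrices=str(tmp_path / "m.dat"),
                cutoff_mode="fixed",
                cutoff_value=0.6,
                non_redundant=flag,
            )
            tables[flag] = run_pipeline(cfg).presence.table
        full = tables[False]
        reduced = tables[True].reindex(index=full.index, fill_value=0)
        assert (reduced.values <= full.values).all()

    def test_contrast_with_unknown_sequence_fails(self, tmp_path):
        from ciscompare.comparative import GroupContrast
        from ciscompare.datasets import load_sensory_vesicle_counts

        pm_path = tmp_path / "t2.tsv"
        cio.write_presence_tsv(load_sensory_vesicle_counts(), pm_path)
        cfg = PipelineConfig(
            output_dir=str(tmp_path / "out"),
            presence_matrix=str(pm_path),
            contrasts=[GroupContrast(frozenset({"nope"}), name="bad")],
        )
        with pytest.raises(ConfigError, match="nope"):
            run_pipeline(cfg)


class TestCli:
    def test_compare_subcommand_reports_differential_site(self, tmp_path):
        from ciscompare.datasets import load_sensory_vesicle_counts

        pm_path = tmp_path / "t2.tsv"
        cio.write_presence_tsv(load_sensory_vesicle_counts(), pm_path)
        runner = CliRunner()
        result = runner.invoke(
            cli_main,
            [
                "compare",
                "--presence", str(pm_path),
                "--positives", "1UP1.4,4UP1.3,2D0.8,1CiHox3,mb1",
                "--negatives", "mb2,ma2,ma3,mb1RARE",
            ],
        )
        assert result.exit_code == 0, result.output
        assert "differential sites (1): Pax6" in result.output

    def test_simulate_then_scan_roundtrip(self, tmp_path):
        runner = CliRunner()
        sim = runner.invoke(
            cli_main,
            ["simulate", "--n-sequences", "2", "--length", "400", "--n-sites", "3",
             "--seed", "5", "--out-prefix", str(tmp_path / "sim")],
        )
        assert sim.exit_code == 0, sim.output
        scan = runner.invoke(
            cli_main,
            ["scan", "--fasta", str(tmp_path / "sim.fa"),
             "--matrices", str(tmp_path / "sim.matrices.dat"),
             "--cutoff", "0.9", "--out-dir", str(tmp_path / "scanout")],
        )
        assert scan.exit_code == 0, scan.output
        assert (tmp_path / "scanout" / "hits.bed").exists()

    def test_run_subcommand_fails_cleanly_on_bad_config(self, tmp_path):
        cfg = tmp_path / "bad.yaml"
        cfg.write_text("output_dir: out\n")  # no inputs at all
        result = CliRunner().invoke(cli_main, ["run", "--config", str(cfg)])
        assert result.exit_code != 0
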