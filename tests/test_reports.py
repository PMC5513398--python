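"""The numbered output-file suite: contracts, determinism, batch semantics."""

import pytest

from genestats.errors import BatchHeaderError
from genestats.reports import (FILE_NAMES, append_batch, batch_lines,
                               write_reports)

MINIMUM_PARAMETERS = [
    "assembly_size_bp", "assembly_size_no_n_bp", "assembly_gc_strict_pct",
    "assembly_gc_naive_pct", "gene_count", "transcript_length_median_bp",
    "cds_length_median_bp", "cds_count_per_transcript_median",
    "cds_coverage_per_gene_median", "coding_amount_bp", "intron_count",
    "intron_length_median_bp", "intron_count_per_transcript_median",
    "intron_coverage_per_gene_median", "intron_amount_bp",
    "intron_density_per_gene_per_bp_median", "n50_bp", "l50", "l90pcg",
]


def read_tsv(path):
    lines = path.read_text().splitlines()
    return [line.split("\t") for line in lines]


class TestWriteReports:
    def test_default_run_writes_all_21_files(self, micro_analysis, tmp_path):
        report = write_reports(micro_analysis, tmp_path)
        assert len(report.files) == 21
        present = sorted(p.name for p in tmp_path.iterdir()
                         if p.name in set(FILE_NAMES.values()))
        assert len(present) == 21

    def test_19_files_parse_as_tsv_with_constant_columns(self, micro_analysis,
                                                         tmp_path):
        report = write_reports(micro_analysis, tmp_path)
        tsv_numbers = set(FILE_NAMES) - {0, 20}
        assert len(tsv_numbers) == 19
        for num in tsv_numbers:
            rows = read_tsv(report.files[num])
            widths = {len(r) for r in rows}
            assert len(widths) == 1, f"ragged TSV in file {num:02d}"

    def test_numeric_cells_reparse_or_are_na(self, micro_analysis, tmp_path):
        report = write_reports(micro_analysis, tmp_path)
        for num in (2, 5, 7, 9, 11):
            header, *rows = read_tsv(report.files[num])
            string_cols = {"scs_id", "gene_id", "transcript_id", "feature_id",
                           "seqid", "strand", "representative_transcript"}
            for row in rows:
                for col, cell in zip(header, row):
                    if col in string_cols:
                        continue
                    if cell != "NA":
                        float(cell)
                    assert cell != "."

    def test_overview_contains_minimum_parameter_set(self, micro_analysis,
                                                     tmp_path):
        report = write_reports(micro_analysis, tmp_path)
        params = {row[0] for row in read_tsv(report.files[1])[1:]}
        missing = [p for p in MINIMUM_PARAMETERS if p not in params]
        assert not missing

    def test_selection_writes_only_overview_and_manifest(self, micro_analysis,
                                                         tmp_path):
        write_reports(micro_analysis, tmp_path, enabled={1})
        names = {p.name for p in tmp_path.iterdir()}
        assert names == {FILE_NAMES[1], FILE_NAMES[13]}

    def test_rerun_is_byte_identical(self, micro_analysis, tmp_path):
        a = write_reports(micro_analysis, tmp_path / "a", date="2000-01-01")
        first = {num: path.read_bytes() for num, path in a.files.items()}
        b = write_reports(micro_analysis, tmp_path / "a", date="2000-01-01")
        for num in first:
            assert first[num] == b.files[num].read_bytes(), \
                f"file {num:02d} differs between identical runs"

    def test_rows_ordered_by_feature_id(self, small_analysis, tmp_path):
        report = write_reports(small_analysis, tmp_path)
        for num in (2, 4, 5, 7, 9, 11):
            ids = [r[0] for r in read_tsv(report.files[num])[1:]]
            assert ids == sorted(ids)


class TestComponentSizes:
    def test_components_sum_to_assembly_size(self, micro_analysis, tmp_path):
        report = write_reports(micro_analysis, tmp_path)
        header, row = read_tsv(report.files[19])
        record = dict(zip(header, row))
        total = (int(record["exon_amount_bp"]) + int(record["intron_amount_bp"])
                 + int(record["remainder_bp"]))
        assert total == int(record["assembly_size_bp"])
        # worked numbers: exons 630 + introns 320 + remainder = 1600
        assert int(record["remainder_bp"]) == 1600 - 630 - 320


class TestBatchFiles:
    def test_two_appends_one_header(self, micro_analysis, tmp_path):
        header, row = batch_lines(micro_analysis)[14]
        path = tmp_path / "batch.tsv"
        append_batch(path, header, row)
        append_batch(path, header, row)
        rows = read_tsv(path)
        assert len(rows) == 3  # header + 2 data lines
        assert rows[0] == header

    def test_first_run_creates_with_header(self, micro_analysis, tmp_path):
        header, row = batch_lines(micro_analysis)[15]
        path = tmp_path / "batch.tsv"
        append_batch(path, header, row)
        assert read_tsv(path) == [header, row]

    def test_header_mismatch_refused_and_file_unchanged(self, micro_analysis,
                                                        tmp_path):
        header, row = batch_lines(micro_analysis)[14]
        path = tmp_path / "batch.tsv"
        append_batch(path, header, row)
        before = path.read_bytes()
        with pytest.raises(BatchHeaderError):
            append_batch(path, header + ["extra"], row + ["1"])
        assert path.read_bytes() == before


class TestCommands:
    def test_command_file_references_protein_fasta(self, micro_analysis,
                                                   tmp_path):
        report = write_reports(micro_analysis, tmp_path)
        text = report.files[20].read_text()
        assert FILE_NAMES[0] in text

    def test_paths_with_spaces_are_quoted(self, micro_analysis, tmp_path):
        out = tmp_path / "dir with spaces"
        report = write_reports(micro_analysis, out)
        text = report.files[20].read_text()
        assert "'" in text and "dir with spaces" in text

    def test_disabled_command_file_absent(self, micro_analysis, tmp_path):
        write_reports(micro_analysis, tmp_path, enabled=set(range(20)))
        assert not (tmp_path / FILE_NAMES[20]).exists()
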