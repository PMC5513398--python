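"""The numbered output-file suite.

A default run writes exactly 21 files, 00-20: a protein FASTA (00), the
overview (01), per-level data and summary TSVs (02-12), the run manifest
(13), batch TSVs holding one line per analyzed genome (14-19) and a
ready-made shell-command file (20).  All but 00 and 20 are TSV with a
single header row, rows ordered by feature ID, "NA" for missing values.

Formatting is fixed so repeated runs are byte-identical: integers unpadded,
percentages and means/medians with 2 decimals, per-bp densities, coverages
and CpG ratios with 6 decimals (a per-kb convenience column accompanies
each per-bp density).
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import math
import os
import shlex
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from . import __version__
from .aggregation import summarize
from .analysis import GenomeAnalysis
from .errors import BatchHeaderError, GenestatsError
from .metrics import DEFAULT_INTRON_BIN_EDGES, length_histogram
from .sequence_io import write_protein_fasta

FILE_NAMES: dict[int, str] = {
    0: "00_analyzed_transcripts_protein.fasta",
    1: "01_overview.tsv",
    2: "02_scs_data.tsv",
    3: "03_scs_summary.tsv",
    4: "04_gene_data.tsv",
    5: "05_transcript_data.tsv",
    6: "06_transcript_summary.tsv",
    7: "07_cds_data.tsv",
    8: "08_cds_summary.tsv",
    9: "09_exon_data.tsv",
    10: "10_exon_summary.tsv",
    11: "11_intron_data.tsv",
    12: "12_intron_summary.tsv",
    13: "13_run_manifest.tsv",
    14: "14_batch_general.tsv",
    15: "15_batch_scs_means.tsv",
    16: "16_batch_scs_medians.tsv",
    17: "17_batch_transcript_means.tsv",
    18: "18_batch_transcript_medians.tsv",
    19: "19_batch_component_sizes.tsv",
    20: "20_bash_commands.txt",
}

ALL_OUTPUTS = frozenset(FILE_NAMES)

_STR_COLUMNS = {
    "genome_name", "scs_id", "gene_id", "transcript_id", "feature_id",
    "seqid", "strand", "representative_transcript", "transcript_choice",
    "metric", "parameter", "key", "value_kind",
}
_INT_COLUMNS = {
    "start", "end", "phase", "l50", "l75", "l90", "l90pcg",
    "span_matches_gene_row",
}


def column_kind(name: str) -> str:
    """Resolve a column/parameter name to its format kind."""
    if name in _STR_COLUMNS:
        return "str"
    if name in _INT_COLUMNS:
        return "int"
    if name.endswith("_pct"):
        return "pct"
    if "per_bp" in name or "coverage" in name or "cpg_oe" in name:
        return "ratio"
    if "mean" in name or "median" in name or "per_kb" in name:
        return "stat"
    if name.endswith(("_bp", "_aa")) or "count" in name or "strand_" in name:
        return "int"
    return "str"


def format_value(value: object, kind: str) -> str:
    """Render one cell; None/NaN become "NA" and '.' is never used."""
    if value is None:
        return "NA"
    if isinstance(value, float) and math.isnan(value):
        return "NA"
    if kind == "int":
        return str(int(value))
    if kind in ("pct", "stat"):
        return f"{float(value):.2f}"
    if kind == "ratio":
        return f"{float(value):.6f}"
    return str(value)


@dataclass
class ReportSet:
    """Paths of the files a run produced, keyed by file number."""

    out_dir: Path
    files: dict[int, Path]


def _write_tsv(path: Path, header: Sequence[str],
               rows: Iterable[Sequence[str]]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def _table_rows(rows: Sequence[Mapping[str, object]],
                columns: Sequence[str]) -> list[list[str]]:
    kinds = [column_kind(c) for c in columns]
    return [[format_value(r.get(c), k) for c, k in zip(columns, kinds)]
            for r in rows]


#: column order per data table (02/04/05/07/09/11)
SCS_COLUMNS = (
    "scs_id", "length_bp", "length_no_n_bp", "n_count", "ambiguity_count",
    "gc_strict_pct", "gc_naive_pct", "cpg_oe", "gene_count",
    "gene_density_per_bp", "gene_density_per_kb", "gene_coverage",
)
GENE_COLUMNS = (
    "gene_id", "seqid", "strand", "transcript_count",
    "representative_transcript", "gene_length_bp", "gene_row_length_bp",
    "span_matches_gene_row",
)
TRANSCRIPT_COLUMNS = (
    "transcript_id", "gene_id", "seqid", "strand", "genomic_length_bp",
    "spliced_length_bp", "exon_count", "cds_count", "intron_count",
    "exon_length_added_bp", "cds_length_added_bp", "intron_length_added_bp",
    "exon_length_mean_bp", "exon_length_median_bp", "intron_length_mean_bp",
    "intron_length_median_bp", "cds_length_mean_bp", "cds_length_median_bp",
    "intron_density_per_bp", "intron_density_per_kb", "cds_density_per_bp",
    "cds_density_per_kb", "exon_coverage", "intron_coverage", "cds_coverage",
    "gc_strict_spliced_pct", "gc_naive_spliced_pct", "cpg_oe_spliced",
    "gc_strict_introns_pct", "gc_naive_introns_pct", "cpg_oe_introns",
    "protein_length_aa",
)
FEATURE_COLUMNS = (
    "feature_id", "transcript_id", "gene_id", "seqid", "start", "end",
    "strand", "length_bp", "gc_strict_pct", "gc_naive_pct", "cpg_oe",
)
CDS_COLUMNS = FEATURE_COLUMNS + ("phase",)

_SUMMARY_HEADER = ("metric", "count", "total", "min", "max", "mean", "median")


def _summary_rows(rows: Sequence[Mapping[str, object]],
                  columns: Sequence[str]) -> list[list[str]]:
    out = []
    for col in columns:
        kind = column_kind(col)
        if kind == "str":
            continue
        stats = summarize([r.get(col) for r in rows])
        value_kind = "ratio" if kind == "ratio" else ("int" if kind == "int"
                                                      else "stat")
        out.append([
            col,
            format_value(stats.count, "int"),
            format_value(stats.total, value_kind),
            format_value(stats.min, value_kind),
            format_value(stats.max, value_kind),
            format_value(stats.mean, "ratio" if kind == "ratio" else "stat"),
            format_value(stats.median, "ratio" if kind == "ratio" else "stat"),
        ])
    return out


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# batch files

_BATCH_GENERAL_KEYS = (
    "genome_name", "scs_count", "assembly_size_bp", "assembly_size_no_n_bp",
    "assembly_n_count", "assembly_gc_strict_pct", "assembly_gc_naive_pct",
    "assembly_cpg_oe", "n50_bp", "l50", "n75_bp", "l75", "n90_bp", "l90",
    "l90pcg", "gene_count", "transcript_count", "exon_count", "cds_count",
    "intron_count", "coding_amount_bp", "exon_amount_bp", "intron_amount_bp",
)
_BATCH_SCS_KEYS = (
    "length_bp", "length_no_n_bp", "n_count", "gc_strict_pct",
    "gc_naive_pct", "cpg_oe", "gene_count", "gene_density_per_bp",
    "gene_coverage",
)
_BATCH_TX_KEYS = (
    "genomic_length_bp", "spliced_length_bp", "exon_count", "cds_count",
    "intron_count", "exon_length_added_bp", "cds_length_added_bp",
    "intron_length_added_bp", "intron_density_per_bp", "exon_coverage",
    "intron_coverage", "cds_coverage", "gc_strict_spliced_pct",
    "gc_naive_spliced_pct", "cpg_oe_spliced", "protein_length_aa",
)


def _agg_line(rows: Sequence[Mapping[str, object]], keys: Sequence[str],
              which: str) -> list[str]:
    cells = []
    for key in keys:
        stats = summarize([r.get(key) for r in rows])
        value = stats.mean if which == "mean" else stats.median
        kind = "ratio" if column_kind(key) == "ratio" else "stat"
        cells.append(format_value(value, kind))
    return cells


def batch_lines(analysis: GenomeAnalysis) -> dict[int, tuple[list[str], list[str]]]:
    """(header, data line) for each batch file 14-19 of one analyzed genome."""
    ov = analysis.overview
    general = [format_value(ov.get(k), column_kind(k))
               for k in _BATCH_GENERAL_KEYS]
    out: dict[int, tuple[list[str], list[str]]] = {
        14: (list(_BATCH_GENERAL_KEYS), general),
    }
    scs_header = ["genome_name"] + [f"{k}_mean" for k in _BATCH_SCS_KEYS]
    out[15] = (scs_header,
               [analysis.name] + _agg_line(analysis.scs_rows, _BATCH_SCS_KEYS, "mean"))
    out[16] = ([h.replace("_mean", "_median") for h in scs_header],
               [analysis.name] + _agg_line(analysis.scs_rows, _BATCH_SCS_KEYS, "median"))
    tx_header = ["genome_name"] + [f"{k}_mean" for k in _BATCH_TX_KEYS]
    out[17] = (tx_header,
               [analysis.name] + _agg_line(analysis.transcript_rows, _BATCH_TX_KEYS, "mean"))
    out[18] = ([h.replace("_mean", "_median") for h in tx_header],
               [analysis.name] + _agg_line(analysis.transcript_rows, _BATCH_TX_KEYS, "median"))

    assembly = ov["assembly_size_bp"]
    exon_amt = ov.get("exon_amount_bp")
    intron_amt = ov.get("intron_amount_bp")
    remainder = (assembly - exon_amt - intron_amt
                 if exon_amt is not None and intron_amt is not None else None)
    out[19] = (
        ["genome_name", "assembly_size_bp", "coding_amount_bp",
         "exon_amount_bp", "intron_amount_bp", "remainder_bp"],
        [analysis.name,
         format_value(assembly, "int"),
         format_value(ov.get("coding_amount_bp"), "int"),
         format_value(exon_amt, "int"),
         format_value(intron_amt, "int"),
         format_value(remainder, "int")],
    )
    return out


def append_batch(path: Path, header: Sequence[str], row: Sequence[str]) -> None:
    """Append one genome line; create the file (with header) if absent.

    An existing file whose header differs is left untouched and the append
    is refused, so batch files never silently mix column sets.
    """
    if path.exists():
        with open(path, encoding="utf-8") as fh:
            existing = fh.readline().rstrip("\n").split("\t")
        if existing != list(header):
            raise BatchHeaderError(
                f"{path}: existing header does not match current column set; "
                f"refusing to append"
            )
        with open(path, "a", encoding="utf-8", newline="\n") as fh:
            fh.write("\t".join(row) + "\n")
    else:
        _write_tsv(path, header, [row])


# ---------------------------------------------------------------------------
# individual writers

def write_component_sizes(analysis: GenomeAnalysis, path: Path) -> None:
    """Component-size overview: coding/intron/exon amounts and the
    non-exonic, non-intronic remainder, all in bp; their sum (exon +
    intron + remainder) equals the assembly size."""
    header, row = batch_lines(analysis)[19]
    _write_tsv(path, header, [row])


def write_commands(protein_fasta: Path, genome_name: str, path: Path) -> None:
    """Ready-made shell lines for downstream gene-set completeness checks
    (BUSCO on the analyzed-transcript protein FASTA); nothing is executed."""
    fasta = shlex.quote(str(protein_fasta))
    name = shlex.quote(f"{genome_name}_busco")
    lines = [
        "# Ready-made commands for downstream analysis of the analyzed-",
        "# transcript protein set. Adjust the lineage dataset before running.",
        "",
        f"busco -i {fasta} -m proteins -l <lineage_odb10> -o {name}",
        f"seqkit stats {fasta}",
        "",
    ]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines))


def _write_manifest(analysis: GenomeAnalysis, path: Path,
                    date: str | None) -> None:
    rows = [
        ("tool", "genestats"),
        ("version", __version__),
        ("genome_name", analysis.name),
        ("fasta_path", str(analysis.fasta_path)),
        ("fasta_sha256", _sha256(analysis.fasta_path)),
        ("gff3_path", str(analysis.gff3_path)),
        ("gff3_sha256", _sha256(analysis.gff3_path)),
        ("transcript_choice", analysis.transcript_choice),
        ("date", date or _dt.date.today().isoformat()),
        ("genes_analyzed", str(len(analysis.gene_rows))),
        ("genes_skipped_no_mrna", str(analysis.annotation.skipped_count)),
        ("warnings", str(len(analysis.warnings))),
    ]
    rows += [("warning", w) for w in analysis.warnings]
    _write_tsv(path, ("key", "value"), rows)


def write_reports(analysis: GenomeAnalysis, out_dir: str | os.PathLike,
                  enabled: Iterable[int] | None = None,
                  intron_bin_edges: Sequence[int] = DEFAULT_INTRON_BIN_EDGES,
                  date: str | None = None) -> ReportSet:
    """Write the (selected) numbered output files for one analyzed genome.

    *enabled* selects file numbers (default: all 21); the run manifest (13)
    is always written so every run documents its inputs.  *date* overrides
    the manifest date (useful for byte-identical reruns).
    """
    selected = set(ALL_OUTPUTS if enabled is None else enabled) | {13}
    unknown = selected - ALL_OUTPUTS
    if unknown:
        raise GenestatsError(f"unknown output file number(s): {sorted(unknown)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not os.access(out, os.W_OK):
        raise GenestatsError(f"output directory {out} is not writable")

    files: dict[int, Path] = {}

    def path_for(num: int) -> Path:
        files[num] = out / FILE_NAMES[num]
        return files[num]

    if 0 in selected:
        write_protein_fasta(str(path_for(0)), analysis.proteins)
    if 1 in selected:
        kinds = [(k, column_kind(k)) for k in analysis.overview]
        _write_tsv(path_for(1), ("parameter", "value"),
                   [[k, format_value(analysis.overview[k], kind)]
                    for k, kind in kinds])
    data_specs = (
        (2, 3, analysis.scs_rows, SCS_COLUMNS),
        (4, None, analysis.gene_rows, GENE_COLUMNS),
        (5, 6, analysis.transcript_rows, TRANSCRIPT_COLUMNS),
        (7, 8, analysis.cds_rows, CDS_COLUMNS),
        (9, 10, analysis.exon_rows, FEATURE_COLUMNS),
        (11, 12, analysis.intron_rows, FEATURE_COLUMNS),
    )
    for data_num, summary_num, rows, columns in data_specs:
        if data_num in selected:
            _write_tsv(path_for(data_num), columns, _table_rows(rows, columns))
        if summary_num is not None and summary_num in selected:
            summary = _summary_rows(rows, columns)
            if summary_num == 12:
                hist = length_histogram(
                    [r["length_bp"] for r in rows], intron_bin_edges
                ) if rows else None
                edges = tuple(intron_bin_edges)
                for i, edge in enumerate(edges):
                    label = (f"length_bin_{edge}_{edges[i + 1] - 1}_bp"
                             if i + 1 < len(edges) else f"length_bin_ge_{edge}_bp")
                    count = hist.counts[i] if hist else 0
                    summary.append([label, str(count), "NA", "NA", "NA",
                                    "NA", "NA"])
            _write_tsv(path_for(summary_num), _SUMMARY_HEADER, summary)

    _write_manifest(analysis, path_for(13), date)

    lines = batch_lines(analysis)
    for num in (14, 15, 16, 17, 18, 19):
        if num in selected:
            header, row = lines[num]
            _write_tsv(path_for(num), header, [row])
    if 20 in selected:
        write_commands(files.get(0, out / FILE_NAMES[0]), analysis.name,
                       path_for(20))
    return ReportSet(out_dir=out, files=files)
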