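"""Roll metric values up the hierarchy: feature -> transcript -> SCS -> assembly.

Every aggregation produces both means and medians; medians of even-sized
numeric lists are interpolated (mean of the middle two).  That convention is
deliberately different from representative-transcript choice, which must
return an actual transcript.  Aggregates over an empty set are NA (never 0):
an absent value must remain distinguishable from a measured zero.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from . import metrics
from .models import GeneModel, ScaffoldRecord, TranscriptModel

#: hierarchy levels with per-feature tables
LEVELS = ("scs", "gene", "transcript", "cds", "exon", "intron")


@dataclass(frozen=True)
class SummaryStats:
    """count/total/min/max/mean/median bundle; all but count NA when empty."""

    count: int
    total: float | None
    min: float | None
    max: float | None
    mean: float | None
    median: float | None


def summarize(values: Iterable[float | None]) -> SummaryStats:
    """Summary statistics of *values*; None entries are treated as missing."""
    xs = [v for v in values if v is not None]
    if not xs:
        return SummaryStats(0, None, None, None, None, None)
    return SummaryStats(
        count=len(xs),
        total=sum(xs),
        min=min(xs),
        max=max(xs),
        mean=statistics.fmean(xs),
        median=statistics.median(xs),
    )


def _mean(values: Sequence[float | None]) -> float | None:
    xs = [v for v in values if v is not None]
    return statistics.fmean(xs) if xs else None


def _median(values: Sequence[float | None]) -> float | None:
    xs = [v for v in values if v is not None]
    return statistics.median(xs) if xs else None


def per_transcript_rollup(transcript: TranscriptModel,
                          spliced_seq: str,
                          intron_seqs: Sequence[str] = (),
                          protein: str | None = None) -> dict[str, object]:
    """One row of per-transcript metrics for the representative transcript.

    *spliced_seq* is the exon concatenation in translation order;
    *intron_seqs* the individual intron sequences (empty for intron-less
    transcripts; their CpG o/e is pooled segment-wise so no dinucleotide
    spans a junction); *protein* the translated CDS (None when no CDS).
    """
    intron_seq = "".join(intron_seqs)
    exon_lengths = [e.length() for e in transcript.exons]
    intron_lengths = [i.length() for i in transcript.introns]
    cds_lengths = [c.length() for c in transcript.cds_segments]
    genomic_len = transcript.genomic_length
    has_cds = bool(cds_lengths)

    gc_spliced = metrics.gc_content(spliced_seq)
    gc_introns = metrics.gc_content(intron_seq) if intron_seq else None

    row: dict[str, object] = {
        "transcript_id": transcript.id,
        "gene_id": transcript.gene_id,
        "seqid": transcript.seqid,
        "strand": transcript.strand,
        "genomic_length_bp": genomic_len,
        "spliced_length_bp": transcript.spliced_length,
        "exon_count": len(exon_lengths),
        "cds_count": len(cds_lengths) if has_cds else None,
        "intron_count": len(intron_lengths),
        "exon_length_added_bp": sum(exon_lengths),
        "cds_length_added_bp": sum(cds_lengths) if has_cds else None,
        "intron_length_added_bp": sum(intron_lengths),
        "exon_length_mean_bp": _mean(exon_lengths),
        "exon_length_median_bp": _median(exon_lengths),
        "intron_length_mean_bp": _mean(intron_lengths),
        "intron_length_median_bp": _median(intron_lengths),
        "cds_length_mean_bp": _mean(cds_lengths) if has_cds else None,
        "cds_length_median_bp": _median(cds_lengths) if has_cds else None,
        "intron_density_per_bp": metrics.density(len(intron_lengths), genomic_len),
        "cds_density_per_bp": (metrics.density(len(cds_lengths), genomic_len)
                               if has_cds else None),
        "exon_coverage": metrics.coverage(sum(exon_lengths), genomic_len),
        "intron_coverage": metrics.coverage(sum(intron_lengths), genomic_len),
        "cds_coverage": (metrics.coverage(sum(cds_lengths), genomic_len)
                         if has_cds else None),
        "gc_strict_spliced_pct": gc_spliced.gc_strict,
        "gc_naive_spliced_pct": gc_spliced.gc_naive,
        "cpg_oe_spliced": metrics.cpg_oe(spliced_seq),
        "gc_strict_introns_pct": gc_introns.gc_strict if gc_introns else None,
        "gc_naive_introns_pct": gc_introns.gc_naive if gc_introns else None,
        "cpg_oe_introns": (metrics.pooled_cpg_oe(intron_seqs)
                           if intron_seq else None),
        "protein_length_aa": len(protein) if protein is not None else None,
    }
    # derived convenience columns (per kb), kept adjacent to the per-bp values
    row["intron_density_per_kb"] = row["intron_density_per_bp"] * 1000
    row["cds_density_per_kb"] = (row["cds_density_per_bp"] * 1000
                                 if row["cds_density_per_bp"] is not None else None)
    return row


def per_scs_rollup(scs: ScaffoldRecord,
                   genes_on_scs: Sequence[GeneModel]) -> dict[str, object]:
    """One row of per-SCS metrics: composition plus gene content."""
    gc = metrics.gc_content(scs.seq)
    n_count = scs.seq.count("N")
    ambiguity_count = scs.length - gc.denominator_strict - n_count
    gene_lengths = [g.gene_length for g in genes_on_scs]
    gene_total = sum(gene_lengths)
    return {
        "scs_id": scs.id,
        "length_bp": scs.length,
        "length_no_n_bp": scs.length - n_count,
        "n_count": n_count,
        "ambiguity_count": ambiguity_count,
        "gc_strict_pct": gc.gc_strict,
        "gc_naive_pct": gc.gc_naive,
        "cpg_oe": metrics.cpg_oe(scs.seq),
        "gene_count": len(genes_on_scs),
        "gene_density_per_bp": metrics.density(len(genes_on_scs), scs.length),
        "gene_density_per_kb": 1000 * len(genes_on_scs) / scs.length,
        "gene_coverage": (gene_total / scs.length
                          if gene_total <= scs.length else None),
    }


def assembly_rollup(name: str,
                    scs_rows: Sequence[Mapping[str, object]],
                    gene_rows: Sequence[Mapping[str, object]],
                    transcript_rows: Sequence[Mapping[str, object]],
                    cds_rows: Sequence[Mapping[str, object]],
                    exon_rows: Sequence[Mapping[str, object]],
                    intron_rows: Sequence[Mapping[str, object]],
                    assembly_gc: metrics.GCResult,
                    assembly_cpg: float | None,
                    skipped_no_mrna: int = 0,
                    span_discrepancies: int = 0) -> dict[str, object]:
    """The assembly-level overview: the standardized minimum parameter set
    plus contiguity, strandedness and the grand mean/median-of-medians.

    Gene-level aggregates are computed on the representative transcripts
    only; with an empty annotation they are NA while assembly composition
    and contiguity are still produced.
    """

    def col(rows: Sequence[Mapping[str, object]], key: str) -> list:
        return [r[key] for r in rows]

    scs_lengths = col(scs_rows, "length_bp")
    total_n = sum(col(scs_rows, "n_count"))
    contig = metrics.contiguity(scs_lengths)
    genes_per_scs = col(scs_rows, "gene_count")
    total_genes = len(gene_rows)

    ov: dict[str, object] = {
        "genome_name": name,
        "scs_count": len(scs_rows),
        "assembly_size_bp": sum(scs_lengths),
        "assembly_size_no_n_bp": sum(scs_lengths) - total_n,
        "assembly_n_count": total_n,
        "assembly_ambiguity_count": sum(col(scs_rows, "ambiguity_count")),
        "assembly_gc_strict_pct": assembly_gc.gc_strict,
        "assembly_gc_naive_pct": assembly_gc.gc_naive,
        "assembly_cpg_oe": assembly_cpg,
        "n50_bp": contig.n_values[0.50],
        "l50": contig.l_values[0.50],
        "n75_bp": contig.n_values[0.75],
        "l75": contig.l_values[0.75],
        "n90_bp": contig.n_values[0.90],
        "l90": contig.l_values[0.90],
        "l90pcg": metrics.l90pcg(genes_per_scs) if total_genes else None,
        "gene_count": total_genes,
        "genes_skipped_no_mrna": skipped_no_mrna,
        "gene_span_discrepancy_count": span_discrepancies,
        "transcript_count": len(transcript_rows),
        "exon_count": len(exon_rows),
        "cds_count": len(cds_rows),
        "intron_count": len(intron_rows),
    }

    # strandedness of analyzed transcripts and their features
    for label, rows in (("transcript", transcript_rows), ("cds", cds_rows),
                        ("exon", exon_rows), ("intron", intron_rows)):
        plus, minus, unknown = metrics.strandedness(col(rows, "strand"))
        ov[f"{label}_strand_plus"] = plus
        ov[f"{label}_strand_minus"] = minus
        ov[f"{label}_strand_unknown"] = unknown

    # length statistics; "transcript length" is the genomic span of the
    # one representative transcript per gene (= gene length)
    for key, src, column in (
        ("transcript_length", transcript_rows, "genomic_length_bp"),
        ("spliced_length", transcript_rows, "spliced_length_bp"),
        ("exon_length", exon_rows, "length_bp"),
        ("cds_length", cds_rows, "length_bp"),
        ("intron_length", intron_rows, "length_bp"),
        ("protein_length", transcript_rows, "protein_length_aa"),
    ):
        values = col(src, column)
        ov[f"{key}_mean" + ("_aa" if key == "protein_length" else "_bp")] = _mean(values)
        ov[f"{key}_median" + ("_aa" if key == "protein_length" else "_bp")] = _median(values)

    # per-transcript count/density/coverage aggregates
    for key, column in (
        ("exon_count_per_transcript", "exon_count"),
        ("cds_count_per_transcript", "cds_count"),
        ("intron_count_per_transcript", "intron_count"),
        ("intron_density_per_gene_per_bp", "intron_density_per_bp"),
        ("cds_density_per_gene_per_bp", "cds_density_per_bp"),
        ("exon_coverage_per_gene", "exon_coverage"),
        ("intron_coverage_per_gene", "intron_coverage"),
        ("cds_coverage_per_gene", "cds_coverage"),
    ):
        values = col(transcript_rows, column)
        ov[f"{key}_mean"] = _mean(values)
        ov[f"{key}_median"] = _median(values)

    # grand mean/median of per-transcript means and medians (skew-sensitive:
    # on right-skewed length data the mean of means exceeds the mean of medians)
    for feat in ("exon", "intron"):
        means = col(transcript_rows, f"{feat}_length_mean_bp")
        medians = col(transcript_rows, f"{feat}_length_median_bp")
        ov[f"{feat}_length_mean_of_transcript_means_bp"] = _mean(means)
        ov[f"{feat}_length_mean_of_transcript_medians_bp"] = _mean(medians)
        ov[f"{feat}_length_median_of_transcript_medians_bp"] = _median(medians)

    cds_added = col(transcript_rows, "cds_length_added_bp")
    ov["coding_amount_bp"] = (sum(v for v in cds_added if v is not None)
                              if any(v is not None for v in cds_added) else None)
    ov["exon_amount_bp"] = (sum(col(transcript_rows, "exon_length_added_bp"))
                            if transcript_rows else None)
    ov["intron_amount_bp"] = (sum(col(transcript_rows, "intron_length_added_bp"))
                              if transcript_rows else None)
    ov["gene_length_mean_bp"] = _mean(col(gene_rows, "gene_length_bp"))
    ov["gene_length_median_bp"] = _median(col(gene_rows, "gene_length_bp"))
    return ov
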