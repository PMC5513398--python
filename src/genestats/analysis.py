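"""End-to-end single-genome analysis: parse -> link -> infer -> select ->
metrics -> aggregate.  The result object feeds the report writers and the
batch machinery; the CLI is a thin wrapper around :func:`analyze_genome`."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from . import aggregation, metrics
from .annotation_io import ParsedAnnotation, parse_gff3, select_representative
from .errors import CoordinateError, TranslationError
from .models import GeneModel, ScaffoldRecord
from .sequence_io import (extract_sequence, parse_fasta, spliced_sequence,
                          translate_representative)

logger = logging.getLogger(__name__)

Row = dict[str, object]


@dataclass
class GenomeAnalysis:
    """All level tables, the overview, and the analyzed-transcript proteins."""

    name: str
    transcript_choice: str
    fasta_path: str
    gff3_path: str
    scaffolds: list[ScaffoldRecord]
    annotation: ParsedAnnotation
    scs_rows: list[Row] = field(default_factory=list)
    gene_rows: list[Row] = field(default_factory=list)
    transcript_rows: list[Row] = field(default_factory=list)
    cds_rows: list[Row] = field(default_factory=list)
    exon_rows: list[Row] = field(default_factory=list)
    intron_rows: list[Row] = field(default_factory=list)
    overview: dict[str, object] = field(default_factory=dict)
    proteins: list[tuple[str, str, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def _feature_row(feature_id: str, interval, transcript_id: str, gene_id: str,
                 seq: str) -> Row:
    gc = metrics.gc_content(seq)
    return {
        "feature_id": feature_id,
        "transcript_id": transcript_id,
        "gene_id": gene_id,
        "seqid": interval.seqid,
        "start": interval.start,
        "end": interval.end,
        "strand": interval.strand,
        "length_bp": interval.length(),
        "gc_strict_pct": gc.gc_strict,
        "gc_naive_pct": gc.gc_naive,
        "cpg_oe": metrics.cpg_oe(seq),
    }


def _assembly_composition(scaffolds) -> tuple[metrics.GCResult, float | None]:
    """Assembly-wide GC (counts are additive) and segment-pooled CpG o/e."""
    gc = metrics.gc_content("".join(s.seq for s in scaffolds))
    cpg = metrics.pooled_cpg_oe(s.seq for s in scaffolds)
    return gc, cpg


def analyze_genome(fasta_path: str, gff3_path: str, name: str,
                   transcript_choice: str = "longest") -> GenomeAnalysis:
    """Analyze one genome: assembly FASTA + protein-coding gene GFF3.

    Per gene exactly one representative transcript (chosen by
    *transcript_choice*) is measured; per-feature tables cover the
    representative transcripts' exons, CDSs and inferred introns.
    """
    scaffolds = parse_fasta(fasta_path)
    by_id = {s.id: s for s in scaffolds}
    annotation = parse_gff3(gff3_path)
    result = GenomeAnalysis(name=name, transcript_choice=transcript_choice,
                            fasta_path=fasta_path, gff3_path=gff3_path,
                            scaffolds=scaffolds, annotation=annotation)
    if annotation.skipped_no_mrna:
        result.warnings.append(
            f"{len(annotation.skipped_no_mrna)} gene(s) without mRNA skipped"
        )
    if annotation.zero_gap_transcripts:
        result.warnings.append(
            f"{len(annotation.zero_gap_transcripts)} transcript(s) with "
            f"zero-gap adjacent exons (no intron emitted)"
        )

    genes_by_scs: dict[str, list[GeneModel]] = {s.id: [] for s in scaffolds}
    span_discrepancies = 0

    for gene in annotation.genes:
        if gene.seqid not in by_id:
            raise CoordinateError(
                f"gene {gene.id}: seqid {gene.seqid!r} present in GFF3 but "
                f"absent from the FASTA assembly"
            )
        scs = by_id[gene.seqid]
        rep = select_representative(gene, transcript_choice)
        genes_by_scs[gene.seqid].append(gene)

        span = rep.genomic_span
        if (gene.row_start, gene.row_end) != (span.start, span.end):
            span_discrepancies += 1
        result.gene_rows.append({
            "gene_id": gene.id,
            "seqid": gene.seqid,
            "strand": gene.strand,
            "transcript_count": len(gene.transcripts),
            "representative_transcript": rep.id,
            "gene_length_bp": gene.gene_length,
            "gene_row_length_bp": gene.row_end - gene.row_start + 1,
            "span_matches_gene_row": int((gene.row_start, gene.row_end)
                                         == (span.start, span.end)),
        })

        spliced = spliced_sequence(rep, scs)
        intron_seqs = [extract_sequence(scs, i) for i in rep.introns]
        protein = None
        if rep.cds_segments:
            try:
                protein = translate_representative(rep, scs)
                result.proteins.append((gene.id, rep.id, protein))
                if "*" in protein:
                    result.warnings.append(
                        f"transcript {rep.id}: internal stop codon(s)"
                    )
            except TranslationError as exc:
                result.warnings.append(str(exc))
        result.transcript_rows.append(
            aggregation.per_transcript_rollup(rep, spliced, intron_seqs, protein)
        )
        for i, exon in enumerate(rep.exons, start=1):
            result.exon_rows.append(_feature_row(
                f"{rep.id}.exon.{i}", exon, rep.id, gene.id,
                extract_sequence(scs, exon)))
        for i, cds in enumerate(rep.cds_segments, start=1):
            row = _feature_row(f"{rep.id}.cds.{i}", cds, rep.id, gene.id,
                               extract_sequence(scs, cds))
            row["phase"] = cds.phase if cds.phase is not None else 0
            result.cds_rows.append(row)
        for i, intron in enumerate(rep.introns, start=1):
            result.intron_rows.append(_feature_row(
                f"{rep.id}.intron.{i}", intron, rep.id, gene.id,
                extract_sequence(scs, intron)))

    for scs in scaffolds:
        result.scs_rows.append(
            aggregation.per_scs_rollup(scs, genes_by_scs[scs.id]))

    # stable ordering by feature ID for every data table
    result.scs_rows.sort(key=lambda r: r["scs_id"])
    result.gene_rows.sort(key=lambda r: r["gene_id"])
    result.transcript_rows.sort(key=lambda r: r["transcript_id"])
    for rows in (result.cds_rows, result.exon_rows, result.intron_rows):
        rows.sort(key=lambda r: r["feature_id"])
    result.proteins.sort(key=lambda p: p[0])

    assembly_gc, assembly_cpg = _assembly_composition(scaffolds)
    result.overview = aggregation.assembly_rollup(
        name=name,
        scs_rows=result.scs_rows,
        gene_rows=result.gene_rows,
        transcript_rows=result.transcript_rows,
        cds_rows=result.cds_rows,
        exon_rows=result.exon_rows,
        intron_rows=result.intron_rows,
        assembly_gc=assembly_gc,
        assembly_cpg=assembly_cpg,
        skipped_no_mrna=annotation.skipped_count,
        span_discrepancies=span_discrepancies,
    )
    result.overview["transcript_choice"] = transcript_choice
    return result
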