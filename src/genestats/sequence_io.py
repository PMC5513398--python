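"""FASTA parsing, feature-sequence extraction and CDS translation.

Sequences are uppercased on input (soft-masking is annotation, not
composition) and U is mapped to T.  Reverse complement and translation are
delegated to Biopython; translation always uses the standard genetic code.
"""

from __future__ import annotations

import logging

from Bio.Seq import Seq
from Bio import SeqIO

from .errors import CoordinateError, FastaParseError, TranslationError
from .models import GenomicInterval, ScaffoldRecord, TranscriptModel

logger = logging.getLogger(__name__)

IUPAC_NUC = frozenset("ACGTNRYKMSWBDHV")


def parse_fasta(path: str) -> list[ScaffoldRecord]:
    """Read a (possibly line-wrapped) nucleotide FASTA into ScaffoldRecords.

    IDs are the first whitespace-delimited header token; duplicates and
    non-IUPAC characters are fatal, with the record and position named.
    """
    records: list[ScaffoldRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seen:
            raise FastaParseError(f"duplicate sequence ID {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise FastaParseError(f"empty sequence under header {rec.id!r}")
        bad = next((i for i, ch in enumerate(seq) if ch not in IUPAC_NUC), None)
        if bad is not None:
            raise FastaParseError(
                f"non-IUPAC character {seq[bad]!r} at position {bad + 1} "
                f"of record {rec.id!r}"
            )
        records.append(ScaffoldRecord(rec.id, seq))
    if not records:
        raise FastaParseError(f"no FASTA records found in {path}")
    return records


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement (R<->Y, K<->M, B<->V, D<->H, S/W/N fixed)."""
    return str(Seq(seq).reverse_complement())


def extract_sequence(scs: ScaffoldRecord, interval: GenomicInterval) -> str:
    """Subsequence of *scs* at a 1-based inclusive interval, minus strand
    returned as reverse complement."""
    if interval.seqid != scs.id:
        raise CoordinateError(
            f"interval seqid {interval.seqid!r} does not match SCS {scs.id!r}"
        )
    if interval.end > scs.length:
        raise CoordinateError(
            f"interval {interval.start}..{interval.end} exceeds length "
            f"{scs.length} of SCS {scs.id!r}"
        )
    sub = scs.seq[interval.start - 1 : interval.end]
    return reverse_complement(sub) if interval.strand == "-" else sub


def spliced_sequence(transcript: TranscriptModel, scs: ScaffoldRecord) -> str:
    """The mRNA sequence: exons concatenated in translation order."""
    parts = [extract_sequence(scs, e) for e in transcript.exons]
    if transcript.strand == "-":
        parts.reverse()
    return "".join(parts)


def coding_sequence(transcript: TranscriptModel, scs: ScaffoldRecord) -> str:
    """CDS segments concatenated in translation order, phase-trimmed.

    Segments are taken ascending-coordinate for + and descending for -,
    each strand-extracted; the first segment's phase bases are skipped.
    Later phases are checked against the running frame and a mismatch is
    only warned about (annotation phases are frequently inconsistent).
    """
    segs = sorted(transcript.cds_segments, key=lambda c: c.start,
                  reverse=transcript.strand == "-")
    if not segs:
        raise TranslationError(f"transcript {transcript.id}: no CDS segments")
    pieces: list[str] = []
    consumed = 0
    for i, seg in enumerate(segs):
        expected_phase = (3 - consumed % 3) % 3
        if i > 0 and seg.phase is not None and seg.phase != expected_phase:
            logger.warning(
                "transcript %s: CDS segment %d..%d declares phase %d, "
                "running frame implies %d; declared phase ignored",
                transcript.id, seg.start, seg.end, seg.phase, expected_phase,
            )
        pieces.append(extract_sequence(scs, seg))
        consumed += seg.length()
    cds = "".join(pieces)
    phase = segs[0].phase or 0
    return cds[phase:]


def translate_representative(transcript: TranscriptModel,
                             scs: ScaffoldRecord) -> str:
    """Protein of the transcript's CDS under the standard genetic code.

    The trailing incomplete codon is dropped, one terminal stop (if present)
    is trimmed, and internal stops appear as '*' with a warning.
    """
    cds = coding_sequence(transcript, scs)
    cds = cds[: len(cds) - len(cds) % 3]
    if len(cds) < 3:
        raise TranslationError(
            f"transcript {transcript.id}: CDS shorter than one codon "
            f"after phase trimming"
        )
    protein = str(Seq(cds).translate(table=1))
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        logger.warning(
            "transcript %s: %d internal stop codon(s) in translation",
            transcript.id, protein.count("*"),
        )
    return protein


def write_protein_fasta(path: str,
                        entries: list[tuple[str, str, str]],
                        width: int = 60) -> None:
    """Write (gene_id, transcript_id, protein) triples as a protein FASTA;
    header is ``>gene_id transcript_id``."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for gene_id, tx_id, protein in entries:
            fh.write(f">{gene_id} {tx_id}\n")
            for i in range(0, len(protein), width):
                fh.write(protein[i : i + width] + "\n")
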