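"""Domain types shared across the package.

Coordinates are 1-based inclusive throughout (GFF3 native); every length is
``end - start + 1``.  A genome is a set of scaffold-or-contig sequences
(SCSs); the annotation is a gene -> mRNA -> exon/CDS hierarchy in which
introns are never parsed but always inferred from exon gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConsistencyError

STRANDS = ("+", "-", "?")


@dataclass(frozen=True)
class GenomicInterval:
    """A strand-aware 1-based inclusive interval on one SCS."""

    seqid: str
    start: int
    end: int
    strand: str = "?"
    phase: int | None = None  # only meaningful for CDS segments

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ConsistencyError(
                f"interval start must be >= 1, got {self.start} on {self.seqid}"
            )
        if self.end < self.start:
            raise ConsistencyError(
                f"interval end {self.end} < start {self.start} on {self.seqid}"
            )
        if self.strand not in STRANDS:
            raise ConsistencyError(f"unknown strand {self.strand!r}")
        if self.phase is not None and self.phase not in (0, 1, 2):
            raise ConsistencyError(f"phase must be 0/1/2, got {self.phase}")

    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class TranscriptModel:
    """One mRNA: ordered exons, optional CDS segments, derived introns.

    ``introns`` is filled by :func:`genestats.annotation_io.infer_introns`;
    ``genomic_span`` covers first exon start to last exon end.
    """

    id: str
    gene_id: str
    exons: list[GenomicInterval] = field(default_factory=list)
    cds_segments: list[GenomicInterval] = field(default_factory=list)
    introns: list[GenomicInterval] = field(default_factory=list)

    @property
    def seqid(self) -> str:
        return self.exons[0].seqid

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def genomic_span(self) -> GenomicInterval:
        return GenomicInterval(
            self.seqid, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def genomic_length(self) -> int:
        """Span length including introns ("gene length")."""
        return self.genomic_span.length()

    @property
    def spliced_length(self) -> int:
        """Summed exon length (mRNA length); the representative-choice criterion."""
        return sum(e.length() for e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(c.length() for c in self.cds_segments)

    @property
    def intron_length(self) -> int:
        return sum(i.length() for i in self.introns)


@dataclass
class GeneModel:
    """A protein-coding gene and its analyzed representative transcript."""

    id: str
    transcripts: list[TranscriptModel]
    seqid: str
    strand: str
    # coordinates of the `gene` row itself, kept to report span discrepancies
    row_start: int = 0
    row_end: int = 0
    representative: TranscriptModel | None = None

    @property
    def gene_length(self) -> int:
        """Genomic length of the representative transcript, introns included."""
        if self.representative is None:
            raise ConsistencyError(f"gene {self.id}: no representative selected")
        return self.representative.genomic_length


@dataclass(frozen=True)
class ScaffoldRecord:
    """One assembled SCS: FASTA id (first whitespace-delimited token) + sequence."""

    id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)
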