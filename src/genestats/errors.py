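"""Exception hierarchy.

Every fatal condition has a named exception so the CLI can report it and
exit non-zero, and so tests can assert on the precise failure mode.
"""


class GenestatsError(Exception):
    """Base class for all package errors."""


class FastaParseError(GenestatsError):
    """Malformed FASTA: empty sequence, duplicate ID, non-IUPAC character."""


class GffParseError(GenestatsError):
    """Malformed GFF3 line (e.g. wrong column count); names the line number."""


class HierarchyError(GenestatsError):
    """Broken gene->mRNA->exon linkage (orphan mRNA, duplicate gene ID)."""


class ConsistencyError(GenestatsError):
    """Internally contradictory coordinates (overlapping exons, mixed
    seqids/strands within one transcript, covered length > container)."""


class CoordinateError(GenestatsError):
    """Interval outside the bounds of its scaffold sequence."""


class TranslationError(GenestatsError):
    """CDS too short to translate after phase trimming."""


class UndefinedInputError(GenestatsError):
    """A metric kernel received input for which the quantity is undefined
    (empty sequence, empty length multiset, zero total)."""


class ConfigError(GenestatsError):
    """Invalid run or fixture configuration."""


class BatchHeaderError(GenestatsError):
    """Existing batch file has an incompatible header; nothing appended."""
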