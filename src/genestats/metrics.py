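"""Pure metric kernels: composition, contiguity, density/coverage, strandedness.

Each function is total over its stated domain and raises
:class:`~genestats.errors.UndefinedInputError` outside it.  Nothing here
touches files or models; inputs are plain sequences and number collections,
so every kernel can be checked against brute-force oracles.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import ConfigError, ConsistencyError, UndefinedInputError

#: IUPAC codes that make a position ambiguous *for GC purposes*.  S (G or C)
#: and W (A or T) are unambiguous for GC and stay in the strict denominator.
GC_AMBIGUOUS = frozenset("NRYKMBDHV")

#: Default intron-length histogram bin edges (decade boundaries, bp).
DEFAULT_INTRON_BIN_EDGES = (1, 10, 100, 1_000, 10_000, 100_000)


@dataclass(frozen=True)
class GCResult:
    """GC percentage computed two ways.

    ``gc_strict`` counts G+C+S over positions unambiguous for GC (total
    length minus N,R,Y,K,M,B,D,H,V); ``gc_naive`` counts G+C over the total
    length.  ``gc_strict`` is None when no unambiguous position exists.
    """

    gc_strict: float | None
    gc_naive: float
    denominator_strict: int
    denominator_total: int


@dataclass(frozen=True)
class ContiguityResult:
    """Nx/Lx for fractions 0.50/0.75/0.90 plus L90pcG (gene-weighted)."""

    n_values: Mapping[float, int]
    l_values: Mapping[float, int]
    l90pcg: int | None = None


@dataclass(frozen=True)
class LengthDistribution:
    """Half-open histogram [e_i, e_{i+1}) with a final overflow bin."""

    bin_edges: tuple[int, ...]
    counts: tuple[int, ...]


def gc_content(seq: str) -> GCResult:
    """Composition of *seq* as a :class:`GCResult`.

    Strict GC excludes positions whose base call is ambiguous for GC
    (N,R,Y,K,M,B,D,H,V) from the denominator and counts S in the numerator;
    naive GC is plain (G+C)/length and depends on assembly quality.
    """
    if not seq:
        raise UndefinedInputError("gc_content: empty sequence")
    counts = Counter(seq.upper())
    total = len(seq)
    ambiguous = sum(counts[c] for c in GC_AMBIGUOUS)
    denom_strict = total - ambiguous
    gc_strict_count = counts["G"] + counts["C"] + counts["S"]
    gc_naive = 100.0 * (counts["G"] + counts["C"]) / total
    gc_strict = 100.0 * gc_strict_count / denom_strict if denom_strict else None
    return GCResult(gc_strict, gc_naive, denom_strict, total)


def cpg_oe(seq: str) -> float | None:
    """CpG observed/expected: obs(CG) * L / (#C * #G); None if #C or #G is 0.

    Values well below 1 indicate CpG depletion (e.g. through methylation-
    driven CpG decay).
    """
    if not seq:
        raise UndefinedInputError("cpg_oe: empty sequence")
    s = seq.upper()
    c, g = s.count("C"), s.count("G")
    if c == 0 or g == 0:
        return None
    observed = s.count("CG")
    return observed * len(s) / (c * g)


def pooled_cpg_oe(seqs: Iterable[str]) -> float | None:
    """CpG o/e over a pool of segments, counted segment-wise.

    Observed CG, #C, #G and length are summed per segment so that no
    spurious dinucleotide spanning a segment junction is counted; the
    ratio then follows the same obs * L / (#C * #G) normalization.
    """
    observed = c = g = total = 0
    for seq in seqs:
        s = seq.upper()
        observed += s.count("CG")
        c += s.count("C")
        g += s.count("G")
        total += len(s)
    if total == 0:
        raise UndefinedInputError("pooled_cpg_oe: no sequence")
    if c == 0 or g == 0:
        return None
    return observed * total / (c * g)


def nx_lx(lengths: Iterable[int], fraction: float) -> tuple[int, int]:
    """(Nx, Lx) of a length multiset.

    Sort descending; Nx is the first length at which the running sum reaches
    ``fraction`` of the total, Lx the number of sequences consumed.  Nx is
    always a member of the input multiset (no interpolation).
    """
    ordered = sorted(lengths, reverse=True)
    if not ordered:
        raise UndefinedInputError("nx_lx: empty length collection")
    if not 0.0 < fraction < 1.0:
        raise ConfigError(f"nx_lx: fraction must be in (0,1), got {fraction}")
    target = fraction * sum(ordered)
    running = 0
    for i, length in enumerate(ordered, start=1):
        running += length
        if running >= target:
            return length, i
    raise AssertionError("unreachable: running sum must reach the target")


def contiguity(lengths: Iterable[int],
               fractions: Sequence[float] = (0.50, 0.75, 0.90)) -> ContiguityResult:
    """Nx/Lx at each fraction, bundled."""
    ordered = list(lengths)
    n_values, l_values = {}, {}
    for f in fractions:
        n_values[f], l_values[f] = nx_lx(ordered, f)
    return ContiguityResult(n_values, l_values)


def l90pcg(genes_per_scs: Iterable[int]) -> int:
    """SCSs needed, in decreasing order of gene content, to hold >= 90% of genes.

    The 90% target is the ceiling of 0.9 * total: "cover 90%" must be met
    with whole genes.  SCSs with zero genes are never needed.
    """
    counts = sorted(genes_per_scs, reverse=True)
    total = sum(counts)
    if total <= 0:
        raise UndefinedInputError("l90pcg: no genes on any SCS")
    target = math.ceil(0.9 * total)
    running = 0
    for i, c in enumerate(counts, start=1):
        running += c
        if running >= target:
            return i
    raise AssertionError("unreachable: cumulative sum reaches the total")


def density(count_of_contained: int, container_length: int) -> float:
    """Number-wise containment: contained-feature count per bp of container."""
    if container_length <= 0:
        raise UndefinedInputError("density: container length must be positive")
    return count_of_contained / container_length


def coverage(covered_length: int, container_length: int) -> float:
    """Length-wise containment: summed contained length over container length."""
    if container_length <= 0:
        raise UndefinedInputError("coverage: container length must be positive")
    if covered_length > container_length:
        raise ConsistencyError(
            f"coverage: covered length {covered_length} exceeds container "
            f"{container_length} (coordinate corruption?)"
        )
    return covered_length / container_length


def strandedness(strands: Iterable[str]) -> tuple[int, int, int]:
    """(plus, minus, unknown) tallies; any label other than +/- is unknown."""
    plus = minus = unknown = 0
    for s in strands:
        if s == "+":
            plus += 1
        elif s == "-":
            minus += 1
        else:
            unknown += 1
    return plus, minus, unknown


def length_histogram(lengths: Iterable[int],
                     bin_edges: Sequence[int] = DEFAULT_INTRON_BIN_EDGES
                     ) -> LengthDistribution:
    """Histogram with half-open bins [e_i, e_{i+1}) plus an overflow bin.

    A value below the first edge falls in the first bin; conservation
    (sum of counts == number of inputs) holds by construction.
    """
    edges = tuple(bin_edges)
    if any(b >= a for b, a in zip(edges, edges[1:])):
        raise ConfigError("length_histogram: bin edges must be strictly increasing")
    if not edges:
        raise ConfigError("length_histogram: at least one bin edge required")
    counts = [0] * len(edges)
    for x in lengths:
        idx = 0
        for j, edge in enumerate(edges):
            if x >= edge:
                idx = j
            else:
                break
        counts[idx] += 1
    return LengthDistribution(edges, tuple(counts))
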