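"""Kernel unit tests: worked examples plus property tests against
brute-force oracles."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from genestats import metrics
from genestats.errors import ConfigError, ConsistencyError, UndefinedInputError
from genestats.sequence_io import reverse_complement

IUPAC = "ACGTNRYKMSWBDHV"


# ---------------------------------------------------------------------------
# worked examples

@pytest.mark.parametrize("seq, strict, naive", [
    ("GCGC", 100.0, 100.0),
    ("GCSN", 100.0, 50.0),          # S counts as GC; N leaves the strict denom
    ("ATWN", 0.0, 0.0),             # W stays in the strict denominator
    ("ACGT", 50.0, 50.0),
])
def test_gc_content_examples(seq, strict, naive):
    result = metrics.gc_content(seq)
    assert result.gc_strict == pytest.approx(strict)
    assert result.gc_naive == pytest.approx(naive)


def test_gc_content_all_ambiguous_has_undefined_strict():
    result = metrics.gc_content("NNNN")
    assert result.gc_strict is None
    assert result.gc_naive == 0.0
    assert result.denominator_strict == 0


def test_gc_content_empty_sequence_rejected():
    with pytest.raises(UndefinedInputError):
        metrics.gc_content("")


@pytest.mark.parametrize("seq, expected", [
    ("CGCG", 2.0),   # 2 CG dinucleotides, #C=#G=2, L=4
    ("CCGG", 1.0),
    ("AAAA", None),  # no C, no G: undefined
    ("CCCC", None),  # G absent: undefined
])
def test_cpg_oe_examples(seq, expected):
    assert metrics.cpg_oe(seq) == (pytest.approx(expected)
                                   if expected is not None else None)


@pytest.mark.parametrize("lengths, fraction, nx, lx", [
    ([10, 8, 5, 3, 2], 0.5, 8, 2),
    ([7], 0.5, 7, 1),
    ([7], 0.9, 7, 1),
    ([10, 8, 5, 3, 2], 0.9, 3, 4),
])
def test_nx_lx_examples(lengths, fraction, nx, lx):
    assert metrics.nx_lx(lengths, fraction) == (nx, lx)


@pytest.mark.parametrize("counts, expected", [
    ([5, 3, 2], 3),        # total 10, target 9, cumulative 5,8,10
    ([10], 1),
    ([4, 4, 1, 1, 0], 3),  # cumulative 4,8,9 reaches ceil(0.9*10)=9
])
def test_l90pcg_examples(counts, expected):
    assert metrics.l90pcg(counts) == expected


@pytest.mark.parametrize("count, length, expected", [
    (4, 1000, 0.004),
    (0, 123, 0.0),
    (1, 500, 0.002),
])
def test_density_examples(count, length, expected):
    assert metrics.density(count, length) == pytest.approx(expected)


def test_coverage_examples():
    assert metrics.coverage(300, 1000) == pytest.approx(0.3)
    assert metrics.coverage(1000, 1000) == pytest.approx(1.0)
    with pytest.raises(ConsistencyError):
        metrics.coverage(1001, 1000)


def test_strandedness_partitions_input():
    assert metrics.strandedness(["+", "+", "-"]) == (2, 1, 0)
    assert metrics.strandedness([]) == (0, 0, 0)
    assert metrics.strandedness(["+", ".", "?"]) == (1, 0, 2)


def test_length_histogram_examples():
    hist = metrics.length_histogram([5, 50, 500], [1, 10, 100])
    assert hist.counts == (1, 1, 1)
    # a value on an edge opens that bin (half-open convention)
    assert metrics.length_histogram([10], [1, 10, 100]).counts == (0, 1, 0)
    with pytest.raises(ConfigError):
        metrics.length_histogram([5], [10, 10])


def test_undefined_inputs_rejected():
    with pytest.raises(UndefinedInputError):
        metrics.nx_lx([], 0.5)
    with pytest.raises(UndefinedInputError):
        metrics.l90pcg([0, 0])
    with pytest.raises(UndefinedInputError):
        metrics.density(1, 0)
    with pytest.raises(UndefinedInputError):
        metrics.coverage(0, 0)


# ---------------------------------------------------------------------------
# properties

@given(st.text(alphabet="ACGTSW", min_size=1, max_size=200))
def test_gc_strict_equals_naive_without_ambiguity(seq):
    """In the clean limit (no N/R/Y/K/M/B/D/H/V) both GC variants agree
    ... except that S, unambiguous for GC, is counted only by the strict
    variant; restrict to ACGT-W for full equality."""
    result = metrics.gc_content(seq.replace("S", "G"))
    assert result.gc_strict == pytest.approx(result.gc_naive)


@given(st.text(alphabet="ACGT", min_size=1, max_size=200))
def test_cpg_oe_invariant_under_reverse_complement(seq):
    """CG is its own reverse complement, and #C/#G swap symmetrically."""
    a = metrics.cpg_oe(seq)
    b = metrics.cpg_oe(reverse_complement(seq))
    if a is None:
        assert b is None
    else:
        assert a == pytest.approx(b)


@given(st.lists(st.integers(min_value=1, max_value=10_000), min_size=1,
                max_size=100),
       st.sampled_from([0.5, 0.75, 0.9]))
def test_nx_lx_matches_exhaustive_oracle(lengths, fraction):
    ordered = sorted(lengths, reverse=True)
    total = sum(ordered)
    expected = None
    for i in range(1, len(ordered) + 1):  # scan all prefixes
        if sum(ordered[:i]) >= fraction * total:
            expected = (ordered[i - 1], i)
            break
    assert metrics.nx_lx(lengths, fraction) == expected
    nx, _ = expected
    assert nx in lengths  # Nx is a member of the multiset


@given(st.lists(st.integers(min_value=0, max_value=50), min_size=1,
                max_size=40).filter(lambda xs: sum(xs) > 0))
def test_l90pcg_against_oracle_and_bounds(counts):
    ordered = sorted(counts, reverse=True)
    target = math.ceil(0.9 * sum(ordered))
    expected = next(i for i in range(1, len(ordered) + 1)
                    if sum(ordered[:i]) >= target)
    got = metrics.l90pcg(counts)
    assert got == expected
    assert got <= sum(1 for c in counts if c > 0)


def test_l90pcg_non_increasing_when_concentrating_genes():
    """Moving a gene onto the fullest SCS (total fixed) cannot raise L90pcG."""
    counts = [6, 3, 3, 2, 1]
    before = metrics.l90pcg(counts)
    after = metrics.l90pcg([7, 3, 3, 2, 0])
    assert after <= before


@given(st.lists(st.integers(min_value=1, max_value=200_000), min_size=0,
                max_size=500))
def test_length_histogram_conserves_counts(lengths):
    hist = metrics.length_histogram(lengths)
    assert sum(hist.counts) == len(lengths)


@given(st.lists(st.integers(min_value=1, max_value=10_000), min_size=1,
                max_size=50))
def test_contiguity_ordering_invariants(lengths):
    result = metrics.contiguity(lengths)
    assert result.n_values[0.50] >= result.n_values[0.75] >= result.n_values[0.90]
    assert result.l_values[0.50] <= result.l_values[0.75] <= result.l_values[0.90]


@given(st.lists(st.text(alphabet="ACGT", min_size=1, max_size=50),
                min_size=1, max_size=10))
def test_pooled_cpg_counts_no_junction_dinucleotides(segments):
    """Pooled o/e over segments equals the ratio built from per-segment
    tallies, never from the concatenation."""
    obs = sum(s.count("CG") for s in segments)
    c = sum(s.count("C") for s in segments)
    g = sum(s.count("G") for s in segments)
    total = sum(len(s) for s in segments)
    expected = obs * total / (c * g) if c and g else None
    got = metrics.pooled_cpg_oe(segments)
    assert got == (pytest.approx(expected) if expected is not None else None)
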