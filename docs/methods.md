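# Methods

`genestats` characterizes a genome assembly together with its
protein-coding gene annotation. This note records the definitions the
package computes, the conventions it fixes where the field has more than
one, and what the synthetic test genomes do and do not establish.

## Inputs and the feature hierarchy

A run consumes a nucleotide FASTA of scaffold-or-contig sequences (SCSs)
and a GFF3 annotation that contains at least `gene`, `mRNA` and `exon`
features linked through `ID`/`Parent` attributes; `CDS` rows are optional.
Genes without any `mRNA` child (non-coding genes) are skipped and counted,
never silently dropped. All coordinates are held 1-based inclusive, GFF3's
native convention, and every length is `end − start + 1`; no conversion to
half-open coordinates happens anywhere, which removes the usual off-by-one
churn at the format boundary.

Introns are not read from the file — most annotation pipelines do not
write them — but inferred from exon gaps: adjacent exons `(e_i, e_{i+1})`
with a gap of at least 1 bp yield the intron `[e_i.end+1, e_{i+1}.start−1]`.
A zero-length gap yields no intron and a warning. Overlapping exons within
one transcript, or exons spanning multiple scaffolds or strands
(trans-splicing), are rejected with named errors: they are outside the
model this package implements. `gene` rows that share one ID
(discontinuous genes) are likewise rejected.

## The representative transcript

All per-gene metrics derive from exactly one representative transcript per
gene, so alternative isoforms never enter aggregates as pseudo-replicates.
The default choice is the *longest* transcript, where length is the summed
exon (spliced mRNA) length, not the genomic span — robust to single huge
introns and the common practice in comparative work; `shortest` and
`median` are alternatives. The median of an even number of transcripts is
the lower-middle element of the length-sorted list, because the choice
must be an actual transcript; ties break on the lexicographically smallest
transcript ID so runs are deterministic. "Gene length" throughout means
the genomic span of the representative transcript, introns included. When
that span differs from the `gene` row's own coordinates (it can, when
another isoform extends further), the representative span wins and the
discrepancy count is reported in the overview.

## Metric definitions

**GC content** is reported two ways. The strict variant counts G+C+S over
all positions that are unambiguous *for GC*: the denominator is total
length minus the count of N, R, Y, K, M, B, D, H and V. S (G or C) is
certain GC and counts in both numerator and denominator; W (A or T) is
certain non-GC and stays in the denominator. The naive variant is plain
(G+C)/length; it shifts with assembly quality (every N dilutes it) and is
included only because much published data used it. Without ambiguity codes
the two coincide. Soft-masked lowercase is uppercased on input: masking is
annotation, not composition.

**CpG observed/expected** is `obs(CG) · L / (#C · #G)`, the standard
normalization of the observed CpG dinucleotide count by the expectation
from the region's separate C and G content; it is undefined (NA) when C or
G is absent. Values well below 1 indicate CpG depletion. When a region is
a pool of segments (the introns of a transcript, the scaffolds of an
assembly), observed counts, #C, #G and lengths are tallied per segment and
then combined, so no spurious CG spanning a segment junction is ever
counted. The spliced transcript is scored as one sequence, because its
exon–exon junctions are real in the mature mRNA.

**Contiguity.** Nx is the length of the sequence at which the descending
cumulative length first reaches x% of the total; Lx is how many sequences
that takes. Nx is always a member of the input multiset, never
interpolated. **L90pcG** transfers the idea to gene content: the number of
SCSs, taken in decreasing order of annotated gene count, needed to hold at
least ⌈0.9 · total genes⌉ genes — the ceiling because "90% of genes" must
be met with whole genes.

**Density** is number-wise containment (count of contained features per bp
of container, e.g. introns per bp of gene); **coverage** is length-wise
containment (summed contained length over container length). For every
representative transcript, exon coverage + intron coverage = 1 exactly —
an identity the test suite asserts to 1e−12. **Strandedness** partitions
transcripts, exons, CDSs and introns into +/−/unknown tallies.

**Translation** of the representative CDS uses the standard genetic code,
concatenating CDS segments in translation order (ascending coordinates on
+, descending on −, each segment strand-extracted), skipping the first
segment's `phase` bases, dropping a trailing partial codon and trimming
one terminal stop. Internal stops are rendered `*` with a warning rather
than failing the run: they are a property of the annotation worth
surfacing, not a reason to lose a genome. Later segments' declared phases
are validated against the running frame and warned about on mismatch;
GFF3 phases are too unreliable in the wild to be trusted over arithmetic.

## Aggregation and the NA policy

Metrics roll up feature → transcript → SCS → assembly, and every
aggregate is produced as both mean and median, including the grand
mean/median of per-transcript medians for exon and intron lengths. Medians
of even-sized value lists are interpolated (mean of the middle two) — a
second, deliberately different median convention from transcript choice,
because here the result is a number, not a transcript. Any aggregate over
an empty set is NA, never 0: a genome with no annotated introns and a
genome whose introns were not measured must remain distinguishable in
cross-genome tables.

## Output conventions

A default run writes 21 numbered files (00–20): protein FASTA (00),
overview (01), per-level data and summary TSVs (02–12), the run manifest
(13), batch TSVs (14–19, one line per genome, appendable across runs for
direct genome comparison) and a shell-command file (20) with a ready-made
BUSCO invocation for the protein set. All TSVs have one header row, rows
ordered by feature ID, and `NA` for missing. Formatting is fixed —
integers unpadded, percentages and means/medians to 2 decimals, per-bp
densities, coverages and CpG ratios to 6 decimals (2 decimals would erase
a typical intron density of ~0.004/bp; a per-kb convenience column is
written alongside) — so a rerun on the same inputs is byte-identical
except for the manifest's date, which can be pinned. The manifest records
input paths, SHA-256 checksums, tool version, transcript-choice mode and
date, so every number in a report can be traced to its exact inputs.
Appending to an existing batch file whose header differs is refused
outright. The intron length distribution is written into the intron
summary (file 12) with decade bins (1, 10, 100, 1 000, 10 000,
100 000 bp) by default, user-configurable.

## Synthetic test genomes

The fixture generator builds multi-scaffold assemblies with
multi-transcript genes on both strands, CDS subsets of exons with valid
phases, IUPAC ambiguity codes and N runs, and records every expected
overview value by independent naive enumeration at write time — never by
calling the kernels under test. Exon and intron lengths are lognormal
(defaults μ=5.0, σ=0.8 and μ=6.0, σ=1.0 in log-bp), giving the
right-skewed distributions real gene structures show, in which
per-transcript means exceed medians — the regime where mean-only
reporting misleads. Ambiguity and N injection is restricted to intergenic
space so feature composition stays deterministic under the structural
truth. Defaults: 5 SCSs of 150–250 kb, 20 genes (tests use 30–200), 1–3
transcripts per gene, 1–6 exons per transcript, GC 0.40, ambiguity rate
0.005, N-run rate 0.002, 40% minus-strand genes. A fixed seed gives
byte-identical FASTA/GFF3 output.

What the fixtures do *not* emulate: codon usage (random CDS content means
internal stop codons occur and are warned about), repeats, homology,
UTR-rich gene ends, or annotation pathologies like shared exons between
genes. Passing the fixture suite therefore establishes coordinate
arithmetic, composition counting and aggregation — not robustness to
every annotation dialect in the wild. The separate hand-built micro
genome (2 scaffolds, 3 genes; see `docs/micro_genome.md`) keeps every
value auditable on paper and anchors the worked example and golden tests.

The test suite's problem sizes (30-gene fixtures for unit tests, 200
genes for ground-truth recovery, 1000 random inputs per kernel oracle)
keep the full run in the low seconds while exercising every code path;
they are sizes at which the brute-force oracles are still trivially
auditable.

## Known limitations

- UTR features and non-coding RNA genes are out of scope; pseudogenes are
  analyzed exactly as annotated.
- Only the standard genetic code is supported.
- Gene coverage per SCS is NA when annotated gene spans overlap enough to
  exceed the SCS length.
- The reproduction tier for a real genome (honey bee, see
  `scripts/reproduce_apis.py`) requires a ~250 Mb NCBI download and is not
  part of the default test run.
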