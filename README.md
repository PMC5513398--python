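# genestats

Standardized characterization of genome assemblies and their
protein-coding gene annotations.

Comparative genomics keeps tripping over non-standardized summary
statistics: gene counts inflated by alternative isoforms, GC content that
silently depends on assembly quality, "exon" and "CDS" used
interchangeably, and means reported for length distributions so
right-skewed that the mean says little. `genestats` takes one assembly
(FASTA of scaffold-or-contig sequences, SCSs) plus one annotation (GFF3
with `gene`/`mRNA`/`exon`, optionally `CDS`) and computes a fully defined
parameter set on every level of the hierarchy — assembly, SCS, gene,
transcript, CDS, exon, intron — always as both mean and median, with
primary data tables alongside the summaries and a batch mode that collects
one line per genome for direct comparison.

Core definitions (details in `docs/methods.md`):

- **One representative transcript per gene** (longest spliced length by
  default; `shortest`/`median` optional) carries all per-gene metrics, so
  isoforms never act as pseudo-replicates.
- **GC two ways**: strict GC = (G+C+S) / (L − #{N,R,Y,K,M,B,D,H,V}),
  robust to base-calling ambiguity; naive GC = (G+C)/L for comparability
  with older literature.
- **CpG o/e** = obs(CG) · L / (#C · #G), the depletion statistic
  normalized by the region's own C and G content.
- **Contiguity**: N50/L50, N75/L75, N90/L90, plus **L90pcG** — the number
  of SCSs, in decreasing order of gene content, holding ≥ 90% of all
  annotated protein-coding genes.
- **Density** (features per bp of container) and **coverage** (contained
  length per container length), e.g. intron density = introns per bp of
  gene; exon + intron coverage of a gene is exactly 1.
- **Introns are inferred** from exon gaps, since annotation pipelines
  rarely write them.

A run writes 21 numbered files: a protein FASTA of the analyzed
transcripts (00), an overview (01), per-level data + summary TSVs
(02–12), a run manifest with input checksums (13), batch TSVs (14–19) and
a ready-made command file for downstream completeness checks (20).

## Worked example

The repository ships a hand-auditable micro genome (2 scaffolds, 3 genes;
fully derived in `docs/micro_genome.md`):

```sh
python - <<'PY'
from genestats.fixtures import worked_micro_genome
worked_micro_genome("example")
PY
genestats run --fasta example/micro_genome.fasta \
              --gff example/micro_genome.gff3 \
              --name micro --out example_out
```

Selected lines of `example_out/micro/01_overview.tsv`:

```
assembly_size_bp        1600
assembly_size_no_n_bp   1590
assembly_gc_strict_pct  23.35
assembly_gc_naive_pct   23.06
n50_bp                  1000
l50                     1
l90pcg                  2
gene_count              3
exon_count              7
intron_count            4
coding_amount_bp        567
exon_amount_bp          630
intron_amount_bp        320
```

Reading: the two scaffolds total 1600 bp of which 10 are N, so the naive
GC (23.06%) dips below the strict, ambiguity-aware GC (23.35%); the
1000 bp scaffold alone covers half the assembly (N50 = 1000, L50 = 1) but
two scaffolds are needed for 90% of the three genes (L90pcG = 2); the
three representative transcripts contribute 7 exons and 4 inferred
introns, with 567 bp of coding sequence inside 630 bp of exons and 320 bp
of introns. The matching per-transcript row for `g1.t1` shows, e.g.,
`exon_coverage 0.714286` and `intron_coverage 0.285714` — summing to 1.

Batch mode:

```sh
genestats batch --batch manifest.tsv --out comparison/
```

where each manifest line is `label<TAB>assembly.fasta<TAB>annotation.gff3`;
per-genome report directories appear under `comparison/` and the shared
`batch_14.tsv` … `batch_19.tsv` gain one line per genome.

Synthetic genomes with independently recorded ground truth (the basis of
the test suite) come from `genestats fixture --out fx --seed 7 --genes 50`
or programmatically via `genestats.fixtures.FixtureSpec` / `generate`.

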