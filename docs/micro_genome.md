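# The worked micro genome

`genestats.fixtures.worked_micro_genome()` writes a fixed 2-scaffold /
3-gene genome small enough that every overview value can be checked by
hand. It anchors the README worked example and the golden tests. All
coordinates are 1-based inclusive.

## Layout

Background sequence is an `AT` dinucleotide repeat (0% GC); each CDS
carries `ATG` + `GCA` repeats + `TAA`, so composition is auditable block
by block.

**s1 (1000 bp)**

| feature | coordinates | notes |
|---|---|---|
| g1 (+) t1 exons | 101–200, 301–450 | spliced 250 bp; intron 201–300 (100 bp) |
| g1 t1 CDS | 131–200 (phase 0), 301–419 (phase 2) | 70 + 119 = 189 bp = 63 codons |
| g1 (+) t2 exon | 101–200 | spliced 100 bp; CDS 131–190 |
| g2 (−) exons | 601–700, 801–900 | intron 701–800 (100 bp) |
| g2 CDS | 801–898 (phase 0), 601–700 (phase 1) | 98 + 100 = 198 bp = 66 codons, translated high→low |
| ambiguity block | 941–950 | `RYKMRYKMRY` (10 codes, none GC-informative) |
| N block | 951–960 | 10 × `N` |

**s2 (600 bp)**

| feature | coordinates | notes |
|---|---|---|
| g3 (+) exons | 101–160, 221–280, 341–400 | three 60 bp exons, two 60 bp introns |
| g3 CDS | all three exons fully | 180 bp = 60 codons, phases 0/0/0 |

g1 has two transcripts; the longest (spliced 250 vs 100) is t1, so t1 is
the representative under the default mode.

## Hand-derived overview values

| parameter | value | derivation |
|---|---|---|
| assembly size | 1600 bp | 1000 + 600 |
| assembly size without Ns | 1590 bp | 1600 − 10 |
| ambiguity count | 10 | the RYKM block |
| N50 / L50 | 1000 / 1 | half of 1600 is 800; the 1000 bp scaffold alone reaches it |
| N75 / L75 | 600 / 2 | 0.75·1600 = 1200 > 1000, so both scaffolds are needed |
| N90 / L90 | 600 / 2 | same prefix |
| L90pcG | 2 | genes per SCS {2, 1}; target ⌈0.9·3⌉ = 3; cumulative 2, 3 |
| gene count | 3 | g1, g2, g3 |
| exon / intron count | 7 / 4 | representative transcripts only: 2+2+3 exons, 1+1+2 introns |
| coding amount | 567 bp | 189 + 198 + 180 |
| exon amount | 630 bp | 250 + 200 + 180 |
| intron amount | 320 bp | 100 + 100 + 60 + 60 |
| remainder | 650 bp | 1600 − 630 − 320 |
| protein lengths | 62, 65, 59 aa | 189/3−1, 198/3−1, 180/3−1 (terminal stop trimmed) |
| strandedness (transcripts) | 2 plus / 1 minus | g1, g3 vs g2 |

GC values are block sums: all G/C bases come from the CDS blocks
(`ATG GCA … TAA` is 5/9 GC per `GCA`-codon stretch) and none from the AT
filler; the run prints a strict GC of 23.35% (369 GC over the 1580
unambiguous positions) and a naive GC of 23.06% (369/1600). No `CG`
dinucleotide occurs anywhere, so every CpG o/e is exactly 0 (or NA where
C or G is absent, as in the pure-AT introns).
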