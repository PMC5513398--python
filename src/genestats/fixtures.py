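"""Synthetic assembly + annotation fixtures with exactly known ground truth.

The generator writes a standard FASTA/GFF3 pair and, at the same time,
computes every expected overview parameter by independent, naive
enumeration over the structures it just wrote — never by calling the metric
kernels under test.  Exon and intron lengths are drawn from lognormal
distributions, so the data are right-skewed and per-transcript means exceed
medians, the situation in which mean-only reporting misleads.

Sequence content is random at a target GC; IUPAC ambiguity codes and N runs
are injected into intergenic space only, so gene-feature coordinates stay
clean while assembly-level composition exercises the strict-vs-naive GC
distinction.
"""

from __future__ import annotations

import math
import random
import statistics
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConfigError

_STOPS = ("TAA", "TAG", "TGA")
_COMPLEMENT = str.maketrans("ACGTNRYKMSWBDHV", "TGCANYRMKSWVBHD")
_AMBIGUITY = "RYKMSWBDHV"


def _revcomp(seq: str) -> str:
    # deliberately local: the oracle must not share code with sequence_io
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# structure descriptions (generator-internal, 1-based inclusive coordinates)

@dataclass
class _Tx:
    id: str
    gene_id: str
    seqid: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int, int]]  # (start, end, phase)

    @property
    def spliced_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def intron_intervals(self) -> list[tuple[int, int]]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return out


@dataclass
class _Gene:
    id: str
    seqid: str
    strand: str
    transcripts: list[_Tx]

    @property
    def span(self) -> tuple[int, int]:
        return (min(t.span[0] for t in self.transcripts),
                max(t.span[1] for t in self.transcripts))


@dataclass(frozen=True)
class FixtureSpec:
    """Shape of a generated genome; fixed seed => byte-identical files."""

    scs_count: int = 5
    scs_length_range: tuple[int, int] = (150_000, 250_000)
    gene_count: int = 20
    transcripts_per_gene_range: tuple[int, int] = (1, 3)
    exons_per_transcript_range: tuple[int, int] = (1, 6)
    exon_length_mu: float = 5.0     # log-bp
    exon_length_sigma: float = 0.8
    intron_length_mu: float = 6.0   # log-bp; Apis-like right skew
    intron_length_sigma: float = 1.0
    gc_target: float = 0.40
    ambiguity_rate: float = 0.005
    n_run_rate: float = 0.002
    minus_strand_fraction: float = 0.4
    rng_seed: int = 0

    def validate(self) -> None:
        if self.scs_count < 1 or self.gene_count < 0:
            raise ConfigError("scs_count >= 1 and gene_count >= 0 required")
        for rate in (self.ambiguity_rate, self.n_run_rate):
            if not 0.0 <= rate < 1.0:
                raise ConfigError("rates must lie in [0, 1)")
        if not 0.0 < self.gc_target < 1.0:
            raise ConfigError("gc_target must lie in (0, 1)")


@dataclass
class GroundTruth:
    """Expected values, computed by naive counting at generation time."""

    overview: dict[str, object]
    per_transcript: dict[str, dict[str, list[int]]]
    genes_per_scs: dict[str, int]
    representative_by_mode: dict[str, dict[str, str]]
    scs_lengths: dict[str, int] = field(default_factory=dict)


@dataclass
class FixtureResult:
    fasta_path: Path
    gff3_path: Path
    truth: GroundTruth


# ---------------------------------------------------------------------------
# naive oracles (independent of the metrics module by construction)

def _naive_nx(lengths: list[int], fraction: float) -> tuple[int, int]:
    ordered = sorted(lengths, reverse=True)
    total = sum(ordered)
    # exhaustive prefix scan
    for i in range(1, len(ordered) + 1):
        if sum(ordered[:i]) >= fraction * total:
            return ordered[i - 1], i
    raise AssertionError


def _naive_l90pcg(counts: list[int]) -> int:
    ordered = sorted(counts, reverse=True)
    target = math.ceil(0.9 * sum(ordered))
    for i in range(1, len(ordered) + 1):
        if sum(ordered[:i]) >= target:
            return i
    raise AssertionError


def _naive_gc(seqs: list[str]) -> tuple[float | None, float, int, int]:
    g = sum(s.count("G") for s in seqs)
    c = sum(s.count("C") for s in seqs)
    s_code = sum(s.count("S") for s in seqs)
    total = sum(len(s) for s in seqs)
    ambiguous = sum(sum(s.count(ch) for ch in "NRYKMBDHV") for s in seqs)
    denom = total - ambiguous
    strict = 100.0 * (g + c + s_code) / denom if denom else None
    return strict, 100.0 * (g + c) / total, denom, total


def _naive_cpg(seqs: list[str]) -> float | None:
    obs = sum(s.count("CG") for s in seqs)
    c = sum(s.count("C") for s in seqs)
    g = sum(s.count("G") for s in seqs)
    total = sum(len(s) for s in seqs)
    if c == 0 or g == 0:
        return None
    return obs * total / (c * g)


def _pick_representative(gene: _Gene, mode: str) -> _Tx:
    ranked = sorted(gene.transcripts, key=lambda t: (t.spliced_length, t.id))
    if mode == "longest":
        best = ranked[-1].spliced_length
        return next(t for t in ranked if t.spliced_length == best)
    if mode == "shortest":
        return ranked[0]
    return ranked[(len(ranked) - 1) // 2]


def _protein_length(tx: _Tx, seq: str) -> int:
    segs = sorted(tx.cds, key=lambda c: c[0], reverse=tx.strand == "-")
    parts = []
    for start, end, _phase in segs:
        sub = seq[start - 1:end]
        parts.append(_revcomp(sub) if tx.strand == "-" else sub)
    cds = "".join(parts)[segs[0][2]:]
    cds = cds[: len(cds) - len(cds) % 3]
    n = len(cds) // 3
    return n - 1 if cds[-3:] in _STOPS else n


def _truth_from_structures(scaffolds: dict[str, str], genes: list[_Gene],
                           mode: str = "longest") -> GroundTruth:
    """Compute the expected overview by straightforward counting."""
    reps = {g.id: _pick_representative(g, mode) for g in genes}
    rep_by_mode = {m: {g.id: _pick_representative(g, m).id for g in genes}
                   for m in ("longest", "shortest", "median")}

    scs_lengths = {sid: len(s) for sid, s in scaffolds.items()}
    genes_per_scs = {sid: 0 for sid in scaffolds}
    for g in genes:
        genes_per_scs[g.seqid] += 1

    seqs = list(scaffolds.values())
    n_count = sum(s.count("N") for s in seqs)
    gc_strict, gc_naive, denom, total = _naive_gc(seqs)
    ambiguity = total - denom - n_count

    exon_lengths, intron_lengths, cds_lengths = [], [], []
    span_lengths, spliced_lengths, protein_lengths = [], [], []
    exon_counts, intron_counts, cds_counts = [], [], []
    intron_densities, cds_densities = [], []
    exon_covs, intron_covs, cds_covs = [], [], []
    tx_means_intron, tx_medians_intron = [], []
    tx_means_exon, tx_medians_exon = [], []
    strands = {"transcript": [], "exon": [], "intron": [], "cds": []}
    per_transcript: dict[str, dict[str, list[int]]] = {}

    for g in genes:
        tx = reps[g.id]
        ex_lens = [e - s + 1 for s, e in tx.exons]
        in_lens = [e - s + 1 for s, e in tx.intron_intervals()]
        cd_lens = [e - s + 1 for s, e, _p in tx.cds]
        span = tx.span[1] - tx.span[0] + 1
        per_transcript[tx.id] = {"exon_lengths": ex_lens, "intron_lengths": in_lens,
                                 "cds_lengths": cd_lens}
        exon_lengths += ex_lens
        intron_lengths += in_lens
        cds_lengths += cd_lens
        span_lengths.append(span)
        spliced_lengths.append(sum(ex_lens))
        protein_lengths.append(_protein_length(tx, scaffolds[tx.seqid]))
        exon_counts.append(len(ex_lens))
        intron_counts.append(len(in_lens))
        cds_counts.append(len(cd_lens))
        intron_densities.append(len(in_lens) / span)
        cds_densities.append(len(cd_lens) / span)
        exon_covs.append(sum(ex_lens) / span)
        intron_covs.append(sum(in_lens) / span)
        cds_covs.append(sum(cd_lens) / span)
        tx_means_exon.append(statistics.fmean(ex_lens))
        tx_medians_exon.append(statistics.median(ex_lens))
        if in_lens:
            tx_means_intron.append(statistics.fmean(in_lens))
            tx_medians_intron.append(statistics.median(in_lens))
        strands["transcript"].append(tx.strand)
        strands["exon"] += [tx.strand] * len(ex_lens)
        strands["intron"] += [tx.strand] * len(in_lens)
        strands["cds"] += [tx.strand] * len(cd_lens)

    def stat_pair(values, prefix, unit="_bp"):
        if not values:
            return {f"{prefix}_mean{unit}": None, f"{prefix}_median{unit}": None}
        return {f"{prefix}_mean{unit}": statistics.fmean(values),
                f"{prefix}_median{unit}": statistics.median(values)}

    lengths = list(scs_lengths.values())
    ov: dict[str, object] = {
        "scs_count": len(scaffolds),
        "assembly_size_bp": total,
        "assembly_size_no_n_bp": total - n_count,
        "assembly_n_count": n_count,
        "assembly_ambiguity_count": ambiguity,
        "assembly_gc_strict_pct": gc_strict,
        "assembly_gc_naive_pct": gc_naive,
        "assembly_cpg_oe": _naive_cpg(seqs),
        "gene_count": len(genes),
        "transcript_count": len(genes),
        "exon_count": len(exon_lengths),
        "cds_count": len(cds_lengths),
        "intron_count": len(intron_lengths),
        "coding_amount_bp": sum(cds_lengths) if genes else None,
        "exon_amount_bp": sum(exon_lengths) if genes else None,
        "intron_amount_bp": sum(intron_lengths) if genes else None,
    }
    for frac, nk, lk in ((0.5, "n50_bp", "l50"), (0.75, "n75_bp", "l75"),
                         (0.9, "n90_bp", "l90")):
        ov[nk], ov[lk] = _naive_nx(lengths, frac)
    ov["l90pcg"] = (_naive_l90pcg(list(genes_per_scs.values()))
                    if genes else None)
    for label, ss in strands.items():
        ov[f"{label}_strand_plus"] = ss.count("+")
        ov[f"{label}_strand_minus"] = ss.count("-")
        ov[f"{label}_strand_unknown"] = len(ss) - ss.count("+") - ss.count("-")
    ov.update(stat_pair(span_lengths, "transcript_length"))
    ov.update(stat_pair(span_lengths, "gene_length"))
    ov.update(stat_pair(spliced_lengths, "spliced_length"))
    ov.update(stat_pair(exon_lengths, "exon_length"))
    ov.update(stat_pair(cds_lengths, "cds_length"))
    ov.update(stat_pair(intron_lengths, "intron_length"))
    ov.update(stat_pair(protein_lengths, "protein_length", "_aa"))
    ov.update(stat_pair(exon_counts, "exon_count_per_transcript", ""))
    ov.update(stat_pair(cds_counts, "cds_count_per_transcript", ""))
    ov.update(stat_pair(intron_counts, "intron_count_per_transcript", ""))
    ov.update(stat_pair(intron_densities, "intron_density_per_gene_per_bp", ""))
    ov.update(stat_pair(cds_densities, "cds_density_per_gene_per_bp", ""))
    ov.update(stat_pair(exon_covs, "exon_coverage_per_gene", ""))
    ov.update(stat_pair(intron_covs, "intron_coverage_per_gene", ""))
    ov.update(stat_pair(cds_covs, "cds_coverage_per_gene", ""))
    ov["exon_length_mean_of_transcript_means_bp"] = (
        statistics.fmean(tx_means_exon) if tx_means_exon else None)
    ov["exon_length_mean_of_transcript_medians_bp"] = (
        statistics.fmean(tx_medians_exon) if tx_medians_exon else None)
    ov["exon_length_median_of_transcript_medians_bp"] = (
        statistics.median(tx_medians_exon) if tx_medians_exon else None)
    ov["intron_length_mean_of_transcript_means_bp"] = (
        statistics.fmean(tx_means_intron) if tx_means_intron else None)
    ov["intron_length_mean_of_transcript_medians_bp"] = (
        statistics.fmean(tx_medians_intron) if tx_medians_intron else None)
    ov["intron_length_median_of_transcript_medians_bp"] = (
        statistics.median(tx_medians_intron) if tx_medians_intron else None)

    return GroundTruth(overview=ov, per_transcript=per_transcript,
                       genes_per_scs=genes_per_scs,
                       representative_by_mode=rep_by_mode,
                       scs_lengths=scs_lengths)


# ---------------------------------------------------------------------------
# generation

def _draw_length(rng: random.Random, mu: float, sigma: float,
                 lo: int, hi: int) -> int:
    return max(lo, min(hi, round(rng.lognormvariate(mu, sigma))))


def _make_gene_structure(rng: random.Random, spec: FixtureSpec, gene_id: str,
                         seqid: str, strand: str, offset: int) -> _Gene:
    """Master exon chain + transcripts that use contiguous sub-runs of it."""
    n_exons = rng.randint(*spec.exons_per_transcript_range)
    exon_lens = [_draw_length(rng, spec.exon_length_mu, spec.exon_length_sigma,
                              12, 5_000) for _ in range(n_exons)]
    intron_lens = [_draw_length(rng, spec.intron_length_mu,
                                spec.intron_length_sigma, 4, 40_000)
                   for _ in range(n_exons - 1)]
    exons: list[tuple[int, int]] = []
    pos = offset
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + el - 1))
        pos += el
        if i < len(intron_lens):
            pos += intron_lens[i]

    n_tx = rng.randint(*spec.transcripts_per_gene_range)
    transcripts: list[_Tx] = []
    for t in range(n_tx):
        if t == 0:
            sub = exons  # first transcript always carries the full chain
        else:
            a = rng.randint(0, n_exons - 1)
            b = rng.randint(a, n_exons - 1)
            sub = exons[a:b + 1]
        tx_id = f"{gene_id}.t{t + 1}"
        transcripts.append(_Tx(tx_id, gene_id, seqid, strand, list(sub),
                               _make_cds(rng, sub, strand)))
    return _Gene(gene_id, seqid, strand, transcripts)


def _make_cds(rng: random.Random, exons: list[tuple[int, int]],
              strand: str) -> list[tuple[int, int, int]]:
    """CDS = contiguous-in-splice-space trim of the exon run, length % 3 == 0."""
    first_len = exons[0][1] - exons[0][0] + 1
    last_len = exons[-1][1] - exons[-1][0] + 1
    trim5 = rng.randint(0, min(9, first_len - 4))
    trim3 = rng.randint(0, min(9, last_len - 4))
    if len(exons) == 1:
        while first_len - trim5 - trim3 < 3:
            trim3 = max(0, trim3 - 1)
            if first_len - trim5 - trim3 < 3:
                trim5 = max(0, trim5 - 1)
    segs = []
    for i, (s, e) in enumerate(exons):
        cs = s + (trim5 if i == 0 and strand == "+" else 0)
        ce = e - (trim3 if i == len(exons) - 1 and strand == "+" else 0)
        if strand == "-":
            cs = s + (trim3 if i == 0 else 0)
            ce = e - (trim5 if i == len(exons) - 1 else 0)
        segs.append([cs, ce])
    total = sum(e - s + 1 for s, e in segs)
    excess = total % 3
    if excess:  # shave the 3' end (genomic high end for +, low end for -)
        if strand == "+":
            segs[-1][1] -= excess
        else:
            segs[0][0] += excess
    # phases along translation order
    order = list(range(len(segs)))
    if strand == "-":
        order.reverse()
    phased: dict[int, int] = {}
    consumed = 0
    for idx in order:
        phased[idx] = (3 - consumed % 3) % 3
        consumed += segs[idx][1] - segs[idx][0] + 1
    return [(s, e, phased[i]) for i, (s, e) in enumerate(segs)]


def _random_sequence(rng: random.Random, length: int, gc: float) -> list[str]:
    weights = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choices("ACGT", weights=weights, k=length)


def _write_fasta(path: Path, scaffolds: dict[str, str], width: int = 80) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for sid, seq in scaffolds.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def _write_gff3(path: Path, genes: list[_Gene]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for gene in sorted(genes, key=lambda g: (g.seqid, g.span[0])):
            gs, ge = gene.span
            fh.write(f"{gene.seqid}\tgenestats_fixture\tgene\t{gs}\t{ge}\t.\t"
                     f"{gene.strand}\t.\tID={gene.id}\n")
            for tx in gene.transcripts:
                ts, te = tx.span
                fh.write(f"{tx.seqid}\tgenestats_fixture\tmRNA\t{ts}\t{te}\t.\t"
                         f"{tx.strand}\t.\tID={tx.id};Parent={gene.id}\n")
                for i, (s, e) in enumerate(tx.exons, start=1):
                    fh.write(f"{tx.seqid}\tgenestats_fixture\texon\t{s}\t{e}"
                             f"\t.\t{tx.strand}\t.\t"
                             f"ID={tx.id}.exon.{i};Parent={tx.id}\n")
                for i, (s, e, phase) in enumerate(tx.cds, start=1):
                    fh.write(f"{tx.seqid}\tgenestats_fixture\tCDS\t{s}\t{e}"
                             f"\t.\t{tx.strand}\t{phase}\t"
                             f"ID={tx.id}.cds.{i};Parent={tx.id}\n")


def generate(spec: FixtureSpec, out_dir: str | Path,
             basename: str = "fixture") -> FixtureResult:
    """Generate a FASTA/GFF3 pair plus its :class:`GroundTruth`."""
    spec.validate()
    rng = random.Random(spec.rng_seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    scs_ids = [f"scaffold_{i + 1:03d}" for i in range(spec.scs_count)]
    scs_lens = {sid: rng.randint(*spec.scs_length_range) for sid in scs_ids}
    cursors = {sid: 200 for sid in scs_ids}
    margin = 200

    genes: list[_Gene] = []
    for gi in range(spec.gene_count):
        gene_id = f"gene{gi + 1:04d}"
        strand = "-" if rng.random() < spec.minus_strand_fraction else "+"
        placed = False
        for sid in sorted(scs_ids, key=lambda s: cursors[s]):
            gene = _make_gene_structure(rng, spec, gene_id, sid, strand,
                                        cursors[sid])
            if gene.span[1] + margin <= scs_lens[sid]:
                cursors[sid] = gene.span[1] + rng.randint(100, 1000)
                genes.append(gene)
                placed = True
                break
        if not placed:
            raise ConfigError(
                f"fixture packing failed: gene {gene_id} does not fit on any "
                f"SCS; enlarge scs_length_range or reduce gene_count"
            )

    # sequence content: random background, ambiguity/N in intergenic space only
    scaffolds: dict[str, str] = {}
    occupied: dict[str, list[tuple[int, int]]] = {sid: [] for sid in scs_ids}
    for g in genes:
        occupied[g.seqid].append(g.span)
    for sid in scs_ids:
        chars = _random_sequence(rng, scs_lens[sid], spec.gc_target)
        inter = []
        prev_end = 0  # 0-based exclusive
        for s, e in sorted(occupied[sid]):
            if s - 1 > prev_end:
                inter.append((prev_end, s - 1))
            prev_end = max(prev_end, e)
        if prev_end < scs_lens[sid]:
            inter.append((prev_end, scs_lens[sid]))
        inter_positions = [p for a, b in inter for p in range(a, b)]
        n_amb = int(spec.ambiguity_rate * len(inter_positions))
        for p in rng.sample(inter_positions, min(n_amb, len(inter_positions))):
            chars[p] = rng.choice(_AMBIGUITY)
        n_runs = int(spec.n_run_rate * len(inter_positions) / 50)
        for _ in range(n_runs):
            a, b = rng.choice(inter)
            if b - a < 5:
                continue
            start = rng.randint(a, b - 5)
            run = min(rng.randint(20, 80), b - start)
            for p in range(start, start + run):
                chars[p] = "N"
        scaffolds[sid] = "".join(chars)

    fasta_path = out / f"{basename}.fasta"
    gff3_path = out / f"{basename}.gff3"
    _write_fasta(fasta_path, scaffolds)
    _write_gff3(gff3_path, genes)
    truth = _truth_from_structures(scaffolds, genes)
    return FixtureResult(fasta_path, gff3_path, truth)


# ---------------------------------------------------------------------------
# the worked micro genome (fixed, human-auditable)

def worked_micro_genome(out_dir: str | Path) -> FixtureResult:
    """A fixed 2-scaffold / 3-gene genome whose every overview value can be
    audited by hand; doubles as the README worked example and golden test.

    Layout (1-based inclusive):

    * s1 (1000 bp): gene g1 (+, 2 transcripts; t1 exons 101-200 and
      301-450 with a 100 bp intron, CDS 131-200 phase 0 + 301-419 phase 2;
      t2 single exon 101-200, CDS 131-190), gene g2 (-, exons 601-700 and
      801-900, 100 bp intron, CDS 801-898 phase 0 + 601-700 phase 1);
      ambiguity codes at 941-950, ten Ns at 951-960.
    * s2 (600 bp): gene g3 (+, exons 101-160 / 221-280 / 341-400, two 60 bp
      introns, CDS = all exons, phases 0/0/0).

    Background is an AT dinucleotide repeat (GC-free), CDS regions carry
    ATG + GCA repeats + TAA, so composition is auditable block by block.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def at_filler(length: int) -> str:
        return ("AT" * (length // 2 + 1))[:length]

    def codons(n_codons: int) -> str:
        return "ATG" + "GCA" * (n_codons - 2) + "TAA"

    s1 = list(at_filler(1000))
    s2 = list(at_filler(600))

    def paint(seq: list[str], start: int, text: str) -> None:
        seq[start - 1:start - 1 + len(text)] = list(text)

    # g1.t1 CDS: 189 bp = 63 codons split 70 (131-200) + 119 (301-419)
    p1 = codons(63)
    paint(s1, 131, p1[:70])
    paint(s1, 301, p1[70:])
    # g2 CDS on minus strand: 198 bp = 66 codons split 98 (801-898) + 100 (601-700)
    p2 = codons(66)
    paint(s1, 801, _revcomp(p2[:98]))
    paint(s1, 601, _revcomp(p2[98:]))
    # ambiguity + N blocks in intergenic s1
    paint(s1, 941, "RYKMRYKMRY")
    paint(s1, 951, "N" * 10)
    # g3 CDS: 180 bp = 60 codons split 60/60/60
    p3 = codons(60)
    paint(s2, 101, p3[:60])
    paint(s2, 221, p3[60:120])
    paint(s2, 341, p3[120:])

    scaffolds = {"s1": "".join(s1), "s2": "".join(s2)}

    g1 = _Gene("g1", "s1", "+", [
        _Tx("g1.t1", "g1", "s1", "+", [(101, 200), (301, 450)],
            [(131, 200, 0), (301, 419, 2)]),
        _Tx("g1.t2", "g1", "s1", "+", [(101, 200)], [(131, 190, 0)]),
    ])
    g2 = _Gene("g2", "s1", "-", [
        _Tx("g2.t1", "g2", "s1", "-", [(601, 700), (801, 900)],
            [(601, 700, 1), (801, 898, 0)]),
    ])
    g3 = _Gene("g3", "s2", "+", [
        _Tx("g3.t1", "g3", "s2", "+",
            [(101, 160), (221, 280), (341, 400)],
            [(101, 160, 0), (221, 280, 0), (341, 400, 0)]),
    ])
    genes = [g1, g2, g3]

    fasta_path = out / "micro_genome.fasta"
    gff3_path = out / "micro_genome.gff3"
    _write_fasta(fasta_path, scaffolds)
    _write_gff3(gff3_path, genes)
    truth = _truth_from_structures(scaffolds, genes)
    return FixtureResult(fasta_path, gff3_path, truth)
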