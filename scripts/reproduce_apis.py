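#!/usr/bin/env python
"""Reproduce the honey-bee (Apis mellifera) gene-structure statistics.

Downloads assembly Amel_4.5 (GCF_000002195.4) and its RefSeq annotation
from NCBI (~250 Mb; network required), runs the default analysis (longest
representative transcript per gene) and writes the comparison quantities to
results/apis_reproduction.json, where tests/test_acceptance.py picks them
up.  Downloads and decompressed inputs are kept under scratch/.

Usage: python scripts/reproduce_apis.py
"""

from __future__ import annotations

import gzip
import json
import shutil
import statistics
import sys
import urllib.request
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from genestats.analysis import analyze_genome  # noqa: E402

BASE = ("https://ftp.ncbi.nlm.nih.gov/genomes/all/GCF/000/002/195/"
        "GCF_000002195.4_Amel_4.5/")
FILES = {
    "fasta": "GCF_000002195.4_Amel_4.5_genomic.fna.gz",
    "gff": "GCF_000002195.4_Amel_4.5_genomic.gff.gz",
}


def fetch(name: str, dest: Path) -> Path:
    out = dest / name
    if not out.exists():
        print(f"downloading {BASE + name} ...")
        urllib.request.urlretrieve(BASE + name, out)
    plain = out.with_suffix("")
    if not plain.exists():
        with gzip.open(out, "rb") as src, open(plain, "wb") as dst:
            shutil.copyfileobj(src, dst)
    return plain


def main() -> int:
    scratch = ROOT / "scratch" / "apis"
    scratch.mkdir(parents=True, exist_ok=True)
    fasta = fetch(FILES["fasta"], scratch)
    gff = fetch(FILES["gff"], scratch)

    analysis = analyze_genome(str(fasta), str(gff), "apis_mellifera")
    ov = analysis.overview
    intron_bearing = sum(1 for r in analysis.transcript_rows
                         if r["intron_count"] > 0)
    tx_with_introns = [r for r in analysis.transcript_rows
                       if r["intron_count"] > 0]
    results = {
        "transcript_count": ov["transcript_count"],
        "exon_count": ov["exon_count"],
        "intron_count": ov["intron_count"],
        "intron_bearing_transcripts": intron_bearing,
        "exon_length_mean_of_transcript_medians_bp":
            ov["exon_length_mean_of_transcript_medians_bp"],
        "exon_length_mean_of_transcript_means_bp":
            ov["exon_length_mean_of_transcript_means_bp"],
        "intron_length_mean_of_transcript_medians_bp":
            statistics.fmean(r["intron_length_median_bp"]
                             for r in tx_with_introns),
        "intron_length_mean_of_transcript_means_bp":
            statistics.fmean(r["intron_length_mean_bp"]
                             for r in tx_with_introns),
    }
    out = ROOT / "results" / "apis_reproduction.json"
    out.parent.mkdir(exist_ok=True)
    out.write_text(json.dumps(results, indent=2) + "\n")
    print(f"wrote {out}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
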