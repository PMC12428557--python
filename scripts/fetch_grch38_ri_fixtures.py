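#!/usr/bin/env python
"""One-time fetch of the five GRCh38 retained-intron regions used by the
worked-example stop-codon tests.

Downloads the forward-strand slices from the Ensembl REST API and writes
``tests/data/grch38_ri_introns.fa`` with headers carrying gene, region,
strand and reading frame. Requires network access; run once, then the test
suite works offline.

Coordinates are 0-based half-open (upstream exon end .. downstream exon
start), as produced by rMATS and consumed by bedtools getfasta.
"""

import json
import sys
import urllib.request
from pathlib import Path

REGIONS = [
    # gene, chrom, start(0-based), end, strand, frame, expected stop count
    ("BRIP1", "17", 61776562, 61780839, "-", 1, 83),
    ("FANCA", "16", 89778850, 89778942, "-", 1, 0),
    ("FANCG", "9", 35077399, 35078604, "-", 3, 14),
    ("TP53", "17", 7673339, 7673534, "-", 1, 2),
    ("VRK1", "14", 96853166, 96855223, "+", 1, 50),
]

OUT = Path(__file__).resolve().parent.parent / "tests" / "data" / "grch38_ri_introns.fa"


def fetch(chrom: str, start: int, end: int) -> str:
    # Ensembl REST is 1-based inclusive on the forward strand
    url = (f"https://rest.ensembl.org/sequence/region/human/"
           f"{chrom}:{start + 1}..{end}:1?content-type=application/json")
    with urllib.request.urlopen(url, timeout=60) as resp:
        return json.load(resp)["seq"].upper()


def main() -> int:
    records = []
    for gene, chrom, start, end, strand, frame, count in REGIONS:
        seq = fetch(chrom, start, end)
        assert len(seq) == end - start, (gene, len(seq), end - start)
        header = (f"{gene} chr{chrom}:{start}-{end}({strand}) "
                  f"frame={frame} expected_stops={count}")
        records.append((header, seq))
        print(f"fetched {gene}: {len(seq)} nt")
    OUT.parent.mkdir(parents=True, exist_ok=True)
    with open(OUT, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for k in range(0, len(seq), 80):
                fh.write(seq[k:k + 80] + "\n")
    print(f"wrote {OUT}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
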