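"""GTF annotation access (CDS segments with transcript grouping)."""

from __future__ import annotations

from typing import Dict, List, Tuple

import gffutils


def load_cds_by_transcript(gtf_path: str) -> Dict[str, Dict]:
    """transcript id -> {'chrom', 'strand', 'intervals': [(start, end), ...]}.

    Intervals are converted from GTF 1-based inclusive to 0-based half-open.
    """
    db = gffutils.create_db(
        gtf_path, dbfn=":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    out: Dict[str, Dict] = {}
    for feat in db.features_of_type("CDS"):
        tx = feat.attributes.get("transcript_id", ["?"])[0]
        rec = out.setdefault(tx, {"chrom": feat.seqid, "strand": feat.strand,
                                  "intervals": []})
        rec["intervals"].append((feat.start - 1, feat.end))
    for rec in out.values():
        rec["intervals"].sort()
    return out


def cds_intervals_for_contig(cds_by_tx: Dict[str, Dict], chrom: str
                             ) -> Dict[str, List[Tuple[int, int]]]:
    return {tx: rec["intervals"] for tx, rec in cds_by_tx.items()
            if rec["chrom"] == chrom}
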