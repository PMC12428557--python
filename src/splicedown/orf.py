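"""Reading-frame determination and in-frame premature stop-codon scanning
for retained-intron events.

Frame k means codons start at offset k-1 of the region sequence taken in
transcript orientation (so a '-' strand intron is scanned on its reverse
complement). Stop positions are reported as 1-based offsets of the codon's
first nucleotide within the region sequence; codons must lie fully inside
the region (boundary-straddling codons are not counted) and any codon
containing N never matches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .events import SpliceEvent, dase_region
from .intervals import GenomeSource, extract_sequence

logger = logging.getLogger(__name__)

STOP_CODONS = ("TAG", "TAA", "TGA")


@dataclass
class StopScanResult:
    """Premature-stop scan of one retained-intron sequence."""

    event_id: str
    frame: int
    stop_count: int = 0
    stop_positions: List[int] = field(default_factory=list)
    stop_codons: List[str] = field(default_factory=list)
    frame_source: str = "user"

    @property
    def first_stop_position(self) -> Optional[int]:
        return self.stop_positions[0] if self.stop_positions else None


def scan_premature_stops(sequence: str, frame: int, event_id: str = "") -> StopScanResult:
    """All in-frame TAG/TAA/TGA codons of ``sequence`` at reading frame 1-3."""
    if frame not in (1, 2, 3):
        raise ValueError(f"frame must be 1, 2 or 3, got {frame}")
    seq = sequence.upper().replace("U", "T")
    positions: List[int] = []
    codons: List[str] = []
    for off in range(frame - 1, len(seq) - 2, 3):
        codon = seq[off:off + 3]
        if codon in STOP_CODONS:
            positions.append(off + 1)  # 1-based first nucleotide
            codons.append(codon)
    return StopScanResult(
        event_id=event_id,
        frame=frame,
        stop_count=len(positions),
        stop_positions=positions,
        stop_codons=codons,
    )


def _transcript_cds_prefix(cds_intervals: Sequence[Tuple[int, int]], strand: str,
                           junction: int) -> Optional[int]:
    """Coding nucleotides 5' of ``junction`` in transcript orientation.

    ``cds_intervals`` are genomic 0-based half-open CDS segments of one
    transcript. Returns None unless some CDS segment abuts the junction (the
    retained intron's transcript-5' boundary).
    """
    ivs = sorted(cds_intervals)
    if strand == "+":
        if not any(end == junction for _, end in ivs):
            return None
        return sum(min(end, junction) - start for start, end in ivs if start < junction)
    if not any(start == junction for start, _ in ivs):
        return None
    return sum(end - max(start, junction) for start, end in ivs if end > junction)


def determine_frame(
    event: SpliceEvent,
    cds_by_transcript: Dict[str, List[Tuple[int, int]]],
    user_frame: Optional[int] = None,
) -> Tuple[int, str]:
    """Reading frame at the retained intron from annotated CDS segments.

    ``cds_by_transcript`` maps transcript id -> genomic CDS intervals. The
    intron's transcript-5' boundary is the upstream-exon 3' end. With c
    coding bases consumed before the intron, frame = 1 + ((3 - c mod 3) mod 3).
    Transcripts that disagree are resolved in favor of the longest CDS (a
    warning is logged). With no covering CDS the caller-supplied frame is
    used; absent both, an error is raised. Returns (frame, provenance).
    """
    region = dase_region(event)
    junction = region.start if event.strand == "+" else region.end
    candidates = []  # (total_cds_len, transcript, frame)
    for tx, ivs in cds_by_transcript.items():
        prefix = _transcript_cds_prefix(ivs, event.strand, junction)
        if prefix is None:
            continue
        frame = 1 + ((3 - prefix % 3) % 3)
        total = sum(e - s for s, e in ivs)
        candidates.append((total, tx, frame))
    if candidates:
        candidates.sort(key=lambda t: (-t[0], t[1]))
        frames = {f for _, _, f in candidates}
        if len(frames) > 1:
            logger.warning(
                "event %s: transcripts disagree on frame (%s); using longest CDS %s",
                event.event_id, sorted(frames), candidates[0][1],
            )
        return candidates[0][2], f"annotation:{candidates[0][1]}"
    if user_frame is not None:
        return user_frame, "user"
    raise ValueError(
        f"event {event.event_id}: no CDS covers the intron junction and no "
        "user frame supplied"
    )


def ri_stop_report(
    ri_events: Sequence[SpliceEvent],
    genome: GenomeSource,
    frames: Dict[str, int],
) -> List[StopScanResult]:
    """Scan each retained intron for in-frame premature stops.

    ``frames`` maps event_id -> frame (1-3). The intron sequence is extracted
    strand-oriented; one result per event.
    """
    results = []
    for ev in ri_events:
        if ev.event_class != "RI":
            raise ValueError(f"event {ev.event_id} is {ev.event_class}, not RI")
        if ev.event_id not in frames:
            raise ValueError(f"no frame supplied for event {ev.event_id}")
        seq = extract_sequence(genome, dase_region(ev))
        results.append(scan_premature_stops(seq, frames[ev.event_id], ev.event_id))
    return results


def write_stop_report_tsv(results: Sequence[StopScanResult], path: str,
                          events: Optional[Sequence[SpliceEvent]] = None) -> None:
    meta = {ev.event_id: ev for ev in events or []}
    with open(path, "w") as fh:
        fh.write("event_id\tgene_symbol\tregion\tdelta_psi\tframe\tstop_count\t"
                 "first_stop_position\tstop_positions\n")
        for res in results:
            ev = meta.get(res.event_id)
            if ev is not None:
                region = dase_region(ev)
                loc = f"{region.chrom}:{region.start}-{region.end}({region.strand})"
                sym, dpsi = ev.gene_symbol, ev.delta_psi
            else:
                loc, sym, dpsi = "NA", "NA", None
            fh.write(
                f"{res.event_id}\t{sym}\t{loc}\t"
                f"{'NA' if dpsi is None else f'{dpsi:.4g}'}\t{res.frame}\t"
                f"{res.stop_count}\t{res.first_stop_position or '---'}\t"
                f"{','.join(map(str, res.stop_positions)) or '---'}\n"
            )
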