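"""Splice-event parsing, PSI quantification, DASE filtering and region extraction.

Consumes rMATS-style per-class tables (JC flavor). Sample 1 is the treatment
group and sample 2 the control group, so ``delta_psi`` (= rMATS
``IncLevelDifference``) is treatment-minus-control mean PSI.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval, GenomeSource, extract_sequence  # noqa: F401

logger = logging.getLogger(__name__)

EVENT_CLASSES = ("SE", "A5SS", "A3SS", "MXE", "RI")

#: genomic coordinate columns per event class, in rMATS order (all 0-based
#: start / exclusive end pairs)
COORD_COLUMNS = {
    "SE": [
        "exonStart_0base", "exonEnd",
        "upstreamES", "upstreamEE",
        "downstreamES", "downstreamEE",
    ],
    "MXE": [
        "1stExonStart_0base", "1stExonEnd",
        "2ndExonStart_0base", "2ndExonEnd",
        "upstreamES", "upstreamEE",
        "downstreamES", "downstreamEE",
    ],
    "RI": [
        "riExonStart_0base", "riExonEnd",
        "upstreamES", "upstreamEE",
        "downstreamES", "downstreamEE",
    ],
    "A3SS": [
        "longExonStart_0base", "longExonEnd",
        "shortES", "shortEE",
        "flankingES", "flankingEE",
    ],
    "A5SS": [
        "longExonStart_0base", "longExonEnd",
        "shortES", "shortEE",
        "flankingES", "flankingEE",
    ],
}

GROUPS = ("treatment", "control")


class PsiUndefinedError(ValueError):
    """Raised when PSI is requested for a replicate with no junction reads."""


def compute_psi(
    inclusion_count: float,
    skipping_count: float,
    inclusion_length: float,
    skipping_length: float,
) -> float:
    """Length-normalized percent spliced in: (I/lI) / (I/lI + S/lS).

    Raises :class:`PsiUndefinedError` when both counts are zero — the event
    must be flagged by the caller, never silently set to 0.
    """
    if inclusion_length <= 0 or skipping_length <= 0:
        raise ValueError("effective lengths must be positive")
    if inclusion_count < 0 or skipping_count < 0:
        raise ValueError("junction counts must be non-negative")
    if inclusion_count == 0 and skipping_count == 0:
        raise PsiUndefinedError("PSI undefined: no inclusion or skipping reads")
    inc = inclusion_count / inclusion_length
    skp = skipping_count / skipping_length
    return inc / (inc + skp)


@dataclass
class SpliceEvent:
    """One alternative-splicing event with class-specific coordinates."""

    event_id: str
    event_class: str
    gene_id: str
    gene_symbol: str
    chrom: str
    strand: str
    coords: Dict[str, int]
    inclusion_counts: Dict[str, List[int]]
    skipping_counts: Dict[str, List[int]]
    inclusion_length: float = 1.0
    skipping_length: float = 1.0
    psi: Dict[str, List[Optional[float]]] = field(default_factory=dict)
    delta_psi: Optional[float] = None
    pvalue: Optional[float] = None
    fdr: Optional[float] = None
    testable: bool = True

    def __post_init__(self):
        if self.event_class not in EVENT_CLASSES:
            raise ValueError(f"unknown event class {self.event_class!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        for col in COORD_COLUMNS[self.event_class]:
            if col not in self.coords:
                raise ValueError(
                    f"event {self.event_id}: missing coordinate column {col!r}"
                )
            if self.coords[col] < 0:
                raise ValueError(
                    f"event {self.event_id}: negative coordinate in {col!r}"
                )
        for grp in GROUPS:
            if any(c < 0 for c in self.inclusion_counts.get(grp, [])):
                raise ValueError(f"event {self.event_id}: negative inclusion count")
            if any(c < 0 for c in self.skipping_counts.get(grp, [])):
                raise ValueError(f"event {self.event_id}: negative skipping count")
        if not self.psi:
            self.psi = {grp: self._psi_replicates(grp) for grp in GROUPS}

    def _psi_replicates(self, group: str) -> List[Optional[float]]:
        out: List[Optional[float]] = []
        for inc, skp in zip(self.inclusion_counts[group], self.skipping_counts[group]):
            try:
                out.append(compute_psi(inc, skp, self.inclusion_length, self.skipping_length))
            except PsiUndefinedError:
                out.append(None)
        return out

    def mean_psi(self, group: str) -> Optional[float]:
        vals = [v for v in self.psi.get(group, []) if v is not None]
        return float(np.mean(vals)) if vals else None

    @property
    def sort_key(self):
        start = min(self.coords[c] for c in COORD_COLUMNS[self.event_class])
        return (self.event_class, self.chrom, start, self.event_id)


def _parse_count_list(text: str) -> List[int]:
    values = []
    for tok in str(text).split(","):
        tok = tok.strip()
        if tok in ("", "NA"):
            continue
        values.append(int(tok))
    return values


def _parse_psi_list(text: str) -> List[Optional[float]]:
    out: List[Optional[float]] = []
    for tok in str(text).split(","):
        tok = tok.strip()
        out.append(None if tok in ("", "NA") else float(tok))
    return out


def read_rmats_events(path: str, event_class: str) -> List[SpliceEvent]:
    """Parse one rMATS per-class table into :class:`SpliceEvent` records.

    Malformed rows raise with the offending 1-based data row number and the
    column name. Missing PSI / statistics entries ("NA") are tolerated.
    """
    if event_class not in EVENT_CLASSES:
        raise ValueError(f"unknown event class tag {event_class!r}")
    coord_cols = COORD_COLUMNS[event_class]
    events: List[SpliceEvent] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for rownum, row in enumerate(reader, start=1):
            col = None
            try:
                coords = {}
                for col in coord_cols:
                    coords[col] = int(row[col])
                col = "IJC_SAMPLE_1"
                inc = {"treatment": _parse_count_list(row["IJC_SAMPLE_1"])}
                col = "SJC_SAMPLE_1"
                skp = {"treatment": _parse_count_list(row["SJC_SAMPLE_1"])}
                col = "IJC_SAMPLE_2"
                inc["control"] = _parse_count_list(row["IJC_SAMPLE_2"])
                col = "SJC_SAMPLE_2"
                skp["control"] = _parse_count_list(row["SJC_SAMPLE_2"])
                col = "IncFormLen"
                inc_len = float(row.get("IncFormLen", 1) or 1)
                col = "SkipFormLen"
                skp_len = float(row.get("SkipFormLen", 1) or 1)

                def _opt_float(name):
                    val = row.get(name, "NA")
                    return None if val in (None, "", "NA") else float(val)

                col = "PValue"
                pvalue = _opt_float("PValue")
                col = "FDR"
                fdr = _opt_float("FDR")
                col = "IncLevelDifference"
                dpsi = _opt_float("IncLevelDifference")
                psi = {}
                if row.get("IncLevel1") not in (None, ""):
                    col = "IncLevel1"
                    psi["treatment"] = _parse_psi_list(row["IncLevel1"])
                    col = "IncLevel2"
                    psi["control"] = _parse_psi_list(row["IncLevel2"])
                    if all(v is None for vals in psi.values() for v in vals):
                        psi = {}  # all-NA: recomputable from counts
                col = None
                ev = SpliceEvent(
                    event_id=f"{event_class}_{row['ID']}",
                    event_class=event_class,
                    gene_id=row.get("GeneID", ""),
                    gene_symbol=row.get("geneSymbol", "").strip('"'),
                    chrom=row["chr"],
                    strand=row["strand"],
                    coords=coords,
                    inclusion_counts=inc,
                    skipping_counts=skp,
                    inclusion_length=inc_len,
                    skipping_length=skp_len,
                    psi=psi,
                    delta_psi=dpsi,
                    pvalue=pvalue,
                    fdr=fdr,
                )
            except (KeyError, ValueError) as exc:
                where = f" (column {col!r})" if col else ""
                raise ValueError(
                    f"{path}: malformed row {rownum}{where}: {exc}"
                ) from exc
            events.append(ev)
    return events


def mean_event_coverage(event: SpliceEvent) -> float:
    """Mean over all replicates (both groups) of inclusion + skipping reads."""
    totals = []
    for grp in GROUPS:
        for inc, skp in zip(event.inclusion_counts[grp], event.skipping_counts[grp]):
            totals.append(inc + skp)
    return float(np.mean(totals)) if totals else 0.0


def filter_dases(
    events: Iterable[SpliceEvent],
    fdr_max: float = 0.05,
    min_abs_dpsi: float = 0.1,
    min_mean_coverage: float = 5.0,
) -> List[SpliceEvent]:
    """Retain events with FDR <= fdr_max, |dPSI| >= min_abs_dpsi and mean
    junction coverage strictly greater than min_mean_coverage.

    Events lacking an FDR or dPSI are rejected with a logged warning. Input
    order is preserved; the filter is idempotent.
    """
    kept = []
    for ev in events:
        if ev.fdr is None or ev.delta_psi is None:
            logger.warning("event %s lacks FDR/dPSI; rejected", ev.event_id)
            continue
        if ev.fdr <= fdr_max and abs(ev.delta_psi) >= min_abs_dpsi \
                and mean_event_coverage(ev) > min_mean_coverage:
            kept.append(ev)
    return kept


def dase_region(event: SpliceEvent) -> GenomicInterval:
    """The per-class target region all downstream analyses consume.

    SE: the alternative exon. MXE: first exon on '+', second on '-'. RI: the
    retained intron (gap between the flanking exons). A3SS/A5SS: the long
    exon minus its overlap with the short exon (a single residual interval;
    the short exon must share exactly one boundary with the long exon).
    """
    c = event.coords
    cls = event.event_class
    if cls == "SE":
        return GenomicInterval(event.chrom, c["exonStart_0base"], c["exonEnd"], event.strand)
    if cls == "MXE":
        if event.strand == "+":
            return GenomicInterval(event.chrom, c["1stExonStart_0base"], c["1stExonEnd"], "+")
        return GenomicInterval(event.chrom, c["2ndExonStart_0base"], c["2ndExonEnd"], "-")
    if cls == "RI":
        # flanking exons sorted genomically; intron is the gap between them
        left_end = min(c["upstreamEE"], c["downstreamEE"])
        right_start = max(c["upstreamES"], c["downstreamES"])
        return GenomicInterval(event.chrom, left_end, right_start, event.strand)
    if cls in ("A3SS", "A5SS"):
        ls, le = c["longExonStart_0base"], c["longExonEnd"]
        ss, se = c["shortES"], c["shortEE"]
        if not (ls <= ss and se <= le):
            raise ValueError(
                f"event {event.event_id}: short exon [{ss},{se}) not contained "
                f"in long exon [{ls},{le})"
            )
        if se == le and ss > ls:
            return GenomicInterval(event.chrom, ls, ss, event.strand)
        if ss == ls and se < le:
            return GenomicInterval(event.chrom, se, le, event.strand)
        raise ValueError(
            f"event {event.event_id}: short exon [{ss},{se}) does not share "
            f"exactly one boundary with long exon [{ls},{le})"
        )
    raise ValueError(f"unknown event class {cls!r}")


def _group_loglik(inc: float, skp: float) -> float:
    total = inc + skp
    if total == 0:
        return 0.0
    p = inc / total
    ll = 0.0
    if inc > 0:
        ll += inc * math.log(p)
    if skp > 0:
        ll += skp * math.log(1 - p)
    return ll


def call_dases_from_counts(events: Sequence[SpliceEvent]) -> List[SpliceEvent]:
    """Populate pvalue/FDR/dPSI with a pooled two-group binomial LRT.

    Length-normalized pooled counts per group; likelihood-ratio test of one
    shared inclusion probability against group-specific probabilities,
    referred to chi-square with 1 df. Benjamini-Hochberg FDR is computed
    jointly across all supplied events (all classes together). This is a
    simplified stand-in for the consumed tool's hierarchical model and is
    meant for synthetic data.
    """
    pvalues = []
    testable_idx = []
    for idx, ev in enumerate(events):
        norm = {}
        for grp in GROUPS:
            inc = sum(ev.inclusion_counts[grp]) / ev.inclusion_length
            skp = sum(ev.skipping_counts[grp]) / ev.skipping_length
            norm[grp] = (inc, skp)
        mt, mc = ev.mean_psi("treatment"), ev.mean_psi("control")
        ev.delta_psi = None if mt is None or mc is None else mt - mc
        if any(sum(pair) == 0 for pair in norm.values()):
            ev.testable = False
            ev.pvalue = None
            ev.fdr = None
            continue
        pooled_inc = sum(v[0] for v in norm.values())
        pooled_skp = sum(v[1] for v in norm.values())
        ll_sep = sum(_group_loglik(*norm[grp]) for grp in GROUPS)
        ll_pool = _group_loglik(pooled_inc, pooled_skp)
        stat = max(0.0, 2.0 * (ll_sep - ll_pool))
        ev.pvalue = float(chi2.sf(stat, df=1)) if stat > 0 else 1.0
        testable_idx.append(idx)
        pvalues.append(ev.pvalue)
    if pvalues:
        fdrs = multipletests(pvalues, method="fdr_bh")[1]
        for idx, q in zip(testable_idx, fdrs):
            events[idx].fdr = float(q)
    return list(events)


def write_events_tsv(events: Sequence[SpliceEvent], path: str) -> None:
    """One row per event: class, gene, region coordinates, dPSI, FDR."""
    rows = sorted(events, key=lambda e: e.sort_key)
    with open(path, "w") as fh:
        fh.write("event_id\tevent_class\tgene_id\tgene_symbol\tchrom\tstrand\t"
                 "region_start\tregion_end\tdelta_psi\tpvalue\tfdr\tmean_coverage\n")
        for ev in rows:
            region = dase_region(ev)
            def fmt(x):
                return "NA" if x is None else f"{x:.6g}"
            fh.write(
                f"{ev.event_id}\t{ev.event_class}\t{ev.gene_id}\t{ev.gene_symbol}\t"
                f"{ev.chrom}\t{ev.strand}\t{region.start}\t{region.end}\t"
                f"{fmt(ev.delta_psi)}\t{fmt(ev.pvalue)}\t{fmt(ev.fdr)}\t"
                f"{mean_event_coverage(ev):.4g}\n"
            )


def write_regions_bed(events: Sequence[SpliceEvent], path: str) -> None:
    """BED6 of DASE regions; score = round(1000 * |dPSI|)."""
    rows = sorted(events, key=lambda e: e.sort_key)
    with open(path, "w") as fh:
        for ev in rows:
            region = dase_region(ev)
            score = 0 if ev.delta_psi is None else round(1000 * abs(ev.delta_psi))
            fh.write(
                f"{region.chrom}\t{region.start}\t{region.end}\t{ev.event_id}\t"
                f"{min(score, 1000)}\t{region.strand}\n"
            )
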