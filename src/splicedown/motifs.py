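"""RBP motif maps around splicing events.

Per-class region layouts use exonic flanks of +/-50 nt and intronic flanks of
+/-250 nt around the class-specific splice sites, labeled R1..Rn in transcript
orientation and collapsed to three regions (Upstream / Exon / Downstream; for
retained introns the intron itself is the Exon region). Motif density is the
motif-covered nucleotide fraction in a 50-nt sliding window (step 1 nt;
windows never span sub-region boundaries), compared between direction groups
(up: dPSI > 0, down: dPSI < 0) and background events with a two-sided
Wilcoxon rank-sum test per window.
"""

from __future__ import annotations

import itertools
import logging
import math
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
from scipy.stats import mannwhitneyu

from .duplex import as_rna
from .events import SpliceEvent, dase_region
from .intervals import GenomicInterval, GenomeSource, extract_sequence

logger = logging.getLogger(__name__)

IUPAC_RNA = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU", "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG", "N": "ACGU",
}

COLLAPSED_REGIONS = ("Upstream", "Exon", "Downstream")

DEFAULT_WINDOW = 50
DEFAULT_EXON_FLANK = 50
DEFAULT_INTRON_FLANK = 250


@dataclass(frozen=True)
class Motif:
    rbp_name: str
    patterns: Tuple[str, ...]

    def __post_init__(self):
        if not self.patterns:
            raise ValueError(f"{self.rbp_name}: motif needs >=1 pattern")
        for pat in self.patterns:
            bad = set(as_rna(pat)) - set(IUPAC_RNA)
            if bad:
                raise ValueError(f"{self.rbp_name}: non-IUPAC symbols {bad}")

    @property
    def min_length(self) -> int:
        return min(len(p) for p in self.patterns)


def read_motif_tsv(path: str) -> List[Motif]:
    """rbp <tab> comma-separated IUPAC patterns."""
    motifs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, pats = line.split("\t")[:2]
            motifs.append(Motif(name, tuple(as_rna(p) for p in pats.split(","))))
    return motifs


def _iupac_regex(pattern: str) -> re.Pattern:
    # lookahead so overlapping occurrences are all reported; classes contain
    # only ACGU, so N in the sequence never matches
    body = "".join(
        c if len(IUPAC_RNA[c]) == 1 else "[" + IUPAC_RNA[c] + "]"
        for c in as_rna(pattern)
    )
    return re.compile(f"(?=({body}))")


def motif_scan(sequence: str, motif: Motif) -> List[int]:
    """Sorted 0-based start positions of all (overlapping) pattern matches."""
    seq = as_rna(sequence)
    starts: Set[int] = set()
    for pat in motif.patterns:
        for m in _iupac_regex(pat).finditer(seq):
            starts.add(m.start())
    return sorted(starts)


def motif_coverage(sequence: str, motif: Motif) -> np.ndarray:
    """Boolean per-nucleotide indicator of motif coverage."""
    cov = np.zeros(len(sequence), dtype=bool)
    seq = as_rna(sequence)
    for pat in motif.patterns:
        k = len(pat)
        for m in _iupac_regex(pat).finditer(seq):
            cov[m.start():m.start() + k] = True
    return cov


# ---------------------------------------------------------------------------
# region layouts


@dataclass
class SubRegion:
    label: str            # R1..Rn
    collapse: str         # Upstream / Exon / Downstream
    nominal: int          # nominal size (50 or 250)
    anchor: str           # '5p' or '3p': which end sits at the splice site grid
    sequence: str         # transcript-oriented, length <= nominal


@dataclass
class RegionLayout:
    event_id: str
    event_class: str
    delta_psi: Optional[float]
    subregions: List[SubRegion] = field(default_factory=list)

    def collapsed(self, region: str) -> List[SubRegion]:
        return [s for s in self.subregions if s.collapse == region]


def _sub(genome, chrom, strand, start, end, take, where):
    """Transcript-oriented slice of a genomic feature.

    take = max nucleotides; where = 'first'/'last' in transcript orientation.
    Returns (interval or None).
    """
    if end - start <= 0:
        return None
    n = min(take, end - start)
    first_genomic = (strand == "+") == (where == "first")
    if first_genomic:
        iv = (start, start + n)
    else:
        iv = (end - n, end)
    return GenomicInterval(chrom, iv[0], iv[1], strand)


def build_region_layout(
    event: SpliceEvent,
    genome: GenomeSource,
    exon_flank: int = DEFAULT_EXON_FLANK,
    intron_flank: int = DEFAULT_INTRON_FLANK,
) -> RegionLayout:
    """Class-specific R1..Rn layout around the alternative region.

    Features shorter than twice the nominal flank are split in half between
    their 'first' and 'last' sub-regions so no nucleotide is double counted.
    """
    c = event.coords
    chrom, strand = event.chrom, event.strand
    cls = event.event_class
    alt = dase_region(event)

    def feature_pair(start, end, take):
        # (first, last) split without overlap
        length = end - start
        if length <= 0:
            return None, None
        first_n = min(take, (length + 1) // 2 if length < 2 * take else take)
        last_n = min(take, length - first_n) if length > first_n else 0
        if strand == "+":
            first = (start, start + first_n)
            last = (end - last_n, end) if last_n else None
        else:
            first = (end - first_n, end)
            last = (start, start + last_n) if last_n else None
        out = [GenomicInterval(chrom, *first, strand) if first_n else None,
               GenomicInterval(chrom, *last, strand) if last_n else None]
        return out[0], out[1]

    def exon_block(iv):  # genomic (start, end) of an exon column pair
        return c[iv[0]], c[iv[1]]

    plan: List[Tuple[str, Optional[GenomicInterval], int, str]] = []

    def add(collapse, interval, nominal, anchor):
        plan.append((collapse, interval, nominal, anchor))

    if cls in ("SE", "MXE"):
        if cls == "SE":
            left_exon = ("upstreamES", "upstreamEE")
            right_exon = ("downstreamES", "downstreamEE")
        else:
            # alt exon is transcript-first MXE exon; its transcript-downstream
            # neighbor is the other mutually exclusive exon
            if strand == "+":
                left_exon = ("upstreamES", "upstreamEE")
                right_exon = ("2ndExonStart_0base", "2ndExonEnd")
            else:
                left_exon = ("1stExonStart_0base", "1stExonEnd")
                right_exon = ("downstreamES", "downstreamEE")
        ls, le = exon_block(left_exon)
        rs, re_ = exon_block(right_exon)
        intron_l = (le, alt.start)
        intron_r = (alt.end, rs)
        if strand == "+":
            up_exon, up_intron = (ls, le), intron_l
            dn_intron, dn_exon = intron_r, (rs, re_)
        else:
            up_exon, up_intron = (rs, re_), intron_r
            dn_intron, dn_exon = intron_l, (ls, le)
        add("Upstream", _sub(genome, chrom, strand, *up_exon, exon_flank, "last"), exon_flank, "3p")
        i1, i2 = feature_pair(*up_intron, intron_flank)
        add("Upstream", i1, intron_flank, "5p")
        add("Upstream", i2, intron_flank, "3p")
        e1, e2 = feature_pair(alt.start, alt.end, exon_flank)
        add("Exon", e1, exon_flank, "5p")
        add("Exon", e2, exon_flank, "3p")
        j1, j2 = feature_pair(*dn_intron, intron_flank)
        add("Downstream", j1, intron_flank, "5p")
        add("Downstream", j2, intron_flank, "3p")
        add("Downstream", _sub(genome, chrom, strand, *dn_exon, exon_flank, "first"), exon_flank, "5p")
    elif cls == "RI":
        up = (c["upstreamES"], c["upstreamEE"])
        dn = (c["downstreamES"], c["downstreamEE"])
        if strand == "-":
            up, dn = dn, up
        add("Upstream", _sub(genome, chrom, strand, *up, exon_flank, "last"), exon_flank, "3p")
        i1, i2 = feature_pair(alt.start, alt.end, intron_flank)
        add("Exon", i1, intron_flank, "5p")
        add("Exon", i2, intron_flank, "3p")
        add("Downstream", _sub(genome, chrom, strand, *dn, exon_flank, "first"), exon_flank, "5p")
    elif cls in ("A3SS", "A5SS"):
        fs, fe = c["flankingES"], c["flankingEE"]
        ss, se = c["shortES"], c["shortEE"]
        ls, le = c["longExonStart_0base"], c["longExonEnd"]
        intron = (fe, ls) if fe <= ls else (le, fs)
        if cls == "A3SS":
            # flanking exon -> intron -> alt region -> short exon (transcript order)
            add("Upstream", _sub(genome, chrom, strand, fs, fe, exon_flank, "last"), exon_flank, "3p")
            i1, i2 = feature_pair(*intron, intron_flank)
            add("Upstream", i1, intron_flank, "5p")
            add("Upstream", i2, intron_flank, "3p")
            e1, e2 = feature_pair(alt.start, alt.end, exon_flank)
            add("Exon", e1, exon_flank, "5p")
            add("Exon", e2, exon_flank, "3p")
            add("Downstream", _sub(genome, chrom, strand, ss, se, exon_flank, "first"), exon_flank, "5p")
        else:
            # short exon -> alt region -> intron -> flanking exon
            add("Upstream", _sub(genome, chrom, strand, ss, se, exon_flank, "last"), exon_flank, "3p")
            e1, e2 = feature_pair(alt.start, alt.end, exon_flank)
            add("Exon", e1, exon_flank, "5p")
            add("Exon", e2, exon_flank, "3p")
            i1, i2 = feature_pair(*intron, intron_flank)
            add("Downstream", i1, intron_flank, "5p")
            add("Downstream", i2, intron_flank, "3p")
            add("Downstream", _sub(genome, chrom, strand, fs, fe, exon_flank, "first"), exon_flank, "5p")
    else:  # pragma: no cover
        raise ValueError(f"unknown event class {cls!r}")

    layout = RegionLayout(event.event_id, cls, event.delta_psi)
    k = 0
    for collapse, interval, nominal, anchor in plan:
        if interval is None:
            continue
        k += 1
        layout.subregions.append(SubRegion(
            label=f"R{k}", collapse=collapse, nominal=nominal, anchor=anchor,
            sequence=as_rna(extract_sequence(genome, interval)),
        ))
    if k == 0:
        raise ValueError(f"event {event.event_id}: no layout sub-regions")
    return layout


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


def _rank_sum(pooled: np.ndarray, idx: Sequence[int]) -> float:
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1  # midranks
        i = j + 1
    return float(ranks[list(idx)].sum())


def wilcoxon_window_test(group_values: Sequence[float],
                         background_values: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration of all assignments when both samples have <= 8
    observations (valid under ties); otherwise the normal approximation with
    tie and continuity corrections. Degenerate input (every pooled value
    identical) gives p = 1.
    """
    x = np.asarray(group_values, dtype=float)
    y = np.asarray(background_values, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("both samples must have >= 3 observations")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    n, m = len(x), len(y)
    if n <= 8 and m <= 8:
        observed = _rank_sum(pooled, range(n))
        lo = hi = 0
        total = 0
        for combo in itertools.combinations(range(n + m), n):
            w = _rank_sum(pooled, combo)
            total += 1
            if w <= observed + 1e-9:
                lo += 1
            if w >= observed - 1e-9:
                hi += 1
        return min(1.0, 2.0 * min(lo, hi) / total)
    res = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                       use_continuity=True)
    p = float(res.pvalue)
    return 1.0 if math.isnan(p) else min(p, 1.0)


# ---------------------------------------------------------------------------
# density profiles


@dataclass
class DensityProfile:
    """Per-window motif densities and direction-vs-background p-values."""

    motif: str
    event_class: str
    window: int
    #: label -> dict with keys 'collapse', 'grid' (grid length), 'mean' (per
    #: group), 'p_up', 'p_down' (np.nan where a group lacks >=3 contributors)
    regions: Dict[str, Dict] = field(default_factory=dict)

    def significant_windows(self, direction: str, alpha: float) -> List[Tuple[str, int]]:
        key = f"p_{direction}"
        out = []
        for label, reg in self.regions.items():
            pvals = reg[key]
            if pvals is None:
                continue
            for w in np.nonzero(pvals < alpha)[0]:
                out.append((label, int(w)))
        return out


def _window_densities(sub: SubRegion, motif: Motif, window: int) -> np.ndarray:
    """Densities on the nominal grid; NaN where the window is not fully
    inside the (possibly truncated) sequence."""
    grid = sub.nominal - window + 1
    out = np.full(max(grid, 0), np.nan)
    seq = sub.sequence
    if grid <= 0 or len(seq) < window:
        return out
    cov = motif_coverage(seq, motif).astype(float)
    sums = np.convolve(cov, np.ones(window), mode="valid")  # len(seq)-window+1
    dens = sums / window
    offset = 0 if sub.anchor == "5p" else sub.nominal - len(seq)
    out[offset:offset + len(dens)] = dens
    return out


def _layout_template(layouts: Sequence[RegionLayout]) -> List[Tuple[str, str, int, str]]:
    # (label, collapse, nominal, anchor) union across events, in R-order
    seen = {}
    for lay in layouts:
        for sub in lay.subregions:
            seen.setdefault(sub.label, (sub.collapse, sub.nominal, sub.anchor))
    return [(lbl, *seen[lbl]) for lbl in sorted(seen, key=lambda s: int(s[1:]))]


def density_profile(
    layouts_by_group: Dict[str, Sequence[RegionLayout]],
    motif: Motif,
    window: int = DEFAULT_WINDOW,
) -> DensityProfile:
    """Sliding-window motif density per group with per-window rank-sum tests.

    ``layouts_by_group`` keys: 'up', 'down', 'background' (groups may be
    absent or empty; their profiles are then absent and the comparison is
    skipped with a log entry).
    """
    all_layouts = [l for ls in layouts_by_group.values() for l in ls]
    if not all_layouts:
        raise ValueError("no events supplied")
    classes = {l.event_class for l in all_layouts}
    if len(classes) > 1:
        raise ValueError(f"mixed event classes in one profile: {classes}")
    template = _layout_template(all_layouts)
    profile = DensityProfile(motif.rbp_name, classes.pop(), window)
    per_group: Dict[str, Dict[str, np.ndarray]] = {}
    for group, layouts in layouts_by_group.items():
        if not layouts:
            logger.info("group %r empty; profile absent", group)
            continue
        mats: Dict[str, List[np.ndarray]] = {lbl: [] for lbl, *_ in template}
        for lay in layouts:
            subs = {s.label: s for s in lay.subregions}
            for lbl, collapse, nominal, anchor in template:
                sub = subs.get(lbl)
                if sub is None:
                    sub = SubRegion(lbl, collapse, nominal, anchor, "")
                mats[lbl].append(_window_densities(sub, motif, window))
        per_group[group] = {lbl: np.vstack(v) for lbl, v in mats.items()}

    bg = per_group.get("background")
    for lbl, collapse, nominal, anchor in template:
        grid = max(nominal - window + 1, 0)
        reg: Dict = {"collapse": collapse, "grid": grid, "mean": {}}
        for group, mats in per_group.items():
            mat = mats[lbl]
            counts = np.sum(~np.isnan(mat), axis=0)
            sums = np.nansum(mat, axis=0)
            reg["mean"][group] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        for direction in ("up", "down"):
            key = f"p_{direction}"
            reg[key] = None
            if bg is None or direction not in per_group:
                continue
            gm, bm = per_group[direction][lbl], bg[lbl]
            pvals = np.full(grid, np.nan)
            for w in range(grid):
                gv = gm[:, w][~np.isnan(gm[:, w])]
                bv = bm[:, w][~np.isnan(bm[:, w])]
                if len(gv) >= 3 and len(bv) >= 3:
                    pvals[w] = wilcoxon_window_test(gv, bv)
            reg[key] = pvals
        profile.regions[lbl] = reg
    return profile


def summarize_enrichment(
    profiles: Iterable[DensityProfile],
    alpha: float = 0.05,
) -> Set[Tuple[str, str, str, str]]:
    """Significant (rbp, event_class, direction, collapsed region) tuples.

    A tuple is significant when >= 1 window of that collapsed region has
    p < alpha in the matching direction-vs-background test.
    """
    summary = set()
    for prof in profiles:
        for direction in ("up", "down"):
            for label, reg in prof.regions.items():
                pvals = reg[f"p_{direction}"]
                if pvals is None:
                    continue
                if np.any(pvals[~np.isnan(pvals)] < alpha):
                    summary.add((prof.motif, prof.event_class, direction,
                                 reg["collapse"]))
    return summary


@dataclass
class CoherentOccurrence:
    event_id: str
    rbp_name: str
    region: str                 # collapsed region
    positions: List[int]        # 0-based within the concatenated region


def coherent_occurrences(
    layouts: Sequence[RegionLayout],
    motifs: Sequence[Motif],
    summary: Set[Tuple[str, str, str, str]],
) -> List[CoherentOccurrence]:
    """Motif occurrences on events of interest that match the enrichment
    summary for the event's class, dPSI direction and collapsed region."""
    out = []
    for lay in layouts:
        if lay.delta_psi is None or lay.delta_psi == 0:
            logger.info("event %s has dPSI 0/undefined; excluded", lay.event_id)
            continue
        direction = "up" if lay.delta_psi > 0 else "down"
        for motif in motifs:
            for region in COLLAPSED_REGIONS:
                if (motif.rbp_name, lay.event_class, direction, region) not in summary:
                    continue
                positions = []
                offset = 0
                for sub in lay.collapsed(region):
                    positions.extend(p + offset for p in motif_scan(sub.sequence, motif))
                    offset += len(sub.sequence)
                if positions:
                    out.append(CoherentOccurrence(lay.event_id, motif.rbp_name,
                                                  region, positions))
    return out


# ---------------------------------------------------------------------------
# RBP network reduction


@dataclass
class RBPNetwork:
    """Physical-interaction network over RBPs with DEG flags."""

    nodes: Dict[str, str]              # name -> 'up' / 'down' / 'none'
    edges: List[Tuple[str, str]]

    def __post_init__(self):
        for a, b in self.edges:
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(f"edge ({a},{b}) references unknown node")


def reduce_rbp_network(network: RBPNetwork) -> RBPNetwork:
    """Drop non-DEG nodes with no path to any DEG node; keep all DEG nodes.

    Idempotent; the retained node set grows monotonically with the DEG set.
    """
    g = nx.Graph()
    g.add_nodes_from(network.nodes)
    g.add_edges_from(network.edges)
    deg_nodes = {n for n, flag in network.nodes.items() if flag != "none"}
    keep = set(deg_nodes)
    for comp in nx.connected_components(g):
        if comp & deg_nodes:
            keep |= comp
    nodes = {n: f for n, f in network.nodes.items() if n in keep}
    edges = [(a, b) for a, b in network.edges if a in keep and b in keep]
    return RBPNetwork(nodes, edges)
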