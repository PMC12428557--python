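"""miRNA-DASE hybridization cascade: mfe filter, seed/post-seed
classification, position-1 adenosine annotation and brain-expression
percentile filtering.

Seed = miRNA positions 2-7; post-seed = positions 13-16. Only perfect
Watson-Crick pairs (A-U, G-C) count as matches for classification; G.U
wobble counts as a non-match even though the energy model rewards it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from Bio import SeqIO

from .duplex import DuplexHit, EnergyModel, as_rna, default_energy_model, duplex_mfe
from .events import SpliceEvent, dase_region
from .intervals import GenomeSource, extract_sequence

logger = logging.getLogger(__name__)

SEED_POSITIONS = tuple(range(2, 8))        # miRNA positions 2..7, 1-based
POST_SEED_POSITIONS = tuple(range(13, 17))  # positions 13..16

SEED_CLASSES = ("Canonical", "Strong", "Compensatory", "Unclassified")


@dataclass(frozen=True)
class MiRNARecord:
    mirna_id: str
    sequence: str  # RNA 5'->3'

    def __post_init__(self):
        seq = self.sequence.upper()
        if set(seq) - set("ACGU"):
            raise ValueError(f"{self.mirna_id}: non-RNA characters in sequence")
        if not 18 <= len(seq) <= 26:
            raise ValueError(f"{self.mirna_id}: length {len(seq)} outside 18..26")
        object.__setattr__(self, "sequence", seq)


def read_mirna_fasta(path: str) -> List[MiRNARecord]:
    records = []
    for rec in SeqIO.parse(path, "fasta"):
        records.append(MiRNARecord(rec.id, as_rna(str(rec.seq))))
    return records


def classify_seed(hit: DuplexHit) -> str:
    """Assign Canonical / Strong / Compensatory from the pairing map.

    Strong: all seed and all post-seed positions Watson-Crick paired.
    Canonical: all seed WC, post-seed not all WC. Compensatory: >=1 seed
    position non-WC while all post-seed positions are WC. Anything else is
    Unclassified (excluded downstream). A miRNA shorter than 16 nt cannot be
    classified.
    """
    pm = hit.pairing_map
    if len(pm) < POST_SEED_POSITIONS[-1]:
        logger.warning("%s: miRNA shorter than 16 nt, cannot classify", hit.mirna_id)
        return "Unclassified"
    seed_wc = all(pm[p - 1] == "WC" for p in SEED_POSITIONS)
    post_wc = all(pm[p - 1] == "WC" for p in POST_SEED_POSITIONS)
    if seed_wc and post_wc:
        return "Strong"
    if seed_wc:
        return "Canonical"
    if post_wc:
        return "Compensatory"
    return "Unclassified"


def annotate_a1(hit: DuplexHit, target_seq: str) -> Tuple[bool, bool]:
    """(a1_adenosine, edge_flag): is the target base opposite miRNA position 1
    an adenosine?

    Position 1 is usually unpaired; its opposite base is then the target base
    immediately 3' (in target orientation) of the partner of position 2. At
    the target boundary the annotation is False with the edge flag set.
    """
    if not hit.is_hit:
        return False, False
    t = as_rna(target_seq)
    p1 = hit.partner_index[0] if len(hit.partner_index) > 0 else None
    if p1 is not None:
        return t[p1] == "A", False
    p2 = hit.partner_index[1] if len(hit.partner_index) > 1 else None
    if p2 is None:
        return False, False
    idx = p2 + 1  # toward the target 3' end
    if idx >= len(t):
        return False, True
    return t[idx] == "A", False


def filter_by_mfe(hits: Iterable[DuplexHit], threshold: float = -30.0,
                  inclusive: bool = True) -> List[DuplexHit]:
    """Keep hits with mfe <= threshold (or strictly < when inclusive=False)."""
    if inclusive:
        return [h for h in hits if h.is_hit and h.mfe <= threshold]
    return [h for h in hits if h.is_hit and h.mfe < threshold]


class ExpressionTable:
    """miRNA id -> tissue expression value (non-negative)."""

    def __init__(self, values: Dict[str, float], provenance: str = ""):
        if any(v < 0 for v in values.values()):
            raise ValueError("expression values must be non-negative")
        self.values = dict(values)
        self.provenance = provenance

    @classmethod
    def from_tsv(cls, path: str) -> "ExpressionTable":
        values = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.lower().startswith("mirna"):
                    continue
                mid, val = line.split("\t")[:2]
                values[mid] = float(val)
        return cls(values, provenance=path)


def percentile_filter(expr: ExpressionTable, q: float = 85.0) -> Set[str]:
    """miRNAs in the high-expression range of the expressed-in-tissue universe.

    Universe = ids with expression > 0; threshold = the q-th percentile of the
    universe's values (linear interpolation); retained ids have value >=
    threshold (inclusive).
    """
    universe = {k: v for k, v in expr.values.items() if v > 0}
    if not universe:
        logger.warning("empty expression universe; nothing retained")
        return set()
    threshold = float(np.percentile(list(universe.values()), q))
    return {k for k, v in universe.items() if v >= threshold}


@dataclass
class HybridizationRow:
    event_id: str
    event_class: str
    gene_symbol: str
    mirna_id: str
    delta_psi: Optional[float]
    mfe: float
    seed_class: str
    a1_adenosine: bool


def hybridization_pipeline(
    dases: Sequence[SpliceEvent],
    genome: GenomeSource,
    mirnas: Sequence[MiRNARecord],
    expr: ExpressionTable,
    model: Optional[EnergyModel] = None,
    mfe_threshold: float = -30.0,
    expression_percentile: float = 85.0,
) -> Tuple[List[HybridizationRow], Dict[str, int]]:
    """Best hit per (miRNA, DASE region) pair, then the three-stage cascade:
    mfe filter -> seed classification (Unclassified dropped) -> expression
    percentile filter. Returns the annotated rows and per-stage pair counts.
    """
    model = model or default_energy_model()
    stage = {"pairs_scanned": 0, "predicted": 0, "mfe_filtered": 0,
             "classified": 0, "expressed": 0}
    hits: List[Tuple[DuplexHit, SpliceEvent, str]] = []
    for ev in sorted(dases, key=lambda e: e.sort_key):
        region_seq = as_rna(extract_sequence(genome, dase_region(ev)))
        for mir in mirnas:
            if len(region_seq) < len(mir.sequence):
                logger.info("region %s shorter than %s; pair skipped",
                            ev.event_id, mir.mirna_id)
                continue
            stage["pairs_scanned"] += 1
            hit = duplex_mfe(mir.sequence, region_seq, model,
                             mirna_id=mir.mirna_id, event_id=ev.event_id)
            if hit.is_hit:
                stage["predicted"] += 1
                hits.append((hit, ev, region_seq))

    kept = [(h, ev, seq) for h, ev, seq in hits if h.mfe <= mfe_threshold]
    stage["mfe_filtered"] = len(kept)

    classified = []
    for hit, ev, seq in kept:
        hit.seed_class = classify_seed(hit)
        if hit.seed_class == "Unclassified":
            continue
        hit.a1_adenosine, hit.a1_edge = annotate_a1(hit, seq)
        classified.append((hit, ev))
    stage["classified"] = len(classified)

    high_expr = percentile_filter(expr, expression_percentile)
    rows = [
        HybridizationRow(ev.event_id, ev.event_class, ev.gene_symbol,
                         hit.mirna_id, ev.delta_psi, hit.mfe,
                         hit.seed_class, hit.a1_adenosine)
        for hit, ev in classified if hit.mirna_id in high_expr
    ]
    stage["expressed"] = len(rows)
    logger.info("hybridization cascade: %s", stage)
    return rows, stage


def write_hybridization_tsv(rows: Sequence[HybridizationRow], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("event_class\tgene_symbol\tevent_id\tmirna\tdelta_psi\t"
                 "mfe_kcal_mol\tseed_class\ta1_adenosine\n")
        for r in rows:
            dpsi = "NA" if r.delta_psi is None else f"{r.delta_psi:.4g}"
            fh.write(f"{r.event_class}\t{r.gene_symbol}\t{r.event_id}\t"
                     f"{r.mirna_id}\t{dpsi}\t{r.mfe:.1f}\t{r.seed_class}\t"
                     f"{str(r.a1_adenosine)}\n")
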