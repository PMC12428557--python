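"""Synthetic dataset generator with machine-readable ground truth.

Emits a toy genome (one contig per gene), a GTF with exons and phased CDS, per
event class rMATS-format junction-count tables, a miRNA FASTA, a tissue
expression table, an RBP motif list, a PPI edge list with DEG flags, and a
truth JSON describing every planted feature, so the full pipeline is testable
without any external download.

Study-shaped defaults: two biological replicates per group; junction counts
Binomial(depth, length-adjusted inclusion probability) per replicate with an
optional beta-binomial overdispersion dial; exons 30-500 nt and introns
80-5000 nt so flank truncation is exercised.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .duplex import PAIRS, as_rna
from .hybrid import MiRNARecord, SEED_POSITIONS, POST_SEED_POSITIONS
from .intervals import reverse_complement
from .motifs import IUPAC_RNA
from .orf import STOP_CODONS

logger = logging.getLogger(__name__)

DNA = "ACGT"
_RNA2DNA = str.maketrans("U", "T")


@dataclass
class SyntheticConfig:
    seed: int = 0
    events_per_class: Dict[str, int] = field(default_factory=lambda: {
        "SE": 12, "MXE": 6, "RI": 8, "A3SS": 6, "A5SS": 6})
    replicates: int = 2
    depth: int = 200
    dase_fraction: float = 0.5
    dase_delta_range: Tuple[float, float] = (0.3, 0.6)
    exon_size_range: Tuple[int, int] = (30, 500)
    intron_size_range: Tuple[int, int] = (80, 5000)
    overdispersion: float = 0.0           # beta-binomial rho; 0 = binomial
    n_mirnas: int = 24
    mirna_length: int = 22
    planted_stops_range: Tuple[int, int] = (1, 3)
    n_strong_sites: int = 2
    n_seed_mut_sites: int = 2
    n_post_mut_sites: int = 2
    motif_rbp: str = "RBFOX1"
    motif_pattern: str = "UGCAUG"
    motif_base_rate: float = 1.0          # expected occurrences per flank
    motif_enrichment: float = 3.0         # rate multiplier in enriched events
    motif_direction: str = "down"         # enriched dPSI direction
    pad: int = 60

    def validate(self) -> None:
        if not 0 <= self.dase_fraction <= 1:
            raise ValueError("dase_fraction must be in [0,1]")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.replicates < 1:
            raise ValueError("need >= 1 replicate per group")
        lo, hi = self.dase_delta_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("dase_delta_range must satisfy 0 < lo <= hi <= 1")
        if min(self.exon_size_range) < 30:
            raise ValueError("exons must be >= 30 nt (miRNA sites must fit)")


# effective lengths in junction equivalents per class (inclusion, skipping)
EFFECTIVE_LENGTHS = {"SE": (2, 1), "MXE": (2, 2), "RI": (2, 1),
                     "A3SS": (1, 1), "A5SS": (1, 1)}


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(DNA), size=n))


def _concretize_iupac(pattern: str, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(IUPAC_RNA[c])) for c in as_rna(pattern))


def _hard_mismatch(mirna_base: str, rng: np.random.Generator) -> str:
    """A target base forming neither a WC nor a wobble pair with mirna_base."""
    options = [b for b in "ACGU" if (mirna_base + b) not in PAIRS]
    return str(rng.choice(options))


@dataclass
class PlantedSite:
    mirna_id: str
    offset: int                      # 0-based start within the region sequence
    mutated_positions: List[int]     # 1-based miRNA positions
    expected_class: str


def plant_mirna_site(
    region_seq: str,
    mirna: MiRNARecord,
    n_mutations: int = 0,
    rng: Optional[np.random.Generator] = None,
    mutate_in: Optional[str] = None,
    offset: Optional[int] = None,
) -> Tuple[str, PlantedSite]:
    """Embed a (near-)perfect antisense site for ``mirna`` in ``region_seq``.

    The site is the reverse complement of the miRNA with ``n_mutations``
    substitutions at random miRNA positions (restricted to the seed or
    post-seed when ``mutate_in`` is 'seed'/'post_seed'); substitutions are
    hard mismatches (neither WC nor wobble). Zero mutations give a
    Strong-class site by construction. Returns (modified sequence in the
    region's alphabet, site record).
    """
    rng = rng or np.random.default_rng()
    L = len(mirna.sequence)
    if len(region_seq) < L:
        raise ValueError(f"region ({len(region_seq)} nt) shorter than miRNA ({L} nt)")
    is_dna = "T" in region_seq.upper() or "U" not in region_seq.upper()
    site = reverse_complement(mirna.sequence)  # RNA alphabet
    # miRNA position p (1-based) pairs site index L - p
    pools = {"seed": list(SEED_POSITIONS), "post_seed": list(POST_SEED_POSITIONS),
             None: list(range(1, L + 1))}
    pool = pools[mutate_in]
    positions = sorted(rng.choice(pool, size=n_mutations, replace=False).tolist()) \
        if n_mutations else []
    site_list = list(site)
    for p in positions:
        site_list[L - p] = _hard_mismatch(mirna.sequence[p - 1], rng)
    site = "".join(site_list)
    seed_wc = not any(p in SEED_POSITIONS for p in positions)
    post_wc = not any(p in POST_SEED_POSITIONS for p in positions)
    expected = ("Strong" if seed_wc and post_wc else
                "Canonical" if seed_wc else
                "Compensatory" if post_wc else "Unclassified")
    if offset is None:
        offset = int(rng.integers(0, len(region_seq) - L + 1))
    if is_dna:
        site = site.translate(_RNA2DNA)
    new_seq = region_seq[:offset] + site + region_seq[offset + L:]
    return new_seq, PlantedSite(mirna.mirna_id, offset, positions, expected)


def _scrub_stops(seq: str, frame: int, rng: np.random.Generator) -> str:
    """Remove every in-frame stop codon by mutating its middle base to C."""
    chars = list(seq)
    for off in range(frame - 1, len(chars) - 2, 3):
        if "".join(chars[off:off + 3]) in STOP_CODONS:
            chars[off + 1] = "C"
    return "".join(chars)


def _naive_stop_positions(seq: str, frame: int) -> List[int]:
    # independent direct rescan used to freeze the truth record
    return [off + 1 for off in range(frame - 1, len(seq) - 2, 3)
            if seq[off:off + 3] in STOP_CODONS]


@dataclass
class SyntheticTruth:
    config: Dict
    events: Dict[str, Dict]
    mirnas: Dict[str, Dict]

    def to_json(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")


@dataclass
class DatasetBundle:
    out_dir: Path
    paths: Dict[str, str]
    truth: SyntheticTruth


# rMATS table headers per class (JC flavor)
_RMATS_STAT_COLS = ("ID", "IJC_SAMPLE_1", "SJC_SAMPLE_1", "IJC_SAMPLE_2",
                    "SJC_SAMPLE_2", "IncFormLen", "SkipFormLen", "PValue",
                    "FDR", "IncLevel1", "IncLevel2", "IncLevelDifference")
_RMATS_HEAD = {
    cls: ["ID", "GeneID", "geneSymbol", "chr", "strand", *coords,
          *_RMATS_STAT_COLS[1:]]
    for cls, coords in {
        "SE": ["exonStart_0base", "exonEnd", "upstreamES", "upstreamEE",
               "downstreamES", "downstreamEE"],
        "MXE": ["1stExonStart_0base", "1stExonEnd", "2ndExonStart_0base",
                "2ndExonEnd", "upstreamES", "upstreamEE", "downstreamES",
                "downstreamEE"],
        "RI": ["riExonStart_0base", "riExonEnd", "upstreamES", "upstreamEE",
               "downstreamES", "downstreamEE"],
        "A3SS": ["longExonStart_0base", "longExonEnd", "shortES", "shortEE",
                 "flankingES", "flankingEE"],
        "A5SS": ["longExonStart_0base", "longExonEnd", "shortES", "shortEE",
                 "flankingES", "flankingEE"],
    }.items()
}


def _draw_counts(rng, depth, psi, lens, replicates, rho):
    li, ls = lens
    q = psi * li / (psi * li + (1 - psi) * ls)
    inc = []
    for _ in range(replicates):
        p = q
        if rho > 0:
            conc = (1 - rho) / rho
            p = rng.beta(q * conc, (1 - q) * conc)
        inc.append(int(rng.binomial(depth, p)))
    return inc, [depth - i for i in inc]


class _GeneBuilder:
    """Assembles one gene in transcript orientation, then maps to genomic."""

    def __init__(self, contig: str, strand: str, pad: int):
        self.contig = contig
        self.strand = strand
        self.pad = pad
        self.features: List[Tuple[str, int, int]] = []  # (name, t_start, t_end)
        self.seq_parts: List[str] = []
        self.cursor = 0

    def add(self, name: str, seq: str) -> None:
        self.features.append((name, self.cursor, self.cursor + len(seq)))
        self.seq_parts.append(seq)
        self.cursor += len(seq)

    def replace(self, name: str, seq: str) -> None:
        for k, (nm, a, b) in enumerate(self.features):
            if nm == name:
                if len(seq) != b - a:
                    raise ValueError("replacement length mismatch")
                self.seq_parts[k] = seq
                return
        raise KeyError(name)

    def feature_seq(self, name: str) -> str:
        for k, (nm, _, _) in enumerate(self.features):
            if nm == name:
                return self.seq_parts[k]
        raise KeyError(name)

    def genomic(self, name: str) -> Tuple[int, int]:
        for nm, a, b in self.features:
            if nm == name:
                if self.strand == "+":
                    return self.pad + a, self.pad + b
                return self.pad + self.cursor - b, self.pad + self.cursor - a
        raise KeyError(name)

    def contig_seq(self, rng) -> str:
        body = "".join(self.seq_parts)
        full = _rand_seq(rng, self.pad) + body + _rand_seq(rng, self.pad)
        return full if self.strand == "+" else reverse_complement(full)


def make_dataset(config: SyntheticConfig, out_dir) -> DatasetBundle:
    """Generate the full file bundle plus its truth record.

    Identical configs (including seed) produce byte-identical bundles.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    out = Path(out_dir)
    (out / "rmats").mkdir(parents=True, exist_ok=True)

    # --- miRNAs and their brain expression ---------------------------------
    mirnas: List[MiRNARecord] = []
    for k in range(config.n_mirnas):
        seq = "".join(rng.choice(list("ACGU"), size=config.mirna_length))
        mirnas.append(MiRNARecord(f"syn-miR-{k + 1}", seq))
    expr_values = np.sort(rng.lognormal(mean=3.0, sigma=1.2, size=config.n_mirnas))
    n_sites = config.n_strong_sites + config.n_seed_mut_sites + config.n_post_mut_sites
    site_mirnas = mirnas[:n_sites]
    # planted miRNAs receive the top expression values so the planted signal
    # survives the percentile filter under default settings
    order = list(range(n_sites)) + list(range(n_sites, config.n_mirnas))
    expr_by_id = {}
    for rank, idx in enumerate(order):
        expr_by_id[mirnas[idx].mirna_id] = float(expr_values[::-1][rank])

    site_plan: List[Tuple[MiRNARecord, int, Optional[str]]] = (
        [(m, 0, None) for m in site_mirnas[:config.n_strong_sites]]
        + [(m, 1, "seed") for m in site_mirnas[config.n_strong_sites:
                                               config.n_strong_sites + config.n_seed_mut_sites]]
        + [(m, 1, "post_seed") for m in site_mirnas[config.n_strong_sites
                                                    + config.n_seed_mut_sites:n_sites]]
    )

    # --- events -------------------------------------------------------------
    contigs: Dict[str, str] = {}
    gtf_lines: List[str] = []
    tables: Dict[str, List[List]] = {cls: [] for cls in _RMATS_HEAD}
    truth_events: Dict[str, Dict] = {}
    gene_no = 0
    site_queue = list(site_plan)

    def rnd(lo, hi):
        return int(rng.integers(lo, hi + 1))

    for cls in ("SE", "MXE", "RI", "A3SS", "A5SS"):
        n_events = config.events_per_class.get(cls, 0)
        n_dase = int(round(n_events * config.dase_fraction))
        for idx in range(n_events):
            gene_no += 1
            gene_id = f"SYNG{gene_no:04d}"
            symbol = f"Syn{gene_no}"
            contig = f"ctg{gene_no:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            gb = _GeneBuilder(contig, strand, config.pad)
            ex = lambda: rnd(*config.exon_size_range)
            intr = lambda: rnd(*config.intron_size_range)

            if cls == "SE":
                for name, ln in (("exonU", ex()), ("intron1", intr()),
                                 ("exonA", ex()), ("intron2", intr()),
                                 ("exonD", ex())):
                    gb.add(name, _rand_seq(rng, ln))
                alt_feature = "exonA"
            elif cls == "MXE":
                for name, ln in (("exonU", ex()), ("intron1", intr()),
                                 ("exonA", ex()), ("intron2", intr()),
                                 ("exonB", ex()), ("intron3", intr()),
                                 ("exonD", ex())):
                    gb.add(name, _rand_seq(rng, ln))
                alt_feature = "exonA"  # transcript-first alternative exon
            elif cls == "RI":
                for name, ln in (("exonU", ex()), ("intron", intr()),
                                 ("exonD", ex())):
                    gb.add(name, _rand_seq(rng, ln))
                alt_feature = "intron"
            else:  # A3SS / A5SS: flanking exon, intron, alt extension + short exon
                alt_len = rnd(30, 120)
                if cls == "A3SS":
                    for name, ln in (("exonF", ex()), ("intron", intr()),
                                     ("alt", alt_len), ("exonS", ex())):
                        gb.add(name, _rand_seq(rng, ln))
                else:
                    for name, ln in (("exonS", ex()), ("alt", alt_len),
                                     ("intron", intr()), ("exonF", ex())):
                        gb.add(name, _rand_seq(rng, ln))
                alt_feature = "alt"

            # ---- truth: PSI and dPSI
            is_dase = idx < n_dase
            psi_c = float(rng.uniform(0.25, 0.6))
            if is_dase:
                delta = float(rng.uniform(*config.dase_delta_range))
                if rng.random() < 0.5:
                    delta = -delta
                psi_t = float(np.clip(psi_c + delta, 0.02, 0.98))
                delta = psi_t - psi_c
            else:
                delta, psi_t = 0.0, psi_c

            event_truth: Dict = {
                "event_class": cls, "gene_id": gene_id, "contig": contig,
                "strand": strand, "psi_control": psi_c, "psi_treatment": psi_t,
                "delta_true": delta, "is_dase": is_dase,
            }

            # ---- planted premature stops in retained introns
            if cls == "RI":
                frame = rnd(1, 3)
                intron_seq = _scrub_stops(gb.feature_seq("intron"), frame, rng)
                n_stops = rnd(*config.planted_stops_range)
                usable = [off for off in range(frame - 1, len(intron_seq) - 2, 3)]
                chosen = sorted(rng.choice(len(usable),
                                           size=min(n_stops, len(usable)),
                                           replace=False).tolist())
                chars = list(intron_seq)
                planted = []
                for c_idx in chosen:
                    off = usable[c_idx]
                    codon = str(rng.choice(list(STOP_CODONS)))
                    chars[off:off + 3] = codon
                    planted.append(off + 1)
                intron_seq = "".join(chars)
                gb.replace("intron", intron_seq)
                event_truth.update(
                    frame=frame, planted_stop_positions=planted,
                    all_stop_positions=_naive_stop_positions(intron_seq, frame),
                )

            # ---- planted miRNA sites in the DASE region (non-RI classes)
            if cls != "RI" and site_queue and is_dase:
                mir, n_mut, where = site_queue.pop(0)
                region_seq = gb.feature_seq(alt_feature)
                new_seq, site = plant_mirna_site(region_seq, mir, n_mut, rng,
                                                 mutate_in=where)
                gb.replace(alt_feature, new_seq)
                event_truth["planted_site"] = asdict(site)

            # ---- planted motif occurrences in the upstream intronic flank (SE)
            if cls == "SE":
                flank_name = "intron1"  # builder is transcript-oriented
                flank = gb.feature_seq(flank_name)
                # window adjacent to the alternative exon, transcript orientation
                win_len = min(250, len(flank))
                rate = config.motif_base_rate
                if is_dase and ((delta < 0) == (config.motif_direction == "down")):
                    rate *= config.motif_enrichment
                n_occ = int(rng.poisson(rate))
                chars = list(flank)
                mlen = len(config.motif_pattern)
                for _ in range(n_occ):
                    inst = _concretize_iupac(config.motif_pattern, rng)
                    inst = inst.translate(_RNA2DNA)
                    pos = len(flank) - win_len + int(rng.integers(0, win_len - mlen + 1))
                    chars[pos:pos + mlen] = inst
                gb.replace(flank_name, "".join(chars))
                event_truth["planted_motif_count"] = n_occ

            # ---- GTF (inclusion isoform) and CDS for RI genes
            contigs[contig] = gb.contig_seq(rng)
            tx_id = f"{gene_id}.t1"
            if cls == "SE":
                exon_names = ["exonU", "exonA", "exonD"]
            elif cls == "MXE":
                exon_names = ["exonU", "exonA", "exonD"]
            elif cls == "RI":
                exon_names = ["exonU", "intron", "exonD"]  # retained isoform
            elif cls == "A3SS":
                exon_names = ["exonF", "alt", "exonS"]
            else:
                exon_names = ["exonS", "alt", "exonF"]
            exon_ivs = sorted(gb.genomic(nm) for nm in exon_names)
            attrs = (f'gene_id "{gene_id}"; transcript_id "{tx_id}"; '
                     f'gene_name "{symbol}";')
            for s, e in exon_ivs:
                gtf_lines.append(f"{contig}\tsyn\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t{attrs}")
            if cls == "RI":
                # CDS over the two flanking exons with the planted frame at the
                # junction: frame f needs c coding bases (c mod 3) before the
                # intron with f = 1 + ((3 - c mod 3) mod 3)
                c_req = {1: 0, 2: 2, 3: 1}[event_truth["frame"]]
                exu_len = len(gb.feature_seq("exonU"))
                offset = (exu_len - c_req) % 3
                up_g = gb.genomic("exonU")
                dn_g = gb.genomic("exonD")
                if strand == "+":
                    cds = [(up_g[0] + offset, up_g[1]), (dn_g[0], dn_g[1])]
                else:
                    cds = [(up_g[0], up_g[1] - offset), (dn_g[0], dn_g[1])]
                consumed = 0
                for s, e in cds:  # already in transcript order
                    phase = (3 - consumed % 3) % 3
                    gtf_lines.append(
                        f"{contig}\tsyn\tCDS\t{s + 1}\t{e}\t.\t{strand}\t{phase}\t{attrs}")
                    consumed += e - s

            # ---- rMATS row
            lens = EFFECTIVE_LENGTHS[cls]
            inc_t, skp_t = _draw_counts(rng, config.depth, psi_t, lens,
                                        config.replicates, config.overdispersion)
            inc_c, skp_c = _draw_counts(rng, config.depth, psi_c, lens,
                                        config.replicates, config.overdispersion)

            def psis(incs, skps):
                vals = []
                for i, s in zip(incs, skps):
                    if i + s == 0:
                        vals.append("NA")
                    else:
                        vals.append(f"{(i / lens[0]) / (i / lens[0] + s / lens[1]):.4f}")
                return vals

            p_t, p_c = psis(inc_t, skp_t), psis(inc_c, skp_c)
            mt = np.mean([float(v) for v in p_t if v != "NA"]) if any(v != "NA" for v in p_t) else None
            mc = np.mean([float(v) for v in p_c if v != "NA"]) if any(v != "NA" for v in p_c) else None
            ild = "NA" if mt is None or mc is None else f"{mt - mc:.4f}"

            if cls == "SE":
                coords = [*gb.genomic("exonA"), *gb.genomic("exonU"), *gb.genomic("exonD")]
                if strand == "-":
                    coords = [*gb.genomic("exonA"), *gb.genomic("exonD"), *gb.genomic("exonU")]
            elif cls == "MXE":
                a, b = gb.genomic("exonA"), gb.genomic("exonB")
                first, second = (a, b) if a[0] < b[0] else (b, a)
                flanks = sorted([gb.genomic("exonU"), gb.genomic("exonD")])
                coords = [*first, *second, *flanks[0], *flanks[1]]
            elif cls == "RI":
                exons = sorted([gb.genomic("exonU"), gb.genomic("exonD")])
                coords = [exons[0][0], exons[1][1], *exons[0], *exons[1]]
            else:
                alt_g = gb.genomic("alt")
                short_g = gb.genomic("exonS")
                long_g = (min(alt_g[0], short_g[0]), max(alt_g[1], short_g[1]))
                coords = [*long_g, *short_g, *gb.genomic("exonF")]

            tables[cls].append([
                idx, gene_id, f'"{symbol}"', contig, strand, *coords,
                ",".join(map(str, inc_t)), ",".join(map(str, skp_t)),
                ",".join(map(str, inc_c)), ",".join(map(str, skp_c)),
                lens[0], lens[1], "NA", "NA",
                ",".join(p_t), ",".join(p_c), ild,
            ])
            truth_events[f"{cls}_{idx}"] = event_truth

    # --- write files ---------------------------------------------------------
    paths: Dict[str, str] = {}

    fasta = out / "genome.fa"
    with open(fasta, "w") as fh:
        for name in sorted(contigs):
            fh.write(f">{name}\n")
            seq = contigs[name]
            for k in range(0, len(seq), 80):
                fh.write(seq[k:k + 80] + "\n")
    paths["genome"] = str(fasta)

    gtf = out / "annotation.gtf"
    with open(gtf, "w") as fh:
        fh.write("\n".join(gtf_lines) + "\n")
    paths["gtf"] = str(gtf)

    for cls, rows in tables.items():
        p = out / "rmats" / f"{cls}.MATS.JC.txt"
        with open(p, "w") as fh:
            fh.write("\t".join(_RMATS_HEAD[cls]) + "\n")
            for row in rows:
                fh.write("\t".join(map(str, row)) + "\n")
        paths[f"rmats_{cls}"] = str(p)

    mfa = out / "mirnas.fa"
    with open(mfa, "w") as fh:
        for m in mirnas:
            fh.write(f">{m.mirna_id}\n{m.sequence}\n")
    paths["mirnas"] = str(mfa)

    etsv = out / "mirna_expression.tsv"
    with open(etsv, "w") as fh:
        fh.write("mirna\tbrain_expression\n")
        for m in mirnas:
            fh.write(f"{m.mirna_id}\t{expr_by_id[m.mirna_id]:.4f}\n")
    paths["expression"] = str(etsv)

    mot = out / "motifs.tsv"
    with open(mot, "w") as fh:
        fh.write(f"{config.motif_rbp}\t{config.motif_pattern}\n")
    paths["motifs"] = str(mot)

    ppi = out / "ppi_edges.tsv"
    deg = out / "degs.tsv"
    srsf = [f"SRSF{k}" for k in (1, 2, 3, 6, 7, 9)]
    fxr = ["FXR1", "FXR2", "FMR1"]
    singles = ["ANKHD1", "HNRNPK", "PABPC4", "RBFOX1"]
    decoys = ["PTBP1", "U2AF2"]
    with open(ppi, "w") as fh:
        fh.write("a\tb\n")
        for i, a in enumerate(srsf):
            for b in srsf[i + 1:]:
                fh.write(f"{a}\t{b}\n")
        for i, a in enumerate(fxr):
            for b in fxr[i + 1:]:
                fh.write(f"{a}\t{b}\n")
        fh.write(f"{decoys[0]}\t{decoys[1]}\n")
    with open(deg, "w") as fh:
        fh.write("gene\tlog2fc\tpadj\n")
        for g in ("SRSF7", "FXR1", "HNRNPK", "PABPC4", "RBFOX1"):
            fh.write(f"{g}\t-1.2\t0.01\n")
        fh.write("ANKHD1\t0.9\t0.01\n")
        for g in srsf[:-2] + fxr[1:] + decoys:
            fh.write(f"{g}\t0.05\t0.9\n")
    paths["ppi"] = str(ppi)
    paths["degs"] = str(deg)

    expr_sorted = np.sort(list(expr_by_id.values()))
    truth = SyntheticTruth(
        config={k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(config).items()},
        events=truth_events,
        mirnas={m.mirna_id: {
            "sequence": m.sequence,
            "expression": expr_by_id[m.mirna_id],
            "percentile_rank": float(
                100.0 * (np.searchsorted(expr_sorted, expr_by_id[m.mirna_id],
                                         side="right") - 1)
                / max(len(expr_sorted) - 1, 1)),
        } for m in mirnas},
    )
    truth.to_json(out / "truth.json")
    paths["truth"] = str(out / "truth.json")
    return DatasetBundle(out, paths, truth)


def bundle_digest(bundle: DatasetBundle) -> Dict[str, str]:
    """SHA-256 of every emitted file (determinism checks)."""
    out = {}
    for key in sorted(bundle.paths):
        h = hashlib.sha256()
        h.update(Path(bundle.paths[key]).read_bytes())
        out[key] = h.hexdigest()
    return out
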