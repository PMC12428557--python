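"""End-to-end orchestration: filter -> regions -> ri-stops -> mirna ->
rbp-maps -> ora, with provenance stamped into every output."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import yaml

from . import __version__
from .annotation import cds_intervals_for_contig, load_cds_by_transcript
from .events import (EVENT_CLASSES, call_dases_from_counts, filter_dases,
                     read_rmats_events, write_events_tsv, write_regions_bed)
from .hybrid import (ExpressionTable, hybridization_pipeline, read_mirna_fasta,
                     write_hybridization_tsv)
from .intervals import GenomeSource
from .motifs import (CoherentOccurrence, RBPNetwork, build_region_layout,
                     coherent_occurrences, density_profile, read_motif_tsv,
                     reduce_rbp_network, summarize_enrichment)
from .ora import AnnotationMap, fisher_ora, write_ora_tsv
from .orf import determine_frame, ri_stop_report, write_stop_report_tsv

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    rmats_dir: str
    genome: str
    out_dir: str
    gtf: Optional[str] = None
    mirnas: Optional[str] = None
    expression: Optional[str] = None
    motifs: Optional[str] = None
    ppi: Optional[str] = None
    degs: Optional[str] = None
    gmt: Optional[str] = None
    fdr_max: float = 0.05
    min_abs_dpsi: float = 0.1
    min_mean_coverage: float = 5.0
    mfe_threshold: float = -30.0
    expression_percentile: float = 85.0
    alpha: float = 0.05
    seed: int = 0
    frames: Dict[str, int] = field(default_factory=dict)  # user frame overrides

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def validate(self) -> None:
        if not 0 <= self.fdr_max <= 1 or not 0 <= self.alpha <= 1:
            raise ValueError("fdr_max and alpha must be in [0,1]")
        if not 0 <= self.min_abs_dpsi <= 1:
            raise ValueError("min_abs_dpsi must be in [0,1]")
        if not 0 <= self.expression_percentile <= 100:
            raise ValueError("expression_percentile must be in [0,100]")
        for attr in ("rmats_dir", "genome"):
            if not Path(getattr(self, attr)).exists():
                raise FileNotFoundError(f"{attr}: {getattr(self, attr)}")

    def digest(self) -> str:
        blob = json.dumps(
            {k: v for k, v in self.__dict__.items()}, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _stamp(path: Path, config_hash: str) -> None:
    text = path.read_text()
    path.write_text(f"# splicedown {__version__} config={config_hash}\n" + text)


def run_all(config: RunConfig) -> Dict:
    """Execute every stage; returns the machine-readable run report.

    Any stage failure aborts with the stage name; outputs of completed stages
    are retained in the output directory.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.digest()
    report: Dict = {"version": __version__, "config_hash": chash, "stages": {}}
    stage = "load"
    try:
        events = []
        for cls in EVENT_CLASSES:
            p = Path(config.rmats_dir) / f"{cls}.MATS.JC.txt"
            if p.exists():
                events.extend(read_rmats_events(str(p), cls))
        if not events:
            raise FileNotFoundError(f"no rMATS tables under {config.rmats_dir}")
        if any(ev.fdr is None for ev in events):
            call_dases_from_counts(events)
        report["stages"]["load"] = {"events": len(events)}

        stage = "filter"
        dases = filter_dases(events, config.fdr_max, config.min_abs_dpsi,
                             config.min_mean_coverage)
        background = [ev for ev in events if ev not in dases and ev.testable]
        write_events_tsv(dases, str(out / "dases.tsv"))
        write_events_tsv(events, str(out / "all_events.tsv"))
        report["stages"]["filter"] = {"dases": len(dases),
                                      "background": len(background)}

        stage = "regions"
        genome = GenomeSource(config.genome)
        write_regions_bed(dases, str(out / "dase_regions.bed"))
        report["stages"]["regions"] = {"regions": len(dases)}

        stage = "ri_stops"
        ri = [ev for ev in dases if ev.event_class == "RI"]
        frames, skipped = {}, []
        cds_by_tx = load_cds_by_transcript(config.gtf) if config.gtf else {}
        for ev in ri:
            try:
                frames[ev.event_id], _ = determine_frame(
                    ev, cds_intervals_for_contig(cds_by_tx, ev.chrom),
                    user_frame=config.frames.get(ev.event_id))
            except ValueError:
                skipped.append(ev.event_id)
        scanned = [ev for ev in ri if ev.event_id in frames]
        stops = ri_stop_report(scanned, genome, frames)
        write_stop_report_tsv(stops, str(out / "ri_stops.tsv"), scanned)
        report["stages"]["ri_stops"] = {
            "ri_dases": len(ri), "scanned": len(scanned),
            "skipped_no_frame": skipped,
            "with_stops": sum(1 for s in stops if s.stop_count),
        }

        stage = "mirna"
        if config.mirnas and config.expression:
            mirnas = read_mirna_fasta(config.mirnas)
            expr = ExpressionTable.from_tsv(config.expression)
            rows, counts = hybridization_pipeline(
                dases, genome, mirnas, expr,
                mfe_threshold=config.mfe_threshold,
                expression_percentile=config.expression_percentile)
            write_hybridization_tsv(rows, str(out / "hybridizations.tsv"))
            report["stages"]["mirna"] = counts
        else:
            report["stages"]["mirna"] = "skipped (no miRNA/expression input)"

        stage = "rbp_maps"
        if config.motifs:
            motifs = read_motif_tsv(config.motifs)
            by_class: Dict[str, Dict[str, List]] = {}
            for ev in events:
                if not ev.testable or ev.delta_psi is None:
                    continue
                group = ("background" if ev not in dases
                         else "up" if ev.delta_psi > 0
                         else "down" if ev.delta_psi < 0 else None)
                if group is None:
                    continue
                lay = build_region_layout(ev, genome)
                by_class.setdefault(ev.event_class, {"up": [], "down": [],
                                                     "background": []})[group].append(lay)
            profiles = []
            for cls, groups in sorted(by_class.items()):
                for motif in motifs:
                    profiles.append(density_profile(groups, motif))
            summary = summarize_enrichment(profiles, config.alpha)
            dase_layouts = [lay for groups in by_class.values()
                            for grp in ("up", "down") for lay in groups[grp]]
            occ = coherent_occurrences(dase_layouts, motifs, summary)
            with open(out / "rbp_summary.tsv", "w") as fh:
                fh.write("rbp\tevent_class\tdirection\tregion\n")
                for tup in sorted(summary):
                    fh.write("\t".join(tup) + "\n")
            with open(out / "rbp_coherent_occurrences.tsv", "w") as fh:
                fh.write("event_id\trbp\tregion\tpositions\n")
                for o in sorted(occ, key=lambda o: (o.event_id, o.rbp_name, o.region)):
                    fh.write(f"{o.event_id}\t{o.rbp_name}\t{o.region}\t"
                             f"{','.join(map(str, o.positions))}\n")
            report["stages"]["rbp_maps"] = {"profiles": len(profiles),
                                            "significant_tuples": len(summary),
                                            "coherent_occurrences": len(occ)}
        else:
            report["stages"]["rbp_maps"] = "skipped (no motif input)"

        stage = "rbp_net"
        if config.ppi and config.degs:
            net = load_rbp_network(config.ppi, config.degs)
            reduced = reduce_rbp_network(net)
            with open(out / "rbp_network.tsv", "w") as fh:
                fh.write("a\tb\n")
                for a, b in sorted(reduced.edges):
                    fh.write(f"{a}\t{b}\n")
            report["stages"]["rbp_net"] = {"nodes": len(reduced.nodes),
                                           "edges": len(reduced.edges)}
        else:
            report["stages"]["rbp_net"] = "skipped (no PPI/DEG input)"

        stage = "ora"
        if config.gmt:
            annotation = AnnotationMap.from_gmt(config.gmt)
            study = sorted({ev.gene_id for ev in dases})
            results = fisher_ora(study, annotation)
            write_ora_tsv(results, str(out / "ora.tsv"))
            report["stages"]["ora"] = {
                "terms": len(results),
                "significant": sum(1 for r in results if r.fdr <= 0.05)}
        else:
            report["stages"]["ora"] = "skipped (no annotation input)"
    except Exception as exc:
        report["failed_stage"] = stage
        report["error"] = str(exc)
        with open(out / "run_report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    for p in sorted(out.iterdir()):
        if p.suffix in (".tsv", ".bed"):
            _stamp(p, chash)
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report


def load_rbp_network(ppi_path: str, deg_path: str) -> RBPNetwork:
    """Edge list TSV (a, b) + DEG table TSV (gene, log2fc, padj at 0.05)."""
    flags: Dict[str, str] = {}
    with open(deg_path) as fh:
        header = fh.readline()
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            gene, lfc, padj = line.rstrip("\n").split("\t")[:3]
            if float(padj) <= 0.05:
                flags[gene] = "up" if float(lfc) > 0 else "down"
            else:
                flags.setdefault(gene, "none")
    edges = []
    with open(ppi_path) as fh:
        header = fh.readline()
        if "\t" in header and not header.lower().startswith("a\t"):
            fh.seek(0)
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            a, b = line.rstrip("\n").split("\t")[:2]
            edges.append((a, b))
            flags.setdefault(a, "none")
            flags.setdefault(b, "none")
    return RBPNetwork(flags, edges)
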