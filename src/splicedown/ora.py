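"""Gene-set over-representation analysis.

One-sided Fisher's exact test (hypergeometric upper tail) per term, fold
enrichment (k/n)/(K/N), Benjamini-Hochberg FDR across tested terms, output
ordered by fold enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Set

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


class AnnotationMap:
    """term -> gene set, with the background universe.

    The default universe is the union of all annotated genes (how term
    databases define their backgrounds); a custom universe may be supplied.
    """

    def __init__(self, terms: Dict[str, Set[str]],
                 universe: Optional[Set[str]] = None,
                 descriptions: Optional[Dict[str, str]] = None):
        self.terms = {t: set(g) for t, g in terms.items() if g}
        if not self.terms:
            raise ValueError("annotation map has no non-empty terms")
        self.universe = set(universe) if universe is not None else \
            set().union(*self.terms.values())
        for term, genes in self.terms.items():
            extra = genes - self.universe
            if extra:
                raise ValueError(f"term {term!r} has genes outside the universe: "
                                 f"{sorted(extra)[:3]}")
        self.descriptions = descriptions or {}

    @classmethod
    def from_gmt(cls, path: str) -> "AnnotationMap":
        terms: Dict[str, Set[str]] = {}
        descriptions = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                term, desc, *genes = parts
                terms[term] = {g for g in genes if g}
                descriptions[term] = desc
        return cls(terms, descriptions=descriptions)


@dataclass
class ORAResult:
    term: str
    k: int      # study genes annotated to the term
    n: int      # study size (within universe)
    K: int      # term size
    N: int      # universe size
    fold_enrichment: float
    p: float
    fdr: float
    description: str = ""


def fisher_ora(study: Iterable[str], annotation: AnnotationMap) -> List[ORAResult]:
    """Over-representation of the study set in every annotated term.

    Study genes outside the universe are dropped with a warning. p is the
    hypergeometric upper-tail probability of observing >= k hits; terms with
    k = 0 are reported with fold 0. Results are sorted by fold enrichment
    (descending), then p, then term.
    """
    study_set = set(study)
    if not study_set:
        raise ValueError("empty study gene set")
    outside = study_set - annotation.universe
    if outside:
        logger.warning("%d study genes outside the universe dropped: %s",
                       len(outside), sorted(outside)[:5])
    study_set &= annotation.universe
    if not study_set:
        raise ValueError("no study genes remain within the universe")
    n = len(study_set)
    N = len(annotation.universe)
    results = []
    for term in sorted(annotation.terms):
        genes = annotation.terms[term]
        K = len(genes)
        k = len(study_set & genes)
        fold = (k / n) / (K / N)
        p = float(hypergeom.sf(k - 1, N, K, n))
        results.append(ORAResult(term, k, n, K, N, fold, p, fdr=1.0,
                                 description=annotation.descriptions.get(term, "")))
    fdrs = multipletests([r.p for r in results], method="fdr_bh")[1]
    for r, q in zip(results, fdrs):
        r.fdr = float(q)
    results.sort(key=lambda r: (-r.fold_enrichment, r.p, r.term))
    return results


def write_ora_tsv(results: List[ORAResult], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("term\tdescription\tn_genes\tterm_size\tuniverse\t"
                 "fold_enrichment\traw_p\tfdr\n")
        for r in results:
            fh.write(f"{r.term}\t{r.description}\t{r.k}\t{r.K}\t{r.N}\t"
                     f"{r.fold_enrichment:.4g}\t{r.p:.4g}\t{r.fdr:.4g}\n")
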