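# splicedown

Downstream annotation of differential alternative-splicing events (DASEs)
from bulk RNA-seq. Given rMATS-style per-class event tables, a reference
genome and annotation, a miRNA catalog with tissue expression, an RBP motif
list and a PPI/DEG table, the package answers the questions a splicing study
asks *after* event calling:

- which events are real DASEs (FDR, effect size, coverage filtering on
  percent-spliced-in values);
- whether a retained intron writes an in-frame premature termination codon
  into the transcript;
- which miRNAs can stably hybridize with the alternative region, and with
  what seed architecture;
- which RNA-binding proteins are positionally enriched around the events;
- which biological processes the affected genes over-represent.

A first-class synthetic-data generator emits toy genomes, annotations,
junction-count tables and planted features with a machine-readable truth
record, so the entire pipeline is testable without any download.

## The statistics in brief

**PSI.** For an event with inclusion/skipping junction reads `I`, `S` and
effective lengths `ℓI`, `ℓS`:

    ψ = (I/ℓI) / (I/ℓI + S/ℓS),     Δψ = mean ψ(treatment) − mean ψ(control)

Events are retained as DASEs when FDR ≤ 0.05, |Δψ| ≥ 0.1 and mean junction
coverage > 5 (all thresholds configurable). A binomial likelihood-ratio test
over pooled, length-normalized counts with Benjamini–Hochberg correction
stands in for the upstream caller when tables carry no statistics (synthetic
data).

**Premature stops.** The retained intron (the gap between the flanking
exons) is extracted strand-aware; codons are read at frame k ∈ {1,2,3}
(offset k−1, step 3, transcript orientation) and every fully contained
TAG/TAA/TGA is reported with its 1-based position. The frame is derived from
annotated CDS phase at the upstream junction, `frame = 1 + ((3 − c mod 3)
mod 3)` for `c` coding bases consumed before the intron, with a user
override.

**miRNA hybridization.** An intermolecular nearest-neighbor dynamic program
(Watson–Crick + G·U pairs, stack energies, bulge/interior-loop penalties,
duplex initiation; no intramolecular structure) yields the minimum free
energy and pairing map per miRNA–region pair. The cascade keeps hits with
mfe ≤ −30 kcal/mol, classifies seed (positions 2–7) / post-seed (13–16)
pairing into Strong / Canonical / Compensatory (G·U counts as non-WC),
annotates the A1 adenosine, and keeps miRNAs at or above the 85th
expression percentile of the brain-expressed universe.

**RBP motif maps.** Around each event, exonic ±50 nt and intronic ±250 nt
sub-regions (R1..Rn, collapsed to Upstream/Exon/Downstream; the retained
intron is the Exon region for RI) are scanned for IUPAC motifs; density is
the motif-covered fraction of a 50-nt sliding window, compared per window
between ΔPSI>0 / ΔPSI<0 events and background with a two-sided Wilcoxon
rank-sum test (exact for n,m ≤ 8). Coherent occurrences are motif hits on
events of interest matching a significant (class, direction, region) tuple,
and the RBP interaction network is reduced to nodes connected to at least
one differentially expressed RBP.

**ORA.** Per term, hypergeometric upper-tail p (one-sided Fisher), fold
enrichment `(k/n)/(K/N)`, BH FDR, sorted by fold.

## Worked example

```bash
splicedown simulate --seed 7 --out-dir demo
splicedown filter --rmats-dir demo/rmats --recompute-stats --out demo/dases.tsv
# -> 19 / 38 events retained
splicedown mirna --rmats-dir demo/rmats --fasta demo/genome.fa \
    --mirna demo/mirnas.fa --expr demo/mirna_expression.tsv --out demo/hybrids.tsv
# -> {"pairs_scanned": 456, "predicted": 456, "mfe_filtered": 6,
#     "classified": 6, "expressed": 4}
```

`dases.tsv` holds one row per retained event with its region, Δψ and FDR
(e.g. `A3SS_0 ... delta_psi 0.48, fdr 1.9e-43, mean_coverage 200` — the
generator planted |Δψ| ≥ 0.3 at depth 200, so true events are called with
very small p). `hybrids.tsv` lists the hybridizations surviving the full
cascade, e.g.

```
event_class  gene_symbol  event_id  mirna      delta_psi  mfe_kcal_mol  seed_class    a1_adenosine
SE           Syn1         SE_0      syn-miR-1  -0.475     -35.6         Strong        True
SE           Syn3         SE_2      syn-miR-3  -0.2584    -35.5         Compensatory  True
```

The planted perfect antisense sites come out as Strong with mfe well below
−30 kcal/mol; the 456→6→6→4 counts show the mfe gate doing almost all of the
filtering, the classifier keeping the planted architectures, and the
expression percentile removing low-expression miRNAs. A full run of every
stage from one YAML config: `splicedown run --config run.yaml`.

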