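# Methods

## Scope and data flow

The package consumes event-level splicing calls (rMATS JC dialect, one table
per event class), never reads. Sample 1 is treated as the treatment group and
sample 2 as the control group, so Δψ is treatment-minus-control throughout.
All internal coordinates are 0-based half-open; rMATS `exonStart_0base` /
`exonEnd` columns map directly, GTF input is converted from 1-based
inclusive, and BED output needs no conversion. Emitted event orderings are
sorted by (class, chromosome, start, event id) so reruns are reproducible.

## PSI quantification and DASE filtering

ψ = (I/ℓI)/(I/ℓI + S/ℓS) per replicate; a replicate with no informative
reads has undefined ψ and is excluded from group means rather than set to 0.
"Mean coverage" is defined as the mean of inclusion+skipping junction reads
over all replicates of both groups; the filter keeps events with FDR ≤ 0.05,
|Δψ| ≥ 0.1 and mean coverage strictly > 5. Defaults follow the thresholds the
filter is normally run with; all are parameters.

When a table carries no p-values (synthetic data), a stand-in two-group test
is available: a binomial likelihood-ratio test on pooled, length-normalized
inclusion/skipping counts (χ², 1 df), BH-corrected jointly across all
classes. This is deliberately simpler than the hierarchical replicate model
of the upstream caller — it ignores replicate overdispersion — and is
intended for data whose truth is known by construction.

## Region extraction

Per class, the analysis region is: SE — the alternative exon; MXE — the
transcript-first alternative exon (first exon on '+', second on '−'); RI —
the gap between the two flanking exons (the retained intron); A3SS/A5SS —
the long exon minus its overlap with the short exon, which must share
exactly one boundary. Sequences are strand-oriented (reverse complement on
'−'). For RI the flanking exons are taken in genomic order and the gap is
computed from min/max boundaries, which makes the rule strand-agnostic.

## Reading frames and premature stop codons

Frame k means codons start at offset k−1 of the intron sequence in
transcript orientation. With c coding bases consumed before the intron
(summed over a transcript's CDS segments 5' of the junction), frame =
1 + ((3 − c mod 3) mod 3); a CDS segment must abut the junction for the
transcript to vote, transcripts disagreeing are resolved toward the longest
CDS with a logged warning, and a user-supplied frame overrides annotation
entirely (provenance is recorded). Stop codons (TAG/TAA/TGA) are counted
only when fully inside the intron; codons containing N never match.
Positions are reported as 1-based offsets of the codon's first nucleotide
within the intron sequence. This offset convention is an internal choice:
stop *counts* are convention-robust, first-position values depend on it.

## Duplex prediction

The hybridization engine is an intermolecular-only nearest-neighbor dynamic
program: states are (miRNA position, target position) pairs joined by
stacks, single-sided bulges, or two-sided interior loops bounded by size
caps (15 per side), plus one duplex-initiation constant (+4.09 kcal/mol).
Allowed pairs are A–U, U–A, C–G, G–C, G·U, U·G. Parameters live in a
plain-text table: Watson–Crick stack increments follow the Xia et al. (1998)
set, wobble stacks and loop initiations the Turner-style rule set, and the
loader completes the stack table under the duplex-reading symmetry
E(p1,p2) = E(rev p2, rev p1). Two simplifications relative to full Turner
rules are deliberate: loop penalties do not depend on the closing pairs, and
there are no terminal/dangling-end bonuses. Energies therefore agree with
external duplex programs only approximately (a couple of kcal/mol); every
quantitative claim in the tests is made against this model's own exhaustive
enumeration oracle, not against an external program, and a ViennaRNA
RNAduplex comparison is kept as a loose sanity check only.

A hit is reported when the optimal energy is negative; otherwise the pair is
a no-hit (mfe 0, empty pairing map). One best hit is kept per miRNA–region
pair, ties broken toward the smallest target start. The reported mfe always
equals the energy recomputed from the reported pairing map (tested to
1e−6). The mfe threshold is inclusive (≤ −30 kcal/mol) and configurable,
matching the symbolic form of the usual filter.

Seed classification uses miRNA positions 2–7 (seed) and 13–16 (post-seed):
Strong = both all-WC; Canonical = seed all-WC, post-seed not; Compensatory =
seed broken, post-seed all-WC; everything else Unclassified and excluded
downstream. G·U wobble is rewarded by the energy model but counts as non-WC
for classification. The A1 annotation asks whether the target base opposite
miRNA position 1 (the base immediately 3', in target orientation, of the
partner of position 2 when position 1 is unpaired) is adenosine; it is an
annotation only, never a filter. The expression filter keeps miRNAs with
value ≥ the q-th percentile (linear interpolation, default q = 85) of the
expressed-in-tissue universe (value > 0).

## Motif maps

Layouts use exonic ±50 nt and intronic ±250 nt sub-regions labeled R1..Rn in
transcript orientation; features shorter than twice the nominal flank are
split in half so no nucleotide is double counted, and each sub-region is
anchored at its splice-site end so truncated events align on the grid.
Collapse map: regions before the alternative region are Upstream, the
alternative region itself is Exon (for RI this is the retained intron), and
regions after it are Downstream.

Motif density is the motif-covered nucleotide fraction of a 50-nt window,
step 1 nt, windows never spanning sub-region boundaries; events contribute
only windows fully inside their (possibly truncated) sequence. This coverage
definition is a recorded design choice — the original motif-map server's
scoring is not fully specified publicly — and the oracle tests pin this
definition. Per window, group-vs-background differences use a two-sided
Wilcoxon rank-sum test: exact enumeration of group assignments when both
samples are ≤ 8 (valid under ties), otherwise the normal approximation with
tie and continuity corrections; a window with all values identical gets
p = 1. No multiple-testing correction is applied across windows (mirroring
per-window dotted p-value curves); the enrichment summary flags a (RBP,
class, direction, collapsed region) when any window is below alpha (default
0.05). Coherent occurrences keep motif hits on events of interest only where
that tuple was flagged; events with Δψ exactly 0 belong to neither
direction. Network reduction keeps all DEG-flagged RBPs plus any node with a
path to one (connected components), which is idempotent.

## Over-representation

One-sided (over-representation) hypergeometric tail only; the universe
defaults to the union of all annotated genes, configurable, since term
databases define backgrounds that way. Results are ordered by fold
enrichment, and exact fold values depend on the chosen universe.

## Synthetic data

The generator emulates the study-shaped conditions: two biological
replicates per group; junction counts per replicate drawn
Binomial(depth, q) with q = ψℓI/(ψℓI + (1−ψ)ℓS), depth 200 by default
(an optional beta-binomial dial adds replicate overdispersion, off by
default); control ψ uniform on (0.25, 0.6); planted DASEs shift ψ by
|Δψ| ∈ (0.3, 0.6) with random sign; effective lengths in junction
equivalents (SE/RI 2:1, MXE 2:2, A3SS/A5SS 1:1). Exons are 30–500 nt and
introns 80–5000 nt so flank truncation is exercised. One contig per gene;
genes get random strands; GTF exons describe the inclusion isoform and RI
genes carry phased CDS so frame determination is testable.

Planted features: retained introns are first scrubbed of in-frame stops
(middle base of each stop codon set to C) and then seeded with 1–3 stop
codons at recorded in-frame offsets; miRNA sites are reverse-complement
insertions with hard-mismatch substitutions (never wobble) restricted to
seed or post-seed positions so the expected class is unambiguous; motif
occurrences are Poisson-planted in the upstream intronic flank of SE events
at a base rate of 1 per flank, ×3 in events of the enriched direction. The
truth record stores planted positions *and* a direct-rescan of the final
sequences, so tests can demand exact recovery. Identical configs produce
byte-identical bundles.

What the generator does not emulate: read-level noise, alignment artifacts,
isoform-level ambiguity, splice-site sequence signals, correlated events
within a gene, and realistic genomic base composition (iid uniform bases).
Passing tests on this data demonstrate correctness of the downstream
arithmetic and calibration of the statistics under the stated model, not
performance on real libraries.

## Problem sizes and numerics

Default test and reproduction runs use bundles of 26–60 events, 24 miRNAs
(22 nt), and regions up to a few kb; the duplex DP is O(L·T·B²) with B the
loop cap and is vectorized over the target axis. The duplex oracle check
enumerates all loop-bounded pairings for both lengths ≤ 9. Energies compare
at 1e−6; percentiles use linear interpolation between order statistics; BH
uses the standard step-up formula. Degenerate inputs are contracts, not
crashes: empty sequences scan to zero stops, targets shorter than the miRNA
are skipped with a log entry, an empty expression universe retains nothing,
and a group with zero reads is flagged untestable rather than tested.

## Known limitations

The stand-in significance test is anti-conservative relative to a model with
replicate overdispersion; duplex energies are model-specific and should not
be compared numerically against other programs' outputs; target-site
accessibility (RNA secondary structure) is not modeled; the shipped RBP
motif list is illustrative and real analyses should supply their own; the
first-stop position convention is internal (counts are the robust quantity).
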