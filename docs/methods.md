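# Methods

## Coordinate conventions

All internal coordinates are 0-based half-open (BED convention); readers for
1-based dialects must convert at the boundary.  Two intervals overlap iff
they share ≥ 1 bp; book-ended intervals ([0,100) and [100,200)) have gap 0
but do not overlap.  This split matters: the 2 kb peak-to-gene rule uses the
*gap* (so a book-ended peak qualifies), while the ChIP-ATAC rule uses
*overlap* (a book-ended ATAC peak does not).  Chromosome names are compared
by exact string equality; a validation step reports name-set mismatches
rather than aliasing `chr2L`/`2L` silently.

narrowPeak summits use the column-10 convention (offset from peak start,
−1 = absent).  Operations that need a summit substitute the floor midpoint
of the interval when it is absent and log how often they did.

## Peak-to-gene assignment and location classes

"Within 2 kb of the gene" is measured edge-to-edge between the peak interval
and the gene span, boundary inclusive (gap ≤ `window_bp`, default 2000).
The alternative summit-to-TSS reading is one parameter away but is not the
default, because the criterion as practised relates peaks to genes, not
summits to promoters.  Assignment is many-to-many on purpose; collapsing to
a nearest gene would hide the enhancer-sharing cases the downstream call is
meant to surface.

Location classes are summit-based with precedence
`tss_proximal` (|summit − TSS| ≤ 1 kb) > `genic` (summit inside a gene
span) > `intergenic`.  The 1 kb TSS window is a documented default, not a
claim about any published fraction; the categories are exhaustive and the
reported percentages sum to 100.

Replicate agreement is reported in both directions (percent of A's peaks
overlapping B is not the percent of B's overlapping A when depths differ)
plus a symmetric merged-base-pair Jaccard.  Replicate display means are
rounded half-up, which is the convention that turns (6902, 4903, 6998) into
the quoted 6,268.

## Ets-site scanning

The operational definition of an Ets site is the literal 4-mer core:
GGAA/GGAT on the forward strand, TTCC/ATCC as the reverse-complement
occurrences.  No position-weight matrix, flank weighting or score threshold
is applied — the core consensus is the only published anchor for this
element class here, and a PWM mode would imply a matrix choice the data do
not constrain.  Site counting near summits is on site *start* positions,
|start − summit| ≤ 200 inclusive (a 401 bp span); the scanned slice is
extended 3 bp per side so cores straddling the window edge are handled, and
edge-clipped windows are counted over the clipped region and flagged.  At
background composition a random position starts a core with probability
4/256 per strand-pair set, ≈ 3.1 expected background sites per 401 bp
window — which is why planted-fixture tests control the window content
explicitly (below) rather than asserting exact counts in raw sequence.

## The cofactor filter

Stages, in order: (1) replicate consensus — appear within the top 20 motifs
in ≥ 4 of 5 replicate tables; (2) tissue expression; (3) co-expression with
the bait.  The verdict records the first failing stage and later stages are
not evaluated, so verdicts partition the candidates and the filter's
monotonicity (lowering any threshold can only grow the retained set) is
testable.  "Expressed in cluster c" means mean log-normalized expression
≥ 0.25 **or** expressing-cell fraction ≥ 0.10 in c; "co-expressed" means the
expressing-cluster sets intersect.  These numeric thresholds replace what is
in practice a visual judgement; they are surfaced as parameters precisely
because they are conventions.  Motif-to-factor mapping (one motif may map to
several factors, e.g. an Ets motif shared by the activator Pnt and the
repressor Aop) is an input table, not an inference.

## Target calling

Criterion 2 pools replicate peaks by merging overlapping intervals across
replicates; a merged region's support is the number of distinct replicates
contributing.  The default `min_replicates_c2 = 1` (union) is the most
permissive reading; a consensus rule is one parameter away.  Criterion 3
links the merged peak to ATAC accessibility (≥ 1 bp against the pooled
per-cluster sets) and records the contributing clusters.  Criterion 4 uses
the τ specificity index over cluster means with τ ≥ 0.8 plus the
requirement that the top cluster belong to the configured target set and
that the gene clear the expression thresholds somewhere; τ is scale-
invariant and lives in [0,1], and an all-zero gene is "not scorable" rather
than τ = 1.  The 0.8 cutoff is a conventional strong-specificity value for
τ-type indices, documented rather than derived.  Ets-site counts annotate
calls (max over supporting summits) but never gate them, mirroring how
multi-site presence is reported as a property of called sets rather than
used as a criterion.

## The synthetic generator

What it emulates: uniform-composition chromosomes; non-overlapping genes on
an even grid whose slot margins guarantee a planted peak can only fall
within 2 kb of its own gene; per target gene one summit-centered ChIP peak
(overlapping the gene's 5′ edge or fully upstream with gap ≤ 2 kb); exactly
`n_planted_ets_sites` cores (default 3) written into the sequence at ≥ 5 bp
spacings within ±200 bp of the summit, with the whole counting window then
purged of accidental cores by mutating non-planted bases until a rescan is
clean — so planted counts are exact by construction; replicate retention of
each true peak as independent Bernoulli(`replicate_sensitivity`) with small
coordinate jitter that leaves the absolute summit fixed; matched ATAC peaks
(probability `atac_match_prob`) restricted to the target clusters for
target genes and broad for background-with-peak genes; Poisson background
peaks (5/Mb/replicate) kept ≥ 1 kb away from planted configurations; and a
gene × cluster expression design in which target genes are on only in the
target clusters (mean 1.5–3.0), background-with-peak genes are broadly on
(τ ≈ 0.1, so they fail only criterion 4), and all other genes are silent.
Cofactor motif tables plant a consensus roster (an Ets motif mapping to
pnt/aop plus nine single-factor motifs) in ≥ 4 of 5 tables, with one factor
left unexpressed and one expressed only where the bait is silent, so each
filter stage removes exactly one planted factor; decoy motifs appear in
≤ 3 tables.

Draws that interact with `replicate_sensitivity` come from fixed-shape
arrays at a fixed point in the seeded stream, so runs differing only in
sensitivity are pathwise coupled: the retained-peak sets are nested and
recall is monotone per seed, which turns the degradation property into a
deterministic assertion instead of a flaky statistical one.

What it does **not** emulate: realistic nucleotide composition, peak-shape
or fragment-length structure, read-level noise, per-cell expression
variance, correlated replicate failures, or enhancers shared between genes.
Passing parameter-recovery tests therefore demonstrates the *logic* of the
integration is correct under the stated statistical structure, not that the
pipeline's defaults are optimal for any particular real tissue.

## Problem sizes and numerical choices

Default simulated conditions: 2 × 500 kb chromosomes, 60 genes, 20 planted
targets, 10 background genes with peaks, 5 replicates, 6 clusters with
targets {R1-7, cone} — large enough that background Ets sites, background
peaks and multi-peak genes all occur, small enough that a full pipeline run
takes well under a second and the 20-seed × 3-sensitivity recovery
experiment a few seconds.  All simulation randomness flows from a single
integer seed through independent named streams (genome, genes, planting),
so fixtures are byte-identical across runs of the same configuration.
Display rounding is half-up; τ boundary comparisons are ≥ on purpose (a
gene at exactly τ = 0.8 is specific); merging peaks requires strict overlap,
never book-ending.

## Known limitations

Criterion 1 is an exclusion list, not a literature model; gene spans are
opaque (no exon/intron substructure); the ATAC pooling treats per-cluster
peak sets as given rather than re-calling accessibility; and the cofactor
filter operates on motif tables as ranked inputs — it neither runs motif
discovery nor deduplicates similar motifs, so its "top 20" is the table's
top 20 as supplied.
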