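# Methods

## Coordinate conventions

All internal coordinates are 0-based half-open on the genomic axis. GTF
input (1-based inclusive) is converted on read and back on write; BED passes
through unchanged. The TSS is the 0-based coordinate of the first
transcribed base (`start` for + genes, `end − 1` for − genes), the TES the
last. "Last nucleotide" logic is therefore unambiguous: the 3′-terminal base
of a half-open feature `[s, e)` is `e − 1` on the + strand and `s` on the −
strand.

One transcript is kept per gene: the transcript with the longest genomic
span, ties broken by lexicographically smallest transcript id. Multi-isoform
analysis is out of scope.

## Read-level filter chain

The order is fixed: deduplication → mispriming removal → 3′-end extraction →
splicing-intermediate removal. Unmapped, secondary and supplementary records
are skipped (counted), and reads with mapping quality below 10 are dropped
before all filters. A `FilterReport` carries the count entering and leaving
each stage; counts reconcile exactly (input = retained + removed at every
stage).

- **Deduplication** keys on (chromosome, 5′-end position, alignment strand,
  UMI); the representative is the first read in coordinate order, ties
  broken by smallest query name. The key includes the mapping position
  because distinct molecules can share a UMI at different loci. UMIs are
  read from the `RX` tag or the `_UMI:<seq>` read-name suffix.
- **Mispriming.** The published pipelines delegate "RT bias" removal to
  external scripts without stating the rule; the rule here is an explicit,
  documented stand-in: a read is removed iff the k (default 6) genomic bases
  immediately 3′-adjacent to its aligned 3′ end, in read orientation, equal
  the RT-primer prefix. Without a reference sequence the stage is a logged
  no-op (a truth-tag mode exists for validation against the simulator).
- **3′-end extraction.** The read 5′ end (leftmost aligned base for +
  alignments, rightmost for −) is the nascent-RNA 3′ end. Library polarity
  is a switch shared between the simulator and the reader: under
  `antisense` (default, standard NET-seq geometry) the transcript strand is
  the opposite of the alignment strand; `sense` keeps them equal.
- **Splicing intermediates** are matched on the transcript strand, because
  they are transcript-strand entities; an alignment-strand mode exists for
  compatibility. Any position falling exactly on a terminal nucleotide is
  removed — including genuine polymerase positions that coincide with one;
  this is inherent to the positional rule, and validation accounts for it by
  computing the expected retained set with the same set-membership rule.

## Tracks and normalization

Each retained position contributes one unit of mass at one base on one
strand. "1× depth" is RPGC with the effective genome size equal to the full
toy-genome length: every value is scaled by `genome_size / n_positions`, so
the genome-wide mean per-base coverage, summing both strands, is exactly 1.
The scale factor is global per library (computed over both strands jointly),
not per strand-file. Empty libraries are an error in `normalize_1x`; the
pipeline catches the case, skips scaling with a warning and proceeds with
the all-zero track so degenerate (silent) runs still produce outputs.

Smoothing is a centred moving average over `[i − ⌊w/2⌋, i − ⌊w/2⌋ + w)`
(default w = 10, anchored left-of-centre since an even window has no exact
centre); edges average over the in-bounds subset, so constants are fixed
points. bedGraph is the canonical track format (text, run-length-merged,
zero runs omitted, `%.17g` values for lossless float round-trips).

## Travelling ratio

`TR = promoter density / body density` with strand-oriented half-open
windows: promoter `[TSS−30, TSS+250)` (280 bp), body `[TSS+300, TES−200)`.
Both statistics are mean per-bp coverage ("density" mode), so uniform
coverage gives TR = 1 regardless of depth; a `sums` mode ratios raw window
totals for the alternative reading. Genes with genomic span ≤ 500 bp are
excluded with reason `too_short`; zero body density yields a NaN TR with
reason `zero_body` — such genes are counted but never plotted in the ECDF,
and never assigned infinity. Whether the original windows were inclusive or
half-open is not documented anywhere we know of; half-open is declared here
and differs from inclusive readings by at most 1–2 bp per window edge.

Genes whose 2.5 kb upstream window intersects any other gene body are
excluded from pausing analyses (`promoter_clash_filter`, default `body`
mode; a `tss` mode tests only the other gene's TSS). Windows are clipped at
chromosome edges, never wrapped.

## Profiles and artifact filtering

Profile matrices are built over `[−W, +W)` (default W = 1000 around the
TSS), orientation-flipped for − strand anchors so positive offsets always
point downstream; windows clipped at chromosome bounds are zero-padded and
flagged. The sense channel reads the anchor's strand, antisense the
opposite.

Row filtering replaces an irreproducible interactive clustering step with a
deterministic concentration rule: a row is removed iff its best 100-bp
window holds ≥ 80% of its total mass AND its total is at or above the 90th
percentile of the totals of *non-concentrated* rows. Using the clean-row
quantile (rather than the all-row quantile) makes the filter idempotent:
re-applying it to its own output removes nothing, because the clean rows —
and hence the threshold — are unchanged while every surviving concentrated
row already sits below it. Zero-total rows are never removed (0/0 ≡ 0). A
k-means mode (k = 6, fixed seed, L1-normalized rows, clusters removed when
their centroid satisfies the same concentration rule) is provided for
fidelity to clustering-style filtering, but the heuristic is canonical
because downstream checks require determinism.

Metaplot confidence bands default to normal-theory 95% intervals
(mean ± 1.96·sd/√n); a bootstrap percentile mode (B = 1000, seed 1729) is
available and agrees with the normal interval on Gaussian-like rows.

## Enhancers

Distal enhancers are those whose interval expanded by ±2000 bp intersects no
gene span; the subsequent expression gate keeps enhancers with RPKM > 1
computed from unnormalized counts (both strands, since eRNA transcription is
bidirectional) against the library's retained-read total. Enhancers present
in both the typical and super BED files are assigned to the super class.
Densities are mean per-bp normalized coverage with both strands summed
(per-strand output behind a flag); whether the original boxplots were
length-normalized is unstated, so mean-per-bp is declared. The class
comparison is a two-sided Mann–Whitney rank-sum test: exact null
distribution when both groups have ≤ 25 observations and no ties, otherwise
the normal approximation with tie correction; identical constant groups
short-circuit to p = 1.

## The simulator

The generator emulates the statistical structure the analysis assumes, not
sequence-level realism. Per gene, 3′-end positions are drawn from a mixture:

- a Gaussian pause peak at `pause_offset` (default 50 bp downstream of the
  TSS, within the 30–60 bp range typical of promoter-proximal pausing) with
  sd `pause_sd` and expected total `pause_height·√(2π)·pause_sd`;
- a uniform body signal from `body_start_offset` (300 bp, matching the TR
  body window) to the TES at `body_rate` per bp, multiplied by `exon_boost`
  inside exons;
- a divergent antisense peak on the opposite strand upstream of the TSS
  (offset 150 bp, sd 40 bp).

Enhancers emit positions uniformly over their span on both strands at a
per-bp rate (super-enhancers default to 5× the typical rate and are
larger). Splicing intermediates are planted exactly at every terminal
nucleotide (Poisson, mean 2 per terminal). Counts are Poisson draws; peak
shapes are Gaussians rounded to integer coordinates — the simplest model
that reproduces the sharp-initiation vs broad-elongation profile classes the
presets encode (`tfiid`: narrow peak, near-zero body; `spt6`/`ssrp1`:
broad; `med14`: silent).

Library artifacts with recorded truth: each molecule receives a UMI (8 nt)
drawn unique within its (chromosome, position, strand) key — so
deduplication is exactly invertible and validation can demand exact set
equality rather than approximate recovery — plus `k ~ Poisson(2)` identical
PCR copies. A 5% mispriming fraction of reads is placed at random unoccupied
positions; the synthetic reference sequence is edited so the primer prefix
appears exactly at their adjacent contexts, while accidental matches at
genuine read contexts are scrubbed by a single-base edit (iterated to a
fixpoint, never touching a planted window). Reads are emitted as a
coordinate-sorted SAM with a synthetic reference FASTA; alignment itself is
out of scope. Default depth (10 genes, duplication mean 2) yields roughly
50–70k aligned reads.

Because features are placed with generous spacing and margins, the simulator
does not exercise: overlapping genes, reads clipped at chromosome edges,
soft-clipped or spliced alignments, sequencing errors, or non-uniform
mappability. Passing tests therefore validate the analysis logic and its
conventions, not robustness to those properties of real libraries.

## Problem sizes and numerical choices

Validation runs use toy genomes of 2 × 150 kb with 4–10 genes — large
enough that every interval class (introns, internal exons, terminal
nucleotides, proximal and distal enhancers) is populated, small enough that
brute-force oracles (per-base window sums, O(n²) interval checks,
exhaustive rank-test enumeration) remain exact and fast. The
travelling-ratio recovery sweep uses 5 pause-height points × 20 seeds with
duplication and mispriming disabled, isolating the metric from the
(separately validated) filters. Pearson attenuation is checked as the mean
correlation over 10 cohorts of 200 enhancers, since a single cohort's
sample correlation has sd ≈ 0.04 at that size; rank-test null calibration
uses 500 replicates of 30 vs 30.

Floating-point notes: window means use numpy pairwise summation and are
compared to oracles at 1e−12 relative tolerance; the exact-TR-of-uniform
check uses dyadic constants so means are exact in binary. bedGraph values
are written with 17 significant digits for lossless round-trips.

## Known limitations

- The mispriming rule is a documented stand-in for an unpublished
  procedure; with real data its parameters (primer prefix, k) must be set
  to the library chemistry or the stage disabled.
- Single transcript per gene; no isoform-aware TSS/TES handling.
- The "termination index" sometimes named alongside the travelling ratio
  has no published definition and is deliberately not implemented.
- bigWig export is optional and untested against browsers; bedGraph is the
  supported interchange format.
- The k-means artifact-filter mode depends on scikit-learn's k-means
  implementation details; only the heuristic mode is guaranteed stable
  across library versions.
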