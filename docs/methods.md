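# Methods

## The scaffolding model

`refscaf` arranges draft-assembly contigs into chromosome-scale
pseudomolecules using nothing but whole-genome alignments to a single
reference genome. The underlying assumption is that the reference's
large-scale structure (chromosome membership, gene order, strand) is
shared with the assembled sample, the way a genetic map would be; the
method is therefore appropriate between a draft assembly and a
conspecific or closely related reference, and degrades as structural
divergence grows. The assembly's own base-level sequence is never
altered: contigs are only grouped, ordered, oriented
(reverse-complemented where needed), and concatenated with fixed N
padding.

The pipeline has three stages, each scored with a confidence in [0, 1]:

1. **Clustering.** Each contig is assigned to the reference chromosome
   it *covers* most, where coverage is the size of the union of
   reference intervals hit by at least one alignment (so stacked
   alignments do not double-count). The clustering confidence is
   covered bases on the assigned chromosome divided by covered bases
   over the whole reference — a contig aligning exclusively to one
   chromosome scores 1.0; one splitting evenly across two scores 0.5.
   Contigs with no alignments, or confidence below
   `min_cluster_confidence` (default 0.2), go to the unlocalized
   "Chr0" pool.
2. **Ordering.** Within a chromosome group, each contig is anchored by
   its *primary* alignment — the one with the largest alignment block
   length (PAF column 11; ties by more matching bases, then smaller
   reference start) — and contigs are sorted by the primary
   alignment's (reference start, reference end). The location
   confidence is covered bases inside [min rstart, max rend] of the
   contig's alignments to its chromosome, divided by that range: a
   contig whose alignments are scattered across a wide region scores
   low.
3. **Orienting.** Every alignment to the assigned chromosome casts a
   vote for its strand, weighted by its block length; the contig takes
   the majority strand and the confidence is the winning share. An
   exact tie resolves to '+'.

All ties anywhere in the pipeline are broken deterministically
(lexicographically smallest reference id for clustering; contig id for
ordering; '+' for orientation), so identical inputs produce
byte-identical outputs.

Alignments come from minimap2 with k-mer and window size 19 (invoked
internally when available), or from any user-supplied PAF; alignments
with block length under `min_aln_len` (default 1000 bp) are discarded
up front. The choice to filter on PAF column 11 rather than the query
span is deliberate: block length is strand-neutral and stable across
PAF dialects. Both the numerator and denominator of the clustering
confidence, and the location confidence, are computed from the
post-filter alignment set.

## Chimeric contig correction

An optional pre-pass breaks contigs whose alignments are discordant.
For each contig, alignments under 10 kbp are removed and the remainder
unique-anchor filtered (an alignment is kept only if at least 10 kbp
of its query interval is not already covered by longer kept
alignments, visiting alignments in decreasing length order).

*Interchromosomal* chimeras are contigs where two or more reference
chromosomes each hold at least 5% of the total alignment length *and*
at least 100 kbp of covered reference span. The break is placed at the
query end of the earlier alignment at the first transition between
qualifying chromosomes along the contig — that is where the sorted
alignments make the transition explicit; a midpoint would have no
additional support. *Intrachromosomal* chimeras jump more than
`intra_ref_dist` on the reference or `intra_qry_dist` on the contig
between consecutive alignments (sorted by reference position) to the
dominant chromosome; here the break goes at the midpoint of the
unaligned query interval, since neither flank is preferred. The
absolute value of the query gap is used, so alignments that overlap on
the contig cannot produce a negative distance.

Both intra-chromosomal distance thresholds default to 2 Mbp. A
multi-megabase default means ordinary structural variants (up to the
hundreds-of-kbp scale) never trigger a break; only rearrangement-scale
discordance does. Correction should be enabled only when such large
differences from the reference are more plausibly misassemblies than
real variation.

At most one interchromosomal and one intrachromosomal break happen per
contig per round; rounds compose, and a round that applies no break is
a fixed point. Breaking only fragments sequence — fragments are named
`<id>_chimera_broken:<start>-<end>` and concatenate back to the
original contig exactly. Intervals read from a GFF3 file (gene models)
suppress any break that would fall inside them; suppression rather
than shifting was chosen because a shifted breakpoint has no alignment
evidence at its new position. Within a round, the intrachromosomal
detector runs on the fragments produced by the interchromosomal pass,
using the original alignments clipped to each fragment (reference
coordinates scaled proportionally — an approximation that is
irrelevant at 2 Mbp thresholds).

## Structural-variant calling

After scaffolding, the pseudomolecules can be re-aligned to the
reference and variants called in two complementary ways.
*Within-alignment* calls read insertion/deletion operations of size
[`min_size`, `max_size`] (defaults 20 bp and 100 kbp) directly off the
CIGAR string (`minimap2 -c`); for '-' strand alignments the query
coordinate walk runs from the alignment's query end downward so
reported coordinates are always on the original query strand.
*Between-alignment* calls consider pairs of unique-anchor-filtered
(10 kbp) alignments consecutive on the query with the same reference
and strand, and compare the query-side gap with the (strand-adjusted)
reference-side gap. The discrepancy |query_gap − ref_gap| is the
variant size; the sign pattern of the two gaps classifies it:

| query gap | ref gap | type |
|---|---|---|
| ≥ 0, larger | ≥ 0 | Insertion |
| ≥ 0 | ≥ 0, larger or equal | Deletion |
| ≥ 0 | < 0 | Tandem_expansion |
| < 0 | ≥ 0 | Tandem_contraction |
| < 0, larger | < 0 | Repeat_expansion |
| < 0 | < 0, larger or equal | Repeat_contraction |

Every (query gap, reference gap) pair with in-range size maps to
exactly one type (a tested totality property). Inversions and
translocations are outside this type system.

Because assembly alignments may traverse N-gaps in either sequence,
each variant carries the fraction of its span overlapping gaps —
reference span for deletion-like types (the affected sequence lives on
the reference), query span for insertion-like types — and variants
above a threshold (default 10%) can be excluded.

### Pan-sample merging

Per-sample call sets merge by breakpoint proximity: two variants link
when they share type, reference and (optionally) strand and both
breakpoints differ by at most `max_dist` (default 1 kbp); clusters are
the transitive closure of links, computed with union-find over a
sorted sweep, and size similarity is deliberately never tested. A
cluster's representative is its largest member (ties resolved by
sample id, then coordinates). `min_support = 1` yields the pan-sample
union, `min_support = n` the intersection; a presence/absence matrix
(variants x samples) and per-gene intersection counts (gene span
± 2 kbp flank; counts also normalized by gene length) derive from the
merged set. Variants on Chr0 or organellar sequences should be
excluded before merging (`--exclude`).

## The benchmark simulator

The simulator partitions a reference into scaffolds whose lengths are
drawn successively from a contig-length distribution until each
chromosome is exhausted (last piece truncated). The distribution is
empirical when a sample of observed contig lengths is supplied; the
parametric fallback is log-normal with meanlog 12.0 and sdlog 1.0
(median ≈ 160 kbp, heavy right tail), chosen to resemble a long-read
plant-genome assembly's contig lengths. Scaffolds more than 50% N are
dropped, a random half of the survivors is reverse-complemented, and
the output order is shuffled; ground truth (chromosome, rank along the
reference, orientation, source interval) is recorded first.

The "hard" condition adds variation before splitting: indel events
(default 10,000 genome-wide, 20 bp–10 kbp, insertions and deletions
50/50, anchors uniform over non-N positions) and SNPs at 1% per non-N
base. Indel events never overlap one another (overlapping draws are
redrawn, with a bounded retry budget), which keeps the mutation log
exactly invertible — a tested property, and the basis for
cross-validating the SV caller against planted events. When the
benchmark runs on a genome smaller than the ~828 Mbp genome the
10,000-indel default was stated for, the count is scaled by genome
length (≈ 12 indels/Mbp), keeping the per-base mutation burden
constant.

Contigs derive from scaffolds by splitting at N-runs ≥ 20 bp
(gap sequence discarded) and dropping pieces under 10 kbp; dropped
pieces leave the truth as well, and source intervals are projected
through the scaffold's orientation back onto reference coordinates, so
a piece of a reverse-complemented scaffold inherits orientation '-'
and a reference interval measured from the scaffold's far end.

### Metrics

Over localized contigs (those outside Chr0): clustering accuracy and
orientation accuracy are the fractions assigned the true chromosome
and true strand. Per chromosome, the predicted contig-id sequence is
compared with the true one by (a) token edit distance (Levenshtein
over ids, computed by dynamic programming and cross-checked against
edlib in the tests) normalized by the true contig count and capped at
2.0 — spurious extra contigs can push the raw distance past the truth
length — and (b) the fraction of *directed* adjacent pairs shared
with the truth; directedness penalizes locally inverted order,
consistent with the edit-distance companion. Chromosomes with fewer
than two true contigs have no pair metric (NaN, excluded from means).
Localization percentages are reported over all contigs and all bases.

What the synthetic benchmark does **not** exercise: real genomes have
repeats, segmental duplications and true structural divergence that
make alignments ambiguous in ways i.i.d. random sequence never is.
Perfect scores on these benchmarks demonstrate the machinery is
correct, not that any real assembly will scaffold perfectly.

## Numerical and degenerate-input choices

- All internal coordinates are 0-based half-open; 1-based inclusive
  appears only in AGP output (and GFF3 input is converted on read).
- A contig whose chromosome range is a single alignment has location
  confidence 1.0 by the formula; accepted as-is.
- Empty inputs: an empty FASTA yields an empty record list; a contig
  with no alignments gets Chr0 with all confidences 0; an empty
  placement set writes an AGP file with only the header.
- `unique_anchor_filter` with threshold 0 is the identity; the filter
  is idempotent and never grows the alignment set.
- Pseudomolecule padding defaults to 100 N; the benchmark uses 0 so
  reconstruction can be compared byte-for-byte.

## Problem sizes used by the test and acceptance runs

The shipped benchmark uses a synthetic reference of five 2 Mbp random
chromosomes (i.i.d. uniform ACGT), ~30–40 simulated contigs, 10
planted chimeras of 300 kbp + 300 kbp, and 200 planted indels of
50 bp–5 kbp in a 2 Mbp sequence. These sizes make every property
(byte-identical reconstruction, perfect accuracy on the easy set,
complete chimera recovery, ≥ 90% SV recall) checkable in seconds while
remaining large relative to every length threshold in the method
(10 kbp anchors, 100 kbp spans, 1 kbp alignment filter).

## Known limitations

- Orientation votes and ordering use alignments to the assigned
  chromosome only; a contig spanning a real translocation will be
  placed by its dominant side.
- Gap sizes between ordered contigs are not estimated; padding is
  fixed.
- Between-alignment SV coordinates inherit minimap2's alignment
  endpoint placement, which can wobble by a few bases around
  homopolymers or short repeats.
- The fragment-alignment clipping used between the two chimera
  detectors within one round scales reference coordinates linearly
  inside an alignment, which is inexact in the presence of large
  indels; rounds re-align from scratch, so composed rounds are not
  affected.
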