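# refscaf

Reference-guided scaffolding of draft genome assemblies, with
confidence scoring, chimeric-contig correction, assembly-based
structural-variant (SV) calling, pan-sample SV merging, and a built-in
simulation benchmark.

## Who this is for

You have a draft assembly (long-read contigs, or short-read scaffolds)
of a genome for which a chromosome-scale reference of the same or a
closely related species exists, and you want chromosome-scale
pseudomolecules — plus a catalog of structural differences from that
reference — in minutes rather than hours. `refscaf` uses only
whole-genome alignments (minimap2, or any PAF you supply): no genetic
map, Hi-C, or optical map is needed, and no input base is ever
altered.

## The method

Contigs are aligned to the reference (alignments with block length
< 1 kbp discarded) and processed in three stages, each with a
per-contig confidence score in [0, 1]:

- **cluster** — a contig joins the chromosome it covers most;
  confidence = covered bp on that chromosome / covered bp genome-wide.
- **order** — contigs sort by the reference (start, end) of their
  longest ("primary") alignment; confidence = covered bp within the
  contig's alignment range / range size.
- **orient** — each alignment votes for its strand, weighted by
  alignment length; confidence = winning share of the vote.

Ordered, oriented contigs are concatenated with N padding into
`<chromosome>_pseudomolecule` sequences; unplaceable contigs are pooled
in **Chr0**. Optionally, contigs whose alignments jump between
chromosomes (or megabases within one) are split first — breaks only
fragment sequence, never add or remove bases, and intervals from a
GFF3 file (e.g. gene models) are protected from breaking.

Re-aligning the pseudomolecules to the reference yields SV calls:
indels read off CIGAR operations inside alignments, plus
insertion/deletion/tandem/repeat events classified from the coordinate
discrepancy between consecutive alignments. Each variant is annotated
with the fraction of its span overlapping N-gaps. Per-sample call sets
merge by breakpoint distance (≤ 1 kbp, type- and strand-aware) into a
pan-sample union or intersection, with a presence/absence matrix and
per-gene intersection counts.

See `docs/methods.md` for the full model, parameter defaults, and
limitations.

## Worked example

Simulate a 12-contig draft assembly from a three-chromosome reference,
scaffold it, and score the result against the simulation's ground
truth:

```bash
refscaf simulate -r reference.fasta --seed 3 -o sim
# 12 scaffolds, 12 contigs

refscaf scaffold -r reference.fasta -q sim/contigs.fasta -g 0 -o scaffold_out
# built 3 pseudomolecules; 12/12 contigs localized

refscaf evaluate --truth sim/contig_truth.tsv \
    --placements scaffold_out/confidence.tsv -o report.json
# {
#   "clustering_accuracy": 1.0,
#   "orientation_accuracy": 1.0,
#   "mean_normalized_edit_distance": 0.0,
#   "mean_adjacent_pair_accuracy": 1.0,
#   "pct_contigs_localized": 1.0,
#   "pct_sequence_localized": 1.0
# }
```

Every contig was assigned its true chromosome (`clustering_accuracy`
1.0) in the true order (`mean_normalized_edit_distance` 0.0 — the
token edit distance between true and predicted contig order, averaged
over chromosomes) and true strand, and 100% of assembled sequence was
localized into pseudomolecules. `scaffold_out/` holds the
pseudomolecule FASTA, an AGP v2.1 placement table, and the per-contig
confidence table:

```
contig                   chromosome  order  orientation  clustering_confidence  location_confidence  orientation_confidence
chr1_274838_445774_ctg0  chr1        1      -            1.000000               1.000000             1.000000
chr1_0_274838_ctg0       chr1        0      +            1.000000               1.000000             1.000000
```

Other subcommands: `correct` (chimera breaking), `callsv` / `mergesv` /
`genesv` (structural variants), each documented via `--help`.

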