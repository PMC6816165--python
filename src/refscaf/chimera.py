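"""Detection and breaking of chimeric contigs from discordant alignments.

A contig is interchromosomally chimeric when, after removing short
alignments and unique-anchor filtering, two or more reference chromosomes
each hold at least 5% of the total alignment length AND cover at least
100 kbp of that chromosome.  It is intrachromosomally chimeric when
consecutive alignments along its dominant chromosome jump farther than a
distance threshold on the reference or on the contig.  Breaking only
fragments the contig: the fragments concatenate back to the original
sequence exactly.  Intervals supplied from a GFF3 file (e.g. gene models)
suppress any breakpoint falling inside them.

At most one interchromosomal and one intrachromosomal break happen per
contig per round; rounds compose, so nested chimeras resolve over
successive rounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .alignment_filtering import (
    ContigAlignments,
    coverage,
    group_by_contig,
    unique_anchor_filter,
)
from .io_formats import AlignmentRecord, SequenceRecord

logger = logging.getLogger(__name__)


@dataclass
class ChimeraConfig:
    min_aln_len: int = 10_000
    cluster_fraction: float = 0.05
    min_ref_span: int = 100_000
    intra_ref_dist: int = 2_000_000
    intra_qry_dist: int = 2_000_000
    unique_anchor_min: int = 10_000

    def __post_init__(self) -> None:
        if not 0.0 < self.cluster_fraction <= 1.0:
            raise ValueError("cluster_fraction must be in (0,1]")
        for name in ("min_aln_len", "min_ref_span", "intra_ref_dist",
                     "intra_qry_dist", "unique_anchor_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class BreakPoint:
    contig_id: str
    position: int  # 0-based offset on the contig
    kind: str  # "interchromosomal" | "intrachromosomal"


def _prefilter(ca: ContigAlignments, config: ChimeraConfig) -> ContigAlignments:
    kept = [a for a in ca.alignments if a.alen >= config.min_aln_len]
    filtered = ContigAlignments(ca.contig_id, ca.qlen, kept)
    return unique_anchor_filter(filtered, config.unique_anchor_min)


def detect_interchromosomal(
    ca: ContigAlignments, config: ChimeraConfig | None = None
) -> BreakPoint | None:
    """Breakpoint at the first query transition between two qualifying chromosomes.

    A chromosome qualifies when its summed alignment block length is at
    least ``cluster_fraction`` of the contig total and its covered
    reference span is at least ``min_ref_span``.
    """
    config = config or ChimeraConfig()
    filtered = _prefilter(ca, config)
    if not filtered.alignments:
        return None
    alen_sum: dict[str, int] = {}
    for aln in filtered.alignments:
        alen_sum[aln.rname] = alen_sum.get(aln.rname, 0) + aln.alen
    total = sum(alen_sum.values())
    cov = coverage(filtered).covered_bp
    qualifying = {
        r
        for r, s in alen_sum.items()
        if s >= config.cluster_fraction * total and cov.get(r, 0) >= config.min_ref_span
    }
    if len(qualifying) < 2:
        return None
    ordered = sorted(
        (a for a in filtered.alignments if a.rname in qualifying),
        key=lambda a: (a.qstart, a.qend),
    )
    for prev, nxt in zip(ordered, ordered[1:]):
        if prev.rname != nxt.rname:
            pos = prev.qend
            if 0 < pos < ca.qlen:
                return BreakPoint(ca.contig_id, pos, "interchromosomal")
    return None


def detect_intrachromosomal(
    ca: ContigAlignments, config: ChimeraConfig | None = None
) -> BreakPoint | None:
    """Breakpoint where consecutive alignments jump too far on reference or query.

    Alignments to the dominant (most-covered) chromosome are sorted by
    reference (rstart, rend); the first consecutive pair whose reference
    gap exceeds ``intra_ref_dist`` or whose absolute query gap exceeds
    ``intra_qry_dist`` yields a break at the midpoint of the intervening
    query interval, clamped inside the contig.
    """
    config = config or ChimeraConfig()
    filtered = _prefilter(ca, config)
    if not filtered.alignments:
        return None
    cov = coverage(filtered).covered_bp
    top = max(cov.values())
    dominant = min(r for r in cov if cov[r] == top)
    ordered = sorted(filtered.on_reference(dominant), key=lambda a: (a.rstart, a.rend))
    for prev, nxt in zip(ordered, ordered[1:]):
        ref_gap = nxt.rstart - prev.rend
        qry_gap = abs(nxt.qstart - prev.qend)
        if ref_gap > config.intra_ref_dist or qry_gap > config.intra_qry_dist:
            mid = (prev.qend + nxt.qstart) // 2
            pos = min(max(mid, 1), ca.qlen - 1)
            return BreakPoint(ca.contig_id, pos, "intrachromosomal")
    return None


def apply_breaks(
    contigs: list[SequenceRecord],
    breakpoints: list[BreakPoint],
    protected: dict[str, list[tuple[int, int]]] | None = None,
) -> tuple[list[SequenceRecord], dict[str, list[str]]]:
    """Split contigs at breakpoints, honoring protected intervals.

    Fragments are named ``<id>_chimera_broken:<start>-<end>`` and their
    in-order concatenation equals the original sequence.  A breakpoint
    inside a protected interval is discarded (the cut is suppressed, any
    other cuts on the contig still apply) and logged.  Returns the new
    contig set plus a map from original id to fragment ids.
    """
    protected = protected or {}
    by_contig: dict[str, list[BreakPoint]] = {}
    for bp in breakpoints:
        by_contig.setdefault(bp.contig_id, []).append(bp)

    out: list[SequenceRecord] = []
    rename: dict[str, list[str]] = {}
    for rec in contigs:
        bps = by_contig.get(rec.id)
        if not bps:
            out.append(rec)
            rename[rec.id] = [rec.id]
            continue
        positions: list[int] = []
        for bp in sorted(bps, key=lambda b: b.position):
            if not 0 < bp.position < rec.length:
                raise ValueError(
                    f"breakpoint {bp.position} out of range for {rec.id} (len {rec.length})"
                )
            if any(s <= bp.position < e for s, e in protected.get(rec.id, [])):
                logger.warning(
                    "breakpoint %d on %s suppressed by protected interval", bp.position, rec.id
                )
                continue
            if bp.position not in positions:
                positions.append(bp.position)
        if not positions:
            out.append(rec)
            rename[rec.id] = [rec.id]
            continue
        bounds = [0] + positions + [rec.length]
        frags = []
        for s, e in zip(bounds, bounds[1:]):
            frag = SequenceRecord(f"{rec.id}_chimera_broken:{s}-{e}", rec.seq[s:e])
            out.append(frag)
            frags.append(frag.id)
        rename[rec.id] = frags
    return out, rename


@dataclass
class BreakReportRow:
    contig_id: str
    position: int
    kind: str
    applied: bool


def correction_round(
    contigs: list[SequenceRecord],
    alignments: list[AlignmentRecord],
    config: ChimeraConfig | None = None,
    protected: dict[str, list[tuple[int, int]]] | None = None,
) -> tuple[list[SequenceRecord], list[BreakReportRow]]:
    """One detect-and-break pass over all contigs.

    Interchromosomal detection runs first; intrachromosomal detection then
    runs on each (possibly already inter-split) fragment's alignments,
    re-derived by clipping the original alignments to the fragment.  A
    chimera-free assembly comes back unchanged (fixed point).
    """
    config = config or ChimeraConfig()
    protected = protected or {}
    grouped = group_by_contig(alignments)

    report: list[BreakReportRow] = []
    inter_breaks: list[BreakPoint] = []
    for rec in contigs:
        ca = grouped.get(rec.id)
        if ca is None:
            continue
        bp = detect_interchromosomal(ca, config)
        if bp is not None:
            inter_breaks.append(bp)
    after_inter, rename = apply_breaks(contigs, inter_breaks, protected)
    applied_inter = {
        bp.contig_id for bp in inter_breaks if len(rename[bp.contig_id]) > 1
    }
    for bp in inter_breaks:
        report.append(BreakReportRow(bp.contig_id, bp.position, bp.kind,
                                     bp.contig_id in applied_inter))

    # intrachromosomal pass on the fragments of this round
    frag_alignments = _clip_alignments_to_fragments(grouped, rename)
    intra_breaks: list[BreakPoint] = []
    frag_protected = _lift_protected(protected, rename)
    for rec in after_inter:
        ca = frag_alignments.get(rec.id)
        if ca is None or not ca.alignments:
            continue
        bp = detect_intrachromosomal(ca, config)
        if bp is not None:
            intra_breaks.append(bp)
    final, rename2 = apply_breaks(after_inter, intra_breaks, frag_protected)
    for bp in intra_breaks:
        report.append(BreakReportRow(bp.contig_id, bp.position, bp.kind,
                                     len(rename2[bp.contig_id]) > 1))
    return final, report


def _fragment_bounds(frag_id: str, original_id: str) -> tuple[int, int]:
    span = frag_id[len(original_id) + len("_chimera_broken:"):]
    s, e = span.split("-")
    return int(s), int(e)


def _clip_alignments_to_fragments(
    grouped: dict[str, ContigAlignments], rename: dict[str, list[str]]
) -> dict[str, ContigAlignments]:
    """Project original per-contig alignments onto broken fragments.

    Alignments are clipped to each fragment's query interval; reference
    coordinates are scaled proportionally to the clipped query fraction —
    an approximation adequate for the coarse distance thresholds used by
    the intrachromosomal detector.
    """
    out: dict[str, ContigAlignments] = {}
    for orig, frags in rename.items():
        ca = grouped.get(orig)
        if ca is None:
            continue
        if frags == [orig]:
            out[orig] = ca
            continue
        for frag_id in frags:
            fs, fe = _fragment_bounds(frag_id, orig)
            flen = fe - fs
            clipped: list[AlignmentRecord] = []
            for a in ca.alignments:
                lo, hi = max(a.qstart, fs), min(a.qend, fe)
                if hi - lo <= 0:
                    continue
                frac_lo = (lo - a.qstart) / (a.qend - a.qstart)
                frac_hi = (hi - a.qstart) / (a.qend - a.qstart)
                rspan = a.rend - a.rstart
                if a.strand == "+":
                    nrs = a.rstart + int(frac_lo * rspan)
                    nre = a.rstart + int(frac_hi * rspan)
                else:
                    nrs = a.rstart + int((1 - frac_hi) * rspan)
                    nre = a.rstart + int((1 - frac_lo) * rspan)
                if nre <= nrs:
                    nre = nrs + 1
                scale = (hi - lo) / (a.qend - a.qstart)
                clipped.append(
                    AlignmentRecord(
                        frag_id, flen, lo - fs, hi - fs, a.strand, a.rname, a.rlen,
                        nrs, min(nre, a.rlen), max(1, int(a.nmatch * scale)),
                        max(1, int(a.alen * scale)), a.mapq, dict(a.tags),
                    )
                )
            out[frag_id] = ContigAlignments(frag_id, flen, clipped)
    return out


def _lift_protected(
    protected: dict[str, list[tuple[int, int]]], rename: dict[str, list[str]]
) -> dict[str, list[tuple[int, int]]]:
    lifted: dict[str, list[tuple[int, int]]] = {}
    for orig, intervals in protected.items():
        for frag_id in rename.get(orig, [orig]):
            if frag_id == orig:
                lifted[orig] = intervals
                continue
            fs, fe = _fragment_bounds(frag_id, orig)
            clipped = [
                (max(s, fs) - fs, min(e, fe) - fs)
                for s, e in intervals
                if min(e, fe) > max(s, fs)
            ]
            if clipped:
                lifted[frag_id] = clipped
    return lifted
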