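"""Assembly-based structural-variant calling and multi-sample merging.

Variants come from whole-genome alignments of an assembly (typically the
pseudomolecules) to a reference, in two ways:

* within an alignment — insertion/deletion operations read directly off
  the alignment's CIGAR string;
* between alignments — for consecutive alignments of the same query on
  the same reference and strand, the discrepancy between the query-side
  gap and the reference-side gap implies an indel (both gaps
  non-negative), a tandem expansion/contraction (alignments overlap on
  one coordinate system), or a repeat expansion/contraction (overlap on
  both).

Because assembly alignments may traverse N-gaps in either sequence, each
variant is annotated with the fraction of its span overlapping gaps, and
high-gap variants can be excluded.  Per-sample call sets are merged with
breakpoint-distance clustering (strand- and type-aware, no size test)
into pan-sample variants, from which a presence/absence matrix and
per-gene intersection counts are derived.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

from .alignment_filtering import ContigAlignments, group_by_contig, unique_anchor_filter
from .io_formats import AlignmentRecord, GapInterval

logger = logging.getLogger(__name__)

INSERTION_LIKE = {"Insertion", "Tandem_expansion", "Repeat_expansion"}
DELETION_LIKE = {"Deletion", "Tandem_contraction", "Repeat_contraction"}
SV_TYPES = INSERTION_LIKE | DELETION_LIKE


@dataclass
class SVCallConfig:
    min_size: int = 20
    max_size: int = 100_000
    unique_anchor_min: int = 10_000
    max_gap_fraction_filter: float = 0.10

    def __post_init__(self) -> None:
        if not 0 < self.min_size <= self.max_size:
            raise ValueError("need 0 < min_size <= max_size")


@dataclass
class StructuralVariant:
    ref: str
    ref_start: int
    ref_end: int
    query: str
    query_start: int
    query_end: int
    size: int
    type: str
    source: str  # within_alignment | between_alignments
    strand: str
    gap_overlap_fraction: float = 0.0
    sample: str = ""

    def __post_init__(self) -> None:
        if self.type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.type}")
        if self.ref_end < self.ref_start:
            raise ValueError("ref_end < ref_start")


_CIGAR_OP = re.compile(r"(\d+)([MIDNSHP=X])")


def _parse_cigar(cg: str) -> list[tuple[int, str]]:
    ops = [(int(n), op) for n, op in _CIGAR_OP.findall(cg)]
    if not ops:
        raise ValueError(f"unparseable CIGAR: {cg!r}")
    return ops


def call_within(
    alignments: list[AlignmentRecord], config: SVCallConfig | None = None, sample: str = ""
) -> list[StructuralVariant]:
    """Indels read off CIGAR operations inside individual alignments.

    Requires the ``cg`` tag (``minimap2 -c``).  Alignments lacking it are
    skipped with a warning.  Query coordinates are reported on the
    original query strand: for '-' alignments the walk starts at qend and
    moves left.
    """
    config = config or SVCallConfig()
    out: list[StructuralVariant] = []
    warned = False
    for aln in alignments:
        cg = aln.tags.get("cg")
        if cg is None:
            if not warned:
                logger.warning(
                    "alignment of %s lacks a cg (CIGAR) tag; within-alignment "
                    "SV calling skipped for such alignments",
                    aln.qname,
                )
                warned = True
            continue
        rpos = aln.rstart
        qpos = aln.qstart if aln.strand == "+" else aln.qend
        step = 1 if aln.strand == "+" else -1
        for length, op in _parse_cigar(cg):
            if op in "M=X":
                rpos += length
                qpos += step * length
            elif op == "I":
                if config.min_size <= length <= config.max_size:
                    qlo = qpos if aln.strand == "+" else qpos - length
                    out.append(
                        StructuralVariant(
                            aln.rname, rpos, rpos, aln.qname, qlo, qlo + length,
                            length, "Insertion", "within_alignment", aln.strand,
                            sample=sample,
                        )
                    )
                qpos += step * length
            elif op in "DN":
                if op == "D" and config.min_size <= length <= config.max_size:
                    out.append(
                        StructuralVariant(
                            aln.rname, rpos, rpos + length, aln.qname,
                            qpos, qpos, length, "Deletion",
                            "within_alignment", aln.strand, sample=sample,
                        )
                    )
                rpos += length
            # S/H/P consume neither reference nor (aligned) query here
    out.sort(key=lambda v: (v.ref, v.ref_start, v.ref_end, v.type))
    return out


def call_between(
    contig_alignments: ContigAlignments, config: SVCallConfig | None = None, sample: str = ""
) -> list[StructuralVariant]:
    """Variants implied by coordinate gaps between consecutive alignments.

    Input alignments are unique-anchor filtered at
    ``config.unique_anchor_min`` first.  Only pairs consecutive on the
    query with the same reference sequence and strand are considered.
    """
    config = config or SVCallConfig()
    filtered = unique_anchor_filter(contig_alignments, config.unique_anchor_min)
    alns = sorted(filtered.alignments, key=lambda a: (a.qstart, a.qend))
    out: list[StructuralVariant] = []
    for prev, nxt in zip(alns, alns[1:]):
        if prev.rname != nxt.rname or prev.strand != nxt.strand:
            continue
        query_gap = nxt.qstart - prev.qend
        if prev.strand == "+":
            ref_gap = nxt.rstart - prev.rend
            ref_lo = prev.rend
        else:
            ref_gap = prev.rstart - nxt.rend
            ref_lo = nxt.rend
        size = abs(query_gap - ref_gap)
        if not config.min_size <= size <= config.max_size:
            continue
        if ref_gap >= 0 and query_gap >= 0:
            svtype = "Insertion" if query_gap > ref_gap else "Deletion"
        elif ref_gap < 0 <= query_gap:
            svtype = "Tandem_expansion"
        elif query_gap < 0 <= ref_gap:
            svtype = "Tandem_contraction"
        else:
            svtype = "Repeat_expansion" if query_gap > ref_gap else "Repeat_contraction"
        ref_start = min(ref_lo, ref_lo + ref_gap) if ref_gap < 0 else ref_lo
        ref_end = ref_lo + max(ref_gap, 0)
        q_start = prev.qend if query_gap >= 0 else nxt.qstart
        q_end = prev.qend + max(query_gap, 0)
        out.append(
            StructuralVariant(
                prev.rname, ref_start, ref_end, contig_alignments.contig_id,
                q_start, q_end, size, svtype, "between_alignments", prev.strand,
                sample=sample,
            )
        )
    out.sort(key=lambda v: (v.ref, v.ref_start, v.ref_end, v.type))
    return out


# ---------------------------------------------------------------------------
# Gap-overlap annotation


def _overlap_bp(start: int, end: int, gaps: list[GapInterval]) -> int:
    return sum(max(0, min(end, g.end) - max(start, g.start)) for g in gaps)


def annotate_gap_overlap(
    svs: list[StructuralVariant],
    ref_gaps: dict[str, list[GapInterval]],
    query_gaps: dict[str, list[GapInterval]],
) -> list[StructuralVariant]:
    """Set each variant's fraction of span overlapping N-gaps (in place).

    Deletion-like variants use their reference span; insertion-like
    variants their query span (that is where the variant sequence lives).
    Zero-length spans get fraction 0.
    """
    for sv in svs:
        if sv.type in DELETION_LIKE:
            span = sv.ref_end - sv.ref_start
            ov = _overlap_bp(sv.ref_start, sv.ref_end, ref_gaps.get(sv.ref, []))
        else:
            span = sv.query_end - sv.query_start
            ov = _overlap_bp(sv.query_start, sv.query_end, query_gaps.get(sv.query, []))
        sv.gap_overlap_fraction = ov / span if span > 0 else 0.0
    return svs


def filter_gap_overlap(
    svs: list[StructuralVariant], max_fraction: float = 0.10
) -> list[StructuralVariant]:
    """Drop variants spanning more than ``max_fraction`` gap sequence."""
    return [sv for sv in svs if sv.gap_overlap_fraction <= max_fraction]


def filter_excluded_refs(
    svs: list[StructuralVariant], excluded: set[str]
) -> list[StructuralVariant]:
    """Drop variants on excluded sequences (unlocalized/organellar groups)."""
    return [sv for sv in svs if sv.ref not in excluded]


# ---------------------------------------------------------------------------
# Multi-sample merging


@dataclass
class MergedVariant:
    representative: StructuralVariant
    support: set[str] = field(default_factory=set)
    members: list[StructuralVariant] = field(default_factory=list)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def merge_svs(
    per_sample: dict[str, list[StructuralVariant]],
    max_dist: int = 1000,
    min_support: int = 1,
    strand_aware: bool = True,
) -> list[MergedVariant]:
    """Cluster per-sample variants by breakpoint proximity.

    Two variants link when they share type, reference (and strand when
    ``strand_aware``) and both their start and end breakpoints differ by
    at most ``max_dist``; clusters are the transitive closure of links
    (size similarity is never tested).  Only clusters supported by at
    least ``min_support`` samples are returned: ``min_support=1`` is the
    pan-sample union, ``min_support=len(per_sample)`` the intersection.

    The representative is the member with the largest size (ties: sample
    id, then coordinates).
    """
    tagged: list[StructuralVariant] = []
    for sample, svs in per_sample.items():
        for sv in svs:
            sv.sample = sample
            tagged.append(sv)

    groups: dict[tuple, list[StructuralVariant]] = {}
    for sv in tagged:
        key = (sv.type, sv.ref, sv.strand if strand_aware else ".")
        groups.setdefault(key, []).append(sv)

    merged: list[MergedVariant] = []
    for key in sorted(groups):
        members = sorted(groups[key], key=lambda v: (v.ref_start, v.ref_end, v.sample))
        uf = _UnionFind(len(members))
        for i, a in enumerate(members):
            for j in range(i + 1, len(members)):
                b = members[j]
                if b.ref_start - a.ref_start > max_dist:
                    break
                if abs(b.ref_end - a.ref_end) <= max_dist:
                    uf.union(i, j)
        clusters: dict[int, list[StructuralVariant]] = {}
        for i, sv in enumerate(members):
            clusters.setdefault(uf.find(i), []).append(sv)
        for root in sorted(clusters):
            cluster = clusters[root]
            support = {sv.sample for sv in cluster}
            if len(support) < min_support:
                continue
            rep = max(
                cluster,
                key=lambda v: (v.size, v.sample, -v.ref_start, -v.ref_end),
            )
            merged.append(MergedVariant(rep, support, cluster))
    merged.sort(key=lambda m: (m.representative.ref, m.representative.ref_start,
                               m.representative.ref_end, m.representative.type))
    return merged


def presence_matrix(merged: list[MergedVariant], samples: list[str]) -> pd.DataFrame:
    """Binary variants x samples table; row sums equal support sizes."""
    rows = []
    index = []
    for m in merged:
        r = m.representative
        index.append(f"{r.ref}:{r.ref_start}-{r.ref_end}:{r.type}")
        rows.append([1 if s in m.support else 0 for s in samples])
    return pd.DataFrame(rows, index=index, columns=samples, dtype=int)


def intersect_genes(
    merged: list[MergedVariant],
    genes: list[tuple[str, str, int, int]],
    flank: int = 2000,
) -> pd.DataFrame:
    """Count merged variants near each gene.

    ``genes`` rows are (gene id, seqid, start, end), 0-based half-open.
    A variant counts when its reference span intersects
    [start - flank, end + flank).  The normalized count divides by the
    gene length (without flanks).
    """
    records = []
    for gid, seqid, gstart, gend in genes:
        lo, hi = gstart - flank, gend + flank
        count = sum(
            1
            for m in merged
            if m.representative.ref == seqid
            and max(m.representative.ref_start, lo)
            < min(max(m.representative.ref_end, m.representative.ref_start + 1), hi)
        )
        length = gend - gstart
        records.append(
            {
                "gene": gid,
                "seqid": seqid,
                "start": gstart,
                "end": gend,
                "n_variants": count,
                "normalized": count / length if length > 0 else float("nan"),
            }
        )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Serialization

SV_COLUMNS = [
    "ref", "ref_start", "ref_end", "id", "size", "strand", "type",
    "query", "query_start", "query_end", "source", "gap_overlap_fraction",
]


def svs_to_rows(svs: list[StructuralVariant]) -> list[dict]:
    return [
        {
            "ref": sv.ref, "ref_start": sv.ref_start, "ref_end": sv.ref_end,
            "id": f"sv_{i + 1}", "size": sv.size, "strand": sv.strand,
            "type": sv.type, "query": sv.query, "query_start": sv.query_start,
            "query_end": sv.query_end, "source": sv.source,
            "gap_overlap_fraction": f"{sv.gap_overlap_fraction:.4f}",
        }
        for i, sv in enumerate(svs)
    ]


def svs_from_rows(rows: list[dict], sample: str = "") -> list[StructuralVariant]:
    return [
        StructuralVariant(
            r["ref"], int(r["ref_start"]), int(r["ref_end"]), r["query"],
            int(r["query_start"]), int(r["query_end"]), int(r["size"]), r["type"],
            r["source"], r["strand"], float(r["gap_overlap_fraction"]), sample,
        )
        for r in rows
    ]
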