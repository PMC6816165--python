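"""Alignment cleaning for the scaffolder and chimera detector.

Length filtering happens at PAF read time (``io_formats.read_paf``); this
module adds per-contig grouping, reference-coverage computation,
unique-anchor filtering, primary-alignment selection, and a thin wrapper
around an external minimap2 executable.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path

from .io_formats import AlignmentRecord


@dataclass
class AlignerConfig:
    """Parameters for the external whole-genome aligner (minimap2).

    k-mer and window size both default to 19 bp; ``extra`` is appended to
    the command line verbatim (``-c`` adds CIGAR strings needed for
    within-alignment SV calling).
    """

    kmer_size: int = 19
    window_size: int = 19
    threads: int = 1
    preset: str | None = None
    extra: list[str] = field(default_factory=list)
    executable: str = "minimap2"

    def __post_init__(self) -> None:
        if self.kmer_size < 1 or self.window_size < 1:
            raise ValueError("kmer_size and window_size must be >= 1")


@dataclass
class ContigAlignments:
    """All alignments of one contig, sorted by (qstart, qend)."""

    contig_id: str
    qlen: int
    alignments: list[AlignmentRecord]

    def __post_init__(self) -> None:
        for aln in self.alignments:
            if aln.qname != self.contig_id:
                raise ValueError(
                    f"alignment qname {aln.qname} does not match contig {self.contig_id}"
                )
        self.alignments.sort(key=lambda a: (a.qstart, a.qend))

    def on_reference(self, rname: str) -> list[AlignmentRecord]:
        return [a for a in self.alignments if a.rname == rname]


def group_by_contig(alignments: list[AlignmentRecord]) -> dict[str, ContigAlignments]:
    """Group a flat alignment list per query contig."""
    grouped: dict[str, list[AlignmentRecord]] = {}
    for aln in alignments:
        grouped.setdefault(aln.qname, []).append(aln)
    return {
        qname: ContigAlignments(qname, alns[0].qlen, alns) for qname, alns in grouped.items()
    }


# ---------------------------------------------------------------------------
# Coverage


def _union_size(intervals: list[tuple[int, int]]) -> int:
    """Total size of the union of half-open intervals."""
    if not intervals:
        return 0
    intervals = sorted(intervals)
    total = 0
    cur_start, cur_end = intervals[0]
    for start, end in intervals[1:]:
        if start > cur_end:
            total += cur_end - cur_start
            cur_start, cur_end = start, end
        else:
            cur_end = max(cur_end, end)
    return total + (cur_end - cur_start)


@dataclass
class CoverageSummary:
    """Reference bases covered by at least one alignment, per chromosome."""

    covered_bp: dict[str, int]

    @property
    def total_covered_bp(self) -> int:
        return sum(self.covered_bp.values())


def coverage(
    contig_alignments: ContigAlignments, restrict_to: str | None = None
) -> CoverageSummary:
    """Size of the union of reference intervals hit by >=1 alignment.

    With ``restrict_to`` set, only alignments to that reference id count.
    """
    per_ref: dict[str, list[tuple[int, int]]] = {}
    for aln in contig_alignments.alignments:
        if restrict_to is not None and aln.rname != restrict_to:
            continue
        per_ref.setdefault(aln.rname, []).append((aln.rstart, aln.rend))
    return CoverageSummary({rname: _union_size(iv) for rname, iv in per_ref.items()})


# ---------------------------------------------------------------------------
# Unique-anchor filtering


def unique_anchor_filter(
    contig_alignments: ContigAlignments, min_unique: int
) -> ContigAlignments:
    """Keep alignments contributing >= ``min_unique`` novel query bases.

    Alignments are visited in decreasing order of block length (ties by
    (qstart, rname, rstart) for determinism); each is accepted iff at
    least ``min_unique`` of its query positions are not covered by the
    query intervals of already-accepted alignments.  ``min_unique`` 0
    disables the filter.  Accepted alignments come back in (qstart, qend)
    order.
    """
    if min_unique < 0:
        raise ValueError("min_unique must be >= 0")
    if min_unique == 0:
        return ContigAlignments(
            contig_alignments.contig_id,
            contig_alignments.qlen,
            list(contig_alignments.alignments),
        )
    order = sorted(
        contig_alignments.alignments, key=lambda a: (-a.alen, a.qstart, a.rname, a.rstart)
    )
    accepted: list[AlignmentRecord] = []
    covered: list[tuple[int, int]] = []  # kept sorted and disjoint
    for aln in order:
        novel = (aln.qend - aln.qstart) - _overlap_with_union(covered, aln.qstart, aln.qend)
        if novel >= min_unique:
            accepted.append(aln)
            covered = _insert_interval(covered, aln.qstart, aln.qend)
    return ContigAlignments(contig_alignments.contig_id, contig_alignments.qlen, accepted)


def _overlap_with_union(covered: list[tuple[int, int]], start: int, end: int) -> int:
    total = 0
    for s, e in covered:
        if e <= start:
            continue
        if s >= end:
            break
        total += min(e, end) - max(s, start)
    return total


def _insert_interval(
    covered: list[tuple[int, int]], start: int, end: int
) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in covered:
        if e < start or s > end:
            merged.append((s, e))
        else:
            start, end = min(s, start), max(e, end)
    merged.append((start, end))
    merged.sort()
    return merged


# ---------------------------------------------------------------------------
# Primary alignment


def primary_alignment(
    contig_alignments: ContigAlignments, assigned_chromosome: str
) -> AlignmentRecord:
    """The longest alignment of the contig to its assigned chromosome.

    Length is the PAF block length; ties break by larger nmatch, then
    smaller rstart.
    """
    candidates = contig_alignments.on_reference(assigned_chromosome)
    if not candidates:
        raise ValueError(
            f"contig {contig_alignments.contig_id} has no alignment to "
            f"{assigned_chromosome}; cluster before selecting a primary alignment"
        )
    return max(candidates, key=lambda a: (a.alen, a.nmatch, -a.rstart))


# ---------------------------------------------------------------------------
# External aligner


def run_aligner(
    reference_path: str | Path,
    query_path: str | Path,
    out_paf: str | Path,
    config: AlignerConfig | None = None,
) -> Path:
    """Align ``query_path`` to ``reference_path`` with minimap2, writing PAF.

    The whole pipeline also accepts a user-supplied PAF, so this wrapper
    is optional at runtime.
    """
    config = config or AlignerConfig()
    exe = shutil.which(config.executable)
    if exe is None:
        raise RuntimeError(
            f"aligner executable {config.executable!r} not found on PATH; "
            "supply precomputed alignments with --paf instead"
        )
    cmd = [
        exe,
        "-k", str(config.kmer_size),
        "-w", str(config.window_size),
        "-t", str(config.threads),
    ]
    if config.preset:
        cmd += ["-x", config.preset]
    cmd += config.extra
    cmd += [str(reference_path), str(query_path)]
    out_paf = Path(out_paf)
    with open(out_paf, "w") as out:
        subprocess.run(cmd, stdout=out, stderr=subprocess.DEVNULL, check=True)
    return out_paf
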