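"""Readers and writers for the external formats the pipeline touches.

All internal coordinates are 0-based, half-open.  The single place where
1-based inclusive coordinates appear is AGP serialization, which performs
the conversion on write (and undoes it on read).

Formats handled: FASTA (read/write), PAF (read), AGP v2.1 (write/read),
tab-separated SV tables (read/write), and a minimal GFF3 reader that
extracts only (seqid, start, end) intervals.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio.SeqIO.FastaIO import SimpleFastaParser

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string, preserving case."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """A named nucleotide sequence (contig, scaffold, or chromosome)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if re.search(r"\s", self.id):
            raise ValueError(f"sequence id contains whitespace: {self.id!r}")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class AlignmentRecord:
    """One query-to-reference alignment interval pair (PAF semantics).

    Coordinates are 0-based half-open on both the query and the reference;
    query coordinates always refer to the original (forward) query strand.
    ``alen`` is the alignment block length (PAF column 11) and ``nmatch``
    the number of matching bases (column 10).  Optional SAM-style tags
    (notably ``cg`` CIGAR strings from ``minimap2 -c``) are kept verbatim
    in ``tags``.
    """

    qname: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    rname: str
    rlen: int
    rstart: int
    rend: int
    nmatch: int
    alen: int
    mapq: int
    tags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.qstart < self.qend <= self.qlen):
            raise ValueError(
                f"bad query interval {self.qstart}-{self.qend} (qlen {self.qlen}) "
                f"for {self.qname}"
            )
        if not (0 <= self.rstart < self.rend <= self.rlen):
            raise ValueError(
                f"bad reference interval {self.rstart}-{self.rend} (rlen {self.rlen}) "
                f"for {self.qname} on {self.rname}"
            )
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.alen <= 0:
            raise ValueError("alignment block length must be positive")

    @property
    def query_span(self) -> int:
        return self.qend - self.qstart

    @property
    def ref_span(self) -> int:
        return self.rend - self.rstart


@dataclass(frozen=True)
class GapInterval:
    """A maximal run of N characters on a sequence (0-based half-open)."""

    seqid: str
    start: int
    end: int

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class PlacementRow:
    """One component (contig or gap) of a pseudomolecule layout.

    ``start``/``end`` are 0-based half-open within the pseudomolecule;
    AGP serialization converts to 1-based inclusive.
    """

    object_id: str
    start: int
    end: int
    is_gap: bool
    component: str  # contig id, or gap length as a string for gap rows
    orientation: str = "+"  # ignored for gaps


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file, preserving record order and base case.

    The record id is the header token up to the first whitespace.
    Raises ``ValueError`` on duplicate ids.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        for header, seq in SimpleFastaParser(handle):
            rid = header.split()[0] if header.split() else header
            if rid in seen:
                raise ValueError(f"duplicate id {rid}")
            seen.add(rid)
            records.append(SequenceRecord(rid, seq))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA with bodies wrapped at ``width`` columns."""
    with open(path, "w") as out:
        for rec in records:
            out.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                out.write(rec.seq[i : i + width] + "\n")
            if not rec.seq:
                out.write("\n")


# ---------------------------------------------------------------------------
# PAF


def _parse_paf_line(line: str, lineno: int) -> AlignmentRecord:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 12:
        raise ValueError(f"malformed PAF line {lineno}: expected >=12 columns, got {len(fields)}")
    try:
        qname = fields[0]
        qlen, qstart, qend = (int(fields[i]) for i in (1, 2, 3))
        strand = fields[4]
        rname = fields[5]
        rlen, rstart, rend, nmatch, alen, mapq = (int(fields[i]) for i in range(6, 12))
    except ValueError as exc:
        raise ValueError(f"malformed PAF line {lineno}: {exc}") from exc
    if min(qstart, qend, rstart, rend) < 0:
        raise ValueError(f"negative coordinate at PAF line {lineno}")
    tags: dict[str, str] = {}
    for raw in fields[12:]:
        parts = raw.split(":", 2)
        if len(parts) == 3:
            tags[parts[0]] = parts[2]
    return AlignmentRecord(
        qname, qlen, qstart, qend, strand, rname, rlen, rstart, rend, nmatch, alen, mapq, tags
    )


def read_paf(path: str | Path, min_len: int = 1000) -> list[AlignmentRecord]:
    """Read a PAF file, dropping alignments with block length < ``min_len``.

    The length filter acts on PAF column 11 (the alignment block length).
    Extra columns beyond the mandatory 12 are retained as a tag map.
    """
    out: list[AlignmentRecord] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            rec = _parse_paf_line(line, lineno)
            if rec.alen >= min_len:
                out.append(rec)
    return out


# ---------------------------------------------------------------------------
# Gap extraction

_N_RUN = re.compile(r"[Nn]+")


def find_gaps(record: SequenceRecord, min_run: int = 20) -> list[GapInterval]:
    """Maximal runs of >= ``min_run`` N/n characters, sorted by start."""
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    return [
        GapInterval(record.id, m.start(), m.end())
        for m in _N_RUN.finditer(record.seq)
        if m.end() - m.start() >= min_run
    ]


# ---------------------------------------------------------------------------
# AGP

_AGP_HEADER = "##agp-version\t2.1"


def _check_tiling(rows: list[PlacementRow], object_id: str) -> None:
    pos = 0
    for row in rows:
        if row.start != pos or row.end <= row.start:
            raise ValueError(
                f"placement rows for {object_id} do not tile: gap/overlap at {row.start} (expected {pos})"
            )
        pos = row.end


def write_agp(placements: dict[str, list[PlacementRow]], path: str | Path) -> None:
    """Write a placement table as AGP v2.1.

    ``placements`` maps pseudomolecule id to its ordered component rows.
    Validates the exact-tiling invariant for every object before any write.
    """
    for oid, rows in placements.items():
        _check_tiling(rows, oid)
    with open(path, "w") as out:
        out.write(_AGP_HEADER + "\n")
        for oid, rows in placements.items():
            for part, row in enumerate(rows, start=1):
                start1, end1 = row.start + 1, row.end
                if row.is_gap:
                    out.write(
                        f"{oid}\t{start1}\t{end1}\t{part}\tU\t{row.end - row.start}\t"
                        f"scaffold\tyes\talign_genus\n"
                    )
                else:
                    clen = row.end - row.start
                    out.write(
                        f"{oid}\t{start1}\t{end1}\t{part}\tW\t{row.component}\t"
                        f"1\t{clen}\t{row.orientation}\n"
                    )


def read_agp(path: str | Path) -> dict[str, list[PlacementRow]]:
    """Read an AGP file written by :func:`write_agp` back into placement rows."""
    placements: dict[str, list[PlacementRow]] = {}
    with open(path) as handle:
        for line in handle:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            oid, start1, end1, _part, ctype = f[0], int(f[1]), int(f[2]), f[3], f[4]
            if ctype in ("U", "N"):
                row = PlacementRow(oid, start1 - 1, end1, True, f[5])
            else:
                row = PlacementRow(oid, start1 - 1, end1, False, f[5], f[8])
            placements.setdefault(oid, []).append(row)
    for oid, rows in placements.items():
        _check_tiling(rows, oid)
    return placements


# ---------------------------------------------------------------------------
# Tab-separated tables


def write_tsv(rows: Iterable[dict], path: str | Path, columns: list[str]) -> None:
    """Write dict rows as a headered TSV with a fixed column order."""
    with open(path, "w") as out:
        out.write("\t".join(columns) + "\n")
        for row in rows:
            out.write("\t".join(str(row[c]) for c in columns) + "\n")


def read_tsv(path: str | Path) -> list[dict[str, str]]:
    """Read a headered TSV into a list of string-valued dicts."""
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        return [
            dict(zip(header, line.rstrip("\n").split("\t")))
            for line in handle
            if line.strip()
        ]


# ---------------------------------------------------------------------------
# GFF3 (intervals only)


def read_gff3_intervals(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Extract (seqid -> sorted 0-based half-open intervals) from a GFF3 file.

    Only columns 1, 4 and 5 are consulted; the feature model is ignored.
    GFF3 coordinates are 1-based inclusive.
    """
    intervals: dict[str, list[tuple[int, int]]] = {}
    with open(path) as handle:
        for line in handle:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 5:
                continue
            intervals.setdefault(f[0], []).append((int(f[3]) - 1, int(f[4])))
    for seqid in intervals:
        intervals[seqid].sort()
    return intervals
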