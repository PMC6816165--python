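"""Cluster, order, and orient contigs into pseudomolecules.

The method: each contig is assigned to the reference chromosome it covers
the most (clustering); within each chromosome group, contigs are sorted
by the reference start/end of their single longest ("primary") alignment
(ordering); and each contig takes the orientation favored by a
base-pair-weighted vote over its alignments to the assigned chromosome
(orienting).  Ordered, oriented contigs are concatenated with a fixed run
of N characters between them.  No input base is altered: reverse-oriented
contigs are reverse-complemented, nothing else changes.

Every contig also receives three confidence scores in [0, 1]:

* clustering confidence — reference bases covered on the assigned
  chromosome divided by covered bases over the whole reference;
* location confidence — covered bases within [min rstart, max rend] of
  the contig's alignments to its chromosome, divided by that range;
* orientation confidence — winning orientation votes over total votes.

Contigs with no alignments, or whose clustering confidence falls below a
threshold, are pooled into the unlocalized "Chr0" group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .alignment_filtering import (
    ContigAlignments,
    coverage,
    primary_alignment,
)
from .io_formats import (
    PlacementRow,
    SequenceRecord,
    reverse_complement,
)

CHR0 = "Chr0"


@dataclass
class ContigPlacement:
    """Where one contig lands: chromosome, rank, strand, and confidences."""

    contig_id: str
    chromosome: str  # reference id, or "Chr0" for unlocalized contigs
    order_index: int | None = None
    orientation: str | None = None
    clustering_confidence: float = 0.0
    location_confidence: float = 0.0
    orientation_confidence: float = 0.0

    @property
    def localized(self) -> bool:
        return self.chromosome != CHR0


@dataclass
class ScaffoldConfig:
    min_aln_len: int = 1000
    pad_size: int = 100
    min_cluster_confidence: float = 0.2
    excluded_refs: frozenset[str] = frozenset()
    skipped_contigs: frozenset[str] = frozenset()
    concat_chr0: bool = False

    def __post_init__(self) -> None:
        if self.pad_size < 0:
            raise ValueError("pad_size must be >= 0")
        if not 0.0 <= self.min_cluster_confidence <= 1.0:
            raise ValueError("min_cluster_confidence must be in [0,1]")


def cluster(
    contig_alignments: ContigAlignments, config: ScaffoldConfig | None = None
) -> tuple[str, float]:
    """Assign a contig to the chromosome it covers the most.

    Returns (chromosome, clustering confidence).  Ties on covered bases
    break to the lexicographically smallest reference id.  Contigs in the
    skip list, with no alignments, or with confidence below the threshold
    are sent to Chr0 (confidence still reported).
    """
    config = config or ScaffoldConfig()
    if contig_alignments.contig_id in config.skipped_contigs:
        return CHR0, 0.0
    cov = coverage(contig_alignments)
    covered = {r: b for r, b in cov.covered_bp.items() if r not in config.excluded_refs}
    total = sum(covered.values())
    if total == 0:
        return CHR0, 0.0
    top = max(covered.values())
    best = min(r for r in covered if covered[r] == top)  # ties: smallest ref id
    conf = covered[best] / total
    if conf < config.min_cluster_confidence:
        return CHR0, conf
    return best, conf


def order(
    group: list[ContigAlignments], chromosome: str
) -> list[tuple[str, int, float]]:
    """Order the contigs of one chromosome group.

    Returns (contig id, order index, location confidence) sorted by the
    primary alignment's (rstart, rend), ties by contig id.  Location
    confidence is covered bases within [min rstart, max rend] of the
    contig's alignments to this chromosome over the range size.
    """
    keyed = []
    for ca in group:
        primary = primary_alignment(ca, chromosome)
        on_chrom = ca.on_reference(chromosome)
        lo = min(a.rstart for a in on_chrom)
        hi = max(a.rend for a in on_chrom)
        covered = coverage(ca, restrict_to=chromosome).covered_bp.get(chromosome, 0)
        loc_conf = covered / (hi - lo) if hi > lo else 1.0
        keyed.append(((primary.rstart, primary.rend, ca.contig_id), ca.contig_id, loc_conf))
    keyed.sort(key=lambda t: t[0])
    return [(cid, idx, conf) for idx, (_, cid, conf) in enumerate(keyed)]


def orient(
    contig_alignments: ContigAlignments, assigned_chromosome: str
) -> tuple[str, float]:
    """Majority orientation by base-pair-weighted vote.

    Each alignment to the assigned chromosome casts alen votes for its
    strand; exact ties resolve to '+'.
    """
    votes = {"+": 0, "-": 0}
    for aln in contig_alignments.on_reference(assigned_chromosome):
        votes[aln.strand] += aln.alen
    total = votes["+"] + votes["-"]
    if total == 0:
        raise ValueError(
            f"no alignments of {contig_alignments.contig_id} to {assigned_chromosome}"
        )
    winner = "+" if votes["+"] >= votes["-"] else "-"
    return winner, votes[winner] / total


def place_contigs(
    contig_alignments: dict[str, ContigAlignments],
    all_contig_ids: list[str],
    config: ScaffoldConfig | None = None,
) -> list[ContigPlacement]:
    """Run clustering, ordering, and orienting over a whole assembly.

    ``all_contig_ids`` lists every contig in the input FASTA so that
    contigs without any alignment still appear (in Chr0).
    """
    config = config or ScaffoldConfig()
    placements: dict[str, ContigPlacement] = {}
    groups: dict[str, list[ContigAlignments]] = {}
    for cid in all_contig_ids:
        ca = contig_alignments.get(cid)
        if ca is None or not ca.alignments:
            placements[cid] = ContigPlacement(cid, CHR0)
            continue
        chrom, conf = cluster(ca, config)
        placements[cid] = ContigPlacement(cid, chrom, clustering_confidence=conf)
        if chrom != CHR0:
            groups.setdefault(chrom, []).append(ca)
    for chrom in sorted(groups):
        for cid, idx, loc_conf in order(groups[chrom], chrom):
            p = placements[cid]
            p.order_index = idx
            p.location_confidence = loc_conf
        for ca in groups[chrom]:
            strand, oconf = orient(ca, chrom)
            p = placements[ca.contig_id]
            p.orientation = strand
            p.orientation_confidence = oconf
    return [placements[cid] for cid in all_contig_ids]


def build(
    contigs: list[SequenceRecord],
    placements: list[ContigPlacement],
    config: ScaffoldConfig | None = None,
) -> tuple[list[SequenceRecord], dict[str, list[PlacementRow]], list[SequenceRecord]]:
    """Assemble pseudomolecule sequences from placements.

    Returns (pseudomolecule records, placement table, Chr0 records).  One
    pseudomolecule per chromosome with at least one contig, named
    "<chromosome>_pseudomolecule", with ``pad_size`` N characters between
    consecutive contigs.  Chr0 contigs are returned unmodified as
    individual records (optionally also concatenated when
    ``config.concat_chr0``).
    """
    config = config or ScaffoldConfig()
    seqs = {rec.id: rec for rec in contigs}
    for p in placements:
        if p.contig_id not in seqs:
            raise ValueError(f"contig {p.contig_id} in placements but missing from FASTA")

    by_chrom: dict[str, list[ContigPlacement]] = {}
    chr0: list[ContigPlacement] = []
    for p in placements:
        if p.localized:
            by_chrom.setdefault(p.chromosome, []).append(p)
        else:
            chr0.append(p)

    pseudomolecules: list[SequenceRecord] = []
    table: dict[str, list[PlacementRow]] = {}
    for chrom in sorted(by_chrom):
        members = sorted(by_chrom[chrom], key=lambda p: p.order_index)
        pid = f"{chrom}_pseudomolecule"
        parts: list[str] = []
        rows: list[PlacementRow] = []
        pos = 0
        for i, p in enumerate(members):
            if i > 0 and config.pad_size > 0:
                parts.append("N" * config.pad_size)
                rows.append(
                    PlacementRow(pid, pos, pos + config.pad_size, True, str(config.pad_size))
                )
                pos += config.pad_size
            seq = seqs[p.contig_id].seq
            if p.orientation == "-":
                seq = reverse_complement(seq)
            parts.append(seq)
            rows.append(
                PlacementRow(pid, pos, pos + len(seq), False, p.contig_id, p.orientation)
            )
            pos += len(seq)
        pseudomolecules.append(SequenceRecord(pid, "".join(parts)))
        table[pid] = rows

    chr0_records = [seqs[p.contig_id] for p in sorted(chr0, key=lambda p: p.contig_id)]
    if config.concat_chr0 and chr0_records:
        pad = "N" * config.pad_size
        pooled = pad.join(rec.seq for rec in chr0_records)
        chr0_records = chr0_records + [SequenceRecord(f"{CHR0}_pseudomolecule", pooled)]
    return pseudomolecules, table, chr0_records


def placements_tsv_rows(placements: list[ContigPlacement]) -> list[dict]:
    """Per-contig confidence table rows for TSV serialization."""
    return [
        {
            "contig": p.contig_id,
            "chromosome": p.chromosome,
            "order": p.order_index if p.order_index is not None else "NA",
            "orientation": p.orientation if p.orientation is not None else "NA",
            "clustering_confidence": f"{p.clustering_confidence:.6f}",
            "location_confidence": f"{p.location_confidence:.6f}",
            "orientation_confidence": f"{p.orientation_confidence:.6f}",
        }
        for p in placements
    ]


PLACEMENT_COLUMNS = [
    "contig",
    "chromosome",
    "order",
    "orientation",
    "clustering_confidence",
    "location_confidence",
    "orientation_confidence",
]
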