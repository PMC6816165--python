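"""Benchmark simulator and scaffolding-accuracy metrics.

The simulator partitions a reference genome into scaffolds whose lengths
are drawn from a contig-length distribution (empirical, or a log-normal
fallback), drops scaffolds that are mostly gap, reverse-complements a
random half, and shuffles the rest — the "easy" assembly.  A "hard"
assembly additionally carries simulated variation: indels (default
10,000 events of 20 bp–10 kbp genome-wide) and SNPs at 1%.  Either
scaffold set can be split into gap-free contigs at N-runs of >= 20 bp
(pieces < 10 kbp discarded).  Ground truth (chromosome, order along the
reference, orientation, source interval) travels with every piece.

Scoring compares a scaffolder's placements to that truth with four
metrics: clustering and orientation accuracy over localized contigs,
and, per chromosome, the token edit distance between true and predicted
contig order (normalized by the true contig count) and the fraction of
correct directed adjacent contig pairs.  Localization percentages are
reported over all contigs and all bases.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .io_formats import SequenceRecord, reverse_complement
from .scaffolder import CHR0, ContigPlacement

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


@dataclass
class LengthDistribution:
    """Scaffold-length source: an empirical sample or a log-normal law.

    The log-normal fallback (meanlog 12.0, sdlog 1.0, ~160 kbp median)
    mimics the length spread of a long-read plant assembly.
    """

    lengths: list[int] | None = None
    meanlog: float = 12.0
    sdlog: float = 1.0
    min_length: int = 10_000

    def draw(self, rng: np.random.Generator) -> int:
        if self.lengths:
            return int(self.lengths[rng.integers(len(self.lengths))])
        return max(self.min_length, int(rng.lognormal(self.meanlog, self.sdlog)))


@dataclass
class TruthRecord:
    piece_id: str
    chromosome: str
    order_index: int
    orientation: str
    source_start: int
    source_end: int

    @property
    def length(self) -> int:
        return self.source_end - self.source_start


@dataclass
class MutationConfig:
    n_indels: int = 10_000
    indel_min: int = 20
    indel_max: int = 10_000
    snp_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.indel_min > self.indel_max:
            raise ValueError("indel_min > indel_max")
        if not 0.0 <= self.snp_rate <= 1.0:
            raise ValueError("snp_rate must be in [0,1]")


@dataclass
class MutationEvent:
    seqid: str
    pos: int  # original (pre-mutation) coordinate
    kind: str  # "insertion" | "deletion" | "snp"
    seq: str  # inserted sequence / deleted sequence / new base
    old: str = ""  # original base, for SNPs

    @property
    def size(self) -> int:
        return len(self.seq) if self.kind != "snp" else 1


# ---------------------------------------------------------------------------
# Scaffold simulation


def simulate_scaffolds(
    reference: list[SequenceRecord],
    dist: LengthDistribution,
    seed: int,
    max_n_fraction: float = 0.5,
) -> tuple[list[SequenceRecord], list[TruthRecord]]:
    """Partition each reference chromosome into shuffled scaffolds.

    Interval lengths are drawn successively from ``dist`` (the last is
    truncated at the chromosome end); pieces more than
    ``max_n_fraction`` N are dropped; a random half of the survivors is
    reverse-complemented; output order is shuffled.  Truth is recorded
    relative to the reference before shuffling.
    """
    rng = np.random.default_rng(seed)
    scaffolds: list[SequenceRecord] = []
    truth: list[TruthRecord] = []
    for chrom_rng, chrom in zip(rng.spawn(len(reference)), reference):
        pieces: list[tuple[int, int]] = []
        pos = 0
        while pos < chrom.length:
            size = min(dist.draw(chrom_rng), chrom.length - pos)
            pieces.append((pos, pos + size))
            pos += size
        kept: list[TruthRecord] = []
        for start, end in pieces:
            seq = chrom.seq[start:end]
            n_frac = (seq.count("N") + seq.count("n")) / len(seq)
            if n_frac > max_n_fraction:
                continue
            pid = f"{chrom.id}_{start}_{end}"
            kept.append(TruthRecord(pid, chrom.id, 0, "+", start, end))
        flip = chrom_rng.random(len(kept)) < 0.5
        for idx, (rec, rc) in enumerate(zip(kept, flip)):
            rec.order_index = idx
            rec.orientation = "-" if rc else "+"
            seq = chrom.seq[rec.source_start:rec.source_end]
            scaffolds.append(
                SequenceRecord(rec.piece_id, reverse_complement(seq) if rc else seq)
            )
        truth.extend(kept)
    perm = np.random.default_rng(seed + 1).permutation(len(scaffolds))
    return [scaffolds[i] for i in perm], truth


# ---------------------------------------------------------------------------
# Mutation


def mutate(
    scaffolds: list[SequenceRecord], config: MutationConfig
) -> tuple[list[SequenceRecord], list[MutationEvent]]:
    """Add indels and SNPs to scaffolds, logging every event.

    Indel anchors fall uniformly over non-N positions genome-wide
    (scaffolds weighted by length); insertion vs deletion is 50/50 with
    uniform size in [indel_min, indel_max].  Indel events never overlap
    each other (redrawn; skipped with a warning after bounded retries),
    so the log is invertible with :func:`invert_mutations`.  SNPs hit
    each non-N base independently at ``snp_rate`` and always change the
    base.
    """
    rng = np.random.default_rng(config.seed)
    total = sum(rec.length for rec in scaffolds)
    weights = np.array([rec.length for rec in scaffolds], dtype=float) / total
    per_scaffold: dict[str, list[MutationEvent]] = {rec.id: [] for rec in scaffolds}
    occupied: dict[str, list[tuple[int, int]]] = {rec.id: [] for rec in scaffolds}
    seqmap = {rec.id: rec.seq for rec in scaffolds}

    n_placed = 0
    for _ in range(config.n_indels):
        for _attempt in range(20):
            sid = scaffolds[rng.choice(len(scaffolds), p=weights)].id
            seq = seqmap[sid]
            size = int(rng.integers(config.indel_min, config.indel_max + 1))
            is_ins = rng.random() < 0.5
            span = 1 if is_ins else size
            if len(seq) <= span + 1:
                continue
            pos = int(rng.integers(1, len(seq) - span))
            if seq[pos] in "Nn":
                continue
            if any(pos < e and pos + span > s for s, e in occupied[sid]):
                continue
            if is_ins:
                ins = "".join(rng.choice(_BASES, size=size))
                per_scaffold[sid].append(MutationEvent(sid, pos, "insertion", ins))
            else:
                per_scaffold[sid].append(
                    MutationEvent(sid, pos, "deletion", seq[pos : pos + size])
                )
            occupied[sid].append((pos, pos + span))
            n_placed += 1
            break
        else:
            logger.warning("indel event skipped after bounded retries")

    out: list[SequenceRecord] = []
    log: list[MutationEvent] = []
    for rec in scaffolds:
        arr = np.frombuffer(rec.seq.upper().encode(), dtype="S1")
        snp_events: list[MutationEvent] = []
        if config.snp_rate > 0:
            eligible = np.flatnonzero(arr != b"N")
            hits = eligible[rng.random(eligible.size) < config.snp_rate]
            for pos in hits:
                old = arr[pos].decode()
                choices = [b for b in "ACGT" if b != old]
                new = choices[int(rng.integers(3))]
                snp_events.append(MutationEvent(rec.id, int(pos), "snp", new, old))
        seq = rec.seq
        if snp_events:
            chars = list(seq)
            for ev in snp_events:
                ev.old = chars[ev.pos]
                chars[ev.pos] = ev.seq
            seq = "".join(chars)
        indels = sorted(per_scaffold[rec.id], key=lambda e: -e.pos)
        for ev in indels:
            if ev.kind == "insertion":
                seq = seq[: ev.pos] + ev.seq + seq[ev.pos :]
            else:
                seq = seq[: ev.pos] + seq[ev.pos + len(ev.seq) :]
        out.append(SequenceRecord(rec.id, seq))
        log.extend(snp_events)
        log.extend(sorted(per_scaffold[rec.id], key=lambda e: e.pos))
    return out, log


def invert_mutations(
    mutated: list[SequenceRecord], log: list[MutationEvent]
) -> list[SequenceRecord]:
    """Undo a mutation log, recovering the original scaffolds exactly."""
    by_seq: dict[str, list[MutationEvent]] = {}
    for ev in log:
        by_seq.setdefault(ev.seqid, []).append(ev)
    out = []
    for rec in mutated:
        seq = rec.seq
        events = by_seq.get(rec.id, [])
        for ev in sorted((e for e in events if e.kind != "snp"), key=lambda e: e.pos):
            if ev.kind == "insertion":
                if seq[ev.pos : ev.pos + len(ev.seq)] != ev.seq:
                    raise ValueError(f"log mismatch at {rec.id}:{ev.pos}")
                seq = seq[: ev.pos] + seq[ev.pos + len(ev.seq) :]
            else:
                seq = seq[: ev.pos] + ev.seq + seq[ev.pos :]
        chars = list(seq)
        for ev in events:
            if ev.kind == "snp":
                chars[ev.pos] = ev.old
        out.append(SequenceRecord(rec.id, "".join(chars)))
    return out


# ---------------------------------------------------------------------------
# Scaffold -> contig splitting


def scaffolds_to_contigs(
    scaffolds: list[SequenceRecord],
    truth: list[TruthRecord],
    min_n_run: int = 20,
    min_len: int = 10_000,
) -> tuple[list[SequenceRecord], list[TruthRecord]]:
    """Split scaffolds into gap-free contigs, updating the truth.

    Pieces between N-runs of >= ``min_n_run`` become contigs (gap
    sequence discarded); pieces shorter than ``min_len`` are dropped
    from both the output and the truth.  Source intervals are projected
    through the scaffold's orientation back onto the reference, and
    order indices are recomputed per chromosome by reference position.
    """
    from .io_formats import find_gaps

    truth_by_id = {t.piece_id: t for t in truth}
    contigs: list[SequenceRecord] = []
    new_truth: list[TruthRecord] = []
    for rec in scaffolds:
        t = truth_by_id[rec.id]
        gaps = find_gaps(rec, min_n_run)
        bounds = [0] + [x for g in gaps for x in (g.start, g.end)] + [rec.length]
        k = 0
        for lo, hi in zip(bounds[::2], bounds[1::2]):
            if hi - lo < min_len:
                continue
            cid = f"{rec.id}_ctg{k}"
            k += 1
            contigs.append(SequenceRecord(cid, rec.seq[lo:hi]))
            if t.orientation == "+":
                src = (t.source_start + lo, t.source_start + hi)
            else:
                src = (t.source_end - hi, t.source_end - lo)
            new_truth.append(
                TruthRecord(cid, t.chromosome, 0, t.orientation, src[0], src[1])
            )
    by_chrom: dict[str, list[TruthRecord]] = {}
    for t in new_truth:
        by_chrom.setdefault(t.chromosome, []).append(t)
    for chrom_truth in by_chrom.values():
        chrom_truth.sort(key=lambda t: (t.source_start, t.source_end))
        for idx, t in enumerate(chrom_truth):
            t.order_index = idx
    return contigs, new_truth


# ---------------------------------------------------------------------------
# Evaluation


def token_edit_distance(a: list[str], b: list[str]) -> int:
    """Levenshtein distance over id tokens (dynamic programming)."""
    vocab = {tok: i for i, tok in enumerate(dict.fromkeys(a + b))}
    xs = np.array([vocab[t] for t in a], dtype=np.int64)
    ys = np.array([vocab[t] for t in b], dtype=np.int64)
    prev = np.arange(ys.size + 1)
    for x in xs:
        cur = np.empty_like(prev)
        cur[0] = prev[0] + 1
        sub = prev[:-1] + (ys != x)
        np.minimum(sub, prev[1:] + 1, out=cur[1:])
        for j in range(1, cur.size):  # insertion propagates left-to-right
            if cur[j - 1] + 1 < cur[j]:
                cur[j] = cur[j - 1] + 1
        prev = cur
    return int(prev[-1])


@dataclass
class EvaluationReport:
    clustering_accuracy: float
    orientation_accuracy: float
    normalized_edit_distance: dict[str, float]
    adjacent_pair_accuracy: dict[str, float]
    pct_contigs_localized: float
    pct_sequence_localized: float
    mean_normalized_edit_distance: float = field(init=False)
    mean_adjacent_pair_accuracy: float = field(init=False)

    def __post_init__(self) -> None:
        ned = [v for v in self.normalized_edit_distance.values() if not math.isnan(v)]
        apa = [v for v in self.adjacent_pair_accuracy.values() if not math.isnan(v)]
        self.mean_normalized_edit_distance = sum(ned) / len(ned) if ned else float("nan")
        self.mean_adjacent_pair_accuracy = sum(apa) / len(apa) if apa else float("nan")


def evaluate(
    placements: list[ContigPlacement],
    truth: list[TruthRecord],
    contig_lengths: dict[str, int] | None = None,
) -> EvaluationReport:
    """Score predicted placements against simulation ground truth.

    Clustering and orientation accuracy are fractions of *localized*
    contigs matching the truth.  Per true chromosome, the predicted id
    sequence (localized contigs assigned there, in predicted order) is
    compared to the true sequence by normalized token edit distance
    (capped at 2) and by the fraction of shared directed adjacent pairs;
    chromosomes with fewer than two true contigs give NaN for the pair
    metric.  Localization percentages are over all truth contigs/bases.
    """
    truth_by_id = {t.piece_id: t for t in truth}
    for p in placements:
        if p.contig_id not in truth_by_id:
            raise ValueError(f"placement references unknown contig {p.contig_id}")
    if contig_lengths is None:
        contig_lengths = {t.piece_id: t.length for t in truth}

    localized = [p for p in placements if p.localized]
    n_cluster_ok = sum(
        1 for p in localized if p.chromosome == truth_by_id[p.contig_id].chromosome
    )
    n_orient_ok = sum(
        1 for p in localized if p.orientation == truth_by_id[p.contig_id].orientation
    )
    clustering_acc = n_cluster_ok / len(localized) if localized else float("nan")
    orientation_acc = n_orient_ok / len(localized) if localized else float("nan")

    true_order: dict[str, list[str]] = {}
    for t in sorted(truth, key=lambda t: t.order_index):
        true_order.setdefault(t.chromosome, []).append(t.piece_id)
    pred_order: dict[str, list[str]] = {}
    for p in sorted(localized, key=lambda p: (p.order_index is None, p.order_index)):
        pred_order.setdefault(p.chromosome, []).append(p.contig_id)

    ned: dict[str, float] = {}
    apa: dict[str, float] = {}
    for chrom, true_ids in true_order.items():
        pred_ids = pred_order.get(chrom, [])
        dist = token_edit_distance(true_ids, pred_ids)
        ned[chrom] = min(dist / len(true_ids), 2.0)
        if len(true_ids) < 2:
            apa[chrom] = float("nan")
        else:
            true_pairs = set(zip(true_ids, true_ids[1:]))
            pred_pairs = set(zip(pred_ids, pred_ids[1:]))
            apa[chrom] = len(true_pairs & pred_pairs) / (len(true_ids) - 1)

    total_bp = sum(contig_lengths[t.piece_id] for t in truth)
    local_bp = sum(contig_lengths[p.contig_id] for p in localized)
    return EvaluationReport(
        clustering_accuracy=clustering_acc,
        orientation_accuracy=orientation_acc,
        normalized_edit_distance=ned,
        adjacent_pair_accuracy=apa,
        pct_contigs_localized=len(localized) / len(truth) if truth else float("nan"),
        pct_sequence_localized=local_bp / total_bp if total_bp else float("nan"),
    )


# ---------------------------------------------------------------------------
# Truth / report serialization helpers

TRUTH_COLUMNS = ["piece", "chromosome", "order", "orientation", "source_start", "source_end"]


def truth_to_rows(truth: list[TruthRecord]) -> list[dict]:
    return [
        {
            "piece": t.piece_id, "chromosome": t.chromosome, "order": t.order_index,
            "orientation": t.orientation, "source_start": t.source_start,
            "source_end": t.source_end,
        }
        for t in truth
    ]


def truth_from_rows(rows: list[dict]) -> list[TruthRecord]:
    return [
        TruthRecord(
            r["piece"], r["chromosome"], int(r["order"]), r["orientation"],
            int(r["source_start"]), int(r["source_end"]),
        )
        for r in rows
    ]
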