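"""End-to-end drivers tying alignment, scaffolding, and SV calling together."""

from __future__ import annotations

import tempfile
from dataclasses import dataclass
from pathlib import Path

from . import chimera as chimera_mod
from .alignment_filtering import AlignerConfig, group_by_contig, run_aligner
from .io_formats import (
    AlignmentRecord,
    PlacementRow,
    SequenceRecord,
    find_gaps,
    read_fasta,
    read_paf,
)
from .scaffolder import ContigPlacement, ScaffoldConfig, build, place_contigs
from .sv_calling import (
    SVCallConfig,
    StructuralVariant,
    annotate_gap_overlap,
    call_between,
    call_within,
)


def obtain_alignments(
    reference_path: str | Path,
    query_path: str | Path,
    paf_path: str | Path | None,
    min_aln_len: int,
    threads: int = 1,
    with_cigar: bool = False,
) -> list[AlignmentRecord]:
    """Load a user-supplied PAF or run the external aligner to make one."""
    if paf_path is not None:
        return read_paf(paf_path, min_len=min_aln_len)
    extra = ["-c"] if with_cigar else []
    with tempfile.TemporaryDirectory() as tmp:
        out = Path(tmp) / "aln.paf"
        run_aligner(
            reference_path, query_path, out,
            AlignerConfig(threads=threads, extra=extra),
        )
        return read_paf(out, min_len=min_aln_len)


@dataclass
class ScaffoldResult:
    placements: list[ContigPlacement]
    pseudomolecules: list[SequenceRecord]
    placement_table: dict[str, list[PlacementRow]]
    chr0: list[SequenceRecord]


def scaffold_assembly(
    contigs: list[SequenceRecord],
    alignments: list[AlignmentRecord],
    config: ScaffoldConfig | None = None,
) -> ScaffoldResult:
    """Cluster, order, orient, and build pseudomolecules from alignments."""
    config = config or ScaffoldConfig()
    grouped = group_by_contig(alignments)
    placements = place_contigs(grouped, [c.id for c in contigs], config)
    pseudos, table, chr0 = build(contigs, placements, config)
    return ScaffoldResult(placements, pseudos, table, chr0)


def call_structural_variants(
    reference: list[SequenceRecord],
    query: list[SequenceRecord],
    alignments: list[AlignmentRecord],
    config: SVCallConfig | None = None,
    sample: str = "",
) -> list[StructuralVariant]:
    """Within- plus between-alignment SV calls with gap-overlap annotation."""
    config = config or SVCallConfig()
    svs = call_within(alignments, config, sample=sample)
    for ca in group_by_contig(alignments).values():
        svs.extend(call_between(ca, config, sample=sample))
    ref_gaps = {r.id: find_gaps(r) for r in reference}
    qry_gaps = {r.id: find_gaps(r) for r in query}
    annotate_gap_overlap(svs, ref_gaps, qry_gaps)
    svs.sort(key=lambda v: (v.ref, v.ref_start, v.ref_end, v.type, v.source))
    return svs


def correct_assembly(
    contigs: list[SequenceRecord],
    reference_path: str | Path,
    paf_path: str | Path | None,
    rounds: int = 1,
    config: chimera_mod.ChimeraConfig | None = None,
    protected: dict[str, list[tuple[int, int]]] | None = None,
    threads: int = 1,
    workdir: str | Path | None = None,
) -> tuple[list[SequenceRecord], list[chimera_mod.BreakReportRow]]:
    """Run one or more chimera-correction rounds.

    The first round can consume a user-supplied PAF; later rounds
    re-align the fragmented contigs, so they require the external
    aligner.
    """
    config = config or chimera_mod.ChimeraConfig()
    report: list[chimera_mod.BreakReportRow] = []
    current = contigs
    for rnd in range(rounds):
        if rnd == 0 and paf_path is not None:
            alignments = read_paf(paf_path, min_len=0)
        else:
            with tempfile.TemporaryDirectory(dir=workdir) as tmp:
                qfa = Path(tmp) / "query.fa"
                from .io_formats import write_fasta

                write_fasta(current, qfa)
                paf = Path(tmp) / "aln.paf"
                run_aligner(reference_path, qfa, paf, AlignerConfig(threads=threads))
                alignments = read_paf(paf, min_len=0)
        current, round_report = chimera_mod.correction_round(
            current, alignments, config, protected
        )
        report.extend(round_report)
        if not any(r.applied for r in round_report):
            break
    return current, report
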