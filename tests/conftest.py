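from __future__ import annotations

import numpy as np
import pytest

from refscaf.io_formats import AlignmentRecord, SequenceRecord, write_fasta


def mk_aln(
    qname="q",
    qlen=1_000_000,
    qstart=0,
    qend=10_000,
    strand="+",
    rname="chr1",
    rlen=10_000_000,
    rstart=0,
    rend=10_000,
    nmatch=None,
    alen=None,
    mapq=60,
    tags=None,
):
    """Alignment-record factory with sensible defaults for unit tests."""
    span = max(qend - qstart, rend - rstart)
    return AlignmentRecord(
        qname, qlen, qstart, qend, strand, rname, rlen, rstart, rend,
        nmatch if nmatch is not None else span,
        alen if alen is not None else span,
        mapq, tags or {},
    )


def random_genome(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture(scope="session")
def small_reference(tmp_path_factory):
    """Three 400 kbp random chromosomes, on disk and in memory."""
    rng = np.random.default_rng(20240901)
    records = [
        SequenceRecord(f"chr{i + 1}", random_genome(rng, 400_000)) for i in range(3)
    ]
    path = tmp_path_factory.mktemp("ref") / "reference.fasta"
    write_fasta(records, path)
    return records, path
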