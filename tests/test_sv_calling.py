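import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from refscaf.alignment_filtering import ContigAlignments
from refscaf.io_formats import GapInterval
from refscaf.sv_calling import (
    SVCallConfig,
    StructuralVariant,
    annotate_gap_overlap,
    call_between,
    call_within,
    filter_gap_overlap,
    intersect_genes,
    merge_svs,
    presence_matrix,
)

from conftest import mk_aln

CFG = SVCallConfig()


def sv(ref_start, ref_end, svtype="Deletion", strand="+", size=None, ref="chr1"):
    return StructuralVariant(
        ref, ref_start, ref_end, "q", 0, 0,
        size if size is not None else max(ref_end - ref_start, 20),
        svtype, "between_alignments", strand,
    )


class TestCallWithin:
    def test_insertion_read_off_cigar(self):
        aln = mk_aln(qstart=0, qend=20_100, rstart=0, rend=20_000,
                     alen=20_100, tags={"cg": "10000M100I10000M"})
        (v,) = call_within([aln], CFG)
        assert (v.type, v.size, v.ref_start, v.ref_end) == ("Insertion", 100, 10_000, 10_000)
        assert (v.query_start, v.query_end) == (10_000, 10_100)

    def test_small_indel_below_threshold_ignored(self):
        aln = mk_aln(qstart=0, qend=20_010, rstart=0, rend=20_000,
                     alen=20_010, tags={"cg": "10000M10I10000M"})
        assert call_within([aln], CFG) == []

    def test_deletion_coordinates(self):
        aln = mk_aln(qstart=0, qend=20_000, rstart=0, rend=20_050,
                     alen=20_050, tags={"cg": "10000M50D10000M"})
        (v,) = call_within([aln], CFG)
        assert (v.type, v.size, v.ref_start, v.ref_end) == ("Deletion", 50, 10_000, 10_050)

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_matches_coordinate_walk_oracle(self, strand):
        """Query coordinates from the CIGAR walk equal a naive per-operation oracle."""
        cg = "5000M40I2000M30D3000M100I1000M"
        qspan = 5000 + 40 + 2000 + 3000 + 100 + 1000
        rspan = 5000 + 2000 + 30 + 3000 + 1000
        aln = mk_aln(qstart=500, qend=500 + qspan, strand=strand,
                     rstart=100, rend=100 + rspan, alen=qspan + 30, qlen=20_000,
                     tags={"cg": cg})
        got = call_within([aln], CFG)
        # oracle: explicit walk accumulating (ref, query) offsets
        import re

        ops = [(int(n), op) for n, op in re.findall(r"(\d+)([MID])", cg)]
        expect = []
        r, qoff = 100, 0
        for n, op in ops:
            if op == "M":
                r, qoff = r + n, qoff + n
            elif op == "I":
                q0 = 500 + qoff if strand == "+" else (500 + qspan) - qoff - n
                expect.append(("Insertion", n, r, q0))
                qoff += n
            else:
                expect.append(("Deletion", n, r, None))
                r += n
        expect = [e for e in expect if e[1] >= CFG.min_size]
        assert len(got) == len(expect)
        for v, (t, n, r0, q0) in zip(sorted(got, key=lambda v: v.ref_start),
                                     sorted(expect, key=lambda e: e[2])):
            assert (v.type, v.size, v.ref_start) == (t, n, r0)
            if q0 is not None:
                assert v.query_start == q0

    def test_missing_cigar_skips_with_no_calls(self):
        aln = mk_aln()
        assert call_within([aln], CFG) == []


class TestCallBetween:
    def _pair(self, query_gap, ref_gap, strand="+"):
        a_q = (0, 50_000)
        b_q = (50_000 + query_gap, 100_000 + query_gap)
        if strand == "+":
            a_r = (100_000, 150_000)
            b_r = (150_000 + ref_gap, 200_000 + ref_gap)
        else:
            b_r = (100_000, 150_000)
            a_r = (150_000 + ref_gap, 200_000 + ref_gap)
        qlen = 300_000
        alns = [
            mk_aln(qstart=a_q[0], qend=a_q[1], rstart=a_r[0], rend=a_r[1],
                   strand=strand, qlen=qlen, rlen=10**6),
            mk_aln(qstart=b_q[0], qend=b_q[1], rstart=b_r[0], rend=b_r[1],
                   strand=strand, qlen=qlen, rlen=10**6),
        ]
        return ContigAlignments("q", qlen, alns)

    @pytest.mark.parametrize(
        "query_gap,ref_gap,expected_type,expected_size",
        [
            (0, 1000, "Deletion", 1000),
            (1000, 0, "Insertion", 1000),
            (500, -500, "Tandem_expansion", 1000),
            (-500, 500, "Tandem_contraction", 1000),
            (-200, -800, "Repeat_expansion", 600),
            (-800, -200, "Repeat_contraction", 600),
        ],
    )
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_classification_table(self, query_gap, ref_gap, expected_type,
                                  expected_size, strand):
        (v,) = call_between(self._pair(query_gap, ref_gap, strand), CFG)
        assert (v.type, v.size, v.strand) == (expected_type, expected_size, strand)

    def test_different_reference_or_strand_pairs_skipped(self):
        alns = [
            mk_aln(qstart=0, qend=50_000, rstart=0, rend=50_000, qlen=200_000),
            mk_aln(qstart=60_000, qend=110_000, rname="chr2", rstart=0, rend=50_000,
                   qlen=200_000),
        ]
        assert call_between(ContigAlignments("q", 200_000, alns), CFG) == []

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(st.integers(-5000, 5000), st.integers(-5000, 5000))
    def test_classification_is_total_in_range(self, query_gap, ref_gap):
        size = abs(query_gap - ref_gap)
        calls = call_between(self._pair(query_gap, ref_gap), CFG)
        if CFG.min_size <= size <= CFG.max_size:
            assert len(calls) == 1
            assert calls[0].size == size
        else:
            assert calls == []


class TestGapOverlap:
    def test_deletion_half_overlapping_gap(self):
        v = sv(100, 200)
        annotate_gap_overlap([v], {"chr1": [GapInterval("chr1", 150, 250)]}, {})
        assert v.gap_overlap_fraction == 0.5

    def test_no_overlap_zero(self):
        v = sv(100, 200)
        annotate_gap_overlap([v], {"chr1": [GapInterval("chr1", 500, 600)]}, {})
        assert v.gap_overlap_fraction == 0.0

    def test_full_overlap_excluded_at_threshold(self):
        v = sv(100, 200)
        annotate_gap_overlap([v], {"chr1": [GapInterval("chr1", 0, 400)]}, {})
        assert v.gap_overlap_fraction == 1.0
        assert filter_gap_overlap([v], 0.10) == []

    def test_insertion_uses_query_span(self):
        v = StructuralVariant("chr1", 100, 100, "q", 1000, 1100, 100,
                              "Insertion", "between_alignments", "+")
        annotate_gap_overlap([v], {"chr1": [GapInterval("chr1", 0, 400)]},
                             {"q": [GapInterval("q", 1050, 1200)]})
        assert v.gap_overlap_fraction == 0.5


class TestMerge:
    def test_nearby_deletions_across_samples_merge(self):
        per_sample = {
            "A": [sv(1000, 1200)],
            "B": [sv(1500, 1700)],
        }
        (m,) = merge_svs(per_sample, max_dist=1000)
        assert m.support == {"A", "B"}

    def test_strand_awareness_separates(self):
        per_sample = {"A": [sv(1000, 1200, strand="+")], "B": [sv(1000, 1200, strand="-")]}
        assert len(merge_svs(per_sample, strand_aware=True)) == 2
        assert len(merge_svs(per_sample, strand_aware=False)) == 1

    def test_intersection_semantics(self):
        per_sample = {"A": [sv(1000, 1200)], "B": [sv(1100, 1300)], "C": []}
        assert merge_svs(per_sample, min_support=3) == []
        (m,) = merge_svs(per_sample, min_support=2)
        assert m.support == {"A", "B"}

    def test_zero_distance_identical_inputs_deduplicate(self):
        per_sample = {s: [sv(1000, 1200), sv(5000, 5400)] for s in ("A", "B", "C")}
        merged = merge_svs(per_sample, max_dist=0)
        assert len(merged) == 2
        assert all(m.support == {"A", "B", "C"} for m in merged)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.sampled_from("ABC"), st.integers(0, 20) , st.integers(1, 10)),
            min_size=1,
            max_size=20,
        ),
        st.integers(0, 5),
    )
    def test_matches_connected_component_oracle(self, raw, max_dist):
        scale = 500
        per_sample: dict[str, list] = {"A": [], "B": [], "C": []}
        for sample, start, span in raw:
            per_sample[sample].append(sv(start * scale, (start + span) * scale))
        merged = merge_svs(per_sample, max_dist=max_dist * scale)
        # oracle: brute-force pairwise linking, connected components by BFS
        allv = [
            (s, v) for s in sorted(per_sample) for v in per_sample[s]
        ]
        n = len(allv)
        adj = {i: set() for i in range(n)}
        for i, j in itertools.combinations(range(n), 2):
            a, b = allv[i][1], allv[j][1]
            if (
                abs(a.ref_start - b.ref_start) <= max_dist * scale
                and abs(a.ref_end - b.ref_end) <= max_dist * scale
            ):
                adj[i].add(j)
                adj[j].add(i)
        seen, components = set(), []
        for i in range(n):
            if i in seen:
                continue
            stack, comp = [i], set()
            while stack:
                k = stack.pop()
                if k in comp:
                    continue
                comp.add(k)
                stack.extend(adj[k] - comp)
            seen |= comp
            components.append(comp)
        expect = sorted(
            sorted((allv[i][1].ref_start, allv[i][1].ref_end, allv[i][0]) for i in comp)
            for comp in components
        )
        got = sorted(
            sorted((v.ref_start, v.ref_end, v.sample) for v in m.members)
            for m in merged
        )
        assert got == expect


class TestMatrixAndGenes:
    def test_presence_matrix_rows_match_support(self):
        per_sample = {
            "s1": [sv(1000, 1200)],
            "s2": [],
            "s3": [sv(1100, 1300)],
        }
        merged = merge_svs(per_sample, max_dist=1000)
        mat = presence_matrix(merged, ["s1", "s2", "s3"])
        assert mat.values.tolist() == [[1, 0, 1]]
        assert int(mat.sum(axis=1).iloc[0]) == len(merged[0].support)

    def test_variant_within_flank_counted(self):
        merged = merge_svs({"A": [sv(9000, 9100)]})
        genes = [("g1", "chr1", 10_000, 20_000)]
        table = intersect_genes(merged, genes, flank=2000)
        assert table.loc[0, "n_variants"] == 1
        assert table.loc[0, "normalized"] == pytest.approx(1e-4)

    def test_variant_outside_flank_not_counted(self):
        merged = merge_svs({"A": [sv(5000, 5100)]})
        table = intersect_genes(merged, [("g1", "chr1", 10_000, 20_000)], flank=2000)
        assert table.loc[0, "n_variants"] == 0
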