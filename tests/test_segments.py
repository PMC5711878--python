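"""Flank extraction, leaflet alternation, alignment projection, pooling."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lwiscape import (
    Leaflet,
    SequenceRecord,
    SequenceSet,
    Side,
    TopologyAnnotation,
    extract_flanks,
    pool_from_projection,
    pool_from_sequence,
    pool_residues,
    project_segment,
)
from lwiscape.segments import LWISegment, SegmentError
from lwiscape.seqio import MembraneSide
from tests.conftest import RAT_SEQ_LEN


def seg_map(segments):
    return {f"{s.tm_label}{s.side.value}": s for s in segments}


class TestExtractFlanks:
    def test_rat_topology_yields_12_segments_60_positions(self, rat_topology):
        segs = extract_flanks(rat_topology, flank_len=5, seq_len=RAT_SEQ_LEN)
        assert len(segs) == 12
        assert sum(len(s) for s in segs) == 60

    def test_tm1_flank_intervals(self, rat_topology):
        m = seg_map(extract_flanks(rat_topology, 5, RAT_SEQ_LEN))
        assert m["Transmembrane1N"].interval == (424, 428)
        assert m["Transmembrane1C"].interval == (455, 459)

    def test_flank_clamped_at_n_terminus(self):
        topo = TopologyAnnotation(
            protein_id="p",
            n_term_side=MembraneSide.CYTOPLASMIC,
            tm_spans=(("TM1", 3, 12),),
        )
        m = seg_map(extract_flanks(topo, 5, 30))
        assert m["TM1N"].interval == (1, 2)
        assert len(m["TM1N"]) == 2

    def test_flank_clamped_at_c_terminus(self):
        topo = TopologyAnnotation(
            protein_id="p",
            n_term_side=MembraneSide.CYTOPLASMIC,
            tm_spans=(("TM1", 3, 12),),
        )
        m = seg_map(extract_flanks(topo, 5, 14))
        assert m["TM1C"].interval == (13, 14)

    def test_flank_runs_into_neighbouring_tm_when_loop_is_short(self, rat_topology):
        # loop between TM3 (ends 532) and TM4 (starts 535) is 2 residues;
        # both flanks extend into the adjacent helix rather than truncating
        m = seg_map(extract_flanks(rat_topology, 5, RAT_SEQ_LEN))
        assert m["Transmembrane3C"].interval == (533, 537)
        assert m["Transmembrane4N"].interval == (530, 534)

    def test_flank_len_below_one_rejected(self, rat_topology):
        with pytest.raises(SegmentError):
            extract_flanks(rat_topology, flank_len=0, seq_len=RAT_SEQ_LEN)

    def test_seq_len_shorter_than_last_tm_rejected(self, rat_topology):
        with pytest.raises(SegmentError):
            extract_flanks(rat_topology, 5, seq_len=600)


class TestLeaflets:
    def test_alternation_from_cytoplasmic_n_terminus(self, rat_topology):
        m = seg_map(extract_flanks(rat_topology, 5, RAT_SEQ_LEN))
        inner = {k for k, s in m.items() if s.leaflet is Leaflet.INNER}
        assert inner == {
            "Transmembrane1N", "Transmembrane2C", "Transmembrane3N",
            "Transmembrane4C", "Transmembrane5N", "Transmembrane6C",
        }

    def test_half_inner_half_outer(self, rat_topology):
        segs = extract_flanks(rat_topology, 5, RAT_SEQ_LEN)
        assert sum(s.leaflet is Leaflet.INNER for s in segs) == 6
        assert sum(s.leaflet is Leaflet.OUTER for s in segs) == 6

    def test_flipping_n_term_side_is_an_involution(self, rat_topology):
        direct = extract_flanks(rat_topology, 5, RAT_SEQ_LEN)
        flipped = extract_flanks(rat_topology.flipped(), 5, RAT_SEQ_LEN)
        for a, b in zip(direct, flipped):
            assert a.interval == b.interval
            assert a.leaflet is not b.leaflet
        back = extract_flanks(rat_topology.flipped().flipped(), 5, RAT_SEQ_LEN)
        assert [s.leaflet for s in back] == [s.leaflet for s in direct]


def _tiny_msa():
    # reference "ref" has 2 gaps; ungapped length 10
    return SequenceSet(
        records=(
            SequenceRecord(id="ref", residues="AC-DEFGH-IKL"),
            SequenceRecord(id="o1", residues="ACMDEFGHWIKL"),
            SequenceRecord(id="o2", residues="AC-DE-GH-IKL"),
        ),
        aligned=True,
    )


class TestProjection:
    def test_reference_round_trip_identity(self):
        msa = _tiny_msa()
        seg = LWISegment("TM1", Side.N, (3, 7))
        proj = project_segment(msa, "ref", seg)
        assert proj.sequences["ref"] == msa["ref"].ungapped[2:7]  # "DEFGH"
        assert len(proj.ref_columns) == len(seg)

    def test_ortholog_gap_stripped_and_counted(self):
        proj = project_segment(_tiny_msa(), "ref", LWISegment("TM1", Side.N, (3, 7)))
        assert proj.sequences["o2"] == "DEGH"
        assert proj.gap_counts["o2"] == 1
        assert proj.gap_counts["o1"] == 0

    def test_segment_beyond_reference_length_rejected(self):
        with pytest.raises(SegmentError, match="exceeds"):
            project_segment(_tiny_msa(), "ref", LWISegment("TM1", Side.N, (8, 12)))

    def test_missing_reference_rejected(self):
        with pytest.raises(SegmentError, match="not in alignment"):
            project_segment(_tiny_msa(), "nope", LWISegment("TM1", Side.N, (1, 3)))

    def test_unaligned_input_rejected(self):
        msa = SequenceSet(records=(SequenceRecord(id="a", residues="ACDE"),))
        with pytest.raises(SegmentError, match="aligned"):
            project_segment(msa, "a", LWISegment("TM1", Side.N, (1, 2)))


class TestPooling:
    def test_rat_multiset_pool_is_60(self, rat_topology):
        segs = extract_flanks(rat_topology, 5, RAT_SEQ_LEN)
        seq = "A" * RAT_SEQ_LEN
        assert len(pool_from_sequence(seq, segs, mode="multiset")) == 60

    def test_rat_dedup_pool_is_58(self, rat_topology):
        # brute-force union of all 12 flank intervals
        segs = extract_flanks(rat_topology, 5, RAT_SEQ_LEN)
        union = set()
        for s in segs:
            union.update(s.positions)
        assert len(union) == 58
        seq = "A" * RAT_SEQ_LEN
        assert len(pool_from_sequence(seq, segs, mode="dedup")) == 58

    def test_counts(self):
        seg = LWISegment("TM1", Side.N, (1, 3))
        pool = pool_residues([(seg, "RRY")])
        assert pool.counts() == {"R": 2, "Y": 1}

    def test_mixed_reference_pools_rejected(self):
        msa = _tiny_msa()
        p1 = project_segment(msa, "ref", LWISegment("TM1", Side.N, (1, 3)))
        p2 = project_segment(msa, "o1", LWISegment("TM1", Side.C, (4, 6)))
        with pytest.raises(SegmentError, match="mixed reference"):
            pool_from_projection([p1, p2], "o1")

    def test_empty_pool_rejected(self):
        with pytest.raises(SegmentError):
            pool_residues([])

    @settings(max_examples=40, derandomize=True)
    @given(
        tm_starts=st.lists(
            st.integers(min_value=10, max_value=180), min_size=1, max_size=6,
            unique=True,
        ),
        flank_len=st.integers(min_value=1, max_value=8),
    )
    def test_segment_count_and_dedup_bound(self, tm_starts, flank_len):
        """2 segments per TM; dedup pool never exceeds multiset pool."""
        spans, last = [], 0
        for i, s in enumerate(sorted(tm_starts)):
            if s <= last:
                return  # overlapping TM draw; skip
            e = s + 5
            spans.append((f"TM{i+1}", s, e))
            last = e
        topo = TopologyAnnotation(
            protein_id="p", n_term_side=MembraneSide.CYTOPLASMIC,
            tm_spans=tuple(spans),
        )
        seq_len = last + flank_len
        segs = extract_flanks(topo, flank_len, seq_len)
        assert len(segs) == 2 * len(spans)
        seq = "A" * seq_len
        multi = pool_from_sequence(seq, segs, "multiset")
        dedup = pool_from_sequence(seq, segs, "dedup")
        assert len(dedup) <= len(multi)
        overlap_free = len({p for s in segs for p in s.positions}) == len(multi)
        assert (len(dedup) == len(multi)) == overlap_free
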