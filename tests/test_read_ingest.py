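import numpy as np
import pysam
import pytest

from nanoterm.read_ingest import (ADAPTER3_SEQ, TSO_SEQ, AlignmentRecord,
                                  filter_alignments, find_adapter, orient_read,
                                  revcomp)
from oracles import infix_edit_distance

RNG = np.random.default_rng(123)
BASES = "ACGT"


def random_seq(n, rng=RNG):
    return "".join(rng.choice(list(BASES), n))


def make_segment(flag=0, mapq=60, cigar=((4, 10), (0, 100), (4, 10)), seq=None):
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": "c", "LN": 10_000}]})
    a = pysam.AlignedSegment(header)
    a.query_name = "r"
    total = sum(n for op, n in cigar if op in (0, 1, 4))
    a.query_sequence = seq or random_seq(total)
    a.flag = flag
    a.reference_id = 0
    a.reference_start = 500
    a.mapping_quality = mapq
    a.cigartuples = list(cigar)
    return a


class TestFilterAlignments:
    @pytest.mark.parametrize("flag,kept", [(0, True), (16, True), (4, False),
                                           (256, False), (2048, False),
                                           (2304, False)])
    def test_flag_mask(self, flag, kept):
        recs = list(filter_alignments([make_segment(flag=flag)]))
        assert bool(recs) is kept

    def test_mapq_threshold(self):
        assert not list(filter_alignments([make_segment(mapq=5)], min_mapq=10))
        assert list(filter_alignments([make_segment(mapq=10)], min_mapq=10))

    def test_clip_extraction(self):
        seq = "A" * 10 + "C" * 100 + "G" * 7
        rec = next(iter(filter_alignments(
            [make_segment(cigar=((4, 10), (0, 100), (4, 7)), seq=seq)])))
        assert rec.left_clip_seq == "A" * 10
        assert rec.right_clip_seq == "G" * 7
        assert rec.left_flank_seq == "C" * 20
        assert rec.aln_start == 500 and rec.aln_end == 600


class TestFindAdapter:
    def test_exact_match_offset_zero(self):
        hit = find_adapter(ADAPTER3_SEQ + random_seq(20), "", ADAPTER3_SEQ, 3,
                           side="right")
        assert hit.edit_distance == 0 and hit.offset_from_alignment == 0

    def test_two_substitutions(self):
        mutated = list(ADAPTER3_SEQ)
        mutated[3], mutated[10] = "C", "A"
        clip = "".join(mutated) + random_seq(10)
        hit = find_adapter(clip, "", ADAPTER3_SEQ, 4, side="right")
        assert hit is not None and hit.edit_distance == 2

    def test_agrees_with_brute_force_on_random_clips(self):
        rng = np.random.default_rng(5)
        for _ in range(40):
            clip = random_seq(60, rng)
            hit = find_adapter(clip, "", ADAPTER3_SEQ, 3, side="right")
            dist, _, _ = infix_edit_distance(ADAPTER3_SEQ, clip)
            if hit is None:
                assert dist > 3
            else:
                assert hit.edit_distance == dist

    def test_adapter_in_flank_gives_negative_offset(self):
        flank = random_seq(3) + ADAPTER3_SEQ  # adapter ends at the boundary
        hit = find_adapter(random_seq(30), flank, ADAPTER3_SEQ, 2, side="left")
        assert hit is not None and hit.offset_from_alignment < 0

    def test_truncated_terminal_adapter_found(self):
        # only the last 14 TSO bases survived basecalling at the read start
        clip = TSO_SEQ[-14:]
        hit = find_adapter(clip, random_seq(20), TSO_SEQ, 6, side="left")
        assert hit is not None


def record_from_layout(tso_side, a3_side, aln_strand="+", tail=0, gap_fill=0):
    """Build an AlignmentRecord whose clips carry adapters per the layout."""
    left = right = ""
    if tso_side == "left":
        left += TSO_SEQ
    else:
        right += revcomp(TSO_SEQ)
    if a3_side == "right":
        right = "A" * tail + ("C" * gap_fill) + ADAPTER3_SEQ + right
        # adapter must sit *after* the tail relative to the alignment
        right = "A" * tail + ADAPTER3_SEQ if gap_fill == 0 else right
    elif a3_side == "left":
        left = revcomp(ADAPTER3_SEQ) + "T" * tail + left
    return AlignmentRecord(
        read_id="r", chrom="c", aln_strand=aln_strand,
        aln_start=1000, aln_end=1400,
        left_clip_seq=left, right_clip_seq=right,
        left_flank_seq=random_seq(20), right_flank_seq=random_seq(20),
        mapq=60, flags=0 if aln_strand == "+" else 16,
    )


class TestOrientRead:
    def test_forward_layout_gives_plus(self):
        r = orient_read(record_from_layout("left", "right"))
        assert r.bio_strand == "+"
        assert r.five_prime_pos == 1000 and r.three_prime_pos == 1400
        assert r.three_prime_gap == 0

    def test_reverse_layout_gives_minus(self):
        r = orient_read(record_from_layout("right", "left"))
        assert r.bio_strand == "-"
        assert r.five_prime_pos == 1400 and r.three_prime_pos == 1000

    def test_single_adapter_rejected(self):
        rec = record_from_layout("none", "right")
        assert orient_read(rec) is None

    def test_conflicting_strands_rejected(self):
        # TSO implies '+', 3' adapter on the left implies '-'
        rec = record_from_layout("left", "left")
        assert orient_read(rec) is None

    def test_tail_segment_and_gap(self):
        r = orient_read(record_from_layout("left", "right", tail=30))
        assert r.three_prime_gap == 30
        assert r.tail_segment == "A" * 30

    def test_minus_tail_segment_reverse_complemented(self):
        r = orient_read(record_from_layout("right", "left", tail=25))
        assert r.bio_strand == "-"
        assert r.tail_segment == "A" * 25

    def test_alignment_strand_flag_is_irrelevant(self):
        # PCR yields both cDNA strands; orientation must come from the clips
        a = orient_read(record_from_layout("left", "right", aln_strand="+"))
        b = orient_read(record_from_layout("left", "right", aln_strand="-"))
        assert a.bio_strand == b.bio_strand == "+"
        assert (a.five_prime_pos, a.three_prime_pos) == \
               (b.five_prime_pos, b.three_prime_pos)

    def test_error_injected_adapters_recovered_exactly(self):
        # interior substitutions keep the proximal adapter edge unambiguous;
        # an error at the adapter base abutting a poly(A) tail legitimately
        # shifts the best match by the tie-break rule
        rng = np.random.default_rng(99)
        for _ in range(50):
            tail = int(rng.integers(0, 40))
            rec = record_from_layout("left", "right", tail=tail)

            def mutate(s, lo, hi, k):
                s = list(s)
                for i in rng.choice(np.arange(lo, hi), size=k, replace=False):
                    s[i] = BASES[(BASES.index(s[i]) + 1) % 4]
                return "".join(s)

            left = mutate(rec.left_clip_seq, 2, len(TSO_SEQ) - 2,
                          int(rng.integers(0, 3)))
            right = rec.right_clip_seq
            right = right[:tail] + mutate(right[tail:], 2, len(ADAPTER3_SEQ) - 2,
                                          int(rng.integers(0, 3)))
            rec = AlignmentRecord(**{**rec.__dict__, "left_clip_seq": left,
                                     "right_clip_seq": right})
            r = orient_read(rec, max_edits_tso=6, max_edits_a3=4)
            assert r is not None and r.bio_strand == "+"
            assert r.three_prime_gap == tail
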