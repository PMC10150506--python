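"""ROI projection, orientation synchronization, haplogrouping and SD-flank
analysis."""

import re

import pytest

from invlandscape.core import AlignmentRecord, GenomicInterval
from invlandscape.haplostruct import (
    HaplotypePainting,
    Risk,
    flank_analysis,
    flanking_sd_pair,
    group_haplotypes,
    project_to_roi,
    select_spanning_assemblies,
    synchronize_orientation,
)

ROI = GenomicInterval("chr1", 50_000, 150_000)


def rec(ts, te, strand="+", qs=0, qe=None, qlen=10**6, name="asm",
        chrom="chr1", cigar=None):
    qe = qe if qe is not None else qs + (te - ts)
    return AlignmentRecord(name, max(qlen, qe), qs, qe, strand, chrom, ts, te, 60,
                           min(qe - qs, te - ts), target_len=10**7, cigar=cigar)


def painting(segments, name="asm", roi=None):
    return HaplotypePainting(name, roi or ROI, tuple(segments))


class TestProjectToRoi:
    def test_proportional_clip(self):
        (out,) = project_to_roi([rec(0, 200_000)], ROI)
        assert (out.target_start, out.target_end) == (50_000, 150_000)
        assert (out.query_start, out.query_end) == (50_000, 150_000)

    def test_record_inside_roi_unchanged(self):
        r = rec(60_000, 90_000, qs=1000)
        assert project_to_roi([r], ROI) == [r]

    def test_non_intersecting_dropped(self):
        assert project_to_roi([rec(200_000, 300_000)], ROI) == []
        assert project_to_roi([rec(60_000, 90_000, chrom="chr2")], ROI) == []

    def test_orientation_conserved(self):
        (out,) = project_to_roi([rec(0, 200_000, strand="-")], ROI)
        assert out.strand == "-"

    def test_minus_strand_query_side(self):
        # on '-' records the target start maps to the query end side
        (out,) = project_to_roi([rec(0, 200_000, strand="-", qs=0, qe=200_000)], ROI)
        assert (out.query_start, out.query_end) == (50_000, 150_000)
        roi_right = GenomicInterval("chr1", 150_000, 200_000)
        (out,) = project_to_roi(
            [rec(0, 200_000, strand="-", qs=0, qe=200_000)], roi_right
        )
        assert (out.query_start, out.query_end) == (0, 50_000)

    def test_matches_base_walk_oracle_with_cigar(self, rng):
        ops = "MID"
        for _ in range(100):
            ts = int(rng.integers(0, 10_000))
            qs = int(rng.integers(0, 10_000))
            strand = "+-"[int(rng.integers(0, 2))]
            cigar = "".join(
                f"{int(rng.integers(1, 200))}{ops[int(rng.integers(0, 3))]}"
                for _ in range(int(rng.integers(1, 8)))
            )
            tlen = sum(int(n) for n, op in re.findall(r"(\d+)([MID])", cigar)
                       if op in "MD")
            qlen_used = sum(int(n) for n, op in re.findall(r"(\d+)([MID])", cigar)
                            if op in "MI")
            if tlen == 0 or qlen_used == 0:
                continue
            r = rec(ts, ts + tlen, strand=strand, qs=qs, qe=qs + qlen_used,
                    qlen=10**6, cigar=cigar)
            # independent per-base walk: query offset at each target offset
            q_of_t = []
            q = r.query_start if strand == "+" else r.query_end
            sign = 1 if strand == "+" else -1
            for n, op in re.findall(r"(\d+)([MID])", cigar):
                n = int(n)
                if op == "M":
                    for _ in range(n):
                        q_of_t.append(q)
                        q += sign
                elif op == "I":
                    q += sign * n
                else:  # D
                    q_of_t.extend([q] * n)
            q_of_t.append(q)  # position at target_end
            t1 = int(rng.integers(ts, ts + tlen))
            t2 = int(rng.integers(t1 + 1, ts + tlen + 1))
            roi = GenomicInterval("chr1", t1, t2)
            out = project_to_roi([r], roi)
            qa, qb = q_of_t[t1 - ts], q_of_t[t2 - ts]
            lo, hi = min(qa, qb), max(qa, qb)
            if lo >= hi:
                assert out == []
            else:
                assert (out[0].query_start, out[0].query_end) == (lo, hi)
                assert (out[0].target_start, out[0].target_end) == (t1, t2)


class TestSpanningSelection:
    def test_edge_distance_rule(self):
        roi = GenomicInterval("chr1", 1_000_000, 3_000_000)
        full = painting([rec(1_050_000, 2_950_000)], "a", roi)  # 50 kbp short
        exact = painting([rec(1_100_000, 2_900_000)], "b", roi)  # exactly 100 kbp
        short = painting([rec(1_150_000, 2_950_000)], "c", roi)  # 150 kbp short
        kept = select_spanning_assemblies([full, exact, short], roi)
        assert [p.assembly_id for p in kept] == ["a", "b"]


class TestSynchronizeOrientation:
    def segs(self, strands, length=60_000):
        return [
            rec(i * length, (i + 1) * length, strand=s, qs=i * length)
            for i, s in enumerate(strands)
        ]

    def test_both_anchors_minus_flips_everything(self):
        p = painting(self.segs(["-", "+", "-"]))
        flipped = synchronize_orientation(p)
        assert [s.strand for s in flipped.segments] == ["+", "-", "+"]
        # query coordinates mirror around the assembly length
        orig = p.segments[0]
        new = flipped.segments[0]
        assert new.query_start == orig.query_len - orig.query_end
        assert new.query_end == orig.query_len - orig.query_start

    def test_mixed_anchors_unchanged(self):
        p = painting(self.segs(["-", "+"]))
        assert synchronize_orientation(p) == p

    def test_idempotent(self):
        p = painting(self.segs(["-", "-", "-"]))
        once = synchronize_orientation(p)
        assert synchronize_orientation(once) == once

    def test_short_segments_are_not_anchors(self):
        # outer '-' segments below the 50 kbp anchor floor: no flip, flagged
        p = painting(self.segs(["-", "+", "-"], length=10_000))
        out = synchronize_orientation(p)
        assert [s.strand for s in out.segments] == ["-", "+", "-"]
        assert out.no_anchor


class TestGrouping:
    def test_identical_paintings_share_a_group(self):
        a = painting([rec(0, 60_000)], "a")
        b = painting([rec(0, 60_000)], "b")
        labels, counts = group_haplotypes([a, b])
        assert labels["a"] == labels["b"]
        assert counts[labels["a"]] == {"ALL": 2}

    def test_extra_inverted_segment_separates(self):
        a = painting([rec(0, 60_000)], "a")
        b = painting([rec(0, 60_000), rec(60_000, 80_000, strand="-")], "b")
        labels, _ = group_haplotypes([a, b])
        assert labels["a"] != labels["b"]

    def test_order_invariance(self):
        ps = [
            painting([rec(0, 60_000)], "a"),
            painting([rec(0, 60_000, strand="-")], "b"),
            painting([rec(0, 60_000)], "c"),
        ]
        fwd, _ = group_haplotypes(ps)
        rev, _ = group_haplotypes(ps[::-1])
        assert fwd == rev

    def test_superpopulation_stratification(self):
        ps = [painting([rec(0, 60_000)], n) for n in ("a", "b", "c")]
        _, counts = group_haplotypes(
            ps, superpopulations={"a": "AFR", "b": "AFR", "c": "EAS"}
        )
        assert counts == {"H1": {"AFR": 2, "EAS": 1}}


def self_rec(l, r, strand, name="asm", qlen=2_000_000):
    (ls, le), (rs, re) = l, r
    return AlignmentRecord(name, qlen, ls, le, strand, name, rs, re, 60,
                           min(le - ls, re - rs), target_len=qlen)


class TestFlankAnalysis:
    def test_direct_pair_far_apart_is_at_risk(self):
        fa = flank_analysis(
            [self_rec((0, 50_000), (650_000, 700_000), "+")], "asm"
        )
        assert fa.direct_bases == 100_000
        assert fa.inverted_bases == 0
        assert fa.risk is Risk.AT_RISK

    def test_inverted_pair_only_is_protected(self):
        fa = flank_analysis(
            [self_rec((0, 50_000), (650_000, 700_000), "-")], "asm"
        )
        assert fa.risk is Risk.PROTECTED

    def test_close_pair_excluded(self):
        fa = flank_analysis(
            [self_rec((0, 50_000), (450_000, 500_000), "+")], "asm"
        )  # inner distance 400 kbp < 500 kbp
        assert fa.direct_bases == 0 and fa.risk is Risk.AMBIGUOUS

    def test_diagonal_and_mirror_duplicates_ignored(self):
        qlen = 2_000_000
        records = [
            AlignmentRecord("asm", qlen, 0, qlen, "+", "asm", 0, qlen, 60, qlen,
                            target_len=qlen),  # identity diagonal
            self_rec((0, 50_000), (650_000, 700_000), "-"),
            self_rec((650_000, 700_000), (0, 50_000), "-"),  # B<->A duplicate
        ]
        fa = flank_analysis(records, "asm")
        assert fa.inverted_bases == 100_000

    def test_no_pairs_is_ambiguous(self):
        fa = flank_analysis([], "asm")
        assert (fa.direct_bases, fa.inverted_bases, fa.risk) == (0, 0, Risk.AMBIGUOUS)


class TestFlankingSdPair:
    inversion = GenomicInterval("asm", 100_000, 775_000)  # ~675 kbp

    def test_bracketing_inverted_pair_found(self):
        pair = flanking_sd_pair(
            [self_rec((0, 90_000), (800_000, 890_000), "-")], self.inversion
        )
        assert pair is not None
        left, right = pair
        assert left.end <= self.inversion.start
        assert right.start >= self.inversion.end

    def test_direct_pair_rejected(self):
        assert flanking_sd_pair(
            [self_rec((0, 90_000), (800_000, 890_000), "+")], self.inversion
        ) is None

    def test_pair_on_one_side_rejected(self):
        both_left = GenomicInterval("asm", 1_500_000, 1_600_000)
        assert flanking_sd_pair(
            [self_rec((0, 90_000), (800_000, 890_000), "-")], both_left
        ) is None
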