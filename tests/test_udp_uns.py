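"""Cropping, read filters, deletion footprints, UDP clustering and UNS."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from generra.roi_profile import ROI
from generra.udp_uns import (
    UDP,
    DeletionFootprint,
    UnpairedUDPError,
    WTRecord,
    align_single_deletion,
    apply_count_filters,
    cluster_udps,
    crop_to_roi,
    filter_read,
    footprint,
    mutant_sequence,
    replicate_concordance,
    reads_to_footprints,
    uns,
    uns_records,
)
from tests.conftest import WORKED_CODE, WORKED_READ, WORKED_REF, make_read


def fp(code, start=0):
    roi = ROI(ref_name="amp1", start=start, end=start + len(code))
    return DeletionFootprint(code=code, roi=roi)


class TestWorkedExample:
    """The printed read/reference alignment and its footprint code."""

    def test_single_deletion_alignment(self):
        assert align_single_deletion(WORKED_READ, WORKED_REF) == \
            [(5, "M"), (5, "D"), (5, "M")]

    def test_footprint_code(self, worked_roi):
        read = make_read([(5, "M"), (5, "D"), (5, "M")], WORKED_READ)
        cropped = crop_to_roi(read, worked_roi)
        assert footprint(cropped, worked_roi).code == WORKED_CODE

    def test_mismatch_tolerated(self, worked_roi):
        # 1 mismatch among 10 aligned positions = 10%, at the keep boundary
        read = make_read([(5, "M"), (5, "D"), (5, "M")], WORKED_READ)
        cropped = crop_to_roi(read, worked_roi)
        keep, reason = filter_read(cropped, WORKED_REF, 0.10)
        assert keep and reason is None


class TestBruteForceFootprintOracle:
    """Simulated single-interval deletions are recovered exactly."""

    @settings(deadline=None, max_examples=60)
    @given(st.data())
    def test_recovers_known_interval(self, data):
        n = data.draw(st.integers(12, 30))
        start = data.draw(st.integers(1, n - 3))
        end = data.draw(st.integers(start + 1, n - 1))
        read = make_read(
            [(start, "M"), (end - start, "D"), (n - end, "M")], "A" * (n - (end - start)))
        roi = ROI(ref_name="amp1", start=0, end=n)
        code = footprint(crop_to_roi(read, roi), roi).code
        expected = "".join("1" if start <= i < end else "0" for i in range(n))
        assert code == expected


class TestCropAndFilter:
    def test_restriction_identity(self):
        # deletions only inside ROI: cropped footprint = restriction
        read = make_read([(10, "M"), (4, "D"), (16, "M")], "A" * 26)
        roi = ROI(ref_name="amp1", start=5, end=20)
        code = crop_to_roi(read, roi).footprint_code()
        assert code == "0" * 5 + "1" * 4 + "0" * 6

    def test_snp_outside_roi_clusters_with_clean_read(self):
        ref = "ACGT" * 10  # 40 nt
        roi = ROI(ref_name="amp1", start=30, end=40)
        clean = make_read([(15, "M"), (3, "D"), (22, "M")], ref[:15] + ref[18:])
        # SNP at reference position 2, far upstream of the ROI
        snp_q = "AC" + "A" + clean.query[3:]
        snp = make_read([(15, "M"), (3, "D"), (22, "M")], snp_q)
        fps, _ = reads_to_footprints([clean, snp], roi, ref[30:40])
        assert len(fps) == 2
        assert fps[0].code == fps[1].code

    def test_soft_clip_inside_roi_flags_truncated(self):
        read = make_read([(10, "M"), (10, "S")], "A" * 20)
        roi = ROI(ref_name="amp1", start=5, end=15)
        cropped = crop_to_roi(read, roi)
        assert cropped.truncated
        assert filter_read(cropped, "A" * 10) == (False, "truncated")

    def test_insertion_inside_roi_discarded(self):
        read = make_read([(7, "M"), (2, "I"), (8, "M")], "A" * 17)
        roi = ROI(ref_name="amp1", start=0, end=15)
        cropped = crop_to_roi(read, roi)
        assert filter_read(cropped, "A" * 15) == (False, "insertion")

    def test_two_mismatches_among_ten_discarded(self, worked_roi):
        query = "AGTAACAATC"  # 2 mismatches vs WORKED_REF after the deletion
        read = make_read([(5, "M"), (5, "D"), (5, "M")], query)
        cropped = crop_to_roi(read, worked_roi)
        assert filter_read(cropped, WORKED_REF, 0.10) == (False, "mismatch")

    def test_two_deletion_blocks(self):
        read = make_read([(3, "M"), (2, "D"), (4, "M"), (2, "D"), (4, "M")], "A" * 11)
        roi = ROI(ref_name="amp1", start=0, end=15)
        assert crop_to_roi(read, roi).footprint_code() == "000110000110000"


class TestClusterUDPs:
    def test_hand_tally(self):
        g = [fp("000")] * 100 + [fp("011")] * 10
        c = [fp("000")] * 100 + [fp("011")] * 40
        udps, wt = cluster_udps(g, c, "ACG")
        assert len(udps) == 1
        assert (udps[0].gdna_count, udps[0].cdna_count) == (10, 40)
        assert (wt.gdna_wt_count, wt.cdna_wt_count) == (100, 100)
        assert udps[0].mutant_sequence == "A"

    def test_count_conservation(self):
        rng = np.random.default_rng(1)
        codes = ["000", "100", "010", "011"]
        g = [fp(codes[i]) for i in rng.integers(0, 4, 200)]
        c = [fp(codes[i]) for i in rng.integers(0, 4, 300)]
        udps, wt = cluster_udps(g, c, "ACG")
        assert sum(u.gdna_count for u in udps) + wt.gdna_wt_count == 200
        assert sum(u.cdna_count for u in udps) + wt.cdna_wt_count == 300

    def test_cdna_only_footprint_is_unpaired(self):
        udps, _ = cluster_udps([fp("000")], [fp("110")], "ACG")
        assert udps[0].gdna_count == 0 and not udps[0].paired

    def test_deterministic_ordering(self):
        g = [fp("001"), fp("110"), fp("100"), fp("011")]
        udps, _ = cluster_udps(g, [], "ACG")
        assert [u.footprint.code for u in udps] == ["100", "110", "011", "001"]


class TestUNS:
    def test_arithmetic_oracle(self):
        udp = UDP(fp("011"), gdna_count=100, cdna_count=200, mutant_sequence="A")
        wt = WTRecord(gdna_wt_count=2000, cdna_wt_count=1000)
        assert uns(udp, wt).uns == pytest.approx(4.0)

    def test_neutral_element(self):
        udp = UDP(fp("011"), 50, 25, "A")
        wt = WTRecord(1000, 500)
        assert uns(udp, wt).uns == pytest.approx(1.0)

    def test_complete_transcript_loss_scores_zero(self):
        udp = UDP(fp("011"), 80, 0, "A")
        assert uns(udp, WTRecord(100, 100)).uns == 0.0

    def test_unpaired_or_zero_wt_excluded_with_reason(self):
        with pytest.raises(UnpairedUDPError):
            uns(UDP(fp("011"), 0, 5, "A"), WTRecord(100, 100))
        with pytest.raises(UnpairedUDPError):
            uns(UDP(fp("011"), 5, 5, "A"), WTRecord(0, 100))
        records, excl = uns_records([UDP(fp("011"), 0, 5, "A")], WTRecord(100, 100))
        assert records == [] and excl[0]["code"] == "011"

    def test_scale_invariance(self):
        udp = UDP(fp("011"), 100, 200, "A")
        wt = WTRecord(2000, 1000)
        base = uns(udp, wt).uns
        for k in (3, 10, 250):
            scaled = uns(UDP(fp("011"), 100, 200 * k, "A"),
                         WTRecord(2000, 1000 * k)).uns
            assert scaled == pytest.approx(base)


class TestCountFilters:
    def rec(self, g, c):
        return uns(UDP(fp("011"), g, c, "A"), WTRecord(1000, 1000))

    def test_wt_boundary_below_100_excludes_amplicon(self):
        kept, excl = apply_count_filters([self.rec(50, 50)], WTRecord(99, 5000))
        assert kept == []
        assert excl[0]["reason"] == "low_wt_reads"

    def test_udp_boundary_at_threshold_kept(self):
        kept, excl = apply_count_filters([self.rec(10, 10)], WTRecord(100, 100))
        assert len(kept) == 1 and excl == []

    def test_udp_below_threshold_dropped(self):
        kept, excl = apply_count_filters([self.rec(9, 500)], WTRecord(100, 100))
        assert kept == [] and excl[0]["reason"] == "low_udp_reads"


class TestReplicateConcordance:
    def recs(self, pairs):
        wt = WTRecord(1000, 1000)
        return [uns(UDP(fp(code), g, c, "A"), wt) for code, g, c in pairs]

    def test_identical_replicates(self):
        r = self.recs([("100", 50, 100), ("010", 50, 25), ("001", 80, 160)])
        slope, r2 = replicate_concordance(r, r)
        assert slope == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_doubled_replicate(self):
        r1 = self.recs([("100", 50, 100), ("010", 50, 25), ("001", 80, 160)])
        r2 = self.recs([("100", 50, 200), ("010", 50, 50), ("001", 80, 320)])
        slope, r2_ = replicate_concordance(r1, r2)
        assert slope == pytest.approx(2.0)
        assert r2_ == pytest.approx(1.0)

    def test_too_few_shared_is_missing(self):
        r1 = self.recs([("100", 50, 100)])
        r2 = self.recs([("100", 50, 100), ("010", 50, 25)])
        assert replicate_concordance(r1, r2) is None


def test_mutant_sequence_length_invariant():
    code = "0110010"
    seq = "ACGTACG"
    mut = mutant_sequence(code, seq)
    assert len(mut) == len(seq) - code.count("1")
    assert mut == "ATAG"
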