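"""Seed-overlap classification, de-novo site exclusion and MRE-scores."""

import numpy as np
import pytest

from generra.mre_score import (
    MREAnnotation,
    assign_group,
    check_coincidental_rres,
    classify_seed_overlap,
    coincidental_rre_report,
    is_distal_only,
    mre_score,
    scan_de_novo_mres,
    score_mre,
    weighted_group_mean,
)
from generra.roi_profile import ROI
from generra.udp_uns import UDP, DeletionFootprint, UNSRecord, WTRecord, uns


MRE = MREAnnotation(gene="g", mre_id="m1", seed_start=10, seed_end=18,
                    binding_start=10, binding_end=32, D=100, L=400)


def fp(deleted, length=50):
    code = "".join("1" if i in deleted else "0" for i in range(length))
    return DeletionFootprint(code=code, roi=ROI("g", 0, length))


def udp(deleted, g=100, c=100):
    f = fp(deleted)
    return UDP(f, g, c, mutant_sequence="A" * (50 - f.n_deleted))


def rec(uns_value, gdna=100, deleted=(11, 12)):
    u = udp(set(deleted), g=gdna, c=gdna)
    return UNSRecord(udp=u, uns=uns_value)


class TestSeedClassification:
    def test_core_seed_deletion(self):
        assert classify_seed_overlap(udp({11, 12, 13}), MRE) == "seed_deleting"

    def test_downstream_only_is_intact(self):
        assert classify_seed_overlap(udp({20, 21, 22}), MRE) == "seed_intact"

    def test_single_distal_position_counts_and_is_flagged(self):
        u = udp({17})  # seed position 8 only
        assert classify_seed_overlap(u, MRE) == "seed_deleting"
        assert is_distal_only(u, MRE)
        assert not is_distal_only(udp({13, 17}), MRE)

    def test_coordinate_mismatch_errors(self):
        small = DeletionFootprint("1" * 5, ROI("g", 0, 5))
        u = UDP(small, 10, 10, "")
        with pytest.raises(ValueError, match="outside ROI"):
            classify_seed_overlap(u, MRE)


class TestDeNovoScan:
    def test_deletion_creates_site(self):
        # deletion juxtaposes GTCC|AGGT -> TCCAGGT appears only in mutant
        wt = "AAGTCCTTTTTAGGTAA"
        mut = "AAGTCCAGGTAA"
        assert scan_de_novo_mres(mut, wt, ["TCCAGGT"]) == ["TCCAGGT"]

    def test_preexisting_site_not_reported(self):
        wt = "TCCAGGTAAATTTCCC"
        mut = "TCCAGGTAAATTT"
        assert scan_de_novo_mres(mut, wt, ["TCCAGGT"]) == []

    def test_empty_seed_list(self):
        assert scan_de_novo_mres("ACGT", "ACGTA", []) == []

    def test_bad_seed_length_rejected(self):
        with pytest.raises(ValueError, match="7-mer"):
            scan_de_novo_mres("ACGT", "ACGTA", ["ACGT"])


class TestCoincidentalRREs:
    def test_identical_distributions(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert check_coincidental_rres(vals, vals) == pytest.approx(1.0)

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(7)
        a = rng.normal(1, 0.5, 20)
        b = a + 10
        assert check_coincidental_rres(b, a) < 0.01

    def test_small_group_missing(self):
        assert check_coincidental_rres([1.0], [1.0, 2.0, 3.0]) is None

    def test_report_flags_per_rre(self):
        records = [rec(10.0, deleted={40, 41}) for _ in range(10)]
        records += [rec(1.0, deleted={11}) for _ in range(10)]
        out = coincidental_rre_report(records, {"polyA": (40, 46)})
        assert out[0]["rre"] == "polyA"
        assert out[0]["n_with"] == 10
        assert out[0]["flagged"]


class TestMREScore:
    def test_weighted_mean_arithmetic(self):
        result = mre_score([rec(2.0, gdna=100), rec(4.0, gdna=300)], "m1")
        assert result.score == pytest.approx(3.5)
        assert result.group == "medium"
        assert result.n_udps == 2

    def test_equal_uns_gives_that_value(self):
        result = mre_score([rec(2.5, gdna=g) for g in (10, 99, 1000)])
        assert result.score == pytest.approx(2.5)

    def test_convex_combination_property(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            vals = rng.uniform(0.1, 20, size=5)
            counts = rng.integers(10, 500, size=5)
            recs = [rec(v, gdna=int(g)) for v, g in zip(vals, counts)]
            s = mre_score(recs).score
            assert vals.min() - 1e-9 <= s <= vals.max() + 1e-9

    def test_split_invariance(self):
        # splitting a UDP's reads into two identical-footprint entries
        whole = mre_score([rec(3.0, gdna=200), rec(6.0, gdna=100)]).score
        split = mre_score(
            [rec(3.0, gdna=120), rec(3.0, gdna=80), rec(6.0, gdna=100)]).score
        assert split == pytest.approx(whole)

    def test_empty_set_errors(self):
        with pytest.raises(ValueError, match="cannot be scored"):
            mre_score([])


class TestAssignGroup:
    @pytest.mark.parametrize("score,group", [
        (1.0, "low"), (1.999, "low"),
        (2.0, "medium"), (3.0, "medium"), (4.0, "medium"),
        (4.001, "high"), (14.06, "high"),
    ])
    def test_boundaries(self, score, group):
        assert assign_group(score) == group

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            assign_group(0.0)


class TestWeightedGroupMean:
    def test_single_record(self):
        assert weighted_group_mean([rec(3.0)]) == pytest.approx(3.0)

    def test_depth_weighting(self):
        got = weighted_group_mean([rec(10.0, gdna=10), rec(1.0, gdna=90)])
        assert got == pytest.approx(1.9)

    def test_binding_region_restriction(self):
        inside = rec(5.0, deleted={11, 12})          # within [10, 32)
        outside = rec(50.0, deleted={11, 40})        # extends past binding region
        got = weighted_group_mean([inside, outside], mre=MRE,
                                  restriction="binding_region_only")
        assert got == pytest.approx(5.0)


class TestScoreMRE:
    def test_exclusion_completeness(self):
        wt_seq = "A" * 50
        records = [
            rec(5.0, deleted={11, 12}),
            rec(2.0, deleted={30, 31}),   # seed intact
            rec(7.0, deleted={13}),
        ]
        result, exclusions = score_mre(records, MRE, [], wt_seq)
        assert result is not None
        assert result.n_udps + len(exclusions) == len(records)
        assert exclusions[0]["reason"] == "seed_intact"

    def test_de_novo_creating_udp_excluded(self):
        wt_seq = "AAGTCC" + "T" * 38 + "AGGTAA"
        # deletion of the middle T-run juxtaposes GTCC|AGGT
        code = "0" * 6 + "1" * 38 + "0" * 6
        f = DeletionFootprint(code, ROI("g", 0, 50))
        u = UDP(f, 100, 100, mutant_sequence="AAGTCCAGGTAA")
        seed_hit = rec(5.0, deleted={11, 12})
        result, exclusions = score_mre(
            [seed_hit, UNSRecord(udp=u, uns=9.0)], MRE, ["TCCAGGT"], wt_seq)
        assert result.n_udps == 1
        assert any(e["reason"].startswith("de_novo_mre") for e in exclusions)

    def test_no_seed_deleting_udps(self):
        result, exclusions = score_mre(
            [rec(2.0, deleted={30})], MRE, [], "A" * 50)
        assert result is None
        assert exclusions[-1]["reason"] == "no_seed_deleting_udps"
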