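"""Segment I/O, arm alteration fractions, and the arm-level CIN classifier."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cinscore.ai_calling import CIN_H, CIN_L
from cinscore.cnv_arms import (
    Segment,
    SegmentError,
    arm_alteration_fraction,
    arm_altered,
    cutoff_scan,
    profile_sample,
    read_segments,
    segments_from_frame,
    write_segments,
)

SEG_HEADER = "sample_id\tchrom\tstart\tend\tcall\n"


def seg_table(rows):
    return io.StringIO(SEG_HEADER + "".join("\t".join(map(str, r)) + "\n" for r in rows))


def brute_force_fraction(segments, arm, calls=("gain", "loss", "AI")):
    """Per-base counting oracle over the arm interval."""
    chrom, start, end = arm
    covered = np.zeros(end - start, dtype=bool)
    for s in segments:
        if s.call in calls and s.chrom == chrom:
            lo, hi = max(s.start, start), min(s.end, end)
            if lo < hi:
                covered[lo - start : hi - start] = True
    return covered.mean()


class TestSegmentIO:
    def test_read_sorts_and_converts_coordinates(self):
        segs = read_segments(seg_table([
            ("S1", "8", 101, 200, "loss"),
            ("S1", "7", 1, 50, "gain"),
        ]))
        assert [s.chrom for s in segs] == ["7", "8"]
        # 1-based inclusive [101, 200] -> 0-based half-open [100, 200)
        assert (segs[1].start, segs[1].end) == (100, 200)

    def test_unknown_call_lists_allowed_labels(self):
        with pytest.raises(SegmentError, match="gain"):
            read_segments(seg_table([("S1", "8", 1, 10, "amp")]))

    def test_inverted_interval_names_row(self):
        with pytest.raises(SegmentError, match="row 2"):
            read_segments(seg_table([("S1", "8", 100, 50, "loss")]))

    def test_round_trip(self, tmp_path):
        segs = read_segments(seg_table([
            ("S1", "8", 101, 200, "loss"),
            ("S2", "chr3", 11, 400, "AI"),
        ]))
        path = tmp_path / "out.seg"
        write_segments(segs, path)
        assert read_segments(path) == segs


class TestArmFraction:
    ARM = ("8", 0, 1000)

    def test_full_arm_loss(self):
        segs = [Segment("S", "8", 0, 1000, "loss")]
        assert arm_alteration_fraction(segs, self.ARM) == 1.0

    def test_overlapping_gains_union(self):
        segs = [Segment("S", "8", 0, 300, "gain"), Segment("S", "8", 200, 500, "gain")]
        assert arm_alteration_fraction(segs, self.ARM) == 0.5

    def test_other_chromosome_ignored(self):
        segs = [Segment("S", "7", 0, 1000, "loss")]
        assert arm_alteration_fraction(segs, self.ARM) == 0.0

    def test_neutral_ignored(self):
        segs = [Segment("S", "8", 0, 1000, "neutral")]
        assert arm_alteration_fraction(segs, self.ARM) == 0.0

    def test_duplicate_segment_no_inflation(self):
        segs = [Segment("S", "8", 100, 400, "AI")]
        assert arm_alteration_fraction(segs * 3, self.ARM) == arm_alteration_fraction(segs, self.ARM)

    @given(st.data())
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_brute_force_oracle(self, data):
        arm_len = data.draw(st.integers(10, 2000))
        n_segs = data.draw(st.integers(0, 10))
        segs = []
        for _ in range(n_segs):
            a = data.draw(st.integers(0, arm_len + 100))
            b = data.draw(st.integers(a + 1, arm_len + 200))
            call = data.draw(st.sampled_from(["gain", "loss", "AI", "neutral"]))
            segs.append(Segment("S", "8", a, b, call))
        arm = ("8", 0, arm_len)
        assert arm_alteration_fraction(segs, arm) == pytest.approx(
            brute_force_fraction(segs, arm), abs=1e-12
        )


class TestArmRule:
    @pytest.mark.parametrize("frac,expected", [(0.80, True), (0.79, False), (1.0, True), (0.0, False)])
    def test_eighty_percent_inclusive(self, frac, expected):
        assert arm_altered(frac) is expected


class TestClassifier:
    def _profile(self, arm_model, segs, sid="S1"):
        return profile_sample(segs, arm_model, sample_id=sid)

    def _full_arm_seg(self, arm_model, arm, call="loss", sid="S1"):
        chrom, start, end = arm_model.interval(arm)
        return Segment(sid, chrom, start, end, call)

    def test_only_18q_altered_is_cin_l(self, arm_model):
        p = self._profile(arm_model, [self._full_arm_seg(arm_model, "18q")])
        assert p.cin_class == CIN_L and p.alteration_ratio == 0.0

    def test_single_non_excluded_arm_is_cin_h(self, arm_model):
        p = self._profile(arm_model, [self._full_arm_seg(arm_model, "7q")])
        assert p.cin_class == CIN_H and p.n_altered_evaluable == 1

    def test_no_segments_cin_l(self, arm_model):
        assert self._profile(arm_model, []).cin_class == CIN_L

    def test_alteration_ratio_denominator_36(self, arm_model):
        segs = [self._full_arm_seg(arm_model, a) for a in ("7q", "8q", "9p")]
        p = self._profile(arm_model, segs)
        assert p.alteration_ratio == pytest.approx(3 / 36)

    def test_ratio_on_exact_grid(self, arm_model, small_cohort):
        from cinscore.synthetic import generate_segments

        segs = segments_from_frame(generate_segments(small_cohort))
        grid = {i / 36 for i in range(37)}
        for sid in {s.sample_id for s in segs}:
            p = profile_sample(segs, arm_model, sample_id=sid)
            assert any(abs(p.alteration_ratio - g) < 1e-12 for g in grid)

    def test_monotone_adding_altered_arm(self, arm_model):
        segs = [self._full_arm_seg(arm_model, "7q")]
        before = self._profile(arm_model, segs)
        segs.append(self._full_arm_seg(arm_model, "9p"))
        after = self._profile(arm_model, segs)
        assert before.cin_class == CIN_H and after.cin_class == CIN_H
        assert after.n_altered_evaluable > before.n_altered_evaluable

    def test_centromere_spanning_segment_split_by_clipping(self, arm_model):
        # one segment across the whole chromosome alters both arms
        chrom, p_start, _ = arm_model.interval("8p")
        _, _, q_end = arm_model.interval("8q")
        p = self._profile(arm_model, [Segment("S1", "8", p_start, q_end, "gain")])
        assert {"8p", "8q"} <= p.altered_arms


class TestCutoffScan:
    def test_perfectly_separable_reaches_100(self):
        ratios = [0.05, 0.1, 0.3, 0.4]
        ref = [CIN_L, CIN_L, CIN_H, CIN_H]
        scan = cutoff_scan(ratios, ref)
        assert scan["concordance_pct"].max() == 100.0
        best = scan.loc[scan["concordance_pct"].idxmax(), "cutoff"]
        assert 0.1 < best <= 0.3

    def test_all_reference_cin_h(self):
        scan = cutoff_scan([0.1, 0.2, 0.3], [CIN_H] * 3)
        top = scan[scan["concordance_pct"] == 100.0]
        assert (top["cutoff"] <= 0.1).all()

    def test_overlapping_classes_tie_at_maximum(self):
        # two classes overlapping in the middle: several cut-offs tie
        ratios = [0.05, 0.11, 0.15, 0.24, 0.3, 0.45]
        ref = [CIN_L, CIN_L, CIN_H, CIN_L, CIN_H, CIN_H]
        scan = cutoff_scan(ratios, ref)
        best = scan["concordance_pct"].max()
        assert (scan["concordance_pct"] == best).sum() >= 2

    def test_error_decomposition_sums(self):
        ratios = [0.05, 0.15, 0.25, 0.35]
        ref = [CIN_L, CIN_H, CIN_L, CIN_H]
        scan = cutoff_scan(ratios, ref)
        n = len(ratios)
        for _, row in scan.iterrows():
            assert row["concordance_pct"] == pytest.approx(
                100.0 * (n - row["false_H"] - row["false_L"]) / n
            )
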