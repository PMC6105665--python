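"""AI values, marker/region calls, MSI gate, CIN cut-off, dilution model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cinscore.ai_calling import (
    AI,
    CIN_H,
    CIN_L,
    NO_AI,
    NOT_EVALUATED_MSI,
    NOT_INFORMATIVE,
    AICallError,
    AIMarkerResult,
    aggregate_region,
    ai_frequency,
    ai_ratio,
    build_profile,
    call_ai_marker,
    classify_cin_pcr,
    classify_ratio_table,
    compute_ai_value,
    dilution_ai_value,
    evaluate_marker,
    lod_scan,
    msi_screen,
    run_two_step,
)
from cinscore.peak_io import NORMAL, TUMOUR, GenotypeCall, PeakRecord

pos_area = st.floats(10.0, 1e6)


def het(tissue, a_short, a_long, marker="M", sizes=(150.0, 158.0)):
    return GenotypeCall("S", tissue, marker,
                        ((sizes[0], a_short), (sizes[1], a_long)), "heterozygous")


class TestComputeAIValue:
    def test_definition_arithmetic(self):
        assert compute_ai_value(het(NORMAL, 1000, 500), het(TUMOUR, 800, 800)) == 2.0

    def test_balanced_tumour_gives_unity(self):
        assert compute_ai_value(het(NORMAL, 700, 300), het(TUMOUR, 700, 300)) == 1.0

    def test_swap_inverts(self):
        n, t = het(NORMAL, 1000, 500), het(TUMOUR, 800, 800)
        assert compute_ai_value(n, t) == 2.0
        assert compute_ai_value(t, n) == 0.5

    @given(ns=pos_area, nl=pos_area, ts=pos_area, tl=pos_area)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_reciprocal_symmetry(self, ns, nl, ts, tl):
        n, t = het(NORMAL, ns, nl), het(TUMOUR, ts, tl)
        assert compute_ai_value(n, t) * compute_ai_value(t, n) == pytest.approx(1.0, rel=1e-9)

    def test_allele_size_mismatch_rejected(self):
        with pytest.raises(AICallError, match="sizes differ"):
            compute_ai_value(het(NORMAL, 1, 1), het(TUMOUR, 1, 1, sizes=(150.0, 162.0)))

    def test_homozygous_normal_rejected(self):
        homo = GenotypeCall("S", NORMAL, "M", ((150.0, 1.0),), "homozygous")
        with pytest.raises(AICallError, match="heterozygous"):
            compute_ai_value(homo, het(TUMOUR, 1, 1))


class TestMarkerCall:
    @pytest.mark.parametrize(
        "value,expected",
        [(0.80, AI), (1.0, NO_AI), (0.82, NO_AI), (1.29, NO_AI), (1.30, AI)],
    )
    def test_strict_threshold_comparison(self, value, expected):
        assert call_ai_marker(value, (0.82, 1.29)) == expected

    def test_informative_requires_het_normal_and_evaluable_tumour(self):
        thr = (0.8, 1.2)
        homo = GenotypeCall("S", NORMAL, "M", ((150.0, 1.0),), "homozygous")
        r = evaluate_marker("T1", homo, het(TUMOUR, 1, 1), thr)
        assert not r.informative and r.ai_call == NOT_INFORMATIVE and r.ai_value is None
        r = evaluate_marker("T1", het(NORMAL, 1, 1), None, thr)
        assert not r.informative
        r = evaluate_marker("T1", het(NORMAL, 1000, 500), het(TUMOUR, 800, 800), thr)
        assert r.informative and r.ai_call == AI and r.ai_value == 2.0


def res(call, marker="M", informative=None):
    informative = call in (AI, NO_AI) if informative is None else informative
    return AIMarkerResult("T", marker, informative, 1.5 if informative else None, call)


class TestAggregation:
    @pytest.mark.parametrize(
        "calls,expected",
        [
            ([AI, NO_AI], AI),
            ([NO_AI, NOT_INFORMATIVE], NO_AI),
            ([NOT_INFORMATIVE, NOT_INFORMATIVE], NOT_INFORMATIVE),
            ([AI], AI),
        ],
    )
    def test_region_any_rule(self, calls, expected):
        assert aggregate_region([res(c) for c in calls]) == expected

    def test_ai_ratio_arithmetic(self):
        results = [res(AI)] * 3 + [res(NO_AI)] * 12
        assert ai_ratio(results) == pytest.approx(0.2)
        assert ai_ratio([res(NO_AI)] * 20) == 0.0

    def test_ai_ratio_no_informative_is_none(self):
        assert ai_ratio([res(NOT_INFORMATIVE)] * 3) is None

    def test_region_ai_count_bounded_by_marker_ai_count(self, panel):
        rng = np.random.default_rng(2)
        results = [
            res(rng.choice([AI, NO_AI, NOT_INFORMATIVE]), marker=m.name)
            for m in panel.ai_markers
        ]
        profile = build_profile("T", results, panel)
        region_ai = sum(c == AI for c in profile.region_results.values())
        assert region_ai <= profile.n_ai_markers


class TestCINCutoff:
    @pytest.mark.parametrize("ratio,expected", [(0.20, CIN_H), (0.19, CIN_L), (0.78, CIN_H), (0.0, CIN_L)])
    def test_inclusive_boundary(self, ratio, expected):
        assert classify_cin_pcr(ratio) == expected

    def test_ratio_table_summary(self):
        out = classify_ratio_table([0.0, 0.19, 0.2, 0.5, 0.78])
        assert out["n_cin_h"] == 3 and out["n_cin_l"] == 2
        assert out["max"] == 0.78


class TestMSIScreen:
    def test_two_shifted_markers_is_msi(self, panel):
        n = {"BAT25": (120.0,), "D2S123": (200.0, 210.0)}
        t = {"BAT25": (116.0, 120.0), "D2S123": (196.0, 200.0, 210.0)}
        r = msi_screen("T", n, t, panel)
        assert r.status == "MSI" and set(r.unstable_markers) == {"BAT25", "D2S123"}

    def test_one_shifted_marker_is_mss(self, panel):
        n = {"BAT26": (113.0,), "D5S346": (100.0, 110.0)}
        t = {"BAT26": (110.0, 113.0), "D5S346": (100.0, 110.0)}
        assert msi_screen("T", n, t, panel).status == "MSS"

    def test_identical_alleles_mss(self, panel):
        sizes = {m.name: (120.0, 124.0) for m in panel.msi_markers}
        assert msi_screen("T", sizes, sizes, panel).status == "MSS"

    def test_no_typed_markers_rejected(self, panel):
        with pytest.raises(AICallError):
            msi_screen("T", {}, {}, panel)


class TestTwoStep:
    def test_msi_cases_gated_and_not_profiled(self, panel, small_cohort):
        recs = [PeakRecord(*r) for r in small_cohort.cohort_peaks.itertuples(index=False)]
        profiles, summary = run_two_step(recs, panel)
        truth = small_cohort.tumour_truth.set_index("tumour_id")
        for p in profiles:
            if truth.loc[p.tumour_id, "msi"]:
                assert p.cin_class == NOT_EVALUATED_MSI
                assert p.ai_ratio is None and p.n_informative_markers == 0
        assert summary.n_msi == int(truth["msi"].sum())
        assert summary.n_cases == len(truth)

    def test_empty_cohort(self, panel):
        profiles, summary = run_two_step([], panel)
        assert profiles == [] and summary.n_cases == 0

    def test_unmatched_case_reported_not_fatal(self, panel):
        recs = [
            PeakRecord("GC1", NORMAL, "D9S171", 160.0, 100.0),
            PeakRecord("GC1", NORMAL, "D9S171", 166.0, 100.0),
        ]
        profiles, _ = run_two_step(recs, panel)
        assert profiles[0].cin_class == "not_evaluable"
        assert "unmatched case" in profiles[0].warnings

    def test_ai_frequency_arithmetic(self, panel):
        profiles = []
        for i in range(100):
            call = AI if i < 71 else NO_AI
            r9 = [res(call, marker="D9S157"), res(NOT_INFORMATIVE, marker="D9S171")]
            profiles.append(build_profile(f"T{i}", r9, panel))
        assert ai_frequency(profiles, "9p21") == pytest.approx(71.0)


class TestDilution:
    def _pair(self):
        n = het(NORMAL, 1000.0, 1000.0)
        t = het(TUMOUR, 200.0, 1000.0)  # strong loss of the shorter allele
        return n, t

    def test_f0_exactly_unity(self):
        n, t = self._pair()
        assert dilution_ai_value(n, t, 0.0) == 1.0

    def test_f1_equals_pure_tumour_value(self):
        n, t = self._pair()
        assert dilution_ai_value(n, t, 1.0) == pytest.approx(compute_ai_value(n, t))

    def test_monotone_in_fraction(self):
        n, t = self._pair()
        grid = np.linspace(0, 1, 11)
        values = [dilution_ai_value(n, t, f) for f in grid]
        assert all(b >= a for a, b in zip(values, values[1:]))
        assert values[0] == 1.0 and values[-1] == pytest.approx(5.0)

    def test_fraction_out_of_range_rejected(self):
        n, t = self._pair()
        with pytest.raises(AICallError):
            dilution_ai_value(n, t, 1.5)


class TestLodScan:
    def _cases(self, effect_areas):
        thr = {"M": (0.8, 1.25)}
        n = {"M": het(NORMAL, 1000.0, 1000.0)}
        t = {"M": het(TUMOUR, effect_areas, 1000.0)}
        return {"T1": (n, t)}, thr

    def test_extreme_ai_stable_at_small_fraction(self):
        # pure AI value 20: near-complete loss; mixture AI ~ 1/(1 - 0.95 f)
        # crosses the 1.25 threshold just above f = 0.21
        cases, thr = self._cases(50.0)
        scan = lod_scan(cases, [0.1, 0.22, 0.3, 0.5, 1.0], thr, cutoff=0.2)
        assert scan["stable_from"].iloc[0] == 0.22

    def test_borderline_tumour_stable_only_near_pure(self):
        # pure AI value ~1.43: crosses the 1.25 threshold only at high purity
        cases, thr = self._cases(700.0)
        scan = lod_scan(cases, [0.2, 0.5, 0.8, 1.0], thr, cutoff=0.2)
        assert scan["stable_from"].iloc[0] == 0.8

    def test_gating_invariant_no_msi_case_has_profile(self, panel, small_cohort):
        recs = [PeakRecord(*r) for r in small_cohort.cohort_peaks.itertuples(index=False)]
        profiles, _ = run_two_step(recs, panel)
        for p in profiles:
            if p.msi is not None and p.msi.status == "MSI":
                assert p.cin_class == NOT_EVALUATED_MSI and not p.region_results
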