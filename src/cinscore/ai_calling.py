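"""Allelic-imbalance calling and two-step MSI -> CIN classification.

The AI value at an informative (heterozygous-normal) marker is the quotient
of the normal and tumour allele ratios::

    AI value = [area(N, shorter) / area(N, longer)]
             x [area(T, longer) / area(T, shorter)]

A balanced tumour gives 1.0; values strictly outside the marker's calibrated
(lower, upper) thresholds are called AI. Per tumour, the AI ratio is the
number of AI markers over the number of informative markers, and tumours
with AI ratio >= 0.2 are classified CIN-H (else CIN-L). Because unstable
microsatellites do not permit a clean allele-ratio comparison, tumours are
screened for MSI first (>= 2 unstable markers of the 5-marker Bethesda
panel) and MSI tumours are excluded from AI/CIN evaluation.

Tumour purity dilutes AI linearly in peak-area space; the dilution model and
limit-of-detection scan quantify the minimal tumour cell content at which
the CIN-H call is stable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import AIThresholds
from .panel_config import MarkerPanel
from .peak_io import (
    NORMAL,
    TUMOUR,
    GenotypeCall,
    PeakRecord,
    allele_ratio,
    genotype_table,
)

__all__ = [
    "AI",
    "NO_AI",
    "NOT_INFORMATIVE",
    "CIN_H",
    "CIN_L",
    "NOT_EVALUATED_MSI",
    "NOT_EVALUABLE",
    "DEFAULT_CIN_CUTOFF",
    "AICallError",
    "AIMarkerResult",
    "TumourAIProfile",
    "MSIResult",
    "CohortSummary",
    "compute_ai_value",
    "call_ai_marker",
    "evaluate_marker",
    "aggregate_region",
    "ai_ratio",
    "ai_frequency",
    "msi_screen",
    "classify_cin_pcr",
    "build_profile",
    "run_two_step",
    "dilution_ai_value",
    "lod_scan",
    "classify_ratio_table",
]

AI = "AI"
NO_AI = "no_AI"
NOT_INFORMATIVE = "not_informative"

CIN_H = "CIN_H"
CIN_L = "CIN_L"
NOT_EVALUATED_MSI = "not_evaluated_MSI"
NOT_EVALUABLE = "not_evaluable"

MSI = "MSI"
MSS = "MSS"

#: tumours with AI ratio >= cutoff are CIN-H (inclusive boundary)
DEFAULT_CIN_CUTOFF = 0.2

#: fragment sizes within this many bp are treated as the same allele
SIZE_TOL_BP = 0.5

#: minimal tumour cellularity below which results carry a warning
MIN_CELLULARITY = 0.25


class AICallError(ValueError):
    """Raised for invalid AI-calling inputs."""


@dataclass(frozen=True)
class AIMarkerResult:
    tumour_id: str
    marker: str
    informative: bool
    ai_value: float | None
    ai_call: str  # AI | no_AI | not_informative
    reason: str | None = None


@dataclass(frozen=True)
class MSIResult:
    tumour_id: str
    unstable_markers: tuple[str, ...]
    n_evaluated: int
    status: str  # MSI | MSS

    def __post_init__(self) -> None:
        expected = MSI if len(self.unstable_markers) >= 2 else MSS
        if self.status != expected:
            raise AICallError("MSI status inconsistent with the >=2-marker rule")


@dataclass(frozen=True)
class TumourAIProfile:
    tumour_id: str
    marker_results: tuple[AIMarkerResult, ...]
    region_results: Mapping[str, str]
    n_ai_markers: int
    n_informative_markers: int
    ai_ratio: float | None
    cin_class: str
    msi: MSIResult | None = None
    cellularity: float | None = None
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class CohortSummary:
    n_cases: int
    n_msi: int
    n_cin_h: int
    n_cin_l: int
    n_not_evaluable: int
    region_frequency_pct: Mapping[str, float]
    region_informative: Mapping[str, int]
    ai_ratios: tuple[float, ...]


def _match_sizes(a: Sequence[float], b: Sequence[float], tol: float = SIZE_TOL_BP) -> bool:
    return len(a) == len(b) and all(abs(x - y) <= tol for x, y in zip(a, b))


def compute_ai_value(normal: GenotypeCall, tumour: GenotypeCall) -> float:
    """Quotient of normal and tumour allele ratios (1.0 = balanced).

    Requires heterozygous calls for the same marker with matching allele
    sizes; satisfies compute_ai_value(N, T) * compute_ai_value(T, N) == 1.
    """
    if normal.marker != tumour.marker:
        raise AICallError(f"marker mismatch: {normal.marker} vs {tumour.marker}")
    if not normal.is_heterozygous:
        raise AICallError(f"normal call for {normal.marker} is {normal.zygosity}, need heterozygous")
    if not tumour.is_heterozygous:
        raise AICallError(f"tumour call for {tumour.marker} is {tumour.zygosity}, need heterozygous")
    if not _match_sizes(normal.sizes, tumour.sizes):
        raise AICallError(
            f"{normal.marker}: allele sizes differ between normal {normal.sizes} "
            f"and tumour {tumour.sizes}"
        )
    return allele_ratio(normal) / allele_ratio(tumour)


def call_ai_marker(ai_value: float, thresholds: AIThresholds | tuple[float, float]) -> str:
    """AI iff the value lies strictly outside (lower, upper)."""
    lower, upper = thresholds.as_tuple() if isinstance(thresholds, AIThresholds) else thresholds
    if not lower <= 1.0 <= upper:
        raise AICallError(f"invalid thresholds ({lower}, {upper})")
    return AI if (ai_value < lower or ai_value > upper) else NO_AI


def evaluate_marker(
    tumour_id: str,
    normal: GenotypeCall | None,
    tumour: GenotypeCall | None,
    thresholds: AIThresholds | tuple[float, float],
) -> AIMarkerResult:
    """Full per-marker evaluation with informativeness bookkeeping.

    Informative means: heterozygous normal and an evaluable matched tumour
    genotype with the same two alleles. Anything else is not informative and
    enters neither the numerator nor the denominator of the AI ratio.
    """
    marker = (normal or tumour).marker  # type: ignore[union-attr]
    if normal is None or tumour is None:
        return AIMarkerResult(tumour_id, marker, False, None, NOT_INFORMATIVE, "missing tissue")
    if not normal.is_heterozygous:
        return AIMarkerResult(
            tumour_id, marker, False, None, NOT_INFORMATIVE, f"normal {normal.zygosity}"
        )
    if not tumour.is_heterozygous or not _match_sizes(normal.sizes, tumour.sizes):
        return AIMarkerResult(
            tumour_id, marker, False, None, NOT_INFORMATIVE, "tumour genotype not evaluable"
        )
    value = compute_ai_value(normal, tumour)
    return AIMarkerResult(tumour_id, marker, True, value, call_ai_marker(value, thresholds))


def aggregate_region(marker_results: Sequence[AIMarkerResult]) -> str:
    """Region call: AI if any member marker shows AI, no_AI if at least one
    informative member and none shows AI, not informative otherwise."""
    calls = [r.ai_call for r in marker_results]
    if AI in calls:
        return AI
    if NO_AI in calls:
        return NO_AI
    return NOT_INFORMATIVE


def ai_ratio(marker_results: Sequence[AIMarkerResult]) -> float | None:
    """Markers with AI over informative markers; None if none informative."""
    informative = [r for r in marker_results if r.informative]
    if not informative:
        return None
    return sum(r.ai_call == AI for r in informative) / len(informative)


def classify_cin_pcr(ratio: float, cutoff: float = DEFAULT_CIN_CUTOFF) -> str:
    """CIN-H iff the AI ratio is >= cutoff (boundary inclusive)."""
    if not 0.0 <= ratio <= 1.0:
        raise AICallError(f"AI ratio {ratio} outside [0, 1]")
    return CIN_H if ratio >= cutoff else CIN_L


def msi_screen(
    tumour_id: str,
    normal_sizes: Mapping[str, Sequence[float]],
    tumour_sizes: Mapping[str, Sequence[float]],
    panel: MarkerPanel,
    size_tol: float = SIZE_TOL_BP,
) -> MSIResult:
    """Score MSI from allele sizes at the 5-marker Bethesda panel.

    A marker is unstable when the tumour shows at least one allele length
    absent from the matched normal (band shift). MSI requires >= 2 unstable
    markers of the panel.
    """
    unstable: list[str] = []
    n_eval = 0
    for m in panel.msi_markers:
        n_sizes = normal_sizes.get(m.name)
        t_sizes = tumour_sizes.get(m.name)
        if not n_sizes or not t_sizes:
            continue
        n_eval += 1
        novel = any(all(abs(t - n) > size_tol for n in n_sizes) for t in t_sizes)
        if novel:
            unstable.append(m.name)
    if n_eval == 0:
        raise AICallError(f"{tumour_id}: no MSI panel markers typed in both tissues")
    status = MSI if len(unstable) >= 2 else MSS
    return MSIResult(tumour_id, tuple(unstable), n_eval, status)


def build_profile(
    tumour_id: str,
    marker_results: Sequence[AIMarkerResult],
    panel: MarkerPanel,
    cutoff: float = DEFAULT_CIN_CUTOFF,
    msi: MSIResult | None = None,
    cellularity: float | None = None,
) -> TumourAIProfile:
    """Assemble the per-tumour profile (region calls, AI ratio, CIN class)."""
    warnings_: list[str] = []
    if msi is not None and msi.status == MSI:
        return TumourAIProfile(
            tumour_id, tuple(marker_results), {}, 0, 0, None, NOT_EVALUATED_MSI, msi, cellularity
        )
    by_marker = {r.marker: r for r in marker_results}
    region_results = {
        region: aggregate_region([by_marker[m.name] for m in members if m.name in by_marker])
        for region, members in panel.regions.items()
    }
    ratio = ai_ratio(marker_results)
    if ratio is None:
        cin = NOT_EVALUABLE
        n_ai = n_inf = 0
    else:
        informative = [r for r in marker_results if r.informative]
        n_inf = len(informative)
        n_ai = sum(r.ai_call == AI for r in informative)
        cin = classify_cin_pcr(ratio, cutoff)
    if cellularity is not None and cellularity < MIN_CELLULARITY:
        warnings_.append(
            f"tumour cellularity {cellularity:.2f} below the {MIN_CELLULARITY:.2f} "
            "reliability floor; classification may be unstable"
        )
    return TumourAIProfile(
        tumour_id,
        tuple(marker_results),
        region_results,
        n_ai,
        n_inf,
        ratio,
        cin,
        msi,
        cellularity,
        tuple(warnings_),
    )


def ai_frequency(profiles: Sequence[TumourAIProfile], region: str) -> float:
    """Percent of informative tumours with AI at *region*."""
    calls = [p.region_results.get(region) for p in profiles if p.cin_class not in (NOT_EVALUATED_MSI,)]
    informative = [c for c in calls if c in (AI, NO_AI)]
    if not informative:
        raise AICallError(f"no informative tumours at region {region}")
    return 100.0 * sum(c == AI for c in informative) / len(informative)


def _sizes_by_marker(calls: Mapping[tuple[str, str, str], GenotypeCall], sample_id: str, tissue: str) -> dict[str, tuple[float, ...]]:
    return {
        marker: call.sizes
        for (sid, tis, marker), call in calls.items()
        if sid == sample_id and tis == tissue
    }


def run_two_step(
    records: Iterable[PeakRecord],
    panel: MarkerPanel,
    thresholds: Mapping[str, AIThresholds] | Mapping[str, tuple[float, float]] | None = None,
    cutoff: float = DEFAULT_CIN_CUTOFF,
    cellularity: Mapping[str, float] | None = None,
) -> tuple[list[TumourAIProfile], CohortSummary]:
    """Two-step protocol over a cohort of matched normal/tumour peak records.

    Step 1 screens every case for MSI; MSI cases are reported but receive no
    AI evaluation. Step 2 computes per-marker AI, region calls, the AI ratio
    and the CIN class for the microsatellite-stable cases. Cases missing one
    tissue are reported as not evaluable; the pipeline continues.

    *thresholds* defaults to the panel's packaged per-marker values.
    """
    if thresholds is None:
        thresholds = panel.thresholds()
    calls = genotype_table(records)
    case_ids = sorted({sid for sid, _, _ in calls})
    profiles: list[TumourAIProfile] = []
    for cid in case_ids:
        cell = None if cellularity is None else cellularity.get(cid)
        n_sizes = _sizes_by_marker(calls, cid, NORMAL)
        t_sizes = _sizes_by_marker(calls, cid, TUMOUR)
        if not n_sizes or not t_sizes:
            profiles.append(
                TumourAIProfile(cid, (), {}, 0, 0, None, NOT_EVALUABLE, None, cell, ("unmatched case",))
            )
            continue
        try:
            msi = msi_screen(cid, n_sizes, t_sizes, panel)
        except AICallError:
            msi = None
        if msi is not None and msi.status == MSI:
            profiles.append(build_profile(cid, (), panel, cutoff, msi, cell))
            continue
        marker_results = [
            evaluate_marker(
                cid,
                calls.get((cid, NORMAL, m.name)),
                calls.get((cid, TUMOUR, m.name)),
                thresholds[m.name],
            )
            for m in panel.ai_markers
            if m.name in thresholds
        ]
        profiles.append(build_profile(cid, marker_results, panel, cutoff, msi, cell))
    return profiles, summarize_cohort(profiles, panel)


def summarize_cohort(profiles: Sequence[TumourAIProfile], panel: MarkerPanel) -> CohortSummary:
    freqs: dict[str, float] = {}
    n_inf: dict[str, int] = {}
    for region in panel.regions:
        calls = [
            p.region_results.get(region)
            for p in profiles
            if p.cin_class in (CIN_H, CIN_L)
        ]
        informative = [c for c in calls if c in (AI, NO_AI)]
        n_inf[region] = len(informative)
        if informative:
            freqs[region] = 100.0 * sum(c == AI for c in informative) / len(informative)
    return CohortSummary(
        n_cases=len(profiles),
        n_msi=sum(p.cin_class == NOT_EVALUATED_MSI for p in profiles),
        n_cin_h=sum(p.cin_class == CIN_H for p in profiles),
        n_cin_l=sum(p.cin_class == CIN_L for p in profiles),
        n_not_evaluable=sum(p.cin_class == NOT_EVALUABLE for p in profiles),
        region_frequency_pct=freqs,
        region_informative=n_inf,
        ai_ratios=tuple(p.ai_ratio for p in profiles if p.ai_ratio is not None),
    )


def classify_ratio_table(ratios: Sequence[float], cutoff: float = DEFAULT_CIN_CUTOFF) -> dict:
    """Apply the CIN cut-off to a table of per-tumour AI ratios.

    Returns counts and percentages of CIN-H/CIN-L plus distribution
    summaries (validation helper for externally supplied per-tumour ratios).
    """
    arr = np.asarray(list(ratios), dtype=float)
    if arr.size == 0:
        raise AICallError("empty ratio table")
    n_h = int(np.sum(arr >= cutoff))
    n_l = int(arr.size - n_h)
    return {
        "n": int(arr.size),
        "n_cin_h": n_h,
        "n_cin_l": n_l,
        "pct_cin_h": 100.0 * n_h / arr.size,
        "pct_cin_l": 100.0 * n_l / arr.size,
        "max": float(arr.max()),
        "min": float(arr.min()),
    }


def dilution_ai_value(normal: GenotypeCall, tumour: GenotypeCall, tumour_fraction: float) -> float:
    """AI value after mixing tumour DNA into its matched normal.

    Each allele's mixture peak area is f * area_T + (1 - f) * area_N (equal
    per-allele amplification efficiency), and the AI value of (normal,
    mixture) is returned. f=0 gives exactly 1.0; f=1 gives the pure-tumour
    value; in between the value moves monotonically.
    """
    f = float(tumour_fraction)
    if not 0.0 <= f <= 1.0:
        raise AICallError(f"tumour fraction {f} outside [0, 1]")
    if not normal.is_heterozygous or not tumour.is_heterozygous:
        raise AICallError("dilution requires heterozygous normal and tumour calls")
    if not _match_sizes(normal.sizes, tumour.sizes):
        raise AICallError("allele sizes differ between normal and tumour")
    (ns_size, ns_area), (nl_size, nl_area) = normal.alleles
    (_, ts_area), (_, tl_area) = tumour.alleles
    mix_short = f * ts_area + (1.0 - f) * ns_area
    mix_long = f * tl_area + (1.0 - f) * nl_area
    mixture = GenotypeCall(
        tumour.sample_id,
        TUMOUR,
        tumour.marker,
        ((ns_size, mix_short), (nl_size, mix_long)),
        "heterozygous",
    )
    return compute_ai_value(normal, mixture)


def lod_scan(
    cases: Mapping[str, tuple[Mapping[str, GenotypeCall], Mapping[str, GenotypeCall]]],
    fractions: Sequence[float],
    thresholds: Mapping[str, AIThresholds] | Mapping[str, tuple[float, float]],
    cutoff: float = DEFAULT_CIN_CUTOFF,
) -> pd.DataFrame:
    """Limit-of-detection scan over a tumour-fraction grid.

    *cases* maps tumour_id -> (normal calls by marker, pure-tumour calls by
    marker). For each tumour and each grid fraction f the diluted AI profile
    is evaluated; the reported ``stable_from`` is the smallest grid f at
    which the classification is CIN-H for every f' >= f (NaN if never).
    """
    fr = sorted(float(f) for f in fractions)
    rows = []
    for tid, (n_calls, t_calls) in sorted(cases.items()):
        shared = [
            m
            for m in n_calls
            if m in t_calls
            and m in thresholds
            and n_calls[m].is_heterozygous
            and t_calls[m].is_heterozygous
            and _match_sizes(n_calls[m].sizes, t_calls[m].sizes)
        ]
        classes = []
        for f in fr:
            results = [
                AIMarkerResult(
                    tid,
                    m,
                    True,
                    (v := dilution_ai_value(n_calls[m], t_calls[m], f)),
                    call_ai_marker(v, thresholds[m]),
                )
                for m in shared
            ]
            ratio = ai_ratio(results)
            classes.append(None if ratio is None else classify_cin_pcr(ratio, cutoff))
        stable_from = math.nan
        for i in range(len(fr) - 1, -1, -1):
            if classes[i] == CIN_H:
                stable_from = fr[i]
            else:
                break
        for f, cls in zip(fr, classes):
            rows.append({"tumour_id": tid, "tumour_fraction": f, "cin_class": cls, "stable_from": stable_from})
    return pd.DataFrame(rows)
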