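"""Arm-level CIN classification from genome-wide segment calls.

Consumes SEG-like tables of segmentation calls (gain / loss / AI / neutral)
from array platforms. A chromosome arm counts as altered when at least 80%
of its length is covered by the union of non-neutral calls; a tumour is
CIN-H when at least one evaluable arm is altered (the evaluable set excludes
the acrocentric short arms and 18p/18q/21q), and the per-tumour alteration
ratio is altered evaluable arms over the evaluable-arm count (36 by
default). Segmentation itself (log2R/BAF processing) is upstream and out of
scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ai_calling import AI, CIN_H, CIN_L, NO_AI, TumourAIProfile
from .panel_config import ArmModel, MarkerPanel, normalize_chrom

__all__ = [
    "Segment",
    "ArmAlterationProfile",
    "SegmentError",
    "CALL_LABELS",
    "ARM_ALTERED_FRACTION",
    "read_segments",
    "write_segments",
    "segments_from_frame",
    "arm_alteration_fraction",
    "arm_altered",
    "profile_sample",
    "classify_cin_arms",
    "alteration_ratio",
    "marker_positions",
    "compare_methods",
    "cutoff_scan",
]

CALL_LABELS = ("gain", "loss", "AI", "neutral")

#: an arm is altered when >= this fraction of it is covered by non-neutral calls
ARM_ALTERED_FRACTION = 0.8


class SegmentError(ValueError):
    """Raised for malformed segment input."""


@dataclass(frozen=True)
class Segment:
    """One segmentation call, internal 0-based half-open coordinates."""

    sample_id: str
    chrom: str
    start: int
    end: int
    call: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise SegmentError(f"segment start {self.start} >= end {self.end}")
        if self.call not in CALL_LABELS:
            raise SegmentError(f"unknown call {self.call!r}; allowed: {CALL_LABELS}")
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))


def segments_from_frame(df: pd.DataFrame, one_based: bool = True) -> list[Segment]:
    required = {"sample_id", "chrom", "start", "end", "call"}
    missing = required - set(df.columns)
    if missing:
        raise SegmentError(f"segment table missing column(s): {sorted(missing)}")
    segs: list[Segment] = []
    offset = 1 if one_based else 0
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        try:
            start = int(row.start) - offset
            end = int(row.end)
        except (TypeError, ValueError) as exc:
            raise SegmentError(f"row {idx}: non-numeric coordinates") from exc
        if start >= end:
            raise SegmentError(f"row {idx}: start >= end after conversion ({row.start}, {row.end})")
        call = str(row.call)
        if call not in CALL_LABELS:
            raise SegmentError(f"row {idx}: unknown call {call!r}; allowed: {CALL_LABELS}")
        segs.append(Segment(str(row.sample_id), str(row.chrom), start, end, call))
    segs.sort(key=lambda s: (s.sample_id, s.chrom, s.start, s.end))
    return segs


def read_segments(source, sep: str | None = None) -> list[Segment]:
    """Read a SEG-like table (1-based inclusive coordinates on disk)."""
    from .peak_io import _sniff_sep

    try:
        df = pd.read_csv(source, sep=sep or _sniff_sep(source), comment="#")
    except SegmentError:
        raise
    except Exception as exc:
        raise SegmentError(f"cannot parse segment table: {exc}") from exc
    return segments_from_frame(df, one_based=True)


def write_segments(segments: Iterable[Segment], path, sep: str = "\t") -> None:
    """Write segments back to 1-based inclusive SEG convention."""
    df = pd.DataFrame(
        [(s.sample_id, s.chrom, s.start + 1, s.end, s.call) for s in segments],
        columns=["sample_id", "chrom", "start", "end", "call"],
    )
    df.to_csv(path, sep=sep, index=False)


def _union_length(intervals: list[tuple[int, int]]) -> int:
    """Total length of the union of half-open intervals (sweep merge)."""
    if not intervals:
        return 0
    intervals.sort()
    total = 0
    cur_s, cur_e = intervals[0]
    for s, e in intervals[1:]:
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    return total + (cur_e - cur_s)


def arm_alteration_fraction(
    segments: Iterable[Segment],
    arm_interval: tuple[str, int, int],
    calls: Sequence[str] = ("gain", "loss", "AI"),
) -> float:
    """Fraction of the arm covered by the union of the given call types.

    Segments crossing the arm boundary are clipped to it, duplicated
    segments do not inflate the coverage (union semantics), and an empty
    segment set gives 0.
    """
    chrom, a_start, a_end = arm_interval
    chrom = normalize_chrom(chrom)
    clipped = [
        (max(s.start, a_start), min(s.end, a_end))
        for s in segments
        if s.call in calls and s.chrom == chrom and s.start < a_end and s.end > a_start
    ]
    return _union_length(clipped) / (a_end - a_start)


def arm_altered(fraction: float, threshold: float = ARM_ALTERED_FRACTION) -> bool:
    """Altered iff at least *threshold* (default 80%) of the arm is covered."""
    if not 0.0 <= fraction <= 1.0:
        raise SegmentError(f"fraction {fraction} outside [0, 1]")
    return fraction >= threshold


@dataclass(frozen=True)
class ArmAlterationProfile:
    sample_id: str
    arm_fractions: Mapping[str, float]
    arm_call_fractions: Mapping[str, Mapping[str, float]]
    altered_arms: frozenset[str]
    n_altered_evaluable: int
    alteration_ratio: float
    cin_class: str


def profile_sample(
    segments: Iterable[Segment],
    arm_model: ArmModel,
    sample_id: str | None = None,
    threshold: float = ARM_ALTERED_FRACTION,
) -> ArmAlterationProfile:
    """Per-arm altered fractions, flags, alteration ratio, and CIN class."""
    segs = list(segments)
    if sample_id is None:
        ids = {s.sample_id for s in segs}
        if len(ids) > 1:
            raise SegmentError(f"segments span multiple samples: {sorted(ids)}; pass sample_id")
        sample_id = next(iter(ids)) if ids else "?"
    else:
        segs = [s for s in segs if s.sample_id == sample_id]
    fractions: dict[str, float] = {}
    per_call: dict[str, dict[str, float]] = {}
    for label in arm_model.arms:
        ival = arm_model.interval(label)
        fractions[label] = arm_alteration_fraction(segs, ival)
        per_call[label] = {
            c: arm_alteration_fraction(segs, ival, calls=(c,)) for c in ("gain", "loss", "AI")
        }
    altered = frozenset(a for a, f in fractions.items() if arm_altered(f, threshold))
    n_alt_eval = len(altered & arm_model.evaluable)
    ratio = n_alt_eval / arm_model.n_evaluable
    cin = CIN_H if n_alt_eval >= 1 else CIN_L
    return ArmAlterationProfile(sample_id, fractions, per_call, altered, n_alt_eval, ratio, cin)


def classify_cin_arms(profile: ArmAlterationProfile) -> str:
    """CIN-H iff at least one evaluable (non-excluded) arm is altered."""
    return profile.cin_class


def alteration_ratio(profile: ArmAlterationProfile) -> float:
    """Altered evaluable arms over the evaluable-arm denominator."""
    return profile.alteration_ratio


def marker_positions(
    panel: MarkerPanel, arm_model: ArmModel, positions: Mapping[str, tuple[str, int]] | None = None
) -> dict[str, tuple[str, int]]:
    """Genomic position per AI marker: user-supplied, else its arm midpoint.

    Microsatellite loci are single points for segment-overlap purposes;
    without an explicit mapping the midpoint of the marker's arm is used (a
    deliberate coarse default — at arm-level resolution the arm is the unit
    of comparison).
    """
    out: dict[str, tuple[str, int]] = {}
    for m in panel.ai_markers:
        if positions is not None and m.name in positions:
            chrom, pos = positions[m.name]
            out[m.name] = (normalize_chrom(chrom), int(pos))
        elif m.arm in arm_model.arms:
            out[m.name] = arm_model.midpoint(m.arm)
    return out


def compare_methods(
    pcr_profiles: Sequence[TumourAIProfile],
    arm_profiles: Sequence[ArmAlterationProfile],
    segments: Iterable[Segment],
    panel: MarkerPanel,
    arm_model: ArmModel,
    positions: Mapping[str, tuple[str, int]] | None = None,
) -> dict:
    """Compare marker-level PCR AI calls with the segment-based genome view.

    Returns locus concordance (percent of informative marker loci whose AI
    call matches the presence of a non-neutral segment over the marker
    position), the Pearson correlation of the per-tumour AI ratio with the
    arm-level alteration ratio, and the percent of shared samples receiving
    the same CIN class. Correlation needs >= 3 shared samples, else NaN.
    """
    arm_by_id = {p.sample_id: p for p in arm_profiles}
    shared = [p for p in pcr_profiles if p.tumour_id in arm_by_id and p.ai_ratio is not None]
    if not shared:
        raise SegmentError("PCR and segment-based sample sets are disjoint")
    pos = marker_positions(panel, arm_model, positions)
    segs_by_id: dict[str, list[Segment]] = {}
    for s in segments:
        segs_by_id.setdefault(s.sample_id, []).append(s)

    n_loci = n_match = 0
    for p in shared:
        segs = segs_by_id.get(p.tumour_id, [])
        for r in p.marker_results:
            if not r.informative or r.marker not in pos:
                continue
            chrom, point = pos[r.marker]
            covered = any(
                s.chrom == chrom and s.start <= point < s.end and s.call != "neutral"
                for s in segs
            )
            n_loci += 1
            n_match += (r.ai_call == AI) == covered
    locus_concordance = 100.0 * n_match / n_loci if n_loci else float("nan")

    pcr_ratios = np.array([p.ai_ratio for p in shared])
    arm_ratios = np.array([arm_by_id[p.tumour_id].alteration_ratio for p in shared])
    if len(shared) >= 3 and np.std(pcr_ratios) > 0 and np.std(arm_ratios) > 0:
        r = float(np.corrcoef(pcr_ratios, arm_ratios)[0, 1])
    else:
        r = float("nan")
    same = [p.cin_class == arm_by_id[p.tumour_id].cin_class for p in shared]
    return {
        "n_shared": len(shared),
        "n_loci": n_loci,
        "locus_concordance_pct": locus_concordance,
        "ratio_correlation": r,
        "classification_concordance_pct": 100.0 * sum(same) / len(same),
    }


def cutoff_scan(
    pcr_ratios: Sequence[float], arm_classes: Sequence[str]
) -> pd.DataFrame:
    """Scan AI-ratio cut-offs against a reference arm-based classification.

    Candidate cut-offs are the sorted distinct ratios plus the midpoints
    between neighbours. For each cut-off c, tumours with ratio >= c are
    called CIN-H; the table reports overall concordance with the reference
    plus the two error types (false_H: called CIN-H but reference CIN-L;
    false_L: the converse).
    """
    ratios = np.asarray(list(pcr_ratios), dtype=float)
    ref = np.asarray(list(arm_classes))
    if ratios.size != ref.size or ratios.size == 0:
        raise SegmentError("paired non-empty ratios and reference classes required")
    distinct = np.unique(ratios)
    candidates = sorted(set(distinct) | {(a + b) / 2.0 for a, b in zip(distinct, distinct[1:])})
    rows = []
    for c in candidates:
        called_h = ratios >= c
        ref_h = ref == CIN_H
        false_h = int(np.sum(called_h & ~ref_h))
        false_l = int(np.sum(~called_h & ref_h))
        rows.append(
            {
                "cutoff": float(c),
                "concordance_pct": 100.0 * float(np.mean(called_h == ref_h)),
                "false_H": false_h,
                "false_L": false_l,
            }
        )
    return pd.DataFrame(rows)
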