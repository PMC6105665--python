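"""Synthetic cohort generator with recorded ground truth.

Emulates the measurement process of the microsatellite AI assay end to end,
so every pipeline stage is testable without access to patient data:

* heterozygous two-allele peak-area pairs with multiplicative lognormal
  amplification noise (per-marker log-SD ``sigma_m``) — allele-ratio
  thresholds are asymmetric around 1 on a ratio scale, which a lognormal
  noise model reproduces naturally;
* marker heterozygosity drawn per sample from the panel's published rates;
* tumour AI effects planted arm-wise (a tumour's altered arms make all of
  its markers on those arms AI-true) with pure-tumour effect magnitude
  ``|log AI|`` drawn uniformly on [log 2, log 6], random direction, and
  attenuation by tumour purity via linear peak-area mixing;
* matched arm-level segment truth (altered arms covered by >= 80%
  non-neutral segments) for the array-based comparison path;
* MSI cases carrying novel tumour alleles at >= 2 Bethesda markers;
* dilution series and repeated-area series for the limit-of-detection and
  heterogeneity analyses.

All randomness flows from a single seed recorded in the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ai_calling import CIN_H, CIN_L
from .panel_config import ArmModel, MarkerPanel, load_default_arm_model, load_default_panel
from .peak_io import NORMAL, TUMOUR, GenotypeCall, PeakRecord

__all__ = ["GeneratorConfig", "SyntheticCohort", "generate_cohort", "generate_segments",
           "generate_dilution_series", "generate_area_series"]

#: fallback heterozygosity for markers without a published rate
DEFAULT_HETEROZYGOSITY = 0.75

#: quasi-monomorphic mononucleotide markers: single constant allele size
MONOMORPHIC_SIZES = {"BAT25": 120.0, "BAT26": 113.0}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the emulated cohort.

    Defaults mirror the assay's establishment conditions: 58 non-tumorous
    calibration tissues, 100 tumour cases of which 10% are MSI, 78% of the
    MSS cases CIN-H, tumour purity uniform on [0.4, 0.9], and amplification
    noise sigma_m = 0.06 (thresholds calibrated under this noise fall within
    the assay's published 0.64-1.56 band).
    """

    seed: int
    n_normals: int = 58
    n_tumours: int = 100
    sigma_m: float = 0.06
    per_marker_sigma: Mapping[str, float] | None = None
    msi_fraction: float = 0.10
    cin_h_fraction: float = 0.78
    purity_range: tuple[float, float] = (0.4, 0.9)
    #: pure-tumour AI effect magnitude: |log AI| ~ U(log(lo), log(hi))
    effect_range: tuple[float, float] = (2.0, 6.0)
    #: altered marker-bearing evaluable arms per CIN-H tumour (inclusive)
    n_altered_arms_cin_h: tuple[int, int] = (4, 10)
    #: probability that a tumour additionally alters 18q (excluded arm)
    p_18q_altered: float = 0.3
    #: extra altered evaluable arms without panel markers per CIN-H tumour
    n_extra_arms: tuple[int, int] = (0, 3)
    base_area: float = 10_000.0
    #: log-SD of total amplification yield (cancels in ratios)
    sigma_yield: float = 0.3

    def __post_init__(self) -> None:
        if not self.sigma_m > 0:
            raise ValueError("sigma_m must be > 0")
        lo, hi = self.purity_range
        if not 0.0 < lo <= hi <= 1.0:
            raise ValueError(f"purity range {self.purity_range} outside (0, 1]")
        if not 1.0 <= self.effect_range[0] <= self.effect_range[1]:
            raise ValueError("effect range must satisfy 1 <= lo <= hi")

    def sigma(self, marker: str) -> float:
        if self.per_marker_sigma is not None and marker in self.per_marker_sigma:
            return float(self.per_marker_sigma[marker])
        return self.sigma_m


@dataclass
class SyntheticCohort:
    """Generated peak tables plus the ground truth behind them."""

    config: GeneratorConfig
    calibration_normals: pd.DataFrame
    cohort_peaks: pd.DataFrame
    tumour_truth: pd.DataFrame
    marker_truth: pd.DataFrame

    @property
    def truth_by_id(self) -> dict[str, dict]:
        return {r["tumour_id"]: dict(r) for _, r in self.tumour_truth.iterrows()}


def _allele_sizes(rng: np.random.Generator, size_range: tuple[int, int]) -> tuple[float, float]:
    """Two distinct allele sizes on the dinucleotide grid of the marker."""
    lo, hi = size_range
    grid = np.arange(lo, hi + 1, 2, dtype=float)
    a, b = rng.choice(grid, size=2, replace=False)
    return (min(a, b), max(a, b))


def _het_rate(marker, panel_default: float = DEFAULT_HETEROZYGOSITY) -> float:
    return marker.heterozygosity if marker.heterozygosity is not None else panel_default


def _novel_size(sizes: tuple[float, ...], size_range: tuple[int, int], step: float = 2.0) -> float:
    """An in-range grid size absent from *sizes* (MSI band shift)."""
    lo, hi = size_range
    for s in np.arange(lo, hi + 1, step, dtype=float):
        if all(abs(s - x) > 0.5 for x in sizes):
            return float(s)
    return float(min(sizes) - step)  # degenerate range: fall back below it


def _emit_sample(
    rows: list,
    rng: np.random.Generator,
    cfg: GeneratorConfig,
    sample_id: str,
    tissue: str,
    marker,
    sizes: tuple[float, ...] | None,
    ratio_shift: float = 1.0,
) -> None:
    """Append peak rows for one sample x marker.

    ``sizes`` of length 2 emits a heterozygous pair whose shorter/longer
    area ratio is ``ratio_shift x exp(N(0, sigma_m^2))``; length 1 a single
    homozygous peak; longer tuples one peak per size (MSI band shifts).
    """
    if sizes is None:
        return
    yield_factor = float(np.exp(rng.normal(0.0, cfg.sigma_yield)))
    base = cfg.base_area * yield_factor
    if len(sizes) == 2:
        ratio = ratio_shift * float(np.exp(rng.normal(0.0, cfg.sigma(marker.name))))
        rows.append((sample_id, tissue, marker.name, sizes[0], base * ratio))
        rows.append((sample_id, tissue, marker.name, sizes[1], base))
    else:
        for s in sizes:
            noise = float(np.exp(rng.normal(0.0, cfg.sigma(marker.name))))
            rows.append((sample_id, tissue, marker.name, s, base * noise))


def _attenuation(effect: float, direction: int, purity: float) -> float:
    """Observed tumour allele-ratio multiplier after purity mixing.

    The pure tumour reduces one allele's contribution by kappa = 1/effect;
    in a mixture with normal DNA at tumour fraction f the affected allele
    keeps a fraction 1 - f (1 - kappa) of its area. direction +1 reduces the
    shorter allele (ratio multiplier m < 1, AI value 1/m > 1), -1 the longer.
    """
    kappa = 1.0 / effect
    m = 1.0 - purity * (1.0 - kappa)
    return m if direction > 0 else 1.0 / m


def generate_cohort(
    config: GeneratorConfig,
    panel: MarkerPanel | None = None,
    arm_model: ArmModel | None = None,
) -> SyntheticCohort:
    """Generate calibration normals, matched tumour/normal pairs, and truth."""
    panel = panel or load_default_panel()
    arm_model = arm_model or load_default_arm_model()
    rng = np.random.default_rng(config.seed)
    ai_markers = panel.ai_markers
    msi_markers = panel.msi_markers
    marker_arms = sorted({m.arm for m in ai_markers})
    evaluable_marker_arms = [a for a in marker_arms if a in arm_model.evaluable]
    non_marker_evaluable = sorted(set(arm_model.evaluable) - set(marker_arms))

    # --- calibration normals (independent non-tumorous tissues) ---
    cal_rows: list = []
    for i in range(config.n_normals):
        sid = f"N{i + 1:03d}"
        for m in ai_markers:
            if rng.random() < _het_rate(m):
                _emit_sample(cal_rows, rng, config, sid, NORMAL, m, _allele_sizes(rng, m.size_range_bp))
            else:
                lo, hi = m.size_range_bp
                size = float(rng.choice(np.arange(lo, hi + 1, 2)))
                _emit_sample(cal_rows, rng, config, sid, NORMAL, m, (size,))

    # --- tumour cohort (matched pairs) ---
    peak_rows: list = []
    truth_rows: list = []
    marker_truth_rows: list = []
    for i in range(config.n_tumours):
        cid = f"GC{i + 1:03d}"
        is_msi = rng.random() < config.msi_fraction
        purity = float(rng.uniform(*config.purity_range))
        if is_msi:
            cin_truth = None
            altered: set[str] = set()
        else:
            cin_truth = CIN_H if rng.random() < config.cin_h_fraction else CIN_L
            altered = set()
            if cin_truth == CIN_H:
                k = int(rng.integers(config.n_altered_arms_cin_h[0], config.n_altered_arms_cin_h[1] + 1))
                k = min(k, len(evaluable_marker_arms))
                altered.update(rng.choice(evaluable_marker_arms, size=k, replace=False))
                k_extra = int(rng.integers(config.n_extra_arms[0], config.n_extra_arms[1] + 1))
                if k_extra and non_marker_evaluable:
                    altered.update(
                        rng.choice(non_marker_evaluable, size=min(k_extra, len(non_marker_evaluable)), replace=False)
                    )
            if rng.random() < config.p_18q_altered:
                altered.add("18q")

        # MSI band shifts: novel tumour alleles at >= 2 Bethesda markers
        unstable: set[str] = set()
        if is_msi:
            k = int(rng.integers(2, len(msi_markers) + 1))
            unstable = set(rng.choice([m.name for m in msi_markers], size=k, replace=False))

        for m in ai_markers:
            het = rng.random() < _het_rate(m)
            ai_true = (not is_msi) and het and (m.arm in altered)
            effect = float(np.exp(rng.uniform(*np.log(config.effect_range)))) if ai_true else 1.0
            direction = int(rng.choice([1, -1])) if ai_true else 0
            if het:
                sizes = _allele_sizes(rng, m.size_range_bp)
                _emit_sample(peak_rows, rng, config, cid, NORMAL, m, sizes)
                if m.name in unstable:
                    # band shift: tumour gains a novel in-range allele
                    t_sizes = tuple(sorted((_novel_size(sizes, m.size_range_bp), *sizes)))
                    _emit_sample(peak_rows, rng, config, cid, TUMOUR, m, t_sizes)
                else:
                    shift = _attenuation(effect, direction, purity) if ai_true else 1.0
                    _emit_sample(peak_rows, rng, config, cid, TUMOUR, m, sizes, ratio_shift=shift)
            else:
                lo, hi = m.size_range_bp
                size = float(rng.choice(np.arange(lo, hi + 1, 2)))
                _emit_sample(peak_rows, rng, config, cid, NORMAL, m, (size,))
                if m.name in unstable:
                    novel = _novel_size((size,), m.size_range_bp)
                    _emit_sample(peak_rows, rng, config, cid, TUMOUR, m, tuple(sorted((novel, size))))
                else:
                    _emit_sample(peak_rows, rng, config, cid, TUMOUR, m, (size,))
            marker_truth_rows.append(
                {
                    "tumour_id": cid,
                    "marker": m.name,
                    "heterozygous": het,
                    "ai_true": ai_true,
                    "effect": effect,
                    "direction": direction,
                }
            )

        # mononucleotide MSI markers (not AI-scored)
        for name, size in MONOMORPHIC_SIZES.items():
            if name not in panel:
                continue
            m = panel.marker(name)
            _emit_sample(peak_rows, rng, config, cid, NORMAL, m, (size,))
            if name in unstable:
                novel = _novel_size((size,), m.size_range_bp, step=3.0)
                _emit_sample(peak_rows, rng, config, cid, TUMOUR, m, tuple(sorted((novel, size))))
            else:
                _emit_sample(peak_rows, rng, config, cid, TUMOUR, m, (size,))

        truth_rows.append(
            {
                "tumour_id": cid,
                "msi": is_msi,
                "cin_class": cin_truth,
                "purity": purity,
                "altered_arms": ",".join(sorted(altered)),
                "unstable_msi_markers": ",".join(sorted(unstable)),
                "seed": config.seed,
            }
        )

    columns = ["sample_id", "tissue", "marker", "size_bp", "peak_area"]
    return SyntheticCohort(
        config=config,
        calibration_normals=pd.DataFrame(cal_rows, columns=columns),
        cohort_peaks=pd.DataFrame(peak_rows, columns=columns),
        tumour_truth=pd.DataFrame(truth_rows),
        marker_truth=pd.DataFrame(marker_truth_rows),
    )


def generate_segments(
    cohort: SyntheticCohort,
    arm_model: ArmModel | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """SEG-like table (1-based inclusive) consistent with the cohort truth.

    Every altered arm of an MSS tumour receives one non-neutral segment
    covering a fraction >= 0.8 of the arm; non-altered arms occasionally get
    small sub-threshold non-neutral segments so the 80% rule is actually
    exercised. MSI tumours emit no segments (they are gated out upstream).
    """
    arm_model = arm_model or load_default_arm_model()
    rng = np.random.default_rng(cohort.config.seed + 1 if seed is None else seed)
    rows = []
    for _, t in cohort.tumour_truth.iterrows():
        if t["msi"]:
            continue
        altered = set(t["altered_arms"].split(",")) - {""}
        for arm in sorted(arm_model.arms):
            chrom, a_start, a_end = arm_model.interval(arm)
            length = a_end - a_start
            if arm in altered:
                cov = float(rng.uniform(0.8, 1.0))
                call = str(rng.choice(["gain", "loss", "AI"]))
                seg_len = int(round(cov * length))
                start = a_start + int(rng.integers(0, length - seg_len + 1))
                rows.append((t["tumour_id"], chrom, start + 1, start + seg_len, call))
            elif rng.random() < 0.15:
                cov = float(rng.uniform(0.05, 0.5))
                call = str(rng.choice(["gain", "loss", "AI"]))
                seg_len = max(1, int(round(cov * length)))
                start = a_start + int(rng.integers(0, length - seg_len + 1))
                rows.append((t["tumour_id"], chrom, start + 1, start + seg_len, call))
    return pd.DataFrame(rows, columns=["sample_id", "chrom", "start", "end", "call"])


def _pure_pair(
    rng: np.random.Generator,
    cfg: GeneratorConfig,
    marker,
    effect: float,
    direction: int,
) -> tuple[GenotypeCall, GenotypeCall]:
    """Matched heterozygous normal and pure-tumour calls for one marker."""
    sizes = _allele_sizes(rng, marker.size_range_bp)
    base_n = cfg.base_area * float(np.exp(rng.normal(0.0, cfg.sigma_yield)))
    r_n = float(np.exp(rng.normal(0.0, cfg.sigma(marker.name))))
    normal = GenotypeCall(
        "case", NORMAL, marker.name, ((sizes[0], base_n * r_n), (sizes[1], base_n)), "heterozygous"
    )
    base_t = cfg.base_area * float(np.exp(rng.normal(0.0, cfg.sigma_yield)))
    shift = _attenuation(effect, direction, 1.0)
    r_t = r_n * shift * float(np.exp(rng.normal(0.0, cfg.sigma(marker.name))))
    tumour = GenotypeCall(
        "case", TUMOUR, marker.name, ((sizes[0], base_t * r_t), (sizes[1], base_t)), "heterozygous"
    )
    return normal, tumour


def generate_dilution_series(
    config: GeneratorConfig,
    panel: MarkerPanel | None = None,
    initial_contents: Sequence[float] = (0.6, 0.7, 0.7, 0.9),
    ai_marker_fraction: float = 0.6,
) -> tuple[dict[str, tuple[dict[str, GenotypeCall], dict[str, GenotypeCall]]], pd.DataFrame]:
    """Matched normal / pure-tumour call sets for limit-of-detection scans.

    Emulates the DNA-mixing design: CIN-H tumours with stated initial
    tumour cell contents whose DNA is mixed stepwise into the matched
    normal. Returns per-tumour (normal calls, pure-tumour calls) keyed by
    marker, plus a truth table (tumour_id, initial_content, n_ai_markers).
    The observed tumour at its initial content is itself a mixture, so the
    pure-tumour effect is planted at full strength and the caller dilutes.
    """
    panel = panel or load_default_panel()
    rng = np.random.default_rng(config.seed + 2)
    cases: dict[str, tuple[dict[str, GenotypeCall], dict[str, GenotypeCall]]] = {}
    truth_rows = []
    for i, content in enumerate(initial_contents):
        tid = f"DIL{i + 1}"
        n_calls: dict[str, GenotypeCall] = {}
        t_calls: dict[str, GenotypeCall] = {}
        n_ai = 0
        for m in panel.ai_markers:
            if rng.random() >= _het_rate(m):
                continue
            ai_true = rng.random() < ai_marker_fraction
            effect = float(np.exp(rng.uniform(*np.log(config.effect_range)))) if ai_true else 1.0
            direction = int(rng.choice([1, -1])) if ai_true else 0
            normal, tumour = _pure_pair(rng, config, m, effect, direction)
            n_calls[m.name] = GenotypeCall(tid, NORMAL, m.name, normal.alleles, "heterozygous")
            t_calls[m.name] = GenotypeCall(tid, TUMOUR, m.name, tumour.alleles, "heterozygous")
            n_ai += ai_true
        cases[tid] = (n_calls, t_calls)
        truth_rows.append(
            {"tumour_id": tid, "initial_content": content, "n_markers": len(n_calls), "n_ai_true": n_ai}
        )
    return cases, pd.DataFrame(truth_rows)


def generate_area_series(
    n_patients: int = 9,
    areas_per_patient: int = 5,
    x_bar: float = 0.3,
    s_w: float = 0.05,
    s_b: float = 0.1,
    seed: int | None = None,
) -> pd.DataFrame:
    """Repeated-area AI ratios: patient truth Normal(x_bar, s_b^2), area
    measurements Normal(truth, s_w^2). Defaults mirror a 9-patient x 5-area
    heterogeneity design around the 0.2 cut-off."""
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_patients):
        true = float(rng.normal(x_bar, s_b))
        for a in range(areas_per_patient):
            rows.append(
                {
                    "patient": f"P{p + 1:02d}",
                    "area": a + 1,
                    "ai_ratio": float(rng.normal(true, s_w)),
                    "true_ratio": true,
                }
            )
    return pd.DataFrame(rows)
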