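"""Intra-/inter-tumour variability of the AI ratio and misclassification risk.

Repeated AI-ratio measurements on several areas of the same tumour separate
measurement/heterogeneity noise (within-tumour SD, s_w) from biological
spread between patients (between-patient SD, s_b). Given a hard CIN cut-off
c, the probability that a patient's observed mean of r repeated
measurements falls on the wrong side of c (the crossing probability) is

    CP(r) = E_x[ 1 - Phi(|x - c| * sqrt(r) / s_w) ],   x ~ Normal(x_bar, s_b^2)

i.e. patient true ratios are Normal(x_bar, s_b^2) and the mean of r
measurements is Normal(x, s_w^2 / r). Averaging r areas shrinks the
measurement SD by 1/sqrt(r), which is exact in this model: CP at r equals
CP at 1 with s_w replaced by s_w/sqrt(r).

Note on normalization: the defining integral uses the *normalized* normal
density for x (without the 1/s_b Jacobian the expression would not be a
probability).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.stats import norm

from .ai_calling import CIN_H, DEFAULT_CIN_CUTOFF, classify_cin_pcr

__all__ = [
    "VarianceComponents",
    "HeterogeneityError",
    "estimate_components",
    "crossing_probability",
    "crossing_probability_mc",
    "area_concordance",
]


class HeterogeneityError(ValueError):
    """Raised for invalid heterogeneity inputs."""


@dataclass(frozen=True)
class VarianceComponents:
    """Inputs of the crossing-probability model."""

    c: float
    x_bar: float
    s_w: float
    s_b: float
    n_patients: int | None = None
    n_areas: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.c < 1.0:
            raise HeterogeneityError(f"cut-off {self.c} outside (0, 1)")
        if self.s_w < 0 or self.s_b < 0:
            raise HeterogeneityError("standard deviations must be non-negative")


def _areas_frame(areas) -> pd.DataFrame:
    if isinstance(areas, pd.DataFrame):
        df = areas
        missing = {"patient", "ai_ratio"} - set(df.columns)
        if missing:
            raise HeterogeneityError(f"areas table missing column(s): {sorted(missing)}")
        return df
    if isinstance(areas, Mapping):
        rows = [
            {"patient": str(p), "ai_ratio": float(v)}
            for p, vals in areas.items()
            for v in vals
        ]
        return pd.DataFrame(rows)
    raise HeterogeneityError("areas must be a DataFrame or mapping patient -> ratios")


def estimate_components(areas, c: float = DEFAULT_CIN_CUTOFF) -> VarianceComponents:
    """One-way variance-components estimate from repeated tumour areas.

    s_w is the pooled within-patient SD (root of the mean per-patient
    unbiased variance), s_b the unbiased SD of the per-patient mean AI
    ratios, and x_bar the mean of the per-patient means. Requires >= 2
    patients with >= 2 areas each.
    """
    df = _areas_frame(areas)
    groups = df.groupby("patient")["ai_ratio"]
    sizes = groups.size()
    if len(sizes) < 2:
        raise HeterogeneityError(f"need >= 2 patients, got {len(sizes)}")
    if (sizes < 2).any():
        bad = sizes[sizes < 2].index.tolist()
        raise HeterogeneityError(f"patients with < 2 areas: {bad}")
    within_vars = groups.var(ddof=1)
    patient_means = groups.mean()
    return VarianceComponents(
        c=c,
        x_bar=float(patient_means.mean()),
        s_w=float(np.sqrt(within_vars.mean())),
        s_b=float(patient_means.std(ddof=1)),
        n_patients=int(len(sizes)),
        n_areas=int(sizes.sum()),
    )


def crossing_probability(vc: VarianceComponents, r: int = 1) -> float:
    """Probability that the mean of r measurements flips the CIN class.

    Evaluated by adaptive quadrature of
    ``(1 - Phi(|x - c| sqrt(r) / s_w)) * N(x; x_bar, s_b^2)`` over
    x_bar +/- 8 s_b to absolute tolerance 1e-8. Degenerate limits are
    handled analytically: s_w = 0 gives 0 (no measurement noise); s_b = 0
    collapses the patient distribution to x_bar.
    """
    if r < 1 or int(r) != r:
        raise HeterogeneityError(f"r must be a positive integer, got {r}")
    se = vc.s_w / np.sqrt(r)
    if vc.s_w == 0.0:
        # without measurement noise only x exactly at c could flip (measure zero)
        return 0.0 if vc.s_b > 0 or vc.x_bar != vc.c else 0.5
    if vc.s_b == 0.0:
        return float(norm.sf(abs(vc.x_bar - vc.c) / se))

    def integrand(x: float) -> float:
        return norm.sf(abs(x - vc.c) / se) * norm.pdf(x, vc.x_bar, vc.s_b)

    lo, hi = vc.x_bar - 8.0 * vc.s_b, vc.x_bar + 8.0 * vc.s_b
    points = [p for p in (vc.c, vc.x_bar) if lo < p < hi]
    value, _ = integrate.quad(integrand, lo, hi, epsabs=1e-8, limit=200, points=points or None)
    return float(value)


def crossing_probability_mc(
    vc: VarianceComponents, r: int = 1, n_draws: int = 1_000_000, seed: int | None = None
) -> tuple[float, float]:
    """Monte-Carlo estimate of the crossing probability and its standard error.

    Draws a true ratio per patient from Normal(x_bar, s_b^2), then the mean
    of r measurements from Normal(true, s_w^2 / r), and counts classification
    flips across the cut-off. Serves as the independent simulation oracle for
    :func:`crossing_probability`.
    """
    rng = np.random.default_rng(seed)
    true = rng.normal(vc.x_bar, vc.s_b, size=n_draws)
    observed = rng.normal(true, vc.s_w / np.sqrt(r), size=n_draws)
    flips = (true >= vc.c) != (observed >= vc.c)
    p = float(np.mean(flips))
    se = float(np.sqrt(max(p * (1.0 - p), 1e-12) / n_draws))
    return p, se


def area_concordance(areas, cutoff: float = DEFAULT_CIN_CUTOFF) -> pd.DataFrame:
    """Per-patient agreement of per-area CIN classes with the majority class.

    Input is an areas table (patient, ai_ratio[, area]). Returns one row per
    patient: number of areas, majority class (ties resolved towards CIN-H,
    the inclusive side of the cut-off), and the count of areas agreeing with
    it.
    """
    df = _areas_frame(areas)
    rows = []
    for patient, grp in df.groupby("patient"):
        classes = [classify_cin_pcr(min(max(v, 0.0), 1.0), cutoff) for v in grp["ai_ratio"]]
        n_h = sum(c == CIN_H for c in classes)
        majority = CIN_H if n_h * 2 >= len(classes) else "CIN_L"
        agree = n_h if majority == CIN_H else len(classes) - n_h
        rows.append(
            {
                "patient": patient,
                "n_areas": len(classes),
                "majority_class": majority,
                "n_concordant": agree,
                "fully_concordant": agree == len(classes),
            }
        )
    return pd.DataFrame(rows)
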