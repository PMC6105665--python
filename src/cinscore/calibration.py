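"""Per-marker AI-threshold calibration from non-tumorous tissues.

The range of variation of allelic amplification for each marker is measured
by forming all ordered pairwise quotients of the per-sample allele ratios of
heterozygous non-tumorous samples. Thresholds for calling allelic imbalance
are the lower bound of the bootstrapped two-sided confidence interval of the
2.5% quantile and the upper bound of the interval of the 97.5% quantile of
those quotients; AI values of tumours outside (lower, upper) are called AI.

Both the quotient set (ordered pairs: a/b and b/a) and the default
percentile bootstrap are symmetric on the log scale, so calibrated bounds
are reciprocal-consistent up to Monte-Carlo error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .peak_io import GenotypeCall, allele_ratio

__all__ = [
    "RatioVariationSet",
    "AIThresholds",
    "CalibrationError",
    "ratio_variation",
    "bootstrap_thresholds",
    "calibrate_markers",
    "calibration_coverage",
]

DEFAULT_N_BOOT = 10_000
DEFAULT_CONF_LEVEL = 0.95
DEFAULT_QUANTILES = (0.025, 0.975)
MIN_QUOTIENTS = 20


class CalibrationError(ValueError):
    """Raised when calibration preconditions are not met."""


@dataclass(frozen=True)
class RatioVariationSet:
    """All ordered pairwise allele-ratio quotients for one marker."""

    marker: str
    quotients: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        q = np.asarray(self.quotients, dtype=float)
        if q.ndim != 1 or not np.all(q > 0):
            raise CalibrationError(f"{self.marker}: quotients must be a 1-D positive array")
        object.__setattr__(self, "quotients", q)


@dataclass(frozen=True)
class AIThresholds:
    """Calibrated (lower, upper) AI thresholds for one marker."""

    marker: str
    lower: float
    upper: float
    n_boot: int
    conf_level: float
    seed: int | None
    n_quotients: int
    n_samples: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate and not self.lower < 1.0 < self.upper:
            raise CalibrationError(
                f"{self.marker}: thresholds must bracket 1.0, got ({self.lower}, {self.upper})"
            )

    def as_tuple(self) -> tuple[float, float]:
        return (self.lower, self.upper)

    def report_row(self) -> dict:
        """Report-style row with thresholds rounded to 2 decimals."""
        return {
            "marker": self.marker,
            "n_quotients": self.n_quotients,
            "lower": round(self.lower, 2),
            "upper": round(self.upper, 2),
            "n_boot": self.n_boot,
            "seed": self.seed,
        }


def ratio_variation(normal_calls: Sequence[GenotypeCall]) -> RatioVariationSet:
    """Quotients r_i/r_j (i != j) of per-sample allele ratios for one marker.

    Ordered pairs are used in both directions, so the returned multiset of
    n(n-1) quotients is closed under reciprocal.
    """
    het = [c for c in normal_calls if c.is_heterozygous]
    markers = {c.marker for c in het}
    if len(markers) > 1:
        raise CalibrationError(f"calls span multiple markers: {sorted(markers)}")
    if len(het) < 2:
        raise CalibrationError(
            f"need >=2 heterozygous normal samples, got {len(het)}"
        )
    marker = next(iter(markers))
    ratios = np.array([allele_ratio(c) for c in het], dtype=float)
    quot = np.outer(ratios, 1.0 / ratios)
    mask = ~np.eye(len(ratios), dtype=bool)
    return RatioVariationSet(marker=marker, quotients=quot[mask], n_samples=len(het))


def _chunked_bootstrap_quantiles(
    values: np.ndarray, n_boot: int, quantiles: Sequence[float], rng: np.random.Generator
) -> np.ndarray:
    """(n_boot, len(quantiles)) bootstrap replicates of empirical quantiles."""
    n = values.size
    out = np.empty((n_boot, len(quantiles)))
    # chunk to bound the resample matrix at ~2e7 entries
    chunk = max(1, int(2e7 // max(n, 1)))
    done = 0
    while done < n_boot:
        b = min(chunk, n_boot - done)
        idx = rng.integers(0, n, size=(b, n))
        out[done : done + b] = np.quantile(values[idx], quantiles, axis=1, method="linear").T
        done += b
    return out


def bootstrap_thresholds(
    varset: RatioVariationSet,
    n_boot: int = DEFAULT_N_BOOT,
    conf_level: float = DEFAULT_CONF_LEVEL,
    seed: int | None = None,
    quantiles: tuple[float, float] = DEFAULT_QUANTILES,
    min_quotients: int = MIN_QUOTIENTS,
    resample: str = "quotient",
    sample_ratios: Sequence[float] | None = None,
) -> AIThresholds:
    """Percentile-bootstrap AI thresholds for one marker.

    lower = lower bound of the two-sided *conf_level* CI of the 2.5% quantile;
    upper = upper bound of the CI of the 97.5% quantile. ``resample`` is
    ``"quotient"`` (default: resample the quotients directly) or ``"sample"``
    (resample per-sample allele ratios and rebuild the quotients; requires
    *sample_ratios*), acknowledging the sample-level dependence among
    quotients.
    """
    q = varset.quotients
    if q.size < min_quotients:
        raise CalibrationError(
            f"{varset.marker}: {q.size} quotients < required floor {min_quotients}"
        )
    if n_boot < 1000:
        raise CalibrationError(f"n_boot must be >= 1000, got {n_boot}")
    if np.allclose(q, q[0]):
        c = float(q[0])
        return AIThresholds(
            varset.marker, c, c, n_boot, conf_level, seed, q.size, varset.n_samples, degenerate=True
        )
    rng = np.random.default_rng(seed)
    alpha = 1.0 - conf_level
    if resample == "quotient":
        stats = _chunked_bootstrap_quantiles(q, n_boot, quantiles, rng)
    elif resample == "sample":
        if sample_ratios is None:
            raise CalibrationError("sample-level resampling requires sample_ratios")
        ratios = np.asarray(sample_ratios, dtype=float)
        n = ratios.size
        stats = np.empty((n_boot, 2))
        mask = ~np.eye(n, dtype=bool)
        for b in range(n_boot):
            rs = ratios[rng.integers(0, n, size=n)]
            qb = np.outer(rs, 1.0 / rs)[mask]
            stats[b] = np.quantile(qb, quantiles, method="linear")
    else:
        raise CalibrationError(f"unknown resample mode {resample!r}")
    lower = float(np.quantile(stats[:, 0], alpha / 2.0, method="linear"))
    upper = float(np.quantile(stats[:, 1], 1.0 - alpha / 2.0, method="linear"))
    return AIThresholds(
        varset.marker, lower, upper, n_boot, conf_level, seed, q.size, varset.n_samples
    )


def calibrate_markers(
    calls_by_marker: Mapping[str, Sequence[GenotypeCall]],
    n_boot: int = DEFAULT_N_BOOT,
    conf_level: float = DEFAULT_CONF_LEVEL,
    seed: int | None = None,
    min_quotients: int = MIN_QUOTIENTS,
) -> dict[str, AIThresholds]:
    """Calibrate every marker with enough heterozygous normals.

    Markers failing the quotient floor are silently omitted (callers can
    diff against the panel to report them); each marker gets an independent
    child seed spawned from *seed* so results do not depend on marker order.
    """
    ss = np.random.SeedSequence(seed)
    out: dict[str, AIThresholds] = {}
    for (marker, calls), child in zip(sorted(calls_by_marker.items()), ss.spawn(len(calls_by_marker))):
        try:
            varset = ratio_variation(calls)
            out[marker] = bootstrap_thresholds(
                varset,
                n_boot=n_boot,
                conf_level=conf_level,
                seed=int(child.generate_state(1)[0] % (2**31)),
                min_quotients=min_quotients,
            )
        except CalibrationError:
            continue
    return out


def calibration_coverage(
    thresholds: Mapping[str, AIThresholds] | Mapping[str, tuple[float, float]],
    sigma_m: float | Mapping[str, float],
    n_sim: int = 10_000,
    seed: int | None = None,
) -> dict[str, float]:
    """Monte-Carlo false-positive AI rate per marker under the null.

    Null AI values are quotients of two independent lognormal amplification
    draws with per-marker log-SD *sigma_m* (the generator's noise model), so
    log(AI) ~ Normal(0, 2 sigma_m^2). Returns the fraction of null values
    falling outside the open interval (lower, upper) for each marker.
    """
    rng = np.random.default_rng(seed)
    rates: dict[str, float] = {}
    for marker in sorted(thresholds):
        thr = thresholds[marker]
        lower, upper = thr.as_tuple() if isinstance(thr, AIThresholds) else thr
        sig = sigma_m[marker] if isinstance(sigma_m, Mapping) else float(sigma_m)
        ai = np.exp(rng.normal(0.0, np.sqrt(2.0) * sig, size=n_sim))
        rates[marker] = float(np.mean((ai < lower) | (ai > upper)))
    return rates
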