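"""Fragment-analysis peak tables and per-marker genotype calls.

Input is a delimited table of called allele peaks (one row per allele peak)
from capillary electrophoresis: sample_id, tissue (normal/tumour), marker,
size_bp, peak_area. Upstream concerns — electropherogram signal processing,
stutter deconvolution, bin calling — are out of scope; peak areas are used
as called.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .panel_config import MarkerPanel

__all__ = [
    "PeakRecord",
    "GenotypeCall",
    "PeakTableError",
    "NORMAL",
    "TUMOUR",
    "read_peak_table",
    "write_peak_table",
    "records_to_frame",
    "genotype_from_peaks",
    "genotype_table",
    "allele_ratio",
]

NORMAL = "normal"
TUMOUR = "tumour"

REQUIRED_COLUMNS = ("sample_id", "tissue", "marker", "size_bp", "peak_area")

_TISSUE_ALIASES = {"normal": NORMAL, "n": NORMAL, "tumour": TUMOUR, "tumor": TUMOUR, "t": TUMOUR}


class PeakTableError(ValueError):
    """Raised for malformed peak tables."""


def _sniff_sep(source) -> str:
    """Detect tab vs comma delimiting from the first non-comment line."""
    if hasattr(source, "read"):
        text = source.read()
        source.seek(0)
    else:
        from pathlib import Path

        try:
            text = Path(source).read_text()
        except OSError as exc:
            raise PeakTableError(f"cannot read peak table: {exc}") from exc
    for line in text.splitlines():
        if line.strip() and not line.startswith("#"):
            return "\t" if "\t" in line else ","
    return "\t"


@dataclass(frozen=True)
class PeakRecord:
    """One called allele peak."""

    sample_id: str
    tissue: str
    marker: str
    size_bp: float
    peak_area: float

    def __post_init__(self) -> None:
        if self.tissue not in (NORMAL, TUMOUR):
            raise PeakTableError(f"tissue must be normal/tumour, got {self.tissue!r}")
        if not self.peak_area > 0:
            raise PeakTableError(f"peak_area must be > 0, got {self.peak_area}")
        if not self.size_bp > 0:
            raise PeakTableError(f"size_bp must be > 0, got {self.size_bp}")


@dataclass(frozen=True)
class GenotypeCall:
    """Alleles of one sample at one marker, ordered by ascending size."""

    sample_id: str
    tissue: str
    marker: str
    alleles: tuple[tuple[float, float], ...]  # (size_bp, peak_area)
    zygosity: str  # heterozygous | homozygous | not_evaluable
    reason: str | None = None

    @property
    def is_heterozygous(self) -> bool:
        return self.zygosity == "heterozygous"

    @property
    def sizes(self) -> tuple[float, ...]:
        return tuple(s for s, _ in self.alleles)

    @property
    def shorter(self) -> tuple[float, float]:
        return self.alleles[0]

    @property
    def longer(self) -> tuple[float, float]:
        return self.alleles[-1]


def read_peak_table(source, sep: str | None = None, panel: MarkerPanel | None = None) -> list[PeakRecord]:
    """Read a peak table (TSV by default, CSV accepted) into records.

    With a *panel*, rows whose fragment size falls outside the marker's
    declared range, or whose marker is unknown, trigger a warning (the row
    is kept: size calibration drift is common and recoverable downstream).
    """
    try:
        df = pd.read_csv(
            source, sep=sep or _sniff_sep(source), comment="#", float_precision="round_trip"
        )
    except PeakTableError:
        raise
    except Exception as exc:
        raise PeakTableError(f"cannot parse peak table: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise PeakTableError(f"peak table missing required column(s): {missing}")

    records: list[PeakRecord] = []
    unknown: set[str] = set()
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        tissue_raw = str(getattr(row, "tissue")).strip().lower()
        tissue = _TISSUE_ALIASES.get(tissue_raw)
        if tissue is None:
            raise PeakTableError(f"row {idx}: unknown tissue {tissue_raw!r} (expected normal/tumour)")
        try:
            size = float(getattr(row, "size_bp"))
            area = float(getattr(row, "peak_area"))
        except (TypeError, ValueError) as exc:
            raise PeakTableError(f"row {idx}: unparseable size_bp/peak_area") from exc
        if not area > 0:
            raise PeakTableError(f"row {idx}: peak_area must be > 0, got {area}")
        marker = str(getattr(row, "marker")).strip()
        rec = PeakRecord(str(getattr(row, "sample_id")), tissue, marker, size, area)
        if panel is not None:
            if marker not in panel:
                unknown.add(marker)
            else:
                lo, hi = panel.marker(marker).size_range_bp
                if not lo <= size <= hi:
                    warnings.warn(
                        f"row {idx}: size {size} bp outside declared range "
                        f"[{lo}, {hi}] for marker {marker}",
                        stacklevel=2,
                    )
        records.append(rec)
    if unknown:
        warnings.warn(f"peak table contains marker(s) not in panel: {sorted(unknown)}", stacklevel=2)
    return records


def records_to_frame(records: Iterable[PeakRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.sample_id, r.tissue, r.marker, r.size_bp, r.peak_area) for r in records],
        columns=list(REQUIRED_COLUMNS),
    )


def write_peak_table(records: Iterable[PeakRecord] | pd.DataFrame, path, sep: str = "\t") -> None:
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df.to_csv(path, sep=sep, index=False)


def genotype_from_peaks(records: Sequence[PeakRecord]) -> GenotypeCall:
    """Collapse the peaks of one sample x marker into a genotype call.

    Two distinct sizes -> heterozygous, one -> homozygous; zero or more than
    two peaks are not evaluable for AI (reason recorded, no exception).
    """
    if not records:
        raise PeakTableError("genotype_from_peaks requires at least the sample/marker context")
    ids = {(r.sample_id, r.tissue, r.marker) for r in records}
    if len(ids) != 1:
        raise PeakTableError(f"records span multiple sample/tissue/marker combinations: {sorted(ids)}")
    sample_id, tissue, marker = next(iter(ids))
    alleles = tuple(sorted(((r.size_bp, r.peak_area) for r in records)))
    sizes = {s for s, _ in alleles}
    if len(alleles) == 2 and len(sizes) == 2:
        zyg, reason = "heterozygous", None
    elif len(alleles) == 1:
        zyg, reason = "homozygous", None
    elif len(alleles) == 2:
        zyg, reason = "not_evaluable", "two peaks with identical size"
    else:
        zyg, reason = "not_evaluable", "ambiguous allele count"
    return GenotypeCall(sample_id, tissue, marker, alleles, zyg, reason)


def genotype_table(
    records: Iterable[PeakRecord],
) -> dict[tuple[str, str, str], GenotypeCall]:
    """Group peaks and call genotypes, keyed by (sample_id, tissue, marker)."""
    groups: dict[tuple[str, str, str], list[PeakRecord]] = {}
    for r in records:
        groups.setdefault((r.sample_id, r.tissue, r.marker), []).append(r)
    return {key: genotype_from_peaks(recs) for key, recs in groups.items()}


def allele_ratio(call: GenotypeCall) -> float:
    """Allele ratio: peak area of the shorter allele over the longer allele."""
    if not call.is_heterozygous:
        raise PeakTableError(
            f"allele ratio requires a heterozygous call, got {call.zygosity} "
            f"({call.sample_id}/{call.marker})"
        )
    (_, area_short), (_, area_long) = call.alleles
    return area_short / area_long
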