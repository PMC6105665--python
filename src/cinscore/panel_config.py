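"""Marker-panel and chromosome-arm configuration.

The panel describes the microsatellite markers used for allelic-imbalance
(AI) scoring and microsatellite-instability (MSI) screening: cytogenetic
region, fragment-size range, population heterozygosity, multiplex PCR
group, and the calibrated per-marker AI thresholds (lower, upper) around
the balanced value 1.0.

The arm model maps chromosome-arm labels to genomic intervals in a declared
genome build and flags which arms enter the arm-level CIN denominator
(autosomal arms minus the acrocentric short arms 13p/14p/15p/21p/22p and
the gastric-cancer exclusion set 18p/18q/21q; 36 arms by default).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "MarkerDef",
    "MarkerPanel",
    "ArmModel",
    "PanelError",
    "load_panel",
    "write_panel",
    "load_default_panel",
    "build_arm_model",
    "load_default_arm_model",
    "DEFAULT_ARM_EXCLUSIONS",
    "ACROCENTRIC_P_ARMS",
    "normalize_chrom",
]

#: short arms of the acrocentric autosomes carry no unique assayable sequence
ACROCENTRIC_P_ARMS = frozenset({"13p", "14p", "15p", "21p", "22p"})

#: arms excluded from the arm-level CIN call (frequent near-ubiquitous
#: alterations in gastric cancer make them uninformative for the classifier)
CIN_ARM_EXCLUSIONS = frozenset({"18p", "18q", "21q"})

DEFAULT_ARM_EXCLUSIONS = ACROCENTRIC_P_ARMS | CIN_ARM_EXCLUSIONS

MSI_PANEL = ("BAT25", "BAT26", "D2S123", "D5S346", "D17S250")


class PanelError(ValueError):
    """Raised for invalid panel or arm-model configuration."""


def normalize_chrom(chrom: str | int) -> str:
    """Return an unprefixed chromosome name ('chr8' and '8' -> '8')."""
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if not c:
        raise PanelError("empty chromosome name")
    return c


@dataclass(frozen=True)
class MarkerDef:
    """One microsatellite marker of the panel."""

    name: str
    region: str
    chrom: str
    size_range_bp: tuple[int, int]
    heterozygosity: float | None = None
    multiplex_group: int | str | None = None
    dye: str | None = None
    ai_thresholds: tuple[float, float] | None = None
    band: str | None = None
    excluded: bool = False
    excluded_reason: str | None = None
    #: opaque annotation from the original calibration (pairwise counts)
    n_calibration_tissues: int | None = None

    def __post_init__(self) -> None:
        lo, hi = self.size_range_bp
        if not lo < hi:
            raise PanelError(f"{self.name}: size range min must be < max, got {self.size_range_bp}")
        if self.heterozygosity is not None and not 0.0 <= self.heterozygosity <= 1.0:
            raise PanelError(f"{self.name}: heterozygosity {self.heterozygosity} outside [0, 1]")
        if self.ai_thresholds is not None:
            lower, upper = self.ai_thresholds
            if not (0.0 < lower < 1.0 < upper):
                raise PanelError(
                    f"{self.name}: AI thresholds must satisfy 0 < lower < 1 < upper, "
                    f"got ({lower}, {upper})"
                )
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))

    @property
    def arm(self) -> str:
        """Chromosome arm the marker maps to, derived from its region label."""
        for i, ch in enumerate(self.region):
            if ch in "pq":
                return self.region[: i + 1]
        raise PanelError(f"{self.name}: region {self.region!r} has no p/q arm letter")

    @property
    def scores_ai(self) -> bool:
        return self.ai_thresholds is not None and not self.excluded


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered marker collection plus derived region/arm groupings."""

    name: str
    build: str
    markers: tuple[MarkerDef, ...]

    def __post_init__(self) -> None:
        names = [m.name for m in self.markers]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise PanelError(f"duplicate marker name(s): {sorted(dupes)}")

    def __iter__(self):
        return iter(self.markers)

    def __len__(self) -> int:
        return len(self.markers)

    def marker(self, name: str) -> MarkerDef:
        for m in self.markers:
            if m.name == name:
                return m
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(m.name == name for m in self.markers)

    @property
    def ai_markers(self) -> tuple[MarkerDef, ...]:
        """Markers that score AI: non-excluded, with calibrated thresholds."""
        return tuple(m for m in self.markers if m.scores_ai)

    @property
    def msi_markers(self) -> tuple[MarkerDef, ...]:
        """The 5-marker Bethesda MSI screen, in canonical order."""
        return tuple(self.marker(n) for n in MSI_PANEL if n in self)

    @property
    def regions(self) -> Mapping[str, tuple[MarkerDef, ...]]:
        """Region label -> AI-scoring member markers (insertion-ordered)."""
        out: dict[str, list[MarkerDef]] = {}
        for m in self.ai_markers:
            out.setdefault(m.region, []).append(m)
        return {r: tuple(ms) for r, ms in out.items()}

    def thresholds(self) -> dict[str, tuple[float, float]]:
        return {m.name: m.ai_thresholds for m in self.ai_markers}


def _marker_from_mapping(rec: Mapping) -> MarkerDef:
    try:
        size_range = tuple(int(v) for v in rec["size_range_bp"])
        thresholds = rec.get("ai_thresholds")
        if thresholds is not None:
            thresholds = (float(thresholds[0]), float(thresholds[1]))
        return MarkerDef(
            name=str(rec["name"]),
            region=str(rec["region"]),
            chrom=str(rec["chrom"]),
            size_range_bp=size_range,  # type: ignore[arg-type]
            heterozygosity=None if rec.get("heterozygosity") is None else float(rec["heterozygosity"]),
            multiplex_group=rec.get("multiplex_group"),
            dye=rec.get("dye"),
            ai_thresholds=thresholds,
            band=rec.get("band"),
            excluded=bool(rec.get("excluded", False)),
            excluded_reason=rec.get("excluded_reason"),
            n_calibration_tissues=(
                None if rec.get("n_calibration_tissues") is None else int(rec["n_calibration_tissues"])
            ),
        )
    except KeyError as exc:
        raise PanelError(f"marker record missing required field {exc}") from exc


def load_panel(source) -> MarkerPanel:
    """Load a marker panel from YAML (path, text, file-like, or mapping).

    The packaged default reproduces the published gastric-carcinoma panel:
    22 threshold-bearing markers over 17 regions, 19 of them in multiplex
    groups 1-4 and the 3 dinucleotides shared with the MSI screen.
    """
    if isinstance(source, Mapping):
        doc = source
    elif hasattr(source, "read"):
        doc = yaml.safe_load(source.read())
    else:
        text = str(source)
        p = Path(text)
        if "\n" not in text and p.suffix in {".yaml", ".yml"} or ("\n" not in text and p.exists()):
            doc = yaml.safe_load(p.read_text())
        else:
            doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping) or "markers" not in doc:
        raise PanelError("panel config must be a mapping with a 'markers' list")
    markers = tuple(_marker_from_mapping(rec) for rec in doc["markers"])
    return MarkerPanel(
        name=str(doc.get("panel", "unnamed")),
        build=str(doc.get("build", "unknown")),
        markers=markers,
    )


def write_panel(panel: MarkerPanel, path=None) -> str:
    """Serialize a panel to YAML; returns the text (and writes it if *path*)."""
    recs = []
    for m in panel.markers:
        rec: dict = {
            "name": m.name,
            "region": m.region,
            "band": m.band,
            "chrom": m.chrom,
            "dye": m.dye,
            "size_range_bp": list(m.size_range_bp),
            "heterozygosity": m.heterozygosity,
            "multiplex_group": m.multiplex_group,
            "ai_thresholds": None if m.ai_thresholds is None else [float(v) for v in m.ai_thresholds],
            "excluded": m.excluded,
        }
        if m.n_calibration_tissues is not None:
            rec["n_calibration_tissues"] = m.n_calibration_tissues
        if m.excluded_reason is not None:
            rec["excluded_reason"] = m.excluded_reason
        recs.append(rec)
    text = yaml.safe_dump(
        {"panel": panel.name, "build": panel.build, "markers": recs},
        sort_keys=False,
        default_flow_style=None,
    )
    if path is not None:
        Path(path).write_text(text)
    return text


def load_default_panel() -> MarkerPanel:
    """The packaged 22-marker gastric-carcinoma panel (``panel_gc22``)."""
    with resources.files("cinscore.data").joinpath("panel_gc22.yaml").open() as fh:
        return load_panel(fh)


@dataclass(frozen=True)
class ArmModel:
    """Chromosome-arm intervals (0-based half-open) and evaluability flags."""

    build: str
    arms: Mapping[str, tuple[str, int, int]]
    evaluable: frozenset[str]

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[tuple[int, int, str]]] = {}
        for label, (chrom, start, end) in self.arms.items():
            if not 0 <= start < end:
                raise PanelError(f"arm {label}: invalid interval [{start}, {end})")
            by_chrom.setdefault(chrom, []).append((start, end, label))
        for chrom, ivals in by_chrom.items():
            ivals.sort()
            for (s1, e1, l1), (s2, e2, l2) in zip(ivals, ivals[1:]):
                if s2 < e1:
                    raise PanelError(f"arms {l1} and {l2} overlap on chromosome {chrom}")
        missing = self.evaluable - set(self.arms)
        if missing:
            raise PanelError(f"evaluable arms absent from model: {sorted(missing)}")

    @property
    def n_evaluable(self) -> int:
        """Denominator of the arm-level alteration ratio."""
        return len(self.evaluable)

    def length(self, label: str) -> int:
        _, start, end = self.arms[label]
        return end - start

    def interval(self, label: str) -> tuple[str, int, int]:
        return self.arms[label]

    def arms_for_chrom(self, chrom: str) -> list[str]:
        chrom = normalize_chrom(chrom)
        return [a for a, (c, _, _) in self.arms.items() if c == chrom]

    def midpoint(self, label: str) -> tuple[str, int]:
        chrom, start, end = self.arms[label]
        return chrom, (start + end) // 2


def _parse_arm_table(text: str) -> tuple[str, dict[str, tuple[str, int, int]]]:
    build = "unknown"
    arms: dict[str, tuple[str, int, int]] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            for tok in line.lstrip("#").split():
                if tok.startswith("build="):
                    build = tok.split("=", 1)[1]
            continue
        fields = line.split()
        if len(fields) < 4:
            raise PanelError(f"arm table line {lineno}: expected 4 columns, got {len(fields)}")
        chrom = normalize_chrom(fields[0])
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise PanelError(f"arm table line {lineno}: non-integer coordinates") from exc
        label = fields[3]
        if label in arms:
            raise PanelError(f"arm table line {lineno}: duplicate arm label {label!r}")
        arms[label] = (chrom, start, end)
    return build, arms


def build_arm_model(
    arm_table,
    exclusions: Iterable[str] = DEFAULT_ARM_EXCLUSIONS,
    build: str | None = None,
) -> ArmModel:
    """Build an :class:`ArmModel` from BED-like text (path, text, file-like).

    ``exclusions`` are arm labels removed from the evaluable set that forms
    the denominator of the arm-level alteration ratio. With the default
    exclusions the packaged autosomal table yields 36 evaluable arms.
    """
    if hasattr(arm_table, "read"):
        text = arm_table.read()
    else:
        s = str(arm_table)
        p = Path(s)
        text = p.read_text() if ("\n" not in s and p.exists()) else s
    parsed_build, arms = _parse_arm_table(text)
    if not arms:
        raise PanelError("arm table contains no arm intervals")
    evaluable = frozenset(arms) - frozenset(exclusions)
    return ArmModel(build=build or parsed_build, arms=arms, evaluable=evaluable)


def load_default_arm_model(exclusions: Iterable[str] = DEFAULT_ARM_EXCLUSIONS) -> ArmModel:
    """The packaged hg19 autosomal arm model (36 evaluable arms by default)."""
    text = resources.files("cinscore.data").joinpath("arms_hg19.bed").read_text()
    return build_arm_model(io.StringIO(text), exclusions=exclusions)
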