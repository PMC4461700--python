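"""Panel configuration, fragment-analysis peak tables and trio genotype I/O.

The screen works on GeneMapper-style peak exports from paired aliquots of each
DNA sample: one digested with a methylation-sensitive enzyme (HpaII), one
undigested.  This module reads those tables, assigns peaks to the amplicons of
a multiplex panel by fragment size, pairs the two run conditions per sample,
and parses trio microsatellite genotype tables for UPD confirmation.  It also
provides small genomic-interval arithmetic used when reporting CNV spans.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .errors import (
    AmbiguousPeakError,
    DuplicateRunError,
    ParseError,
    ValidationError,
)
from .upd_trio import TrioGenotype

logger = logging.getLogger("imprintscan")

DEFAULT_PANEL_NAME = "panel_imprint4"


class Condition(str, enum.Enum):
    DIGESTED = "digested"
    UNDIGESTED = "undigested"


class AmpliconKind(str, enum.Enum):
    DMR = "DMR"
    REFERENCE = "REFERENCE"


class Parent(str, enum.Enum):
    MATERNAL = "maternal"
    PATERNAL = "paternal"
    NA = "na"


class Role(str, enum.Enum):
    CONTROL = "control"
    PATIENT = "patient"


@dataclass(frozen=True)
class AmpliconDef:
    """One amplicon of the multiplex: either a DMR probe or a reference.

    A DMR amplicon spans HpaII sites of a differentially methylated region and
    amplifies from the digested aliquot only where the template was methylated;
    a REFERENCE amplicon has no HpaII site and amplifies equally from both
    aliquots, providing the normalization basis.
    """

    name: str
    locus: str
    expected_size: int
    size_tolerance: float
    kind: AmpliconKind
    chrom_band: str = ""
    methylated_parent: Parent = Parent.NA
    hypo_syndrome: str = ""
    hyper_syndrome: str = ""

    def __post_init__(self) -> None:
        if self.expected_size <= 0:
            raise ValidationError(
                f"amplicon {self.name!r}: expected_size must be > 0")
        if self.size_tolerance < 0:
            raise ValidationError(
                f"amplicon {self.name!r}: size_tolerance must be >= 0")
        if self.kind is AmpliconKind.REFERENCE:
            if self.methylated_parent is not Parent.NA:
                raise ValidationError(
                    f"amplicon {self.name!r}: a REFERENCE amplicon has no "
                    "methylated parent")
        elif self.methylated_parent is Parent.NA:
            raise ValidationError(
                f"amplicon {self.name!r}: a DMR amplicon needs "
                "methylated_parent maternal or paternal")


@dataclass(frozen=True)
class PanelConfig:
    """An ordered multiplex design with at least one DMR and one reference."""

    amplicons: tuple[AmpliconDef, ...]
    name: str = "unnamed"
    version: str = "0"

    def __post_init__(self) -> None:
        object.__setattr__(self, "amplicons", tuple(self.amplicons))
        names = [a.name for a in self.amplicons]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValidationError(
                f"panel {self.name!r}: duplicate amplicon names {sorted(dupes)}")
        kinds = {a.kind for a in self.amplicons}
        if AmpliconKind.REFERENCE not in kinds:
            raise ValidationError(
                f"panel {self.name!r}: at least one REFERENCE amplicon required")
        if AmpliconKind.DMR not in kinds:
            raise ValidationError(
                f"panel {self.name!r}: at least one DMR amplicon required")

    @property
    def dmr_amplicons(self) -> tuple[AmpliconDef, ...]:
        return tuple(a for a in self.amplicons if a.kind is AmpliconKind.DMR)

    @property
    def reference_amplicons(self) -> tuple[AmpliconDef, ...]:
        return tuple(a for a in self.amplicons
                     if a.kind is AmpliconKind.REFERENCE)

    def by_name(self, name: str) -> AmpliconDef:
        for a in self.amplicons:
            if a.name == name:
                return a
        raise KeyError(name)

    def amplicon_for_locus(self, locus: str) -> AmpliconDef:
        for a in self.dmr_amplicons:
            if a.locus == locus:
                return a
        raise KeyError(locus)


@dataclass(frozen=True)
class PeakRecord:
    """One called peak of a fragment-analysis run (areas in fluorescence units)."""

    sample_id: str
    condition: Condition
    size: float
    area: float
    height: float | None = None
    amplicon: str | None = None
    role: Role | None = None

    def __post_init__(self) -> None:
        if self.area < 0:
            raise ValidationError(
                f"sample {self.sample_id}: negative peak area {self.area}")
        if self.height is not None and self.height < 0:
            raise ValidationError(
                f"sample {self.sample_id}: negative peak height {self.height}")


@dataclass(frozen=True)
class SamplePair:
    """Digested and undigested peak profiles of one individual.

    Both maps cover the full panel amplicon set; expected peaks that were not
    observed are stored as area 0 and listed in ``missing`` as
    ``(condition value, amplicon name)`` — a fully digested unmethylated DMR
    legitimately yields no peak in the digested aliquot.
    """

    sample_id: str
    digested: dict[str, float]
    undigested: dict[str, float]
    role: Role = Role.PATIENT
    missing: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self) -> None:
        if set(self.digested) != set(self.undigested):
            raise ValidationError(
                f"sample {self.sample_id}: digested and undigested profiles "
                "cover different amplicon sets")

    def areas(self, condition: Condition) -> dict[str, float]:
        return self.digested if condition is Condition.DIGESTED else self.undigested


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive interval, clinical array-nomenclature style."""

    chrom: str
    start: int
    end: int
    assembly: str = "GRCh37/hg19"

    def __post_init__(self) -> None:
        if not (self.end >= self.start >= 1):
            raise ValidationError(
                f"interval {self.chrom}:{self.start}-{self.end}: "
                "end >= start >= 1 required")

    @property
    def span_bp(self) -> int:
        return self.end - self.start + 1


class SpanUnit(str, enum.Enum):
    KB = "KB"
    MB = "MB"


def interval_span(interval: GenomicInterval, unit: SpanUnit | str) -> float:
    """Span of a 1-based inclusive interval, rounded for report text.

    KB: integer kilobases, half-up.  MB: one-decimal megabases, half-up.
    """
    if not isinstance(unit, SpanUnit):
        unit = SpanUnit(str(unit).upper())
    bp = Decimal(interval.span_bp)
    if unit is SpanUnit.KB:
        return float((bp / Decimal(1000)).quantize(Decimal("1"), ROUND_HALF_UP))
    return float((bp / Decimal(1_000_000)).quantize(Decimal("0.1"), ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Panel configuration I/O


_AMPLICON_FIELDS = {
    "name", "locus", "expected_size", "size_tolerance", "kind", "chrom_band",
    "methylated_parent", "hypo_syndrome", "hyper_syndrome",
}


def _amplicon_from_mapping(raw: dict, index: int) -> AmpliconDef:
    if not isinstance(raw, dict):
        raise ParseError(f"amplicon #{index}: expected a mapping, got {type(raw).__name__}")
    unknown = set(raw) - _AMPLICON_FIELDS
    if unknown:
        raise ParseError(f"amplicon #{index}: unknown field(s) {sorted(unknown)}")
    missing = {"name", "locus", "expected_size", "size_tolerance", "kind"} - set(raw)
    if missing:
        raise ParseError(f"amplicon #{index}: missing field(s) {sorted(missing)}")
    try:
        kind = AmpliconKind(str(raw["kind"]).upper())
    except ValueError:
        raise ParseError(
            f"amplicon #{index} ({raw.get('name')}): kind must be DMR or "
            f"REFERENCE, got {raw['kind']!r}") from None
    parent_raw = raw.get("methylated_parent", "na") or "na"
    try:
        parent = Parent(str(parent_raw).lower())
    except ValueError:
        raise ParseError(
            f"amplicon #{index} ({raw.get('name')}): methylated_parent must "
            f"be maternal, paternal or na, got {parent_raw!r}") from None
    return AmpliconDef(
        name=str(raw["name"]),
        locus=str(raw["locus"]),
        expected_size=int(raw["expected_size"]),
        size_tolerance=float(raw["size_tolerance"]),
        kind=kind,
        chrom_band=str(raw.get("chrom_band", "") or ""),
        methylated_parent=parent,
        hypo_syndrome=str(raw.get("hypo_syndrome", "") or ""),
        hyper_syndrome=str(raw.get("hyper_syndrome", "") or ""),
    )


def panel_from_mapping(doc: dict) -> PanelConfig:
    if not isinstance(doc, dict) or "amplicons" not in doc:
        raise ParseError("panel config must be a mapping with an 'amplicons' list")
    amps = [_amplicon_from_mapping(a, i) for i, a in enumerate(doc["amplicons"])]
    return PanelConfig(
        amplicons=tuple(amps),
        name=str(doc.get("name", "unnamed")),
        version=str(doc.get("version", "0")),
    )


def read_panel_config(path: str | Path) -> PanelConfig:
    """Read and validate a YAML (or JSON) panel configuration."""
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ParseError(f"{path}: not valid YAML/JSON: {exc}") from exc
    try:
        return panel_from_mapping(doc)
    except ValidationError as exc:
        raise type(exc)(f"{path}: {exc}") from exc


def default_panel() -> PanelConfig:
    """The shipped four-locus panel (KCNQ1OT1, H19, SNRPN, MEG3 + references)."""
    text = (resources.files("imprintscan") / "data" /
            f"{DEFAULT_PANEL_NAME}.yaml").read_text(encoding="utf-8")
    return panel_from_mapping(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# Peak table I/O


_PEAK_COLUMNS = ("sample_id", "condition", "size", "area")


def _assign_amplicon(size: float, panel: PanelConfig,
                     sample_id: str) -> str | None:
    matches = [a for a in panel.amplicons
               if abs(size - a.expected_size) <= a.size_tolerance]
    if len(matches) > 1:
        raise AmbiguousPeakError(
            f"sample {sample_id}: peak size {size} falls inside the window of "
            f"multiple amplicons: {[a.name for a in matches]}")
    if not matches:
        logger.warning("sample %s: peak at %.2f bp not assigned to any "
                       "amplicon; excluded downstream", sample_id, size)
        return None
    return matches[0].name


def read_peak_table(path: str | Path, panel: PanelConfig) -> list[PeakRecord]:
    """Read a peak-table CSV and assign each peak to a panel amplicon.

    Required columns: ``sample_id,condition,size,area`` (``height`` and
    ``role`` optional).  A peak is assigned to the unique amplicon whose size
    window contains it; peaks matching no window are kept but flagged
    unassigned, peaks matching two windows raise :class:`AmbiguousPeakError`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"sample_id": str})
    except Exception as exc:
        raise ParseError(f"{path}: cannot read CSV: {exc}") from exc
    missing = [c for c in _PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")

    records: list[PeakRecord] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        try:
            condition = Condition(str(row.condition).strip().lower())
        except ValueError:
            raise ParseError(
                f"{path}, line {idx}: condition must be digested/undigested, "
                f"got {row.condition!r}") from None
        role = None
        if "role" in df.columns and isinstance(getattr(row, "role", None), str):
            try:
                role = Role(row.role.strip().lower())
            except ValueError:
                raise ParseError(
                    f"{path}, line {idx}: role must be control/patient, "
                    f"got {row.role!r}") from None
        size = float(row.size)
        height = None
        if "height" in df.columns and not pd.isna(getattr(row, "height")):
            height = float(row.height)
        records.append(PeakRecord(
            sample_id=str(row.sample_id),
            condition=condition,
            size=size,
            area=float(row.area),
            height=height,
            amplicon=_assign_amplicon(size, panel, str(row.sample_id)),
            role=role,
        ))
    return records


def write_peak_table(records: list[PeakRecord], path: str | Path) -> None:
    """Write peak records back to the canonical CSV layout."""
    rows = [{
        "sample_id": r.sample_id,
        "condition": r.condition.value,
        "size": r.size,
        "height": "" if r.height is None else r.height,
        "area": r.area,
        **({"role": r.role.value} if r.role is not None else {}),
    } for r in records]
    columns = ["sample_id", "condition", "size", "height", "area"]
    if any(r.role is not None for r in records):
        columns.append("role")
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def pair_runs(
    records: list[PeakRecord],
    panel: PanelConfig,
    controls: list[str] | set[str] | None = None,
) -> list[SamplePair]:
    """Pair digested/undigested runs into one :class:`SamplePair` per sample.

    Samples missing one condition are reported and dropped.  A second run of
    the same condition (the same amplicon observed twice for one
    sample/condition) raises :class:`DuplicateRunError` — there is no
    replicate-merging rule, so silent averaging is never performed.  Expected
    amplicons with no observed peak are stored as area 0 and flagged missing.
    """
    controls = set(controls or ())
    profiles: dict[str, dict[Condition, dict[str, float]]] = {}
    roles: dict[str, Role] = {}
    for r in records:
        if r.amplicon is None:
            continue
        per_sample = profiles.setdefault(r.sample_id, {})
        areas = per_sample.setdefault(r.condition, {})
        if r.amplicon in areas:
            raise DuplicateRunError(
                f"sample {r.sample_id}: duplicate {r.condition.value} "
                f"measurement for amplicon {r.amplicon}")
        areas[r.amplicon] = r.area
        if r.role is not None:
            roles[r.sample_id] = r.role

    panel_names = [a.name for a in panel.amplicons]
    pairs: list[SamplePair] = []
    for sample_id, per_condition in profiles.items():
        if set(per_condition) != {Condition.DIGESTED, Condition.UNDIGESTED}:
            have = ", ".join(sorted(c.value for c in per_condition))
            logger.warning("sample %s dropped: only %s run(s) present",
                           sample_id, have)
            continue
        missing: set[tuple[str, str]] = set()
        filled: dict[Condition, dict[str, float]] = {}
        for cond, areas in per_condition.items():
            full = {}
            for name in panel_names:
                if name in areas:
                    full[name] = areas[name]
                else:
                    full[name] = 0.0
                    missing.add((cond.value, name))
            filled[cond] = full
        # role priority: explicit controls list, then CSV role column
        role = Role.CONTROL if sample_id in controls else roles.get(
            sample_id, Role.PATIENT)
        pairs.append(SamplePair(
            sample_id=sample_id,
            digested=filled[Condition.DIGESTED],
            undigested=filled[Condition.UNDIGESTED],
            role=role,
            missing=frozenset(missing),
        ))
    return pairs


# ---------------------------------------------------------------------------
# Trio genotype I/O


_TRIO_COLUMNS = ("trio_id", "marker", "chrom", "mother", "father", "child")
_MISSING_TOKENS = {"", ".", "-", "nan", "na"}


def _parse_alleles(cell, who: str, marker: str, cap: int) -> tuple[str, ...]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return ()
    text = str(cell).strip()
    if text.lower() in _MISSING_TOKENS:
        return ()
    alleles = tuple(a.strip() for a in text.split("/") if a.strip())
    if len(alleles) > cap:
        raise ParseError(
            f"marker {marker}: {who} genotype {text!r} has more than "
            f"{cap} alleles")
    if len(alleles) == 1:
        alleles = (alleles[0], alleles[0])  # single entry = homozygous
    return alleles


def read_trio_genotypes(path: str | Path) -> list[TrioGenotype]:
    """Read a trio genotype CSV (``trio_id,marker,chrom,mother,father,child``).

    Alleles are slash-separated labels; missing genotypes are allowed and
    yield empty allele sets.  A parent with more than two alleles is a parse
    error; a child with three distinct alleles is kept and flagged triallelic
    (duplication evidence handled downstream).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:
        raise ParseError(f"{path}: cannot read CSV: {exc}") from exc
    missing = [c for c in _TRIO_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    out = []
    for row in df.itertuples(index=False):
        marker = str(row.marker)
        out.append(TrioGenotype(
            trio_id=str(row.trio_id),
            marker=marker,
            chrom=str(row.chrom),
            mother=_parse_alleles(row.mother, "mother", marker, 2),
            father=_parse_alleles(row.father, "father", marker, 2),
            child=_parse_alleles(row.child, "child", marker, 3),
        ))
    return out
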