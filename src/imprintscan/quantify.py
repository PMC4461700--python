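"""Relative-area quantification of methylation (M) and gene dosage (D).

The measurement chain: each peak area is divided by a per-sample denominator
(relative area), relative areas are normalized to the averaged relative areas
of a control cohort, and for every DMR amplicon the normalized value of the
digested aliquot is the methylation value M while the normalized value of the
undigested aliquot is the dosage value D.  On this scale a normal sample sits
at M = D = 1; a mosaic loss of methylation in a fraction c of cells gives
M = 1 - c, and a copy-number state (CN_mat, CN_pat) gives
D = (CN_mat + CN_pat) / 2.

Two denominator modes are provided.  ``ALL_PEAKS`` divides by the sum of all
assigned peak areas of the sample/condition (the historical spreadsheet
convention).  ``REFERENCE_ONLY`` divides by the summed area of the reference
amplicons only; because the references are unaffected by digestion, this makes
M exactly linear in the number of methylated copies and is the default for
quantification.  ALL_PEAKS shrinks its own denominator when DMR peaks shrink
and therefore biases M upward; it is retained for comparison.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import BaselineError, DegenerateDataError, ValidationError
from .panel_io import AmpliconKind, Condition, PanelConfig, SamplePair

FLAG_MISSING_PEAK = "MISSING_PEAK"
FLAG_LOW_CONTROL_N = "LOW_CONTROL_N"
FLAG_ZERO_DOSAGE = "ZERO_DOSAGE"

DEFAULT_MIN_CONTROLS = 5


class DenominatorMode(str, enum.Enum):
    ALL_PEAKS = "ALL_PEAKS"
    REFERENCE_ONLY = "REFERENCE_ONLY"


@dataclass(frozen=True)
class RelativeProfile:
    """Per-amplicon relative areas of one sample under one run condition."""

    sample_id: str
    condition: Condition
    rel: dict[str, float]
    denominator_mode: DenominatorMode
    missing: frozenset[str] = frozenset()


@dataclass(frozen=True)
class ControlBaseline:
    """Condition-specific averaged relative areas over the control cohort.

    ``means[condition][amplicon]`` is the arithmetic mean control relative
    area; ``cv`` holds the corresponding coefficients of variation
    (population SD / mean), recorded for QC.
    """

    means: dict[Condition, dict[str, float]]
    cv: dict[Condition, dict[str, float]]
    n_controls: int
    mode: DenominatorMode
    low_n: bool = False


@dataclass(frozen=True)
class LocusMeasurement:
    """Normalized methylation (M) and dosage (D) values of one DMR locus."""

    sample_id: str
    locus: str
    M: float
    D: float
    M_per_copy: float
    percent_loss: float
    percent_gain: float
    flags: frozenset[str] = frozenset()


def relative_areas(
    pair: SamplePair,
    panel: PanelConfig,
    mode: DenominatorMode = DenominatorMode.REFERENCE_ONLY,
) -> tuple[RelativeProfile, RelativeProfile]:
    """Relative peak areas of both conditions, computed independently.

    ALL_PEAKS: rel[a] = A[a] / sum of all assigned areas.
    REFERENCE_ONLY: rel[a] = A[a] / sum of reference-amplicon areas.
    Returns ``(digested, undigested)`` profiles.
    """
    mode = DenominatorMode(mode)
    ref_names = {a.name for a in panel.reference_amplicons}
    profiles = []
    for condition in (Condition.DIGESTED, Condition.UNDIGESTED):
        areas = pair.areas(condition)
        if mode is DenominatorMode.ALL_PEAKS:
            denom = sum(areas.values())
        else:
            denom = sum(v for k, v in areas.items() if k in ref_names)
        if denom <= 0:
            basis = ("all peaks" if mode is DenominatorMode.ALL_PEAKS
                     else "reference peaks")
            raise DegenerateDataError(
                f"sample {pair.sample_id}, {condition.value} run: total area "
                f"of {basis} is zero; sample cannot be quantified")
        rel = {k: v / denom for k, v in areas.items()}
        missing = frozenset(a for c, a in pair.missing if c == condition.value)
        profiles.append(RelativeProfile(
            sample_id=pair.sample_id,
            condition=condition,
            rel=rel,
            denominator_mode=mode,
            missing=missing,
        ))
    return profiles[0], profiles[1]


def build_baseline(
    controls: list[SamplePair],
    panel: PanelConfig,
    mode: DenominatorMode = DenominatorMode.REFERENCE_ONLY,
    min_controls: int = DEFAULT_MIN_CONTROLS,
    allow_low_n: bool = False,
) -> ControlBaseline:
    """Average control relative areas per condition and amplicon.

    Requires ``min_controls`` control pairs unless ``allow_low_n`` is set, in
    which case the LOW_CONTROL_N flag propagates to every downstream
    measurement.  An amplicon whose control mean is zero cannot normalize
    anything and raises :class:`BaselineError`.
    """
    low_n = len(controls) < min_controls
    if low_n and not allow_low_n:
        raise BaselineError(
            f"{len(controls)} control pair(s) provided but {min_controls} "
            "required (set allow_low_n to override)")
    if not controls:
        raise BaselineError("cannot build a baseline from zero controls")

    values: dict[Condition, dict[str, list[float]]] = {
        Condition.DIGESTED: {}, Condition.UNDIGESTED: {}}
    for pair in controls:
        dig, undig = relative_areas(pair, panel, mode)
        for profile in (dig, undig):
            for name, rel in profile.rel.items():
                values[profile.condition].setdefault(name, []).append(rel)

    means: dict[Condition, dict[str, float]] = {}
    cvs: dict[Condition, dict[str, float]] = {}
    for condition, per_amplicon in values.items():
        means[condition] = {}
        cvs[condition] = {}
        for name, xs in per_amplicon.items():
            arr = np.asarray(xs, dtype=float)
            mean = float(arr.mean())
            if mean <= 0:
                raise BaselineError(
                    f"control mean relative area for amplicon {name!r} "
                    f"({condition.value}) is zero; it cannot normalize")
            means[condition][name] = mean
            cvs[condition][name] = float(arr.std(ddof=0) / mean)
    return ControlBaseline(means=means, cv=cvs, n_controls=len(controls),
                           mode=mode, low_n=low_n)


def normalize(profile: RelativeProfile,
              baseline: ControlBaseline) -> dict[str, float]:
    """Divide relative areas by the control means of the same condition."""
    if profile.denominator_mode is not baseline.mode:
        raise ValidationError(
            f"profile computed in {profile.denominator_mode.value} mode but "
            f"baseline in {baseline.mode.value} mode")
    base = baseline.means[profile.condition]
    out = {}
    for name, rel in profile.rel.items():
        if name not in base:
            raise BaselineError(
                f"amplicon {name!r} absent from the control baseline")
        out[name] = rel / base[name]
    return out


def measure_loci(
    pair: SamplePair,
    baseline: ControlBaseline,
    panel: PanelConfig,
) -> list[LocusMeasurement]:
    """One (M, D) measurement per DMR locus of the panel.

    D is the normalized undigested value, M the normalized digested value.
    M is deliberately NOT dosage-corrected (M, not M/D, is compared with the
    normal range downstream); M_per_copy = M/D is reported alongside and set
    to 0 with a flag when D = 0, so complete deletions stay reportable.
    """
    dig, undig = relative_areas(pair, panel, baseline.mode)
    norm_dig = normalize(dig, baseline)
    norm_undig = normalize(undig, baseline)

    measurements = []
    for amplicon in panel.dmr_amplicons:
        m = norm_dig[amplicon.name]
        d = norm_undig[amplicon.name]
        flags = set()
        if amplicon.name in dig.missing or amplicon.name in undig.missing:
            flags.add(FLAG_MISSING_PEAK)
        if baseline.low_n:
            flags.add(FLAG_LOW_CONTROL_N)
        if d > 0:
            m_per_copy = m / d
        else:
            m_per_copy = 0.0
            flags.add(FLAG_ZERO_DOSAGE)
        measurements.append(LocusMeasurement(
            sample_id=pair.sample_id,
            locus=amplicon.locus,
            M=m,
            D=d,
            M_per_copy=m_per_copy,
            percent_loss=100.0 * (1.0 - m) if m < 1.0 else 0.0,
            percent_gain=100.0 * (m - 1.0) if m > 1.0 else 0.0,
            flags=frozenset(flags),
        ))
    return measurements


def control_leave_one_out(
    controls: list[SamplePair],
    panel: PanelConfig,
    mode: DenominatorMode = DenominatorMode.REFERENCE_ONLY,
    low: float = 0.8,
    high: float = 1.2,
) -> list[dict]:
    """QC: normalize each control against a baseline built from the others.

    Controls falling outside [low, high] at any locus are reported, never
    auto-excluded; the caller decides what to do with a drifting control.
    """
    findings = []
    if len(controls) < 2:
        return findings
    for i, pair in enumerate(controls):
        others = controls[:i] + controls[i + 1:]
        base = build_baseline(others, panel, mode, min_controls=1,
                              allow_low_n=True)
        for meas in measure_loci(pair, base, panel):
            outside = not (low <= meas.M <= high) or not (low <= meas.D <= high)
            if outside:
                findings.append({
                    "control_id": pair.sample_id,
                    "locus": meas.locus,
                    "M": meas.M,
                    "D": meas.D,
                })
    return findings
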