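"""Synthetic peak tables and trio genotypes with the assay's molecular structure.

The generator models the quantities the screen actually measures.  Each DMR
carries a parental-origin copy-number state (CN_mat, CN_pat) and per-allele
methylated fractions; only methylated copies survive the methylation-sensitive
digest, so the amplifiable template is

    undigested: CN_mat + CN_pat
    digested:   CN_mat * meth_mat + CN_pat * meth_pat
                + (1 - digestion_completeness) * unmethylated copies

Reference amplicons have no HpaII site and amplify from template 2 in both
aliquots.  Observed peak areas multiply the template by an amplicon-specific
efficiency, a per-sample loading factor, and multiplicative lognormal noise
(capillary peak areas are positive and scale-proportional; default sigma 0.05).
Loading and global efficiency rescalings cancel in the downstream statistic.

A mosaic epimutation demethylating the normally methylated allele in a
fraction c of cells is expressed as ``meth = 1 - c`` on that allele, giving a
pipeline methylation value M = 1 - c; the five published alteration archetypes
(partial LOM 80% and 40%, duplication-driven GOM, UPD(14)pat GOM, UPD(14)mat
complete LOM) ship as the ``table1_patient_specs`` fixture pack.

Trio genotypes are simulated from equifrequent marker alleles under
biparental inheritance, iso-/heterodisomy of either parent, or a triallelic
duplication (child with two distinct maternal alleles plus one paternal).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .panel_io import (
    AmpliconDef,
    AmpliconKind,
    Condition,
    PanelConfig,
    Parent,
    PeakRecord,
    Role,
    SamplePair,
    default_panel,
    write_peak_table,
)
from .upd_trio import TrioGenotype

REFERENCE_TEMPLATE = 2.0  # both parental copies, in both aliquots


@dataclass(frozen=True)
class EpigenotypeSpec:
    """Ground-truth molecular state of one DMR locus in one sample."""

    locus: str
    cn_maternal: int = 1
    cn_paternal: int = 1
    meth_maternal: float = 0.0
    meth_paternal: float = 0.0

    def __post_init__(self) -> None:
        if self.cn_maternal < 0 or self.cn_paternal < 0:
            raise ValidationError(f"{self.locus}: copy numbers must be >= 0")
        for frac in (self.meth_maternal, self.meth_paternal):
            if not 0.0 <= frac <= 1.0:
                raise ValidationError(
                    f"{self.locus}: methylated fractions must lie in [0, 1]")


def normal_epigenotype(amplicon: AmpliconDef) -> EpigenotypeSpec:
    """Biparental, fully methylated on the normally methylated parent."""
    mat = 1.0 if amplicon.methylated_parent is Parent.MATERNAL else 0.0
    pat = 1.0 if amplicon.methylated_parent is Parent.PATERNAL else 0.0
    return EpigenotypeSpec(locus=amplicon.locus,
                           meth_maternal=mat, meth_paternal=pat)


def mosaic_lom(amplicon: AmpliconDef, c: float) -> EpigenotypeSpec:
    """LOM of the normally methylated allele in a fraction ``c`` of cells."""
    spec = normal_epigenotype(amplicon)
    if amplicon.methylated_parent is Parent.MATERNAL:
        return EpigenotypeSpec(spec.locus, meth_maternal=1.0 - c,
                               meth_paternal=0.0)
    return EpigenotypeSpec(spec.locus, meth_maternal=0.0,
                           meth_paternal=1.0 - c)


@dataclass(frozen=True)
class SampleSpec:
    """Ground truth for one synthetic individual."""

    sample_id: str
    role: Role = Role.PATIENT
    epigenotypes: dict[str, EpigenotypeSpec] = field(default_factory=dict)
    loading_factor: float = 1.0
    noise_sigma: float = 0.0
    digestion_completeness: float = 1.0

    def __post_init__(self) -> None:
        if self.loading_factor <= 0:
            raise ValidationError("loading_factor must be positive")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if not 0.0 <= self.digestion_completeness <= 1.0:
            raise ValidationError("digestion_completeness must lie in [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    """A full simulated cohort; every draw derives from ``seed``."""

    specs: tuple[SampleSpec, ...]
    seed: int
    panel: PanelConfig
    amplicon_efficiencies: dict[str, float] = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return sum(1 for s in self.specs if s.role is Role.PATIENT)

    @property
    def n_controls(self) -> int:
        return sum(1 for s in self.specs if s.role is Role.CONTROL)


def expected_template(
    spec: EpigenotypeSpec,
    condition: Condition,
    digestion_completeness: float = 1.0,
) -> float:
    """Amplifiable copies of a DMR amplicon under one run condition.

    Only methylated copies resist the methylation-sensitive digest; with
    incomplete digestion a fraction of the unmethylated copies survives too.
    """
    total = float(spec.cn_maternal + spec.cn_paternal)
    if condition is Condition.UNDIGESTED:
        return total
    methylated = (spec.cn_maternal * spec.meth_maternal
                  + spec.cn_paternal * spec.meth_paternal)
    unmethylated = total - methylated
    return methylated + (1.0 - digestion_completeness) * unmethylated


def simulate_sample_pair(
    spec: SampleSpec,
    panel: PanelConfig,
    efficiencies: dict[str, float] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[SamplePair, list[PeakRecord]]:
    """Realize one digested/undigested pair of peak profiles.

    ``area = efficiency * template * loading_factor * LogNormal(0, sigma)``;
    with ``noise_sigma = 0`` the output is exactly deterministic.  Amplicons
    with zero template produce no peak record (the SamplePair stores area 0
    with a missing-peak flag), mirroring a fully digested unmethylated DMR.
    """
    efficiencies = efficiencies or {}
    if spec.noise_sigma > 0 and rng is None:
        raise ValidationError("noise_sigma > 0 requires an rng")

    areas: dict[Condition, dict[str, float]] = {}
    records: list[PeakRecord] = []
    missing: set[tuple[str, str]] = set()
    for condition in (Condition.DIGESTED, Condition.UNDIGESTED):
        per_amplicon: dict[str, float] = {}
        for amplicon in panel.amplicons:
            if amplicon.kind is AmpliconKind.REFERENCE:
                template = REFERENCE_TEMPLATE
            else:
                eg = spec.epigenotypes.get(amplicon.locus)
                if eg is None:
                    eg = normal_epigenotype(amplicon)
                template = expected_template(eg, condition,
                                             spec.digestion_completeness)
            area = (efficiencies.get(amplicon.name, 1.0) * template
                    * spec.loading_factor)
            if spec.noise_sigma > 0 and area > 0:
                area *= float(np.exp(rng.normal(0.0, spec.noise_sigma)))
            per_amplicon[amplicon.name] = area
            if area > 0:
                records.append(PeakRecord(
                    sample_id=spec.sample_id,
                    condition=condition,
                    size=float(amplicon.expected_size),
                    area=area,
                    height=None,
                    amplicon=amplicon.name,
                    role=spec.role,
                ))
            else:
                missing.add((condition.value, amplicon.name))
        areas[condition] = per_amplicon

    pair = SamplePair(
        sample_id=spec.sample_id,
        digested=areas[Condition.DIGESTED],
        undigested=areas[Condition.UNDIGESTED],
        role=spec.role,
        missing=frozenset(missing),
    )
    return pair, records


def _truth_rows(spec: SampleSpec, panel: PanelConfig) -> list[dict]:
    rows = []
    for amplicon in panel.dmr_amplicons:
        eg = spec.epigenotypes.get(amplicon.locus) or normal_epigenotype(amplicon)
        meth_on_imprinted = (eg.meth_maternal
                             if amplicon.methylated_parent is Parent.MATERNAL
                             else eg.meth_paternal)
        default = normal_epigenotype(amplicon)
        rows.append({
            "sample_id": spec.sample_id,
            "role": spec.role.value,
            "locus": amplicon.locus,
            "cn_maternal": eg.cn_maternal,
            "cn_paternal": eg.cn_paternal,
            "meth_maternal": eg.meth_maternal,
            "meth_paternal": eg.meth_paternal,
            "mosaic_loss_fraction": 1.0 - meth_on_imprinted,
            "altered": eg != default,
        })
    return rows


def simulate_cohort(
    cohort: CohortSpec,
    out_dir: str | Path | None = None,
) -> tuple[list[PeakRecord], pd.DataFrame]:
    """Simulate every sample of a cohort; deterministic given the seed.

    Returns the peak records and a truth table (one row per sample and DMR
    locus).  When ``out_dir`` is given, writes ``peaks.csv`` and ``truth.tsv``
    there; identical CohortSpecs produce byte-identical files.
    """
    rng = np.random.default_rng([int(cohort.seed), 1])
    records: list[PeakRecord] = []
    truth: list[dict] = []
    for spec in cohort.specs:
        _, recs = simulate_sample_pair(spec, cohort.panel,
                                       cohort.amplicon_efficiencies, rng)
        records.extend(recs)
        truth.extend(_truth_rows(spec, cohort.panel))
    truth_df = pd.DataFrame(
        truth, columns=["sample_id", "role", "locus", "cn_maternal",
                        "cn_paternal", "meth_maternal", "meth_paternal",
                        "mosaic_loss_fraction", "altered"])
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_peak_table(records, out_dir / "peaks.csv")
        truth_df.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return records, truth_df


# ---------------------------------------------------------------------------
# Published alteration archetypes and the screening-cohort scenario


def table1_patient_specs(
    panel: PanelConfig | None = None,
    noise_sigma: float = 0.0,
    id_prefix: str = "patient_",
) -> list[SampleSpec]:
    """The five alteration archetypes found by the published screen.

    1. 80% mosaic LOM at KCNQ1OT1 (epimutation), normal dosage.
    2. Paternal 11p15 duplication: H19 GOM with dosage gain, plus a
       KCNQ1OT1 dosage gain on the unmethylated (paternal) allele.
    3. 40% mosaic LOM at SNRPN (epimutation), normal dosage.
    4. UPD(14)pat: MEG3 GOM with normal dosage.
    5. UPD(14)mat: MEG3 complete LOM with normal dosage.
    """
    panel = panel or default_panel()
    kcnq = panel.amplicon_for_locus("KCNQ1OT1")
    h19 = panel.amplicon_for_locus("H19")
    snrpn = panel.amplicon_for_locus("SNRPN")
    meg3 = panel.amplicon_for_locus("MEG3")

    def sample(i: int, epigenotypes: dict[str, EpigenotypeSpec]) -> SampleSpec:
        return SampleSpec(sample_id=f"{id_prefix}{i}", role=Role.PATIENT,
                          epigenotypes=epigenotypes, noise_sigma=noise_sigma)

    return [
        sample(1, {"KCNQ1OT1": mosaic_lom(kcnq, 0.8)}),
        sample(2, {
            "H19": EpigenotypeSpec("H19", cn_maternal=1, cn_paternal=2,
                                   meth_maternal=0.0, meth_paternal=1.0),
            "KCNQ1OT1": EpigenotypeSpec("KCNQ1OT1", cn_maternal=1,
                                        cn_paternal=2, meth_maternal=1.0,
                                        meth_paternal=0.0),
        }),
        sample(3, {"SNRPN": mosaic_lom(snrpn, 0.4)}),
        sample(4, {"MEG3": EpigenotypeSpec("MEG3", cn_maternal=0,
                                           cn_paternal=2, meth_maternal=0.0,
                                           meth_paternal=1.0)}),
        sample(5, {"MEG3": EpigenotypeSpec("MEG3", cn_maternal=2,
                                           cn_paternal=0, meth_maternal=0.0,
                                           meth_paternal=1.0)}),
    ]


def screening_cohort(
    panel: PanelConfig | None = None,
    n_patients: int = 412,
    n_controls: int = 20,
    noise_sigma: float = 0.05,
    seed: int = 2015,
) -> CohortSpec:
    """The full screening scenario: published cohort size, five positives.

    The first five patients carry the alteration archetypes; the remaining
    patients and all controls are molecularly normal.  Per-sample loading
    factors and per-amplicon efficiencies are drawn once (lognormal, sigma
    0.3/0.5) so that the scale invariances of the statistic are exercised.
    """
    panel = panel or default_panel()
    if n_patients < 5:
        raise ValidationError("the scenario embeds 5 positives; "
                              "n_patients must be >= 5")
    rng = np.random.default_rng([int(seed), 0])
    efficiencies = {a.name: float(np.exp(rng.normal(0.0, 0.5)))
                    for a in panel.amplicons}

    def loading() -> float:
        return float(np.exp(rng.normal(0.0, 0.3)))

    specs: list[SampleSpec] = []
    for i in range(1, n_controls + 1):
        specs.append(SampleSpec(sample_id=f"control_{i:03d}",
                                role=Role.CONTROL, noise_sigma=noise_sigma,
                                loading_factor=loading()))
    archetypes = table1_patient_specs(panel, noise_sigma=noise_sigma)
    for base in archetypes:
        specs.append(SampleSpec(
            sample_id=base.sample_id, role=Role.PATIENT,
            epigenotypes=base.epigenotypes, noise_sigma=noise_sigma,
            loading_factor=loading()))
    for i in range(len(archetypes) + 1, n_patients + 1):
        specs.append(SampleSpec(sample_id=f"patient_{i}", role=Role.PATIENT,
                                noise_sigma=noise_sigma,
                                loading_factor=loading()))
    return CohortSpec(specs=tuple(specs), seed=seed, panel=panel,
                      amplicon_efficiencies=efficiencies)


# ---------------------------------------------------------------------------
# Trio simulation


class TrioScenario(str, enum.Enum):
    BIPARENTAL = "BIPARENTAL"
    UPD_MAT_ISO = "UPD_MAT_ISO"
    UPD_MAT_HET = "UPD_MAT_HET"
    UPD_PAT_ISO = "UPD_PAT_ISO"
    UPD_PAT_HET = "UPD_PAT_HET"
    DUP_TRIALLELIC = "DUP_TRIALLELIC"


def simulate_trio(
    scenario: TrioScenario | str,
    n_markers: int = 8,
    n_alleles: int = 4,
    seed: int | np.random.Generator = 0,
    trio_id: str = "trio_1",
    chrom: str = "14",
) -> list[TrioGenotype]:
    """Simulate one trio's microsatellite genotypes under a scenario.

    Parental genotypes are drawn from ``n_alleles`` equifrequent alleles per
    marker; the child is constructed per scenario.  For DUP_TRIALLELIC the
    child carries both maternal alleles plus one paternal allele — the marker
    only shows three distinct alleles where the parental genotypes permit.
    """
    if not isinstance(scenario, TrioScenario):
        scenario = TrioScenario(str(scenario).upper())
    if n_alleles < 2:
        raise ValidationError("n_alleles must be >= 2")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    alleles = [str(i) for i in range(1, n_alleles + 1)]
    out = []
    for i in range(1, n_markers + 1):
        mother = tuple(str(a) for a in rng.choice(alleles, size=2))
        father = tuple(str(a) for a in rng.choice(alleles, size=2))
        if scenario is TrioScenario.BIPARENTAL:
            child = (str(rng.choice(mother)), str(rng.choice(father)))
        elif scenario is TrioScenario.UPD_MAT_ISO:
            a = str(rng.choice(mother))
            child = (a, a)
        elif scenario is TrioScenario.UPD_MAT_HET:
            child = mother
        elif scenario is TrioScenario.UPD_PAT_ISO:
            a = str(rng.choice(father))
            child = (a, a)
        elif scenario is TrioScenario.UPD_PAT_HET:
            child = father
        else:  # DUP_TRIALLELIC: two maternal copies + one paternal
            child = (mother[0], mother[1], str(rng.choice(father)))
        out.append(TrioGenotype(
            trio_id=trio_id,
            marker=f"D{chrom}S{100 + i}",
            chrom=chrom,
            mother=mother,
            father=father,
            child=child,
        ))
    return out


def write_trio_table(genotypes: list[TrioGenotype], path: str | Path) -> None:
    """Write trio genotypes in the CSV layout read_trio_genotypes expects."""
    rows = [{
        "trio_id": g.trio_id,
        "marker": g.marker,
        "chrom": g.chrom,
        "mother": "/".join(g.mother),
        "father": "/".join(g.father),
        "child": "/".join(g.child),
    } for g in genotypes]
    pd.DataFrame(rows, columns=["trio_id", "marker", "chrom", "mother",
                                "father", "child"]).to_csv(path, index=False)
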