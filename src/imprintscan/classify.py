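"""Epigenotype classification and mechanism hypotheses.

Control-normalized values within 1 +/- 0.2 are considered normal; methylation
values below the range are partial loss of methylation (LOM), values at or
below ``complete_loss_max`` complete LOM, and values above the range gain of
methylation (GOM).  Dosage values are classed against the same range.

For each abnormal locus the classifier lists the molecular mechanisms that
could produce the observed (M, D) combination, using the parent-of-origin
methylation map of the panel: e.g. LOM at a maternally methylated DMR with
normal dosage is produced either by an epimutation or by paternal UPD, while
GOM with increased dosage points at a duplication of the methylated allele.
The hypothesis list is ordered by prior plausibility but never truncated;
discrimination requires the confirmation assays (MS-MLPA, microsatellite
segregation), which are emitted as a recommendation.  Trio segregation
results, when available, are reconciled afterwards: a biparental verdict
removes the UPD hypotheses, a matching UPD verdict confirms one.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace

from .errors import ChromosomeMismatchError, IncompleteScreenError, ValidationError
from .panel_io import AmpliconDef, PanelConfig, Parent
from .quantify import LocusMeasurement
from .upd_trio import UPDCall, UPDVerdict

#: MS-MLPA kits used to confirm screen positives at each locus.
MSMLPA_KITS = {
    "KCNQ1OT1": "SALSA ME030",
    "H19": "SALSA ME030",
    "SNRPN": "SALSA ME028",
}


class MethylationClass(str, enum.Enum):
    NORMAL = "NORMAL"
    PARTIAL_LOM = "PARTIAL_LOM"
    COMPLETE_LOM = "COMPLETE_LOM"
    GOM = "GOM"


class DosageClass(str, enum.Enum):
    NORMAL = "NORMAL"
    GAIN = "GAIN"
    LOSS = "LOSS"


class Mechanism(str, enum.Enum):
    EPIMUTATION = "EPIMUTATION"
    UPD_MATERNAL = "UPD_MATERNAL"
    UPD_PATERNAL = "UPD_PATERNAL"
    CNV_DUP_METHYLATED_ALLELE = "CNV_DUP_METHYLATED_ALLELE"
    CNV_DUP_UNMETHYLATED_ALLELE = "CNV_DUP_UNMETHYLATED_ALLELE"
    CNV_DEL = "CNV_DEL"


@dataclass(frozen=True)
class NormalRange:
    """The 1 +/- 0.2 normal band, inclusive at both ends."""

    low: float = 0.8
    high: float = 1.2
    complete_loss_max: float = 0.1

    def __post_init__(self) -> None:
        if not (0 <= self.complete_loss_max < self.low < 1 < self.high):
            raise ValidationError(
                "normal range requires 0 <= complete_loss_max < low < 1 < high"
                f" (got {self.complete_loss_max}, {self.low}, {self.high})")


@dataclass(frozen=True)
class MechanismHypothesis:
    mechanism: Mechanism
    syndrome: str = ""
    consistent_with_dosage: bool = True


@dataclass(frozen=True)
class EpigenotypeCall:
    """Per-locus epigenotype with mechanism hypotheses and follow-up advice."""

    sample_id: str
    locus: str
    chrom_band: str
    M: float
    D: float
    methylation_class: MethylationClass
    dosage_class: DosageClass
    mechanisms: tuple[MechanismHypothesis, ...] = ()
    confirmed_mechanism: str = ""
    recommendation: str = ""
    multilocus_candidate: bool = False

    @property
    def abnormal_methylation(self) -> bool:
        return self.methylation_class is not MethylationClass.NORMAL

    @property
    def abnormal(self) -> bool:
        return (self.methylation_class is not MethylationClass.NORMAL
                or self.dosage_class is not DosageClass.NORMAL)


@dataclass(frozen=True)
class SampleSummary:
    sample_id: str
    positive: bool
    abnormal_loci: tuple[str, ...]
    multilocus_candidate: bool


def _upd_of(parent: Parent) -> Mechanism:
    return (Mechanism.UPD_MATERNAL if parent is Parent.MATERNAL
            else Mechanism.UPD_PATERNAL)


def _other(parent: Parent) -> Parent:
    return Parent.PATERNAL if parent is Parent.MATERNAL else Parent.MATERNAL


def _recommendation(amplicon: AmpliconDef) -> str:
    kit = MSMLPA_KITS.get(amplicon.locus, "")
    msmlpa = f"MS-MLPA ({kit})" if kit else "MS-MLPA"
    return (f"confirm with {msmlpa} and microsatellite segregation analysis "
            f"of the parental trio at {amplicon.chrom_band or amplicon.locus}")


def classify_locus(
    meas: LocusMeasurement,
    amplicon: AmpliconDef,
    normal_range: NormalRange = NormalRange(),
) -> EpigenotypeCall:
    """Classify one locus measurement and derive mechanism hypotheses."""
    if meas.locus != amplicon.locus:
        raise ValidationError(
            f"measurement locus {meas.locus!r} does not match amplicon locus "
            f"{amplicon.locus!r}")
    r = normal_range
    m, d = meas.M, meas.D

    if r.low <= m <= r.high:
        meth = MethylationClass.NORMAL
    elif m > r.high:
        meth = MethylationClass.GOM
    elif m <= r.complete_loss_max:
        meth = MethylationClass.COMPLETE_LOM
    else:
        meth = MethylationClass.PARTIAL_LOM

    if r.low <= d <= r.high:
        dose = DosageClass.NORMAL
    elif d > r.high:
        dose = DosageClass.GAIN
    else:
        dose = DosageClass.LOSS

    lom = meth in (MethylationClass.PARTIAL_LOM, MethylationClass.COMPLETE_LOM)
    gom = meth is MethylationClass.GOM
    hypo_syn = amplicon.hypo_syndrome
    hyper_syn = amplicon.hyper_syndrome
    parent = amplicon.methylated_parent

    mechanisms: list[MechanismHypothesis] = []

    def hyp(mech: Mechanism, syndrome: str, wants: DosageClass) -> MechanismHypothesis:
        return MechanismHypothesis(mech, syndrome, consistent_with_dosage=dose is wants)

    if dose is DosageClass.LOSS:
        mechanisms = [hyp(Mechanism.CNV_DEL,
                          hypo_syn if lom else "", DosageClass.LOSS)]
    elif dose is DosageClass.GAIN:
        if gom:
            mechanisms = [hyp(Mechanism.CNV_DUP_METHYLATED_ALLELE, hyper_syn,
                              DosageClass.GAIN)]
        else:
            mechanisms = [hyp(Mechanism.CNV_DUP_UNMETHYLATED_ALLELE,
                              hypo_syn if lom else "", DosageClass.GAIN)]
    else:  # normal dosage
        if lom:
            epi = hyp(Mechanism.EPIMUTATION, hypo_syn, DosageClass.NORMAL)
            upd = hyp(_upd_of(_other(parent)), hypo_syn, DosageClass.NORMAL)
            # a complete loss is more often whole-tissue (UPD) than mosaic
            mechanisms = ([upd, epi] if meth is MethylationClass.COMPLETE_LOM
                          else [epi, upd])
        elif gom:
            mechanisms = [hyp(_upd_of(parent), hyper_syn, DosageClass.NORMAL),
                          hyp(Mechanism.EPIMUTATION, hyper_syn,
                              DosageClass.NORMAL)]

    abnormal = meth is not MethylationClass.NORMAL or dose is not DosageClass.NORMAL
    return EpigenotypeCall(
        sample_id=meas.sample_id,
        locus=meas.locus,
        chrom_band=amplicon.chrom_band,
        M=m,
        D=d,
        methylation_class=meth,
        dosage_class=dose,
        mechanisms=tuple(mechanisms),
        recommendation=_recommendation(amplicon) if abnormal else "",
    )


def screen_sample(
    measurements: list[LocusMeasurement],
    panel: PanelConfig,
    normal_range: NormalRange = NormalRange(),
) -> tuple[list[EpigenotypeCall], SampleSummary]:
    """Classify every panel locus of one sample and summarize.

    The screen follows the published decision rule: a sample is POSITIVE when
    the methylation value of any locus leaves the normal range, and a
    multilocus-methylation-defect candidate when two or more loci do.  Dosage
    abnormalities are reported on the calls (and trigger the confirmation
    recommendation) but do not by themselves flag the screen.
    """
    by_locus = {m.locus: m for m in measurements}
    panel_loci = [a.locus for a in panel.dmr_amplicons]
    missing = [loc for loc in panel_loci if loc not in by_locus]
    if missing:
        sample = measurements[0].sample_id if measurements else "?"
        raise IncompleteScreenError(
            f"sample {sample}: no measurement for panel loci {missing}")

    calls = [classify_locus(by_locus[a.locus], a, normal_range)
             for a in panel.dmr_amplicons]
    abnormal_meth = tuple(c.locus for c in calls if c.abnormal_methylation)
    multilocus = len(abnormal_meth) >= 2
    calls = [replace(c, multilocus_candidate=multilocus) for c in calls]
    sample_id = calls[0].sample_id
    summary = SampleSummary(
        sample_id=sample_id,
        positive=bool(abnormal_meth),
        abnormal_loci=abnormal_meth,
        multilocus_candidate=multilocus,
    )
    return calls, summary


_CHROM_RE = re.compile(r"^(?:chr)?(\d{1,2}|[XY])", re.IGNORECASE)


def _chrom_of(text: str) -> str:
    match = _CHROM_RE.match(text.strip())
    if not match:
        raise ValidationError(f"cannot extract a chromosome from {text!r}")
    return match.group(1).upper()


def reconcile_with_upd(call: EpigenotypeCall,
                       upd: UPDCall | None) -> EpigenotypeCall:
    """Fold a trio segregation verdict into the mechanism hypotheses.

    The methylation screen is evaluated blind; this step runs afterwards and
    only touches the mechanism list and confirmation status.  A BIPARENTAL
    verdict excludes the UPD hypotheses (promoting epimutation when listed);
    a UPD verdict matching a listed hypothesis confirms it and demotes the
    rest.  Everything else (inconclusive/inconsistent trios, normal calls)
    leaves the call unchanged.
    """
    if upd is None:
        return call
    if _chrom_of(call.chrom_band) != _chrom_of(upd.chrom):
        raise ChromosomeMismatchError(
            f"UPD call for chromosome {upd.chrom} applied to locus "
            f"{call.locus} ({call.chrom_band})")
    if not call.mechanisms:
        return call

    upd_mechs = {Mechanism.UPD_MATERNAL, Mechanism.UPD_PATERNAL}
    if upd.verdict is UPDVerdict.BIPARENTAL:
        kept = tuple(h for h in call.mechanisms if h.mechanism not in upd_mechs)
        if not kept:
            return replace(call, mechanisms=(), confirmed_mechanism="")
        confirmed = ""
        if len(kept) == 1 or kept[0].mechanism is Mechanism.EPIMUTATION:
            confirmed = f"{kept[0].mechanism.value} (UPD excluded by segregation)"
        return replace(call, mechanisms=kept, confirmed_mechanism=confirmed)

    verdict_mech = {
        UPDVerdict.UPD_MATERNAL: Mechanism.UPD_MATERNAL,
        UPDVerdict.UPD_PATERNAL: Mechanism.UPD_PATERNAL,
    }.get(upd.verdict)
    if verdict_mech is None:  # INCONCLUSIVE / INCONSISTENT: nothing to fold in
        return call
    matching = [h for h in call.mechanisms if h.mechanism is verdict_mech]
    if not matching:
        return call
    others = [h for h in call.mechanisms if h.mechanism is not verdict_mech]
    return replace(
        call,
        mechanisms=tuple(matching + others),
        confirmed_mechanism=(f"{verdict_mech.value} "
                             f"({upd.disomy_type.value.lower()}, "
                             f"{upd.n_supporting} supporting markers)"),
    )
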