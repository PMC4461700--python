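"""Trio microsatellite segregation analysis for uniparental disomy (UPD).

A child normally inherits one allele of each marker from each parent.  Under
UPD both homologues come from a single parent: isodisomy duplicates one
homologue (the child is homozygous at informative markers), heterodisomy
transmits both homologues of that parent.  Per-marker classification here is
done by *explanation enumeration*: a marker only supports a single-parent
verdict when a biparental transmission cannot explain the child's genotype,
and it is uninformative whenever both kinds of explanation coexist.

A child carrying three distinct alleles indicates a duplication; such markers
are reported separately (``TRIALLELIC``) and never counted as UPD support.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field, replace

from .errors import ValidationError


class MarkerVerdict(str, enum.Enum):
    BIPARENTAL = "BIPARENTAL"
    MATERNAL_ONLY = "MATERNAL_ONLY"
    PATERNAL_ONLY = "PATERNAL_ONLY"
    UNINFORMATIVE = "UNINFORMATIVE"
    MENDELIAN_ERROR = "MENDELIAN_ERROR"
    TRIALLELIC = "TRIALLELIC"


class Zygosity(str, enum.Enum):
    ISO = "ISO"
    HETERO = "HETERO"
    NA = "NA"


class UPDVerdict(str, enum.Enum):
    BIPARENTAL = "BIPARENTAL"
    UPD_MATERNAL = "UPD_MATERNAL"
    UPD_PATERNAL = "UPD_PATERNAL"
    INCONCLUSIVE = "INCONCLUSIVE"
    INCONSISTENT = "INCONSISTENT"


class DisomyType(str, enum.Enum):
    ISODISOMY = "ISODISOMY"
    HETERODISOMY = "HETERODISOMY"
    MIXED = "MIXED"
    NA = "NA"


@dataclass(frozen=True)
class TrioGenotype:
    """Genotypes of mother, father and child at one microsatellite marker.

    Alleles are unordered label multisets (repeat-size labels compared by
    string equality).  Parents carry at most two alleles; a child may carry
    three when a duplication is present.  Empty tuples denote a missing
    genotype.
    """

    trio_id: str
    marker: str
    chrom: str
    mother: tuple[str, ...]
    father: tuple[str, ...]
    child: tuple[str, ...]

    def __post_init__(self) -> None:
        for who, alleles, cap in (
            ("mother", self.mother, 2),
            ("father", self.father, 2),
            ("child", self.child, 3),
        ):
            if len(alleles) > cap:
                raise ValidationError(
                    f"marker {self.marker}: {who} has {len(alleles)} alleles "
                    f"(at most {cap} allowed)"
                )
        object.__setattr__(self, "mother", tuple(sorted(self.mother)))
        object.__setattr__(self, "father", tuple(sorted(self.father)))
        object.__setattr__(self, "child", tuple(sorted(self.child)))

    @property
    def child_triallelic(self) -> bool:
        return len(set(self.child)) == 3


@dataclass(frozen=True)
class MarkerCall:
    marker: str
    verdict: MarkerVerdict
    zygosity_evidence: Zygosity = Zygosity.NA
    detail: str = ""


@dataclass(frozen=True)
class UPDCall:
    """Aggregate segregation verdict for one trio on one chromosome."""

    trio_id: str
    chrom: str
    verdict: UPDVerdict
    disomy_type: DisomyType
    n_informative: int
    n_supporting: int
    marker_calls: tuple[MarkerCall, ...] = field(default_factory=tuple)


def _as_pair(alleles: tuple[str, ...]) -> tuple[str, str]:
    """A one-allele genotype is treated as homozygous."""
    if len(alleles) == 1:
        return (alleles[0], alleles[0])
    return (alleles[0], alleles[1])


def _triallelic_detail(g: TrioGenotype) -> str:
    mother, father = set(g.mother), set(g.father)
    m_only = [a for a in g.child if a in mother and a not in father]
    p_only = [a for a in g.child if a in father and a not in mother]
    shared = [a for a in g.child if a in father and a in mother]
    alien = [a for a in g.child if a not in father and a not in mother]
    if alien:
        return f"allele(s) {','.join(alien)} absent from both parents"
    if not shared:
        return f"{len(m_only)} maternal + {len(p_only)} paternal alleles"
    return "parental origin not fully phaseable"


def classify_marker(g: TrioGenotype) -> MarkerCall:
    """Classify one marker by enumerating the transmissions that explain it.

    Explanations considered: biparental (one allele from each parent),
    maternal disomy (iso: one maternal homologue twice; hetero: both maternal
    homologues) and the symmetric paternal disomy.  A marker is decisive only
    when exactly one family of explanations survives.
    """
    if not g.mother or not g.father or not g.child:
        return MarkerCall(g.marker, MarkerVerdict.UNINFORMATIVE,
                          detail="missing genotype")
    if g.child_triallelic:
        return MarkerCall(g.marker, MarkerVerdict.TRIALLELIC,
                          detail=_triallelic_detail(g))
    if len(g.child) == 3:
        # three entries, two distinct: a duplication without a third allele
        # label; not phaseable as a disomy pattern.
        return MarkerCall(g.marker, MarkerVerdict.UNINFORMATIVE,
                          detail="three alleles, only two distinct")

    mother, father = set(g.mother), set(g.father)
    x, y = _as_pair(g.child)

    biparental = (x in mother and y in father) or (y in mother and x in father)
    if x == y:
        maternal = x in mother
        paternal = x in father
    else:
        maternal = x in mother and y in mother
        paternal = x in father and y in father

    if not (biparental or maternal or paternal):
        return MarkerCall(g.marker, MarkerVerdict.MENDELIAN_ERROR,
                          detail="no transmission explains the child genotype")
    if biparental and not maternal and not paternal:
        return MarkerCall(g.marker, MarkerVerdict.BIPARENTAL)
    if maternal and not biparental and not paternal:
        zyg = Zygosity.ISO if x == y else Zygosity.HETERO
        return MarkerCall(g.marker, MarkerVerdict.MATERNAL_ONLY, zyg)
    if paternal and not biparental and not maternal:
        zyg = Zygosity.ISO if x == y else Zygosity.HETERO
        return MarkerCall(g.marker, MarkerVerdict.PATERNAL_ONLY, zyg)
    # Both a biparental and a single-parent explanation coexist.
    return MarkerCall(g.marker, MarkerVerdict.UNINFORMATIVE,
                      detail="biparental and disomic explanations coexist")


def call_upd(
    calls: list[MarkerCall] | tuple[MarkerCall, ...],
    trio_id: str = "",
    chrom: str = "",
    min_supporting: int = 3,
    max_mendelian_errors: int = 0,
) -> UPDCall:
    """Aggregate per-marker calls into a chromosome-level UPD verdict.

    A UPD verdict requires ``min_supporting`` concordant single-parent-only
    markers and not a single opposite-parent-only marker; any Mendelian-error
    excess (tolerance ``max_mendelian_errors``, default 0) or the presence of
    both maternal-only and paternal-only markers is ``INCONSISTENT``.
    Triallelic markers are duplication evidence and never count as support.
    """
    if not calls:
        raise ValidationError("call_upd requires at least one marker call")
    tally = Counter(c.verdict for c in calls)
    n_mat = tally[MarkerVerdict.MATERNAL_ONLY]
    n_pat = tally[MarkerVerdict.PATERNAL_ONLY]
    n_bip = tally[MarkerVerdict.BIPARENTAL]
    n_err = tally[MarkerVerdict.MENDELIAN_ERROR]
    n_informative = n_mat + n_pat + n_bip

    verdict = UPDVerdict.INCONCLUSIVE
    n_supporting = 0
    if n_err > max_mendelian_errors or (n_mat > 0 and n_pat > 0):
        verdict = UPDVerdict.INCONSISTENT
    elif n_mat >= min_supporting and n_pat == 0:
        verdict, n_supporting = UPDVerdict.UPD_MATERNAL, n_mat
    elif n_pat >= min_supporting and n_mat == 0:
        verdict, n_supporting = UPDVerdict.UPD_PATERNAL, n_pat
    elif n_bip >= min_supporting and n_mat == 0 and n_pat == 0:
        verdict, n_supporting = UPDVerdict.BIPARENTAL, n_bip

    disomy = DisomyType.NA
    if verdict in (UPDVerdict.UPD_MATERNAL, UPDVerdict.UPD_PATERNAL):
        want = (MarkerVerdict.MATERNAL_ONLY
                if verdict is UPDVerdict.UPD_MATERNAL
                else MarkerVerdict.PATERNAL_ONLY)
        zygs = {c.zygosity_evidence for c in calls if c.verdict is want}
        if zygs == {Zygosity.ISO}:
            disomy = DisomyType.ISODISOMY
        elif zygs == {Zygosity.HETERO}:
            disomy = DisomyType.HETERODISOMY
        else:
            disomy = DisomyType.MIXED

    return UPDCall(
        trio_id=trio_id,
        chrom=chrom,
        verdict=verdict,
        disomy_type=disomy,
        n_informative=n_informative,
        n_supporting=n_supporting,
        marker_calls=tuple(calls),
    )


def analyze_trios(
    genotypes: list[TrioGenotype],
    min_supporting: int = 3,
    max_mendelian_errors: int = 0,
) -> list[UPDCall]:
    """Group genotypes by (trio, chromosome) and call UPD for each group."""
    groups: dict[tuple[str, str], list[TrioGenotype]] = {}
    for g in genotypes:
        groups.setdefault((g.trio_id, g.chrom), []).append(g)
    out = []
    for (trio_id, chrom), gs in groups.items():
        calls = [classify_marker(g) for g in gs]
        out.append(call_upd(calls, trio_id=trio_id, chrom=chrom,
                            min_supporting=min_supporting,
                            max_mendelian_errors=max_mendelian_errors))
    return out


def swap_parents(g: TrioGenotype) -> TrioGenotype:
    """Exchange maternal and paternal genotypes (symmetry checks)."""
    return replace(g, mother=g.father, father=g.mother)
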