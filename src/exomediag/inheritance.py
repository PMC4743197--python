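"""Sequential Mendelian inheritance models applied per family.

The models are evaluated in the order autosomal recessive (homozygous,
then compound heterozygous), autosomal dominant, X-linked; all candidates
are returned in that priority order and downstream causality
classification decides among them.

Genotype semantics: a pedigree member is *genotyped* at a variant when a
call other than ``no_call`` is present for it; missing genotypes are never
treated as reference. Mitochondrial and Y variants are outside model scope.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from typing import Iterable

from .types import (
    AnnotatedVariant,
    CARRIER_GENOTYPES,
    Genotype,
    Individual,
    Pedigree,
    Sex,
)


class ModelType(str, enum.Enum):
    AR_HOM = "AR_hom"
    AR_COMPHET = "AR_comphet"
    AD = "AD"
    XL = "XL"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Evaluation priority: recessive models first, then dominant, then X-linked.
MODEL_PRIORITY = {
    ModelType.AR_HOM: 0,
    ModelType.AR_COMPHET: 1,
    ModelType.AD: 2,
    ModelType.XL: 3,
}


class DeNovoStatus(str, enum.Enum):
    CONFIRMED = "confirmed"
    PROBABLE = "probable"
    UNKNOWN = "unknown"
    INHERITED = "inherited"
    NOT_ASSESSED = "not_assessed"


@dataclass
class ModelCandidate:
    """A variant (or same-gene variant pair) satisfying one inheritance
    model in one family."""

    family_id: str
    model: ModelType
    variants: tuple[AnnotatedVariant, ...]
    de_novo_status: DeNovoStatus = DeNovoStatus.NOT_ASSESSED
    phase_unknown: bool = False
    down_ranked: bool = False
    fallback: bool = False
    segregation_notes: str = ""

    def __post_init__(self) -> None:
        genes = {v.gene for v in self.variants}
        if len(genes) != 1:
            raise ValueError("all variants of a candidate must share one gene")
        n_expected = 2 if self.model is ModelType.AR_COMPHET else 1
        if len(self.variants) != n_expected:
            raise ValueError(
                f"{self.model} candidate needs {n_expected} variant(s)"
            )

    @property
    def gene(self) -> str:
        return self.variants[0].gene

    @property
    def variant_keys(self) -> tuple:
        return tuple(v.key for v in self.variants)

    def sort_key(self) -> tuple:
        return (MODEL_PRIORITY[self.model], self.gene, self.variant_keys)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _is_genotyped(variant: AnnotatedVariant, sample: str) -> bool:
    return variant.genotype(sample) is not Genotype.NO_CALL


def _carries(variant: AnnotatedVariant, sample: str) -> bool | None:
    """Whether ``sample`` carries the ALT allele; None when not genotyped."""
    gt = variant.genotype(sample)
    if gt is Genotype.NO_CALL:
        return None
    return gt in CARRIER_GENOTYPES


def _parents_of_affecteds(pedigree: Pedigree) -> tuple[Individual | None, Individual | None]:
    """Father and mother of the first affected member that has parent links."""
    for affected in pedigree.affected_members():
        father = pedigree.father_of(affected.individual_id)
        mother = pedigree.mother_of(affected.individual_id)
        if father is not None or mother is not None:
            return father, mother
    return None, None


def _notes(variant: AnnotatedVariant, members: Iterable[Individual]) -> str:
    parts = []
    for m in members:
        gt = variant.genotype(m.individual_id)
        if gt is not Genotype.NO_CALL:
            parts.append(f"{m.individual_id}:{gt.value}")
    return ";".join(parts)


def _de_novo_status(
    variant: AnnotatedVariant, pedigree: Pedigree
) -> DeNovoStatus:
    """De novo assessment over the affected members' parents.

    Priority: an affected carrier parent makes the variant inherited; both
    parents reference-genotyped makes it confirmed de novo; one parent
    reference and the other untested makes it probable; anything else is
    unknown.
    """
    best = DeNovoStatus.UNKNOWN
    order = {
        DeNovoStatus.INHERITED: 0,
        DeNovoStatus.CONFIRMED: 1,
        DeNovoStatus.PROBABLE: 2,
        DeNovoStatus.UNKNOWN: 3,
    }
    for affected in pedigree.affected_members():
        father = pedigree.father_of(affected.individual_id)
        mother = pedigree.mother_of(affected.individual_id)
        statuses = []
        inherited = False
        for parent in (father, mother):
            if parent is None:
                statuses.append(None)
                continue
            carries = _carries(variant, parent.individual_id)
            statuses.append(carries)
            if carries and parent.affected:
                inherited = True
        if inherited:
            status = DeNovoStatus.INHERITED
        elif statuses == [False, False]:
            status = DeNovoStatus.CONFIRMED
        elif False in statuses and None in statuses:
            status = DeNovoStatus.PROBABLE
        else:
            status = DeNovoStatus.UNKNOWN
        if order[status] < order[best]:
            best = status
    return best


# ---------------------------------------------------------------------------
# autosomal recessive
# ---------------------------------------------------------------------------


def _ar_hom_fits(variant: AnnotatedVariant, pedigree: Pedigree) -> bool:
    if not variant.is_autosomal:
        return False
    affected = pedigree.affected_members()
    if not affected:
        return False
    if any(
        variant.genotype(a.individual_id) is not Genotype.HOM_ALT for a in affected
    ):
        return False
    # each genotyped parent of an affected must be an obligate het carrier
    for a in affected:
        for parent in (
            pedigree.father_of(a.individual_id),
            pedigree.mother_of(a.individual_id),
        ):
            if parent is None:
                continue
            gt = variant.genotype(parent.individual_id)
            if gt is not Genotype.NO_CALL and gt is not Genotype.HET:
                return False
    # no genotyped unaffected member may be homozygous for the allele
    return all(
        variant.genotype(u.individual_id) is not Genotype.HOM_ALT
        for u in pedigree.unaffected_members()
    )


def _comphet_pair_fits(
    v1: AnnotatedVariant, v2: AnnotatedVariant, pedigree: Pedigree
) -> tuple[bool, bool]:
    """Whether a same-gene het pair fits compound heterozygosity.

    Returns (fits, phase_unknown). With both parents genotyped at both
    sites, a trans configuration must be possible: one variant carried by
    each parent under some assignment. Otherwise the pair qualifies with
    the phase flagged unknown.
    """
    affected = pedigree.affected_members()
    if not affected:
        return False, False
    for a in affected:
        if (
            v1.genotype(a.individual_id) is not Genotype.HET
            or v2.genotype(a.individual_id) is not Genotype.HET
        ):
            return False, False
    # an unaffected member carrying both alleles contradicts the model
    for u in pedigree.unaffected_members():
        if _carries(v1, u.individual_id) and _carries(v2, u.individual_id):
            return False, False
    father, mother = _parents_of_affecteds(pedigree)
    statuses = []
    for parent in (father, mother):
        if parent is None:
            statuses.append((None, None))
        else:
            statuses.append(
                (
                    _carries(v1, parent.individual_id),
                    _carries(v2, parent.individual_id),
                )
            )
    (f1, f2), (m1, m2) = statuses
    if None not in (f1, f2, m1, m2):
        trans = (f1 and m2) or (f2 and m1)
        return bool(trans), False
    return True, True


def candidates_recessive(
    variants: Iterable[AnnotatedVariant], pedigree: Pedigree
) -> list[ModelCandidate]:
    """Autosomal recessive candidates: homozygous, then compound het."""
    variants = list(variants)
    family_id = _family_id(pedigree)
    out: list[ModelCandidate] = []
    members = pedigree.members()

    for v in variants:
        if _ar_hom_fits(v, pedigree):
            out.append(
                ModelCandidate(
                    family_id=family_id,
                    model=ModelType.AR_HOM,
                    variants=(v,),
                    segregation_notes=_notes(v, members),
                )
            )

    affected = pedigree.affected_members()
    by_gene: dict[str, list[AnnotatedVariant]] = {}
    for v in variants:
        if not v.is_autosomal or not v.gene:
            continue
        if affected and all(
            v.genotype(a.individual_id) is Genotype.HET for a in affected
        ):
            by_gene.setdefault(v.gene, []).append(v)
    for gene in sorted(by_gene):
        gene_variants = sorted(by_gene[gene], key=lambda v: v.key)
        for v1, v2 in itertools.combinations(gene_variants, 2):
            fits, phase_unknown = _comphet_pair_fits(v1, v2, pedigree)
            if fits:
                out.append(
                    ModelCandidate(
                        family_id=family_id,
                        model=ModelType.AR_COMPHET,
                        variants=(v1, v2),
                        phase_unknown=phase_unknown,
                        segregation_notes=(
                            _notes(v1, members) + "|" + _notes(v2, members)
                        ),
                    )
                )
    out.sort(key=ModelCandidate.sort_key)
    return out


# ---------------------------------------------------------------------------
# autosomal dominant
# ---------------------------------------------------------------------------


def _ad_fits(variant: AnnotatedVariant, pedigree: Pedigree) -> tuple[bool, bool]:
    """(fits, down_ranked): het (or hom, down-ranked) in every affected,
    absent from every genotyped unaffected member."""
    if not variant.is_autosomal:
        return False, False
    affected = pedigree.affected_members()
    if not affected:
        return False, False
    down_ranked = False
    for a in affected:
        gt = variant.genotype(a.individual_id)
        if gt is Genotype.HOM_ALT:
            down_ranked = True
        elif gt is not Genotype.HET:
            return False, False
    for u in pedigree.unaffected_members():
        if _carries(variant, u.individual_id):
            return False, False
    return True, down_ranked


def candidates_dominant(
    variants: Iterable[AnnotatedVariant], pedigree: Pedigree
) -> list[ModelCandidate]:
    family_id = _family_id(pedigree)
    members = pedigree.members()
    out = []
    for v in variants:
        fits, down_ranked = _ad_fits(v, pedigree)
        if fits:
            out.append(
                ModelCandidate(
                    family_id=family_id,
                    model=ModelType.AD,
                    variants=(v,),
                    de_novo_status=_de_novo_status(v, pedigree),
                    down_ranked=down_ranked,
                    segregation_notes=_notes(v, members),
                )
            )
    out.sort(key=ModelCandidate.sort_key)
    return out


# ---------------------------------------------------------------------------
# X-linked
# ---------------------------------------------------------------------------


def _xl_fits(variant: AnnotatedVariant, pedigree: Pedigree) -> bool:
    if not variant.is_x:
        return False
    affected = pedigree.affected_members()
    if not affected:
        return False
    for a in affected:
        gt = variant.genotype(a.individual_id)
        if a.sex is Sex.MALE:
            if gt is not Genotype.HEMI:
                return False
        else:
            if gt not in (Genotype.HET, Genotype.HOM_ALT):
                return False
    for u in pedigree.unaffected_members():
        gt = variant.genotype(u.individual_id)
        if u.sex is Sex.MALE and gt is Genotype.HEMI:
            return False
        if u.sex is Sex.FEMALE and gt is Genotype.HOM_ALT:
            return False
    return True


def candidates_xlinked(
    variants: Iterable[AnnotatedVariant], pedigree: Pedigree
) -> list[ModelCandidate]:
    family_id = _family_id(pedigree)
    members = pedigree.members()
    out = []
    for v in variants:
        if _xl_fits(v, pedigree):
            out.append(
                ModelCandidate(
                    family_id=family_id,
                    model=ModelType.XL,
                    variants=(v,),
                    de_novo_status=_de_novo_status(v, pedigree),
                    segregation_notes=_notes(v, members),
                )
            )
    out.sort(key=ModelCandidate.sort_key)
    return out


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def _family_id(pedigree: Pedigree) -> str:
    fids = pedigree.family_ids
    if len(fids) != 1:
        raise ValueError(
            "inheritance models operate on a single family; got "
            + ", ".join(fids)
        )
    return fids[0]


def apply_sequential_models(
    variants: Iterable[AnnotatedVariant],
    pedigree: Pedigree,
    fallback: bool = False,
) -> list[ModelCandidate]:
    """Evaluate all models and return candidates in priority order
    (recessive first, then dominant, then X-linked). No model suppresses
    another; causality classification ranks the survivors."""
    variants = list(variants)
    candidates = (
        candidates_recessive(variants, pedigree)
        + candidates_dominant(variants, pedigree)
        + candidates_xlinked(variants, pedigree)
    )
    if fallback:
        for c in candidates:
            c.fallback = True
    candidates.sort(key=ModelCandidate.sort_key)
    return candidates
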