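"""Causality classification of inheritance-model candidates.

A candidate is designated *causative* only when all of the following hold:

* the gene is known to cause a disorder whose clinical features (HPO
  terms) overlap the patient's, under a compatible inheritance mode;
* the variant is Sanger-confirmed;
* it is absent from, or rare (at or below the cascade frequency cap) in,
  all consulted population databases, including the two consulted only at
  this stage;
* it is reported pathogenic, truncating/splice-disrupting, or predicted
  deleterious by at least three prediction algorithms (for a compound
  heterozygote, each allele must qualify);
* familial segregation, where testable, is consistent with the model.

An inconsistent segregation excludes the candidate outright; anything
short of the full rule set remains a (non-causative) candidate.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

from .inheritance import (
    DeNovoStatus,
    MODEL_PRIORITY,
    ModelCandidate,
    ModelType,
    _carries,
    _comphet_pair_fits,
    apply_sequential_models,
)
from .types import (
    ALL_DATABASES,
    AnnotatedVariant,
    GenePanel,
    Genotype,
    InheritanceMode,
    KnownPathogenicTable,
    Pedigree,
    PredictionVerdict,
    Sex,
    TRUNCATING_CONSEQUENCES,
)

#: Number of affirmative deleterious predictions required of a
#: non-truncating, non-reported variant.
MIN_DELETERIOUS_PREDICTIONS = 3


class Deleteriousness(str, enum.Enum):
    KNOWN_PATHOGENIC = "known_pathogenic"
    TRUNCATING_OR_SPLICE = "truncating_or_splice"
    PREDICTED = "predicted_deleterious"
    INSUFFICIENT = "insufficient"


_DELETERIOUSNESS_RANK = {
    Deleteriousness.KNOWN_PATHOGENIC: 3,
    Deleteriousness.TRUNCATING_OR_SPLICE: 2,
    Deleteriousness.PREDICTED: 1,
    Deleteriousness.INSUFFICIENT: 0,
}


class Segregation(str, enum.Enum):
    YES = "yes"
    NO = "no"
    UNTESTABLE = "untestable"


class VerdictClass(str, enum.Enum):
    CAUSATIVE = "causative"
    CANDIDATE = "candidate"
    EXCLUDED = "excluded"


@dataclass
class EvidenceSummary:
    gene_disease_match: bool
    deleteriousness: Deleteriousness
    n_deleterious_predictions: int
    population_absent: bool
    segregation_consistent: Segregation
    sanger_confirmed: bool

    @property
    def deleteriousness_sufficient(self) -> bool:
        """Reported pathogenic, truncating/splice, or >= 3 deleterious
        predictions (the weakest allele of a pair governs)."""
        if self.deleteriousness in (
            Deleteriousness.KNOWN_PATHOGENIC,
            Deleteriousness.TRUNCATING_OR_SPLICE,
        ):
            return True
        return (
            self.deleteriousness is Deleteriousness.PREDICTED
            and self.n_deleterious_predictions >= MIN_DELETERIOUS_PREDICTIONS
        )


@dataclass
class CausalityVerdict:
    candidate: ModelCandidate
    verdict: VerdictClass
    evidence: EvidenceSummary

    @property
    def family_id(self) -> str:
        return self.candidate.family_id


# ---------------------------------------------------------------------------
# evidence
# ---------------------------------------------------------------------------


def _variant_deleteriousness(
    variant: AnnotatedVariant, table: KnownPathogenicTable | None
) -> tuple[Deleteriousness, int]:
    k = sum(
        1
        for verdict in variant.prediction_verdicts.values()
        if verdict is PredictionVerdict.DELETERIOUS
    )
    if variant.known_pathogenic or (table is not None and table.contains(variant)):
        return Deleteriousness.KNOWN_PATHOGENIC, k
    if variant.consequence in TRUNCATING_CONSEQUENCES:
        return Deleteriousness.TRUNCATING_OR_SPLICE, k
    if variant.prediction_verdicts:
        return Deleteriousness.PREDICTED, k
    return Deleteriousness.INSUFFICIENT, 0


_MODEL_TO_MODE = {
    ModelType.AR_HOM: InheritanceMode.AR,
    ModelType.AR_COMPHET: InheritanceMode.AR,
    ModelType.AD: InheritanceMode.AD,
    ModelType.XL: InheritanceMode.XL,
}


def assess_evidence(
    candidate: ModelCandidate,
    panel: GenePanel,
    patient_hpo: Iterable[str],
    known_pathogenic_table: KnownPathogenicTable | None = None,
    pedigree: Pedigree | None = None,
    databases: Sequence[str] = ALL_DATABASES,
    max_af: float = 0.02,
) -> EvidenceSummary:
    """Compute the evidence fields for one candidate.

    For a compound heterozygote both alleles must individually qualify on
    deleteriousness and population absence; the summary reports the weaker
    allele's class. ``max_af`` mirrors the cascade's benign-frequency cap:
    an observed frequency at or below it does not count against causality.
    """
    patient_terms = set(patient_hpo)
    mode = _MODEL_TO_MODE[candidate.model]

    if candidate.fallback:
        entry = (
            known_pathogenic_table.lookup(candidate.variants[0])
            if known_pathogenic_table is not None
            else None
        )
        gene_disease_match = bool(entry and entry.hpo_terms & patient_terms)
    else:
        gene_disease_match = any(
            entry.hpo_terms & patient_terms and mode in entry.inheritance_modes
            for entry in panel.entries_for_gene(candidate.gene)
        )

    classes = [
        _variant_deleteriousness(v, known_pathogenic_table)
        for v in candidate.variants
    ]
    deleteriousness, k = min(
        classes, key=lambda ck: (_DELETERIOUSNESS_RANK[ck[0]], ck[1])
    )

    population_absent = all(
        v.pop_freqs.get(db, 0.0) <= max_af
        for v in candidate.variants
        for db in databases
    )

    segregation = (
        check_segregation(candidate, pedigree)
        if pedigree is not None
        else Segregation.UNTESTABLE
    )

    return EvidenceSummary(
        gene_disease_match=gene_disease_match,
        deleteriousness=deleteriousness,
        n_deleterious_predictions=k,
        population_absent=population_absent,
        segregation_consistent=segregation,
        sanger_confirmed=all(v.sanger_confirmed for v in candidate.variants),
    )


# ---------------------------------------------------------------------------
# segregation
# ---------------------------------------------------------------------------


def _member_compatible(
    candidate: ModelCandidate, pedigree: Pedigree, individual_id: str
) -> bool:
    """Compatibility of one genotyped relative with the candidate's model."""
    ind = pedigree[individual_id]
    model = candidate.model
    v = candidate.variants[0]
    gt = v.genotype(individual_id)

    if ind.affected:
        # affected relatives must carry the candidate genotype
        if model is ModelType.AR_HOM:
            return gt is Genotype.HOM_ALT
        if model is ModelType.AR_COMPHET:
            return all(
                x.genotype(individual_id) is Genotype.HET
                for x in candidate.variants
            )
        if model is ModelType.AD:
            return gt in (Genotype.HET, Genotype.HOM_ALT)
        if ind.sex is Sex.MALE:
            return gt is Genotype.HEMI
        return gt in (Genotype.HET, Genotype.HOM_ALT)

    if model is ModelType.AR_HOM:
        is_parent = any(
            pedigree.father_of(a.individual_id) is ind
            or pedigree.mother_of(a.individual_id) is ind
            for a in pedigree.affected_members()
        )
        if is_parent:
            return gt is Genotype.HET
        return gt is not Genotype.HOM_ALT
    if model is ModelType.AR_COMPHET:
        return not all(
            _carries(x, individual_id) for x in candidate.variants
        )
    if model is ModelType.AD:
        return not _carries(v, individual_id)
    if ind.sex is Sex.MALE:
        return gt is not Genotype.HEMI
    return gt is not Genotype.HOM_ALT


def check_segregation(
    candidate: ModelCandidate, pedigree: Pedigree
) -> Segregation:
    """Test familial segregation of the candidate against every genotyped
    relative. ``yes`` requires at least one genotyped relative beyond the
    affected members themselves and no incompatibility; any incompatible
    relative yields ``no``; with no informative relatives: ``untestable``."""
    family = pedigree.family(candidate.family_id)
    affected = family.affected_members()
    # the first affected member is the index case; everyone else genotyped
    # (parents, sibs affected or not, extended relatives) is informative
    index_case = affected[0].individual_id if affected else None
    relatives = [
        m.individual_id
        for m in family.members()
        if m.individual_id != index_case
        and all(
            v.genotype(m.individual_id) is not Genotype.NO_CALL
            for v in candidate.variants
        )
    ]
    if not relatives:
        return Segregation.UNTESTABLE
    for rid in relatives:
        if not _member_compatible(candidate, family, rid):
            return Segregation.NO
    if candidate.model is ModelType.AR_COMPHET:
        fits, _ = _comphet_pair_fits(*candidate.variants, family)
        if not fits:
            return Segregation.NO
    return Segregation.YES


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def classify(
    candidates_with_evidence: Iterable[tuple[ModelCandidate, EvidenceSummary]],
) -> list[CausalityVerdict]:
    """Assign verdicts and rank them (per family: causative recessive
    first, then causative dominant/X-linked, then remaining candidates;
    ties broken by deleteriousness class, then gene symbol)."""
    verdicts = []
    for candidate, evidence in candidates_with_evidence:
        if evidence.segregation_consistent is Segregation.NO:
            verdict = VerdictClass.EXCLUDED
        elif (
            evidence.gene_disease_match
            and evidence.sanger_confirmed
            and evidence.population_absent
            and evidence.deleteriousness_sufficient
        ):
            verdict = VerdictClass.CAUSATIVE
        else:
            verdict = VerdictClass.CANDIDATE
        verdicts.append(CausalityVerdict(candidate, verdict, evidence))

    verdict_order = {
        VerdictClass.CAUSATIVE: 0,
        VerdictClass.CANDIDATE: 1,
        VerdictClass.EXCLUDED: 2,
    }
    verdicts.sort(
        key=lambda v: (
            v.family_id,
            verdict_order[v.verdict],
            MODEL_PRIORITY[v.candidate.model],
            -_DELETERIOUSNESS_RANK[v.evidence.deleteriousness],
            int(v.candidate.down_ranked),
            v.candidate.gene,
            v.candidate.variant_keys,
        )
    )
    return verdicts


def hgmd_fallback(
    unmatched: Iterable[AnnotatedVariant],
    known_pathogenic_table: KnownPathogenicTable,
    pedigree: Pedigree,
) -> list[ModelCandidate]:
    """Fallback path for phenotype-unmatched variants: those present in
    the known-pathogenic lookup re-enter inheritance modelling and surface
    as candidates flagged ``fallback``; their gene-disease match is later
    decided from the lookup's disorder annotation."""
    hits = [v for v in unmatched if known_pathogenic_table.contains(v)]
    if not hits:
        return []
    return apply_sequential_models(hits, pedigree, fallback=True)
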