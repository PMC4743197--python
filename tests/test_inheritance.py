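"""Mendelian model candidates: worked family configurations, the
brute-force enumeration oracle, and structural properties."""

from __future__ import annotations

import numpy as np
import pytest

from exomediag import (
    Consequence,
    DeNovoStatus,
    Genotype,
    Individual,
    ModelType,
    Pedigree,
    Sex,
    apply_sequential_models,
    candidates_dominant,
    candidates_recessive,
    candidates_xlinked,
)
from conftest import make_sib_quartet, make_trio, make_variant
from oracles import brute_force_candidates, candidate_set

HOM = Genotype.HOM_ALT
HET = Genotype.HET
REF = Genotype.HOM_REF
HEMI = Genotype.HEMI
NC = Genotype.NO_CALL


class TestRecessive:
    def test_homozygous_child_with_carrier_parents(self):
        """The classic recessive trio: child homozygous, both parents
        heterozygous carriers."""
        ped = make_trio()
        v = make_variant(gene="ERCC8",
                         genotypes={"C": HOM, "F": HET, "M": HET})
        cands = candidates_recessive([v], ped)
        assert [c.model for c in cands] == [ModelType.AR_HOM]

    @pytest.mark.parametrize(
        "father_gt,mother_gt,fits",
        [(HET, HET, True), (REF, HET, False), (HOM, HET, False),
         (NC, HET, True)],
    )
    def test_parents_must_be_het_or_untyped(self, father_gt, mother_gt, fits):
        ped = make_trio()
        v = make_variant(genotypes={"C": HOM, "F": father_gt, "M": mother_gt})
        assert bool(candidates_recessive([v], ped)) is fits

    def test_comphet_sib_pair_one_allele_per_parent(self):
        ped = make_sib_quartet()
        v1 = make_variant(chrom="18", pos=1_000_000, gene="RTTN",
                          consequence=Consequence.FRAMESHIFT,
                          genotypes={"S1": HET, "S2": HET, "F": HET, "M": REF})
        v2 = make_variant(chrom="18", pos=2_000_000, gene="RTTN",
                          consequence=Consequence.MISSENSE,
                          genotypes={"S1": HET, "S2": HET, "F": REF, "M": HET})
        cands = candidates_recessive([v1, v2], ped)
        assert len(cands) == 1
        c = cands[0]
        assert c.model is ModelType.AR_COMPHET and not c.phase_unknown
        assert set(c.variant_keys) == {v1.key, v2.key}

    def test_cis_pair_from_one_parent_rejected(self):
        """Two het variants both transmitted by the mother cannot be a
        compound heterozygote (cis configuration)."""
        ped = make_trio()
        v1 = make_variant(pos=1_000_000, gene="G",
                          genotypes={"C": HET, "F": REF, "M": HET})
        v2 = make_variant(pos=2_000_000, gene="G",
                          genotypes={"C": HET, "F": REF, "M": HET})
        assert candidates_recessive([v1, v2], ped) == []

    def test_parents_unavailable_pair_flagged_phase_unknown(self):
        ped = make_trio()
        v1 = make_variant(pos=1_000_000, gene="G", genotypes={"C": HET})
        v2 = make_variant(pos=2_000_000, gene="G", genotypes={"C": HET})
        cands = candidates_recessive([v1, v2], ped)
        assert len(cands) == 1 and cands[0].phase_unknown

    def test_unaffected_sib_carrying_both_alleles_rejects_pair(self):
        ped = make_sib_quartet(affected=(True, False))
        gts1 = {"S1": HET, "S2": HET, "F": HET, "M": REF}
        gts2 = {"S1": HET, "S2": HET, "F": REF, "M": HET}
        v1 = make_variant(pos=1_000_000, gene="G", genotypes=gts1)
        v2 = make_variant(pos=2_000_000, gene="G", genotypes=gts2)
        assert candidates_recessive([v1, v2], ped) == []


class TestDominant:
    def test_inherited_from_affected_mother_with_clear_aunt(self):
        """Affected child and affected carrier mother; the unaffected
        maternal aunt does not carry the variant."""
        ped = Pedigree(
            [
                Individual("FAM", "F", None, None, Sex.MALE, False),
                Individual("FAM", "M", None, None, Sex.FEMALE, True),
                Individual("FAM", "C", "F", "M", Sex.MALE, True),
                Individual("FAM", "AUNT", None, None, Sex.FEMALE, False),
            ]
        )
        v = make_variant(gene="KIF11", consequence=Consequence.FRAMESHIFT,
                         genotypes={"C": HET, "M": HET, "F": REF,
                                    "AUNT": REF})
        cands = candidates_dominant([v], ped)
        assert len(cands) == 1
        assert cands[0].de_novo_status is DeNovoStatus.INHERITED

    def test_absent_in_mother_father_untested_is_probable_de_novo(self):
        ped = make_trio()
        v = make_variant(gene="DYRK1A",
                         genotypes={"C": HET, "M": REF})  # father untyped
        cands = candidates_dominant([v], ped)
        assert len(cands) == 1
        assert cands[0].de_novo_status is DeNovoStatus.PROBABLE

    def test_absent_in_both_parents_is_confirmed_de_novo(self):
        ped = make_trio()
        v = make_variant(genotypes={"C": HET, "F": REF, "M": REF})
        assert candidates_dominant([v], ped)[0].de_novo_status is (
            DeNovoStatus.CONFIRMED
        )

    def test_unaffected_carrier_sib_rejects_candidate(self):
        ped = make_sib_quartet(affected=(True, False))
        v = make_variant(genotypes={"S1": HET, "S2": HET, "F": REF, "M": REF})
        assert candidates_dominant([v], ped) == []

    def test_homozygous_affected_allowed_but_down_ranked(self):
        ped = make_trio()
        v = make_variant(genotypes={"C": HOM})
        cands = candidates_dominant([v], ped)
        assert len(cands) == 1 and cands[0].down_ranked


class TestXLinked:
    def test_de_novo_het_female_on_chrx(self):
        ped = make_trio(child_sex=Sex.FEMALE)
        v = make_variant(chrom="X", gene="CASK",
                         consequence=Consequence.SPLICE_SITE,
                         genotypes={"C": HET, "F": REF, "M": REF})
        cands = candidates_xlinked([v], ped)
        assert len(cands) == 1
        assert cands[0].de_novo_status is DeNovoStatus.CONFIRMED

    def test_unaffected_hemizygous_brother_rejects(self):
        ped = Pedigree(
            [
                Individual("FAM", "F", None, None, Sex.MALE, False),
                Individual("FAM", "M", None, None, Sex.FEMALE, False),
                Individual("FAM", "C", "F", "M", Sex.FEMALE, True),
                Individual("FAM", "BRO", "F", "M", Sex.MALE, False),
            ]
        )
        v = make_variant(chrom="X",
                         genotypes={"C": HET, "BRO": HEMI, "F": REF, "M": HET})
        assert candidates_xlinked([v], ped) == []

    def test_autosomal_variant_never_x_linked(self):
        ped = make_trio()
        v = make_variant(chrom="7", genotypes={"C": HET, "F": REF, "M": REF})
        assert candidates_xlinked([v], ped) == []

    def test_affected_male_must_be_hemizygous(self):
        ped = make_trio(child_sex=Sex.MALE)
        v = make_variant(chrom="X", genotypes={"C": HEMI, "F": REF, "M": HET})
        assert len(candidates_xlinked([v], ped)) == 1
        v2 = make_variant(chrom="X", genotypes={"C": HET, "F": REF, "M": HET})
        assert candidates_xlinked([v2], ped) == []


class TestSequentialOrdering:
    def test_recessive_candidates_listed_before_dominant(self):
        ped = make_trio()
        ar = make_variant(pos=1_000_000, gene="GA",
                          genotypes={"C": HOM, "F": HET, "M": HET})
        ad = make_variant(pos=2_000_000, gene="GB",
                          genotypes={"C": HET, "F": REF, "M": REF})
        cands = apply_sequential_models([ar, ad], ped)
        assert [c.model for c in cands] == [ModelType.AR_HOM, ModelType.AD]

    def test_family_with_no_candidates_yields_empty(self):
        ped = make_trio()
        v = make_variant(genotypes={"C": REF, "F": HET, "M": HET})
        assert apply_sequential_models([v], ped) == []

    def test_adding_unrelated_variant_never_removes_candidates(self):
        ped = make_trio()
        base = [
            make_variant(pos=1_000_000, gene="GA",
                         genotypes={"C": HOM, "F": HET, "M": HET}),
            make_variant(pos=2_000_000, gene="GB",
                         genotypes={"C": HET, "F": REF, "M": REF}),
        ]
        before = candidate_set(apply_sequential_models(base, ped))
        extra = make_variant(pos=9_000_000, gene="GZ",
                             genotypes={"C": HET, "F": HET, "M": REF})
        after = candidate_set(apply_sequential_models(base + [extra], ped))
        assert before <= after


# ---------------------------------------------------------------------------
# randomized oracle equivalence
# ---------------------------------------------------------------------------

_GENES = ["G1", "G2", "G3", ""]
_AUTO_GTS = [REF, HET, HOM, NC]
_MALE_X_GTS = [REF, HEMI, NC]


def _random_family(rng: np.random.Generator, index: int):
    """A random pedigree (trio / quartet / extended) with <= 20 variants of
    random genotype configurations, some on chrX, some samples untyped."""
    fam = f"R{index}"
    members = [
        Individual(fam, "F", None, None, Sex.MALE, bool(rng.random() < 0.1)),
        Individual(fam, "M", None, None, Sex.FEMALE, bool(rng.random() < 0.1)),
        Individual(fam, "C1", "F", "M",
                   Sex.MALE if rng.random() < 0.5 else Sex.FEMALE, True),
    ]
    if rng.random() < 0.5:
        members.append(
            Individual(fam, "C2", "F", "M",
                       Sex.MALE if rng.random() < 0.5 else Sex.FEMALE,
                       bool(rng.random() < 0.6))
        )
    if rng.random() < 0.2:
        members.append(
            Individual(fam, "U", None, None, Sex.FEMALE, False)
        )
    ped = Pedigree(members)
    # with some probability, parents are entirely ungenotyped
    typed = {m.individual_id for m in members}
    if rng.random() < 0.3:
        typed -= {"F"}
    if rng.random() < 0.3:
        typed -= {"M"}

    variants = []
    n = int(rng.integers(1, 21))
    for i in range(n):
        on_x = rng.random() < 0.25
        chrom = "X" if on_x else str(rng.integers(1, 23))
        genotypes = {}
        for m in members:
            if m.individual_id not in typed:
                continue
            if on_x and m.sex is Sex.MALE:
                genotypes[m.individual_id] = _MALE_X_GTS[
                    int(rng.integers(len(_MALE_X_GTS)))
                ]
            else:
                genotypes[m.individual_id] = _AUTO_GTS[
                    int(rng.integers(len(_AUTO_GTS)))
                ]
        variants.append(
            make_variant(
                chrom=chrom,
                pos=1_000_000 + i * 1000,
                gene=_GENES[int(rng.integers(len(_GENES)))],
                genotypes=genotypes,
            )
        )
    return variants, ped


def test_candidates_match_brute_force_enumeration_on_random_families():
    """On 200 random families the sequential models return exactly the
    candidate set of an exhaustive enumerator that tests every variant and
    every same-gene variant pair against the model definitions."""
    rng = np.random.default_rng(20_240_901)
    checked = 0
    for index in range(200):
        variants, ped = _random_family(rng, index)
        got = candidate_set(apply_sequential_models(variants, ped))
        expected = brute_force_candidates(variants, ped)
        assert got == expected, f"family {index}"
        checked += len(expected)
    assert checked > 100  # the families are not trivially empty


def test_comphet_pairs_always_trans_when_parents_genotyped():
    """Whenever both parents are genotyped at both sites of a reported
    pair, the two variants have disjoint single-parent origins. Random
    parental carrier configurations with a double-het child."""
    rng = np.random.default_rng(7)
    parent_gts = [REF, HET, HOM]
    reported = 0
    for index in range(300):
        ped = make_trio()
        gts = [parent_gts[int(rng.integers(3))] for _ in range(4)]
        v1 = make_variant(pos=1_000_000, gene="G",
                          genotypes={"C": HET, "F": gts[0], "M": gts[1]})
        v2 = make_variant(pos=2_000_000, gene="G",
                          genotypes={"C": HET, "F": gts[2], "M": gts[3]})
        for c in candidates_recessive([v1, v2], ped):
            if c.model is not ModelType.AR_COMPHET:
                continue
            assert not c.phase_unknown
            f1, f2 = v1.genotype("F") in (HET, HOM), v2.genotype("F") in (HET, HOM)
            m1, m2 = v1.genotype("M") in (HET, HOM), v2.genotype("M") in (HET, HOM)
            assert (f1 and m2) or (f2 and m1)
            reported += 1
    assert reported > 20
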