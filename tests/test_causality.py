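"""Causality rules: evidence assessment, segregation, verdict logic."""

from __future__ import annotations

import itertools

import pytest

from exomediag import (
    Consequence,
    Deleteriousness,
    GenePanel,
    GenePanelEntry,
    Genotype,
    Individual,
    InheritanceMode,
    KnownPathogenicEntry,
    KnownPathogenicTable,
    ModelCandidate,
    ModelType,
    Pedigree,
    PredictionVerdict,
    Segregation,
    Sex,
    VerdictClass,
    assess_evidence,
    check_segregation,
    classify,
    hgmd_fallback,
)
from exomediag.causality import EvidenceSummary
from conftest import make_sib_quartet, make_trio, make_variant

HOM = Genotype.HOM_ALT
HET = Genotype.HET
REF = Genotype.HOM_REF

HPO = frozenset({"HP:0011451", "HP:0000234"})
PANEL = GenePanel(
    [
        GenePanelEntry("RAB3GAP1", frozenset({"HP:0011451"}),
                       "Warburg Micro syndrome 1",
                       frozenset({InheritanceMode.AR})),
        GenePanelEntry("RNASEH2B", frozenset({"HP:0011451"}),
                       "Aicardi-Goutieres syndrome 2",
                       frozenset({InheritanceMode.AR})),
        GenePanelEntry("ADGENE", frozenset({"HP:0011451"}),
                       "Synthetic dominant disorder",
                       frozenset({InheritanceMode.AD})),
    ]
)


def _candidate(variant, model=ModelType.AR_HOM, fallback=False):
    return ModelCandidate(
        family_id="FAM", model=model, variants=(variant,), fallback=fallback
    )


class TestEvidence:
    def test_truncating_panel_gene_absent_from_databases(self):
        """A frameshift in a phenotype-matched recessive gene, never seen
        in any database, carries truncating-class evidence."""
        v = make_variant(
            gene="RAB3GAP1", consequence=Consequence.FRAMESHIFT,
            genotypes={"C": HOM, "F": HET, "M": HET}, sanger_confirmed=True,
        )
        e = assess_evidence(_candidate(v), PANEL, HPO, pedigree=make_trio())
        assert e.deleteriousness is Deleteriousness.TRUNCATING_OR_SPLICE
        assert e.gene_disease_match and e.population_absent
        assert e.segregation_consistent is Segregation.YES
        assert e.sanger_confirmed

    def test_missense_with_three_deleterious_verdicts(self):
        v = make_variant(
            gene="RAB3GAP1", consequence=Consequence.MISSENSE,
            genotypes={"C": HOM, "F": HET, "M": HET},
            predictions={
                "SIFT": PredictionVerdict.DELETERIOUS,
                "Polyphen": PredictionVerdict.DELETERIOUS,
                "MutationTaster": PredictionVerdict.DELETERIOUS,
                "Provean": PredictionVerdict.TOLERATED,
            },
        )
        e = assess_evidence(_candidate(v), PANEL, HPO)
        assert e.deleteriousness is Deleteriousness.PREDICTED
        assert e.n_deleterious_predictions == 3
        assert e.deleteriousness_sufficient

    def test_known_pathogenic_at_rare_database_frequency(self):
        """A reported pathogenic missense observed at 0.13 % stays
        population-absent under the 2 % cap and classifies causative."""
        v = make_variant(
            gene="RNASEH2B", consequence=Consequence.MISSENSE,
            genotypes={"C": HOM, "F": HET, "M": HET},
            pop_freqs={"ExAC": 0.0013},
            known_pathogenic=True, sanger_confirmed=True,
        )
        c = _candidate(v)
        e = assess_evidence(c, PANEL, HPO, pedigree=make_trio())
        assert e.deleteriousness is Deleteriousness.KNOWN_PATHOGENIC
        assert e.population_absent
        verdicts = classify([(c, e)])
        assert verdicts[0].verdict is VerdictClass.CAUSATIVE

    def test_common_database_frequency_blocks_population_absent(self):
        v = make_variant(gene="RAB3GAP1", pop_freqs={"EVS": 0.05},
                         genotypes={"C": HOM})
        e = assess_evidence(_candidate(v), PANEL, HPO)
        assert not e.population_absent

    def test_panel_mode_mismatch_blocks_gene_disease_match(self):
        v = make_variant(gene="ADGENE", genotypes={"C": HOM, "F": HET,
                                                   "M": HET})
        e = assess_evidence(_candidate(v, ModelType.AR_HOM), PANEL, HPO)
        assert not e.gene_disease_match  # ADGENE is dominant-only
        e2 = assess_evidence(
            _candidate(
                make_variant(gene="ADGENE", genotypes={"C": HET}),
                ModelType.AD,
            ),
            PANEL, HPO,
        )
        assert e2.gene_disease_match

    def test_comphet_weaker_allele_governs(self):
        v1 = make_variant(pos=1_000_000, gene="RNASEH2B",
                          consequence=Consequence.FRAMESHIFT,
                          genotypes={"C": HET})
        v2 = make_variant(pos=2_000_000, gene="RNASEH2B",
                          consequence=Consequence.MISSENSE,
                          genotypes={"C": HET},
                          predictions={"SIFT": PredictionVerdict.DELETERIOUS,
                                       "Polyphen": PredictionVerdict.DELETERIOUS})
        c = ModelCandidate("FAM", ModelType.AR_COMPHET, (v1, v2))
        e = assess_evidence(c, PANEL, HPO)
        assert e.deleteriousness is Deleteriousness.PREDICTED
        assert e.n_deleterious_predictions == 2
        assert not e.deleteriousness_sufficient


class TestSegregation:
    def test_recessive_with_both_parents_het_is_consistent(self):
        ped = make_trio()
        v = make_variant(genotypes={"C": HOM, "F": HET, "M": HET})
        assert check_segregation(_candidate(v), ped) is Segregation.YES

    def test_dominant_variant_in_unaffected_aunt_is_inconsistent(self):
        ped = Pedigree(
            [
                Individual("FAM", "F", None, None, Sex.MALE, False),
                Individual("FAM", "M", None, None, Sex.FEMALE, True),
                Individual("FAM", "C", "F", "M", Sex.MALE, True),
                Individual("FAM", "AUNT", None, None, Sex.FEMALE, False),
            ]
        )
        v = make_variant(genotypes={"C": HET, "M": HET, "F": REF,
                                    "AUNT": HET})
        c = _candidate(v, ModelType.AD)
        assert check_segregation(c, ped) is Segregation.NO

    def test_singleton_without_relatives_is_untestable(self):
        ped = Pedigree(
            [Individual("FAM", "C", None, None, Sex.FEMALE, True)]
        )
        v = make_variant(genotypes={"C": HOM})
        assert check_segregation(_candidate(v), ped) is Segregation.UNTESTABLE

    def test_affected_sib_must_share_the_candidate_genotype(self):
        ped = make_sib_quartet()
        v = make_variant(genotypes={"S1": HOM, "S2": HET, "F": HET, "M": HET})
        # candidate asserted on S1 only; genotyped affected sib S2 is het
        c = ModelCandidate("FAM", ModelType.AR_HOM, (v,))
        assert check_segregation(c, ped) is Segregation.NO


class TestClassification:
    def _evidence(self, **kwargs) -> EvidenceSummary:
        base = dict(
            gene_disease_match=True,
            deleteriousness=Deleteriousness.TRUNCATING_OR_SPLICE,
            n_deleterious_predictions=0,
            population_absent=True,
            segregation_consistent=Segregation.YES,
            sanger_confirmed=True,
        )
        base.update(kwargs)
        return EvidenceSummary(**base)

    def _verdict(self, evidence) -> VerdictClass:
        c = _candidate(make_variant(genotypes={"C": HOM}))
        return classify([(c, evidence)])[0].verdict

    def test_all_criteria_met_is_causative(self):
        assert self._verdict(self._evidence()) is VerdictClass.CAUSATIVE

    def test_two_prediction_missense_never_causative(self):
        e = self._evidence(
            deleteriousness=Deleteriousness.PREDICTED,
            n_deleterious_predictions=2,
        )
        assert self._verdict(e) is VerdictClass.CANDIDATE

    def test_inconsistent_segregation_excludes_regardless_of_evidence(self):
        e = self._evidence(segregation_consistent=Segregation.NO)
        assert self._verdict(e) is VerdictClass.EXCLUDED

    def test_no_causative_without_sanger_confirmation(self):
        e = self._evidence(sanger_confirmed=False)
        assert self._verdict(e) is VerdictClass.CANDIDATE

    def test_verdict_monotone_in_every_evidence_field(self):
        """Strengthening any single evidence field never demotes the
        verdict, over the full evidence lattice."""
        rank = {VerdictClass.EXCLUDED: 0, VerdictClass.CANDIDATE: 1,
                VerdictClass.CAUSATIVE: 2}
        bools = [False, True]
        dels = [Deleteriousness.INSUFFICIENT, Deleteriousness.PREDICTED,
                Deleteriousness.TRUNCATING_OR_SPLICE,
                Deleteriousness.KNOWN_PATHOGENIC]
        segs = [Segregation.NO, Segregation.UNTESTABLE, Segregation.YES]
        ks = [0, 2, 3]
        space = list(itertools.product(bools, dels, ks, bools, segs, bools))

        def verdict(point):
            gm, dl, k, pa, seg, sc = point
            return self._verdict(
                self._evidence(
                    gene_disease_match=gm, deleteriousness=dl,
                    n_deleterious_predictions=k, population_absent=pa,
                    segregation_consistent=seg, sanger_confirmed=sc,
                )
            )

        def stronger(a, b):
            """point a >= point b field-wise in evidence strength"""
            gm_a, dl_a, k_a, pa_a, seg_a, sc_a = a
            gm_b, dl_b, k_b, pa_b, seg_b, sc_b = b
            return (
                gm_a >= gm_b
                and dels.index(dl_a) >= dels.index(dl_b)
                and k_a >= k_b
                and pa_a >= pa_b
                and segs.index(seg_a) >= segs.index(seg_b)
                and sc_a >= sc_b
            )

        verdicts = {p: verdict(p) for p in space}
        for a in space:
            for b in space:
                if stronger(a, b):
                    assert rank[verdicts[a]] >= rank[verdicts[b]], (a, b)

    def test_causative_recessive_ranked_before_causative_dominant(self):
        ar = _candidate(
            make_variant(gene="RAB3GAP1", genotypes={"C": HOM}),
            ModelType.AR_HOM,
        )
        ad = _candidate(
            make_variant(gene="ADGENE", pos=2_000_000,
                         genotypes={"C": HET}),
            ModelType.AD,
        )
        e = self._evidence()
        verdicts = classify([(ad, e), (ar, e)])
        assert [v.candidate.model for v in verdicts] == [
            ModelType.AR_HOM, ModelType.AD
        ]


class TestFallback:
    TABLE = KnownPathogenicTable(
        [
            KnownPathogenicEntry(
                chrom="12", pos=9_000_000, ref="A", alt="G", gene="OFFPANEL",
                disorder="Known disorder", hpo_terms=frozenset({"HP:0011451"}),
            )
        ]
    )

    def test_lookup_hit_surfaces_as_fallback_candidate(self):
        ped = make_trio()
        v = make_variant(chrom="12", pos=9_000_000, ref="A", alt="G",
                         gene="OFFPANEL",
                         genotypes={"C": HET, "F": REF, "M": REF},
                         sanger_confirmed=True)
        cands = hgmd_fallback([v], self.TABLE, ped)
        assert len(cands) == 1 and cands[0].fallback
        e = assess_evidence(cands[0], GenePanel([]), HPO,
                            known_pathogenic_table=self.TABLE, pedigree=ped)
        # gene-disease match comes from the lookup's annotation
        assert e.gene_disease_match
        assert e.deleteriousness is Deleteriousness.KNOWN_PATHOGENIC
        assert classify([(cands[0], e)])[0].verdict is VerdictClass.CAUSATIVE

    def test_lookup_miss_is_dropped(self):
        ped = make_trio()
        v = make_variant(chrom="12", pos=9_999_999, ref="A", alt="G",
                         genotypes={"C": HET, "F": REF, "M": REF})
        assert hgmd_fallback([v], self.TABLE, ped) == []

    def test_empty_lookup_produces_no_candidates(self):
        ped = make_trio()
        v = make_variant(genotypes={"C": HET, "F": REF, "M": REF})
        assert hgmd_fallback([v], KnownPathogenicTable([]), ped) == []

    def test_fallback_without_phenotype_annotation_is_not_causative(self):
        table = KnownPathogenicTable(
            [KnownPathogenicEntry(chrom="12", pos=9_000_000, ref="A",
                                  alt="G", disorder="Unannotated")]
        )
        ped = make_trio()
        v = make_variant(chrom="12", pos=9_000_000, ref="A", alt="G",
                         genotypes={"C": HET, "F": REF, "M": REF},
                         sanger_confirmed=True)
        cands = hgmd_fallback([v], table, ped)
        e = assess_evidence(cands[0], GenePanel([]), HPO,
                            known_pathogenic_table=table, pedigree=ped)
        assert not e.gene_disease_match
        assert classify([(cands[0], e)])[0].verdict is VerdictClass.CANDIDATE
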