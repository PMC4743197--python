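"""Shared fixtures: variant/pedigree builders and the packaged seed-1 cohort."""

from __future__ import annotations

import pytest

from exomediag import (
    AnnotatedVariant,
    CohortConfig,
    Consequence,
    Genotype,
    Individual,
    Pedigree,
    PredictionVerdict,
    Sex,
    generate_cohort,
)


def make_variant(
    chrom: str = "1",
    pos: int = 1_000_000,
    ref: str = "A",
    alt: str = "T",
    gene: str = "GENE1",
    consequence: Consequence = Consequence.MISSENSE,
    genotypes: dict[str, Genotype] | None = None,
    depths: dict[str, int] | None = None,
    pop_freqs: dict[str, float] | None = None,
    predictions: dict[str, PredictionVerdict] | None = None,
    known_pathogenic: bool = False,
    sanger_confirmed: bool = False,
) -> AnnotatedVariant:
    return AnnotatedVariant(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=gene,
        consequence=consequence,
        genotypes=dict(genotypes or {}),
        read_depths=dict(depths or {}),
        pop_freqs=dict(pop_freqs or {}),
        prediction_verdicts=dict(predictions or {}),
        known_pathogenic=known_pathogenic,
        sanger_confirmed=sanger_confirmed,
    )


def make_trio(
    child_sex: Sex = Sex.FEMALE,
    family_id: str = "FAM",
    child_id: str = "C",
    consanguineous: bool = False,
) -> Pedigree:
    """Affected child, unaffected genotype-able parents F and M."""
    return Pedigree(
        [
            Individual(family_id, "F", None, None, Sex.MALE, False),
            Individual(family_id, "M", None, None, Sex.FEMALE, False),
            Individual(
                family_id, child_id, "F", "M", child_sex, True,
                consanguineous_parents=consanguineous,
            ),
        ]
    )


def make_sib_quartet(
    sexes: tuple[Sex, Sex] = (Sex.FEMALE, Sex.FEMALE),
    affected: tuple[bool, bool] = (True, True),
    family_id: str = "FAM",
) -> Pedigree:
    return Pedigree(
        [
            Individual(family_id, "F", None, None, Sex.MALE, False),
            Individual(family_id, "M", None, None, Sex.FEMALE, False),
            Individual(family_id, "S1", "F", "M", sexes[0], affected[0]),
            Individual(family_id, "S2", "F", "M", sexes[1], affected[1]),
        ]
    )


@pytest.fixture(scope="session")
def seed1_bundle():
    """The packaged synthetic study cohort (35 families, seed 1)."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def seed1_cohort_dir(seed1_bundle, tmp_path_factory):
    """The seed-1 bundle written out in the on-disk cohort layout."""
    out = tmp_path_factory.mktemp("cohort-seed1")
    seed1_bundle.write(out)
    return out
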