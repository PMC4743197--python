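"""Synthetic diagnostic-exome cohort generator.

Emulates the structure of a 35-family microcephaly exome study: 38
patients (three sib-pairs), six consanguineous families, a phenotype
table with ages and head-circumference (OFC) Z-scores, per-family
annotated VCFs, same-run control samples, a phenotype-driven gene panel,
a known-pathogenic lookup, and SNP-array genotype tracks with planted
runs of homozygosity / shared haplotypes.

Ten families carry a planted causal genotype (gene, zygosity,
consequence class and inheritance mode mirroring the study's established
diagnoses): seven autosomal recessive (three homozygous, four compound
heterozygous), two autosomal dominant (one maternally inherited, one
probable de novo with the father unavailable) and one X-linked de novo.
Planted causal alleles are Sanger-confirmed, well covered, and absent or
rare in the population databases; background variants are not
Sanger-confirmed, so end-to-end recovery of exactly the planted
diagnoses is a meaningful pipeline test. A machine-readable truth ledger
accompanies every bundle.

The per-sample background variant count is scaled far below a real exome
(which carries tens of thousands of calls) to keep generated bundles
small; every filter stage still operates non-trivially.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigError
from .inheritance import ModelType
from .io import (
    write_controls,
    write_gene_panel,
    write_known_pathogenic,
    write_ped,
    write_snp_tracks,
    write_vcf,
)
from .roh import SharingMode, SnpGenotypeTrack
from .types import (
    AnnotatedVariant,
    Consequence,
    GenePanel,
    GenePanelEntry,
    Genotype,
    Individual,
    InheritanceMode,
    KnownPathogenicEntry,
    KnownPathogenicTable,
    Pedigree,
    PredictionVerdict,
    Sex,
    VariantKey,
)

# ---------------------------------------------------------------------------
# cohort phenotype fixture (38 patients; ages in years, OFC in SD units;
# None = not available). Sib groups: 8+9, 10+11, 27+28. Consanguinity is
# carried per patient as reported, including the lone table annotation for
# patient 31 that is absent from the running-text list of six.
# ---------------------------------------------------------------------------

#: (patient, age, sex, ofc_z, consanguineous_parents, sib_group)
PATIENT_TABLE: tuple[tuple[int, float, str, float | None, bool, int | None], ...] = (
    (1, 8, "f", -3.0, False, None),
    (2, 5, "f", -5.3, False, None),
    (3, 3, "f", -6.3, False, None),
    (4, 2, "m", -4.6, False, None),
    (5, 8, "m", -3.3, False, None),
    (6, 31, "f", -5.0, False, None),
    (7, 4, "m", -3.6, False, None),
    (8, 5, "f", -4.4, False, 8),
    (9, 10, "f", -5.2, False, 8),
    (10, 56, "f", None, False, 10),
    (11, 57, "f", -7.1, False, 10),
    (12, 3, "m", -4.6, False, None),
    (13, 10, "m", -5.0, False, None),
    (14, 1, "m", -3.2, False, None),
    (15, 0.5, "f", -7.0, False, None),
    (16, 3, "m", -3.3, True, None),
    (17, 2, "f", -3.0, False, None),
    (18, 23, "m", -3.0, False, None),
    (19, 22, "f", -4.0, False, None),
    (20, 4, "m", -3.9, False, None),
    (21, 11, "f", -4.8, False, None),
    (22, 5, "f", -8.0, False, None),
    (23, 2, "m", -4.9, True, None),
    (24, 19, "f", -3.0, False, None),
    (25, 2, "m", -4.5, False, None),
    (26, 5, "f", -3.9, False, None),
    (27, 5, "m", -4.5, True, 27),
    (28, 13, "f", None, True, 27),
    (29, 1, "f", -3.0, True, None),
    (30, 1, "f", -5.2, False, None),
    (31, 3, "m", -3.4, True, None),
    (32, 14, "f", -6.8, False, None),
    (33, 2, "f", -3.1, False, None),
    (34, 0, "f", -3.9, False, None),
    (35, 4, "m", -4.4, True, None),
    (36, 16, "f", -3.7, False, None),
    (37, 2, "m", -3.5, False, None),
    (38, 0.5, "m", -5.2, False, None),
)

#: HPO terms assigned to every synthetic patient (congenital microcephaly,
#: abnormality of the head).
PATIENT_HPO = ("HP:0011451", "HP:0000234")


def patient_id(n: int) -> str:
    return f"P{n:02d}"


def family_of_patient(n: int) -> str:
    for num, _, _, _, _, sib in PATIENT_TABLE:
        if num == n and sib is not None:
            return f"F{sib:02d}"
    return f"F{n:02d}"


# ---------------------------------------------------------------------------
# causal configurations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CausalAllele:
    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: Consequence
    protein_change: str | None
    #: which parent transmits the allele: father / mother / both (one copy
    #: each, homozygous child) / de_novo
    origin: str
    known_pathogenic: bool = False
    pop_freqs: tuple[tuple[str, float], ...] = ()
    deleterious_predictions: tuple[str, ...] = ()

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class CausalSpec:
    """One planted molecular diagnosis: the proband (patient number), the
    gene, the inheritance model and the causal allele(s) with their
    parental-origin plan."""

    proband: int
    gene: str
    model: ModelType
    alleles: tuple[CausalAllele, ...]

    def __post_init__(self) -> None:
        if self.model is ModelType.AR_COMPHET:
            if len(self.alleles) != 2:
                raise ConfigError(f"{self.gene}: compound het needs 2 alleles")
            if {a.origin for a in self.alleles} != {"father", "mother"}:
                raise ConfigError(
                    f"{self.gene}: compound-het alleles need distinct "
                    "parental origins"
                )
        else:
            if len(self.alleles) != 1:
                raise ConfigError(f"{self.gene}: model takes exactly 1 allele")
            if self.model is ModelType.AR_HOM and self.alleles[0].origin != "both":
                raise ConfigError(
                    f"{self.gene}: homozygous allele must come from both parents"
                )


_D3 = ("SIFT", "Polyphen", "MutationTaster")

#: The ten planted diagnoses: (proband, gene, model, alleles). Coordinates
#: are synthetic but chromosome assignments follow the real loci.
TABLE2_CAUSAL_SPECS: tuple[CausalSpec, ...] = (
    CausalSpec(
        1, "RAB3GAP1", ModelType.AR_HOM,
        (CausalAllele("2", 135_800_000, "CACTG", "C", Consequence.FRAMESHIFT,
                      "p.T159Afs*19", "both", known_pathogenic=True),),
    ),
    CausalSpec(
        4, "KIF11", ModelType.AD,
        (CausalAllele("10", 94_350_000, "C", "CT", Consequence.FRAMESHIFT,
                      "p.S348Efs*8", "mother"),),
    ),
    CausalSpec(
        6, "ASPM", ModelType.AR_COMPHET,
        (
            CausalAllele("1", 197_070_000, "GAGAA", "G", Consequence.FRAMESHIFT,
                         "p.K2595Yfs*20", "father"),
            CausalAllele("1", 197_090_000, "G", "C", Consequence.SPLICE_SITE,
                         None, "mother"),
        ),
    ),
    CausalSpec(
        8, "RTTN", ModelType.AR_COMPHET,
        (
            CausalAllele("18", 67_800_000, "GC", "G", Consequence.FRAMESHIFT,
                         "p.E1397Kfs*7", "father"),
            CausalAllele("18", 67_820_000, "A", "G", Consequence.MISSENSE,
                         "p.H865R", "mother",
                         deleterious_predictions=_D3),
        ),
    ),
    CausalSpec(
        16, "ERCC8", ModelType.AR_HOM,
        (CausalAllele("5", 30_000_000, "CAG", "CTG", Consequence.FRAMESHIFT,
                      "p.R99Sfs*26", "both"),),
    ),
    CausalSpec(
        19, "CASK", ModelType.XL,
        (CausalAllele("X", 41_500_000, "A", "C", Consequence.SPLICE_SITE,
                      None, "de_novo"),),
    ),
    CausalSpec(
        23, "DYRK1A", ModelType.AD,
        (CausalAllele("21", 38_860_000, "CT", "C", Consequence.FRAMESHIFT,
                      "p.F478Sfs*114", "de_novo"),),
    ),
    CausalSpec(
        24, "BRCA2", ModelType.AR_HOM,
        (CausalAllele("13", 32_940_000, "T", "TA", Consequence.FRAMESHIFT,
                      "p.Y3225Ifs*30", "both", known_pathogenic=True),),
    ),
    CausalSpec(
        26, "RNASEH2B", ModelType.AR_COMPHET,
        (
            CausalAllele("13", 51_500_000, "G", "A", Consequence.MISSENSE,
                         "p.A177T", "father", known_pathogenic=True,
                         pop_freqs=(("ExAC", 0.0013),),
                         deleterious_predictions=_D3),
            CausalAllele("13", 51_520_000, "T", "G", Consequence.MISSENSE,
                         "p.V185G", "mother", known_pathogenic=True,
                         deleterious_predictions=_D3),
        ),
    ),
    CausalSpec(
        32, "ASPM", ModelType.AR_COMPHET,
        (
            CausalAllele("1", 197_075_000, "C", "T", Consequence.STOP_GAINED,
                         "p.R797*", "father"),
            CausalAllele("1", 197_085_000, "T", "TA", Consequence.FRAMESHIFT,
                         "p.N688Kfs*5", "mother"),
        ),
    ),
)

#: Disorder names and inheritance modes for the causal genes on the panel.
CAUSAL_PANEL_ROWS: tuple[tuple[str, str, str], ...] = (
    ("RAB3GAP1", "Warburg Micro syndrome 1", "AR"),
    ("KIF11", "Microcephaly with or without chorioretinopathy, lymphedema, "
              "or mental retardation", "AD"),
    ("ASPM", "Primary microcephaly 5", "AR"),
    ("RTTN", "Polymicrogyria with seizures", "AR"),
    ("ERCC8", "Cockayne syndrome type A", "AR"),
    ("CASK", "Mental retardation and microcephaly with pontine and "
             "cerebellar hypoplasia", "XL"),
    ("DYRK1A", "Autosomal dominant mental retardation 7", "AD"),
    ("BRCA2", "Fanconi anemia, complementation group D1", "AR"),
    ("RNASEH2B", "Aicardi-Goutieres syndrome 2", "AR"),
)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class RohPlan:
    """A homozygous or shared stretch planted into SNP-array tracks."""

    samples: tuple[str, ...]
    mode: SharingMode
    chrom: str
    start: int
    end: int

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


def default_roh_plans() -> list[RohPlan]:
    """Array plans mirroring the study design: an 8 Mb autozygous stretch
    around the recessive locus of the consanguineous proband, plus one
    planted sharing region per sib-pair (same-homozygous for the
    consanguineous pair, allele-combination sharing for the recessive
    pair, single-allele sharing for the dominant pair)."""
    return [
        RohPlan((patient_id(16),), SharingMode.SINGLE_ROH,
                "5", 26_000_001, 34_000_000),
        RohPlan((patient_id(8), patient_id(9)), SharingMode.RECESSIVE_SHARED,
                "18", 20_000_001, 26_000_000),
        RohPlan((patient_id(10), patient_id(11)), SharingMode.DOMINANT_SHARED,
                "2", 10_000_001, 22_000_000),
        RohPlan((patient_id(27), patient_id(28)), SharingMode.SIBS_SHARED_HOM,
                "7", 15_000_001, 25_000_000),
    ]


@dataclass
class CohortConfig:
    """Knobs of the synthetic cohort.

    The defaults reproduce the study conditions: 35 families (38 patients,
    three sib-pairs, six consanguineous families) with the ten causal
    configurations embedded. ``seed`` is mandatory.
    """

    seed: int
    n_families: int = 35
    causal_specs: tuple[CausalSpec, ...] = TABLE2_CAUSAL_SPECS
    #: background variant sites shared across the cohort
    n_background_sites: int = 150
    #: fraction of background sites that are common (AF 5-50 %) and hence
    #: removable by the benign-frequency filter; the rest are rare (< 2 %)
    common_site_fraction: float = 0.9
    #: fraction of background sites annotated to panel genes
    panel_gene_fraction: float = 0.2
    #: decoy panel entries beyond the causal genes
    n_decoy_panel_genes: int = 20
    n_background_genes: int = 60
    #: same-run control samples and planted artifact sites
    n_controls: int = 8
    n_artifact_sites: int = 5
    #: low-coverage variants planted per proband to exercise the depth filter
    n_lowdepth_sites_per_family: int = 2
    #: SNP-array simulation
    snp_density_per_mb: float = 40.0
    snp_chrom_length: int = 50_000_000
    roh_plans: list[RohPlan] = field(default_factory=default_roh_plans)
    no_call_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if self.n_families < 1:
            raise ConfigError("n_families must be positive")
        if len(self.causal_specs) > self.n_families:
            raise ConfigError(
                f"{len(self.causal_specs)} causal specs exceed "
                f"{self.n_families} families"
            )
        if self.snp_density_per_mb <= 0:
            raise ConfigError("SNP density must be positive")
        if not 0 <= self.common_site_fraction <= 1:
            raise ConfigError("common_site_fraction must lie in [0,1]")
        for plan in self.roh_plans:
            if plan.end > self.snp_chrom_length:
                raise ConfigError(
                    f"planted region {plan.chrom}:{plan.start}-{plan.end} "
                    "exceeds the simulated chromosome"
                )


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------


@dataclass
class CohortBundle:
    """In-memory synthetic cohort plus its machine-readable truth ledger."""

    config: CohortConfig
    pedigree: Pedigree
    phenotype_rows: list[dict]
    panel: GenePanel
    known_pathogenic: KnownPathogenicTable
    family_variants: dict[str, list[AnnotatedVariant]]
    family_samples: dict[str, list[str]]
    controls: dict[str, set[VariantKey]]
    snp_tracks: dict[str, SnpGenotypeTrack]
    truth: dict

    @property
    def family_ids(self) -> list[str]:
        return sorted(self.family_variants)

    def write(self, outdir: str | os.PathLike) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_ped(outdir / "pedigree.ped", self.pedigree)
        _write_phenotypes(outdir / "phenotypes.tsv", self.phenotype_rows)
        write_gene_panel(outdir / "gene_panel.tsv", self.panel)
        write_known_pathogenic(
            outdir / "known_pathogenic.tsv", self.known_pathogenic
        )
        write_controls(outdir / "controls.tsv", self.controls)
        write_snp_tracks(outdir / "snp_tracks.tsv", self.snp_tracks)
        vcf_dir = outdir / "vcf"
        vcf_dir.mkdir(exist_ok=True)
        for fam in self.family_ids:
            write_vcf(
                vcf_dir / f"{fam}.vcf",
                self.family_variants[fam],
                self.family_samples[fam],
            )
        with open(outdir / "truth.json", "w", encoding="utf-8") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _write_phenotypes(path, rows: list[dict]) -> None:
    import pandas as pd

    pd.DataFrame(
        rows,
        columns=["family", "patient", "age", "sex", "ofc_z",
                 "consanguineous", "affected", "hpo_terms"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pedigree / phenotype construction
# ---------------------------------------------------------------------------


def build_study_pedigree() -> tuple[Pedigree, dict[str, list[str]]]:
    """The 35-family study pedigree: one trio per singleton patient, a
    quartet per sib-pair; family F04 additionally carries the proband's
    affected mother and an unaffected maternal aunt; the father of family
    F23 is ungenotyped (present in the pedigree only)."""
    individuals: list[Individual] = []
    genotyped: dict[str, list[str]] = {}
    families: dict[str, list[tuple[int, str, bool]]] = {}
    for num, _age, sex, _ofc, consang, _sib in PATIENT_TABLE:
        fam = family_of_patient(num)
        families.setdefault(fam, []).append((num, sex, consang))

    for fam in sorted(families):
        patients = families[fam]
        father, mother = f"{fam}_FA", f"{fam}_MO"
        consang = any(c for _, _, c in patients)
        mother_affected = fam == "F04"
        individuals.append(
            Individual(fam, father, None, None, Sex.MALE, False)
        )
        individuals.append(
            Individual(fam, mother, None, None, Sex.FEMALE, mother_affected)
        )
        samples = []
        for num, sex, _ in patients:
            pid = patient_id(num)
            individuals.append(
                Individual(
                    fam, pid, father, mother,
                    Sex.MALE if sex == "m" else Sex.FEMALE,
                    True, consanguineous_parents=consang,
                )
            )
            samples.append(pid)
        samples += [father, mother]
        if fam == "F23":
            samples.remove(father)  # father unavailable for testing
        if fam == "F04":
            aunt = f"{fam}_AUNT"
            individuals.append(
                Individual(fam, aunt, None, None, Sex.FEMALE, False)
            )
            samples.append(aunt)
        genotyped[fam] = samples
    return Pedigree(individuals), genotyped


def build_study_phenotype_rows() -> list[dict]:
    rows = []
    for num, age, sex, ofc, consang, _sib in PATIENT_TABLE:
        rows.append(
            {
                "family": family_of_patient(num),
                "patient": patient_id(num),
                "age": age,
                "sex": sex,
                "ofc_z": "" if ofc is None else ofc,
                "consanguineous": int(consang),
                "affected": 1,
                "hpo_terms": ",".join(PATIENT_HPO),
            }
        )
    return rows


def build_gene_panel(config: CohortConfig) -> GenePanel:
    entries = [
        GenePanelEntry(
            gene=gene,
            hpo_terms=frozenset({"HP:0011451", "HP:0000234", "HP:0002011"}),
            disorder=disorder,
            inheritance_modes=frozenset({InheritanceMode(mode)}),
        )
        for gene, disorder, mode in CAUSAL_PANEL_ROWS
    ]
    for i in range(config.n_decoy_panel_genes):
        entries.append(
            GenePanelEntry(
                gene=f"PANELG{i + 1:02d}",
                hpo_terms=frozenset({"HP:0011451", "HP:0000707"}),
                disorder=f"Synthetic microcephaly disorder {i + 1}",
                inheritance_modes=frozenset(
                    {InheritanceMode.AR, InheritanceMode.AD}
                ),
            )
        )
    return GenePanel(entries)


def build_known_pathogenic(config: CohortConfig) -> KnownPathogenicTable:
    """Lookup rows for the literature-reported causal alleles plus decoys."""
    entries = []
    reported = {"RAB3GAP1", "BRCA2", "RNASEH2B"}
    disorders = dict((g, d) for g, d, _ in CAUSAL_PANEL_ROWS)
    for spec in config.causal_specs:
        if spec.gene not in reported:
            continue
        for allele in spec.alleles:
            entries.append(
                KnownPathogenicEntry(
                    chrom=allele.chrom, pos=allele.pos,
                    ref=allele.ref, alt=allele.alt,
                    gene=spec.gene, protein_change=allele.protein_change,
                    disorder=disorders.get(spec.gene, ""),
                    hpo_terms=frozenset({"HP:0011451"}),
                )
            )
    # decoy entries at coordinates no cohort variant occupies
    for i in range(5):
        entries.append(
            KnownPathogenicEntry(
                chrom="9", pos=1_000_000 + i * 10_000, ref="A", alt="G",
                gene=f"DECOY{i + 1}", protein_change=None,
                disorder="Synthetic unrelated disorder",
                hpo_terms=frozenset({"HP:0001250"}),
            )
        )
    return KnownPathogenicTable(entries)


# ---------------------------------------------------------------------------
# background variant sites
# ---------------------------------------------------------------------------

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class _Site:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: Consequence
    af_true: float
    pop_freqs: tuple[tuple[str, float], ...]
    predictions: tuple[tuple[str, str], ...]


def _draw_background_sites(config: CohortConfig, rng: np.random.Generator,
                           panel: GenePanel) -> list[_Site]:
    panel_genes = sorted(
        {e.gene for e in panel.entries} - {g for g, _, _ in CAUSAL_PANEL_ROWS}
    )
    background_genes = [f"BGDG{i + 1:03d}" for i in range(config.n_background_genes)]
    sites: list[_Site] = []
    used_pos: set[tuple[str, int]] = set()
    for _ in range(config.n_background_sites):
        chrom = str(rng.integers(1, 23))
        pos = int(rng.integers(1_000_000, 200_000_000))
        while (chrom, pos) in used_pos:
            pos = int(rng.integers(1_000_000, 200_000_000))
        used_pos.add((chrom, pos))
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        in_panel = rng.random() < config.panel_gene_fraction
        gene = (
            panel_genes[int(rng.integers(len(panel_genes)))]
            if in_panel and panel_genes
            else background_genes[int(rng.integers(len(background_genes)))]
        )
        consequence = rng.choice(
            [Consequence.MISSENSE, Consequence.SYNONYMOUS, Consequence.OTHER],
            p=[0.4, 0.4, 0.2],
        )
        if rng.random() < config.common_site_fraction:
            af = float(rng.uniform(0.05, 0.5))
            freqs = []
            for db in ("dbSNP", "1000G", "Seattle", "GoNL"):
                jitter = float(np.clip(af * rng.uniform(0.9, 1.1), 0.001, 0.999))
                freqs.append((db, round(jitter, 6)))
        else:
            af = float(rng.uniform(0.0005, 0.01))
            freqs = []
            for db in ("dbSNP", "1000G", "Seattle", "GoNL", "EVS", "ExAC"):
                if rng.random() < 0.3:
                    freqs.append((db, round(float(rng.uniform(0.0001, 0.019)), 6)))
        predictions = []
        if consequence is Consequence.MISSENSE:
            for alg in _D3:
                predictions.append(
                    (alg, str(rng.choice(["D", "T", "U"], p=[0.2, 0.6, 0.2])))
                )
        sites.append(
            _Site(
                chrom=chrom, pos=pos, ref=str(ref), alt=str(alt), gene=gene,
                consequence=Consequence(consequence), af_true=af,
                pop_freqs=tuple(freqs), predictions=tuple(predictions),
            )
        )
    sites.sort(key=lambda s: (int(s.chrom), s.pos))
    return sites


def _draw_artifact_sites(config: CohortConfig, rng: np.random.Generator) -> list[_Site]:
    """Run-artifact sites: rare, panel-gene annotated, recurring in every
    control sample; they must survive depth and frequency filters so that
    only the control stage catches them."""
    sites = []
    for i in range(config.n_artifact_sites):
        sites.append(
            _Site(
                chrom="11", pos=5_000_000 + i * 50_000, ref="G", alt="T",
                gene=f"PANELG{(i % max(config.n_decoy_panel_genes, 1)) + 1:02d}",
                consequence=Consequence.MISSENSE, af_true=0.0,
                pop_freqs=(), predictions=(),
            )
        )
    return sites


# ---------------------------------------------------------------------------
# genotype sampling
# ---------------------------------------------------------------------------


def _hwe_genotype(af: float, rng: np.random.Generator) -> Genotype:
    alleles = rng.random(2) < af
    n = int(alleles.sum())
    return (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT)[n]


_GT_TO_ALLELES = {
    Genotype.HOM_REF: (0, 0),
    Genotype.HET: (0, 1),
    Genotype.HOM_ALT: (1, 1),
}


def _child_genotype(
    father: Genotype, mother: Genotype, rng: np.random.Generator
) -> Genotype:
    fa = _GT_TO_ALLELES[father][int(rng.integers(2))]
    ma = _GT_TO_ALLELES[mother][int(rng.integers(2))]
    return (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT)[fa + ma]


def _depth(rng: np.random.Generator) -> int:
    return int(rng.integers(10, 80))


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def generate_cohort(config: CohortConfig) -> CohortBundle:
    """Generate the full synthetic cohort bundle, deterministic in the seed."""
    rng = np.random.default_rng(config.seed)
    if config.n_families != 35:
        raise ConfigError(
            "this generator models the 35-family study design; "
            "n_families must be 35"
        )
    pedigree, family_samples = build_study_pedigree()
    phenotype_rows = build_study_phenotype_rows()
    panel = build_gene_panel(config)
    known_path = build_known_pathogenic(config)
    specs_by_family = {
        family_of_patient(s.proband): s for s in config.causal_specs
    }

    background = _draw_background_sites(config, rng, panel)
    artifacts = _draw_artifact_sites(config, rng)

    family_variants: dict[str, list[AnnotatedVariant]] = {}
    truth_causal = []
    for fam in sorted(family_samples):
        samples = family_samples[fam]
        fam_ped = pedigree.family(fam)
        members = {i.individual_id: i for i in fam_ped.members()}
        father_id, mother_id = f"{fam}_FA", f"{fam}_MO"
        children = [
            s for s in samples
            if members[s].father_id is not None
        ]
        variants: list[AnnotatedVariant] = []

        # background sites: parents from Hardy-Weinberg at the site's true
        # frequency, children by Mendelian transmission
        lowdepth_budget = config.n_lowdepth_sites_per_family
        for site in background:
            father_gt = _hwe_genotype(site.af_true, rng)
            mother_gt = _hwe_genotype(site.af_true, rng)
            genotypes = {}
            if father_id in samples:
                genotypes[father_id] = father_gt
            if mother_id in samples:
                genotypes[mother_id] = mother_gt
            for child in children:
                genotypes[child] = _child_genotype(father_gt, mother_gt, rng)
            for extra in samples:
                if extra not in genotypes:  # e.g. the F04 aunt
                    genotypes[extra] = _hwe_genotype(site.af_true, rng)
            if not any(
                genotypes[s] is not Genotype.HOM_REF for s in samples
            ):
                continue
            depths = {s: _depth(rng) for s in samples}
            proband = children[0] if children else samples[0]
            if (
                lowdepth_budget > 0
                and genotypes[proband] is Genotype.HET
                and site.af_true < 0.05
            ):
                depths[proband] = int(rng.integers(1, 5))
                lowdepth_budget -= 1
            variants.append(
                AnnotatedVariant(
                    chrom=site.chrom, pos=site.pos, ref=site.ref,
                    alt=site.alt, gene=site.gene,
                    consequence=site.consequence,
                    genotypes=genotypes, read_depths=depths,
                    pop_freqs=dict(site.pop_freqs),
                    prediction_verdicts={
                        alg: {"D": PredictionVerdict.DELETERIOUS,
                              "T": PredictionVerdict.TOLERATED,
                              "U": PredictionVerdict.UNKNOWN}[code]
                        for alg, code in site.predictions
                    },
                )
            )

        # run artifacts: systematic miscalls recurring across samples,
        # planted heterozygous family-wide in roughly a third of families
        for site in artifacts:
            if rng.random() < 0.35 and children:
                genotypes = {s: Genotype.HET for s in samples}
                variants.append(
                    AnnotatedVariant(
                        chrom=site.chrom, pos=site.pos, ref=site.ref,
                        alt=site.alt, gene=site.gene,
                        consequence=site.consequence,
                        genotypes=genotypes,
                        read_depths={s: _depth(rng) for s in samples},
                    )
                )

        # planted causal genotype
        spec = specs_by_family.get(fam)
        if spec is not None:
            affected = [
                s for s in children if members[s].affected
            ]
            for allele in spec.alleles:
                genotypes = {}
                if allele.origin == "both":
                    parent_gts = {father_id: Genotype.HET,
                                  mother_id: Genotype.HET}
                    child_gt = Genotype.HOM_ALT
                elif allele.origin == "father":
                    parent_gts = {father_id: Genotype.HET,
                                  mother_id: Genotype.HOM_REF}
                    child_gt = Genotype.HET
                elif allele.origin == "mother":
                    parent_gts = {father_id: Genotype.HOM_REF,
                                  mother_id: Genotype.HET}
                    child_gt = Genotype.HET
                else:  # de novo
                    parent_gts = {father_id: Genotype.HOM_REF,
                                  mother_id: Genotype.HOM_REF}
                    child_gt = Genotype.HET
                for parent, gt in parent_gts.items():
                    if parent in samples:
                        genotypes[parent] = gt
                for child in affected:
                    genotypes[child] = child_gt
                for extra in samples:
                    if extra not in genotypes:
                        genotypes[extra] = Genotype.HOM_REF
                variants.append(
                    AnnotatedVariant(
                        chrom=allele.chrom, pos=allele.pos, ref=allele.ref,
                        alt=allele.alt, gene=spec.gene,
                        consequence=allele.consequence,
                        genotypes=genotypes,
                        read_depths={s: int(rng.integers(20, 61))
                                     for s in samples},
                        pop_freqs=dict(allele.pop_freqs),
                        prediction_verdicts={
                            alg: PredictionVerdict.DELETERIOUS
                            for alg in allele.deleterious_predictions
                        },
                        known_pathogenic=allele.known_pathogenic,
                        sanger_confirmed=True,
                        protein_change=allele.protein_change,
                    )
                )
            truth_causal.append(
                {
                    "family": fam,
                    "patients": sorted(
                        s for s in children if members[s].affected
                    ),
                    "gene": spec.gene,
                    "model": spec.model.value,
                    "variants": [list(a.key) for a in spec.alleles],
                }
            )
        family_variants[fam] = variants

    # control samples: every artifact site plus a frequency-proportional
    # draw of the common background sites
    controls: dict[str, set[VariantKey]] = {}
    for i in range(config.n_controls):
        keys = {(s.chrom, s.pos, s.ref, s.alt) for s in artifacts}
        for site in background:
            carrier_prob = 1 - (1 - site.af_true) ** 2
            if rng.random() < carrier_prob:
                keys.add((site.chrom, site.pos, site.ref, site.alt))
        controls[f"CTRL{i + 1}"] = keys

    snp_tracks, truth_roh = _generate_array_tracks(config, rng)

    truth = {
        "seed": config.seed,
        "n_families": config.n_families,
        "causal": sorted(truth_causal, key=lambda t: t["family"]),
        "roh": truth_roh,
        "artifact_sites": sorted(
            [list(k) for k in {(s.chrom, s.pos, s.ref, s.alt)
                               for s in artifacts}]
        ),
    }
    return CohortBundle(
        config=config,
        pedigree=pedigree,
        phenotype_rows=phenotype_rows,
        panel=panel,
        known_pathogenic=known_path,
        family_variants=family_variants,
        family_samples=family_samples,
        controls=controls,
        snp_tracks=snp_tracks,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# SNP-array tracks
# ---------------------------------------------------------------------------


def _snp_positions(
    chrom_length: int, density_per_mb: float, rng: np.random.Generator
) -> list[int]:
    n = int(chrom_length / 1e6 * density_per_mb)
    positions: np.ndarray = np.unique(
        rng.integers(1, chrom_length + 1, size=2 * n)
    )
    while len(positions) < n:  # pragma: no cover - astronomically unlikely
        positions = np.unique(
            np.concatenate(
                [positions, rng.integers(1, chrom_length + 1, size=n)]
            )
        )
    keep = np.sort(rng.choice(len(positions), size=n, replace=False))
    return [int(p) for p in positions[keep]]


def generate_snp_track(
    sample_id: str,
    chrom: str,
    chrom_length: int,
    density_per_mb: float,
    roh_plan: list[tuple[int, int]] | None = None,
    rng: np.random.Generator | int | None = None,
    no_call_rate: float = 0.0,
) -> tuple[SnpGenotypeTrack, list[dict]]:
    """Simulate a single-sample SNP genotype track.

    Outside planted runs of homozygosity, genotypes follow Hardy-Weinberg
    at a per-SNP minor-allele frequency drawn uniformly from [0.05, 0.5];
    inside a planted run every call is homozygous. Returns the track and
    the planted-truth interval records.
    """
    if density_per_mb <= 0:
        raise ConfigError("SNP density must be positive")
    roh_plan = roh_plan or []
    for start, end in roh_plan:
        if start < 1 or end > chrom_length or start > end:
            raise ConfigError(
                f"planted ROH {start}-{end} outside chromosome of length "
                f"{chrom_length}"
            )
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    positions = _snp_positions(chrom_length, density_per_mb, rng)
    records = []
    for pos in positions:
        maf = float(rng.uniform(0.05, 0.5))
        in_roh = any(start <= pos <= end for start, end in roh_plan)
        if no_call_rate and rng.random() < no_call_rate:
            gt = "NC"
        elif in_roh:
            gt = "BB" if rng.random() < maf else "AA"
        else:
            u = rng.random()
            if u < (1 - maf) ** 2:
                gt = "AA"
            elif u < (1 - maf) ** 2 + 2 * maf * (1 - maf):
                gt = "AB"
            else:
                gt = "BB"
        records.append((chrom, pos, gt))
    truth = [
        {"sample": sample_id, "chrom": chrom, "start": start, "end": end,
         "mode": SharingMode.SINGLE_ROH.value}
        for start, end in roh_plan
    ]
    return SnpGenotypeTrack(sample_id=sample_id, records=records), truth


def generate_sib_pair_tracks(
    sample_a: str,
    sample_b: str,
    chrom: str,
    chrom_length: int,
    density_per_mb: float,
    shared_plan: tuple[SharingMode, int, int] | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[SnpGenotypeTrack, SnpGenotypeTrack, list[dict]]:
    """Simulate two sib tracks on identical SNP positions with one planted
    sharing region of the requested mode."""
    if density_per_mb <= 0:
        raise ConfigError("SNP density must be positive")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    positions = _snp_positions(chrom_length, density_per_mb, rng)
    rec_a, rec_b = [], []
    mode, start, end = shared_plan if shared_plan else (None, 0, -1)
    if shared_plan and (start < 1 or end > chrom_length):
        raise ConfigError("planted shared region outside chromosome")

    def hwe(maf: float) -> str:
        u = rng.random()
        if u < (1 - maf) ** 2:
            return "AA"
        if u < (1 - maf) ** 2 + 2 * maf * (1 - maf):
            return "AB"
        return "BB"

    for pos in positions:
        maf = float(rng.uniform(0.05, 0.5))
        if shared_plan and start <= pos <= end:
            if mode is SharingMode.SIBS_SHARED_HOM:
                gt = "BB" if rng.random() < maf else "AA"
                ga = gb = gt
            elif mode is SharingMode.RECESSIVE_SHARED:
                ga = gb = hwe(maf)
            else:  # dominant: share at least one allele
                ga = hwe(maf)
                if ga == "AB":
                    gb = hwe(maf)
                elif rng.random() < 0.5:
                    gb = "AB"
                else:
                    gb = ga
            rec_a.append((chrom, pos, ga))
            rec_b.append((chrom, pos, gb))
        else:
            rec_a.append((chrom, pos, hwe(maf)))
            rec_b.append((chrom, pos, hwe(maf)))
    truth = (
        [{"samples": [sample_a, sample_b], "chrom": chrom, "start": start,
          "end": end, "mode": mode.value}]
        if shared_plan
        else []
    )
    return (
        SnpGenotypeTrack(sample_id=sample_a, records=rec_a),
        SnpGenotypeTrack(sample_id=sample_b, records=rec_b),
        truth,
    )


def _generate_array_tracks(
    config: CohortConfig, rng: np.random.Generator
) -> tuple[dict[str, SnpGenotypeTrack], list[dict]]:
    tracks: dict[str, SnpGenotypeTrack] = {}
    truth: list[dict] = []
    for plan in config.roh_plans:
        if plan.mode is SharingMode.SINGLE_ROH:
            track, t = generate_snp_track(
                plan.samples[0], plan.chrom, config.snp_chrom_length,
                config.snp_density_per_mb,
                roh_plan=[(plan.start, plan.end)], rng=rng,
                no_call_rate=config.no_call_rate,
            )
            tracks[plan.samples[0]] = track
            truth.extend(t)
        else:
            track_a, track_b, t = generate_sib_pair_tracks(
                plan.samples[0], plan.samples[1], plan.chrom,
                config.snp_chrom_length, config.snp_density_per_mb,
                shared_plan=(plan.mode, plan.start, plan.end), rng=rng,
            )
            tracks[plan.samples[0]] = track_a
            tracks[plan.samples[1]] = track_b
            truth.extend(t)
    return tracks, truth


def config_to_dict(config: CohortConfig) -> dict:
    d = dataclasses.asdict(config)
    d["causal_specs"] = [s.gene for s in config.causal_specs]
    d["roh_plans"] = [
        {"samples": list(p.samples), "mode": p.mode.value, "chrom": p.chrom,
         "start": p.start, "end": p.end}
        for p in config.roh_plans
    ]
    return d
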