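"""Core domain types: annotated variants, pedigrees, phenotypes, gene panels.

Conventions used throughout the package:

* Genomic positions are 1-based inclusive (VCF convention); intervals
  produced by the ROH module are likewise 1-based inclusive in memory and
  only converted to 0-based half-open when written as BED.
* chrX is recognised under the labels ``X``, ``chrX`` and ``23``; male
  genotypes on chrX are normalised to hemizygous calls.
* An absent population frequency means "not observed in that database",
  which is deliberately distinct from an observed frequency of 0.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import PedigreeError, SchemaError, ValidationError

X_LABELS = {"X", "chrX", "23"}
Y_LABELS = {"Y", "chrY", "24"}
MT_LABELS = {"MT", "chrM", "chrMT", "M", "25"}

#: Population databases consulted by the 2 % benign-frequency filter.
CASCADE_DATABASES = ("dbSNP", "1000G", "Seattle", "GoNL")
#: Additional databases consulted only at the causality stage.
CAUSALITY_EXTRA_DATABASES = ("EVS", "ExAC")
ALL_DATABASES = CASCADE_DATABASES + CAUSALITY_EXTRA_DATABASES

#: HPO terms used as the default phenotype-panel query: microcephaly
#: (congenital, postnatal, progressive), nervous-system abnormality,
#: and abnormality of the head.
DEFAULT_HPO_QUERY = frozenset(
    {
        "HP:0011451",
        "HP:0005484",
        "HP:0000253",
        "HP:0002011",
        "HP:0000707",
        "HP:0000234",
    }
)

_HPO_RE = re.compile(r"^HP:\d{7}$")


class Genotype(str, enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    HEMI = "hemi"
    NO_CALL = "no_call"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Genotypes that carry at least one ALT allele.
CARRIER_GENOTYPES = frozenset({Genotype.HET, Genotype.HOM_ALT, Genotype.HEMI})


class Consequence(str, enum.Enum):
    FRAMESHIFT = "frameshift"
    STOP_GAINED = "stop_gained"
    SPLICE_SITE = "splice_site"
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    INFRAME_INDEL = "inframe_indel"
    OTHER = "other"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Consequence classes treated as truncating / splice-disrupting.
TRUNCATING_CONSEQUENCES = frozenset(
    {Consequence.FRAMESHIFT, Consequence.STOP_GAINED, Consequence.SPLICE_SITE}
)


class PredictionVerdict(str, enum.Enum):
    DELETERIOUS = "deleterious"
    TOLERATED = "tolerated"
    UNKNOWN = "unknown"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class InheritanceMode(str, enum.Enum):
    AR = "AR"
    AD = "AD"
    XL = "XL"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


VariantKey = tuple[str, int, str, str]


@dataclass
class AnnotatedVariant:
    """One biallelic called variant with its annotations and genotypes.

    Multi-allelic VCF records are decomposed before construction, so
    ``alt`` is always a single allele and every per-sample genotype is
    expressed relative to that allele.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    consequence: Consequence = Consequence.OTHER
    genotypes: dict[str, Genotype] = field(default_factory=dict)
    read_depths: dict[str, int] = field(default_factory=dict)
    pop_freqs: dict[str, float] = field(default_factory=dict)
    prediction_verdicts: dict[str, PredictionVerdict] = field(default_factory=dict)
    known_pathogenic: bool = False
    sanger_confirmed: bool = False
    protein_change: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        for db, freq in self.pop_freqs.items():
            if not 0.0 <= freq <= 1.0:
                raise ValidationError(
                    f"allele frequency {freq} in {db} outside [0,1] "
                    f"at {self.chrom}:{self.pos}"
                )
        for sample, depth in self.read_depths.items():
            if depth < 0:
                raise ValidationError(f"negative read depth for {sample}")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_x(self) -> bool:
        return self.chrom in X_LABELS

    @property
    def is_autosomal(self) -> bool:
        return not (
            self.chrom in X_LABELS or self.chrom in Y_LABELS or self.chrom in MT_LABELS
        )

    def genotype(self, sample: str) -> Genotype:
        return self.genotypes.get(sample, Genotype.NO_CALL)

    def is_carrier(self, sample: str) -> bool:
        return self.genotype(sample) in CARRIER_GENOTYPES

    def depth(self, sample: str) -> int:
        """Read depth for ``sample``; missing depth counts as 0."""
        return self.read_depths.get(sample, 0)


@dataclass(frozen=True)
class Individual:
    family_id: str
    individual_id: str
    father_id: str | None
    mother_id: str | None
    sex: Sex
    affected: bool
    consanguineous_parents: bool = False


class Pedigree:
    """A set of individuals with resolved parental links.

    May span several families (a whole-cohort PED file); :meth:`family`
    extracts the single-family view that the inheritance models operate on.
    """

    def __init__(self, individuals: Iterable[Individual]):
        self.individuals: dict[str, Individual] = {}
        for ind in individuals:
            if ind.individual_id in self.individuals:
                raise PedigreeError(f"duplicate individual id {ind.individual_id}")
            self.individuals[ind.individual_id] = ind
        self._check_structure()

    def _check_structure(self) -> None:
        for ind in self.individuals.values():
            for parent_id in (ind.father_id, ind.mother_id):
                if parent_id is not None and parent_id in self.individuals:
                    parent = self.individuals[parent_id]
                    if parent.family_id != ind.family_id:
                        raise PedigreeError(
                            f"parent {parent_id} of {ind.individual_id} "
                            "belongs to a different family"
                        )
        # no individual may be its own ancestor
        for start in self.individuals:
            seen: set[str] = set()
            stack = [start]
            while stack:
                cur = self.individuals.get(stack.pop())
                if cur is None:
                    continue
                for parent_id in (cur.father_id, cur.mother_id):
                    if parent_id is None:
                        continue
                    if parent_id == start:
                        raise PedigreeError(
                            f"cyclic parentage involving {start}"
                        )
                    if parent_id not in seen:
                        seen.add(parent_id)
                        stack.append(parent_id)

    def __len__(self) -> int:
        return len(self.individuals)

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self.individuals

    def __getitem__(self, individual_id: str) -> Individual:
        return self.individuals[individual_id]

    @property
    def family_ids(self) -> list[str]:
        return sorted({ind.family_id for ind in self.individuals.values()})

    def family(self, family_id: str) -> "Pedigree":
        members = [
            ind for ind in self.individuals.values() if ind.family_id == family_id
        ]
        if not members:
            raise PedigreeError(f"no such family: {family_id}")
        return Pedigree(members)

    def members(self) -> list[Individual]:
        return sorted(self.individuals.values(), key=lambda i: i.individual_id)

    def affected_members(self) -> list[Individual]:
        return [i for i in self.members() if i.affected]

    def unaffected_members(self) -> list[Individual]:
        return [i for i in self.members() if not i.affected]

    def father_of(self, individual_id: str) -> Individual | None:
        fid = self.individuals[individual_id].father_id
        return self.individuals.get(fid) if fid else None

    def mother_of(self, individual_id: str) -> Individual | None:
        mid = self.individuals[individual_id].mother_id
        return self.individuals.get(mid) if mid else None

    def is_consanguineous_family(self, family_id: str) -> bool:
        return any(
            i.consanguineous_parents
            for i in self.individuals.values()
            if i.family_id == family_id
        )

    def n_affected_in_family(self, family_id: str) -> int:
        return sum(
            1
            for i in self.individuals.values()
            if i.family_id == family_id and i.affected
        )


@dataclass(frozen=True)
class PhenotypeRecord:
    individual_id: str
    age: float | None
    ofc_z: float | None
    hpo_terms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.ofc_z is not None and not (
            float("-inf") < self.ofc_z < float("inf")
        ):
            raise ValidationError(f"non-finite OFC Z-score for {self.individual_id}")
        for term in self.hpo_terms:
            if not _HPO_RE.match(term):
                raise ValidationError(f"invalid HPO id {term!r}")


class PhenotypeTable:
    """Phenotype records keyed by individual id."""

    def __init__(self, records: Iterable[PhenotypeRecord]):
        self.records: dict[str, PhenotypeRecord] = {}
        for rec in records:
            if rec.individual_id in self.records:
                raise SchemaError(f"duplicate phenotype row for {rec.individual_id}")
            self.records[rec.individual_id] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self.records

    def __getitem__(self, individual_id: str) -> PhenotypeRecord:
        return self.records[individual_id]

    def hpo_terms(self, individual_id: str) -> frozenset[str]:
        rec = self.records.get(individual_id)
        return rec.hpo_terms if rec is not None else frozenset()


@dataclass(frozen=True)
class GenePanelEntry:
    gene: str
    hpo_terms: frozenset[str]
    disorder: str
    inheritance_modes: frozenset[InheritanceMode]

    def __post_init__(self) -> None:
        if not self.inheritance_modes:
            raise ValidationError(
                f"panel entry for {self.gene} has no inheritance mode"
            )


class GenePanel:
    """Gene <-> phenotype-term <-> disorder associations used for filtering."""

    def __init__(self, entries: Iterable[GenePanelEntry]):
        self.entries: list[GenePanelEntry] = []
        seen: set[tuple[str, str]] = set()
        for entry in entries:
            key = (entry.gene, entry.disorder)
            if key in seen:
                raise SchemaError(f"duplicate panel row for gene/disorder {key}")
            seen.add(key)
            self.entries.append(entry)

    def __len__(self) -> int:
        return len(self.entries)

    def entries_for_gene(self, gene: str) -> list[GenePanelEntry]:
        return [e for e in self.entries if e.gene == gene]

    def gene_matches_terms(self, gene: str, query_terms: Iterable[str]) -> bool:
        """True if any panel entry for ``gene`` shares an HPO term with the query."""
        query = set(query_terms)
        return any(e.hpo_terms & query for e in self.entries_for_gene(gene))


@dataclass(frozen=True)
class KnownPathogenicEntry:
    """One row of the known-pathogenic lookup (a stand-in for a curated
    mutation database), keyed by coordinates or by (gene, protein change)."""

    chrom: str | None = None
    pos: int | None = None
    ref: str | None = None
    alt: str | None = None
    gene: str | None = None
    protein_change: str | None = None
    disorder: str = ""
    hpo_terms: frozenset[str] = frozenset()

    @property
    def coord_key(self) -> VariantKey | None:
        if self.chrom and self.pos and self.ref and self.alt:
            return (self.chrom, self.pos, self.ref, self.alt)
        return None

    @property
    def protein_key(self) -> tuple[str, str] | None:
        if self.gene and self.protein_change:
            return (self.gene, self.protein_change)
        return None


class KnownPathogenicTable:
    def __init__(self, entries: Iterable[KnownPathogenicEntry]):
        self.by_coord: dict[VariantKey, KnownPathogenicEntry] = {}
        self.by_protein: dict[tuple[str, str], KnownPathogenicEntry] = {}
        self.entries: list[KnownPathogenicEntry] = []
        for entry in entries:
            ck, pk = entry.coord_key, entry.protein_key
            if ck is None and pk is None:
                raise SchemaError(
                    "known-pathogenic row needs coordinates or gene+protein change"
                )
            if ck is not None:
                if ck in self.by_coord:
                    raise SchemaError(f"duplicate known-pathogenic key {ck}")
                self.by_coord[ck] = entry
            if pk is not None:
                if pk in self.by_protein:
                    raise SchemaError(f"duplicate known-pathogenic key {pk}")
                self.by_protein[pk] = entry
            self.entries.append(entry)

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, variant: AnnotatedVariant) -> KnownPathogenicEntry | None:
        entry = self.by_coord.get(variant.key)
        if entry is not None:
            return entry
        if variant.gene and variant.protein_change:
            return self.by_protein.get((variant.gene, variant.protein_change))
        return None

    def contains(self, variant: AnnotatedVariant) -> bool:
        return self.lookup(variant) is not None


def sample_ids(variants: Iterable[AnnotatedVariant]) -> set[str]:
    """All sample ids genotyped in any of the given variants."""
    out: set[str] = set()
    for v in variants:
        out.update(v.genotypes)
    return out


def genotyped_samples(
    variants: Iterable[AnnotatedVariant], pedigree: Pedigree
) -> set[str]:
    """Pedigree members that have genotype data in the variant set."""
    return sample_ids(variants) & set(pedigree.individuals)
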