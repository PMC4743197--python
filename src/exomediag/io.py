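"""Readers and writers for the file formats the pipeline touches.

VCF handling is built on :mod:`pysam`. The annotation dialect is a flat
INFO/FORMAT encoding of the fields the prioritization rules consume:

* ``GENE`` (Number=1, String) — gene symbol for the site.
* ``CSQCLASS`` (Number=A, String) — consequence class per ALT allele.
* ``AF_<db>`` (Number=A, Float) — allele frequency per population database
  (``dbSNP``, ``1000G``, ``Seattle``, ``GoNL``, ``EVS``, ``ExAC``); an
  absent key means the allele was not observed in that database.
* ``PRED_<alg>`` (Number=A, String) — per-algorithm deleteriousness verdict
  ``D``/``T``/``U``.
* ``KNOWN_PATH``, ``SANGER`` (Number=A, Integer) — 0/1 flags.
* ``HGVSP`` (Number=A, String) — optional protein-level change.
* FORMAT ``GT`` and ``DP``.

Multi-allelic sites are decomposed into one :class:`AnnotatedVariant` per
ALT allele on read; the writer emits biallelic records only.
"""

from __future__ import annotations

import math
import os
from typing import Iterable, Sequence

import pandas as pd
import pysam

from .errors import ParseError, PedigreeError, ReconciliationError, SchemaError
from .types import (
    ALL_DATABASES,
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
    PhenotypeRecord,
    PhenotypeTable,
    PredictionVerdict,
    Sex,
    X_LABELS,
)

_VERDICT_CODES = {
    "D": PredictionVerdict.DELETERIOUS,
    "T": PredictionVerdict.TOLERATED,
    "U": PredictionVerdict.UNKNOWN,
}
_VERDICT_TO_CODE = {v: k for k, v in _VERDICT_CODES.items()}

#: Default contig lengths (b37-like, rounded) used when writing VCFs.
DEFAULT_CONTIGS = {str(c): 250_000_000 for c in range(1, 23)} | {"X": 156_000_000}


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def _decode_gt(
    alleles: tuple[int | None, ...] | None, alt_index: int, male_x: bool
) -> Genotype:
    """Re-express a GT tuple relative to one kept ALT allele."""
    if alleles is None or len(alleles) == 0 or any(a is None for a in alleles):
        return Genotype.NO_CALL
    n_alt = sum(1 for a in alleles if a == alt_index)
    if len(alleles) == 1:
        return Genotype.HEMI if n_alt else Genotype.HOM_REF
    if male_x:
        # whole chrX treated as hemizygous in males (pseudoautosomal
        # handling is out of scope by default)
        return Genotype.HEMI if n_alt else Genotype.HOM_REF
    if n_alt >= 2:
        return Genotype.HOM_ALT
    if n_alt == 1:
        return Genotype.HET
    return Genotype.HOM_REF


def _per_alt(value, i: int):
    """Index a Number=A INFO value; scalars are shared across alleles."""
    if isinstance(value, tuple):
        return value[i] if i < len(value) else None
    return value


def _info_get(rec, key):
    """INFO lookup tolerating keys absent from the VCF header (pysam
    raises rather than returning the default for undeclared keys)."""
    try:
        return rec.info.get(key)
    except (KeyError, ValueError):
        return None


def read_vcf(path: str | os.PathLike, pedigree: Pedigree) -> list[AnnotatedVariant]:
    """Read an annotated VCF into decomposed :class:`AnnotatedVariant` records.

    Every sample in the VCF header must be present in ``pedigree``; sex from
    the pedigree drives hemizygous normalisation on chrX.
    """
    path = os.fspath(path)
    try:
        vcf = pysam.VariantFile(path)
    except (OSError, ValueError) as err:
        raise ParseError(f"cannot parse VCF {path}: {err}") from err

    samples = list(vcf.header.samples)
    unknown = [s for s in samples if s not in pedigree]
    if unknown:
        raise ReconciliationError(
            f"samples in {path} absent from pedigree: {', '.join(unknown)}"
        )
    male = {s: pedigree[s].sex is Sex.MALE for s in samples}

    db_keys = [k for k in vcf.header.info if k.startswith("AF_")]
    pred_keys = [k for k in vcf.header.info if k.startswith("PRED_")]

    out: list[AnnotatedVariant] = []
    try:
        records = list(vcf)
    except (OSError, ValueError) as err:
        raise ParseError(f"cannot parse VCF {path}: {err}") from err
    for rec in records:
        if rec.alts is None:
            continue
        gene = _info_get(rec, "GENE") or ""
        male_x = {s: male[s] and rec.chrom in X_LABELS for s in samples}
        for i, alt in enumerate(rec.alts):
            alt_index = i + 1
            csq_raw = _per_alt(_info_get(rec, "CSQCLASS"), i)
            try:
                csq = Consequence(csq_raw) if csq_raw else Consequence.OTHER
            except ValueError as err:
                raise ParseError(
                    f"{path}: unknown consequence {csq_raw!r} at "
                    f"{rec.chrom}:{rec.pos}"
                ) from err
            pop_freqs = {}
            for key in db_keys:
                val = _per_alt(_info_get(rec, key), i)
                if val is not None and not math.isnan(val):
                    pop_freqs[key[3:]] = round(float(val), 6)
            verdicts = {}
            for key in pred_keys:
                code = _per_alt(_info_get(rec, key), i)
                if code:
                    verdicts[key[5:]] = _VERDICT_CODES.get(
                        code, PredictionVerdict.UNKNOWN
                    )
            genotypes = {}
            depths = {}
            for s in samples:
                fmt = rec.samples[s]
                genotypes[s] = _decode_gt(fmt.get("GT"), alt_index, male_x[s])
                dp = fmt.get("DP")
                if dp is not None:
                    depths[s] = int(dp)
            hgvsp = _per_alt(_info_get(rec, "HGVSP"), i)
            out.append(
                AnnotatedVariant(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alt,
                    gene=str(gene),
                    consequence=csq,
                    genotypes=genotypes,
                    read_depths=depths,
                    pop_freqs=pop_freqs,
                    prediction_verdicts=verdicts,
                    known_pathogenic=bool(_per_alt(_info_get(rec, "KNOWN_PATH"), i)),
                    sanger_confirmed=bool(_per_alt(_info_get(rec, "SANGER"), i)),
                    protein_change=str(hgvsp) if hgvsp else None,
                )
            )
    vcf.close()
    return out


def _vcf_header(
    samples: Sequence[str], contigs: dict[str, int]
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for contig, length in contigs.items():
        header.contigs.add(contig, length=length)
    header.info.add("GENE", 1, "String", "Gene symbol")
    header.info.add("CSQCLASS", "A", "String", "Consequence class per ALT")
    for db in ALL_DATABASES:
        header.info.add(f"AF_{db}", "A", "Float", f"Allele frequency in {db}")
    for alg in ("SIFT", "Polyphen", "MutationTaster", "AlignGVGD", "Provean"):
        header.info.add(f"PRED_{alg}", "A", "String", f"{alg} verdict (D/T/U)")
    header.info.add("KNOWN_PATH", "A", "Integer", "Reported pathogenic (0/1)")
    header.info.add("SANGER", "A", "Integer", "Sanger confirmed (0/1)")
    header.info.add("HGVSP", "A", "String", "Protein change")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    for s in samples:
        header.add_sample(s)
    return header


_GT_TUPLES = {
    Genotype.HOM_REF: (0, 0),
    Genotype.HET: (0, 1),
    Genotype.HOM_ALT: (1, 1),
    Genotype.HEMI: (1,),
    Genotype.NO_CALL: (None, None),
}


def write_vcf(
    path: str | os.PathLike,
    variants: Iterable[AnnotatedVariant],
    samples: Sequence[str],
    contigs: dict[str, int] | None = None,
) -> None:
    """Write decomposed variants as a biallelic, coordinate-sorted VCF."""
    contigs = dict(contigs) if contigs else dict(DEFAULT_CONTIGS)
    variants = list(variants)
    for v in variants:
        if v.chrom not in contigs:
            contigs[v.chrom] = 250_000_000
    order = {c: i for i, c in enumerate(contigs)}
    variants.sort(key=lambda v: (order[v.chrom], v.pos, v.ref, v.alt))

    header = _vcf_header(samples, contigs)
    with pysam.VariantFile(os.fspath(path), "w", header=header) as out:
        for v in variants:
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt)
            )
            if v.gene:
                rec.info["GENE"] = v.gene
            rec.info["CSQCLASS"] = (v.consequence.value,)
            for db, freq in sorted(v.pop_freqs.items()):
                rec.info[f"AF_{db}"] = (freq,)
            for alg, verdict in sorted(v.prediction_verdicts.items()):
                rec.info[f"PRED_{alg}"] = (_VERDICT_TO_CODE[verdict],)
            rec.info["KNOWN_PATH"] = (int(v.known_pathogenic),)
            rec.info["SANGER"] = (int(v.sanger_confirmed),)
            if v.protein_change:
                rec.info["HGVSP"] = (v.protein_change,)
            for s in samples:
                rec.samples[s]["GT"] = _GT_TUPLES[v.genotype(s)]
                if s in v.read_depths:
                    rec.samples[s]["DP"] = v.read_depths[s]
            out.write(rec)


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------

_SEX_CODES = {"1": Sex.MALE, "2": Sex.FEMALE}
_AFFECTION_CODES = {"1": False, "2": True, "0": False, "-9": False}


def read_ped(path: str | os.PathLike) -> Pedigree:
    """Read a 6-column PED file (plus optional 7th ``consang`` 0/1 column)."""
    individuals: list[Individual] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected >= 6 PED columns")
            fam, iid, father, mother, sex_code, affection = fields[:6]
            if sex_code not in _SEX_CODES:
                raise ParseError(
                    f"{path}:{lineno}: unknown sex code {sex_code!r}"
                )
            if affection not in _AFFECTION_CODES:
                raise ParseError(
                    f"{path}:{lineno}: unknown affection code {affection!r}"
                )
            if father == iid or mother == iid:
                raise PedigreeError(
                    f"{path}:{lineno}: {iid} listed as its own parent"
                )
            consang = len(fields) >= 7 and fields[6] == "1"
            individuals.append(
                Individual(
                    family_id=fam,
                    individual_id=iid,
                    father_id=None if father == "0" else father,
                    mother_id=None if mother == "0" else mother,
                    sex=_SEX_CODES[sex_code],
                    affected=_AFFECTION_CODES[affection],
                    consanguineous_parents=consang,
                )
            )
    return Pedigree(individuals)


def write_ped(path: str | os.PathLike, pedigree: Pedigree) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ind in sorted(
            pedigree.individuals.values(),
            key=lambda i: (i.family_id, i.individual_id),
        ):
            fh.write(
                "\t".join(
                    [
                        ind.family_id,
                        ind.individual_id,
                        ind.father_id or "0",
                        ind.mother_id or "0",
                        "1" if ind.sex is Sex.MALE else "2",
                        "2" if ind.affected else "1",
                        "1" if ind.consanguineous_parents else "0",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------


def _read_tsv(path: str | os.PathLike, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as err:
        raise ParseError(f"cannot parse {path}: {err}") from err
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {missing}")
    return df


def _split_terms(raw: str) -> frozenset[str]:
    return frozenset(t.strip() for t in raw.split(",") if t.strip())


def read_gene_panel(path: str | os.PathLike) -> GenePanel:
    """Read a gene panel TSV: gene, hpo_terms, disorder, inheritance_modes."""
    df = _read_tsv(path, ["gene", "hpo_terms", "disorder", "inheritance_modes"])
    entries = []
    for row in df.itertuples(index=False):
        try:
            modes = frozenset(
                InheritanceMode(m.strip())
                for m in row.inheritance_modes.split(",")
                if m.strip()
            )
        except ValueError as err:
            raise SchemaError(
                f"{path}: bad inheritance mode for {row.gene}: {err}"
            ) from err
        entries.append(
            GenePanelEntry(
                gene=row.gene,
                hpo_terms=_split_terms(row.hpo_terms),
                disorder=row.disorder,
                inheritance_modes=modes,
            )
        )
    return GenePanel(entries)


def write_gene_panel(path: str | os.PathLike, panel: GenePanel) -> None:
    rows = [
        {
            "gene": e.gene,
            "hpo_terms": ",".join(sorted(e.hpo_terms)),
            "disorder": e.disorder,
            "inheritance_modes": ",".join(sorted(m.value for m in e.inheritance_modes)),
        }
        for e in panel.entries
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | os.PathLike) -> PhenotypeTable:
    """Read the phenotype TSV: family, patient, age, sex, ofc_z, consang,
    affected, hpo_terms. Empty age/ofc_z fields mean "not available"."""
    df = _read_tsv(
        path,
        ["family", "patient", "age", "sex", "ofc_z", "consanguineous",
         "affected", "hpo_terms"],
    )
    records = []
    for row in df.itertuples(index=False):
        records.append(
            PhenotypeRecord(
                individual_id=row.patient,
                age=float(row.age) if row.age != "" else None,
                ofc_z=float(row.ofc_z) if row.ofc_z != "" else None,
                hpo_terms=_split_terms(row.hpo_terms),
            )
        )
    return PhenotypeTable(records)


def read_phenotype_frame(path: str | os.PathLike) -> pd.DataFrame:
    """The raw phenotype table (including family/sex/consanguinity columns)."""
    df = _read_tsv(
        path,
        ["family", "patient", "age", "sex", "ofc_z", "consanguineous",
         "affected", "hpo_terms"],
    )
    if df["patient"].duplicated().any():
        raise SchemaError(f"{path}: duplicate patient rows")
    return df


def read_known_pathogenic(path: str | os.PathLike) -> KnownPathogenicTable:
    """Read the known-pathogenic lookup TSV (curated-database stand-in)."""
    df = _read_tsv(
        path,
        ["chrom", "pos", "ref", "alt", "gene", "protein_change", "disorder",
         "hpo_terms"],
    )
    entries = []
    for row in df.itertuples(index=False):
        entries.append(
            KnownPathogenicEntry(
                chrom=row.chrom or None,
                pos=int(row.pos) if row.pos != "" else None,
                ref=row.ref or None,
                alt=row.alt or None,
                gene=row.gene or None,
                protein_change=row.protein_change or None,
                disorder=row.disorder,
                hpo_terms=_split_terms(row.hpo_terms),
            )
        )
    return KnownPathogenicTable(entries)


def write_known_pathogenic(
    path: str | os.PathLike, table: KnownPathogenicTable
) -> None:
    rows = [
        {
            "chrom": e.chrom or "",
            "pos": e.pos if e.pos is not None else "",
            "ref": e.ref or "",
            "alt": e.alt or "",
            "gene": e.gene or "",
            "protein_change": e.protein_change or "",
            "disorder": e.disorder,
            "hpo_terms": ",".join(sorted(e.hpo_terms)),
        }
        for e in table.entries
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# control variant sets and SNP genotype tracks
# ---------------------------------------------------------------------------


def read_controls(path: str | os.PathLike) -> dict[str, set[tuple[str, int, str, str]]]:
    """Control-sample variant sets: TSV with sample, chrom, pos, ref, alt."""
    df = _read_tsv(path, ["sample", "chrom", "pos", "ref", "alt"])
    out: dict[str, set[tuple[str, int, str, str]]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.sample, set()).add(
            (row.chrom, int(row.pos), row.ref, row.alt)
        )
    return out


def write_controls(
    path: str | os.PathLike,
    controls: dict[str, set[tuple[str, int, str, str]]],
) -> None:
    rows = [
        {"sample": s, "chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3]}
        for s in sorted(controls)
        for k in sorted(controls[s])
    ]
    pd.DataFrame(rows, columns=["sample", "chrom", "pos", "ref", "alt"]).to_csv(
        path, sep="\t", index=False
    )


def read_snp_tracks(path: str | os.PathLike):
    """Read SNP genotype tracks (TSV: sample, chrom, pos, genotype)."""
    from .roh import SnpGenotypeTrack  # local import to avoid a cycle

    df = _read_tsv(path, ["sample", "chrom", "pos", "genotype"])
    tracks = {}
    for sample, group in df.groupby("sample", sort=True):
        records = [
            (row.chrom, int(row.pos), row.genotype)
            for row in group.itertuples(index=False)
        ]
        tracks[sample] = SnpGenotypeTrack(sample_id=sample, records=records)
    return tracks


def write_snp_tracks(path: str | os.PathLike, tracks) -> None:
    rows = [
        {"sample": t.sample_id, "chrom": chrom, "pos": pos, "genotype": gt}
        for t in (tracks.values() if isinstance(tracks, dict) else tracks)
        for chrom, pos, gt in t.records
    ]
    pd.DataFrame(rows, columns=["sample", "chrom", "pos", "genotype"]).to_csv(
        path, sep="\t", index=False
    )
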