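"""Cohort-level summaries and end-to-end pipeline orchestration.

The diagnostic yield is reported at the family level (diagnosed families /
all families), with diagnosed patients counted separately: every affected
member of a diagnosed family counts, so an affected sib-pair contributes
two patients to one family's diagnosis. Percentages round to the nearest
integer, halves away from zero.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .causality import (
    CausalityVerdict,
    VerdictClass,
    assess_evidence,
    classify,
    hgmd_fallback,
)
from .errors import ExomediagError, ReconciliationError
from .filters import CascadeConfig, FilterTrace, apply_cascade
from .inheritance import ModelType, apply_sequential_models
from .io import (
    read_controls,
    read_gene_panel,
    read_known_pathogenic,
    read_ped,
    read_phenotype_frame,
    read_vcf,
)
from .types import GenePanel, InheritanceMode, KnownPathogenicTable, Pedigree

logger = logging.getLogger(__name__)

_MODEL_TO_MODE = {
    ModelType.AR_HOM: InheritanceMode.AR,
    ModelType.AR_COMPHET: InheritanceMode.AR,
    ModelType.AD: InheritanceMode.AD,
    ModelType.XL: InheritanceMode.XL,
}


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (so 28.57 % -> 29)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class CohortReport:
    n_families: int
    n_patients: int
    n_diagnosed_families: int
    n_diagnosed_patients: int
    yield_percent: int
    model_breakdown: dict[str, int]
    distinct_causal_genes: list[str]
    mean_age_years: int | None
    mean_ofc_z: float | None
    n_suspected_recessive: int
    suspected_recessive_percent: int
    diagnosed_families: dict[str, dict] = field(default_factory=dict)
    failed_families: list[str] = field(default_factory=list)

    @property
    def n_distinct_causal_genes(self) -> int:
        return len(self.distinct_causal_genes)

    def to_dict(self) -> dict:
        return {
            "n_families": self.n_families,
            "n_patients": self.n_patients,
            "n_diagnosed_families": self.n_diagnosed_families,
            "n_diagnosed_patients": self.n_diagnosed_patients,
            "yield_percent": self.yield_percent,
            "model_breakdown": self.model_breakdown,
            "n_distinct_causal_genes": self.n_distinct_causal_genes,
            "distinct_causal_genes": self.distinct_causal_genes,
            "mean_age_years": self.mean_age_years,
            "mean_ofc_z": self.mean_ofc_z,
            "n_suspected_recessive": self.n_suspected_recessive,
            "suspected_recessive_percent": self.suspected_recessive_percent,
            "diagnosed_families": self.diagnosed_families,
            "failed_families": self.failed_families,
        }

    def to_text(self) -> str:
        lines = [
            f"Families analysed:      {self.n_families}",
            f"Patients analysed:      {self.n_patients}",
            f"Diagnosed families:     {self.n_diagnosed_families} "
            f"({self.yield_percent} %)",
            f"Diagnosed patients:     {self.n_diagnosed_patients}",
            "Inheritance breakdown:  "
            + ", ".join(
                f"{m}={self.model_breakdown.get(m, 0)}" for m in ("AR", "AD", "XL")
            ),
            f"Distinct causal genes:  {self.n_distinct_causal_genes} "
            f"({', '.join(self.distinct_causal_genes)})",
            f"Mean age (years):       {self.mean_age_years}",
            f"Mean OFC Z-score:       {self.mean_ofc_z}",
            f"Suspected recessive:    {self.n_suspected_recessive}/"
            f"{self.n_families} ({self.suspected_recessive_percent} %)",
        ]
        for fam in sorted(self.diagnosed_families):
            d = self.diagnosed_families[fam]
            lines.append(
                f"  {fam}: {d['gene']} ({d['model']}), "
                f"patients {', '.join(d['patients'])}"
            )
        if self.failed_families:
            lines.append("Failed families:        "
                         + ", ".join(self.failed_families))
        return "\n".join(lines) + "\n"


def _max_affected_sibship(family: Pedigree) -> int:
    """Largest set of affected full sibs (shared parent pair) in a family.
    An affected parent is not a sib of its children and does not make a
    family 'suspected recessive'."""
    sibships: dict[tuple[str | None, str | None], int] = {}
    for ind in family.affected_members():
        if ind.father_id is None and ind.mother_id is None:
            continue
        key = (ind.father_id, ind.mother_id)
        sibships[key] = sibships.get(key, 0) + 1
    return max(sibships.values(), default=0)


def phenotype_summary(
    phenotype_frame: pd.DataFrame, pedigree: Pedigree
) -> dict:
    """Cohort descriptives from the phenotype table and the pedigree.

    Mean age rounds to the nearest year; the mean OFC Z-score keeps one
    decimal and skips missing values. A family is suspected recessive when
    its parents are consanguineous or it contains two or more affected
    sibs.
    """
    ages = pd.to_numeric(phenotype_frame["age"], errors="coerce").dropna()
    ofc = pd.to_numeric(
        phenotype_frame["ofc_z"].replace("", None), errors="coerce"
    ).dropna()
    families = pedigree.family_ids
    suspected = [
        fam
        for fam in families
        if pedigree.is_consanguineous_family(fam)
        or _max_affected_sibship(pedigree.family(fam)) >= 2
    ]
    return {
        "mean_age_years": (
            round_half_away(float(ages.mean())) if len(ages) else None
        ),
        "mean_ofc_z": (
            float(f"{float(ofc.mean()):.1f}") if len(ofc) else None
        ),
        "n_ofc_available": int(len(ofc)),
        "n_suspected_recessive": len(suspected),
        "suspected_recessive_percent": round_half_away(
            100.0 * len(suspected) / len(families)
        )
        if families
        else 0,
        "suspected_recessive_families": suspected,
    }


def summarize_cohort(
    verdicts_by_family: dict[str, list[CausalityVerdict]],
    pedigree: Pedigree,
    phenotype_frame: pd.DataFrame,
    failed_families: list[str] | None = None,
) -> CohortReport:
    """Aggregate per-family verdicts into the cohort report.

    A family counts as diagnosed when it has at least one causative
    verdict; its reported gene/model is the top-ranked causative one.
    """
    families = pedigree.family_ids
    for fam in verdicts_by_family:
        if fam not in families:
            raise ReconciliationError(
                f"verdicts for family {fam} absent from pedigree"
            )
    n_patients = int((phenotype_frame["affected"].astype(int) == 1).sum())
    study_patients = set(phenotype_frame["patient"])

    diagnosed: dict[str, dict] = {}
    model_breakdown = {"AR": 0, "AD": 0, "XL": 0}
    genes: set[str] = set()
    n_diagnosed_patients = 0
    for fam in sorted(verdicts_by_family):
        causative = [
            v
            for v in verdicts_by_family[fam]
            if v.verdict is VerdictClass.CAUSATIVE
        ]
        if not causative:
            continue
        top = causative[0]  # classify() already ranked per family
        mode = _MODEL_TO_MODE[top.candidate.model].value
        model_breakdown[mode] += 1
        genes.add(top.candidate.gene)
        # diagnosed patients are affected *study patients*; an affected
        # relative outside the phenotype table (e.g. a transmitting
        # parent) supports segregation but is not a cohort patient
        affected = [
            i.individual_id
            for i in pedigree.family(fam).affected_members()
            if i.individual_id in study_patients
        ]
        n_diagnosed_patients += len(affected)
        diagnosed[fam] = {
            "gene": top.candidate.gene,
            "model": top.candidate.model.value,
            "mode": mode,
            "patients": affected,
            "variants": [list(k) for k in top.candidate.variant_keys],
        }

    summary = phenotype_summary(phenotype_frame, pedigree)
    n_families = len(families)
    return CohortReport(
        n_families=n_families,
        n_patients=n_patients,
        n_diagnosed_families=len(diagnosed),
        n_diagnosed_patients=n_diagnosed_patients,
        yield_percent=round_half_away(100.0 * len(diagnosed) / n_families)
        if n_families
        else 0,
        model_breakdown=model_breakdown,
        distinct_causal_genes=sorted(genes),
        mean_age_years=summary["mean_age_years"],
        mean_ofc_z=summary["mean_ofc_z"],
        n_suspected_recessive=summary["n_suspected_recessive"],
        suspected_recessive_percent=summary["suspected_recessive_percent"],
        diagnosed_families=diagnosed,
        failed_families=sorted(failed_families or []),
    )


# ---------------------------------------------------------------------------
# family-level and cohort-level pipeline
# ---------------------------------------------------------------------------


@dataclass
class FamilyResult:
    family_id: str
    verdicts: list[CausalityVerdict]
    trace: FilterTrace
    error: str | None = None


def analyse_family(
    variants,
    family_pedigree: Pedigree,
    panel: GenePanel,
    known_pathogenic: KnownPathogenicTable,
    patient_hpo,
    config: CascadeConfig | None = None,
    controls=None,
) -> FamilyResult:
    """Filter cascade -> sequential inheritance models -> fallback ->
    causality classification, for one family."""
    config = config or CascadeConfig()
    family_id = family_pedigree.family_ids[0]
    matched, unmatched, trace, _removals = apply_cascade(
        variants, family_pedigree, config, panel, controls
    )
    candidates = apply_sequential_models(matched, family_pedigree)
    candidates += hgmd_fallback(unmatched, known_pathogenic, family_pedigree)
    assessed = [
        (
            c,
            assess_evidence(
                c,
                panel,
                patient_hpo,
                known_pathogenic_table=known_pathogenic,
                pedigree=family_pedigree,
                max_af=config.max_af,
            ),
        )
        for c in candidates
    ]
    verdicts = classify(assessed)
    logger.info(
        "%s: %d variants in, %d matched, %d candidates, %d causative",
        family_id, trace.n_in, len(matched), len(candidates),
        sum(1 for v in verdicts if v.verdict is VerdictClass.CAUSATIVE),
    )
    return FamilyResult(family_id=family_id, verdicts=verdicts, trace=trace)


@dataclass
class PipelineResult:
    report: CohortReport
    family_results: dict[str, FamilyResult]

    @property
    def ok(self) -> bool:
        return not self.report.failed_families


def run_pipeline(
    cohort_dir: str | os.PathLike,
    config: CascadeConfig | None = None,
    out_dir: str | os.PathLike | None = None,
) -> PipelineResult:
    """Run the full pipeline on a cohort directory (the layout written by
    the simulator: ``pedigree.ped``, ``phenotypes.tsv``, ``gene_panel.tsv``,
    ``known_pathogenic.tsv``, ``controls.tsv``, ``vcf/<family>.vcf``).

    Families are processed in sorted order; the result is independent of
    processing order. A family whose VCF fails to parse is marked failed
    and the remaining families are still analysed.
    """
    cohort_dir = Path(cohort_dir)
    config = config or CascadeConfig()
    pedigree = read_ped(cohort_dir / "pedigree.ped")
    phenotype_frame = read_phenotype_frame(cohort_dir / "phenotypes.tsv")
    panel = read_gene_panel(cohort_dir / "gene_panel.tsv")
    known_path = read_known_pathogenic(cohort_dir / "known_pathogenic.tsv")
    controls_path = cohort_dir / "controls.tsv"
    controls = read_controls(controls_path) if controls_path.exists() else {}
    hpo_by_patient = {
        row.patient: frozenset(
            t.strip() for t in row.hpo_terms.split(",") if t.strip()
        )
        for row in phenotype_frame.itertuples(index=False)
    }

    family_results: dict[str, FamilyResult] = {}
    failed: list[str] = []
    for fam in pedigree.family_ids:
        fam_ped = pedigree.family(fam)
        vcf_path = cohort_dir / "vcf" / f"{fam}.vcf"
        try:
            variants = read_vcf(vcf_path, fam_ped)
            patient_hpo = frozenset().union(
                *(
                    hpo_by_patient.get(a.individual_id, frozenset())
                    for a in fam_ped.affected_members()
                )
            )
            family_results[fam] = analyse_family(
                variants, fam_ped, panel, known_path, patient_hpo,
                config, controls,
            )
        except ExomediagError as err:
            logger.error("family %s failed: %s", fam, err)
            failed.append(fam)
            family_results[fam] = FamilyResult(
                family_id=fam, verdicts=[], trace=FilterTrace(), error=str(err)
            )

    report = summarize_cohort(
        {f: r.verdicts for f, r in family_results.items() if r.error is None},
        pedigree,
        phenotype_frame,
        failed_families=failed,
    )
    if out_dir is not None:
        _write_outputs(Path(out_dir), report, family_results)
    return PipelineResult(report=report, family_results=family_results)


def _write_outputs(
    out_dir: Path,
    report: CohortReport,
    family_results: dict[str, FamilyResult],
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out_dir / "report.txt", "w", encoding="utf-8") as fh:
        fh.write(report.to_text())
    verdict_rows = []
    trace_rows = []
    for fam in sorted(family_results):
        result = family_results[fam]
        for v in result.verdicts:
            verdict_rows.append(
                {
                    "family": fam,
                    "gene": v.candidate.gene,
                    "model": v.candidate.model.value,
                    "verdict": v.verdict.value,
                    "variants": ";".join(
                        f"{c}:{p}:{r}>{a}" for c, p, r, a in
                        v.candidate.variant_keys
                    ),
                    "de_novo_status": v.candidate.de_novo_status.value,
                    "fallback": int(v.candidate.fallback),
                    "gene_disease_match": int(v.evidence.gene_disease_match),
                    "deleteriousness": v.evidence.deleteriousness.value,
                    "n_deleterious_predictions":
                        v.evidence.n_deleterious_predictions,
                    "population_absent": int(v.evidence.population_absent),
                    "segregation": v.evidence.segregation_consistent.value,
                    "sanger_confirmed": int(v.evidence.sanger_confirmed),
                }
            )
        for row in result.trace.to_rows():
            trace_rows.append({"family": fam, **row})
    pd.DataFrame(
        verdict_rows,
        columns=["family", "gene", "model", "verdict", "variants",
                 "de_novo_status", "fallback", "gene_disease_match",
                 "deleteriousness", "n_deleterious_predictions",
                 "population_absent", "segregation", "sanger_confirmed"],
    ).to_csv(out_dir / "verdicts.tsv", sep="\t", index=False)
    pd.DataFrame(
        trace_rows, columns=["family", "stage", "n_in", "n_removed", "n_out"]
    ).to_csv(out_dir / "filter_trace.tsv", sep="\t", index=False)
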