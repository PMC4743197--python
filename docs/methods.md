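# Methods

This note documents the rules the package implements, the choices made
where the procedure was genuinely open, the statistical structure of the
synthetic cohort, and the limits of what passing tests demonstrate.

## Filter cascade

Stages run in a fixed order — read depth, population frequency, run
controls, phenotype panel — with per-stage accounting (`FilterTrace`;
counts are conserved: every input variant ends in exactly one of
matched, unmatched, or a stage's removal list).

* **Depth** (`min_reads`, default 5): a variant is removed when any
  *affected carrier* is covered by fewer than `min_reads` reads. The
  rule is conjunctive across affected sibs — a candidate unsupported in
  one affected member is unreliable family-wide. A missing depth value
  is treated as 0 (and logged). Low coverage in a non-carrier is
  irrelevant.
* **Population frequency** (`max_af`, default 0.02): removed when the
  allele frequency is *strictly above* the cap in at least one consulted
  database (default dbSNP, 1000G, Seattle, GoNL). The rule is
  disjunctive per database; whether the original procedure consulted
  per-database maxima or a combined frequency is not documented, so the
  stricter per-database reading is used. "Not observed in a database"
  is deliberately distinct from "observed at 0" and never triggers
  removal.
* **Run controls** (`control_min_count`, default 4 of 8): an allele
  recurring in at least `control_min_count` same-run control samples is
  treated as a systematic artifact. "Annotated in the controls" is
  ambiguous between *any* and *all* controls; recurrence in half the
  controls is used as the default artifact signature (the frequency
  stage already removes genuinely common variation), and both extremes
  are configurable and tested. With no controls supplied the stage is
  skipped with a warning.
* **Phenotype panel**: a variant matches when its gene has at least one
  panel HPO term inside the query set (default: the three microcephaly
  terms HP:0011451, HP:0005484, HP:0000253, plus HP:0002011, HP:0000707,
  HP:0000234). Matching is exact-term set intersection; ontology
  descendant closure is not applied (the query names terms, not closure
  semantics — an OBO-driven closure could be layered on without
  changing the interface). Unmatched variants (including those without a
  gene symbol) are retained for the known-pathogenic fallback.

Properties maintained and tested: threshold monotonicity (nested
survivor sets over frequency/depth grids), commutativity of the depth
and frequency stages, count conservation.

## Inheritance models

Models are evaluated per family in the order AR-homozygous,
AR-compound-heterozygous, AD, XL; all candidates are returned in that
priority order (no model suppresses another — it is left to causality
ranking, since the sequential procedure being emulated does not state
that a recessive hit suppressed dominant evaluation). Missing genotypes
are never treated as reference. Mitochondrial and chrY variants are out
of model scope and reach only the fallback path.

* **AR hom**: homozygous-alt in every affected member; every genotyped
  parent of an affected must be an obligate heterozygous carrier; no
  genotyped unaffected member may be homozygous-alt.
* **AR comphet**: two heterozygous variants in one gene in every
  affected member. With both parents genotyped at both sites a *trans*
  configuration must be possible (an assignment with one variant carried
  by each parent — two variants both from one parent are rejected as
  cis). With a parent unavailable, any qualifying pair is kept and
  flagged `phase_unknown` rather than dropped: read-backed phasing is
  not part of the consumed data, and sib-pair compound heterozygotes
  must remain discoverable. An unaffected member carrying both alleles
  refutes the pair.
* **AD**: heterozygous (homozygous tolerated but down-ranked) in every
  affected; absent from every genotyped unaffected member. De novo
  status: affected carrier parent → `inherited`; both parents
  reference → `confirmed`; one parent reference, the other untested →
  `probable`; otherwise `unknown`.
* **XL**: chrX only (labels `X`, `chrX`, `23`; male genotypes there are
  normalised to hemizygous on VCF read — pseudoautosomal regions are
  treated as part of the hemizygous X by default). Affected females
  must be het (hom-alt accepted), affected males hemizygous; an
  unaffected hemizygous male refutes the candidate.

The candidate generator is verified against an independent brute-force
enumerator (every variant and every same-gene pair tested directly
against these definitions) on randomized families, and is monotone:
adding an unrelated variant never removes a candidate.

## Causality classification

Evidence per candidate: gene–disease match (a panel entry for the gene
sharing ≥ 1 HPO term with the patient's terms *and* listing a compatible
inheritance mode — a deliberate operationalization of "clinical features
consistent with the phenotype", which in practice is a manual
judgement); deleteriousness class with priority known-pathogenic >
truncating-or-splice (frameshift, stop-gained, splice-site) > predicted
(k = count of affirmative deleterious verdicts; unknown verdicts count
neither way; k ≥ 3 required); population absence (frequency ≤ the 2 %
cascade cap in all six databases — an observed rare frequency such as
0.13 % does not block causality); segregation (every genotyped relative
beyond the index case compatible with the model; `untestable` with no
informative relatives); Sanger confirmation (a boolean consumed from the
input — wet-lab validation itself is out of scope). For compound
heterozygotes the weaker allele governs deleteriousness and population
absence.

Verdicts: `excluded` on inconsistent segregation; `causative` when all
remaining criteria hold; otherwise `candidate`. The verdict function is
monotone in every evidence field. Per-family ranking: causative
recessive before causative dominant/X-linked, then by deleteriousness
class and gene symbol. A family is diagnosed iff it has ≥ 1 causative
verdict; diagnosed *patients* are the affected phenotype-table patients
of diagnosed families (an affected transmitting parent supports
segregation but is not a cohort patient).

The fallback path re-enters phenotype-unmatched variants that appear in
the known-pathogenic lookup into the same model/classification
machinery, flagged `fallback`; their gene–disease match is decided from
the lookup row's own HPO annotation (no annotation → no match). Lookup
hits that satisfy no Mendelian model do not surface — they could not
segregate under any reportable model.

## ROH and shared-haplotype scanning

Genotype tracks are biallelic calls (`AA/AB/BB/NC`) at strictly
increasing positions. Four maximal-run modes share one scanner, differing
only in the per-SNP state:

| mode | supports a run | breaks a run |
|---|---|---|
| single ROH | hom call | het call |
| sibs shared hom | both hom and equal | anything else called |
| recessive shared | identical genotypes (AB=AB counts) | called and unequal |
| dominant shared | ≥ 1 shared allele | AA vs BB only |

No-calls neither break nor support a run; a run is reported only if its
internal no-call fraction is ≤ `max_nocall_fraction` (default 10 %).
Reporting minima default to 25 SNPs and 1 Mb — conventional array-ROH
floors; the minima are not dictated by the source procedure, and the
8 Mb finding the recovery test targets sits far above either. Interval
ends are the outermost supporting SNPs (no extrapolation to flanking
midpoints); in memory intervals are 1-based inclusive, on disk BED is
0-based half-open. The modes are nested (shared-hom ⊆ recessive ⊆
dominant) whenever the no-call cap does not censor a looser-mode run; the
nesting property test therefore disables the cap, which is a reporting
filter rather than part of the run semantics. Genotyping-error tolerance
inside runs defaults to zero incompatible SNPs (an interpretation; a
configurable allowance would relax it). All four detectors reproduce an
O(n²) brute-force maximal-interval oracle on small random tracks.

## Synthetic cohort

The generator emulates the study conditions, not generic exomes:

* **Design**: 35 families, 38 patients, three sib-pairs (families F08,
  F10, F27), six consanguineous families (F16, F23, F27, F29, F31, F35).
  The phenotype table ships the study's patient characteristics verbatim
  (ages, sexes, OFC Z-scores with two missing values); its arithmetic —
  mean age 10 years, mean OFC −4.5 SD over 36 values, 8/35 = 23 %
  suspected-recessive — is itself a test target. The source tables
  disagree on consanguinity for one patient (the running text lists six
  patients in five families; the table annotates one more); both fields
  are kept as printed, and the per-table count (six consanguineous
  families) is what makes the 8/35 arithmetic cohere. Likewise the
  running text says five patients over 18 while the table contains six;
  the report computes from the table.
* **Families** are trios (proband + genotyped parents), extended in F04
  by an affected transmitting mother and an unaffected maternal aunt,
  and reduced in F23 by an unavailable father (present in the pedigree,
  absent from the VCF) — the two configurations that exercise
  `inherited` and `probable` de novo status.
* **Causal configurations**: ten `CausalSpec`s (3 AR-hom, 4 AR-comphet
  with one allele per parent, 2 AD — one maternally inherited, one de
  novo — and 1 XL de novo in a female), each with the gene, consequence
  class and reported-pathogenic status of the corresponding established
  diagnosis; coordinates are synthetic, chromosome assignments real.
  Causal alleles are Sanger-confirmed, covered at ≥ 20 reads, and absent
  from the databases except the *RNASEH2B* missense at ExAC 0.13 %
  (deliberately planted to pin the rare-but-reported boundary case).
* **Background**: 150 cohort-wide sites, 90 % common (AF 5–50 %, present
  in all four cascade databases with ±10 % jitter — frequencies are
  generated jointly, mimicking databases that overlap heavily on common
  variation) and 10 % rare (< 2 %, sporadic database presence); 20 %
  sit in decoy panel genes so the phenotype match stage passes
  non-causal variants through. Parents draw Hardy–Weinberg genotypes at
  the site frequency; children inherit Mendelianly. Two rare
  heterozygous calls per proband are planted at depth < 5 to exercise
  the depth stage; five artifact sites recur heterozygous family-wide
  in ~⅓ of families and in all eight control samples. Background calls
  are never Sanger-confirmed, which is what makes "exactly the ten
  planted families are diagnosed" a sharp end-to-end assertion.
  Background variation is autosomal; the X-linked model is exercised by
  the planted configuration and by randomized unit tests rather than by
  background noise. The per-sample variant count is scaled far below a
  real exome (tens of thousands of calls) to keep bundles small and the
  suite fast; every stage still removes a non-trivial fraction.
* **SNP-array tracks**: per-SNP MAF ~ U(0.05, 0.5), Hardy–Weinberg
  genotypes outside planted regions, all-homozygous inside a planted
  ROH; default 40 SNPs/Mb on a 50 Mb chromosome window. Plans: an 8 Mb
  stretch around the recessive *ERCC8* locus of consanguineous proband
  P16, plus one planted sharing region per sib-pair (same-homozygous,
  same-combination, ≥ 1-shared-allele respectively). Sib tracks outside
  planted regions are drawn independently — real sibs share ~50 % of
  their genome IBD, so detected sharing outside planted regions is
  *under*-represented relative to reality; recovery tests only assert
  coverage of the planted truth. No linkage disequilibrium is modelled.
* **Determinism**: a single `numpy` `default_rng(seed)` drives
  everything; all written artifacts iterate sorted containers, so a
  bundle is byte-identical across runs and hash seeds.

What passing tests do *not* show: performance on real exome-scale call
sets, robustness to annotation noise (the generator emits clean,
complete annotations), LD-realistic haplotype structure, CNVs, or the
clinical judgement steps (phenotype consistency, literature review) that
the rule set operationalizes.

## Numerical and rounding conventions

Percentages round to the nearest integer, halves away from zero
(10/35 → 28.57 → 29); mean OFC keeps one decimal; mean age rounds to the
nearest year. Allele frequencies survive VCF round-trips to six
decimals (float32 storage); positions and depths are exact integers.
Yield is family-based (both family and patient counts are reported to
avoid ambiguity). Problem sizes used by the shipped verification runs:
the 35-family cohort with 150 background sites, random oracle families
of ≤ 20 variants (200 replicates), random tracks of ≤ 200 SNPs
(100 replicates), and 2 000-SNP array tracks — sizes at which the
brute-force oracles remain exact references while the whole suite runs
in seconds.
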