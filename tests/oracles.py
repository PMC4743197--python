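"""Independent brute-force oracles used by the test suite.

These restate the inheritance-model definitions and the maximal-run
interval semantics directly, without reusing the package's scanning or
candidate-generation code paths, so that agreement between the two is a
meaningful check.
"""

from __future__ import annotations

import itertools

from exomediag import Genotype, Pedigree, Sex
from exomediag.roh import ScanConfig

HET = Genotype.HET
HOM_REF = Genotype.HOM_REF
HOM_ALT = Genotype.HOM_ALT
HEMI = Genotype.HEMI
NO_CALL = Genotype.NO_CALL


def _gt(variant, sample):
    return variant.genotypes.get(sample, NO_CALL)


def _carries(variant, sample):
    gt = _gt(variant, sample)
    if gt is NO_CALL:
        return None
    return gt in (HET, HOM_ALT, HEMI)


def _first_affected_parents(ped: Pedigree):
    for a in ped.affected_members():
        fa, mo = ped.father_of(a.individual_id), ped.mother_of(a.individual_id)
        if fa is not None or mo is not None:
            return fa, mo
    return None, None


def brute_force_candidates(variants, ped: Pedigree) -> set[tuple]:
    """All (model, sorted variant-key tuple) pairs satisfying the model
    definitions, by exhaustive enumeration of variants and variant pairs."""
    out: set[tuple] = set()
    affected = ped.affected_members()
    unaffected = ped.unaffected_members()
    if not affected:
        return out

    # --- autosomal recessive, homozygous -------------------------------
    for v in variants:
        if not v.is_autosomal:
            continue
        if not all(_gt(v, a.individual_id) is HOM_ALT for a in affected):
            continue
        parents_ok = True
        for a in affected:
            for p in (ped.father_of(a.individual_id),
                      ped.mother_of(a.individual_id)):
                if p is not None and _gt(v, p.individual_id) not in (
                    NO_CALL, HET
                ):
                    parents_ok = False
        if not parents_ok:
            continue
        if any(_gt(v, u.individual_id) is HOM_ALT for u in unaffected):
            continue
        out.add(("AR_hom", (v.key,)))

    # --- autosomal recessive, compound heterozygous --------------------
    for v1, v2 in itertools.combinations(variants, 2):
        if v1.gene != v2.gene or not v1.gene:
            continue
        if not (v1.is_autosomal and v2.is_autosomal):
            continue
        if not all(
            _gt(v1, a.individual_id) is HET and _gt(v2, a.individual_id) is HET
            for a in affected
        ):
            continue
        if any(
            _carries(v1, u.individual_id) and _carries(v2, u.individual_id)
            for u in unaffected
        ):
            continue
        father, mother = _first_affected_parents(ped)
        statuses = [
            (None, None) if p is None
            else (_carries(v1, p.individual_id), _carries(v2, p.individual_id))
            for p in (father, mother)
        ]
        (f1, f2), (m1, m2) = statuses
        if None not in (f1, f2, m1, m2):
            if not ((f1 and m2) or (f2 and m1)):
                continue
        out.add(("AR_comphet", tuple(sorted((v1.key, v2.key)))))

    # --- autosomal dominant --------------------------------------------
    for v in variants:
        if not v.is_autosomal:
            continue
        if not all(
            _gt(v, a.individual_id) in (HET, HOM_ALT) for a in affected
        ):
            continue
        if any(_carries(v, u.individual_id) for u in unaffected):
            continue
        out.add(("AD", (v.key,)))

    # --- X-linked -------------------------------------------------------
    for v in variants:
        if not v.is_x:
            continue
        ok = True
        for a in affected:
            gt = _gt(v, a.individual_id)
            if a.sex is Sex.MALE:
                ok = ok and gt is HEMI
            else:
                ok = ok and gt in (HET, HOM_ALT)
        for u in unaffected:
            gt = _gt(v, u.individual_id)
            if u.sex is Sex.MALE and gt is HEMI:
                ok = False
            if u.sex is Sex.FEMALE and gt is HOM_ALT:
                ok = False
        if ok:
            out.add(("XL", (v.key,)))

    return out


def candidate_set(candidates) -> set[tuple]:
    """Normalise package ModelCandidates to the oracle's comparison form."""
    return {
        (c.model.value, tuple(sorted(c.variant_keys))) for c in candidates
    }


# ---------------------------------------------------------------------------
# interval oracle
# ---------------------------------------------------------------------------

SUPPORT, NEUTRAL, BREAK = 0, 1, 2


def single_state(gt: str) -> int:
    if gt == "NC":
        return NEUTRAL
    return SUPPORT if gt in ("AA", "BB") else BREAK


def shared_hom_state(a: str, b: str) -> int:
    if a == "NC" or b == "NC":
        return NEUTRAL
    return SUPPORT if a == b and a in ("AA", "BB") else BREAK


def recessive_state(a: str, b: str) -> int:
    if a == "NC" or b == "NC":
        return NEUTRAL
    return SUPPORT if a == b else BREAK


def dominant_state(a: str, b: str) -> int:
    if a == "NC" or b == "NC":
        return NEUTRAL
    return BREAK if {a, b} == {"AA", "BB"} else SUPPORT


def brute_force_intervals(
    positions: list[int], states: list[int], config: ScanConfig
) -> set[tuple[int, int, int]]:
    """All maximal qualifying runs as (start, end, n_support) triples, by
    O(n^2) enumeration of candidate endpoint pairs."""
    n = len(positions)
    out = set()
    for i in range(n):
        if states[i] != SUPPORT:
            continue
        for j in range(i, n):
            if states[j] != SUPPORT:
                continue
            between = states[i : j + 1]
            if BREAK in between:
                continue
            # maximality: no extension to an outer supporting SNP without
            # crossing a break
            left_ext = any(
                states[k] == SUPPORT
                and BREAK not in states[k:i]
                for k in range(i)
            )
            right_ext = any(
                states[k] == SUPPORT
                and BREAK not in states[j + 1 : k + 1]
                for k in range(j + 1, n)
            )
            if left_ext or right_ext:
                continue
            n_support = sum(1 for s in between if s == SUPPORT)
            span = j - i + 1
            nocall_fraction = (span - n_support) / span
            if (
                n_support >= config.min_snps
                and positions[j] - positions[i] + 1 >= config.min_length
                and nocall_fraction <= config.max_nocall_fraction
            ):
                out.add((positions[i], positions[j], n_support))
    return out
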