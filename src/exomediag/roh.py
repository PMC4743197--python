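"""Runs of homozygosity and sib-pair haplotype sharing from SNP-array calls.

Four scanning modes over biallelic genotype tracks (``AA``/``AB``/``BB``/
``NC`` for no-call):

* ``single_roh`` — maximal runs of homozygous calls within one sample;
* ``sibs_shared_hom`` — both sibs homozygous for the *same* allele;
* ``recessive_shared`` — both sibs with the identical genotype (``AB`` ==
  ``AB`` counts), i.e. a shared allele combination;
* ``dominant_shared`` — sibs sharing at least one allele at every SNP
  (only an ``AA``-vs-``BB`` opposition breaks a run).

The modes are strictly nested: every interval under a stricter mode is
contained in an interval of a looser mode on the same input.

No-calls never break a run and never support one; a run is reported only
if its internal no-call fraction stays at or below a configurable cap.
Interval ends are the outermost supporting SNPs (1-based inclusive; BED
output converts to 0-based half-open).
"""

from __future__ import annotations

import enum
import os
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from .errors import ValidationError

HOMOZYGOUS = {"AA", "BB"}
GENOTYPE_CODES = {"AA", "AB", "BB", "NC"}


class SharingMode(str, enum.Enum):
    SINGLE_ROH = "single_roh"
    SIBS_SHARED_HOM = "sibs_shared_hom"
    RECESSIVE_SHARED = "recessive_shared"
    DOMINANT_SHARED = "dominant_shared"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class ScanConfig:
    """Reporting minima for interval scanning.

    min_snps: minimum supporting SNPs per interval (default 25).
    min_length: minimum interval length in bp (default 1 Mb).
    max_nocall_fraction: maximum tolerated fraction of no-calls between the
        outermost supporting SNPs of a run (default 0.10).
    """

    min_snps: int = 25
    min_length: int = 1_000_000
    max_nocall_fraction: float = 0.10


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    n_snps: int
    mode: SharingMode

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError("interval start > end")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class SnpGenotypeTrack:
    """Ordered biallelic genotype calls for one sample."""

    sample_id: str
    records: list[tuple[str, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        last: dict[str, int] = {}
        for chrom, pos, gt in self.records:
            if gt not in GENOTYPE_CODES:
                raise ValidationError(
                    f"bad genotype code {gt!r} at {chrom}:{pos} "
                    f"({self.sample_id})"
                )
            if chrom in last and pos <= last[chrom]:
                raise ValidationError(
                    f"track {self.sample_id} not strictly increasing at "
                    f"{chrom}:{pos}"
                )
            last[chrom] = pos

    def by_chrom(self) -> dict[str, list[tuple[int, str]]]:
        out: dict[str, list[tuple[int, str]]] = {}
        for chrom, pos, gt in self.records:
            out.setdefault(chrom, []).append((pos, gt))
        return out

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# generic maximal-run scanner
# ---------------------------------------------------------------------------

# Per-SNP states: SUPPORT extends a run and counts toward n_snps; NEUTRAL
# (no-call) is tolerated inside a run; BREAK terminates it.
_SUPPORT, _NEUTRAL, _BREAK = 0, 1, 2


def _scan_runs(
    chrom: str,
    positions: Sequence[int],
    states: Sequence[int],
    mode: SharingMode,
    config: ScanConfig,
) -> list[GenomicInterval]:
    intervals = []
    i, n = 0, len(positions)
    while i < n:
        if states[i] != _SUPPORT:
            i += 1
            continue
        j = i
        last_support = i
        n_support = 0
        while j < n and states[j] != _BREAK:
            if states[j] == _SUPPORT:
                n_support += 1
                last_support = j
            j += 1
        start, end = positions[i], positions[last_support]
        span = last_support - i + 1
        nocall_fraction = (span - n_support) / span
        if (
            n_support >= config.min_snps
            and end - start + 1 >= config.min_length
            and nocall_fraction <= config.max_nocall_fraction
        ):
            intervals.append(
                GenomicInterval(
                    chrom=chrom,
                    start=start,
                    end=end,
                    n_snps=n_support,
                    mode=mode,
                )
            )
        i = j + 1
    return intervals


def _single_state(gt: str) -> int:
    if gt == "NC":
        return _NEUTRAL
    return _SUPPORT if gt in HOMOZYGOUS else _BREAK


def _pair_state_shared_hom(a: str, b: str) -> int:
    if a == "NC" or b == "NC":
        return _NEUTRAL
    return _SUPPORT if (a in HOMOZYGOUS and a == b) else _BREAK


def _pair_state_recessive(a: str, b: str) -> int:
    if a == "NC" or b == "NC":
        return _NEUTRAL
    return _SUPPORT if a == b else _BREAK


def _pair_state_dominant(a: str, b: str) -> int:
    if a == "NC" or b == "NC":
        return _NEUTRAL
    # only opposite homozygotes share no allele
    return _BREAK if {a, b} == {"AA", "BB"} else _SUPPORT


def detect_roh_single(
    track: SnpGenotypeTrack, config: ScanConfig | None = None
) -> list[GenomicInterval]:
    """Stretches of homozygosity within a single sample: maximal runs of
    consecutive homozygous calls (a heterozygous call terminates a run)."""
    config = config or ScanConfig()
    intervals = []
    for chrom, snps in track.by_chrom().items():
        positions = [p for p, _ in snps]
        states = [_single_state(g) for _, g in snps]
        intervals.extend(
            _scan_runs(chrom, positions, states, SharingMode.SINGLE_ROH, config)
        )
    return intervals


def _paired_scan(
    track_a: SnpGenotypeTrack,
    track_b: SnpGenotypeTrack,
    pair_state: Callable[[str, str], int],
    mode: SharingMode,
    config: ScanConfig,
) -> list[GenomicInterval]:
    by_a, by_b = track_a.by_chrom(), track_b.by_chrom()
    if sorted(by_a) != sorted(by_b) or any(
        [p for p, _ in by_a[c]] != [p for p, _ in by_b[c]] for c in by_a
    ):
        raise ValidationError(
            f"tracks {track_a.sample_id} and {track_b.sample_id} are not on "
            "identical SNP positions"
        )
    intervals = []
    for chrom in by_a:
        positions = [p for p, _ in by_a[chrom]]
        states = [
            pair_state(ga, gb)
            for (_, ga), (_, gb) in zip(by_a[chrom], by_b[chrom])
        ]
        intervals.extend(_scan_runs(chrom, positions, states, mode, config))
    return intervals


def shared_homozygous_sibs(
    track_a: SnpGenotypeTrack,
    track_b: SnpGenotypeTrack,
    config: ScanConfig | None = None,
) -> list[GenomicInterval]:
    """Regions in which both siblings share the same homozygous alleles."""
    return _paired_scan(
        track_a, track_b, _pair_state_shared_hom,
        SharingMode.SIBS_SHARED_HOM, config or ScanConfig(),
    )


def shared_haplotype_recessive(
    track_a: SnpGenotypeTrack,
    track_b: SnpGenotypeTrack,
    config: ScanConfig | None = None,
) -> list[GenomicInterval]:
    """Regions in which both siblings share the same combination of
    alleles (identical genotypes, heterozygous included)."""
    return _paired_scan(
        track_a, track_b, _pair_state_recessive,
        SharingMode.RECESSIVE_SHARED, config or ScanConfig(),
    )


def shared_haplotype_dominant(
    track_a: SnpGenotypeTrack,
    track_b: SnpGenotypeTrack,
    config: ScanConfig | None = None,
) -> list[GenomicInterval]:
    """Regions in which both siblings share at least one allele at each
    SNP position."""
    return _paired_scan(
        track_a, track_b, _pair_state_dominant,
        SharingMode.DOMINANT_SHARED, config or ScanConfig(),
    )


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------


def write_intervals_bed(
    path: str | os.PathLike, intervals: Iterable[GenomicInterval]
) -> None:
    """Write intervals as BED (0-based half-open) with the mode as name."""
    with open(path, "w", encoding="utf-8") as fh:
        for iv in sorted(intervals, key=lambda i: (i.chrom, i.start, i.end)):
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{iv.mode.value}\n")


def write_intervals_tsv(
    path: str | os.PathLike, intervals: Iterable[GenomicInterval]
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("chrom\tstart\tend\tlength_bp\tn_snps\tmode\n")
        for iv in sorted(intervals, key=lambda i: (i.chrom, i.start, i.end)):
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.length_bp}\t"
                f"{iv.n_snps}\t{iv.mode.value}\n"
            )
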