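"""Pericentromeric region construction and inversion enrichment testing.

A pericentromeric region is built from the centromeric satellite annotation
(censat): contiguous blocks of human satellite (HSAT), alpha satellite and
rDNA are merged and padded by 1 Mbp of flanking sequence. Enrichment of
inversions in these regions is assessed per chromosome with a permutation
test: each inversion keeps its length and is repositioned uniformly along
its chromosome, the overlap count is recorded per permutation, and the
one-sided empirical p-value is Bonferroni-corrected across chromosomes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .core import (
    AnnotationTrack,
    GenomicInterval,
    intersect_length,
    merge_intervals,
)

__all__ = [
    "PericentromericRegion",
    "PermutationResult",
    "CompositionBreakdown",
    "DEFAULT_SEED_CLASSES",
    "DEFAULT_PRIORITY",
    "build_pericentromeric_regions",
    "classify_pericentromeric",
    "permutation_test",
    "bonferroni",
    "sd_pairs",
    "composition_breakdown",
    "association_label",
]

#: Satellite classes that seed a pericentromeric region.
DEFAULT_SEED_CLASSES = frozenset({"HSAT", "ASAT", "RDNA"})

#: Priority used to assign a base covered by several annotation classes.
DEFAULT_PRIORITY = ("RDNA", "HSAT", "BSAT", "ASAT", "MON", "SD_PAIR")


@dataclass(frozen=True)
class PericentromericRegion:
    chrom: str
    interval: GenomicInterval
    source_classes: frozenset[str]


@dataclass
class PermutationResult:
    """Per-chromosome enrichment of inversions in a region set."""

    chrom: str
    observed: int
    null_counts: np.ndarray
    p_value: float
    fold: float
    n_perm: int
    p_adjusted: float | None = None


@dataclass
class CompositionBreakdown:
    """Base-pair decomposition of one inversion by annotation class."""

    region_id: str
    bases: dict[str, int] = field(default_factory=dict)

    def total(self) -> int:
        return sum(self.bases.values())


def build_pericentromeric_regions(
    censat: AnnotationTrack,
    chrom_sizes: dict[str, int],
    flank: int = 1_000_000,
    seed_classes: frozenset[str] = DEFAULT_SEED_CLASSES,
    merge_gap: int = 0,
) -> list[PericentromericRegion]:
    """Merge satellite seeds, pad by ``flank`` on both sides and clip.

    Seed records (HSAT, alpha satellite, rDNA by default) are merged per
    chromosome with ``merge_gap`` tolerance, extended by ``flank`` bases on
    each side, clipped to [0, chromosome size) and re-merged, so regions
    whose flanks touch coalesce into one.
    """
    regions: list[PericentromericRegion] = []
    for chrom in censat.chroms():
        if chrom not in chrom_sizes:
            raise ValueError(f"chromosome {chrom!r} missing from chrom_sizes")
        seeds = [
            iv
            for iv, label in censat.records
            if iv.chrom == chrom and label in seed_classes
        ]
        if not seeds:
            continue
        size = chrom_sizes[chrom]
        padded = [
            GenomicInterval(chrom, max(0, iv.start - flank), min(size, iv.end + flank))
            for iv in merge_intervals(seeds, max_gap=merge_gap)
        ]
        for merged in merge_intervals(padded, max_gap=0):
            classes = frozenset(
                label
                for iv, label in censat.records
                if label in seed_classes and iv.intersects(merged)
            )
            regions.append(PericentromericRegion(chrom, merged, classes))
    return regions


def classify_pericentromeric(
    inversions: list[GenomicInterval], regions: list[PericentromericRegion]
) -> list[bool]:
    """True per inversion iff it overlaps any pericentromeric region by
    at least one base pair (half-open abutment does not count)."""
    return [
        any(inv.intersects(r.interval) for r in regions) for inv in inversions
    ]


def permutation_test(
    inversions: list[GenomicInterval],
    regions: list[PericentromericRegion],
    chrom_size: int,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> PermutationResult:
    """One-sided per-chromosome enrichment test by uniform repositioning.

    Each inversion keeps its length and is independently assigned a uniform
    start in ``[0, chrom_size - length]`` at every permutation; the null
    statistic is the per-permutation count of inversions overlapping the
    region set. ``p = (1 + #{null >= observed}) / (n_perm + 1)`` (never
    exactly zero); ``fold = observed / mean(null)``.
    """
    if not inversions:
        raise ValueError("permutation_test requires at least one inversion")
    chroms = {iv.chrom for iv in inversions}
    if len(chroms) > 1:
        raise ValueError(f"inversions must be on one chromosome, got {sorted(chroms)}")
    chrom = chroms.pop()
    spans = [
        (r.interval.start, r.interval.end)
        for r in regions
        if r.chrom == chrom
    ]
    observed = sum(
        any(iv.start < re and iv.end > rs for rs, re in spans) for iv in inversions
    )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    null = np.zeros(n_perm, dtype=np.int64)
    for iv in inversions:
        length = iv.length()
        if length > chrom_size:
            raise ValueError(
                f"inversion {iv} longer than chromosome ({chrom_size} bp)"
            )
        starts = rng.integers(0, chrom_size - length + 1, size=n_perm)
        hit = np.zeros(n_perm, dtype=bool)
        for rs, re in spans:
            hit |= (starts < re) & (starts + length > rs)
        null += hit
    p = (1 + int(np.sum(null >= observed))) / (n_perm + 1)
    mean_null = float(null.mean())
    fold = observed / mean_null if mean_null > 0 else float("inf")
    return PermutationResult(chrom, observed, null, p, fold, n_perm)


def bonferroni(
    results: list[PermutationResult], n_tests: int | None = None
) -> list[PermutationResult]:
    """Fill ``p_adjusted = min(1, p * n_tests)`` on a copy of each result."""
    if n_tests is None:
        n_tests = len(results)
    return [
        replace(r, p_adjusted=min(1.0, r.p_value * n_tests)) for r in results
    ]


def sd_pairs(
    sds: AnnotationTrack, max_separation: int = 5_000_000
) -> list[tuple[GenomicInterval, GenomicInterval]]:
    """Intrachromosomal segmental-duplication pairs within ``max_separation``.

    All same-chromosome SD records are paired all-vs-all; a pair qualifies
    when the inner distance (end of the left mate to start of the right
    mate) is at most ``max_separation``. Overlapping mates count as
    distance 0.
    """
    pairs = []
    for chrom in sds.chroms():
        records = sorted(sds.intervals(chrom, label="SD"), key=lambda i: (i.start, i.end))
        for a, b in itertools.combinations(records, 2):
            inner = max(0, b.start - a.end)
            if inner <= max_separation:
                pairs.append((a, b))
    return pairs


def composition_breakdown(
    inv: GenomicInterval,
    tracks: dict[str, list[GenomicInterval]],
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
    region_id: str = "",
) -> CompositionBreakdown:
    """Assign every base of an inversion to exactly one annotation class.

    ``tracks`` maps class label to intervals (e.g. satellite classes plus
    the footprint of SD pairs under label ``SD_PAIR``). Bases covered by
    several classes go to the earliest class in ``priority``; bases covered
    by none are ``OTHER``. Class bases always sum to the inversion length.
    """
    remaining = [inv]
    bases: dict[str, int] = {}
    for label in priority:
        ivs = tracks.get(label, [])
        covered = sum(intersect_length(piece, ivs) for piece in remaining)
        bases[label] = covered
        if covered:
            blocks = merge_intervals(
                [
                    GenomicInterval(inv.chrom, max(p.start, iv.start), min(p.end, iv.end))
                    for p in remaining
                    for iv in ivs
                    if iv.intersects(p)
                ]
            )
            remaining = _subtract(remaining, blocks)
    bases["OTHER"] = sum(p.length() for p in remaining)
    return CompositionBreakdown(region_id or str(inv), bases)


def _subtract(
    pieces: list[GenomicInterval], blocks: list[GenomicInterval]
) -> list[GenomicInterval]:
    """Set-subtract merged ``blocks`` from ``pieces`` (same chromosome)."""
    out = []
    for piece in pieces:
        cursor = piece.start
        for b in blocks:
            if not b.intersects(piece):
                continue
            if b.start > cursor:
                out.append(GenomicInterval(piece.chrom, cursor, min(b.start, piece.end)))
            cursor = max(cursor, b.end)
            if cursor >= piece.end:
                break
        if cursor < piece.end:
            out.append(GenomicInterval(piece.chrom, cursor, piece.end))
    return out


def association_label(breakdown: CompositionBreakdown) -> str:
    """Mutually exclusive inversion-level label from its majority class.

    Returns ``"SD"`` when SD-pair bases dominate, ``"SATELLITE"`` when a
    satellite class dominates, else ``"OTHER"``; ties resolve in that order.
    """
    sat = sum(
        breakdown.bases.get(label, 0)
        for label in ("RDNA", "HSAT", "BSAT", "ASAT", "MON")
    )
    sd = breakdown.bases.get("SD_PAIR", 0)
    other = breakdown.bases.get("OTHER", 0)
    best = max(sd, sat, other)
    if best == 0:
        return "OTHER"
    if sd == best:
        return "SD"
    if sat == best:
        return "SATELLITE"
    return "OTHER"
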