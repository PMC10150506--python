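"""Cross-assembly remapping of inversion intervals and novelty calling.

An inversion called against one assembly is translated to another by
aligning the sequence of the inverted region (externally, e.g. minimap2
``-ax asm20 --secondary=no --eqx``) and post-processing the resulting PAF:
drop mapping-quality-zero and off-chromosome hits, collapse split mappings
separated by at most 100 kbp, and reject remaps whose size differs from the
original by more than 50%. Inversions are then classified against the
nonsyntenic mask (sequence present in the source assembly only): sites that
fail to remap and/or sit almost entirely in nonsyntenic sequence are the
candidates for genuinely novel inversions.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .core import (
    AlignmentRecord,
    AnnotationTrack,
    GenomicInterval,
    merge_intervals,
    overlap_fraction,
    reciprocal_overlap,
)

__all__ = [
    "RemapStatus",
    "RemapResult",
    "NoveltyClass",
    "NOVEL_CLASSES",
    "filter_alignments",
    "collapse_mappings",
    "apply_size_filter",
    "remap_interval",
    "classify_novelty",
]


class RemapStatus(enum.Enum):
    MAPPED = "MAPPED"
    FAILED = "FAILED"


@dataclass(frozen=True)
class RemapResult:
    """Outcome of remapping one inversion to the other reference."""

    region_id: str
    status: RemapStatus
    mapped_interval: GenomicInterval | None = None
    size_ratio: float | None = None

    def __post_init__(self):
        if (self.status is RemapStatus.MAPPED) != (self.mapped_interval is not None):
            raise ValueError("mapped_interval present iff status is MAPPED")


class NoveltyClass(enum.Enum):
    """Cross of remap outcome and nonsyntenic overlap at the threshold."""

    SYNTENIC_MAPPED = "SYNTENIC_MAPPED"
    NONSYNTENIC_MAPPED = "NONSYNTENIC_MAPPED"
    FAILED_ONLY = "FAILED_ONLY"
    NONSYNTENIC_FAILED = "NONSYNTENIC_FAILED"


#: The "putative novel" classes: everything except a clean syntenic remap.
NOVEL_CLASSES = frozenset(
    {
        NoveltyClass.NONSYNTENIC_MAPPED,
        NoveltyClass.FAILED_ONLY,
        NoveltyClass.NONSYNTENIC_FAILED,
    }
)


def filter_alignments(
    records: list[AlignmentRecord],
    source_chrom: str,
    homolog_map: dict[str, str] | None = None,
) -> list[AlignmentRecord]:
    """Drop mapping-quality-zero hits and hits to the wrong chromosome.

    The expected target chromosome is the homolog of ``source_chrom`` under
    ``homolog_map`` (identity by default, i.e. same chromosome name in both
    assemblies).
    """
    expected = (homolog_map or {}).get(source_chrom, source_chrom)
    return [
        r for r in records if r.mapq > 0 and r.target_chrom == expected
    ]


def collapse_mappings(
    records: list[AlignmentRecord], max_gap: int = 100_000
) -> list[GenomicInterval]:
    """Collapse split mappings on the target into chains.

    Target intervals whose end-to-start distance is at most ``max_gap`` are
    merged; a strictly larger gap starts a new chain. Records must share one
    target chromosome (run after :func:`filter_alignments`).
    """
    if not records:
        return []
    return merge_intervals([r.target_interval() for r in records], max_gap=max_gap)


def apply_size_filter(
    original: GenomicInterval,
    collapsed: list[GenomicInterval],
    records: list[AlignmentRecord] | None = None,
    region_id: str = "",
    min_ratio: float = 0.5,
    max_ratio: float = 1.5,
) -> RemapResult:
    """Pick the best collapsed chain and accept it if its size is within
    [min_ratio, max_ratio] of the original span (boundaries inclusive:
    only chains *more than* 50% larger or smaller are rejected).

    The best chain is the one gathering the most aligned bases from
    ``records`` (falling back to chain length when records are not given);
    ties break to the leftmost start.
    """
    if not collapsed:
        return RemapResult(region_id, RemapStatus.FAILED)

    def weight(chain: GenomicInterval) -> int:
        if records is None:
            return chain.length()
        return sum(
            r.aligned_bases
            for r in records
            if chain.intersects(r.target_interval())
        )

    best = max(collapsed, key=lambda c: (weight(c), -c.start))
    ratio = best.length() / original.length()
    if min_ratio <= ratio <= max_ratio:
        return RemapResult(region_id, RemapStatus.MAPPED, best, ratio)
    return RemapResult(region_id, RemapStatus.FAILED)


def remap_interval(
    original: GenomicInterval,
    records: list[AlignmentRecord],
    region_id: str = "",
    homolog_map: dict[str, str] | None = None,
    max_gap: int = 100_000,
) -> RemapResult:
    """Full remap of one inversion: filter -> collapse -> size filter."""
    kept = filter_alignments(records, original.chrom, homolog_map)
    collapsed = collapse_mappings(kept, max_gap=max_gap)
    return apply_size_filter(
        original, collapsed, records=kept, region_id=region_id or str(original)
    )


def classify_novelty(
    inv: GenomicInterval,
    remap: RemapResult,
    nonsyntenic: AnnotationTrack,
    threshold: float = 0.90,
    reciprocal: bool = False,
) -> NoveltyClass:
    """Classify an inversion by remap outcome and nonsyntenic overlap.

    The overlap with the nonsyntenic mask is computed in the inversion's own
    reference coordinates, either one-way (fraction of the inversion covered;
    default) or reciprocally (both directions must reach the threshold).
    """
    if reciprocal:
        f_inv, f_track = reciprocal_overlap(inv, nonsyntenic)
        nonsyn = f_inv >= threshold and f_track >= threshold
    else:
        nonsyn = overlap_fraction(inv, nonsyntenic) >= threshold
    mapped = remap.status is RemapStatus.MAPPED
    if nonsyn:
        return NoveltyClass.NONSYNTENIC_MAPPED if mapped else NoveltyClass.NONSYNTENIC_FAILED
    return NoveltyClass.SYNTENIC_MAPPED if mapped else NoveltyClass.FAILED_ONLY
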