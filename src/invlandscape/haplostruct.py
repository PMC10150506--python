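"""Structural classification of assembled haplotypes over a region.

Assembled haplotypes aligned to a reference are "painted" over a region of
interest (ROI): each alignment segment carries an orientation (+/-), and the
ordered orientation pattern — the painting signature — groups haplotypes
into structural haplogroups. Self-alignments of each haplotype expose
segmental-duplication (SD) pairs; the balance of SD bases in direct versus
inverted relative orientation around a locus predicts whether the haplotype
is predisposed to copy-number rearrangement (direct repeats) or to
inversion (inverted repeats).
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, replace

from .core import AlignmentRecord, GenomicInterval

__all__ = [
    "HaplotypePainting",
    "Risk",
    "FlankAnalysis",
    "project_to_roi",
    "paint_assembly",
    "select_spanning_assemblies",
    "synchronize_orientation",
    "group_haplotypes",
    "flank_analysis",
    "flanking_sd_pair",
]

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


@dataclass(frozen=True)
class HaplotypePainting:
    """One assembly's alignment segments over an ROI, ordered by target."""

    assembly_id: str
    roi: GenomicInterval
    segments: tuple[AlignmentRecord, ...]
    no_anchor: bool = False  # set when orientation could not be synchronized

    def signature(self, bin_size: int = 10_000) -> tuple:
        """Orientation/position pattern, rounded to ``bin_size`` bins."""
        return tuple(
            (
                seg.strand,
                round(seg.target_start / bin_size),
                round(seg.target_end / bin_size),
            )
            for seg in self.segments
        )


class Risk(enum.Enum):
    AT_RISK = "AT_RISK"
    PROTECTED = "PROTECTED"
    AMBIGUOUS = "AMBIGUOUS"


@dataclass(frozen=True)
class FlankAnalysis:
    """Direct vs inverted SD base tallies from one haplotype's
    self-alignments, and the implied rearrangement-risk call."""

    assembly_id: str
    direct_bases: int
    inverted_bases: int
    risk: Risk


# ---------------------------------------------------------------------------
# Alignment projection
# ---------------------------------------------------------------------------

def _query_pos_at(record: AlignmentRecord, t_pos: int) -> int:
    """Query offset corresponding to target position ``t_pos``.

    Monotone increasing from query_start at target_start for '+' records,
    decreasing from query_end for '-' records. Uses the base-level CIGAR
    when present, linear interpolation otherwise.
    """
    ts, te = record.target_start, record.target_end
    t_pos = min(max(t_pos, ts), te)
    if record.cigar is None:
        frac = (t_pos - ts) / (te - ts)
        span = record.query_end - record.query_start
        if record.strand == "+":
            return record.query_start + round(frac * span)
        return record.query_end - round(frac * span)
    # CIGAR walk: target advances forward from target_start; query advances
    # from query_start (+) or backwards from query_end (-).
    t = ts
    q = record.query_start if record.strand == "+" else record.query_end
    sign = 1 if record.strand == "+" else -1
    for n, op in _CIGAR_RE.findall(record.cigar):
        n = int(n)
        if op in "M=X":
            if t + n > t_pos:
                return q + sign * (t_pos - t)
            t += n
            q += sign * n
        elif op == "I":
            q += sign * n
        elif op in "DN":
            if t + n > t_pos:
                return q
            t += n
    return q


def project_to_roi(
    records: list[AlignmentRecord], roi: GenomicInterval
) -> list[AlignmentRecord]:
    """Clip alignments to an ROI on the target, cutting query spans
    consistently (PAF 'liftover').

    Records not intersecting the ROI are dropped; records fully inside it
    pass through unchanged. Orientation is conserved. Query coordinates at
    the cut points come from the base-level CIGAR when present, else from
    proportional interpolation.
    """
    out = []
    for rec in records:
        if rec.target_chrom != roi.chrom or not rec.target_interval().intersects(roi):
            continue
        if rec.target_start >= roi.start and rec.target_end <= roi.end:
            out.append(rec)
            continue
        t1 = max(rec.target_start, roi.start)
        t2 = min(rec.target_end, roi.end)
        qa, qb = _query_pos_at(rec, t1), _query_pos_at(rec, t2)
        q1, q2 = min(qa, qb), max(qa, qb)
        if q1 >= q2:
            continue  # clip fell entirely in a query deletion
        scale = (t2 - t1) / (rec.target_end - rec.target_start)
        out.append(
            replace(
                rec,
                query_start=q1,
                query_end=q2,
                target_start=t1,
                target_end=t2,
                aligned_bases=max(1, round(rec.aligned_bases * scale)),
                cigar=None,
            )
        )
    return out


def paint_assembly(
    assembly_id: str, records: list[AlignmentRecord], roi: GenomicInterval
) -> HaplotypePainting:
    """Project one assembly's alignments to the ROI and order by target."""
    own = [r for r in records if r.query_name == assembly_id]
    segs = sorted(
        project_to_roi(own, roi), key=lambda r: (r.target_start, r.target_end)
    )
    return HaplotypePainting(assembly_id, roi, tuple(segs))


# ---------------------------------------------------------------------------
# Haplogroup analysis
# ---------------------------------------------------------------------------

def select_spanning_assemblies(
    paintings: list[HaplotypePainting],
    roi: GenomicInterval,
    max_edge_distance: int = 100_000,
) -> list[HaplotypePainting]:
    """Keep assemblies whose alignments reach within ``max_edge_distance``
    of both ROI edges (inclusive), i.e. contigs spanning the whole ROI."""
    kept = []
    for p in paintings:
        if not p.segments:
            continue
        left = min(s.target_start for s in p.segments)
        right = max(s.target_end for s in p.segments)
        if left <= roi.start + max_edge_distance and right >= roi.end - max_edge_distance:
            kept.append(p)
    return kept


def synchronize_orientation(
    painting: HaplotypePainting, min_anchor: int = 50_000
) -> HaplotypePainting:
    """Flip a painting when its outermost long alignments are both minus.

    Mirrors reverse-complementing the assembly sequence: if the first and
    last alignment segments of at least ``min_anchor`` bases are both '-',
    all orientations flip and query coordinates mirror; otherwise the
    painting is unchanged. Idempotent after one application. With no anchor
    segment the painting is returned unchanged and flagged.
    """
    anchors = [
        s for s in painting.segments if s.target_end - s.target_start >= min_anchor
    ]
    if not anchors:
        return replace(painting, no_anchor=True)
    if not (anchors[0].strand == "-" and anchors[-1].strand == "-"):
        return painting
    flipped = tuple(
        replace(
            s,
            strand="+" if s.strand == "-" else "-",
            query_start=s.query_len - s.query_end,
            query_end=s.query_len - s.query_start,
        )
        for s in painting.segments
    )
    return replace(painting, segments=flipped)


def group_haplotypes(
    paintings: list[HaplotypePainting],
    bin_size: int = 10_000,
    superpopulations: dict[str, str] | None = None,
) -> tuple[dict[str, str], dict[str, dict[str, int]]]:
    """Group orientation-synchronized paintings into structural haplogroups.

    Paintings with identical binned signatures share a haplogroup. Groups
    are labelled H1, H2, ... by decreasing size (ties by signature), so the
    labelling is invariant to input order. Returns the assembly -> group
    mapping and per-group counts stratified by superpopulation (single
    stratum "ALL" when no mapping is given).
    """
    by_sig: dict[tuple, list[HaplotypePainting]] = {}
    for p in paintings:
        by_sig.setdefault(p.signature(bin_size), []).append(p)
    ordered = sorted(by_sig.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    labels: dict[str, str] = {}
    counts: dict[str, dict[str, int]] = {}
    for rank, (_, members) in enumerate(ordered, start=1):
        group = f"H{rank}"
        counts[group] = {}
        for p in members:
            labels[p.assembly_id] = group
            pop = (superpopulations or {}).get(p.assembly_id, "ALL")
            counts[group][pop] = counts[group].get(pop, 0) + 1
    return labels, counts


# ---------------------------------------------------------------------------
# Self-alignment (SD pair) analysis
# ---------------------------------------------------------------------------

def _self_pairs(
    self_alignments: list[AlignmentRecord],
) -> list[tuple[GenomicInterval, GenomicInterval, str, int]]:
    """Deduplicated non-diagonal self-alignment pairs as
    (left span, right span, strand, aligned bases)."""
    seen = set()
    pairs = []
    for rec in self_alignments:
        if rec.query_name != rec.target_chrom:
            continue
        a = (rec.query_start, rec.query_end)
        b = (rec.target_start, rec.target_end)
        if a == b and rec.strand == "+":
            continue  # trivial identity diagonal
        left, right = sorted([a, b])
        key = (left, right, rec.strand)
        if key in seen:
            continue
        seen.add(key)
        pairs.append(
            (
                GenomicInterval(rec.query_name, *left),
                GenomicInterval(rec.query_name, *right),
                rec.strand,
                rec.aligned_bases,
            )
        )
    return pairs


def flank_analysis(
    self_alignments: list[AlignmentRecord],
    assembly_id: str,
    min_separation: int = 500_000,
    margin: int = 0,
) -> FlankAnalysis:
    """Tally SD bases by relative orientation from self-alignments.

    Only pairs whose inner distance (end of the left mate to start of the
    right mate) is at least ``min_separation`` qualify; both mates' lengths
    are summed under their relative orientation ('+' = direct, '-' =
    inverted). More direct than inverted bases (beyond ``margin``) marks the
    haplotype AT_RISK for copy-number rearrangement; the mirror case is
    PROTECTED; equal tallies (or no qualifying pair) are AMBIGUOUS.
    """
    direct = inverted = 0
    for left, right, strand, _ in _self_pairs(self_alignments):
        if right.start - left.end < min_separation:
            continue
        bases = left.length() + right.length()
        if strand == "+":
            direct += bases
        else:
            inverted += bases
    if direct > inverted + margin:
        risk = Risk.AT_RISK
    elif inverted > direct + margin:
        risk = Risk.PROTECTED
    else:
        risk = Risk.AMBIGUOUS
    return FlankAnalysis(assembly_id, direct, inverted, risk)


def flanking_sd_pair(
    self_alignments: list[AlignmentRecord],
    inversion: GenomicInterval,
    min_separation: int = 500_000,
) -> tuple[GenomicInterval, GenomicInterval] | None:
    """The inverted SD pair bracketing an inversion, or None.

    Candidate pairs are inverted-orientation self-alignment pairs at least
    ``min_separation`` apart with one mate entirely on each side of the
    inversion; the candidate with the most aligned bases wins.
    """
    candidates = [
        (left, right, bases)
        for left, right, strand, bases in _self_pairs(self_alignments)
        if strand == "-"
        and right.start - left.end >= min_separation
        and left.end <= inversion.start
        and right.start >= inversion.end
    ]
    if not candidates:
        return None
    left, right, _ = max(candidates, key=lambda c: (c[2], -c[0].start))
    return left, right
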