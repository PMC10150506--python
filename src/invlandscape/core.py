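"""Coordinate conventions, interval arithmetic and plain-text genomic I/O.

All coordinates are 0-based, half-open (BED/PAF convention). 1-based
inclusive coordinates (the convention used when regions are quoted as
``chr7:57,456,486-61,949,954``) exist only at the presentation layer; use
:func:`from_one_based` / :func:`to_one_based` at that boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "GenomicInterval",
    "AlignmentRecord",
    "AnnotationTrack",
    "CLASS_LABELS",
    "MixedChromosomeError",
    "FileFormatError",
    "merge_intervals",
    "intersect_length",
    "union_length",
    "overlap_fraction",
    "reciprocal_overlap",
    "from_one_based",
    "to_one_based",
    "parse_region",
    "read_bed",
    "write_bed",
    "read_paf",
    "write_paf",
]

#: Closed vocabulary of annotation class labels: human satellite (HSAT),
#: beta satellite (BSAT), alpha satellite (ASAT), monomeric alpha satellite
#: (MON), ribosomal DNA (RDNA), segmental duplication (SD), nonsyntenic
#: sequence and everything else.
CLASS_LABELS = frozenset(
    {"HSAT", "BSAT", "ASAT", "MON", "RDNA", "SD", "OTHER", "NONSYNTENIC"}
)


class MixedChromosomeError(ValueError):
    """Raised when an operation requires intervals from one chromosome."""


class FileFormatError(ValueError):
    """Raised on a malformed BED/PAF/table line; carries the line number."""

    def __init__(self, path: str, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")
        self.path = path
        self.line_no = line_no


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A chromosome-anchored span, 0-based half-open, in base pairs."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )

    def length(self) -> int:
        return self.end - self.start

    def intersects(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersection_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class AlignmentRecord:
    """One PAF-style pairwise mapping between a query sequence and a target.

    Both query and target spans are 0-based half-open. ``strand`` is '+'
    when the query aligns to the forward strand of the target, '-'
    otherwise. ``aligned_bases`` is the matched-base count (PAF column 10);
    ``cigar`` holds the optional ``cg:Z:`` tag for base-level projection.
    """

    query_name: str
    query_len: int
    query_start: int
    query_end: int
    strand: str
    target_chrom: str
    target_start: int
    target_end: int
    mapq: int
    aligned_bases: int
    target_len: int = 0
    cigar: str | None = None

    def __post_init__(self):
        if not (self.query_start < self.query_end <= self.query_len):
            raise ValueError(
                f"require query_start < query_end <= query_len, got "
                f"{self.query_start}, {self.query_end}, {self.query_len}"
            )
        if not self.target_start < self.target_end:
            raise ValueError("require target_start < target_end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 0 <= self.mapq <= 60:
            raise ValueError(f"mapq must be in [0, 60], got {self.mapq}")

    def query_interval(self) -> GenomicInterval:
        return GenomicInterval(self.query_name, self.query_start, self.query_end)

    def target_interval(self) -> GenomicInterval:
        return GenomicInterval(self.target_chrom, self.target_start, self.target_end)


@dataclass
class AnnotationTrack:
    """A named list of (interval, class label) records, e.g. a censat BED."""

    name: str
    records: list[tuple[GenomicInterval, str]] = field(default_factory=list)

    def __post_init__(self):
        for iv, label in self.records:
            if label not in CLASS_LABELS:
                raise ValueError(
                    f"unknown class label {label!r}; allowed: {sorted(CLASS_LABELS)}"
                )

    def intervals(self, chrom: str | None = None, label: str | None = None):
        """Intervals filtered by chromosome and/or class label."""
        return [
            iv
            for iv, lab in self.records
            if (chrom is None or iv.chrom == chrom)
            and (label is None or lab == label)
        ]

    def chroms(self) -> list[str]:
        return sorted({iv.chrom for iv, _ in self.records})

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------

def merge_intervals(
    intervals: Sequence[GenomicInterval], max_gap: int = 0
) -> list[GenomicInterval]:
    """Merge intervals whose gap is <= ``max_gap`` (sort-and-sweep).

    All intervals must lie on one chromosome. The result is sorted and any
    two output intervals are separated by strictly more than ``max_gap``
    bases. ``max_gap=0`` merges bookended and overlapping intervals only.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    if not intervals:
        return []
    chroms = {iv.chrom for iv in intervals}
    if len(chroms) > 1:
        raise MixedChromosomeError(
            f"merge_intervals requires one chromosome, got {sorted(chroms)}"
        )
    out: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda i: (i.start, i.end)):
        if out and iv.start - out[-1].end <= max_gap:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(iv)
    return out


def intersect_length(a: GenomicInterval, intervals: Iterable[GenomicInterval]) -> int:
    """Bases of ``a`` covered by the union of ``intervals`` (no double count)."""
    clipped = [
        GenomicInterval(a.chrom, max(a.start, iv.start), min(a.end, iv.end))
        for iv in intervals
        if iv.intersects(a)
    ]
    return sum(iv.length() for iv in merge_intervals(clipped)) if clipped else 0


def union_length(intervals: Sequence[GenomicInterval]) -> int:
    """Total bases in the union of intervals (may span chromosomes)."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    return sum(
        sum(m.length() for m in merge_intervals(ivs)) for ivs in by_chrom.values()
    )


def overlap_fraction(a: GenomicInterval, track: AnnotationTrack) -> float:
    """Fraction of ``a`` covered by the union of track records.

    Overlapping track records are counted once (union semantics), so the
    result is always in [0, 1]. An empty track gives 0.
    """
    return intersect_length(a, (iv for iv, _ in track.records)) / a.length()


def reciprocal_overlap(a: GenomicInterval, track: AnnotationTrack) -> tuple[float, float]:
    """Overlap of ``a`` with a track, measured in both directions.

    Returns ``(f_a, f_track)`` where ``f_a`` is the fraction of ``a``
    covered by intersecting track records and ``f_track`` is the fraction
    of the union of those intersecting records covered by ``a``. A
    reciprocal-overlap test at threshold ``t`` requires both >= ``t``.
    """
    hits = [iv for iv, _ in track.records if iv.intersects(a)]
    if not hits:
        return 0.0, 0.0
    inter = intersect_length(a, hits)
    return inter / a.length(), inter / union_length(hits)


# ---------------------------------------------------------------------------
# Coordinate convention converters
# ---------------------------------------------------------------------------

def from_one_based(chrom: str, start1: int, end1: int) -> GenomicInterval:
    """Build an interval from 1-based inclusive coordinates."""
    return GenomicInterval(chrom, start1 - 1, end1)


def to_one_based(iv: GenomicInterval) -> tuple[str, int, int]:
    """Present an interval as 1-based inclusive (chrom, start, end)."""
    return iv.chrom, iv.start + 1, iv.end


def parse_region(text: str) -> GenomicInterval:
    """Parse a ``chrom:start-end`` string (0-based half-open, as written)."""
    try:
        chrom, span = text.rsplit(":", 1)
        start, end = span.replace(",", "").split("-")
        return GenomicInterval(chrom, int(start), int(end))
    except (ValueError, IndexError) as exc:
        raise ValueError(f"cannot parse region {text!r}: {exc}") from exc


# ---------------------------------------------------------------------------
# BED / PAF I/O
# ---------------------------------------------------------------------------

def read_bed(
    path: str,
    name: str | None = None,
    default_label: str = "OTHER",
) -> AnnotationTrack:
    """Read a BED file (0-based half-open; optional 4th column class label).

    An absent 4th column falls back to ``default_label``. Unknown labels and
    malformed lines raise :class:`FileFormatError` with the line number.
    """
    records: list[tuple[GenomicInterval, str]] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FileFormatError(path, line_no, "expected >= 3 BED columns")
            try:
                iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            except ValueError as exc:
                raise FileFormatError(path, line_no, str(exc)) from exc
            label = fields[3] if len(fields) >= 4 and fields[3] else default_label
            if label not in CLASS_LABELS:
                raise FileFormatError(
                    path, line_no, f"unknown class label {label!r}"
                )
            records.append((iv, label))
    import os

    return AnnotationTrack(name or os.path.basename(path), records)


def write_bed(track: AnnotationTrack, path: str) -> None:
    """Write a 4-column BED; read_bed(write_bed(t)) round-trips records."""
    with open(path, "w") as fh:
        for iv, label in track.records:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{label}\n")


def _parse_paf_line(path: str, line_no: int, line: str) -> AlignmentRecord:
    fields = line.split("\t")
    if len(fields) < 12:
        raise FileFormatError(path, line_no, "expected >= 12 PAF columns")
    cigar = None
    for tag in fields[12:]:
        if tag.startswith("cg:Z:"):
            cigar = tag[5:]
    try:
        return AlignmentRecord(
            query_name=fields[0],
            query_len=int(fields[1]),
            query_start=int(fields[2]),
            query_end=int(fields[3]),
            strand=fields[4],
            target_chrom=fields[5],
            target_len=int(fields[6]),
            target_start=int(fields[7]),
            target_end=int(fields[8]),
            aligned_bases=int(fields[9]),
            mapq=int(fields[11]),
            cigar=cigar,
        )
    except ValueError as exc:
        raise FileFormatError(path, line_no, str(exc)) from exc


def read_paf(path: str) -> list[AlignmentRecord]:
    """Read a minimap2-style PAF file (12 mandatory columns + tags)."""
    records = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            records.append(_parse_paf_line(path, line_no, line))
    return records


def paf_line(rec: AlignmentRecord) -> str:
    """Format one alignment as a PAF line (block length = target span)."""
    fields = [
        rec.query_name,
        str(rec.query_len),
        str(rec.query_start),
        str(rec.query_end),
        rec.strand,
        rec.target_chrom,
        str(rec.target_len),
        str(rec.target_start),
        str(rec.target_end),
        str(rec.aligned_bases),
        str(rec.target_end - rec.target_start),
        str(rec.mapq),
    ]
    if rec.cigar:
        fields.append(f"cg:Z:{rec.cigar}")
    return "\t".join(fields)


def write_paf(records: Iterable[AlignmentRecord], path: str) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(paf_line(rec) + "\n")
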