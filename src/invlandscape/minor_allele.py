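"""Minor-allele and misorientation calling between two references.

For each region genotyped against both references, Watson/Crick read counts
are pooled across all unrelated samples and the Crick (plus-strand)
fractions compared. When the pooled strand fractions differ by at least 25
percentage points — with comparable read depth in both references — the
reference with the smaller Crick fraction carries the less frequent
("minor") orientation of the polymorphism. Regions where the whole
population is homozygously inverted against that same reference are
reclassified as reference misorientations rather than low-frequency
polymorphisms.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping

from .genotyper import Genotype, StrandCount, detect_misorientation

__all__ = [
    "RegionStrandSummary",
    "Verdict",
    "ReconciledLabel",
    "MinorAlleleCall",
    "summarize_region",
    "call_minor_allele",
    "reconcile_with_misorientation",
]


@dataclass(frozen=True)
class RegionStrandSummary:
    """Pooled strand counts for one region against one reference."""

    region_id: str
    reference_id: str
    watson_total: int
    crick_total: int
    callable: bool

    @property
    def total(self) -> int:
        return self.watson_total + self.crick_total

    @property
    def crick_fraction(self) -> float:
        if self.total == 0:
            raise ZeroDivisionError("no reads pooled for this region")
        return self.crick_total / self.total


class Verdict(enum.Enum):
    MINOR_IN_REF_A = "MINOR_IN_REF_A"
    MINOR_IN_REF_B = "MINOR_IN_REF_B"
    CONCORDANT = "CONCORDANT"
    NO_CALL = "NO_CALL"


class ReconciledLabel(enum.Enum):
    MINOR_ALLELE = "MINOR_ALLELE"
    MISORIENTATION = "MISORIENTATION"
    CONCORDANT = "CONCORDANT"
    NO_CALL = "NO_CALL"


@dataclass(frozen=True)
class MinorAlleleCall:
    region_id: str
    verdict: Verdict
    fraction_difference: float | None = None
    consistency_metric: float | None = None


def summarize_region(
    counts: Iterable[StrandCount], min_reads: int = 20
) -> RegionStrandSummary:
    """Pool strand counts for one region x one reference across samples.

    The summary is callable only with at least ``min_reads`` pooled reads.
    All counts must share one region and one reference.
    """
    counts = list(counts)
    if not counts:
        return RegionStrandSummary("", "", 0, 0, callable=False)
    regions = {c.region_id for c in counts}
    refs = {c.reference_id for c in counts}
    if len(regions) > 1 or len(refs) > 1:
        raise ValueError("summarize_region pools one region x one reference")
    watson = sum(c.watson for c in counts)
    crick = sum(c.crick for c in counts)
    return RegionStrandSummary(
        regions.pop(), refs.pop(), watson, crick,
        callable=(watson + crick) >= min_reads,
    )


def call_minor_allele(
    a: RegionStrandSummary,
    b: RegionStrandSummary,
    diff_threshold: float = 0.25,
    consistency_threshold: float = 0.25,
) -> MinorAlleleCall:
    """Compare one region's pooled strand fractions between references.

    ``fraction_difference`` is the absolute difference of Crick fractions
    (on the 0-1 scale). ``consistency_metric`` is the relative difference of
    pooled read totals, |tA - tB| / max(tA, tB); a large value signals that
    the two references did not attract comparable read sets over this
    region, so no call is made. A minor allele is reported in the reference
    with the *smaller* Crick fraction (more reads in inverted orientation).
    """
    region_id = a.region_id or b.region_id
    if not (a.callable and b.callable):
        return MinorAlleleCall(region_id, Verdict.NO_CALL)
    diff = abs(a.crick_fraction - b.crick_fraction)
    consistency = abs(a.total - b.total) / max(a.total, b.total)
    if consistency > consistency_threshold:
        return MinorAlleleCall(region_id, Verdict.NO_CALL, diff, consistency)
    if diff >= diff_threshold:
        verdict = (
            Verdict.MINOR_IN_REF_A
            if a.crick_fraction < b.crick_fraction
            else Verdict.MINOR_IN_REF_B
        )
        return MinorAlleleCall(region_id, verdict, diff, consistency)
    return MinorAlleleCall(region_id, Verdict.CONCORDANT, diff, consistency)


def reconcile_with_misorientation(
    call: MinorAlleleCall,
    genotypes_on_minor_ref: Mapping[str, Genotype] | None,
    min_called: int | None = None,
) -> ReconciledLabel:
    """Decide misorientation vs genuine minor allele for a MINOR_* call.

    ``genotypes_on_minor_ref`` is the region's genotype column against the
    reference named in the verdict. If the whole population is homozygously
    inverted there, the site is a misoriented reference segment; otherwise
    it stays a minor allele. CONCORDANT and NO_CALL pass through.
    """
    if call.verdict is Verdict.CONCORDANT:
        return ReconciledLabel.CONCORDANT
    if call.verdict is Verdict.NO_CALL:
        return ReconciledLabel.NO_CALL
    if genotypes_on_minor_ref is not None and detect_misorientation(
        genotypes_on_minor_ref, min_called=min_called
    ):
        return ReconciledLabel.MISORIENTATION
    return ReconciledLabel.MINOR_ALLELE
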