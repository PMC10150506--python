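"""Inversion genotyping from Strand-seq Watson/Crick read counts.

In strand-state-corrected Strand-seq data, reads over a directly oriented
locus align to the plus strand (Crick) while reads over an inverted locus
align to the minus strand (Watson). The Crick fraction of a region
therefore encodes its inversion genotype: ~1 for homozygous direct, ~0.5
for heterozygous (one homologue inverted), ~0 for homozygous inverted.
A region where every sample in a population is homozygous inverted against
a reference is most parsimoniously a misoriented reference segment rather
than a fixed polymorphism.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import GenomicInterval

__all__ = [
    "Genotype",
    "StrandCount",
    "UndefinedAlleleFrequencyError",
    "genotype_region",
    "genotype_counts_table",
    "inverted_allele_frequency",
    "detect_misorientation",
    "binned_strand_profile",
    "read_counts_table",
    "write_genotype_matrix",
]


class Genotype(enum.Enum):
    """Diploid inversion genotype relative to the reference orientation."""

    HOM_DIRECT = "HOM_DIRECT"
    HET = "HET"
    HOM_INV = "HOM_INV"
    NO_CALL = "NO_CALL"


#: Genotypes that count toward allele frequencies.
CALLED = (Genotype.HOM_DIRECT, Genotype.HET, Genotype.HOM_INV)


@dataclass(frozen=True)
class StrandCount:
    """Watson (minus strand) and Crick (plus strand) read tallies for one
    sample x region x reference combination."""

    sample_id: str
    region_id: str
    reference_id: str
    watson: int
    crick: int

    def __post_init__(self):
        if self.watson < 0 or self.crick < 0:
            raise ValueError("read counts must be non-negative")

    def total(self) -> int:
        return self.watson + self.crick


class UndefinedAlleleFrequencyError(ValueError):
    """Raised when a frequency is requested from a column with no calls."""


def genotype_region(
    counts: StrandCount,
    min_reads: int = 20,
    hom_frac: float = 0.8,
    het_band: float = 0.35,
) -> Genotype:
    """Call the inversion genotype of one sample over one region.

    With ``f = crick / (watson + crick)``:

    * ``f >= hom_frac``              -> HOM_DIRECT
    * ``f <= 1 - hom_frac``          -> HOM_INV
    * ``het_band <= f <= 1-het_band``-> HET
    * otherwise, or fewer than ``min_reads`` total reads -> NO_CALL

    The gaps between the homozygous and heterozygous bands are deliberate
    guard zones: ambiguous strand fractions are left uncalled rather than
    forced into a genotype.
    """
    total = counts.total()
    if total < min_reads or total == 0:
        return Genotype.NO_CALL
    # both fractions computed directly so the band edges are exact
    f_crick = counts.crick / total
    f_watson = counts.watson / total
    if f_crick >= hom_frac:
        return Genotype.HOM_DIRECT
    if f_watson >= hom_frac:
        return Genotype.HOM_INV
    if f_crick >= het_band and f_watson >= het_band:
        return Genotype.HET
    return Genotype.NO_CALL


def genotype_counts_table(
    counts: pd.DataFrame,
    min_reads: int = 20,
    hom_frac: float = 0.8,
    het_band: float = 0.35,
) -> dict[str, dict[str, Genotype]]:
    """Genotype every (region, sample) cell of a long-format count table.

    ``counts`` needs columns sample_id, region_id, watson, crick (a
    reference_id column, if present, must be single-valued). Returns the
    genotype matrix as ``{region_id: {sample_id: Genotype}}``.
    """
    if "reference_id" in counts.columns and counts["reference_id"].nunique() > 1:
        raise ValueError("count table mixes references; genotype one at a time")
    matrix: dict[str, dict[str, Genotype]] = {}
    for row in counts.itertuples(index=False):
        sc = StrandCount(
            str(row.sample_id),
            str(row.region_id),
            str(getattr(row, "reference_id", "ref")),
            int(row.watson),
            int(row.crick),
        )
        matrix.setdefault(sc.region_id, {})[sc.sample_id] = genotype_region(
            sc, min_reads=min_reads, hom_frac=hom_frac, het_band=het_band
        )
    return matrix


def inverted_allele_frequency(column: Mapping[str, Genotype]) -> float:
    """Inverted-allele frequency of one region across samples.

    NO_CALL samples are treated as missing data: they are excluded from both
    the numerator and the denominator. Raises
    :class:`UndefinedAlleleFrequencyError` when no sample is called.
    """
    hom_inv = sum(1 for g in column.values() if g is Genotype.HOM_INV)
    het = sum(1 for g in column.values() if g is Genotype.HET)
    called = sum(1 for g in column.values() if g in CALLED)
    if called == 0:
        raise UndefinedAlleleFrequencyError("no called genotypes in column")
    return (2 * hom_inv + het) / (2 * called)


def detect_misorientation(
    column: Mapping[str, Genotype], min_called: int | None = None
) -> bool:
    """Flag a region as a reference misorientation.

    True iff at least ``min_called`` samples are called and every called
    genotype is HOM_INV — i.e. the whole population appears homozygously
    inverted against this reference. ``min_called`` defaults to the number
    of samples in the column, so by default every sample must be
    genotypable and inverted.
    """
    if min_called is None:
        min_called = len(column)
    called = [g for g in column.values() if g in CALLED]
    if len(called) < min_called or not called:
        return False
    return all(g is Genotype.HOM_INV for g in called)


def binned_strand_profile(
    watson_positions: Sequence[int],
    crick_positions: Sequence[int],
    region: GenomicInterval,
    bin_size: int = 50_000,
    step: int = 10_000,
) -> list[tuple[GenomicInterval, int, int]]:
    """Sliding-window Watson/Crick read-count profile over a region.

    Bins of ``bin_size`` start every ``step`` bases at ``region.start`` and
    are emitted while they fit inside the region; a read belongs to every
    bin containing its start position. Returns
    ``[(bin interval, watson count, crick count), ...]``.
    """
    if step > bin_size:
        raise ValueError("step must be <= bin_size")
    out = []
    start = region.start
    while start + bin_size <= region.end:
        end = start + bin_size
        w = sum(1 for p in watson_positions if start <= p < end)
        c = sum(1 for p in crick_positions if start <= p < end)
        out.append((GenomicInterval(region.chrom, start, end), w, c))
        start += step
    return out


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

def read_counts_table(path: str) -> pd.DataFrame:
    """Read a tab-separated strand count table
    (sample_id, region_id, reference_id, watson, crick)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "region_id": str})
    required = {"sample_id", "region_id", "reference_id", "watson", "crick"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    return df


def write_genotype_matrix(
    matrix: Mapping[str, Mapping[str, Genotype]], path: str
) -> None:
    """Write a genotype matrix as a region x sample TSV of genotype names."""
    df = pd.DataFrame(
        {
            region: {s: g.value for s, g in column.items()}
            for region, column in matrix.items()
        }
    ).T.sort_index()
    df.index.name = "region_id"
    df.to_csv(path, sep="\t")
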