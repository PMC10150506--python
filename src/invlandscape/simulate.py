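"""Synthetic two-reference world with known truth.

The generator emulates the study design behind the analysis pipeline: a
population of diploid samples genotyped by Strand-seq against two reference
assemblies — reference A complete (satellites and pericentromeric sequence
assembled, everything correctly oriented) and reference B with misoriented
segments and missing (nonsyntenic-in-A) pericentromeric sequence. Diploid
genotypes are drawn under Hardy-Weinberg at planned allele frequencies;
region-level Watson/Crick read counts follow a Poisson depth with a
Bernoulli strand-error; alignment records for remapping and for assembled
haplotypes are constructed analytically from the plan, so every downstream
stage can be checked against exact truth.

Coordinates of reference B reuse reference A's: deleted (nonsyntenic)
blocks leave a gap rather than shifting downstream features. This keeps
truth bookkeeping exact and is a deliberate simplification relative to real
assembly coordinate shifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .core import AlignmentRecord, AnnotationTrack, GenomicInterval
from .genotyper import Genotype
from .remap import NoveltyClass

__all__ = [
    "InversionPlan",
    "HaplotypePlan",
    "SimulationConfig",
    "TruthSet",
    "World",
    "simulate_genotypes",
    "simulate_strand_counts",
    "simulate_remap_alignments",
    "simulate_haplotype_alignments",
    "simulate_world",
    "study_config",
    "study_haplotype_plans",
]

REF_A = "refA"  # the complete assembly
REF_B = "refB"  # misoriented + missing pericentromeric sequence


@dataclass(frozen=True)
class InversionPlan:
    """One planned inversion: interval, truth frequency and expected fate."""

    region_id: str
    chrom: str
    start: int
    end: int
    allele_freq: float
    variant_class: str = "BAL"  # BAL | INVDUP | CPX
    novelty: NoveltyClass = NoveltyClass.SYNTENIC_MAPPED
    misoriented_in_b: bool = False
    pericentromeric: bool = False

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass(frozen=True)
class HaplotypePlan:
    """Structural plan of one assembled haplotype over an ROI.

    ``segments`` are (target_start, target_end, strand) in reference
    coordinates, ordered along the target; the assembly is their
    concatenation. ``sd_pairs`` are (left_start, left_end, right_start,
    right_end, strand) in *assembly* coordinates and become self-alignment
    records.
    """

    assembly_id: str
    segments: tuple[tuple[int, int, str], ...]
    sd_pairs: tuple[tuple[int, int, int, int, str], ...] = ()
    superpopulation: str = "ALL"

    def structure_key(self) -> tuple:
        """Hashable identity of the planted structure (the truth grouping)."""
        return self.segments


@dataclass
class SimulationConfig:
    seed: int = 0
    chrom_lengths: dict[str, int] = field(default_factory=dict)
    satellites: list[tuple[str, int, int, str]] = field(default_factory=list)
    sds: list[tuple[str, int, int]] = field(default_factory=list)
    inversions: list[InversionPlan] = field(default_factory=list)
    nonsyntenic: list[tuple[str, int, int]] = field(default_factory=list)
    n_samples: int = 41
    coverage: float = 50.0
    background_error: float = 0.02
    haplotypes: list[HaplotypePlan] = field(default_factory=list)
    roi: GenomicInterval | None = None

    def validate(self) -> None:
        if not 0.0 <= self.background_error <= 0.1:
            raise ValueError("background_error must be in [0, 0.1]")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        for chrom, start, end, label in self.satellites:
            self._check_span(chrom, start, end, f"satellite {label}")
        for chrom, start, end in self.sds:
            self._check_span(chrom, start, end, "SD")
        for chrom, start, end in self.nonsyntenic:
            self._check_span(chrom, start, end, "nonsyntenic block")
        seen = set()
        for inv in self.inversions:
            if inv.region_id in seen:
                raise ValueError(f"duplicate region_id {inv.region_id!r}")
            seen.add(inv.region_id)
            self._check_span(inv.chrom, inv.start, inv.end, inv.region_id)
            if not 0.0 <= inv.allele_freq <= 1.0:
                raise ValueError(f"{inv.region_id}: allele_freq outside [0, 1]")
            if inv.misoriented_in_b and inv.novelty in (
                NoveltyClass.NONSYNTENIC_FAILED,
            ):
                raise ValueError(
                    f"{inv.region_id}: cannot be both flipped and deleted in {REF_B}"
                )

    def _check_span(self, chrom: str, start: int, end: int, what: str) -> None:
        if chrom not in self.chrom_lengths:
            raise ValueError(f"{what}: unknown chromosome {chrom!r}")
        if not 0 <= start < end <= self.chrom_lengths[chrom]:
            raise ValueError(f"{what}: span [{start}, {end}) outside {chrom}")


@dataclass
class TruthSet:
    """Everything the pipeline is supposed to recover."""

    sample_ids: list[str]
    genotypes: dict[str, dict[str, Genotype]]  # w.r.t. reference A orientation
    frequencies: dict[str, float]
    misoriented_in_b: set[str]  # regions whose reference-B orientation is flipped
    expected_misorientation_calls_b: set[str]  # flips fixed direct in the population
    expected_novelty: dict[str, NoveltyClass]
    nonsyntenic: AnnotationTrack
    haplogroups: dict[str, tuple]  # assembly -> planted structure key


@dataclass
class World:
    config: SimulationConfig
    truth: TruthSet
    censat: AnnotationTrack
    sds: AnnotationTrack
    counts: pd.DataFrame  # both references, long format
    remap_paf: list[AlignmentRecord]
    assembly_paf: list[AlignmentRecord]
    self_paf: list[AlignmentRecord]
    callset: pd.DataFrame


# ---------------------------------------------------------------------------
# Component generators (pure functions of their rng)
# ---------------------------------------------------------------------------

def simulate_genotypes(
    inversions: Iterable[InversionPlan],
    n_samples: int,
    rng: np.random.Generator,
    sample_ids: list[str] | None = None,
) -> dict[str, dict[str, Genotype]]:
    """Draw diploid genotypes under Hardy-Weinberg at the planned frequency:
    P(HOM_INV) = f^2, P(HET) = 2f(1-f), P(HOM_DIRECT) = (1-f)^2."""
    if sample_ids is None:
        sample_ids = [f"S{i:03d}" for i in range(n_samples)]
    out: dict[str, dict[str, Genotype]] = {}
    for inv in inversions:
        f = inv.allele_freq
        alleles = rng.random((n_samples, 2)) < f
        dosage = alleles.sum(axis=1)
        out[inv.region_id] = {
            s: (Genotype.HOM_INV, Genotype.HET)[2 - d]
            if d >= 1
            else Genotype.HOM_DIRECT
            for s, d in zip(sample_ids, dosage)
        }
    return out


_P_DIRECT = {Genotype.HOM_DIRECT: 1.0, Genotype.HET: 0.5, Genotype.HOM_INV: 0.0}


def simulate_strand_counts(
    genotypes: dict[str, dict[str, Genotype]],
    coverage: float,
    background_error: float,
    rng: np.random.Generator,
    reference_id: str,
    flipped: set[str] = frozenset(),
    deleted: set[str] = frozenset(),
) -> pd.DataFrame:
    """Region-level Watson/Crick counts for one reference.

    Read depth per sample x region is Poisson(coverage); each read reports
    Crick with probability ``(1-e)*p + e*(1-p)`` where ``p`` is the direct-
    allele dosage fraction of the genotype *under the region's orientation
    in this reference* (flipped regions mirror it). Deleted regions emit no
    rows.
    """
    rows = []
    for region_id, column in genotypes.items():
        if region_id in deleted:
            continue
        flip = region_id in flipped
        for sample_id, gt in column.items():
            p = _P_DIRECT[gt]
            if flip:
                p = 1.0 - p
            p_crick = (1.0 - background_error) * p + background_error * (1.0 - p)
            n = int(rng.poisson(coverage))
            crick = int(rng.binomial(n, p_crick)) if n else 0
            rows.append((sample_id, region_id, reference_id, n - crick, crick))
    return pd.DataFrame(
        rows, columns=["sample_id", "region_id", "reference_id", "watson", "crick"]
    )


def simulate_remap_alignments(
    inversions: Iterable[InversionPlan],
    chrom_lengths: dict[str, int],
    rng: np.random.Generator,
) -> list[AlignmentRecord]:
    """PAF records for mapping each inversion's sequence onto reference B,
    constructed to realize the planned remap fate.

    Cleanly syntenic inversions map back at their own coordinates (split in
    two chained pieces when long enough, to exercise collapsing, plus an
    occasional mapq-0 or off-chromosome decoy that filtering must drop).
    FAILED_ONLY inversions yield two short far-apart mappings that no chain
    survives; deleted (NONSYNTENIC_FAILED) sequence yields nothing.
    """
    records: list[AlignmentRecord] = []
    other = {c: [o for o in chrom_lengths if o != c] for c in chrom_lengths}
    for inv in inversions:
        length = inv.end - inv.start
        qname = inv.region_id
        if inv.novelty is NoveltyClass.NONSYNTENIC_FAILED:
            continue
        if inv.novelty is NoveltyClass.FAILED_ONLY:
            if length >= 10_000:
                piece = max(1, int(0.3 * length))
                far = inv.start + piece + 150_000
                far_end = min(far + piece, chrom_lengths[inv.chrom])
                records.append(
                    AlignmentRecord(qname, length, 0, piece, "+", inv.chrom,
                                    inv.start, inv.start + piece, 60, piece,
                                    target_len=chrom_lengths[inv.chrom])
                )
                if far_end > far:
                    records.append(
                        AlignmentRecord(qname, length, piece, 2 * piece, "+",
                                        inv.chrom, far, far_end, 60,
                                        far_end - far,
                                        target_len=chrom_lengths[inv.chrom])
                    )
            continue
        # MAPPED fates: clean chain at the original coordinates.
        split = length >= 40_000 and rng.random() < 0.5
        if split:
            l1 = length // 2
            gap = min(30_000, int(0.3 * length))
            end2 = min(inv.start + l1 + gap + (length - l1), chrom_lengths[inv.chrom])
            records.append(
                AlignmentRecord(qname, length, 0, l1, "+", inv.chrom,
                                inv.start, inv.start + l1, 60, l1,
                                target_len=chrom_lengths[inv.chrom])
            )
            records.append(
                AlignmentRecord(qname, length, l1, length, "+", inv.chrom,
                                inv.start + l1 + gap, end2, 60, length - l1,
                                target_len=chrom_lengths[inv.chrom])
            )
        else:
            records.append(
                AlignmentRecord(qname, length, 0, length, "+", inv.chrom,
                                inv.start, inv.end, 60, length,
                                target_len=chrom_lengths[inv.chrom])
            )
        if rng.random() < 0.3:  # mapq-0 decoy on the right chromosome
            records.append(
                AlignmentRecord(qname, length, 0, max(1, length // 4), "+",
                                inv.chrom, inv.start, inv.start + max(1, length // 4),
                                0, max(1, length // 4),
                                target_len=chrom_lengths[inv.chrom])
            )
        if other[inv.chrom] and rng.random() < 0.3:  # off-chromosome decoy
            oc = other[inv.chrom][0]
            span = min(max(1, length // 3), chrom_lengths[oc])
            records.append(
                AlignmentRecord(qname, length, 0, span, "-", oc, 0, span, 60,
                                span, target_len=chrom_lengths[oc])
            )
    return records


def simulate_haplotype_alignments(
    plans: Iterable[HaplotypePlan],
    ref_chrom: str,
    ref_len: int,
) -> tuple[list[AlignmentRecord], list[AlignmentRecord]]:
    """Assembly-to-reference and self-alignment PAF records from plans.

    The assembly is the concatenation of the planned target segments, so
    query offsets accumulate in plan order; self-alignment records realize
    the planned SD pairs (plus the trivial identity diagonal, which
    downstream analysis must ignore).
    """
    to_ref: list[AlignmentRecord] = []
    self_aln: list[AlignmentRecord] = []
    for plan in plans:
        qlen = sum(e - s for s, e, _ in plan.segments)
        offset = 0
        for t_start, t_end, strand in plan.segments:
            seg = t_end - t_start
            to_ref.append(
                AlignmentRecord(plan.assembly_id, qlen, offset, offset + seg,
                                strand, ref_chrom, t_start, t_end, 60, seg,
                                target_len=ref_len)
            )
            offset += seg
        self_aln.append(  # identity diagonal
            AlignmentRecord(plan.assembly_id, qlen, 0, qlen, "+",
                            plan.assembly_id, 0, qlen, 60, qlen, target_len=qlen)
        )
        for ls, le, rs, re, strand in plan.sd_pairs:
            self_aln.append(
                AlignmentRecord(plan.assembly_id, qlen, ls, le, strand,
                                plan.assembly_id, rs, re, 60, min(le - ls, re - rs),
                                target_len=qlen)
            )
    return to_ref, self_aln


# ---------------------------------------------------------------------------
# World assembly
# ---------------------------------------------------------------------------

def simulate_world(config: SimulationConfig) -> World:
    """Generate the full two-reference world; pure function of the config."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    censat = AnnotationTrack(
        "censat",
        [(GenomicInterval(c, s, e), lab) for c, s, e, lab in config.satellites],
    )
    sds = AnnotationTrack(
        "sd", [(GenomicInterval(c, s, e), "SD") for c, s, e in config.sds]
    )

    # Nonsyntenic mask: explicit blocks plus the span of every inversion
    # planted in reference-A-only sequence.
    nonsyn_records = [
        (GenomicInterval(c, s, e), "NONSYNTENIC") for c, s, e in config.nonsyntenic
    ]
    for inv in config.inversions:
        if inv.novelty in (NoveltyClass.NONSYNTENIC_MAPPED, NoveltyClass.NONSYNTENIC_FAILED):
            nonsyn_records.append((inv.interval(), "NONSYNTENIC"))
    nonsyntenic = AnnotationTrack("nonsyntenic", nonsyn_records)

    sample_ids = [f"S{i:03d}" for i in range(config.n_samples)]
    genotypes = simulate_genotypes(
        config.inversions, config.n_samples, rng, sample_ids
    )
    frequencies = {i.region_id: i.allele_freq for i in config.inversions}
    flipped = {i.region_id for i in config.inversions if i.misoriented_in_b}
    deleted = {
        i.region_id
        for i in config.inversions
        if i.novelty is NoveltyClass.NONSYNTENIC_FAILED
    }

    counts_a = simulate_strand_counts(
        genotypes, config.coverage, config.background_error, rng, REF_A
    )
    counts_b = simulate_strand_counts(
        genotypes, config.coverage, config.background_error, rng, REF_B,
        flipped=flipped, deleted=deleted,
    )
    counts = pd.concat([counts_a, counts_b], ignore_index=True)

    remap_paf = simulate_remap_alignments(
        config.inversions, config.chrom_lengths, rng
    )
    roi = config.roi
    assembly_paf: list[AlignmentRecord] = []
    self_paf: list[AlignmentRecord] = []
    if config.haplotypes:
        if roi is None:
            raise ValueError("haplotype plans require a roi in the config")
        assembly_paf, self_paf = simulate_haplotype_alignments(
            config.haplotypes, roi.chrom, config.chrom_lengths[roi.chrom]
        )

    truth = TruthSet(
        sample_ids=sample_ids,
        genotypes=genotypes,
        frequencies=frequencies,
        misoriented_in_b=flipped,
        expected_misorientation_calls_b={
            i.region_id
            for i in config.inversions
            if i.misoriented_in_b and i.allele_freq == 0.0
        },
        expected_novelty={i.region_id: i.novelty for i in config.inversions},
        nonsyntenic=nonsyntenic,
        haplogroups={p.assembly_id: p.structure_key() for p in config.haplotypes},
    )
    callset = pd.DataFrame(
        [
            (i.region_id, i.chrom, i.start, i.end, i.variant_class, i.allele_freq)
            for i in config.inversions
        ],
        columns=["region_id", "chrom", "start", "end", "variant_class", "allele_freq"],
    )
    return World(config, truth, censat, sds, counts, remap_paf,
                 assembly_paf, self_paf, callset)


# ---------------------------------------------------------------------------
# Study-scale default world
# ---------------------------------------------------------------------------

def study_config(
    seed: int = 0,
    n_chromosomes: int = 3,
    chrom_length: int = 50_000_000,
    n_inversions_per_chrom: int = 20,
    n_samples: int = 41,
    coverage: float = 50.0,
    background_error: float = 0.02,
    pericentromeric_fraction: float = 0.3,
    n_misoriented: int = 3,
    include_haplotypes: bool = True,
) -> SimulationConfig:
    """A study-like default world.

    Each chromosome carries a central satellite array (HSAT/ASAT/BSAT/MON,
    plus rDNA on the first chromosome), SD pairs, and a catalogue of
    inversions with log-uniform sizes (10 kbp - 500 kbp) and uniform
    (0.05-0.95) inverted-allele frequencies; a configurable share of
    inversions is planted inside the pericentromeric zone. Reference B
    lacks the first chromosome's satellite zone (nonsyntenic in A) and
    carries a few misoriented segments. Population size, read depth and
    strand-error defaults (41 samples, 50 reads/region, 2%) mirror the
    study conditions the pipeline is meant for.
    """
    rng = np.random.default_rng(seed)
    chroms = {f"chr{i + 1}": chrom_length for i in range(n_chromosomes)}
    mid = chrom_length // 2
    satellites = []
    sds: list[tuple[str, int, int]] = []
    for ci, chrom in enumerate(chroms):
        satellites += [
            (chrom, mid - 2_500_000, mid - 1_500_000, "HSAT"),
            (chrom, mid - 1_400_000, mid - 1_100_000, "MON"),
            (chrom, mid - 1_000_000, mid + 1_000_000, "ASAT"),
            (chrom, mid + 1_200_000, mid + 1_600_000, "BSAT"),
        ]
        if ci == 0:
            satellites.append((chrom, mid + 2_000_000, mid + 2_400_000, "RDNA"))
        # two SD pairs per chromosome: one near the satellite zone, one distal
        sds += [
            (chrom, mid - 4_000_000, mid - 3_900_000),
            (chrom, mid - 1_050_000, mid - 950_000),
            (chrom, chrom_length - 10_000_000, chrom_length - 9_950_000),
            (chrom, chrom_length - 8_000_000, chrom_length - 7_950_000),
        ]

    # planted-pericentromeric inversions fall strictly inside the built
    # regions (satellite seeds + 1 Mbp flank); planted-arm inversions stay
    # clear of them, so the planted flag matches the classifier's answer
    peri_zone = (mid - 3_400_000, mid + 1_900_000)
    arm_clear = (mid - 3_600_000, mid + 4_500_000)
    inversions: list[InversionPlan] = []
    nonsyn_chrom = "chr1"
    for chrom in chroms:
        for k in range(n_inversions_per_chrom):
            rid = f"{chrom}-inv{k:03d}"
            size = int(10 ** rng.uniform(4, np.log10(5e5)))
            peri = rng.random() < pericentromeric_fraction
            if peri:
                start = int(rng.integers(peri_zone[0], peri_zone[1] - size))
            else:
                arm = rng.random() < 0.5
                lo, hi = (3_500_000, arm_clear[0] - size) if arm else (
                    arm_clear[1], chrom_length - size
                )
                start = int(rng.integers(lo, max(lo + 1, hi)))
            freq = float(rng.uniform(0.05, 0.95))
            novelty = NoveltyClass.SYNTENIC_MAPPED
            if chrom == nonsyn_chrom and peri:
                # new-in-A pericentromeric sequence: absent or restructured in B
                novelty = (
                    NoveltyClass.NONSYNTENIC_FAILED
                    if rng.random() < 0.5
                    else NoveltyClass.NONSYNTENIC_MAPPED
                )
            elif rng.random() < 0.05:
                novelty = NoveltyClass.FAILED_ONLY
            inversions.append(
                InversionPlan(rid, chrom, start, start + size, freq,
                              novelty=novelty, pericentromeric=peri)
            )
    # misoriented reference-B segments: fixed direct in the population
    for m in range(n_misoriented):
        chrom = list(chroms)[m % n_chromosomes]
        start = 2_000_000 + m * 1_000_000
        inversions.append(
            InversionPlan(
                f"{chrom}-misorient{m}", chrom, start, start + 200_000,
                allele_freq=0.0, misoriented_in_b=True,
            )
        )
    # polymorphic regions where the two references disagree in orientation:
    # reference B carries the minor allele at six sites, reference A at two
    for m, freq in enumerate([0.15, 0.2, 0.25, 0.2, 0.3, 0.15, 0.8, 0.85]):
        chrom = list(chroms)[m % n_chromosomes]
        start = 6_000_000 + m * 800_000
        inversions.append(
            InversionPlan(
                f"{chrom}-minor{m}", chrom, start, start + 150_000,
                allele_freq=freq, misoriented_in_b=True,
            )
        )

    roi = GenomicInterval("chr1", 40_000_000, 43_000_000)
    haplotypes = study_haplotype_plans(roi) if include_haplotypes else []
    return SimulationConfig(
        seed=seed,
        chrom_lengths=chroms,
        satellites=satellites,
        sds=sds,
        inversions=inversions,
        nonsyntenic=[(nonsyn_chrom, mid - 2_500_000, mid + 2_400_000)],
        n_samples=n_samples,
        coverage=coverage,
        background_error=background_error,
        haplotypes=haplotypes,
        roi=roi,
    )


def write_world(world: World, out_dir: str) -> None:
    """Write a simulated world as plain-text files (BED/TSV/PAF/JSON)."""
    import json
    import os

    from .core import write_bed, write_paf

    os.makedirs(out_dir, exist_ok=True)

    def p(name: str) -> str:
        return os.path.join(out_dir, name)

    write_bed(world.censat, p("refA.censat.bed"))
    write_bed(world.sds, p("refA.sd.bed"))
    write_bed(world.truth.nonsyntenic, p("nonsyntenic.bed"))
    for ref, name in ((REF_A, "counts.refA.tsv"), (REF_B, "counts.refB.tsv")):
        world.counts[world.counts["reference_id"] == ref].to_csv(
            p(name), sep="\t", index=False
        )
    world.callset.to_csv(p("callset.tsv"), sep="\t", index=False)
    write_paf(world.remap_paf, p("remap.paf"))
    write_paf(world.assembly_paf, p("alignments.paf"))
    write_paf(world.self_paf, p("self_alignments.paf"))
    truth = {
        "sample_ids": world.truth.sample_ids,
        "genotypes": {
            region: {s: g.value for s, g in column.items()}
            for region, column in world.truth.genotypes.items()
        },
        "frequencies": world.truth.frequencies,
        "misoriented_in_refB": sorted(world.truth.misoriented_in_b),
        "expected_novelty": {
            rid: cls.value for rid, cls in world.truth.expected_novelty.items()
        },
        "haplogroups": {
            a: [list(seg) for seg in key]
            for a, key in world.truth.haplogroups.items()
        },
    }
    with open(p("truth.json"), "w") as fh:
        json.dump(truth, fh, indent=1)


def study_haplotype_plans(
    roi: GenomicInterval, n_assemblies: int = 20
) -> list[HaplotypePlan]:
    """Assemblies drawn from five planted structural configurations over the
    ROI: direct, one inverted block (two sizes), two inverted blocks, and an
    extra inverted segment; each with flanking SD pairs in direct or
    inverted orientation."""
    s = roi.start
    seg = (roi.end - roi.start) // 6  # 500 kbp for the default 3-Mbp ROI
    plans: list[tuple[tuple, tuple]] = [
        # structure 1: fully direct; direct SD pair far apart -> mCNV risk
        (
            ((s, s + 3 * seg, "+"), (s + 3 * seg, s + 6 * seg, "+")),
            ((0, 50_000, 3 * seg, 3 * seg + 50_000, "+"),),
        ),
        # structure 2: middle block inverted; inverted SD pair -> protected
        (
            ((s, s + 2 * seg, "+"), (s + 2 * seg, s + 4 * seg, "-"),
             (s + 4 * seg, s + 6 * seg, "+")),
            ((0, 50_000, 5 * seg, 5 * seg + 50_000, "-"),),
        ),
        # structure 3: small inverted block near the right edge
        (
            ((s, s + 5 * seg, "+"), (s + 5 * seg, s + 5 * seg + seg // 2, "-"),
             (s + 5 * seg + seg // 2, s + 6 * seg, "+")),
            ((0, 40_000, 4 * seg, 4 * seg + 40_000, "-"),),
        ),
        # structure 4: two inverted blocks
        (
            ((s, s + seg, "+"), (s + seg, s + 2 * seg, "-"),
             (s + 2 * seg, s + 4 * seg, "+"), (s + 4 * seg, s + 5 * seg, "-"),
             (s + 5 * seg, s + 6 * seg, "+")),
            ((0, 30_000, 3 * seg, 3 * seg + 30_000, "-"),
             (seg, seg + 30_000, 5 * seg, 5 * seg + 30_000, "+")),
        ),
        # structure 5: large inversion covering two thirds of the ROI
        (
            ((s, s + seg, "+"), (s + seg, s + 5 * seg, "-"),
             (s + 5 * seg, s + 6 * seg, "+")),
            ((0, 60_000, 5 * seg + seg // 2, 5 * seg + seg // 2 + 60_000, "-"),),
        ),
    ]
    pops = ["AFR", "EUR", "EAS", "SAS", "AMR"]
    out = []
    for i in range(n_assemblies):
        segments, sd_pairs = plans[i % len(plans)]
        out.append(
            HaplotypePlan(
                assembly_id=f"ASM{i:02d}",
                segments=segments,
                sd_pairs=sd_pairs,
                superpopulation=pops[(i // len(plans) + i) % len(pops)],
            )
        )
    return out
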