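"""End-to-end orchestration and callset-level summary statistics."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .core import AnnotationTrack, GenomicInterval
from .genotyper import (
    Genotype,
    StrandCount,
    UndefinedAlleleFrequencyError,
    detect_misorientation,
    genotype_counts_table,
    inverted_allele_frequency,
)
from .haplostruct import (
    flank_analysis,
    group_haplotypes,
    paint_assembly,
    select_spanning_assemblies,
    synchronize_orientation,
)
from .minor_allele import (
    MinorAlleleCall,
    ReconciledLabel,
    Verdict,
    call_minor_allele,
    reconcile_with_misorientation,
    summarize_region,
)
from .pericentromere import (
    bonferroni,
    build_pericentromeric_regions,
    classify_pericentromeric,
    composition_breakdown,
    permutation_test,
    sd_pairs,
)
from .remap import NOVEL_CLASSES, NoveltyClass, RemapResult, RemapStatus, remap_interval
from .simulate import REF_A, REF_B, World

__all__ = [
    "CallsetSummary",
    "PipelineResult",
    "summarize_callset",
    "backgammon_table",
    "percent",
    "fold_change",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# Summary arithmetic
# ---------------------------------------------------------------------------

def percent(count: float, denominator: float) -> float:
    """100 * count / denominator; undefined (NaN) on a zero denominator."""
    return 100.0 * count / denominator if denominator else float("nan")


def fold_change(numerator: float, denominator: float) -> float:
    """Simple ratio; undefined (NaN) on a zero denominator."""
    return numerator / denominator if denominator else float("nan")


@dataclass
class CallsetSummary:
    """Headline arithmetic of a callset and its per-stage results."""

    n_total: int
    class_counts: dict[str, int]
    inverted_bases: dict[str, int]  # per reference, balanced inversions only
    novelty_counts: dict[str, int]
    n_novel: int
    novel_sensitivity_gain_pct: float
    n_pericentromeric: int
    pericentromeric_pct: float
    minor_allele_counts: dict[str, int]
    minor_allele_fold_reduction: float
    misorientation_counts: dict[str, int]

    def validate(self) -> None:
        if sum(self.class_counts.values()) != self.n_total:
            raise ValueError("variant-class counts must sum to callset size")
        if sum(self.novelty_counts.get(c.value, 0) for c in NOVEL_CLASSES) != self.n_novel:
            raise ValueError("novelty-category counts must sum to the novel total")


def summarize_callset(
    callset: pd.DataFrame,
    novelty: dict[str, NoveltyClass],
    pericentromeric: dict[str, bool],
    remaps: dict[str, RemapResult],
    minor_calls: list[MinorAlleleCall] | None = None,
    reconciled: dict[str, ReconciledLabel] | None = None,
    misorientations: dict[str, int] | None = None,
) -> CallsetSummary:
    """Aggregate one callset and its stage outputs into a summary.

    Invariant to row order. The balanced-inversion denominator is used for
    the novelty and pericentromeric percentages; inverted bases count each
    balanced inversion's span once per reference (source span for the native
    reference, remapped span for the other).
    """
    callset = callset.copy()
    class_counts = callset["variant_class"].value_counts().to_dict()
    balanced = callset[callset["variant_class"] == "BAL"]
    n_bal = len(balanced)

    bases_a = int((balanced["end"] - balanced["start"]).sum())
    bases_b = 0
    for rid in balanced["region_id"]:
        r = remaps.get(rid)
        if r is not None and r.status is RemapStatus.MAPPED:
            bases_b += r.mapped_interval.length()

    novelty_counts: dict[str, int] = {}
    for rid in balanced["region_id"]:
        cls = novelty.get(rid)
        if cls is not None:
            novelty_counts[cls.value] = novelty_counts.get(cls.value, 0) + 1
    n_novel = sum(novelty_counts.get(c.value, 0) for c in NOVEL_CLASSES)

    n_peri = sum(bool(pericentromeric.get(rid)) for rid in balanced["region_id"])

    minor_counts = {REF_A: 0, REF_B: 0}
    if minor_calls:
        for call in minor_calls:
            label = (reconciled or {}).get(call.region_id)
            if reconciled is not None and label is not ReconciledLabel.MINOR_ALLELE:
                continue
            if call.verdict is Verdict.MINOR_IN_REF_A:
                minor_counts[REF_A] += 1
            elif call.verdict is Verdict.MINOR_IN_REF_B:
                minor_counts[REF_B] += 1

    summary = CallsetSummary(
        n_total=len(callset),
        class_counts=class_counts,
        inverted_bases={REF_A: bases_a, REF_B: bases_b},
        novelty_counts=novelty_counts,
        n_novel=n_novel,
        novel_sensitivity_gain_pct=percent(n_novel, n_bal),
        n_pericentromeric=n_peri,
        pericentromeric_pct=percent(n_peri, n_bal),
        minor_allele_counts=minor_counts,
        minor_allele_fold_reduction=fold_change(
            minor_counts[REF_B], minor_counts[REF_A]
        ),
        misorientation_counts=misorientations or {},
    )
    summary.validate()
    return summary


def backgammon_table(
    matrices: dict[str, dict[str, dict[str, Genotype]]],
    regions: list[str],
    samples: list[str],
) -> pd.DataFrame:
    """Long-format haplotype x region orientation table (backgammon plot).

    Genotype-level input: a HET sample contributes one inverted and one
    direct haplotype row; NO_CALL contributes two missing rows. Per
    reference the row count is exactly ``2 * len(samples) * len(regions)``.
    """
    orient = {
        Genotype.HOM_DIRECT: ("direct", "direct"),
        Genotype.HET: ("inverted", "direct"),
        Genotype.HOM_INV: ("inverted", "inverted"),
        Genotype.NO_CALL: ("missing", "missing"),
    }
    rows = []
    for reference, matrix in matrices.items():
        for region in regions:
            column = matrix.get(region, {})
            for sample in samples:
                o1, o2 = orient[column.get(sample, Genotype.NO_CALL)]
                rows.append((reference, region, sample, 1, o1))
                rows.append((reference, region, sample, 2, o2))
    return pd.DataFrame(
        rows, columns=["reference", "region_id", "sample_id", "haplotype", "orientation"]
    )


# ---------------------------------------------------------------------------
# End-to-end pipeline on a simulated (or equivalently structured) world
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    genotypes: dict[str, dict[str, dict[str, Genotype]]]  # per reference
    frequencies: dict[str, dict[str, float]]  # per reference, NaN-free subset
    misoriented: dict[str, set[str]]  # per reference
    remaps: dict[str, RemapResult]
    novelty: dict[str, NoveltyClass]
    pericentromeric: dict[str, bool]
    permutation: pd.DataFrame
    composition: pd.DataFrame
    minor_calls: list[MinorAlleleCall]
    reconciled: dict[str, ReconciledLabel]
    haplogroups: dict[str, str] = field(default_factory=dict)
    haplogroup_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    flanks: list = field(default_factory=list)
    summary: CallsetSummary | None = None


def run_pipeline(
    world: World,
    n_perm: int = 1000,
    seed: int = 0,
    min_reads: int = 20,
    novelty_threshold: float = 0.90,
    reciprocal: bool = False,
) -> PipelineResult:
    """Run every stage on a world and assemble the summary.

    The world provides exactly what the real analysis consumes: per-sample
    strand count tables against both references, the inversion callset with
    source coordinates (reference A), PAF mappings of each inverted sequence
    onto reference B, the nonsyntenic mask, censat and SD annotation, and
    (optionally) assembly alignments over an ROI.
    """
    from .remap import classify_novelty

    # 1. genotype each reference
    genotypes = {}
    for ref in (REF_A, REF_B):
        table = world.counts[world.counts["reference_id"] == ref]
        genotypes[ref] = genotype_counts_table(table, min_reads=min_reads)

    frequencies: dict[str, dict[str, float]] = {}
    misoriented: dict[str, set[str]] = {}
    for ref, matrix in genotypes.items():
        freqs = {}
        flagged = set()
        for region, column in matrix.items():
            try:
                freqs[region] = inverted_allele_frequency(column)
            except UndefinedAlleleFrequencyError:
                pass
            if detect_misorientation(column):
                flagged.add(region)
        frequencies[ref] = freqs
        misoriented[ref] = flagged

    # 2. remap every inversion to reference B and classify novelty
    by_query: dict[str, list] = {}
    for rec in world.remap_paf:
        by_query.setdefault(rec.query_name, []).append(rec)
    remaps: dict[str, RemapResult] = {}
    novelty: dict[str, NoveltyClass] = {}
    for row in world.callset.itertuples(index=False):
        iv = GenomicInterval(row.chrom, row.start, row.end)
        result = remap_interval(
            iv, by_query.get(row.region_id, []), region_id=row.region_id
        )
        remaps[row.region_id] = result
        novelty[row.region_id] = classify_novelty(
            iv, result, world.truth.nonsyntenic,
            threshold=novelty_threshold, reciprocal=reciprocal,
        )

    # 3. pericentromeric classification, enrichment and composition
    regions = build_pericentromeric_regions(
        world.censat, world.config.chrom_lengths
    )
    callset_ivs = {
        row.region_id: GenomicInterval(row.chrom, row.start, row.end)
        for row in world.callset.itertuples(index=False)
    }
    flags = classify_pericentromeric(list(callset_ivs.values()), regions)
    pericent = dict(zip(callset_ivs.keys(), flags))

    perm_rows = []
    results = []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in callset_ivs.values():
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for i, (chrom, ivs) in enumerate(sorted(by_chrom.items())):
        results.append(
            permutation_test(
                ivs, regions, world.config.chrom_lengths[chrom],
                n_perm=n_perm, seed=seed + i,
            )
        )
    for r in bonferroni(results):
        perm_rows.append(
            (r.chrom, r.observed, float(r.null_counts.mean()), r.p_value,
             r.fold, r.p_adjusted)
        )
    permutation = pd.DataFrame(
        perm_rows,
        columns=["chrom", "observed", "null_mean", "p_value", "fold", "p_adjusted"],
    )

    pair_footprint: dict[str, list[GenomicInterval]] = {}
    for a, b in sd_pairs(world.sds):
        pair_footprint.setdefault(a.chrom, []).extend([a, b])
    comp_rows = []
    for rid, iv in callset_ivs.items():
        if not pericent[rid]:
            continue
        tracks = {
            label: [x for x, lab in world.censat.records
                    if lab == label and x.chrom == iv.chrom]
            for label in ("RDNA", "HSAT", "BSAT", "ASAT", "MON")
        }
        tracks["SD_PAIR"] = pair_footprint.get(iv.chrom, [])
        breakdown = composition_breakdown(iv, tracks, region_id=rid)
        comp_rows.append({"region_id": rid, **breakdown.bases})
    composition = pd.DataFrame(comp_rows)

    # 4. minor alleles between references
    minor_calls = []
    reconciled = {}
    pooled = (
        world.counts.groupby(["region_id", "reference_id"])[["watson", "crick"]]
        .sum()
        .reset_index()
    )
    for region in sorted(callset_ivs):
        summaries = {}
        for ref in (REF_A, REF_B):
            sel = pooled[
                (pooled["region_id"] == region) & (pooled["reference_id"] == ref)
            ]
            counts = [
                StrandCount("pooled", region, ref, int(r.watson), int(r.crick))
                for r in sel.itertuples(index=False)
            ]
            summaries[ref] = summarize_region(counts, min_reads=min_reads)
        call = call_minor_allele(summaries[REF_A], summaries[REF_B])
        minor_calls.append(call)
        minor_ref = {
            Verdict.MINOR_IN_REF_A: REF_A,
            Verdict.MINOR_IN_REF_B: REF_B,
        }.get(call.verdict)
        column = genotypes.get(minor_ref, {}).get(region) if minor_ref else None
        reconciled[region] = reconcile_with_misorientation(call, column)

    # 5. haplotype structure over the ROI, when the world has assemblies
    haplogroups: dict[str, str] = {}
    haplo_counts: dict[str, dict[str, int]] = {}
    flanks = []
    if world.assembly_paf and world.config.roi is not None:
        roi = world.config.roi
        assemblies = sorted({r.query_name for r in world.assembly_paf})
        paintings = [
            synchronize_orientation(paint_assembly(a, world.assembly_paf, roi))
            for a in assemblies
        ]
        paintings = select_spanning_assemblies(paintings, roi)
        pops = {p.assembly_id: p.superpopulation for p in world.config.haplotypes}
        haplogroups, haplo_counts = group_haplotypes(
            paintings, superpopulations=pops
        )
        for a in assemblies:
            own = [r for r in world.self_paf if r.query_name == a]
            flanks.append(flank_analysis(own, a))

    misorient_counts = {ref: len(m) for ref, m in misoriented.items()}
    summary = summarize_callset(
        world.callset, novelty, pericent, remaps,
        minor_calls=minor_calls, reconciled=reconciled,
        misorientations=misorient_counts,
    )
    return PipelineResult(
        genotypes=genotypes,
        frequencies=frequencies,
        misoriented=misoriented,
        remaps=remaps,
        novelty=novelty,
        pericentromeric=pericent,
        permutation=permutation,
        composition=composition,
        minor_calls=minor_calls,
        reconciled=reconciled,
        haplogroups=haplogroups,
        haplogroup_counts=haplo_counts,
        flanks=flanks,
        summary=summary,
    )
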