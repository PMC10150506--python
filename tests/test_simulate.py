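"""The synthetic two-reference world: determinism, sampling statistics and
plan consistency."""

import numpy as np
import pandas as pd
import pytest

from invlandscape.core import GenomicInterval
from invlandscape.genotyper import Genotype
from invlandscape.haplostruct import paint_assembly
from invlandscape.remap import NoveltyClass
from invlandscape.simulate import (
    REF_A,
    REF_B,
    HaplotypePlan,
    InversionPlan,
    SimulationConfig,
    simulate_genotypes,
    simulate_haplotype_alignments,
    simulate_strand_counts,
    simulate_world,
    study_config,
    write_world,
)

MB = 1_000_000


def tiny_config(**kw):
    base = dict(
        seed=5,
        chrom_lengths={"chr1": 10 * MB},
        satellites=[("chr1", 4 * MB, 5 * MB, "ASAT")],
        sds=[("chr1", 3 * MB, 3 * MB + 100_000)],
        inversions=[
            InversionPlan("inv1", "chr1", 1 * MB, 1 * MB + 100_000, 0.5),
            InversionPlan("inv2", "chr1", 6 * MB, 6 * MB + 50_000, 0.2),
        ],
        n_samples=10,
        coverage=50.0,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    def test_out_of_chromosome_span_rejected(self):
        cfg = tiny_config(
            inversions=[InversionPlan("x", "chr1", 9 * MB, 11 * MB, 0.5)]
        )
        with pytest.raises(ValueError, match="outside chr1"):
            simulate_world(cfg)

    def test_bad_frequency_rejected(self):
        cfg = tiny_config(inversions=[InversionPlan("x", "chr1", 0, MB, 1.5)])
        with pytest.raises(ValueError, match="allele_freq"):
            simulate_world(cfg)

    def test_duplicate_region_id_rejected(self):
        cfg = tiny_config(
            inversions=[
                InversionPlan("x", "chr1", 0, MB, 0.5),
                InversionPlan("x", "chr1", 2 * MB, 3 * MB, 0.5),
            ]
        )
        with pytest.raises(ValueError, match="duplicate"):
            simulate_world(cfg)

    def test_flipped_and_deleted_is_infeasible(self):
        cfg = tiny_config(
            inversions=[
                InversionPlan("x", "chr1", 0, MB, 0.5, misoriented_in_b=True,
                              novelty=NoveltyClass.NONSYNTENIC_FAILED)
            ]
        )
        with pytest.raises(ValueError, match="flipped and deleted"):
            simulate_world(cfg)

    def test_background_error_bounded(self):
        with pytest.raises(ValueError, match="background_error"):
            simulate_world(tiny_config(background_error=0.5))


class TestDeterminism:
    def test_same_seed_identical_world(self):
        w1 = simulate_world(tiny_config())
        w2 = simulate_world(tiny_config())
        pd.testing.assert_frame_equal(w1.counts, w2.counts)
        assert w1.remap_paf == w2.remap_paf
        assert w1.truth.genotypes == w2.truth.genotypes

    def test_different_seed_differs(self):
        w1 = simulate_world(tiny_config(seed=1))
        w2 = simulate_world(tiny_config(seed=2))
        assert not w1.counts.equals(w2.counts)

    def test_write_world_round_trip_is_plain_text(self, tmp_path):
        world = simulate_world(tiny_config())
        write_world(world, str(tmp_path))
        for name in ("refA.censat.bed", "counts.refA.tsv", "counts.refB.tsv",
                     "callset.tsv", "truth.json", "remap.paf"):
            assert (tmp_path / name).exists()
        counts = pd.read_csv(tmp_path / "counts.refA.tsv", sep="\t")
        assert len(counts) == 2 * 10  # regions x samples


class TestIdentityWorld:
    def test_empty_plans_make_references_agree(self):
        world = simulate_world(tiny_config())
        assert world.truth.misoriented_in_b == set()
        assert len(world.truth.nonsyntenic) == 0
        # pooled Crick fractions agree between references (same genotypes,
        # independent noise only)
        pooled = world.counts.groupby(["region_id", "reference_id"]).sum(
            numeric_only=True
        )
        for region in ("inv1", "inv2"):
            fa = pooled.loc[(region, REF_A)]
            fb = pooled.loc[(region, REF_B)]
            assert abs(
                fa.crick / (fa.crick + fa.watson)
                - fb.crick / (fb.crick + fb.watson)
            ) < 0.1

    def test_one_flipped_region_differs_only_there(self):
        cfg = tiny_config(
            inversions=[
                InversionPlan("keep", "chr1", 1 * MB, 1 * MB + 100_000, 0.0),
                InversionPlan("flip", "chr1", 6 * MB, 6 * MB + 50_000, 0.0,
                              misoriented_in_b=True),
            ]
        )
        world = simulate_world(cfg)
        assert world.truth.misoriented_in_b == {"flip"}
        pooled = world.counts.groupby(["region_id", "reference_id"]).sum(
            numeric_only=True
        )
        # f=0 population: direct against A everywhere; flipped region reads
        # go Watson against B
        assert pooled.loc[("flip", REF_A)].crick > pooled.loc[("flip", REF_A)].watson
        assert pooled.loc[("flip", REF_B)].watson > pooled.loc[("flip", REF_B)].crick
        assert pooled.loc[("keep", REF_B)].crick > pooled.loc[("keep", REF_B)].watson


class TestHardyWeinberg:
    def test_fixed_frequencies(self, rng):
        plans = [InversionPlan("a", "chr1", 0, MB, 1.0),
                 InversionPlan("b", "chr1", 0, MB, 0.0)]
        genos = simulate_genotypes(plans, 200, rng)
        assert set(genos["a"].values()) == {Genotype.HOM_INV}
        assert set(genos["b"].values()) == {Genotype.HOM_DIRECT}

    def test_het_fraction_at_half(self, rng):
        # f = 0.5: P(HET) = 0.5; with n = 10,000 the observed fraction sits
        # within 3 standard errors
        plans = [InversionPlan("a", "chr1", 0, MB, 0.5)]
        genos = simulate_genotypes(plans, 10_000, rng)
        het = sum(1 for g in genos["a"].values() if g is Genotype.HET) / 10_000
        se = np.sqrt(0.5 * 0.5 / 10_000)
        assert abs(het - 0.5) < 3 * se


class TestStrandCounts:
    def table(self, gt, e, coverage=1000, rng=None, flipped=frozenset()):
        genos = {"r": {f"s{i}": gt for i in range(50)}}
        return simulate_strand_counts(
            genos, coverage, e, rng or np.random.default_rng(0), REF_A,
            flipped=flipped,
        )

    def test_hom_direct_no_error_all_crick(self, rng):
        df = self.table(Genotype.HOM_DIRECT, 0.0, rng=rng)
        assert (df.watson == 0).all()

    def test_het_crick_fraction_half(self, rng):
        df = self.table(Genotype.HET, 0.02, rng=rng)
        frac = df.crick.sum() / (df.crick.sum() + df.watson.sum())
        n = df.crick.sum() + df.watson.sum()
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_hom_inv_crick_fraction_matches_error_rate(self, rng):
        df = self.table(Genotype.HOM_INV, 0.02, rng=rng)
        n = int(df.crick.sum() + df.watson.sum())
        frac = df.crick.sum() / n
        assert abs(frac - 0.02) < 3 * np.sqrt(0.02 * 0.98 / n)

    def test_flipped_region_mirrors_orientation(self, rng):
        df = self.table(Genotype.HOM_DIRECT, 0.0, rng=rng, flipped={"r"})
        assert (df.crick == 0).all()

    def test_depth_is_poisson_with_given_mean(self, rng):
        df = self.table(Genotype.HET, 0.0, coverage=50, rng=rng)
        totals = df.watson + df.crick
        assert abs(totals.mean() - 50) < 3 * np.sqrt(50 / len(totals))


class TestHaplotypeAlignments:
    def test_painting_reproduces_the_plan_signature(self):
        roi = GenomicInterval("chr1", 0, 300_000)
        plan = HaplotypePlan(
            "asm1",
            segments=((0, 100_000, "+"), (100_000, 200_000, "-"),
                      (200_000, 300_000, "+")),
        )
        to_ref, _ = simulate_haplotype_alignments([plan], "chr1", 10 * MB)
        painting = paint_assembly("asm1", to_ref, roi)
        assert painting.signature() == (
            ("+", 0, 10), ("-", 10, 20), ("+", 20, 30)
        )

    def test_single_inverted_segment_emits_one_minus_record(self):
        plan = HaplotypePlan("asm1", segments=((0, 50_000, "-"),))
        to_ref, _ = simulate_haplotype_alignments([plan], "chr1", 10 * MB)
        assert [r.strand for r in to_ref] == ["-"]

    def test_planted_sd_pair_qualifies_in_flank_analysis(self):
        from invlandscape.haplostruct import Risk, flank_analysis

        plan = HaplotypePlan(
            "asm1",
            segments=((0, 2 * MB, "+"),),
            sd_pairs=((0, 50_000, 650_000, 700_000, "+"),),
        )
        _, self_aln = simulate_haplotype_alignments([plan], "chr1", 10 * MB)
        fa = flank_analysis(self_aln, "asm1")
        assert fa.direct_bases == 100_000
        assert fa.risk is Risk.AT_RISK


class TestStudyWorld:
    def test_study_world_is_consistent(self):
        world = simulate_world(study_config(seed=3))
        cfg = world.config
        assert cfg.n_samples == 41
        assert len(world.truth.sample_ids) == 41
        # every planted nonsyntenic inversion is covered by the mask
        for inv in cfg.inversions:
            if inv.novelty in (NoveltyClass.NONSYNTENIC_MAPPED,
                               NoveltyClass.NONSYNTENIC_FAILED):
                from invlandscape.core import overlap_fraction

                assert overlap_fraction(
                    inv.interval(), world.truth.nonsyntenic
                ) >= 0.9
        # counts exist for both references except deleted regions
        by_ref = world.counts.groupby("reference_id")["region_id"].nunique()
        deleted = sum(
            1 for i in cfg.inversions
            if i.novelty is NoveltyClass.NONSYNTENIC_FAILED
        )
        assert by_ref[REF_A] == len(cfg.inversions)
        assert by_ref[REF_B] == len(cfg.inversions) - deleted
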