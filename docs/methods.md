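# Methods

## Coordinates and formats

All internal coordinates are 0-based half-open on named chromosomes, the
native convention of BED and PAF; 1-based inclusive coordinates exist only
at the presentation boundary (`from_one_based`/`to_one_based`). Chromosome
matching is exact string equality — no chr/non-chr aliasing is attempted,
so inputs must use one naming scheme consistently. Annotation class labels
form a closed vocabulary (HSAT, BSAT, ASAT, MON, RDNA, SD, NONSYNTENIC,
OTHER); unknown labels are rejected at parse time with the offending line
number rather than silently coerced.

Overlap between an interval and a track is defined on the **union** of
track bases (overlapping records are never double counted). Where a
reciprocal criterion is wanted, both directions are computed on the
intersecting records: the fraction of the interval covered, and the
fraction of the union of intersecting records covered. The novelty
classifier exposes both as a flag (`reciprocal=False` by default, i.e. the
one-way "percent overlap" reading); the two readings coincide except when a
small inversion sits inside a much larger nonsyntenic block, where the
reciprocal mode is stricter.

## Genotyping model

With Watson (minus-strand) count W and Crick (plus-strand) count C over a
strand-state-corrected region, and f = C/(W+C):

| condition                | call        |
|--------------------------|-------------|
| W + C < 20               | NO_CALL     |
| f ≥ 0.8                  | HOM_DIRECT  |
| W/(W+C) ≥ 0.8            | HOM_INV     |
| 0.35 ≤ f ≤ 0.65          | HET         |
| otherwise                | NO_CALL     |

The 20-read floor is the published evidence requirement; the band edges are
this package's choice (the original analysis delegates calling to prior
tooling). The gaps (0.2–0.35 and 0.65–0.8) are deliberate guard zones:
ambiguous strand fractions stay uncalled instead of being forced into a
genotype. Both homozygous tests are evaluated on their own fraction so the
band edges are exact in floating point (0.2 as W-fraction ≥ 0.8, not as
C-fraction ≤ 1−0.8).

Allele frequencies treat NO_CALL samples as missing data — excluded from
numerator and denominator — rather than as reference-orientation carriers.
**Genotype concordance is therefore reported over called genotypes**, with
the call rate reported alongside. This matters for interpretation: at
coverage 50 a true heterozygote leaves the 0.35–0.65 band ~3–4% of the time
by binomial noise alone and is (correctly) left uncalled, so call rate,
not concordance, is where depth limitations show up.

Misorientation detection requires every called genotype to be HOM_INV and,
by default, every sample in the column to be called (`min_called` defaults
to the column size). The default is deliberately strict — the definition of
a misorientation presumes genotypability across the whole panel — and can
be relaxed for panels with dropout.

## Remapping and novelty

Remapping consumes externally produced PAF (the intended aligner invocation
is minimap2 `-ax asm20 --secondary=no --eqx` on the extracted inverted
sequence; the package never shells out, keeping tests offline). The
pipeline is: drop mapq 0 and off-chromosome hits (the expected chromosome
is the source chromosome's homolog, identity-mapped by default); merge
target intervals whose end-to-start gap is ≤ 100 kbp (a gap of exactly
100,000 merges; 100,001 splits); pick the chain gathering the most aligned
bases (ties to the leftmost start — the published procedure is silent here,
so the tie-break is chosen to be deterministic); accept it if its length is
within [0.5, 1.5] of the original ("more than 50% larger or smaller" is
read strictly, so a ratio of exactly 1.5 passes).

Novelty is the cross of remap outcome × (nonsyntenic overlap ≥ 0.90):
SYNTENIC_MAPPED, NONSYNTENIC_MAPPED, FAILED_ONLY, NONSYNTENIC_FAILED. The
classes partition any callset; the putative-novel set is everything except
SYNTENIC_MAPPED.

## Pericentromeric enrichment

Pericentromeres are built from HSAT + alpha-satellite + rDNA seed records:
merged per chromosome (bookended merge, gap 0, configurable), padded by
1 Mbp per side, clipped to the chromosome, re-merged. Classification is ≥ 1
overlapping base pair (half-open abutment is not overlap).

The permutation test repositions each inversion independently and uniformly
on [0, chrom_size − length] at each of n_perm = 1,000 permutations;
randomized inversions may overlap each other (independent placement is the
simpler null and matches per-region randomization). The test is one-sided
for enrichment with the (k+1)/(n+1) empirical p-value convention, so p is
never 0 and never below 1/(n_perm+1). Identical seeds give bitwise-identical
null counts. Bonferroni correction multiplies by the number of chromosomes
tested, capped at 1. Fold is observed/mean(null); a zero null mean yields
+inf.

Base composition assigns every inverted base to exactly one class by a
configurable priority (default RDNA > HSAT > BSAT > ASAT > MON > SD_PAIR >
OTHER; the published figure does not state its precedence), so class bases
always sum exactly to the inversion length. SD pairs are intrachromosomal
SD records paired all-vs-all with inner distance ≤ 5 Mbp. The mutually
exclusive inversion-level association label takes the majority-base class
with ties resolved SD > satellite > other.

## Minor alleles

Counts are pooled across unrelated samples per region per reference; a
summary is callable at ≥ 20 pooled reads. The call compares Crick
fractions: fraction_difference = |f_A − f_B| on the absolute 0–1 scale
(fractions are already normalized, so "25% different" is read as 0.25
absolute). The published depth-comparability sentence is ambiguous about
its operand; it is implemented as the relative difference of pooled totals,
|t_A − t_B| / max(t_A, t_B) ≤ 0.25 — a guard against non-homologous
remapping inflating one reference's count. Precedence: uncallable → NO_CALL;
depth-inconsistent → NO_CALL; difference ≥ 0.25 → minor allele in the
reference with the smaller Crick fraction; otherwise CONCORDANT. Swapping
the references swaps the minor side and fixes the other verdicts
(antisymmetry is property-tested). A MINOR_* call whose region is
population-wide homozygously inverted on the minor reference is relabeled
MISORIENTATION.

## Haplotype structure

ROI projection clips alignment records on the target and cuts query spans
using the base-level CIGAR when present, otherwise by proportional
interpolation (a PAF record without CIGAR cannot be projected exactly; the
linear cut is the stated contract). Boundary convention: insertions at a
clip boundary are consumed before reporting the query position, which makes
the op-level walk agree with a per-base walk. Orientation is never changed
by clipping. Spanning selection keeps assemblies whose alignments reach
within 100 kbp (inclusive) of both ROI edges. Orientation synchronization
flips a painting — strands inverted, query coordinates mirrored — exactly
when its first and last ≥ 50 kbp segments are both minus; it is idempotent,
and a painting with no anchor segment is returned unchanged but flagged.

Haplogrouping uses exact equality of the binned signature (strand plus
target endpoints rounded to 10 kbp, absorbing small alignment jitter); the
published analysis grouped structures visually, and exact-signature
grouping is the deterministic surrogate. Labels are assigned H1, H2, … by
decreasing group size with signature order breaking ties, so grouping is
invariant to input order.

Self-alignment analysis excludes the identity diagonal, deduplicates
A↔B/B↔A mirror records, and keeps pairs whose **inner** distance (end of
left mate to start of right mate) is ≥ 500 kbp — "at least 500 kbp apart"
is not further specified in the source, and inner distance matches the
flanking usage; it is configurable. Direct/inverted base tallies sum both
mates' lengths. Risk: AT_RISK iff direct > inverted (+ optional margin,
default 0), PROTECTED iff inverted > direct, else AMBIGUOUS — including
the no-qualifying-pair case. The flanking-SD-pair selector additionally
requires inverted orientation and one mate strictly on each side of the
inversion, choosing the pair with the most aligned bases.

## Synthetic world

The generator is a pure function of its config (seed included): identical
configs give byte-identical outputs. Defaults mirror the study conditions:
41 diploid samples, coverage 50 expected reads per region, 2% strand error,
three 50-Mbp chromosomes with central satellite arrays, 20 inversions per
chromosome (log-uniform 10–500 kbp, inverted-allele frequencies uniform on
0.05–0.95, 30% planted pericentromeric), three misoriented reference-B
segments fixed direct in the population, eight polymorphic regions where
the references disagree in orientation, and one reference-A-only
pericentromeric block.

Genotypes are Hardy–Weinberg draws at the planned frequency; read depth per
sample × region is Poisson(coverage); each read reports Crick with
probability (1−e)·p + e·(1−p), where p ∈ {1, 0.5, 0} is the direct-dosage
fraction under the region's orientation in that reference. Reference B =
reference A with planned regions flipped (mirroring p) and
NONSYNTENIC_FAILED regions deleted. Deletions leave coordinate gaps rather
than shifting downstream features — a deliberate simplification keeping
truth bookkeeping exact; real assemblies would shift coordinates.
Alignment records (remap, assembly-to-reference, self-alignments) are
constructed analytically from the plan, never by running an aligner: clean
remaps come back at their own coordinates (sometimes split into two chained
pieces, with occasional mapq-0/off-chromosome decoys that filtering must
drop), FAILED_ONLY sites yield two short far-apart mappings no chain
survives, deleted sites yield nothing.

What the world does **not** emulate: sequence content (no FASTA), real
alignment noise and breakpoint micro-homology, single-cell strand states
(WW/WC/CC) and library QC, coordinate shifts from deletions, relatedness
between samples. Passing tests therefore demonstrate the correctness of the
decision rules and statistics under the stated noise model, not robustness
to aligner artifacts or strand-state miscorrection.

## Problem sizes and numerical choices

The validation suite runs at deliberately chosen desk scales: genotype
recovery on 40 samples × 200 regions; misorientation detection on 10
flipped + 50 polymorphic regions; permutation calibration on 100 replicate
worlds of 6 chromosomes × 20 inversions and power on 100 single-chromosome
worlds with 30% of 20 inversions planted in a 10% pericentromere (the
enrichment test is per chromosome, so the power property is assessed
without an extra Bonferroni factor over unplanted chromosomes); haplogroup
recovery on 20 assemblies from 5 planted structures. Population-scale
results (hundreds of inversions over 41 human genomes and two full
references) require the original sequencing data and assemblies and are out
of scope; the summary module instead verifies the arithmetic of such
callset statistics from their category counts.

Known limitations: the misorientation rule is vacuously strict for regions
with true allele frequency near 1 (a fixed inversion is indistinguishable
from a misorientation by design — the published definition has the same
property); the minor-allele depth-consistency metric is one of several
defensible readings of the source and is pluggable; haplogroup recovery by
exact signature will split haplotypes differing by alignment jitter larger
than the 10-kbp bin.
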