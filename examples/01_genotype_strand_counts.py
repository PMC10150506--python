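"""Genotype one region from Strand-seq Watson/Crick read counts.

Crick (plus-strand) reads come from directly oriented DNA, Watson
(minus-strand) reads from inverted DNA, so the Crick fraction of a region
encodes its diploid inversion genotype.
"""

from invlandscape import StrandCount, genotype_region, inverted_allele_frequency
from invlandscape.genotyper import detect_misorientation

samples = {
    "NA19240": (52, 1),    # Watson-only: both homologues inverted
    "HG00733": (25, 27),   # balanced: one homologue inverted
    "HG00512": (2, 48),    # Crick-only: direct on both homologues
    "NA12878": (8, 6),     # 14 reads < 20: too little evidence
}

column = {}
for sample, (watson, crick) in samples.items():
    counts = StrandCount(sample, "chr1-inv1", "T2T", watson, crick)
    column[sample] = genotype_region(counts)
    print(f"{sample}: W={watson:3d} C={crick:3d} -> {column[sample].value}")

freq = inverted_allele_frequency(column)
print(f"\ninverted allele frequency: {freq:.3f}")
print("  (2*HOM_INV + HET haplotypes over 2*called samples; NO_CALL excluded)")
print(f"misorientation: {detect_misorientation(column)}")
print("  (True only if every called sample were homozygously inverted,")
print("   i.e. the reference segment itself is flipped)")
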