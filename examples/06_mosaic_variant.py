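"""Mosaic (postzygotic) variant arithmetic from read counts.

A de novo variant found in 12 of 49 sequencing reads is well below the
~50% expected for a constitutive heterozygous variant, pointing to
postzygotic origin; under the heterozygous-carrier assumption the carrier
cell fraction is twice the allele fraction.
"""

from granulequant import VariantReadCounts, cell_fraction, vaf

counts = VariantReadCounts(alt_reads=12, total_reads=49, tissue="blood")
fraction, ci_low, ci_high = vaf(counts)

print(f"variant allele fraction: {100 * fraction:.1f}% "
      f"(Wilson 95% CI {100 * ci_low:.1f}-{100 * ci_high:.1f}%)")
print(f"carrier cell fraction (2 x VAF, heterozygous): {100 * cell_fraction(fraction):.1f}%")
# 24.5% of reads -> an estimated 49% of cells carry the variant; the CI
# spans roughly 15-38% of reads, i.e. 29-76% of cells.
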