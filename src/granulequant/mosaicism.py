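"""Postzygotic (mosaic) variant arithmetic from sequencing read counts.

The variant allele fraction (VAF) of a candidate mosaic variant is the
ratio of alternate-allele reads to total reads at the site, with a Wilson
score confidence interval (well behaved at small counts, unlike the Wald
interval).  Under the standard assumption that the variant is heterozygous
in every carrier cell, the fraction of cells carrying it is 2 x VAF,
capped at 1; a VAF above 0.5 is inconsistent with that assumption and
triggers a warning.
"""

from __future__ import annotations

import dataclasses
import warnings

from statsmodels.stats.proportion import proportion_confint

__all__ = ["VariantReadCounts", "vaf", "cell_fraction"]


@dataclasses.dataclass(frozen=True)
class VariantReadCounts:
    """Alternate / total read counts for one variant in one tissue."""

    alt_reads: int
    total_reads: int
    tissue: str = ""

    def __post_init__(self) -> None:
        if self.total_reads <= 0:
            raise ValueError("total_reads must be positive")
        if not 0 <= self.alt_reads <= self.total_reads:
            raise ValueError("need 0 <= alt_reads <= total_reads")


def vaf(counts: VariantReadCounts, ci_level: float = 0.95) -> tuple[float, float, float]:
    """Variant allele fraction with a Wilson score interval.

    Returns ``(fraction, ci_low, ci_high)``, all on the 0–1 scale.
    """
    fraction = counts.alt_reads / counts.total_reads
    ci_low, ci_high = proportion_confint(
        counts.alt_reads, counts.total_reads, alpha=1 - ci_level, method="wilson"
    )
    return float(fraction), float(ci_low), float(ci_high)


def cell_fraction(vaf_value: float, genotype_assumption: str = "heterozygous") -> float:
    """Fraction of cells carrying the variant, from its allele fraction.

    Only the heterozygous-carrier assumption is implemented: every carrier
    cell contributes one alternate and one reference allele, so the carrier
    cell fraction is ``2 x VAF`` (capped at 1).
    """
    if genotype_assumption != "heterozygous":
        raise ValueError(f"unknown genotype assumption: {genotype_assumption!r}")
    if not 0.0 <= vaf_value <= 1.0:
        raise ValueError("VAF must lie in [0, 1]")
    if vaf_value > 0.5:
        warnings.warn(
            "VAF above 0.5 is inconsistent with a heterozygous mosaic variant",
            stacklevel=2,
        )
    return min(2.0 * vaf_value, 1.0)
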