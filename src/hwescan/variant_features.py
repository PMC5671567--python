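"""Per-variant explanatory features for dissecting Hardy-Weinberg departures.

Five variables are computed for each variant: the fraction of missing
genotypes, the variant type (SNP vs indel), the overall minor allele
frequency, the cross-population standard deviation of allele frequencies
(MAF-SD, a surrogate for population substructure), and overlap with
copy-number loss/gain polymorphism intervals.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Optional

import numpy as np
from intervaltree import IntervalTree

from .hwe_core import allele_a_frequency
from .types import (
    GenomicInterval,
    IntervalKind,
    VariantFeatures,
    VariantRecord,
    VariantType,
    normalize_chrom,
)

_VALID_BASES = set("ACGT")


def classify_variant_type(ref: str, alt: str) -> VariantType:
    """SNP if both alleles are single bases, INDEL if lengths differ.

    Equal-length multi-base substitutions (MNPs) are neither and come back
    as ``OTHER``; they are excluded from SNP-vs-indel contrasts rather than
    silently binned.  Symbolic or empty alleles are rejected.
    """
    for allele in (ref, alt):
        if not allele or not set(allele.upper()) <= _VALID_BASES:
            raise ValueError(f"invalid or symbolic allele: {allele!r}")
    if len(ref) == 1 and len(alt) == 1:
        return VariantType.SNP
    if len(ref) != len(alt):
        return VariantType.INDEL
    return VariantType.OTHER


def missing_fraction(v: VariantRecord) -> float:
    """Fraction of the cohort with no genotype call: (N - called) / N."""
    total = v.cohort_n
    if total <= 0:
        raise ValueError("cohort size must be positive")
    called = v.pooled_counts().n_called
    if called > total:
        raise ValueError(
            f"called genotypes ({called}) exceed cohort size ({total})"
        )
    return (total - called) / total


def maf_sd(
    freqs: Mapping[str, float], included_pops: Optional[Iterable[str]] = None
) -> float:
    """Cross-population SD of the unfolded allele-A frequencies (divisor N).

    Returns NaN when fewer than two populations are included.  Folding the
    frequencies before taking the SD would conflate substructure with
    allele-label flips, so the unfolded frequencies are used.
    """
    pops = set(freqs) if included_pops is None else set(included_pops)
    vals = [freqs[p] for p in sorted(pops) if p in freqs]
    if len(vals) < 2:
        return math.nan
    return float(np.std(vals, ddof=0))


def build_interval_index(intervals: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    """Index CNV intervals per (normalized) chromosome for overlap queries."""
    index: dict[str, IntervalTree] = {}
    for iv in intervals:
        index.setdefault(normalize_chrom(iv.chrom), IntervalTree()).addi(
            iv.start, iv.end, iv
        )
    return index


def annotate_cnv_overlap(
    v: VariantRecord,
    intervals: Iterable[GenomicInterval] | dict[str, IntervalTree],
) -> tuple[bool, bool]:
    """(cnv_loss, cnv_gain): does the variant position fall in a LOSS / GAIN
    interval?  Point-in-interval on the 1-based anchor position (VCF POS),
    converted to the intervals' 0-based half-open convention; chromosome
    names are normalized (``chr17`` == ``17``).
    """
    index = (
        intervals
        if isinstance(intervals, dict)
        else build_interval_index(intervals)
    )
    tree = index.get(normalize_chrom(v.chrom))
    if tree is None:
        return False, False
    hits = [hit.data for hit in tree.at(v.pos - 1)]
    loss = any(iv.kind is IntervalKind.LOSS for iv in hits)
    gain = any(iv.kind is IntervalKind.GAIN for iv in hits)
    return loss, gain


def build_features(
    v: VariantRecord,
    intervals: Iterable[GenomicInterval] | dict[str, IntervalTree] = (),
    included_pops: Optional[Iterable[str]] = None,
) -> VariantFeatures:
    """Assemble the five explanatory variables for one variant.

    ``included_pops`` restricts the per-population frequencies entering
    MAF-SD (e.g. populations dropped by the population-specific MAF filter);
    the overall MAF is always computed from the pooled counts, folded to
    [0, 0.5].
    """
    freqs = {
        pop: allele_a_frequency(c)
        for pop, c in v.per_pop.items()
        if c.n_called > 0
    }
    pooled = v.pooled_counts()
    m = allele_a_frequency(pooled)
    loss, gain = annotate_cnv_overlap(v, intervals)
    return VariantFeatures(
        variant_id=v.variant_id,
        missing_fraction=missing_fraction(v),
        variant_type=classify_variant_type(v.ref, v.alt),
        maf_overall=min(m, 1.0 - m),
        allele_a_freq_per_pop=freqs,
        maf_sd=maf_sd(freqs, included_pops),
        cnv_loss=loss,
        cnv_gain=gain,
    )
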