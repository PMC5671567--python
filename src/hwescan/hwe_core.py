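"""Hardy-Weinberg goodness-of-fit testing and directional classification.

For a biallelic variant with called genotype counts (n_AA, n_AB, n_BB) the
allele-A frequency is estimated from the same counts,

    m = (2 n_AA + n_AB) / (2 n_called),

Hardy-Weinberg expected counts are (n m^2, 2 n m (1-m), n (1-m)^2) with
n = n_called, and the departure statistic is the 3-category chi-square
goodness of fit.  By default the p-value uses 2 degrees of freedom, for
which p = exp(-chi2/2) in closed form; pass ``dof=1`` for the conventional
test that subtracts the one estimated parameter.

The direction of a significant departure is read off the observed/expected
heterozygote ratio O/E = n_AB / (2 n m (1-m)): a deficit (O/E < 1) is a
loss of heterozygosity (LoH), an excess (O/E > 1) a gain (GoH).
"""

from __future__ import annotations

import math
from typing import Mapping

from scipy.stats import chi2 as _chi2_dist

from .types import (
    Classification,
    FilterDecision,
    GenotypeCounts,
    HWETestResult,
    RejectionReason,
    UntestableVariantError,
)

#: Default significance threshold for declaring a departure.
DEFAULT_ALPHA = 1e-5
#: Default degrees of freedom for the goodness-of-fit p-value.
DEFAULT_DOF = 2


def allele_a_frequency(counts: GenotypeCounts) -> float:
    """Estimate the allele-A frequency m from called genotype counts.

    Raises
    ------
    UntestableVariantError
        If the distribution has no called genotypes.
    """
    n = counts.n_called
    if n == 0:
        raise UntestableVariantError("no called genotypes; variant untestable")
    return (2 * counts.n_aa + counts.n_ab) / (2 * n)


def folded_maf(counts: GenotypeCounts) -> float:
    """Minor allele frequency, i.e. min(m, 1-m)."""
    m = allele_a_frequency(counts)
    return min(m, 1.0 - m)


def expected_genotype_counts(counts: GenotypeCounts) -> tuple[float, float, float]:
    """Hardy-Weinberg expected (AA, AB, BB) counts; they sum to n_called."""
    n = counts.n_called
    m = allele_a_frequency(counts)
    return (n * m * m, n * 2.0 * m * (1.0 - m), n * (1.0 - m) * (1.0 - m))


def oe_het_ratio(counts: GenotypeCounts) -> float:
    """Observed over HW-expected heterozygote count; NaN when expected is 0."""
    _, exp_ab, _ = expected_genotype_counts(counts)
    if exp_ab == 0.0:
        return math.nan
    return counts.n_ab / exp_ab


def hwe_test(counts: GenotypeCounts, dof: int = DEFAULT_DOF) -> HWETestResult:
    """Chi-square goodness-of-fit test of Hardy-Weinberg proportions.

    Returns an :class:`HWETestResult` with the classification left at
    ``NONE`` (use :func:`classify_departure` to label the direction).
    Monomorphic distributions (m in {0, 1}) are untestable and come back
    with NaN statistics and ``Classification.UNDEFINED``.
    """
    m = allele_a_frequency(counts)
    exp_aa, exp_ab, exp_bb = expected_genotype_counts(counts)
    if m == 0.0 or m == 1.0:
        return HWETestResult(
            allele_a_freq=m,
            expected_aa=exp_aa,
            expected_ab=exp_ab,
            expected_bb=exp_bb,
            chi2=math.nan,
            dof=dof,
            p_value=math.nan,
            oe_het_ratio=math.nan,
            classification=Classification.UNDEFINED,
        )
    chi2 = (
        (counts.n_aa - exp_aa) ** 2 / exp_aa
        + (counts.n_ab - exp_ab) ** 2 / exp_ab
        + (counts.n_bb - exp_bb) ** 2 / exp_bb
    )
    p = float(_chi2_dist.sf(chi2, dof))
    return HWETestResult(
        allele_a_freq=m,
        expected_aa=exp_aa,
        expected_ab=exp_ab,
        expected_bb=exp_bb,
        chi2=chi2,
        dof=dof,
        p_value=p,
        oe_het_ratio=counts.n_ab / exp_ab,
        classification=Classification.NONE,
    )


def classify_departure(
    result: HWETestResult, alpha: float = DEFAULT_ALPHA
) -> Classification:
    """Label a test result as NONE / LOH / GOH / UNDEFINED.

    A departure is significant when ``p < alpha``; its direction is the
    sign of O/E - 1.  A significant departure with O/E exactly 1 has no
    direction and is UNDEFINED, as are monomorphic (NaN) results.
    """
    if math.isnan(result.p_value) or math.isnan(result.oe_het_ratio):
        return Classification.UNDEFINED
    if result.p_value >= alpha:
        return Classification.NONE
    if result.oe_het_ratio < 1.0:
        return Classification.LOH
    if result.oe_het_ratio > 1.0:
        return Classification.GOH
    return Classification.UNDEFINED


def test_and_classify(
    counts: GenotypeCounts, alpha: float = DEFAULT_ALPHA, dof: int = DEFAULT_DOF
) -> HWETestResult:
    """Run :func:`hwe_test` and attach the directional classification."""
    res = hwe_test(counts, dof=dof)
    label = classify_departure(res, alpha=alpha)
    if label is res.classification:
        return res
    return HWETestResult(
        allele_a_freq=res.allele_a_freq,
        expected_aa=res.expected_aa,
        expected_ab=res.expected_ab,
        expected_bb=res.expected_bb,
        chi2=res.chi2,
        dof=res.dof,
        p_value=res.p_value,
        oe_het_ratio=res.oe_het_ratio,
        classification=label,
    )


def variant_filter(
    per_pop_counts: Mapping[str, GenotypeCounts],
    total_n: int,
    min_call_rate: float = 0.80,
    min_maf: float = 0.01,
    pop_min_maf: float = 0.001,
) -> tuple[FilterDecision, set[str]]:
    """Variant inclusion filter and per-population analysis set.

    A variant is excluded outright when its pooled call rate (called
    genotypes over ``total_n``) is below ``min_call_rate`` or its pooled
    folded MAF is below ``min_maf``.  An included variant is still dropped
    from any population whose own folded MAF is below ``pop_min_maf``
    (or that has no called genotypes).

    Strict re-analysis mode is simply ``min_call_rate=0.98``.

    Returns the :class:`FilterDecision` and the set of population labels
    to analyse (empty when excluded).
    """
    if not per_pop_counts:
        raise ValueError("per_pop_counts must contain at least one population")
    if total_n <= 0:
        raise ValueError("total_n must be positive")

    n_called = sum(c.n_called for c in per_pop_counts.values())
    reasons: list[RejectionReason] = []
    if n_called / total_n < min_call_rate:
        reasons.append(RejectionReason.LOW_CALL_RATE)
    pooled = GenotypeCounts(
        n_aa=sum(c.n_aa for c in per_pop_counts.values()),
        n_ab=sum(c.n_ab for c in per_pop_counts.values()),
        n_bb=sum(c.n_bb for c in per_pop_counts.values()),
    )
    if n_called == 0 or folded_maf(pooled) < min_maf:
        reasons.append(RejectionReason.LOW_MAF_OVERALL)
    if reasons:
        return FilterDecision(included=False, reasons=tuple(reasons)), set()

    analyse = {
        pop
        for pop, c in per_pop_counts.items()
        if c.n_called > 0 and folded_maf(c) >= pop_min_maf
    }
    return FilterDecision(included=True), analyse


def hwe_test_batch(counts: "np.ndarray", dof: int = DEFAULT_DOF):
    """Vectorized chi-square HWE test over an (n_reps, 3) array of
    (AA, AB, BB) counts.

    Returns ``(chi2, p, oe)`` arrays; rows that are monomorphic come back
    NaN.  Used for simulation-scale calibration; single-distribution
    analysis goes through :func:`hwe_test`.
    """
    import numpy as np

    c = np.asarray(counts, dtype=float)
    n = c.sum(axis=1)
    m = (2 * c[:, 0] + c[:, 1]) / (2 * n)
    poly = (m > 0) & (m < 1)
    exp = np.column_stack([n * m**2, n * 2 * m * (1 - m), n * (1 - m) ** 2])
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = ((c - exp) ** 2 / exp).sum(axis=1)
        oe = c[:, 1] / exp[:, 1]
    chi2[~poly] = np.nan
    oe[~poly] = np.nan
    p = _chi2_dist.sf(chi2, dof)
    return chi2, p, oe


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (report precision for p-values)."""
    if x == 0 or math.isnan(x) or math.isinf(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))
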