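"""Shared domain types.

The atomic observation throughout the package is one genotype-count
distribution: the numbers of A/A, A/B and B/B calls (plus missing calls)
for one biallelic variant in one population.  Everything else —
Hardy-Weinberg test results, variant records, feature vectors, intervals —
is built from that.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional


class Classification(str, Enum):
    """Directional label for a Hardy-Weinberg departure.

    ``LOH`` (loss of heterozygosity) means a significant departure with
    fewer heterozygotes than expected (O/E < 1); ``GOH`` (gain of
    heterozygosity) means a significant excess (O/E > 1).  ``NONE`` is a
    non-significant test; ``UNDEFINED`` covers monomorphic distributions
    and the degenerate significant case with O/E exactly 1.
    """

    NONE = "NONE"
    LOH = "LOH"
    GOH = "GOH"
    UNDEFINED = "UNDEFINED"


class UntestableVariantError(ValueError):
    """Raised when a genotype distribution has no called genotypes."""


@dataclass(frozen=True)
class GenotypeCounts:
    """Observed genotype counts for one variant in one population.

    Parameters
    ----------
    n_aa, n_ab, n_bb
        Counts of A/A homozygotes, heterozygotes and B/B homozygotes.
        Allele A is by convention the VCF REF allele (count tables must
        state their convention).
    n_missing
        Individuals with no genotype call at this site.
    """

    n_aa: int
    n_ab: int
    n_bb: int
    n_missing: int = 0

    def __post_init__(self) -> None:
        for name in ("n_aa", "n_ab", "n_bb", "n_missing"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                # numpy integer scalars are fine; coerce them
                if hasattr(v, "item") and float(v) == int(v):
                    object.__setattr__(self, name, int(v))
                    v = int(v)
                else:
                    raise TypeError(f"{name} must be an integer, got {v!r}")
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")

    @property
    def n_called(self) -> int:
        return self.n_aa + self.n_ab + self.n_bb

    @property
    def n_total(self) -> int:
        return self.n_called + self.n_missing


@dataclass(frozen=True)
class HWETestResult:
    """Result of the Hardy-Weinberg goodness-of-fit test for one distribution.

    ``p_value`` comes from the upper tail of a chi-square distribution with
    ``dof`` degrees of freedom (default 2, for which ``p = exp(-chi2/2)``).
    ``oe_het_ratio`` is the observed over HW-expected heterozygote count.
    Monomorphic inputs yield NaN statistics and ``Classification.UNDEFINED``.
    """

    allele_a_freq: float
    expected_aa: float
    expected_ab: float
    expected_bb: float
    chi2: float
    dof: int
    p_value: float
    oe_het_ratio: float
    classification: Classification = Classification.NONE

    @property
    def minus_log10_p(self) -> float:
        if math.isnan(self.p_value):
            return math.nan
        if self.p_value <= 0.0:
            return math.inf
        return -math.log10(self.p_value)


class RejectionReason(str, Enum):
    LOW_CALL_RATE = "LOW_CALL_RATE"
    LOW_MAF_OVERALL = "LOW_MAF_OVERALL"
    LOW_MAF_POPULATION = "LOW_MAF_POPULATION"


@dataclass(frozen=True)
class FilterDecision:
    """Outcome of the variant inclusion filter."""

    included: bool
    reasons: tuple[RejectionReason, ...] = ()

    def __post_init__(self) -> None:
        if self.included != (len(self.reasons) == 0):
            raise ValueError("included must be True iff reasons is empty")


class VariantType(str, Enum):
    SNP = "SNP"
    INDEL = "INDEL"
    OTHER = "OTHER"  # equal-length multi-base substitution (MNP)


class IntervalKind(str, Enum):
    LOSS = "LOSS"
    GAIN = "GAIN"


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix so ``chr17`` and ``17`` join."""
    c = str(chrom)
    return c[3:] if c.lower().startswith("chr") else c


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval, optionally a CNV loss/gain."""

    chrom: str
    start: int
    end: int
    kind: Optional[IntervalKind] = None
    frequency: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"start must be < end, got [{self.start}, {self.end})")

    def contains_pos(self, chrom: str, pos_1based: int) -> bool:
        """Point-in-interval on a 1-based variant anchor position."""
        if normalize_chrom(chrom) != normalize_chrom(self.chrom):
            return False
        return self.start <= pos_1based - 1 < self.end


@dataclass
class VariantRecord:
    """A biallelic variant with per-population genotype counts."""

    variant_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    per_pop: dict[str, GenotypeCounts] = field(default_factory=dict)
    total_n: Optional[int] = None

    def pooled_counts(self) -> GenotypeCounts:
        return GenotypeCounts(
            n_aa=sum(c.n_aa for c in self.per_pop.values()),
            n_ab=sum(c.n_ab for c in self.per_pop.values()),
            n_bb=sum(c.n_bb for c in self.per_pop.values()),
            n_missing=sum(c.n_missing for c in self.per_pop.values()),
        )

    @property
    def cohort_n(self) -> int:
        """Denominator for missingness: total_n if set, else summed n_total."""
        if self.total_n is not None:
            return self.total_n
        return self.pooled_counts().n_total


@dataclass(frozen=True)
class VariantFeatures:
    """The five per-variant explanatory variables used to dissect departures.

    All frequencies are on the fraction scale internally; the report layer
    multiplies missingness and MAF-SD by 100 for display.
    """

    variant_id: str
    missing_fraction: float
    variant_type: VariantType
    maf_overall: float
    allele_a_freq_per_pop: Mapping[str, float]
    maf_sd: float  # NaN when < 2 included populations
    cnv_loss: bool
    cnv_gain: bool
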