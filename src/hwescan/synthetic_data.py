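"""Genotype-count generators for each mechanism that distorts Hardy-Weinberg
proportions, with ground-truth labels.

Each generator draws the genotype distribution of ``n`` diploid individuals
at a biallelic locus and returns :class:`~hwescan.types.GenotypeCounts`.
Closed-form expectations for the heterozygote O/E ratio under each
mechanism (used by the tests) are:

============  =========================================  =================
mechanism     model                                       O/E heterozygotes
============  =========================================  =================
HWE           multinomial (p^2, 2pq, q^2)                 1
INBREEDING    excess homozygosity F                       1 - F
STRATIFIED    Wahlund mixture of K sub-populations        sum(w 2 p_k q_k) / (2 p_bar q_bar)
DELETION      hemizygotes called homozygous               (1-d)/(1+d)  [MISSING]
                                                          (1-d)^2      [FORCED_HOM]
PARALOG       collapsed paralogs, constitutive hets       2 (at het_fraction 1)
DROPOUT       per-allele call failure at rate e           enumeration (see tests)
============  =========================================  =================

Every generator reduces exactly to :func:`sim_hwe` when its distortion
parameter is zero, and all randomness flows from a single seeded
``numpy.random.Generator`` per call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .types import GenomicInterval, GenotypeCounts, IntervalKind, VariantRecord


class Mechanism(str, Enum):
    HWE = "HWE"
    INBREEDING = "INBREEDING"
    STRATIFIED = "STRATIFIED"
    DELETION = "DELETION"
    PARALOG = "PARALOG"
    DROPOUT = "DROPOUT"


class DeletionMode(str, Enum):
    #: homozygous-deletion carriers have no genotype call (exome-style data)
    MISSING = "MISSING"
    #: homozygous-deletion carriers are force-called homozygous
    #: (imputation/panel-style data where every sample gets a genotype)
    FORCED_HOM = "FORCED_HOM"


@dataclass(frozen=True)
class MechanismParams:
    """Ground-truth parameters attached to each simulated distribution."""

    mechanism: Mechanism
    n: int
    allele_a_freq: float = 0.5
    inbreeding_f: float = 0.0
    subpop_weights: tuple[float, ...] = ()
    subpop_freqs: tuple[float, ...] = ()
    deletion_freq: float = 0.0
    deletion_mode: DeletionMode = DeletionMode.MISSING
    dropout_rate: float = 0.0
    het_fraction: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0


@dataclass
class SimulatedCohort:
    """A set of simulated variants plus the truth table that generated them."""

    variants: list[VariantRecord]
    truth: dict[str, MechanismParams]
    layout: list[GenomicInterval] = field(default_factory=list)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _draw(rng: np.random.Generator, n: int, probs: Sequence[float]) -> GenotypeCounts:
    pvals = np.clip(np.array(list(probs) + [1.0 - sum(probs)]), 0.0, None)
    pvals /= pvals.sum()
    aa, ab, bb, miss = rng.multinomial(n, pvals)
    return GenotypeCounts(int(aa), int(ab), int(bb), int(miss))


def apply_missingness(
    counts: GenotypeCounts, missing_rate: float, seed
) -> GenotypeCounts:
    """Thin called genotypes: each call independently lost at ``missing_rate``."""
    if missing_rate == 0.0:
        return counts
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = _rng(seed)
    keep = [rng.binomial(c, 1.0 - missing_rate) for c in (counts.n_aa, counts.n_ab, counts.n_bb)]
    lost = counts.n_called - sum(keep)
    return GenotypeCounts(*map(int, keep), n_missing=counts.n_missing + int(lost))


def sim_hwe(n: int, p: float, seed) -> GenotypeCounts:
    """Multinomial draw of n genotypes at Hardy-Weinberg proportions."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    rng = _rng(seed)
    q = 1.0 - p
    return _draw(rng, n, (p * p, 2 * p * q, q * q))


def sim_hwe_batch(n_reps: int, n: int, p: float, seed) -> np.ndarray:
    """``n_reps`` independent HWE draws as an (n_reps, 3) count array."""
    rng = _rng(seed)
    q = 1.0 - p
    return rng.multinomial(n, (p * p, 2 * p * q, q * q), size=n_reps)


def sim_inbreeding(n: int, p: float, F: float, seed) -> GenotypeCounts:
    """Genotypes under inbreeding coefficient F: heterozygosity shrunk by 1-F."""
    if not 0.0 <= F <= 1.0:
        raise ValueError("F must be in [0, 1]")
    if F == 0.0:
        return sim_hwe(n, p, seed)
    rng = _rng(seed)
    q = 1.0 - p
    probs = (p * p + F * p * q, 2 * p * q * (1.0 - F), q * q + F * p * q)
    return _draw(rng, n, probs)


def sim_stratified(
    n: int, weights: Sequence[float], freqs: Sequence[float], seed
) -> GenotypeCounts:
    """Pooled genotypes from K sub-populations each in internal HWE.

    Pooling sub-populations with different allele frequencies produces the
    Wahlund heterozygote deficit sum(w 2 p_k q_k) / (2 p_bar q_bar).
    """
    if len(weights) != len(freqs) or len(weights) < 2:
        raise ValueError("need >= 2 sub-populations with matching weights")
    if not math.isclose(sum(weights), 1.0, abs_tol=1e-9):
        raise ValueError("weights must sum to 1")
    rng = _rng(seed)
    probs = [0.0, 0.0, 0.0]
    for w, pk in zip(weights, freqs):
        qk = 1.0 - pk
        probs[0] += w * pk * pk
        probs[1] += w * 2 * pk * qk
        probs[2] += w * qk * qk
    return _draw(rng, n, probs)


def sim_deletion_overlay(
    n: int,
    p: float,
    d: float,
    delmode: DeletionMode = DeletionMode.MISSING,
    seed=None,
) -> GenotypeCounts:
    """A SNP inside a deletion polymorphism at deletion-allele frequency d.

    Individuals carrying one deleted chromosome are hemizygous and get
    called homozygous for the surviving allele.  Homozygous-deletion
    carriers are missing (``MISSING``) or force-called homozygous for an
    allele drawn at frequency p (``FORCED_HOM``).  The deletion and SNP
    alleles are drawn independently.
    """
    if not 0.0 <= d < 1.0:
        raise ValueError("d must be in [0, 1)")
    if d == 0.0:
        return sim_hwe(n, p, seed)
    rng = _rng(seed)
    q = 1.0 - p
    dq = 1.0 - d
    # deletion genotype: +/+ (dq^2), del/+ (2 d dq), del/del (d^2)
    p_aa = dq * dq * p * p + 2 * d * dq * p
    p_ab = dq * dq * 2 * p * q
    p_bb = dq * dq * q * q + 2 * d * dq * q
    if delmode is DeletionMode.MISSING:
        return _draw(rng, n, (p_aa, p_ab, p_bb))  # remainder d^2 -> missing
    p_aa += d * d * p
    p_bb += d * d * q
    return _draw(rng, n, (p_aa, p_ab, p_bb))


def sim_paralog_collapse(n: int, het_fraction: float = 1.0, seed=None) -> GenotypeCounts:
    """Two collapsed diverged paralog copies genotyped as one locus.

    Paralogous sequence differences make each affected individual appear
    constitutively heterozygous: ``het_fraction`` of individuals are called
    A/B regardless of genotype, the remainder drawn HWE at p = 0.5.
    """
    if not 0.0 <= het_fraction <= 1.0:
        raise ValueError("het_fraction must be in [0, 1]")
    if het_fraction == 0.0:
        return sim_hwe(n, 0.5, seed)
    rng = _rng(seed)
    probs = (
        (1 - het_fraction) * 0.25,
        het_fraction + (1 - het_fraction) * 0.5,
        (1 - het_fraction) * 0.25,
    )
    return _draw(rng, n, probs)


def dropout_call_probs(p: float, e: float) -> tuple[float, float, float, float]:
    """Exact per-individual call probabilities (AA, AB, BB, missing) for a
    true-HWE locus at frequency p with per-allele dropout rate e.

    Each allele of a genotype independently fails at rate e.  A heterozygote
    with one surviving allele is called homozygous for it; with none,
    missing.  A homozygote is missing only when both alleles fail.
    """
    q = 1.0 - p
    ok = 1.0 - e
    het = 2 * p * q
    return (
        p * p * (1 - e * e) + het * e * ok,      # called AA
        het * ok * ok,                            # called AB
        q * q * (1 - e * e) + het * e * ok,      # called BB
        (p * p + q * q) * e * e + het * e * e,   # missing
    )


def sim_allelic_dropout(
    n: Optional[int] = None,
    p: Optional[float] = None,
    e: float = 0.0,
    seed=None,
    counts: Optional[GenotypeCounts] = None,
) -> GenotypeCounts:
    """Genotype calls after per-allele dropout at rate e.

    Either simulate a true-HWE locus (give ``n`` and ``p``) or degrade an
    existing observed distribution (give ``counts``); in the latter case
    dropout is applied to each called genotype of ``counts``.
    """
    if not 0.0 <= e <= 1.0:
        raise ValueError("e must be in [0, 1]")
    rng = _rng(seed)
    if counts is None:
        if n is None or p is None:
            raise ValueError("give either counts or both n and p")
        if e == 0.0:
            return sim_hwe(n, p, seed)
        return _draw(rng, n, dropout_call_probs(p, e)[:3])
    if e == 0.0:
        return counts
    ok = 1.0 - e
    # homozygotes: missing iff both alleles fail
    aa = int(rng.binomial(counts.n_aa, 1 - e * e))
    bb = int(rng.binomial(counts.n_bb, 1 - e * e))
    # heterozygotes: both survive / one survives (-> either hom) / none
    het_fates = rng.multinomial(counts.n_ab, [ok * ok, e * ok, e * ok, e * e])
    ab = int(het_fates[0])
    aa += int(het_fates[1])
    bb += int(het_fates[2])
    missing = counts.n_total - aa - ab - bb
    return GenotypeCounts(aa, ab, bb, int(missing))


def simulate_counts(params: MechanismParams) -> GenotypeCounts:
    """Dispatch on the mechanism, then overlay uniform missingness."""
    m, seed = params.mechanism, params.seed
    if m is Mechanism.HWE:
        c = sim_hwe(params.n, params.allele_a_freq, seed)
    elif m is Mechanism.INBREEDING:
        c = sim_inbreeding(params.n, params.allele_a_freq, params.inbreeding_f, seed)
    elif m is Mechanism.STRATIFIED:
        c = sim_stratified(params.n, params.subpop_weights, params.subpop_freqs, seed)
    elif m is Mechanism.DELETION:
        c = sim_deletion_overlay(
            params.n, params.allele_a_freq, params.deletion_freq,
            params.deletion_mode, seed,
        )
    elif m is Mechanism.PARALOG:
        c = sim_paralog_collapse(params.n, params.het_fraction, seed)
    elif m is Mechanism.DROPOUT:
        c = sim_allelic_dropout(
            n=params.n, p=params.allele_a_freq, e=params.dropout_rate, seed=seed
        )
    else:  # pragma: no cover
        raise ValueError(f"unknown mechanism {m}")
    if params.missing_rate:
        c = apply_missingness(c, params.missing_rate, int(seed) + 1)
    return c


# --------------------------------------------------------------------------
# region-scale simulation

_BASES = "ACGT"


def sim_region(
    layout: Sequence[tuple],
    n: int = 5000,
    n_variants: int = 500,
    chrom: str = "1",
    region_start: int = 1,
    region_end: int = 1_000_000,
    background_p_range: tuple[float, float] = (0.1, 0.9),
    seed: int = 0,
) -> SimulatedCohort:
    """A genomic region of SNPs with mechanism intervals overlaid.

    ``layout`` entries are ``(interval, params)`` or
    ``(interval, params, n_forced)``; with ``n_forced`` that many variant
    positions are guaranteed inside the interval (e.g. a dense run of
    paralog-collapsed sites in a short segment).  All ``n_variants``
    positions (forced plus uniform fill) are unique; a variant falling
    inside a layout interval is generated under that interval's mechanism
    (same sample size n), otherwise under HWE at an allele frequency drawn
    uniformly from ``background_p_range``.  Returns a single-population
    cohort labelled ``POP`` with its truth table; the layout intervals are
    carried along for downstream annotation.

    Layout intervals must not overlap.
    """
    entries = [(e[0], e[1], e[2] if len(e) > 2 else 0) for e in layout]
    ivs = [iv for iv, _, _ in entries]
    for i, a in enumerate(ivs):
        for b in ivs[i + 1 :]:
            if a.chrom == b.chrom and a.start < b.end and b.start < a.end:
                raise ValueError("layout intervals must not overlap")
    rng = np.random.default_rng(seed)
    forced: list[np.ndarray] = []
    for iv, _, n_forced in entries:
        if n_forced:
            lo = max(region_start, iv.start + 1)  # 1-based positions in interval
            hi = min(region_end, iv.end)
            forced.append(
                rng.choice(np.arange(lo, hi + 1), size=n_forced, replace=False)
            )
    forced_pos = (
        np.concatenate(forced) if forced else np.array([], dtype=int)
    )
    n_fill = n_variants - len(forced_pos)
    if n_fill < 0:
        raise ValueError("forced variants exceed n_variants")
    pool = np.setdiff1d(np.arange(region_start, region_end), forced_pos)
    positions = np.sort(
        np.concatenate([forced_pos, rng.choice(pool, size=n_fill, replace=False)])
    )
    layout = [(iv, params) for iv, params, _ in entries]
    variants: list[VariantRecord] = []
    truth: dict[str, MechanismParams] = {}
    for i, pos in enumerate(positions):
        pos = int(pos)
        vid = f"sim{i:05d}"
        params = None
        for iv, mech in layout:
            if iv.contains_pos(chrom, pos):
                params = MechanismParams(
                    **{**mech.__dict__, "n": n, "seed": int(rng.integers(2**31))}
                )
                break
        if params is None:
            params = MechanismParams(
                mechanism=Mechanism.HWE,
                n=n,
                allele_a_freq=float(rng.uniform(*background_p_range)),
                seed=int(rng.integers(2**31)),
            )
        counts = simulate_counts(params)
        ref, alt = rng.choice(list(_BASES), size=2, replace=False)
        variants.append(
            VariantRecord(
                variant_id=vid,
                chrom=chrom,
                pos=pos,
                ref=str(ref),
                alt=str(alt),
                per_pop={"POP": counts},
                total_n=n,
            )
        )
        truth[vid] = params
    return SimulatedCohort(variants=variants, truth=truth, layout=list(ivs))


def sim_multi_population_cohort(
    n_variants: int = 60,
    populations: Sequence[str] = ("AFR", "AMR", "EAS", "FIN", "NFE", "SAS"),
    n_per_pop: int = 2000,
    loh_fraction: float = 0.1,
    goh_fraction: float = 0.1,
    goh_missing_rate: float = 0.15,
    stratified_spread: float = 0.3,
    het_fraction: float = 0.8,
    seed: int = 0,
) -> SimulatedCohort:
    """A multi-population count-table cohort with labelled mechanisms.

    Emulates an exome-style extract: most variants in HWE in every
    population; a ``loh_fraction`` generated under hidden two-way
    stratification (sub-population frequencies p +/- ``stratified_spread``,
    Wahlund heterozygote deficit, clean genotyping); a ``goh_fraction``
    under paralog collapse with ``goh_missing_rate`` extra missingness
    (spurious heterozygosity correlated with low genotyping rate — the
    genotyping-error signature).  GoH variants carry indel REF/ALT alleles
    so variant-type contrasts have signal, mirroring the association
    between indel calls and spurious heterozygosity.
    """
    rng = np.random.default_rng(seed)
    n_loh = int(round(n_variants * loh_fraction))
    n_goh = int(round(n_variants * goh_fraction))
    variants: list[VariantRecord] = []
    truth: dict[str, MechanismParams] = {}
    total_n = n_per_pop * len(populations)
    for i in range(n_variants):
        vid = f"var{i:05d}"
        p = float(rng.uniform(0.15, 0.85))
        if i < n_loh:
            mech, ref, alt = Mechanism.STRATIFIED, "A", "G"
        elif i < n_loh + n_goh:
            mech, ref, alt = Mechanism.PARALOG, "A", "AT"
        else:
            mech, ref, alt = Mechanism.HWE, "A", "G"
        subpop_freqs = (
            max(0.02, p - stratified_spread),
            min(0.98, p + stratified_spread),
        )
        per_pop = {}
        for pop in populations:
            params = MechanismParams(
                mechanism=mech,
                n=n_per_pop,
                allele_a_freq=p,
                subpop_weights=(0.5, 0.5) if mech is Mechanism.STRATIFIED else (),
                subpop_freqs=subpop_freqs if mech is Mechanism.STRATIFIED else (),
                het_fraction=het_fraction if mech is Mechanism.PARALOG else 0.0,
                missing_rate=goh_missing_rate if mech is Mechanism.PARALOG else 0.0,
                seed=int(rng.integers(2**31)),
            )
            per_pop[pop] = simulate_counts(params)
        variants.append(
            VariantRecord(
                variant_id=vid,
                chrom="1",
                pos=1000 + i * 1000,
                ref=ref,
                alt=alt,
                per_pop=per_pop,
                total_n=total_n,
            )
        )
        truth[vid] = MechanismParams(
            mechanism=mech, n=n_per_pop, allele_a_freq=p, seed=seed
        )
    return SimulatedCohort(variants=variants, truth=truth)
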