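"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written on a different arithmetic path
from the package: exact rational arithmetic for the chi-square statistic,
combinatorial enumeration for the Mann-Whitney and Fisher tests.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction


def chi2_exact(n_aa: int, n_ab: int, n_bb: int) -> Fraction:
    """HWE goodness-of-fit chi-square as an exact rational number."""
    n = n_aa + n_ab + n_bb
    m = Fraction(2 * n_aa + n_ab, 2 * n)
    exp = (n * m * m, n * 2 * m * (1 - m), n * (1 - m) * (1 - m))
    obs = (n_aa, n_ab, n_bb)
    return sum(Fraction((o - e) ** 2) / e for o, e in zip(obs, exp))


def mannwhitney_exact_p(x: list[float], y: list[float]) -> float:
    """Two-sided exact Mann-Whitney p by enumerating all group assignments.

    Requires tie-free pooled data.  p = fraction of assignments whose U is
    at least as extreme (min(U, n1*n2 - U) <= observed) as the observed one.
    """
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires no ties"
    n1 = len(x)

    def u_of(group: tuple[float, ...]) -> int:
        other = [v for v in pooled if v not in group]
        return sum(1 for a in group for b in other if a > b)

    u_obs = u_of(tuple(x))
    n_total = n1 * len(y)
    stat_obs = min(u_obs, n_total - u_obs)
    hits = 0
    total = 0
    for combo in itertools.combinations(pooled, n1):
        u = u_of(combo)
        if min(u, n_total - u) <= stat_obs:
            hits += 1
        total += 1
    return hits / total


def fisher_exact_p(table: list[list[int]]) -> float:
    """Two-sided Fisher p by hypergeometric enumeration over the margin."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(k: int) -> Fraction:
        return Fraction(
            math.comb(r1, k) * math.comb(r2, c1 - k), math.comb(n, c1)
        )

    p_obs = prob(a)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        if prob(k) <= p_obs:
            total += prob(k)
    return float(total)


def dropout_call_probs_oracle(p: float, e: float) -> tuple[float, float, float, float]:
    """Enumerate every (true genotype, per-allele fate) combination."""
    out = [0.0, 0.0, 0.0, 0.0]  # AA, AB, BB, missing
    genotypes = {("A", "A"): p * p, ("A", "B"): 2 * p * (1 - p), ("B", "B"): (1 - p) ** 2}
    for (a1, a2), gp in genotypes.items():
        for f1 in (True, False):  # True = allele observed
            for f2 in (True, False):
                fp = (1 - e if f1 else e) * (1 - e if f2 else e)
                seen = [al for al, ok in ((a1, f1), (a2, f2)) if ok]
                if not seen:
                    out[3] += gp * fp
                elif set(seen) == {"A", "B"}:
                    out[1] += gp * fp
                elif set(seen) == {"A"}:
                    out[0] += gp * fp
                else:
                    out[2] += gp * fp
    return tuple(out)
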