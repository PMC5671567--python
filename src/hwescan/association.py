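"""Group comparisons between departing and in-HWE genotype distributions.

The unit of analysis is one variant x population genotype distribution.
Distributions classified LoH or GoH are each compared against the in-HWE
controls, feature by feature: continuous features (missingness, MAF,
MAF-SD) by two-sided Mann-Whitney, categorical features (indel type,
CNV-loss, CNV-gain) by Pearson chi-square on the 2x2 table (Fisher's exact
test when expected cells are small), and the distribution of departure
counts across populations by a 2xK chi-square heterogeneity test.

Variant-level features (type, MAF-SD, CNV flags) are replicated across a
variant's populations, which induces pseudo-replication; the report is
descriptive QC, not inference about independent observations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import Classification


class TestKind(str, Enum):
    MANN_WHITNEY = "MANN_WHITNEY"
    CHI2 = "CHI2"
    FISHER = "FISHER"


@dataclass(frozen=True)
class GroupSummary:
    """Summary of one feature in one group: median/IQR or count/percent."""

    group: str
    n: int
    median: Optional[float] = None
    iqr: Optional[float] = None
    count: Optional[int] = None
    percent: Optional[float] = None


@dataclass(frozen=True)
class FeatureComparison:
    feature: str
    control: GroupSummary
    departure: GroupSummary
    test: TestKind
    statistic: float
    p_value: float


def _summarize_continuous(label: str, values: Sequence[float]) -> GroupSummary:
    arr = np.asarray(values, dtype=float)
    q75, q25 = np.percentile(arr, [75, 25])
    return GroupSummary(
        group=label, n=len(arr), median=float(np.median(arr)), iqr=float(q75 - q25)
    )


#: group size above which the Mann-Whitney switches to the tie-corrected
#: normal approximation
EXACT_MW_MAX_N = 20


def compare_continuous(
    group_values: Sequence[float],
    control_values: Sequence[float],
    feature: str = "",
    group_label: str = "departure",
) -> FeatureComparison:
    """Two-sided Mann-Whitney U of a departure group against controls.

    Exact enumeration when both groups have at most 20 values and there
    are no ties; the tie-corrected normal approximation otherwise.
    """
    if len(group_values) == 0 or len(control_values) == 0:
        raise ValueError("both groups must be non-empty")
    g = np.asarray(group_values, dtype=float)
    c = np.asarray(control_values, dtype=float)
    pooled = np.concatenate([g, c])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = (
        "exact"
        if (len(g) <= EXACT_MW_MAX_N and len(c) <= EXACT_MW_MAX_N and no_ties)
        else "asymptotic"
    )
    res = stats.mannwhitneyu(g, c, alternative="two-sided", method=method)
    return FeatureComparison(
        feature=feature,
        control=_summarize_continuous("control", c),
        departure=_summarize_continuous(group_label, g),
        test=TestKind.MANN_WHITNEY,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )


def compare_categorical(
    table: Sequence[Sequence[int]],
    min_expected_for_chi2: float = 5.0,
    feature: str = "",
    group_label: str = "departure",
) -> FeatureComparison:
    """Pearson chi-square (no continuity correction) or Fisher's exact test
    on a 2x2 table ``[[departure_yes, departure_no], [control_yes, control_no]]``.

    Fisher is used when any expected cell falls below
    ``min_expected_for_chi2``.  A zero margin makes the table uninformative:
    p = 1 with a warning.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative counts")
    dep_n, ctrl_n = int(t[0].sum()), int(t[1].sum())

    def summary(label: str, row: np.ndarray) -> GroupSummary:
        n = int(row.sum())
        cnt = int(row[0])
        return GroupSummary(
            group=label,
            n=n,
            count=cnt,
            percent=100.0 * cnt / n if n else math.nan,
        )

    dep_sum = summary(group_label, t[0])
    ctrl_sum = summary("control", t[1])

    if 0 in t.sum(axis=0) or 0 in t.sum(axis=1):
        warnings.warn("degenerate 2x2 table (zero margin); p set to 1")
        return FeatureComparison(
            feature, ctrl_sum, dep_sum, TestKind.CHI2, 0.0, 1.0
        )

    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    if (expected >= min_expected_for_chi2).all():
        chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
        return FeatureComparison(
            feature, ctrl_sum, dep_sum, TestKind.CHI2, float(chi2), float(p)
        )
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return FeatureComparison(
        feature, ctrl_sum, dep_sum, TestKind.FISHER, float(odds), float(p)
    )


def population_heterogeneity(
    departure_counts: Mapping[str, int],
    control_counts: Mapping[str, int],
    feature: str = "heterogeneity",
    group_label: str = "departure",
) -> FeatureComparison:
    """Chi-square heterogeneity of departure counts across populations.

    Tests the 2xK contingency table (departure vs control, by population)
    with K-1 degrees of freedom.  Both maps must cover the same set of
    at least two populations.
    """
    if set(departure_counts) != set(control_counts):
        raise ValueError("departure and control maps must cover the same populations")
    pops = sorted(departure_counts)
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    table = np.array(
        [[departure_counts[p] for p in pops], [control_counts[p] for p in pops]],
        dtype=int,
    )
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    dep_n = int(table[0].sum())
    ctrl_n = int(table[1].sum())
    return FeatureComparison(
        feature=feature,
        control=GroupSummary(group="control", n=ctrl_n),
        departure=GroupSummary(group=group_label, n=dep_n),
        test=TestKind.CHI2,
        statistic=float(chi2),
        p_value=float(p),
    )


# --------------------------------------------------------------------------
# full report

_CONTINUOUS = [
    ("missing_pct", "Missing genotypes (%)"),
    ("maf_overall", "MAF"),
    ("maf_sd_pct", "MAF-SD between populations (%)"),
]
_CATEGORICAL = [
    ("is_indel", "Insertion/deletion type"),
    ("cnv_loss", "CNV-loss"),
    ("cnv_gain", "CNV-gain"),
]


def build_association_report(results: pd.DataFrame) -> pd.DataFrame:
    """Compare LoH and GoH distributions against in-HWE controls on each feature.

    ``results`` has one row per variant x population with columns
    ``classification``, ``population``, ``missing_fraction``,
    ``variant_type``, ``maf_overall``, ``maf_sd``, ``cnv_loss``,
    ``cnv_gain``.  Display scales follow the field's reporting convention:
    missingness and MAF-SD as percent, MAF as a fraction.

    Returns a long-format table with one row per (departure class, feature):
    control and departure summaries, test kind, statistic and p-value.
    An empty departure class is skipped with a warning.
    """
    df = results.copy()
    df["missing_pct"] = 100.0 * df["missing_fraction"].astype(float)
    df["maf_sd_pct"] = 100.0 * df["maf_sd"].astype(float)
    df["is_indel"] = df["variant_type"].astype(str) == "INDEL"
    controls = df[df["classification"].astype(str) == Classification.NONE.value]
    if controls.empty:
        raise ValueError("no in-HWE control distributions to compare against")

    rows: list[dict] = []
    for label in (Classification.LOH.value, Classification.GOH.value):
        dep = df[df["classification"].astype(str) == label]
        if dep.empty:
            warnings.warn(f"no {label} distributions; comparisons skipped")
            continue
        for col, name in _CONTINUOUS:
            dvals = dep[col].dropna()
            cvals = controls[col].dropna()
            if dvals.empty or cvals.empty:
                continue
            cmp_ = compare_continuous(dvals, cvals, feature=name, group_label=label)
            rows.append(_comparison_row(label, cmp_))
        for col, name in _CATEGORICAL:
            table = [
                [int(dep[col].sum()), int((~dep[col].astype(bool)).sum())],
                [int(controls[col].sum()), int((~controls[col].astype(bool)).sum())],
            ]
            cmp_ = compare_categorical(table, feature=name, group_label=label)
            rows.append(_comparison_row(label, cmp_))
        dep_by_pop = dep.groupby("population").size().to_dict()
        ctrl_by_pop = controls.groupby("population").size().to_dict()
        all_pops = sorted(set(dep_by_pop) | set(ctrl_by_pop))
        if len(all_pops) >= 2:
            cmp_ = population_heterogeneity(
                {p: dep_by_pop.get(p, 0) for p in all_pops},
                {p: ctrl_by_pop.get(p, 0) for p in all_pops},
                feature="Heterogeneity across populations",
                group_label=label,
            )
            rows.append(_comparison_row(label, cmp_))
    return pd.DataFrame(rows)


def _comparison_row(label: str, cmp_: FeatureComparison) -> dict:
    return {
        "departure_class": label,
        "feature": cmp_.feature,
        "control_n": cmp_.control.n,
        "control_median": cmp_.control.median,
        "control_iqr": cmp_.control.iqr,
        "control_count": cmp_.control.count,
        "control_percent": cmp_.control.percent,
        "departure_n": cmp_.departure.n,
        "departure_median": cmp_.departure.median,
        "departure_iqr": cmp_.departure.iqr,
        "departure_count": cmp_.departure.count,
        "departure_percent": cmp_.departure.percent,
        "test": cmp_.test.value,
        "statistic": cmp_.statistic,
        "p_value": cmp_.p_value,
    }
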