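"""Region scans for clustered Hardy-Weinberg departures.

Departures cluster along the genome for mechanistic reasons: every SNP
inside a common deletion polymorphism loses heterozygotes, and collapsed
paralogous segments produce tight runs of constitutive heterozygotes.  A
scan runs the HWE test on every common variant of a region in one
population, builds a plot-ready track of -log10(p) and O/E values, merges
nearby significant variants into cluster calls, and summarises departure
inside vs outside user-supplied intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import association
from .hwe_core import DEFAULT_ALPHA, DEFAULT_DOF, folded_maf, test_and_classify
from .types import (
    Classification,
    GenomicInterval,
    VariantRecord,
    normalize_chrom,
)
from .variant_features import classify_variant_type

#: cap for -log10(p) so that p = 0 stays plottable
MINUS_LOG10_P_CAP = 320.0

TRACK_COLUMNS = [
    "chrom",
    "pos",
    "variant_id",
    "variant_type",
    "minus_log10_p",
    "oe_het_ratio",
    "classification",
]


class ClusterDirection(str, Enum):
    LOH = "LOH"
    GOH = "GOH"
    MIXED = "MIXED"


@dataclass
class ScanTrack:
    """Per-variant departure track for one region and one population."""

    data: pd.DataFrame
    alpha: float = DEFAULT_ALPHA
    #: False when the source data reports no missing genotypes at all
    #: (e.g. force-called panels), in which case missingness carries no QC signal.
    missingness_usable: bool = True

    def __len__(self) -> int:
        return len(self.data)

    @property
    def significant(self) -> pd.DataFrame:
        return self.data[self.data["classification"].isin(["LOH", "GOH"])]


@dataclass(frozen=True)
class ClusterCall:
    """A run of nearby significant departures sharing (or mixing) direction."""

    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    n_variants: int
    n_significant: int
    direction: ClusterDirection

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start must be <= end")


def scan_region(
    variants: Sequence[VariantRecord],
    population: str = "POP",
    region: Optional[GenomicInterval] = None,
    alpha: float = DEFAULT_ALPHA,
    min_maf: float = 0.01,
    dof: int = DEFAULT_DOF,
) -> ScanTrack:
    """Test every common variant of a region and emit the departure track.

    Variants with folded MAF <= ``min_maf`` in the chosen population (or
    with no called genotypes) are excluded, mirroring the common-variant
    selection used for region-scale replication.  The track is sorted by
    (chrom, pos); -log10(p) is capped at 320.
    """
    rows = []
    any_missing = False
    for v in variants:
        if region is not None and not region.contains_pos(v.chrom, v.pos):
            continue
        counts = v.per_pop.get(population)
        if counts is None or counts.n_called == 0:
            continue
        any_missing = any_missing or counts.n_missing > 0
        if folded_maf(counts) <= min_maf:
            continue
        res = test_and_classify(counts, alpha=alpha, dof=dof)
        if math.isnan(res.p_value):
            mlp = math.nan
        else:
            mlp = min(res.minus_log10_p, MINUS_LOG10_P_CAP)
        rows.append(
            {
                "chrom": normalize_chrom(v.chrom),
                "pos": v.pos,
                "variant_id": v.variant_id,
                "variant_type": classify_variant_type(v.ref, v.alt).value,
                "minus_log10_p": mlp,
                "oe_het_ratio": res.oe_het_ratio,
                "classification": res.classification.value,
            }
        )
    df = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return ScanTrack(data=df, alpha=alpha, missingness_usable=any_missing)


def detect_clusters(
    track: ScanTrack,
    window_bp: int = 10_000,
    min_cluster_size: int = 5,
    direction_pure: bool = True,
) -> list[ClusterCall]:
    """Greedy merge of significant variants within ``window_bp`` of each other.

    Consecutive significant variants (per chromosome) closer than
    ``window_bp`` join one cluster; clusters with fewer than
    ``min_cluster_size`` significant members are dropped.  With
    ``direction_pure`` only clusters whose significant members all share
    one direction are reported; otherwise mixed clusters come back with
    direction ``MIXED``.
    """
    sig = track.significant.sort_values(["chrom", "pos"])
    calls: list[ClusterCall] = []
    for chrom, grp in sig.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy()
        labels = grp["classification"].to_numpy()
        if len(pos) == 0:
            continue
        breaks = np.where(np.diff(pos) > window_bp)[0] + 1
        for seg in np.split(np.arange(len(pos)), breaks):
            if len(seg) < min_cluster_size:
                continue
            dirs = set(labels[seg])
            direction = (
                ClusterDirection(labels[seg][0])
                if len(dirs) == 1
                else ClusterDirection.MIXED
            )
            if direction_pure and direction is ClusterDirection.MIXED:
                continue
            start, end = int(pos[seg[0]]), int(pos[seg[-1]])
            in_span = track.data[
                (track.data["chrom"] == chrom)
                & (track.data["pos"] >= start)
                & (track.data["pos"] <= end)
            ]
            calls.append(
                ClusterCall(
                    chrom=str(chrom),
                    start=start,
                    end=end,
                    n_variants=len(in_span),
                    n_significant=len(seg),
                    direction=direction,
                )
            )
    return calls


def interval_departure_summary(
    track: ScanTrack, interval: GenomicInterval
) -> dict[str, float]:
    """Departure counts and O/E medians inside vs outside an interval.

    Medians are NaN when the corresponding side is empty.  "Inside" is
    point-in-interval on the 1-based variant positions.
    """
    df = track.data
    on_chrom = df["chrom"] == normalize_chrom(interval.chrom)
    inside_mask = (
        on_chrom
        & (df["pos"] - 1 >= interval.start)
        & (df["pos"] - 1 < interval.end)
    )
    inside = df[inside_mask]
    outside = df[~inside_mask]
    sig_inside = inside[inside["classification"].isin(["LOH", "GOH"])]
    return {
        "n_inside": int(len(inside)),
        "n_significant": int(len(sig_inside)),
        "n_loh": int((inside["classification"] == "LOH").sum()),
        "n_goh": int((inside["classification"] == "GOH").sum()),
        "median_oe_inside": float(inside["oe_het_ratio"].median())
        if len(inside)
        else math.nan,
        "median_oe_outside": float(outside["oe_het_ratio"].median())
        if len(outside)
        else math.nan,
    }


def indel_vs_snp_departure_rate(
    track: ScanTrack,
) -> tuple[list[list[int]], Optional[association.FeatureComparison]]:
    """Cross-tabulate variant type against significant departure.

    Returns the 2x2 table ``[[indel_sig, indel_ok], [snp_sig, snp_ok]]``
    and its chi-square/Fisher comparison (None when the track holds only
    one variant type, in which case the contrast is undefined).
    """
    df = track.data
    is_sig = df["classification"].isin(["LOH", "GOH"])
    is_indel = df["variant_type"] == "INDEL"
    is_snp = df["variant_type"] == "SNP"
    table = [
        [int((is_indel & is_sig).sum()), int((is_indel & ~is_sig).sum())],
        [int((is_snp & is_sig).sum()), int((is_snp & ~is_sig).sum())],
    ]
    if is_indel.sum() == 0 or is_snp.sum() == 0:
        return table, None
    cmp_ = association.compare_categorical(
        table, feature="indel_vs_snp_departure", group_label="INDEL"
    )
    return table, cmp_
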