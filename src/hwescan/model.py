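"""Model/Results front end for the directional HWE-departure analysis.

:class:`HWEDepartureModel` is built from variant records (count table,
tidy DataFrame or VCF); :meth:`HWEDepartureModel.fit` applies the
inclusion filters, runs the Hardy-Weinberg goodness-of-fit test on every
variant x population distribution, classifies each departure as loss or
gain of heterozygosity, and attaches the five explanatory features.  The
returned :class:`HWEDepartureResults` carries the per-distribution table,
group summaries, the feature-association report and region-scan helpers.

Example
-------
>>> from hwescan import HWEDepartureModel, datasets
>>> res = HWEDepartureModel(datasets.example_variants()).fit()
>>> print(res.summary())                          # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import association, genomic_scan, io as _io
from .hwe_core import (
    DEFAULT_ALPHA,
    DEFAULT_DOF,
    round_sig,
    test_and_classify,
    variant_filter,
)
from .types import (
    Classification,
    GenomicInterval,
    GenotypeCounts,
    VariantRecord,
)
from .variant_features import build_features, build_interval_index

RESULT_COLUMNS = [
    "variant_id",
    "population",
    "n_aa",
    "n_ab",
    "n_bb",
    "n_missing",
    "allele_a_freq",
    "exp_aa",
    "exp_ab",
    "exp_bb",
    "chi2",
    "dof",
    "p_hwe",
    "oe_ratio",
    "classification",
]

FEATURE_COLUMNS = [
    "variant_id",
    "missing_fraction",
    "variant_type",
    "maf_overall",
    "maf_sd",
    "cnv_loss",
    "cnv_gain",
]


class HWEDepartureModel:
    """Directional Hardy-Weinberg departure analysis of a genotyped cohort.

    Parameters
    ----------
    variants
        Biallelic variants with per-population genotype counts.
    total_n
        Cohort size used as the missingness denominator and call-rate
        denominator for every variant; defaults to each variant's own
        total (called + missing) when unset.
    alpha
        Significance threshold for declaring a departure (default 1e-5).
    dof
        Degrees of freedom for the goodness-of-fit p-value (default 2;
        use 1 for the conventional test that subtracts the estimated
        allele frequency).
    min_call_rate, min_maf, pop_min_maf
        Inclusion filters: pooled call rate >= 0.80, pooled folded
        MAF >= 0.01, per-population folded MAF >= 0.001.
    cnv_intervals
        Copy-number loss/gain polymorphism intervals for feature annotation.
    """

    def __init__(
        self,
        variants: Sequence[VariantRecord],
        total_n: Optional[int] = None,
        alpha: float = DEFAULT_ALPHA,
        dof: int = DEFAULT_DOF,
        min_call_rate: float = 0.80,
        min_maf: float = 0.01,
        pop_min_maf: float = 0.001,
        cnv_intervals: Sequence[GenomicInterval] = (),
    ) -> None:
        self.variants = list(variants)
        self.total_n = total_n
        self.alpha = alpha
        self.dof = dof
        self.min_call_rate = min_call_rate
        self.min_maf = min_maf
        self.pop_min_maf = pop_min_maf
        self.cnv_intervals = list(cnv_intervals)
        self._interval_index = build_interval_index(self.cnv_intervals)

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_counts_table(cls, path: str | Path, **kwargs) -> "HWEDepartureModel":
        """Build from a genotype-count TSV (see :mod:`hwescan.io`)."""
        return cls(_io.read_counts_table(path), **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "HWEDepartureModel":
        """Build from a tidy DataFrame with one row per variant x population.

        Required columns: ``variant_id, chrom, pos, ref, alt, population,
        n_aa, n_ab, n_bb, n_missing``.
        """
        records: dict[str, VariantRecord] = {}
        for row in df.itertuples(index=False):
            vid = str(row.variant_id)
            rec = records.setdefault(
                vid,
                VariantRecord(
                    variant_id=vid,
                    chrom=str(row.chrom),
                    pos=int(row.pos),
                    ref=str(row.ref),
                    alt=str(row.alt),
                ),
            )
            rec.per_pop[str(row.population)] = GenotypeCounts(
                int(row.n_aa), int(row.n_ab), int(row.n_bb), int(row.n_missing)
            )
        return cls(list(records.values()), **kwargs)

    @classmethod
    def from_vcf(
        cls,
        path: str | Path,
        sample_to_population: Mapping[str, str],
        region: Optional[GenomicInterval] = None,
        **kwargs,
    ) -> "HWEDepartureModel":
        """Build by counting genotypes from a multi-sample VCF."""
        return cls(
            _io.read_vcf_counts(path, sample_to_population, region=region),
            **kwargs,
        )

    # -- fitting -----------------------------------------------------------

    def fit(self, strict: bool = False) -> "HWEDepartureResults":
        """Filter, test and classify every variant x population distribution.

        With ``strict=True`` the call-rate threshold is raised to 0.98
        (the high-quality re-analysis mode that suppresses
        genotyping-error departures).
        """
        min_call_rate = 0.98 if strict else self.min_call_rate
        result_rows: list[dict] = []
        feature_rows: list[dict] = []
        filter_log: list[dict] = []
        for v in self.variants:
            total = self.total_n if self.total_n is not None else v.cohort_n
            decision, analyse = variant_filter(
                v.per_pop,
                total_n=total,
                min_call_rate=min_call_rate,
                min_maf=self.min_maf,
                pop_min_maf=self.pop_min_maf,
            )
            filter_log.append(
                {
                    "variant_id": v.variant_id,
                    "included": decision.included,
                    "reasons": ",".join(r.value for r in decision.reasons),
                    "n_populations_analyzed": len(analyse),
                }
            )
            if not decision.included:
                continue
            feats = build_features(v, self._interval_index, included_pops=analyse)
            feature_rows.append(
                {
                    "variant_id": v.variant_id,
                    "missing_fraction": feats.missing_fraction,
                    "variant_type": feats.variant_type.value,
                    "maf_overall": feats.maf_overall,
                    "maf_sd": feats.maf_sd,
                    "cnv_loss": feats.cnv_loss,
                    "cnv_gain": feats.cnv_gain,
                }
            )
            for pop in sorted(analyse):
                c = v.per_pop[pop]
                r = test_and_classify(c, alpha=self.alpha, dof=self.dof)
                result_rows.append(
                    {
                        "variant_id": v.variant_id,
                        "population": pop,
                        "n_aa": c.n_aa,
                        "n_ab": c.n_ab,
                        "n_bb": c.n_bb,
                        "n_missing": c.n_missing,
                        "allele_a_freq": r.allele_a_freq,
                        "exp_aa": r.expected_aa,
                        "exp_ab": r.expected_ab,
                        "exp_bb": r.expected_bb,
                        "chi2": r.chi2,
                        "dof": r.dof,
                        "p_hwe": r.p_value,
                        "oe_ratio": r.oe_het_ratio,
                        "classification": r.classification.value,
                    }
                )
        results = pd.DataFrame(result_rows, columns=RESULT_COLUMNS)
        features = pd.DataFrame(feature_rows, columns=FEATURE_COLUMNS)
        return HWEDepartureResults(
            model=self,
            results=results,
            features=features,
            filter_log=pd.DataFrame(filter_log),
            strict=strict,
        )


@dataclass
class HWEDepartureResults:
    """Fitted per-distribution tests, classifications and features.

    Attributes
    ----------
    results
        One row per analysed variant x population: observed and expected
        counts, allele-A frequency, chi-square, p, O/E heterozygote ratio
        and the NONE/LOH/GOH/UNDEFINED classification.
    features
        One row per included variant: the five explanatory variables.
    filter_log
        Per-variant inclusion decisions with rejection reasons.
    """

    model: HWEDepartureModel
    results: pd.DataFrame
    features: pd.DataFrame
    filter_log: pd.DataFrame
    strict: bool = False

    # -- derived tables ----------------------------------------------------

    @property
    def merged(self) -> pd.DataFrame:
        """Per-distribution rows joined with their variant-level features."""
        return self.results.merge(self.features, on="variant_id", how="left")

    def class_counts(self) -> pd.Series:
        levels = [c.value for c in Classification]
        return (
            self.results["classification"]
            .value_counts()
            .reindex(levels, fill_value=0)
        )

    def association_report(self) -> pd.DataFrame:
        """Feature comparisons of LoH and GoH groups against in-HWE controls."""
        return association.build_association_report(self.merged)

    def scan_track(
        self,
        population: str,
        region: Optional[GenomicInterval] = None,
        min_maf: float = 0.01,
    ) -> genomic_scan.ScanTrack:
        """Departure track over the model's variants for one population."""
        return genomic_scan.scan_region(
            self.model.variants,
            population=population,
            region=region,
            alpha=self.model.alpha,
            min_maf=min_maf,
            dof=self.model.dof,
        )

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary of the fit."""
        n_var = len(self.model.variants)
        n_inc = int(self.filter_log["included"].sum()) if len(self.filter_log) else 0
        cc = self.class_counts()
        n_dist = len(self.results)
        lines = [
            "Directional HWE-departure analysis",
            "==================================",
            f"variants supplied:            {n_var}",
            f"variants passing filters:     {n_inc}",
            f"genotype distributions:       {n_dist}",
            f"alpha: {self.model.alpha:g}   dof: {self.model.dof}"
            f"   strict call-rate mode: {self.strict}",
            "",
            "classification counts:",
        ]
        for label in ("NONE", "LOH", "GOH", "UNDEFINED"):
            n = int(cc.get(label, 0))
            pct = 100.0 * n / n_dist if n_dist else 0.0
            lines.append(f"  {label:<10} {n:>6}  ({pct:5.1f}%)")
        sig = self.results[self.results["classification"].isin(["LOH", "GOH"])]
        if len(sig):
            lines.append("")
            lines.append("significant departures by population:")
            by_pop = sig.groupby(["population", "classification"]).size()
            for (pop, label), n in by_pop.items():
                lines.append(f"  {pop:<6} {label:<4} {int(n):>5}")
        return "\n".join(lines)

    def report_frame(self) -> pd.DataFrame:
        """Results at report precision: expected counts to integers, O/E and
        frequencies to 2 decimals, p to 2 significant figures."""
        df = self.results.copy()
        for col in ("exp_aa", "exp_ab", "exp_bb"):
            df[col] = df[col].round().astype("Int64")
        df["allele_a_freq"] = df["allele_a_freq"].round(2)
        df["oe_ratio"] = df["oe_ratio"].round(2)
        df["p_hwe"] = df["p_hwe"].map(lambda p: round_sig(p, 2))
        return df
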