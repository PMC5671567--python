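"""Tests for the mechanism generators: reductions, closed forms, oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hwescan import synthetic_data as sd
from hwescan.hwe_core import oe_het_ratio
from hwescan.hwe_core import test_and_classify as classify_counts
from hwescan.types import Classification, GenomicInterval, IntervalKind

from .oracles import dropout_call_probs_oracle


def oe_se(oe: float, het_prob: float, n: int, exp_het_frac: float) -> float:
    """Rough Monte-Carlo standard error of the simulated O/E ratio: the
    numerator is a binomial proportion, the denominator is ~fixed."""
    return math.sqrt(het_prob * (1 - het_prob) / n) / exp_het_frac


class TestReductions:
    """Every generator reduces exactly to the HWE generator when its
    distortion parameter is zero (same seed, same draw)."""

    def test_inbreeding_f0(self):
        assert sd.sim_inbreeding(1000, 0.3, 0.0, 9) == sd.sim_hwe(1000, 0.3, 9)

    def test_deletion_d0(self):
        assert sd.sim_deletion_overlay(1000, 0.3, 0.0, seed=9) == sd.sim_hwe(1000, 0.3, 9)

    def test_dropout_e0(self):
        assert sd.sim_allelic_dropout(n=1000, p=0.3, e=0.0, seed=9) == sd.sim_hwe(1000, 0.3, 9)

    def test_paralog_hf0(self):
        assert sd.sim_paralog_collapse(1000, 0.0, seed=9) == sd.sim_hwe(1000, 0.5, 9)


class TestHWEGenerator:
    def test_determinism_under_seed(self):
        assert sd.sim_hwe(500, 0.4, 123) == sd.sim_hwe(500, 0.4, 123)

    def test_monomorphic_limit(self):
        assert sd.sim_hwe(100, 1.0, 0) == sd.sim_hwe(100, 1.0, 1)
        assert sd.sim_hwe(100, 1.0, 0).n_aa == 100

    def test_large_n_oe_near_one(self):
        c = sd.sim_hwe(10**6, 0.5, 7)
        assert oe_het_ratio(c) == pytest.approx(1.0, abs=0.005)

    @given(st.integers(1, 500), st.floats(0.01, 0.99), st.integers(0, 2**20))
    @settings(max_examples=100, deadline=None)
    def test_counts_conserve_n(self, n, p, seed):
        c = sd.sim_hwe(n, p, seed)
        assert c.n_total == n


class TestInbreeding:
    def test_closed_form_oe_is_one_minus_f(self):
        c = sd.sim_inbreeding(100_000, 0.5, 0.25, 3)
        assert oe_het_ratio(c) == pytest.approx(0.75, abs=0.02)

    def test_f1_has_no_heterozygotes(self):
        assert sd.sim_inbreeding(10_000, 0.5, 1.0, 3).n_ab == 0

    def test_parameter_recovery_slope(self):
        """Regressing the heterozygote deficit 1 - O/E on F recovers a
        slope of 1."""
        fs, deficits = [], []
        rng = np.random.default_rng(2024)
        for F in np.arange(0.0, 0.51, 0.1):
            for _ in range(20):
                c = sd.sim_inbreeding(100_000, 0.5, float(F), int(rng.integers(2**31)))
                fs.append(F)
                deficits.append(1.0 - oe_het_ratio(c))
        slope = np.polyfit(fs, deficits, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.05)


class TestStratified:
    def test_wahlund_closed_form(self):
        c = sd.sim_stratified(100_000, (0.5, 0.5), (0.2, 0.8), 4)
        assert oe_het_ratio(c) == pytest.approx(0.64, abs=0.02)

    def test_no_structure_when_frequencies_equal(self):
        c = sd.sim_stratified(100_000, (0.5, 0.5), (0.3, 0.3), 4)
        assert oe_het_ratio(c) == pytest.approx(1.0, abs=0.02)

    def test_published_east_asian_subpopulation_frequencies_give_loh(self):
        # five sub-population frequencies reported for the stratified example
        freqs = (0.21, 0.65, 0.40, 0.67, 0.17)
        c = sd.sim_stratified(100_000, (0.2,) * 5, freqs, 4)
        r = classify_counts(c)
        assert r.classification is Classification.LOH

    def test_wahlund_identity_on_grid(self):
        rng = np.random.default_rng(8)
        grid = [
            ((0.5, 0.5), (0.3, 0.7)),
            ((0.25, 0.75), (0.1, 0.6)),
            ((0.2, 0.3, 0.5), (0.2, 0.5, 0.8)),
        ]
        n = 100_000
        for weights, freqs in grid:
            c = sd.sim_stratified(n, weights, freqs, int(rng.integers(2**31)))
            het = sum(w * 2 * p * (1 - p) for w, p in zip(weights, freqs))
            pbar = sum(w * p for w, p in zip(weights, freqs))
            expected_oe = het / (2 * pbar * (1 - pbar))
            se = oe_se(expected_oe, het, n, 2 * pbar * (1 - pbar))
            assert oe_het_ratio(c) == pytest.approx(expected_oe, abs=3 * se + 1e-3)

    def test_bad_weights_rejected(self):
        with pytest.raises(ValueError):
            sd.sim_stratified(100, (0.5, 0.6), (0.2, 0.8), 0)


class TestDeletionOverlay:
    def test_missing_mode_closed_form(self):
        c = sd.sim_deletion_overlay(100_000, 0.5, 0.5, sd.DeletionMode.MISSING, 5)
        assert oe_het_ratio(c) == pytest.approx(1 / 3, abs=0.02)
        # homozygous-deletion carriers are missing
        assert c.n_missing == pytest.approx(25_000, abs=700)

    def test_forced_hom_mode_closed_form(self):
        c = sd.sim_deletion_overlay(100_000, 0.5, 0.5, sd.DeletionMode.FORCED_HOM, 5)
        assert oe_het_ratio(c) == pytest.approx(0.25, abs=0.02)
        assert c.n_missing == 0

    def test_identity_on_grid(self):
        rng = np.random.default_rng(9)
        n = 100_000
        for d in (0.2, 0.5, 0.7):
            for mode, formula in (
                (sd.DeletionMode.MISSING, (1 - d) / (1 + d)),
                (sd.DeletionMode.FORCED_HOM, (1 - d) ** 2),
            ):
                c = sd.sim_deletion_overlay(n, 0.5, d, mode, int(rng.integers(2**31)))
                het = (1 - d) ** 2 * 0.5
                # expected het count is 2pq of the *called* genotypes
                called = 1 - d * d if mode is sd.DeletionMode.MISSING else 1.0
                se = oe_se(formula, het, n, 0.5 * called)
                assert oe_het_ratio(c) == pytest.approx(formula, abs=3 * se + 2e-3), (d, mode)


class TestParalogCollapse:
    def test_constitutive_heterozygotes(self):
        c = sd.sim_paralog_collapse(100, 1.0, 0)
        assert (c.n_aa, c.n_ab, c.n_bb) == (0, 100, 0)
        assert oe_het_ratio(c) == pytest.approx(2.0)

    @pytest.mark.parametrize("n", [24, 100, 5000])
    def test_classified_goh_above_power_threshold(self, n):
        r = classify_counts(sd.sim_paralog_collapse(n, 1.0, 0))
        assert r.classification is Classification.GOH
        assert r.chi2 == pytest.approx(n)


class TestAllelicDropout:
    def test_call_probs_match_enumeration_oracle(self):
        for p in (0.1, 0.5, 0.8):
            for e in (0.0, 0.2, 0.9):
                ours = sd.dropout_call_probs(p, e)
                oracle = dropout_call_probs_oracle(p, e)
                assert ours == pytest.approx(oracle, abs=1e-12), (p, e)
                assert sum(ours) == pytest.approx(1.0, abs=1e-12)

    def test_simulated_oe_matches_enumeration(self):
        p, e, n = 0.5, 0.2, 100_000
        paa, pab, pbb, _ = sd.dropout_call_probs(p, e)
        called = paa + pab + pbb
        m = (2 * paa + pab) / (2 * called)
        implied_oe = (pab / called) / (2 * m * (1 - m))
        c = sd.sim_allelic_dropout(n=n, p=p, e=e, seed=6)
        assert oe_het_ratio(c) == pytest.approx(implied_oe, abs=0.02)

    def test_e1_loses_every_genotype(self):
        c = sd.sim_allelic_dropout(n=1000, p=0.5, e=1.0, seed=0)
        assert c.n_called == 0 and c.n_missing == 1000

    def test_degrading_existing_counts_conserves_n(self):
        base = sd.sim_hwe(5000, 0.4, 1)
        degraded = sd.sim_allelic_dropout(counts=base, e=0.3, seed=2)
        assert degraded.n_total == base.n_total
        assert degraded.n_ab < base.n_ab

    def test_e0_counts_unchanged(self):
        base = sd.sim_hwe(100, 0.4, 1)
        assert sd.sim_allelic_dropout(counts=base, e=0.0, seed=2) == base


class TestMissingness:
    def test_rate_and_conservation(self):
        c = sd.apply_missingness(sd.sim_hwe(100_000, 0.5, 1), 0.15, 2)
        assert c.n_total == 100_000
        assert c.n_missing == pytest.approx(15_000, abs=400)

    def test_zero_rate_identity(self):
        base = sd.sim_hwe(100, 0.5, 1)
        assert sd.apply_missingness(base, 0.0, 2) == base


class TestSimRegion:
    layout = [
        (
            GenomicInterval("1", 200_000, 250_000, kind=IntervalKind.LOSS),
            sd.MechanismParams(mechanism=sd.Mechanism.DELETION, n=0, deletion_freq=0.5),
        ),
        (
            GenomicInterval("1", 700_000, 702_400, kind=IntervalKind.GAIN),
            sd.MechanismParams(mechanism=sd.Mechanism.PARALOG, n=0, het_fraction=1.0),
            11,
        ),
    ]

    def test_truth_table_covers_every_variant(self):
        cohort = sd.sim_region(self.layout, n=500, n_variants=100, seed=1)
        assert set(cohort.truth) == {v.variant_id for v in cohort.variants}
        assert len(cohort.variants) == 100

    def test_forced_variants_land_inside_their_interval(self):
        cohort = sd.sim_region(self.layout, n=500, n_variants=100, seed=1)
        iv = self.layout[1][0]
        inside = [v for v in cohort.variants if iv.contains_pos(v.chrom, v.pos)]
        assert len(inside) >= 11
        assert all(
            cohort.truth[v.variant_id].mechanism is sd.Mechanism.PARALOG
            for v in inside
        )

    def test_deterministic_under_seed(self):
        a = sd.sim_region(self.layout, n=200, n_variants=50, seed=4)
        b = sd.sim_region(self.layout, n=200, n_variants=50, seed=4)
        assert [v.pos for v in a.variants] == [v.pos for v in b.variants]
        assert all(
            x.per_pop["POP"] == y.per_pop["POP"]
            for x, y in zip(a.variants, b.variants)
        )

    def test_overlapping_intervals_rejected(self):
        bad = [
            (GenomicInterval("1", 100, 300, kind=IntervalKind.LOSS),
             sd.MechanismParams(mechanism=sd.Mechanism.HWE, n=0)),
            (GenomicInterval("1", 200, 400, kind=IntervalKind.GAIN),
             sd.MechanismParams(mechanism=sd.Mechanism.HWE, n=0)),
        ]
        with pytest.raises(ValueError):
            sd.sim_region(bad, n=100, n_variants=10, seed=0)
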