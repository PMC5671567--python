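"""Unit and property tests for the HWE goodness-of-fit core."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hwescan import datasets, hwe_core
from hwescan.types import (
    Classification,
    GenotypeCounts,
    RejectionReason,
    UntestableVariantError,
)

from .oracles import chi2_exact

counts_st = st.tuples(
    st.integers(0, 3000), st.integers(0, 3000), st.integers(0, 3000)
).filter(lambda t: sum(t) > 0)


class TestAlleleFrequency:
    @pytest.mark.parametrize(
        "counts, expected, ndigits",
        [
            ((110, 1620, 2198), 0.23, 2),  # published African row of the indel example
            ((100, 0, 0), 1.0, 12),  # monomorphic
            ((2392, 1463, 429), 0.7291, 4),
        ],
    )
    def test_examples(self, counts, expected, ndigits):
        m = hwe_core.allele_a_frequency(GenotypeCounts(*counts))
        assert round(m, ndigits) == pytest.approx(expected)

    def test_no_called_genotypes_is_untestable(self):
        with pytest.raises(UntestableVariantError):
            hwe_core.allele_a_frequency(GenotypeCounts(0, 0, 0, 50))


class TestExpectedCounts:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((195, 1396, 4190), (138, 1510, 4133)),  # published Latino row
            ((25, 50, 25), (25, 50, 25)),  # exact HW proportions
            ((9, 42, 49), (9, 42, 49)),  # m = 0.3 at n = 100
        ],
    )
    def test_examples(self, counts, expected):
        exp = hwe_core.expected_genotype_counts(GenotypeCounts(*counts))
        assert tuple(round(e) for e in exp) == expected

    @given(counts_st)
    @settings(max_examples=200, deadline=None)
    def test_expected_counts_sum_to_n_called(self, counts):
        c = GenotypeCounts(*counts)
        assert sum(hwe_core.expected_genotype_counts(c)) == pytest.approx(
            c.n_called, abs=1e-6 * max(c.n_called, 1)
        )


class TestHWETest:
    def test_published_strong_departure(self):
        r = hwe_core.hwe_test(GenotypeCounts(2392, 1463, 429))
        assert r.chi2 == pytest.approx(78.64, abs=0.05)
        assert hwe_core.round_sig(r.p_value) == 8.4e-18

    def test_exact_hw_proportions_give_zero_statistic(self):
        r = hwe_core.hwe_test(GenotypeCounts(25, 50, 25))
        assert r.chi2 == 0.0
        assert r.p_value == 1.0

    def test_all_heterozygote_closed_form(self):
        r = hwe_core.hwe_test(GenotypeCounts(0, 100, 0))
        assert r.chi2 == pytest.approx(100.0)
        assert r.p_value == pytest.approx(math.exp(-50), rel=1e-9)

    def test_monomorphic_is_undefined_not_in_hwe(self):
        r = hwe_core.hwe_test(GenotypeCounts(100, 0, 0))
        assert r.classification is Classification.UNDEFINED
        assert math.isnan(r.p_value)
        assert hwe_core.classify_departure(r) is Classification.UNDEFINED

    @given(counts_st)
    @settings(max_examples=300, deadline=None)
    def test_closed_form_identity_dof2(self, counts):
        """At 2 degrees of freedom, p = exp(-chi2/2) identically."""
        r = hwe_core.hwe_test(GenotypeCounts(*counts))
        if not math.isnan(r.chi2):
            assert r.p_value == pytest.approx(math.exp(-r.chi2 / 2), abs=1e-12)

    @given(counts_st)
    @settings(max_examples=300, deadline=None)
    def test_allele_label_swap_symmetry(self, counts):
        aa, ab, bb = counts
        r1 = hwe_core.hwe_test(GenotypeCounts(aa, ab, bb))
        r2 = hwe_core.hwe_test(GenotypeCounts(bb, ab, aa))
        assert r2.allele_a_freq == pytest.approx(1 - r1.allele_a_freq, abs=1e-12)
        if math.isnan(r1.chi2):
            assert math.isnan(r2.chi2)
        else:
            assert r2.chi2 == pytest.approx(r1.chi2, rel=1e-9)
            assert r2.p_value == pytest.approx(r1.p_value, rel=1e-9)

    def test_dof1_is_more_significant_than_dof2(self):
        c = GenotypeCounts(2392, 1463, 429)
        assert hwe_core.hwe_test(c, dof=1).p_value < hwe_core.hwe_test(c, dof=2).p_value

    def test_brute_force_oracle_equivalence_small_n(self):
        """chi2 matches exact rational arithmetic for every distribution
        with at most 12 called genotypes."""
        checked = 0
        for n in range(1, 13):
            for aa in range(n + 1):
                for ab in range(n + 1 - aa):
                    bb = n - aa - ab
                    c = GenotypeCounts(aa, ab, bb)
                    m = hwe_core.allele_a_frequency(c)
                    if m in (0.0, 1.0):
                        continue
                    r = hwe_core.hwe_test(c)
                    assert r.chi2 == pytest.approx(
                        float(chi2_exact(aa, ab, bb)), rel=1e-9
                    ), (aa, ab, bb)
                    checked += 1
        assert checked > 300

    def test_batch_matches_scalar(self):
        arr = np.array([[2392, 1463, 429], [25, 50, 25], [0, 100, 0]])
        chi2, p, oe = hwe_core.hwe_test_batch(arr)
        for i, row in enumerate(arr):
            r = hwe_core.hwe_test(GenotypeCounts(*map(int, row)))
            assert chi2[i] == pytest.approx(r.chi2, rel=1e-12)
            assert oe[i] == pytest.approx(r.oe_het_ratio, rel=1e-12)


class TestOERatio:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((531, 2895, 1412), 1.24),  # published Latino row of the indel example
            ((25, 50, 25), 1.0),
            ((0, 100, 0), 2.0),
        ],
    )
    def test_examples(self, counts, expected):
        assert hwe_core.oe_het_ratio(GenotypeCounts(*counts)) == pytest.approx(
            expected, abs=5e-3
        )

    def test_monomorphic_is_nan(self):
        assert math.isnan(hwe_core.oe_het_ratio(GenotypeCounts(10, 0, 0)))


class TestClassification:
    def test_directional_labels_from_published_counts(self):
        loh = hwe_core.test_and_classify(datasets.example_counts("rs7551421", "EAS"))
        goh = hwe_core.test_and_classify(datasets.example_counts("rs58896934", "AFR"))
        none = hwe_core.test_and_classify(GenotypeCounts(25, 50, 25))
        assert loh.classification is Classification.LOH
        assert goh.classification is Classification.GOH
        assert none.classification is Classification.NONE

    @given(counts_st)
    @settings(max_examples=300, deadline=None)
    def test_classification_consistent_with_p_and_direction(self, counts):
        r = hwe_core.test_and_classify(GenotypeCounts(*counts))
        if r.classification is Classification.LOH:
            assert r.p_value < hwe_core.DEFAULT_ALPHA and r.oe_het_ratio < 1
        elif r.classification is Classification.GOH:
            assert r.p_value < hwe_core.DEFAULT_ALPHA and r.oe_het_ratio > 1
        elif r.classification is Classification.NONE:
            assert r.p_value >= hwe_core.DEFAULT_ALPHA


class TestVariantFilter:
    def test_low_call_rate_excluded(self):
        dec, pops = hwe_core.variant_filter(
            {"NFE": GenotypeCounts(16000, 16000, 16000)}, total_n=60706
        )
        assert not dec.included
        assert RejectionReason.LOW_CALL_RATE in dec.reasons
        assert pops == set()

    def test_rare_variant_excluded(self):
        dec, _ = hwe_core.variant_filter(
            {"NFE": GenotypeCounts(990, 10, 0)}, total_n=1000
        )
        assert dec.reasons == (RejectionReason.LOW_MAF_OVERALL,)

    def test_population_with_local_rare_allele_dropped(self):
        per_pop = {
            "NFE": GenotypeCounts(250, 500, 250),
            "EAS": GenotypeCounts(999, 1, 0),  # folded MAF 0.0005
        }
        dec, pops = hwe_core.variant_filter(per_pop, total_n=2000)
        assert dec.included
        assert pops == {"NFE"}

    def test_strict_mode_is_a_call_rate_of_98_percent(self):
        per_pop = {"NFE": GenotypeCounts(300, 400, 260, n_missing=40)}
        dec_default, _ = hwe_core.variant_filter(per_pop, total_n=1000)
        dec_strict, _ = hwe_core.variant_filter(
            per_pop, total_n=1000, min_call_rate=0.98
        )
        assert dec_default.included and not dec_strict.included

    def test_empty_population_map_rejected(self):
        with pytest.raises(ValueError):
            hwe_core.variant_filter({}, total_n=100)
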