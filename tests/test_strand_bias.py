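"""Informative-set construction, exact binomial test, arm fractions."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mirqpcr import (
    CtMatrix,
    ProbePanel,
    call_expressed,
    count_arms,
    exact_binomial_test,
    informative_set,
    sister_name,
    strand_bias_test,
    strand_expression_fraction,
)

from conftest import toy_ct_frame


def enumeration_pvalues(n: int, p0: float = 0.5):
    """Independent oracle: exhaust all 2**n arm assignments.

    Returns (one_sided, two_sided) p-value lists indexed by k, from the
    outcome-count histogram over every bitmask.
    """
    counts = [0] * (n + 1)
    for mask in range(2**n):
        counts[mask.bit_count()] += 1
    p = Fraction(p0)
    q = 1 - p
    pmf = [c * p**k * q ** (n - k) for k, c in enumerate(counts)]
    one = [float(sum(pmf[k:])) for k in range(n + 1)]
    two = [float(sum(m for m in pmf if m <= pmf[k])) for k in range(n + 1)]
    return one, two


class TestInformativeSet:
    panel = ProbePanel(
        ["miR-125a-3p", "miR-125a-5p", "miR-451", "miR-1237-3p", "miR-9-5p", "miR-9-3p"]
    )

    def test_three_exclusion_classes(self):
        part = informative_set(["miR-125a-3p", "miR-451", "miR-1237-3p"], self.panel)
        assert part["informative_3p"] == ["miR-125a-3p"]
        assert part["no_arm_info"] == ["miR-451"]
        assert part["missing_sister"] == ["miR-1237-3p"]
        assert part["informative_5p"] == []

    def test_all_informative(self):
        part = informative_set(["miR-125a-3p", "miR-9-5p"], self.panel)
        assert not part["no_arm_info"] and not part["missing_sister"]
        assert count_arms(part) == (1, 1)

    def test_empty_input(self):
        part = informative_set([], self.panel)
        assert count_arms(part) == (0, 0)

    def test_partition_is_exhaustive_and_exclusive(self, default_discovery):
        called = list(
            default_discovery["table"].index[default_discovery["table"]["overexpressed"]]
        )
        part = informative_set(called, default_discovery["panel"])
        assert sum(len(v) for v in part.values()) == len(called)
        flat = [a for v in part.values() for a in v]
        assert len(set(flat)) == len(flat)


def test_published_top10_names_count_nine_3p_one_5p(table1_names):
    """Arm counting over the 10 printed marker names gives 9 -3p / 1 -5p."""
    panel = ProbePanel(table1_names + [sister_name(n) for n in table1_names])
    part = informative_set(table1_names, panel)
    assert count_arms(part) == (9, 1)


class TestExactBinomial:
    def test_all_successes_closed_form(self):
        assert exact_binomial_test(10, 10) == pytest.approx(2.0**-10)
        assert exact_binomial_test(7, 7, null_prob=0.3) == pytest.approx(0.3**7)

    def test_frozen_enumeration_values(self):
        # values computed with the exhaustive-enumeration oracle
        assert exact_binomial_test(5, 10) == pytest.approx(638 / 1024)
        assert exact_binomial_test(21, 30) == pytest.approx(22964087 / 2**30)
        assert exact_binomial_test(9, 10) == pytest.approx(11 / 1024)
        assert exact_binomial_test(9, 10, sidedness="two_sided") == pytest.approx(22 / 1024)

    @pytest.mark.parametrize("n", [1, 4, 9, 12])
    def test_matches_enumeration_oracle(self, n):
        one, two = enumeration_pvalues(n)
        for k in range(n + 1):
            assert exact_binomial_test(k, n) == pytest.approx(one[k], abs=1e-12)
            assert exact_binomial_test(k, n, sidedness="two_sided") == pytest.approx(
                two[k], abs=1e-12
            )

    @pytest.mark.parametrize("p0", [0.3, 0.5, 0.7])
    def test_cross_checks_against_scipy(self, p0):
        for k, n in [(0, 5), (3, 7), (9, 10), (21, 30), (14, 30)]:
            assert exact_binomial_test(k, n, p0) == pytest.approx(
                stats.binomtest(k, n, p0, alternative="greater").pvalue, rel=1e-9
            )
            assert exact_binomial_test(k, n, p0, sidedness="two_sided") == pytest.approx(
                stats.binomtest(k, n, p0, alternative="two-sided").pvalue, rel=1e-6
            )

    @settings(derandomize=True)
    @given(st.integers(1, 25))
    def test_one_sided_nonincreasing_in_k(self, n):
        ps = [exact_binomial_test(k, n) for k in range(n + 1)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        assert ps[-1] == pytest.approx(0.5**n)

    def test_zero_informative_is_error(self):
        with pytest.raises(ValueError, match="no informative"):
            exact_binomial_test(0, 0)


def test_strand_bias_test_counts_are_consistent(default_discovery):
    table, panel = default_discovery["table"], default_discovery["panel"]
    called = list(table.index[table["overexpressed"]])
    res = strand_bias_test(called, panel)
    assert res.n_input == res.n_no_arm_info + res.n_missing_sister + res.n_informative
    assert res.n_informative == res.n_3p + res.n_5p
    assert 0 <= res.p_value <= 1
    # the generator programs a 70% -3p share among informative spikes
    assert res.n_3p > res.n_5p
    assert res.p_value < 0.05


class TestArmFractions:
    panel = ProbePanel(["miR-1-3p", "miR-1-5p", "miR-2-3p", "miR-2-5p", "miR-451"])

    def _mask(self, data, samples):
        values = toy_ct_frame(data, samples)
        return call_expressed(CtMatrix(values, values.isna()))

    def test_balanced_sample_is_fifty_fifty(self):
        mask = self._mask(
            {"miR-1-3p": [30.0], "miR-1-5p": [30.0], "miR-2-3p": [30.0], "miR-2-5p": [30.0]},
            ["s1"],
        )
        frac = strand_expression_fraction(mask, self.panel)
        assert frac.loc["s1", "pct_3p"] == pytest.approx(50.0)
        assert frac.loc["s1", "pct_5p"] == pytest.approx(50.0)

    def test_only_3p_expressed(self):
        mask = self._mask(
            {"miR-1-3p": [30.0], "miR-1-5p": [np.nan], "miR-2-3p": [30.0],
             "miR-2-5p": [np.nan], "miR-451": [25.0]},
            ["s1"],
        )
        frac = strand_expression_fraction(mask, self.panel)
        assert frac.loc["s1", "pct_3p"] == pytest.approx(100.0)
        assert frac.loc["s1", "pct_5p"] == pytest.approx(0.0)

    def test_empty_denominator_is_flagged(self):
        mask = self._mask({"miR-451": [25.0, 25.0]}, ["s1", "s2"])
        frac = strand_expression_fraction(mask, self.panel)
        assert frac["undefined"].all()
        assert frac["pct_3p"].isna().all()

    def test_fractions_sum_to_100(self, default_normalized):
        frac = strand_expression_fraction(
            default_normalized["mask"], default_normalized["panel"]
        )
        defined = frac[~frac["undefined"]]
        assert len(defined) == len(frac)
        assert np.allclose(defined["pct_3p"] + defined["pct_5p"], 100.0)

    def test_case_3p_fraction_exceeds_cohort_mean(self):
        """With baselines straddling the detection limit, the case's -3p
        spikes pull extra 3p assays into its expressed set, so its dual-probe
        %3p exceeds the cohort mean (the programmed arm excess)."""
        from mirqpcr import simulate_cohort
        from mirqpcr.simulate import SimConfig

        cfg = SimConfig(
            seed=9, baseline_ct_low=30.0, baseline_ct_high=41.0, censor_limit=45.0
        )
        matrix, _, panel, truth = simulate_cohort(cfg)
        mask = call_expressed(matrix)
        frac = strand_expression_fraction(mask, panel)
        others = frac.drop(index=truth.index_case)
        assert frac.loc[truth.index_case, "pct_3p"] > others["pct_3p"].mean()
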