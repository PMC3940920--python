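"""Expression calling, QC checks and global-mean normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirqpcr import (
    CtMatrix,
    call_expressed,
    global_mean_normalize,
    hemolysis_check,
    qc_report,
    spikein_check,
    simulate_cohort,
)
from mirqpcr.simulate import SPIKE_IN, SimConfig

from conftest import toy_ct_frame


def make_matrix(data: dict, samples: list[str]) -> CtMatrix:
    values = toy_ct_frame(data, samples)
    return CtMatrix(values, values.isna())


class TestCallExpressed:
    def test_boundary_inclusive_at_threshold(self):
        m = make_matrix({"a": [37.0], "b": [37.01], "c": [np.nan]}, ["s1"])
        mask = call_expressed(m, 37.0)
        assert bool(mask.expressed.loc["a", "s1"])
        assert not bool(mask.expressed.loc["b", "s1"])
        assert not bool(mask.expressed.loc["c", "s1"])  # censored is never expressed
        assert mask.global_set == ["a"]

    def test_global_set_is_union_over_samples(self):
        m = make_matrix({"a": [30, np.nan], "b": [np.nan, 30], "c": [39, 39]}, ["s1", "s2"])
        assert call_expressed(m, 37.0).global_set == ["a", "b"]


class TestHemolysis:
    def test_two_marker_delta_flags(self):
        m = make_matrix({"miR-23a": [25.0, 24.0], "miR-451": [17.0, 17.1]}, ["s1", "s2"])
        rep = hemolysis_check(m, delta_threshold=7.0)
        assert rep.loc["s1", "hemolysis_delta"] == pytest.approx(8.0)
        assert bool(rep.loc["s1", "hemolysis_risk"])
        assert rep.loc["s2", "hemolysis_delta"] == pytest.approx(6.9)
        assert not bool(rep.loc["s2", "hemolysis_risk"])  # boundary: 6.9 <= 7

    def test_single_marker_median_rule_on_generator_truth(self):
        """A generator-hemolyzed sample (miR-451 shifted -6 cycles) is caught
        by the single-marker rule once miR-23a is removed from the matrix."""
        cfg = SimConfig(seed=5, hemolysis_samples=("CTRL03",))
        matrix, sheet, _, _ = simulate_cohort(cfg)
        no23a = CtMatrix(
            matrix.values.drop(index="miR-23a"), matrix.censored.drop(index="miR-23a")
        )
        rep = hemolysis_check(no23a, sheet)
        assert rep.loc["CTRL03", "hemolysis_rule"] == "single_marker"
        flagged = set(rep.index[rep["hemolysis_risk"]])
        assert flagged == {"CTRL03"}
        # the two-marker rule flags it as well (delta jumps by 6 cycles)
        rep2 = hemolysis_check(matrix, sheet)
        assert bool(rep2.loc["CTRL03", "hemolysis_risk"])

    def test_mir451_absent_is_instructive_error(self):
        m = make_matrix({"miR-1-3p": [20.0]}, ["s1"])
        with pytest.raises(ValueError, match="disable"):
            hemolysis_check(m)


class TestSpikeIn:
    def test_flat_spikein_never_fails(self):
        m = make_matrix({SPIKE_IN: [20.0, 20.0, 20.0]}, ["s1", "s2", "s3"])
        rep = spikein_check(m, [SPIKE_IN])
        assert (rep["spikein_delta"] == 0).all()
        assert not rep["spikein_fail"].any()

    def test_deviant_sample_fails(self):
        m = make_matrix({SPIKE_IN: [20.0, 20.0, 23.5]}, ["s1", "s2", "s3"])
        rep = spikein_check(m, [SPIKE_IN], max_delta=2.0)
        assert list(rep.index[rep["spikein_fail"]]) == ["s3"]

    def test_generator_injected_failure_is_flagged(self):
        cfg = SimConfig(seed=5, spikein_fail_samples=("OT04",))
        matrix, sheet, _, _ = simulate_cohort(cfg)
        mask = call_expressed(matrix)
        rep = qc_report(matrix, mask, sheet, spikein_names=[SPIKE_IN])
        assert set(rep.index[rep["spikein_fail"]]) == {"OT04"}

    def test_missing_spikein_is_error(self):
        m = make_matrix({"miR-1": [20.0]}, ["s1"])
        with pytest.raises(ValueError, match="cel-miR-39-3p"):
            spikein_check(m, [SPIKE_IN])


class TestGlobalMeanNormalize:
    def test_uniform_sample_centers_to_zero(self):
        m = make_matrix({"a": [30.0], "b": [30.0], "c": [30.0]}, ["s1"])
        norm = global_mean_normalize(m, call_expressed(m))
        assert (norm.delta_ct["s1"] == 0).all()
        assert (norm.linear["s1"] == 1.0).all()

    def test_two_assay_split(self):
        m = make_matrix({"a": [25.0], "b": [35.0]}, ["s1"])
        norm = global_mean_normalize(m, call_expressed(m))
        assert norm.delta_ct.loc["a", "s1"] == pytest.approx(-5.0)
        assert norm.delta_ct.loc["b", "s1"] == pytest.approx(5.0)
        assert norm.linear.loc["a", "s1"] == pytest.approx(32.0)
        assert norm.linear.loc["b", "s1"] == pytest.approx(1 / 32)

    def test_hand_oracle_with_censored_cell(self):
        # s1 mean over {24,30,36} = 30; s2 mean over {26,34} = 30 (B censored)
        m = make_matrix({"A": [24.0, 26.0], "B": [30.0, np.nan], "C": [36.0, 34.0]},
                        ["s1", "s2"])
        norm = global_mean_normalize(m, call_expressed(m))
        expected = toy_ct_frame(
            {"A": [-6.0, -4.0], "B": [0.0, np.nan], "C": [6.0, 4.0]}, ["s1", "s2"]
        )
        pd.testing.assert_frame_equal(norm.delta_ct, expected)

    def test_spikeins_excluded_from_sample_mean(self):
        m = make_matrix({"a": [25.0], "b": [35.0], SPIKE_IN: [10.0]}, ["s1"])
        norm = global_mean_normalize(m, call_expressed(m), [SPIKE_IN])
        assert norm.sample_mean_ct["s1"] == pytest.approx(30.0)

    def test_sample_with_no_expressed_assays_is_error(self):
        m = make_matrix({"a": [30.0, 39.0], "b": [31.0, np.nan]}, ["s1", "s2"])
        with pytest.raises(ValueError, match="s2"):
            global_mean_normalize(m, call_expressed(m, 37.0))


@st.composite
def random_ct_matrix(draw):
    n_assays = draw(st.integers(2, 8))
    n_samples = draw(st.integers(1, 5))
    seed = draw(st.integers(0, 2**20))
    rng = np.random.default_rng(seed)
    ct = rng.uniform(20, 36, (n_assays, n_samples))
    censor = rng.random((n_assays, n_samples)) < 0.15
    values = pd.DataFrame(
        np.where(censor, np.nan, ct),
        index=[f"miR-x{i}-3p" for i in range(n_assays)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    # ensure every sample keeps at least one expressed assay
    values.iloc[0] = rng.uniform(20, 36, n_samples)
    return CtMatrix(values, values.isna())


@settings(derandomize=True, max_examples=60)
@given(random_ct_matrix())
def test_per_sample_delta_ct_mean_is_zero(matrix):
    """Centering conservation: included assays average to 0 per sample."""
    mask = call_expressed(matrix)
    norm = global_mean_normalize(matrix, mask)
    included = norm.delta_ct.loc[mask.global_set].where(mask.expressed)
    assert np.allclose(included.mean(axis=0, skipna=True), 0.0, atol=1e-9)
    assert (norm.linear.stack() > 0).all()


@settings(derandomize=True, max_examples=60)
@given(random_ct_matrix(), st.floats(-3, 3))
def test_shift_invariance(matrix, c):
    """Adding a constant to every Ct of one sample leaves delta_ct unchanged."""
    mask = call_expressed(matrix, ct_threshold=50)  # keep calls identical post-shift
    norm = global_mean_normalize(matrix, mask)
    shifted_values = matrix.values.copy()
    shifted_values.iloc[:, 0] = shifted_values.iloc[:, 0] + c
    shifted = CtMatrix(shifted_values, shifted_values.isna())
    norm2 = global_mean_normalize(shifted, call_expressed(shifted, ct_threshold=50))
    pd.testing.assert_frame_equal(norm.delta_ct, norm2.delta_ct, atol=1e-9, rtol=0)


def test_linear_strictly_decreasing_in_ct():
    """Holding the sample mean fixed, a lower Ct gives a higher linear level."""
    m = make_matrix({"a": [25.0], "b": [35.0]}, ["s1"])
    norm = global_mean_normalize(m, call_expressed(m))
    lo = 2.0 ** (-(24.0 - norm.sample_mean_ct["s1"]))
    assert lo > norm.linear.loc["a", "s1"]
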