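"""Observer-agreement statistics against brute-force and scipy oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cinedenoise import (
    build_table,
    exvivo_comparison,
    paired_differences,
    paired_ttest,
    pearson_r,
    significance_stars,
)

positive_vectors = st.lists(st.floats(1.0, 1000.0), min_size=4, max_size=12)


class TestPairedDifferences:
    def test_identical_measurements_all_zero(self):
        out = paired_differences([3.0, 4.0, 5.0], [3.0, 4.0, 5.0])
        assert out == (0.0, 0.0, 0.0, 0.0)

    def test_definition_arithmetic(self):
        mean_diff, _, mean_rel, _ = paired_differences([110.0, 110.0], [90.0, 90.0])
        assert mean_diff == pytest.approx(20.0)
        assert mean_rel == pytest.approx(20.0)

    def test_matches_spreadsheet_oracle(self):
        rng = np.random.default_rng(10)
        ref = rng.uniform(50, 150, 10)
        oth = ref + rng.normal(0, 5, 10)
        got = paired_differences(ref, oth)
        # hand-rolled recomputation, plain Python
        d = [a - b for a, b in zip(ref, oth)]
        rel = [100 * (a - b) / ((a + b) / 2) for a, b in zip(ref, oth)]

        def mean(v):
            return sum(v) / len(v)

        def sd(v):
            m = mean(v)
            return math.sqrt(sum((x - m) ** 2 for x in v) / (len(v) - 1))

        expected = (mean(d), sd(d), mean(rel), sd(rel))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_zero_average_pair_named_in_error(self):
        with pytest.raises(ValueError, match="pair 1"):
            paired_differences([5.0, 2.0], [3.0, -2.0])

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            paired_differences([110.0], [90.0])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(a=positive_vectors, b=positive_vectors)
    def test_swapping_arguments_negates_means(self, a, b):
        n = min(len(a), len(b))
        a, b = a[:n], b[:n]
        fwd = paired_differences(a, b)
        rev = paired_differences(b, a)
        assert fwd[0] == pytest.approx(-rev[0], abs=1e-9)
        assert fwd[2] == pytest.approx(-rev[2], abs=1e-9)


class TestPearsonR:
    def test_perfect_linear_relation(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_r(a, 2 * a + 3) == pytest.approx(1.0)
        assert pearson_r(a, -a) == pytest.approx(-1.0)

    def test_matches_scipy(self):
        rng = np.random.default_rng(11)
        a = rng.normal(size=20)
        b = 0.5 * a + rng.normal(size=20)
        assert pearson_r(a, b) == pytest.approx(stats.pearsonr(a, b).statistic, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPairedTtest:
    def test_identical_vectors_null_case(self):
        assert paired_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (0.0, 1.0)

    def test_symmetric_differences_give_zero_t(self):
        a = np.zeros(6)
        b = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        t, p = paired_ttest(a, b)
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_matches_scipy_ttest_rel(self):
        rng = np.random.default_rng(12)
        a = rng.normal(10, 2, 10)
        b = a + rng.normal(0.5, 1, 10)
        t, p = paired_ttest(a, b)
        ref = stats.ttest_rel(a, b)
        assert t == pytest.approx(ref.statistic, abs=1e-9)
        assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_constant_nonzero_differences_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            paired_ttest([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])


class TestExvivoComparison:
    def test_proportional_bias(self):
        gold = np.array([400.0, 600.0, 800.0])
        mean_pct, sd_pct, r = exvivo_comparison(1.05 * gold, gold)
        assert mean_pct == pytest.approx(5.0)
        assert sd_pct == pytest.approx(0.0)
        assert r == pytest.approx(1.0)

    def test_denominator_is_gold_not_average(self):
        mean_pct, _, _ = exvivo_comparison([110.0, 210.0, 440.0], [100.0, 200.0, 400.0])
        assert mean_pct == pytest.approx((10.0 + 5.0 + 10.0) / 3)

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(13)
        gold = rng.uniform(400, 1000, 8)
        img = gold * rng.uniform(0.9, 1.1, 8)
        mean_pct, sd_pct, r = exvivo_comparison(img, gold)
        pct = [100 * (i - g) / g for i, g in zip(img, gold)]
        m = sum(pct) / len(pct)
        s = math.sqrt(sum((x - m) ** 2 for x in pct) / (len(pct) - 1))
        assert mean_pct == pytest.approx(m, abs=1e-12)
        assert sd_pct == pytest.approx(s, abs=1e-12)

    def test_zero_gold_rejected(self):
        with pytest.raises(ValueError):
            exvivo_comparison([1.0, 2.0, 3.0], [1.0, 0.0, 3.0])


class TestSignificanceStars:
    @pytest.mark.parametrize("p,stars", [
        (0.2, ""), (0.05, "*"), (0.02, "*"), (0.01, "**"),
        (0.005, "**"), (0.001, "***"), (1e-6, "***"), (float("nan"), ""),
    ])
    def test_three_thresholds(self, p, stars):
        assert significance_stars(p) == stars


def _measurements(n_subjects=5, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    base = {"EDV": 500.0, "ESV": 150.0, "EF": 70.0, "LVM": 700.0}
    for condition in ("raw", "aniso", "tv", "ornlm"):
        for s in range(n_subjects):
            subject_scale = 1.0 + 0.1 * s
            for observer, repeat in ((1, 1), (1, 2), (2, 1)):
                for parameter, value in base.items():
                    rows.append({
                        "condition": condition, "subject": s,
                        "observer": observer, "repeat": repeat,
                        "parameter": parameter,
                        "value": value * subject_scale + rng.normal(0, noise),
                    })
    return pd.DataFrame(rows)


class TestBuildTable:
    def test_structure_four_conditions_by_four_parameters(self):
        table = build_table(_measurements(noise=1.0))
        for study in ("intra", "inter"):
            sub = table[table["study"] == study]
            assert len(sub) == 16
            assert set(sub["condition"]) == {"raw", "aniso", "tv", "ornlm"}

    def test_perfect_observers_give_zero_rows_without_stars(self):
        table = build_table(_measurements(noise=0.0))
        assert (table["mean_diff"] == 0).all()
        assert (table["stars"] == "").all()

    def test_gold_rows_for_both_observers(self):
        meas = _measurements(noise=1.0)
        gold = {s: 700.0 * (1.0 + 0.1 * s) for s in range(5)}
        table = build_table(meas, lvm_gold=gold)
        goldrows = table[table["study"] == "gold"]
        assert len(goldrows) == 8  # 4 conditions x 2 observers
        assert (goldrows["parameter"] == "LVM").all()

    def test_missing_repeat_drops_row(self, caplog):
        meas = _measurements(noise=1.0)
        meas = meas[~((meas["observer"] == 1) & (meas["repeat"] == 2))]
        table = build_table(meas)
        assert (table["study"] == "intra").sum() == 0
        assert (table["study"] == "inter").sum() == 16

    def test_deterministic(self):
        meas = _measurements(noise=2.0, seed=3)
        pd.testing.assert_frame_equal(build_table(meas), build_table(meas))
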