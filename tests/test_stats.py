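"""Agreement statistics: exact reproduction of published worked examples,
closed-form oracles, and distributional properties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

from microbic.stats import (
    build_agreement_table,
    classify_strength,
    paired_t_from_pairs,
    paired_t_from_summary,
    pearson_from_pairs,
    pearson_p_from_r,
    round2,
)

# Published two-sided P-values recomputable from their printed (r, n) inputs.
CORRELATION_CASES = [
    (0.74, 6, 0.09),  # implant group, 0-degree plane
    (0.46, 6, 0.36),  # TCP group
    (0.30, 6, 0.56),  # BMP-2 group
    (0.84, 6, 0.04),  # implant group, multi-angle mean
    (0.81, 6, 0.05),  # 45-degree plane
    (0.71, 6, 0.11),  # 90-degree plane
    (0.41, 6, 0.42),  # 135-degree plane
]

# Paired t-tests from printed (mean difference, SD, n).
PAIRED_CASES = [
    (5.07, 9.44, 6, 0.25),  # implant group
    (-2.14, 9.17, 6, 0.59),  # TCP group
    (6.03, 21.01, 6, 0.51),  # BMP-2 group
]


@pytest.mark.parametrize("r,n,expected_p", CORRELATION_CASES)
def test_published_correlation_p_values_reproduce(r, n, expected_p):
    res = pearson_p_from_r(r, n)
    assert res.p_value_2dp == pytest.approx(expected_p)


@pytest.mark.parametrize("mean_diff,sd_diff,n,expected_p", PAIRED_CASES)
def test_published_paired_t_p_values_reproduce(mean_diff, sd_diff, n, expected_p):
    res = paired_t_from_summary(mean_diff, sd_diff, n)
    assert res.p_value_2dp == pytest.approx(expected_p)


def test_mean_differences_from_published_group_means():
    groups = [(67.02, 61.95, 5.07), (31.94, 34.08, -2.14), (47.97, 41.94, 6.03)]
    for mean_hist, mean_uct, expected in groups:
        assert round2(mean_hist - mean_uct) == pytest.approx(expected)


class TestPearson:
    def test_identity_and_anti_identity(self):
        x = [1.0, 2.0, 4.0, 4.5, 7.0, 9.0]
        assert pearson_from_pairs(x, x).r == pytest.approx(1.0)
        assert pearson_from_pairs(x, [-v for v in x]).r == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 4.0, 6.0, 9.0])
        # from-scratch covariance / variance computation
        r_direct = ((x - x.mean()) * (y - y.mean())).sum() / math.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert pearson_from_pairs(x, y).r == pytest.approx(r_direct, abs=1e-12)

    def test_zero_variance_and_length_mismatch(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson_from_pairs([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError, match="mismatch"):
            pearson_from_pairs([1, 2], [1, 2, 3])

    def test_r_of_zero_gives_p_one(self):
        assert pearson_p_from_r(0.0, 10).p_value == pytest.approx(1.0)

    def test_perfect_correlation_limit_flagged(self):
        res = pearson_p_from_r(1.0, 6)
        assert res.at_limit and res.p_value == 0.0

    @settings(deadline=None, derandomize=True)
    @given(
        r=st.floats(0.01, 0.95),
        delta=st.floats(0.01, 0.04),
        n=st.integers(4, 30),
    )
    def test_p_strictly_decreasing_in_abs_r_and_sign_invariant(self, r, delta, n):
        lo = pearson_p_from_r(r, n).p_value
        hi = pearson_p_from_r(r + delta, n).p_value
        assert hi < lo
        assert pearson_p_from_r(-r, n).p_value == pytest.approx(lo)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        scale=st.floats(0.1, 50.0),
        shift=st.floats(-100.0, 100.0),
        seed=st.integers(0, 2**16),
    )
    def test_affine_invariance_positive_slope(self, scale, shift, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        base = pearson_from_pairs(x, y).r
        transformed = pearson_from_pairs(scale * x + shift, y).r
        assert transformed == pytest.approx(base, abs=1e-9)


class TestPairedT:
    def test_identical_pairs_give_p_one(self):
        x = [3.0, 4.0, 5.5]
        res = paired_t_from_pairs(x, list(x))
        assert res.p_value == 1.0 and res.mean_diff == 0.0
        res = paired_t_from_summary(0.0, 1.0, 6)
        assert res.p_value == pytest.approx(1.0)
        assert res.mean_diff == 0.0

    def test_hand_computed_t_statistic(self):
        # x=(1,2,3), y=(0,0,0): differences mean 2, sd 1, n 3 -> t = 2*sqrt(3)
        res = paired_t_from_pairs([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert res.t_stat == pytest.approx(2.0 * math.sqrt(3.0), abs=1e-9)
        assert res.t_stat == pytest.approx(3.464, abs=1e-3)

    def test_pairs_consistent_with_summary(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(60, 10, size=6), rng.normal(55, 12, size=6)
        d = x - y
        from_pairs = paired_t_from_pairs(x, y)
        from_summary = paired_t_from_summary(d.mean(), d.std(ddof=1), 6)
        assert from_pairs.p_value == pytest.approx(from_summary.p_value)
        assert from_pairs.mean_diff == pytest.approx(from_pairs.mean_a - from_pairs.mean_b)

    def test_sign_invariance_and_errors(self):
        assert paired_t_from_summary(-2.14, 9.17, 6).p_value == pytest.approx(
            paired_t_from_summary(2.14, 9.17, 6).p_value
        )
        with pytest.raises(ValueError):
            paired_t_from_summary(1.0, 0.0, 6)
        with pytest.raises(ValueError):
            paired_t_from_summary(1.0, 1.0, 1)


def _t_pdf(x, df):
    c = math.gamma((df + 1) / 2.0) / (math.sqrt(df * math.pi) * math.gamma(df / 2.0))
    return c * (1.0 + x * x / df) ** (-(df + 1) / 2.0)


@pytest.mark.parametrize("r,n", [(0.74, 6), (0.41, 6), (0.3, 10)])
def test_p_values_agree_with_density_integration_oracle(r, n):
    """Two-sided tail probabilities match numerical integration of the
    Student-t density written from its closed form."""
    res = pearson_p_from_r(r, n)
    tail, _ = integrate.quad(_t_pdf, abs(res.t_stat), np.inf, args=(n - 2,))
    assert res.p_value == pytest.approx(2.0 * tail, abs=1e-6)


class TestStrengthLabels:
    @pytest.mark.parametrize(
        "r,label",
        [
            (0.74, "strong"),
            (0.46, "moderate"),
            (0.30, "weak"),
            (0.41, "moderate"),
            (-0.75, "strong"),
            (0.39, "weak"),
            (0.70, "strong"),
        ],
    )
    def test_labels(self, r, label):
        assert classify_strength(r) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_strength(1.2)


class TestAgreementTable:
    def test_perfect_agreement_row(self):
        x = np.array([60.0, 65.0, 70.0, 58.0, 63.0, 72.0])
        table = build_agreement_table({"g": (x, x.copy() + 0.0)})
        row = table.loc["g"]
        assert row.mean_diff == 0.0
        assert row.r == pytest.approx(1.0)
        assert row.paired_t_p == pytest.approx(1.0)

    def test_rows_equal_individual_statistics(self):
        rng = np.random.default_rng(8)
        groups = {
            name: (rng.normal(60, 8, 6), rng.normal(55, 10, 6)) for name in ("a", "b")
        }
        table = build_agreement_table(groups)
        for name, (x, y) in groups.items():
            assert table.loc[name, "r"] == pytest.approx(pearson_from_pairs(x, y).r)
            assert table.loc[name, "paired_t_p"] == pytest.approx(paired_t_from_pairs(x, y).p_value)

    def test_degenerate_group_errors(self):
        with pytest.raises(ValueError):
            build_agreement_table({"g": ([1.0], [2.0])})
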