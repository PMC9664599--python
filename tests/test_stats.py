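"""Statistical operations against independent hand/brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hospicost import (
    compare_groups,
    eta_squared,
    inr_to_usd,
    kruskal_wallis,
    lowess_curve,
    median_iqr,
    pearson_r,
    spearman_r,
)
from hospicost.errors import DomainError
from hospicost.report import format_p, format_usd


def kruskal_oracle(groups):
    """Brute-force H from explicit ranks (no ties): H = 12/(N(N+1)) Σ n_i R̄_i² − 3(N+1)."""
    flat = np.concatenate(groups)
    order = flat.argsort()
    ranks = np.empty(len(flat))
    ranks[order] = np.arange(1, len(flat) + 1)
    N = len(flat)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += len(g) * r.mean() ** 2
        start += len(g)
    return 12.0 / (N * (N + 1)) * h - 3 * (N + 1)


class TestMedianIqr:
    def test_singleton(self):
        assert median_iqr([5]) == {"median": 5.0, "q1": 5.0, "q3": 5.0}

    def test_even_length_symmetry(self):
        assert median_iqr([1, 2, 3, 4])["median"] == pytest.approx(2.5)

    def test_lognormal_simulation_recovers_median(self):
        rng = np.random.default_rng(31)
        m = 52.0
        draws = m * np.exp(0.5 * rng.standard_normal(1000))
        assert abs(median_iqr(draws)["median"] / m - 1) < 0.05

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            median_iqr([])


class TestKruskalWallis:
    def test_three_group_hand_case(self):
        # ranks 1..9 split consecutively: H = 7.2 by hand
        out = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert out["H"] == pytest.approx(7.2)

    def test_identical_groups_h_zero(self):
        out = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert out["H"] == pytest.approx(0.0)
        assert out["p"] == pytest.approx(1.0)

    def test_single_group_rejected(self):
        with pytest.raises(DomainError):
            kruskal_wallis([[1, 2, 3]])
        with pytest.raises(DomainError):
            kruskal_wallis([[1, 2], []])

    def test_matches_exhaustive_rank_oracle_small_n(self):
        """All-distinct data, total n <= 8, many random splits into 2-3 groups."""
        rng = np.random.default_rng(77)
        for _ in range(200):
            n = int(rng.integers(4, 9))
            vals = rng.permutation(np.arange(1, 50))[:n] + rng.uniform(0, 0.4, n)
            k = int(rng.integers(2, 4))
            cuts = sorted(rng.choice(np.arange(1, n), size=k - 1, replace=False))
            groups = np.split(vals, cuts)
            if any(len(g) == 0 for g in groups):
                continue
            got = kruskal_wallis([g.tolist() for g in groups])["H"]
            assert got == pytest.approx(kruskal_oracle(groups), rel=1e-10)

    def test_two_groups_equals_ranksum_equivalent(self):
        """For two groups the tie-free H equals the squared standardized
        Wilcoxon rank-sum statistic (checked by enumeration over placements)."""
        vals = np.arange(1.0, 7.0)  # n = 6 distinct values
        for idx in itertools.combinations(range(6), 2):
            a = vals[list(idx)]
            b = np.delete(vals, list(idx))
            H = kruskal_wallis([a.tolist(), b.tolist()])["H"]
            n1, n2, N = len(a), len(b), 6
            ranks = vals  # values are their own ranks
            R1 = ranks[list(idx)].sum()
            expected = (R1 - n1 * (N + 1) / 2) ** 2 / (n1 * n2 * (N + 1) / 12)
            assert H == pytest.approx(expected, rel=1e-10)


class TestEtaSquared:
    def test_null_expectation_is_zero(self):
        assert eta_squared(2.0, 3, 100)["eta2"] == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "H,k,n,expected,label",
        [
            (10.0, 3, 100, 8 / 97, "moderate"),
            (20.0, 3, 50, 18 / 47, "large"),
            (3.0, 3, 203, 1 / 200, "below_small"),
            (4.0, 3, 202, 0.01005025, "small"),
            (1.0, 3, 100, -1 / 97, "below_small"),  # H < k-1: negative, reported as-is
        ],
    )
    def test_hand_grid(self, H, k, n, expected, label):
        out = eta_squared(H, k, n)
        assert out["eta2"] == pytest.approx(expected, rel=1e-6)
        assert out["effect_label"] == label

    @pytest.mark.parametrize(
        "eta2,label", [(0.01, "small"), (0.06, "moderate"), (0.14, "large"), (0.0099, "below_small")]
    )
    def test_label_boundaries(self, eta2, label):
        # choose H so that (H - k + 1)/(n - k) hits the bin edge exactly
        k, n = 3, 103
        H = eta2 * (n - k) + k - 1
        assert eta_squared(H, k, n)["effect_label"] == label

    def test_n_not_greater_than_k_rejected(self):
        with pytest.raises(DomainError):
            eta_squared(5.0, 3, 3)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1)["r"] == pytest.approx(1.0)

    def test_perfect_inverse(self):
        x = np.arange(10.0)
        assert pearson_r(x, -x)["r"] == pytest.approx(-1.0)

    def test_five_point_hand_covariance(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 8.0])
        y = np.array([3.0, 1.0, 4.0, 7.0, 6.0])
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert pearson_r(x, y)["r"] == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(DomainError):
            pearson_r([1, 1, 1], [1, 2, 3])

    @given(
        a=st.floats(0.1, 10),
        b=st.floats(-5, 5),
        c=st.floats(0.1, 10),
        d=st.floats(-5, 5),
    )
    @settings(max_examples=100, deadline=None)
    def test_affine_invariance_and_sign_flip(self, a, b, c, d):
        rng = np.random.default_rng(5)
        x = rng.normal(size=30)
        y = rng.normal(size=30) + 0.5 * x
        r0 = pearson_r(x, y)["r"]
        assert pearson_r(a * x + b, c * y + d)["r"] == pytest.approx(r0, rel=1e-9)
        assert pearson_r(-x, y)["r"] == pytest.approx(-r0, rel=1e-9)

    def test_spearman_option(self):
        x = np.arange(20.0)
        assert spearman_r(x, np.exp(x))["r"] == pytest.approx(1.0)


class TestLowess:
    def test_reproduces_linear_data(self):
        x = np.linspace(0, 10, 50)
        y = 3 * x + 2
        cx, cy = lowess_curve(x, y)
        assert np.max(np.abs(cy - (3 * cx + 2))) < 1e-6 * np.ptp(y)

    def test_monotone_on_convex_decreasing(self):
        x = np.linspace(1, 10, 80)
        cx, cy = lowess_curve(x, 1.0 / x)
        assert (np.diff(cy) <= 1e-9).all()

    def test_u_shape_minimum_interior(self):
        x = np.linspace(-3, 3, 120)
        rng = np.random.default_rng(8)
        y = x**2 + rng.normal(0, 0.1, x.size)
        cx, cy = lowess_curve(x, y, span=0.4)
        imin = int(np.argmin(cy))
        assert 0 < imin < len(cx) - 1
        assert abs(cx[imin]) < 1.0

    def test_degenerate_x_rejected(self):
        with pytest.raises(DomainError):
            lowess_curve(np.ones(20), np.arange(20.0))

    def test_strictly_increasing_curve_x(self):
        rng = np.random.default_rng(9)
        x = rng.choice(np.arange(30.0), size=40, replace=True)
        cx, _ = lowess_curve(x, x + rng.normal(0, 1, 40))
        assert (np.diff(cx) > 0).all()


class TestCurrency:
    def test_rate_identity(self):
        assert inr_to_usd(76.21) == pytest.approx(1.0)

    def test_presentation_rounding(self):
        assert format_usd(inr_to_usd(185.0)) == "2.43"
        assert format_usd(inr_to_usd(5690.0)) == "75"

    def test_p_value_formatting(self):
        assert format_p(0.00012) == "< 0.0005"
        assert format_p(0.3831) == "0.3831"


class TestCompareGroups:
    def test_same_data_both_groups_h_zero(self):
        vals = [3.0, 1.0, 4.0, 1.5, 9.0]
        df = pd.DataFrame({"g": ["a"] * 5 + ["b"] * 5, "v": vals * 2})
        comp = compare_groups(df, "g", "v")
        assert comp.H == pytest.approx(0.0)
        assert comp.p == pytest.approx(1.0)

    def test_shifted_groups_detected_with_large_effect(self):
        rng = np.random.default_rng(13)
        df = pd.DataFrame(
            {
                "g": np.repeat(["a", "b", "c"], 40),
                "v": np.concatenate(
                    [rng.normal(0, 1, 40), rng.normal(3, 1, 40), rng.normal(6, 1, 40)]
                ),
            }
        )
        comp = compare_groups(df, "g", "v")
        assert comp.p < 1e-6
        assert comp.effect_label == "large"
        assert comp.k == 3 and comp.n_total == 120

    def test_undefined_outcomes_filtered(self):
        df = pd.DataFrame(
            {"g": ["a", "a", "a", "b", "b", "b"], "v": [1.0, np.nan, 2.0, 3.0, 4.0, np.inf]}
        )
        comp = compare_groups(df, "g", "v")
        assert comp.n_total == 4

    def test_fewer_than_two_groups_rejected(self):
        df = pd.DataFrame({"g": ["a"] * 4, "v": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(DomainError):
            compare_groups(df, "g", "v")
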