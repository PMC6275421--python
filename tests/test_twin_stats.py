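"""Pearson correlation, its p-value, pooling and the Falconer partition."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from twinct.ct_io import TwinDesign
from twinct.normalization import ExpressionMatrix
from twinct.twin_stats import (CorrelationError, correlation_pvalue,
                               falconer_h2, pearson_r, zygosity_correlation)


def sigma_formula_r(x, y):
    """Independent oracle: Pearson r via the direct Σ formulas."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = math.sqrt(n * sxx - sx * sx) * math.sqrt(n * syy - sy * sy)
    return num / den


class TestPearsonR:
    def test_identical_vectors(self):
        assert pearson_r([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # n=4, Σxy=28, Σx=Σy=10, Σx²=Σy²=30 → r = (112-100)/20 = 0.6
        assert pearson_r([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_negated_vector(self):
        x = [1.0, 2.0, 4.0]
        assert pearson_r(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_nan_entries_dropped_pairwise(self):
        x = [1.0, 2.0, 3.0, 4.0, np.nan]
        y = [2.0, 1.0, 4.0, 3.0, 100.0]
        assert pearson_r(x, y) == pytest.approx(0.6)

    def test_constant_side_is_named(self):
        with pytest.raises(CorrelationError, match="second"):
            pearson_r([1, 2, 3], [5, 5, 5])

    def test_too_few_observations(self):
        with pytest.raises(CorrelationError):
            pearson_r([1, 2], [3, 4])

    def test_matches_sigma_formula_oracle_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = rng.integers(3, 21)
            x = rng.normal(size=n)
            y = rng.normal(size=n) + 0.5 * x
            r = pearson_r(x, y)
            assert r == pytest.approx(sigma_formula_r(list(x), list(y)), rel=1e-12)

    @given(a=st.floats(min_value=0.1, max_value=10), b=st.floats(min_value=-5, max_value=5))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_affine_invariance(self, a, b):
        x = np.array([0.3, 1.7, 2.2, 4.8, 5.1])
        y = np.array([1.1, 0.4, 2.9, 3.0, 4.2])
        r0 = pearson_r(x, y)
        assert pearson_r(a * x + b, y) == pytest.approx(r0, abs=1e-9)
        assert pearson_r(-a * x + b, y) == pytest.approx(-r0, abs=1e-9)


class TestCorrelationPvalue:
    def test_null_correlation_gives_one(self):
        assert correlation_pvalue(0.0, 10) == pytest.approx(1.0)

    def test_matches_t_distribution_oracle(self):
        # t = 0.6325·√8/√(1−0.4) ≈ 2.31 on 8 df → p ≈ 0.0496
        r, n = 0.6325, 10
        t = r * math.sqrt(n - 2) / math.sqrt(1 - r * r)
        expected = 2 * stats.t.sf(t, n - 2)
        assert correlation_pvalue(r, n) == pytest.approx(expected, rel=1e-12)
        assert correlation_pvalue(r, n) == pytest.approx(0.0496, abs=5e-4)

    def test_exact_fit_returns_zero(self):
        assert correlation_pvalue(1.0, 5) == 0.0

    def test_strictly_decreasing_in_abs_r_and_n(self):
        rs = [0.1, 0.3, 0.5, 0.7, 0.9]
        ps = [correlation_pvalue(r, 12) for r in rs]
        assert all(p1 > p2 for p1, p2 in zip(ps, ps[1:]))
        ns = [5, 10, 20, 40]
        ps = [correlation_pvalue(0.4, n) for n in ns]
        assert all(p1 > p2 for p1, p2 in zip(ps, ps[1:]))


class TestZygosityCorrelation:
    def _expr_design(self, vectors):
        """vectors: {pair_id: (zygosity, a_values, b_values)}"""
        rows, cols, data = [], [], {}
        for pair_id, (zyg, a, b) in vectors.items():
            for member, vals in (("A", a), ("B", b)):
                sample = f"{pair_id}{member}"
                data[sample] = vals
                rows.append((sample, pair_id, member, zyg))
        design = TwinDesign(pd.DataFrame(rows, columns=["sample_id", "pair_id", "member", "zygosity"]))
        n = len(next(iter(data.values())))
        expr = ExpressionMatrix(pd.DataFrame(data, index=[f"m{i}" for i in range(n)]))
        return expr, design

    def test_identical_member_vectors_give_r_one(self):
        v = [1.0, 2.0, 5.0, 3.0]
        expr, design = self._expr_design({"P1": ("monozygotic", v, v)})
        res = zygosity_correlation(expr, design, "monozygotic")
        assert res.r == pytest.approx(1.0) and res.n == 4

    def test_equal_per_pair_r_is_fixed_point_of_pooling(self):
        a = [1.0, 2.0, 3.0, 4.0]
        b = [2.0, 1.0, 4.0, 3.0]  # r = 0.6 within each pair
        expr, design = self._expr_design({
            "P1": ("dizygotic", a, b),
            "P2": ("dizygotic", a, b),
        })
        res = zygosity_correlation(expr, design, "dizygotic")
        assert res.r == pytest.approx(0.6, abs=1e-12)
        assert res.n == 8
        assert set(res.per_pair) == {"P1", "P2"}

    def test_flagged_mirnas_dropped_pairwise(self):
        a = [1.0, 2.0, 3.0, 4.0, np.nan]
        b = [2.0, 1.0, 4.0, 3.0, 9.0]
        expr, design = self._expr_design({"P1": ("monozygotic", a, b)})
        res = zygosity_correlation(expr, design, "monozygotic")
        assert res.r == pytest.approx(0.6) and res.n == 4

    def test_no_pairs_of_requested_zygosity(self):
        expr, design = self._expr_design({"P1": ("monozygotic", [1, 2, 3], [1, 2, 3])})
        with pytest.raises(CorrelationError):
            zygosity_correlation(expr, design, "dizygotic")


class TestFalconerH2:
    def test_published_partition(self):
        est = falconer_h2(0.61, 0.15)
        assert est.h2_raw == pytest.approx(0.92)
        assert est.h2_clamped == pytest.approx(0.92)
        assert est.environment_share == pytest.approx(0.08)

    def test_classic_additive_case(self):
        assert falconer_h2(0.5, 0.25).h2_raw == pytest.approx(0.5)

    def test_negative_raw_clamps_to_zero(self):
        est = falconer_h2(0.2, 0.3)
        assert est.h2_raw == pytest.approx(-0.2)
        assert est.h2_clamped == 0.0
        assert est.environment_share == 1.0

    def test_out_of_range_correlation_rejected(self):
        with pytest.raises(ValueError, match="r_mz"):
            falconer_h2(1.5, 0.0)

    @given(r=st.floats(min_value=-1, max_value=1))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_equal_correlations_give_zero_h2(self, r):
        assert falconer_h2(r, r).h2_raw == 0.0

    @given(r_mz=st.floats(min_value=-1, max_value=1), r_dz=st.floats(min_value=-1, max_value=1))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_shares_always_sum_to_one(self, r_mz, r_dz):
        est = falconer_h2(r_mz, r_dz)
        assert 0.0 <= est.h2_clamped <= 1.0
        assert est.h2_clamped + est.environment_share == pytest.approx(1.0)
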