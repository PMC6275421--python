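"""Discordance folds, binning and genetics-vs-environment grouping."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twinct.ct_io import TwinDesign
from twinct.discordance import (HIGH, LOW, MODERATE, NOT_EXPRESSED,
                                BinThresholds, DiscordanceRecord,
                                assign_group, bin_counts,
                                classify_discordance, discordance_fold,
                                pair_discordance, zygosity_composite_folds)
from twinct.normalization import ExpressionMatrix

dct = st.floats(min_value=-5.0, max_value=25.0)


def _rec(mirna, fold, zygosity="dizygotic", thresholds=BinThresholds()):
    return DiscordanceRecord(mirna, "P", zygosity, None, None, fold,
                             NOT_EXPRESSED if fold is None else classify_discordance(fold, thresholds))


class TestDiscordanceFold:
    @pytest.mark.parametrize("a,b,expected", [
        (9.07, 16.08, 128.89),   # fraternal miR-181d
        (10.82, 10.05, 1.70),    # identical miR-29a
    ])
    def test_published_fold_values(self, a, b, expected):
        assert discordance_fold(a, b) == pytest.approx(expected, abs=0.01)

    def test_equal_expression_means_fold_one(self):
        assert discordance_fold(12.3, 12.3) == 1.0

    @given(a=dct, b=dct)
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_symmetric_at_least_one_and_log_exact(self, a, b):
        f = discordance_fold(a, b)
        assert f == discordance_fold(b, a)
        assert f >= 1.0
        assert math.log2(f) == pytest.approx(abs(a - b), abs=1e-12)


class TestClassifyDiscordance:
    @pytest.mark.parametrize("fold,expected", [
        (128.89, HIGH),
        (10.63, HIGH),
        (1.97, LOW),
        (2.0, MODERATE),    # boundaries are moderate: bins use strict inequalities
        (10.0, MODERATE),
        (5.0, MODERATE),
    ])
    def test_examples(self, fold, expected):
        assert classify_discordance(fold) == expected

    def test_fold_below_one_rejected(self):
        with pytest.raises(ValueError):
            classify_discordance(0.5)

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ValueError):
            BinThresholds(low_below=12.0, high_above=10.0)

    @given(fold=st.floats(min_value=1.0, max_value=1e6))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_bins_partition_finite_folds(self, fold):
        assert classify_discordance(fold) in {LOW, MODERATE, HIGH}

    @given(d1=st.floats(min_value=0, max_value=20), d2=st.floats(min_value=0, max_value=20))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_monotone_in_delta_delta_ct(self, d1, d2):
        """A larger |ΔΔCt| never moves the bin from high toward low."""
        order = {LOW: 0, MODERATE: 1, HIGH: 2}
        lo, hi = sorted((d1, d2))
        assert order[classify_discordance(2.0 ** lo)] <= order[classify_discordance(2.0 ** hi)]


class TestPairDiscordance:
    def _expr(self, data, samples):
        return ExpressionMatrix(pd.DataFrame(data, columns=samples))

    def test_two_mirnas_one_pair(self, one_pair_design):
        expr = self._expr({"P1A": [5.0, 3.0], "P1B": [5.0, 8.0]}, ["P1A", "P1B"])
        expr.values.index = ["m1", "m2"]
        recs = pair_discordance(expr, one_pair_design)
        by_name = {r.mirna: r for r in recs}
        assert by_name["m1"].fold == pytest.approx(1.0) and by_name["m1"].bin == LOW
        assert by_name["m2"].fold == pytest.approx(32.0) and by_name["m2"].bin == HIGH

    def test_empty_mirna_set(self, one_pair_design):
        expr = ExpressionMatrix(pd.DataFrame(columns=["P1A", "P1B"], dtype=float))
        recs = pair_discordance(expr, one_pair_design)
        assert recs == []
        assert bin_counts(recs).empty

    def test_flagged_mirna_carries_not_expressed_bin(self, one_pair_design):
        expr = self._expr({"P1A": [np.nan, 4.0], "P1B": [5.0, 4.5]}, ["P1A", "P1B"])
        expr.values.index = ["m1", "m2"]
        recs = {r.mirna: r for r in pair_discordance(expr, one_pair_design)}
        assert recs["m1"].bin == NOT_EXPRESSED and recs["m1"].fold is None
        counts = bin_counts(list(recs.values()))
        assert int(counts.loc["monozygotic"].sum()) == 1  # flagged record excluded

    def test_missing_member_sample_is_design_error(self, one_pair_design):
        from twinct.ct_io import DesignError
        expr = self._expr({"P1A": [5.0]}, ["P1A"])
        with pytest.raises(DesignError, match="P1B"):
            pair_discordance(expr, one_pair_design)


class TestCompositeFolds:
    def test_single_pair_is_identity(self):
        recs = [_rec("m1", 32.0)]
        pooled = zygosity_composite_folds(recs, "dizygotic")
        assert pooled["m1"].fold == pytest.approx(32.0)

    def test_geometric_mean_of_two_pairs(self):
        recs = [_rec("m1", 4.0), _rec("m1", 16.0)]
        pooled = zygosity_composite_folds(recs, "dizygotic")
        assert pooled["m1"].fold == pytest.approx(8.0)  # 2^((2+4)/2)

    def test_all_pairs_flagged_stays_not_expressed(self):
        recs = [_rec("m1", None), _rec("m1", None)]
        pooled = zygosity_composite_folds(recs, "dizygotic")
        assert pooled["m1"].bin == NOT_EXPRESSED


class TestAssignGroup:
    @pytest.mark.parametrize("mirna,frat_fold,ident_fold,expected", [
        ("miR-129-3P", 8248.98, 1.00, "A"),  # high fraternal, low identical: genetic
        ("miR-181b", 61.81, 837.53, "B"),    # high in both, identical larger: environment
        ("miR-17", 123.63, 22.16, "C"),      # high in both, fraternal larger: mixed
        ("miR-92a", 1.00, 10.92, "D"),       # high identical only
        ("miR-x", 5.0, 5.0, "none"),         # moderate in both: unclassified
        ("miR-y", 128.0, 5.0, "none"),       # high fraternal, moderate identical
    ])
    def test_rule(self, mirna, frat_fold, ident_fold, expected):
        g = assign_group(_rec(mirna, frat_fold), _rec(mirna, ident_fold, "monozygotic"))
        assert g.group == expected

    def test_equal_high_folds_tie_goes_to_b(self):
        g = assign_group(_rec("m", 50.0), _rec("m", 50.0, "monozygotic"))
        assert g.group == "B"

    def test_not_expressed_gives_none_with_flag(self):
        g = assign_group(_rec("m", None), _rec("m", 12.0, "monozygotic"))
        assert g.group == "none" and g.not_expressed

    def test_mismatched_mirnas_rejected(self):
        with pytest.raises(ValueError):
            assign_group(_rec("m1", 12.0), _rec("m2", 12.0, "monozygotic"))
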