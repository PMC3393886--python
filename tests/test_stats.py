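"""t-tests, split-plot ANOVA (with an independent library oracle), correlations."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cppherit import (
    bonferroni_alpha,
    correlation_matrix,
    display_alpha,
    paired_t,
    rm_anova,
    unpaired_t,
)
from cppherit.stats import UnbalancedDesignError


class TestBonferroni:
    @pytest.mark.parametrize(
        "k,exact,displayed",
        [(3, 0.05 / 3, 0.017), (4, 0.0125, 0.013), (6, 0.05 / 6, 0.0083), (1, 0.05, 0.05)],
    )
    def test_thresholds_and_display(self, k, exact, displayed):
        a = bonferroni_alpha(0.05, k)
        assert a == exact
        assert display_alpha(a) == displayed

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)

    @given(
        alpha=st.floats(0.001, 1.0, allow_nan=False),
        k=st.integers(1, 1000),
    )
    @settings(max_examples=50, deadline=None)
    def test_threshold_times_k_recovers_alpha(self, alpha, k):
        assert bonferroni_alpha(alpha, k) * k == pytest.approx(alpha, rel=1e-12)


class TestPairedT:
    def test_identical_pairs(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p_value == 1.0 and res.degenerate

    def test_hand_computed_example(self):
        # differences (1, 2, 3): mean 2, sd 1 -> t = 2*sqrt(3)
        res = paired_t([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(2 * math.sqrt(3), rel=1e-12)
        assert res.df == 2

    def test_constant_nonzero_difference_degenerate(self):
        res = paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert res.degenerate and res.statistic == math.inf and res.p_value == 0.0

    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=20))
    @settings(max_examples=40, deadline=None)
    def test_antisymmetry(self, xs):
        rng = np.random.default_rng(0)
        ys = rng.normal(0, 1, len(xs))
        a = paired_t(np.asarray(xs), ys)
        b = paired_t(ys, np.asarray(xs))
        assert a.statistic == pytest.approx(-b.statistic, rel=1e-9, abs=1e-12)


class TestUnpairedT:
    def test_identical_groups(self):
        res = unpaired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0

    def test_separated_groups(self):
        res = unpaired_t([0.0, 0.001], [1.0, 0.999])
        assert abs(res.statistic) > 100 and res.p_value < 1e-3

    def test_matches_pooled_formula_on_toy_groups(self):
        x = np.array([1.0, 2.0, 4.0])
        y = np.array([2.0, 5.0, 6.0])
        # direct pooled-variance computation
        sp2 = ((x.var(ddof=1) * 2) + (y.var(ddof=1) * 2)) / 4
        t_direct = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / 3 + 1 / 3))
        res = unpaired_t(x, y, pooled=True)
        assert res.statistic == pytest.approx(t_direct, rel=1e-12)
        assert res.df == 4


def _long(Y, groups=None):
    """subjects x days array -> long table."""
    n, b = Y.shape
    rows = []
    for i in range(n):
        for j in range(b):
            rows.append(
                {
                    "animal_id": f"s{i}",
                    "day": j + 1,
                    "value": Y[i, j],
                    "group": None if groups is None else groups[i],
                }
            )
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_constant_data_gives_zero_f(self):
        out = rm_anova(_long(np.full((4, 3), 7.0)))
        assert out["within"].statistic == 0.0 and out["within"].degenerate

    def test_df_pattern_mixed_design(self):
        rng = np.random.default_rng(1)
        Y = rng.normal(0, 1, (62, 3))
        groups = ["LG"] * 31 + ["SM"] * 31
        out = rm_anova(_long(Y, groups), between="group")
        assert out["within"].df == (2, 120)
        assert out["between"].df == (1, 60)
        assert out["interaction"].df == (2, 120)

    def test_matches_pingouin_mixed_anova(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        Y = rng.normal(0, 1, (16, 3)) + np.array([0.0, 0.4, 0.8])
        groups = ["a"] * 8 + ["b"] * 8
        df = _long(Y, groups)
        ours = rm_anova(df, between="group")
        ref = pg.mixed_anova(
            data=df, dv="value", within="day", subject="animal_id", between="group"
        ).set_index("Source")
        assert ours["between"].statistic == pytest.approx(ref.loc["group", "F"], rel=1e-6)
        assert ours["within"].statistic == pytest.approx(ref.loc["day", "F"], rel=1e-6)
        assert ours["interaction"].statistic == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-6
        )

    def test_matches_pingouin_within_only(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        Y = rng.normal(0, 1, (10, 4)) + rng.normal(0, 1, (10, 1))
        df = _long(Y)
        ours = rm_anova(df)
        ref = pg.rm_anova(data=df, dv="value", within="day", subject="animal_id")
        assert ours["within"].statistic == pytest.approx(ref["F"].iloc[0], rel=1e-6)
        assert ours["within"].p_value == pytest.approx(ref["p_unc"].iloc[0], rel=1e-6)

    def test_injected_day_effect_detected(self):
        rng = np.random.default_rng(4)
        Y = rng.normal(0, 1, (40, 3)) + np.array([0.0, 1.0, 2.0])
        out = rm_anova(_long(Y))
        assert out["within"].p_value < 1e-6

    def test_unbalanced_rejected(self):
        df = _long(np.zeros((4, 3)))
        with pytest.raises(UnbalancedDesignError):
            rm_anova(df.iloc[:-1])


class TestCorrelations:
    def test_diagonal_and_symmetry(self, study):
        ph = study["phenotypes"]
        res = correlation_matrix(ph, ["D1_pref", "D8_CPP", "D8_minus_D1"])
        assert np.allclose(np.diag(res.r), 1.0)
        assert res.r.equals(res.r.T)

    def test_constant_trait_is_missing_not_zero(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [5.0, 5.0, 5.0, 5.0]})
        res = correlation_matrix(df, ["a", "b"])
        assert np.isnan(res.r.loc["a", "b"]) and np.isnan(res.p.loc["a", "b"])

    def test_null_correlations_mostly_small(self):
        rng = np.random.default_rng(5)
        hits = 0
        reps = 200
        for _ in range(reps):
            df = pd.DataFrame(rng.normal(0, 1, (105, 2)), columns=["x", "y"])
            r = correlation_matrix(df, ["x", "y"]).r.loc["x", "y"]
            hits += abs(r) < 0.2
        assert hits / reps > 0.90  # ~95% expected under the null at n=105

    def test_d8_cpp_correlates_with_gain_contrast(self, study):
        # D8 = D1-noise + gain: the contrast shares the gain term
        res = correlation_matrix(study["phenotypes"], ["D8_CPP", "D8_minus_D1"])
        assert res.r.loc["D8_CPP", "D8_minus_D1"] > 0.3
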