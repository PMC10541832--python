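"""Agreement statistics: ICC(2,1), Pearson, Bland-Altman."""

import numpy as np
import pytest
from scipy import stats as sps

from dloplan import (
    RatingsTable,
    bland_altman,
    compare_methods,
    icc_two_way_random_absolute,
    interpret_icc,
    pearson,
)
from dloplan.agreement import _anova_mean_squares, agree_within
from dloplan.errors import DegenerateDataError

# a small two-rater table with hand-checkable ANOVA arithmetic
HAND_TABLE = np.array([
    [9.0, 10.0],
    [11.0, 12.0],
    [14.0, 13.0],
    [8.0, 9.0],
    [12.0, 14.0],
    [10.0, 10.0],
])


def _icc21_brute_force(x: np.ndarray) -> float:
    """Direct ANOVA decomposition, written out independently."""
    n, k = x.shape
    grand = x.mean()
    msr = k * ((x.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((x.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    sse = ((x - x.mean(axis=1, keepdims=True)
            - x.mean(axis=0, keepdims=True) + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestIcc:
    def test_identical_columns_give_unity(self):
        x = np.column_stack([HAND_TABLE[:, 0], HAND_TABLE[:, 0]])
        icc, ci = icc_two_way_random_absolute(RatingsTable(x))
        assert icc == pytest.approx(1.0, abs=1e-12)
        assert ci[0] <= icc <= ci[1] + 1e-12

    def test_constant_offset_penalized_under_absolute_agreement(self):
        base = HAND_TABLE[:, 0]
        x = np.column_stack([base, base + 10.0])
        icc, _ = icc_two_way_random_absolute(RatingsTable(x))
        # consistency ICC of the same data is exactly 1; absolute agreement
        # must be substantially lower
        assert icc < 0.5

    def test_hand_table_matches_brute_force(self):
        icc, _ = icc_two_way_random_absolute(RatingsTable(HAND_TABLE))
        assert icc == pytest.approx(_icc21_brute_force(HAND_TABLE), abs=1e-12)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        n, k = HAND_TABLE.shape
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "score": HAND_TABLE.ravel(),
        })
        res = pingouin.intraclass_corr(df, targets="subject", raters="rater",
                                       ratings="score")
        # single-measure, two-way random, absolute agreement row; its label
        # varies across pingouin versions ("ICC2" vs "ICC(A,1)")
        mask = res["Type"].isin(["ICC2", "ICC(A,1)"])
        ref = res.loc[mask].iloc[0]
        ci_col = "CI95%" if "CI95%" in res.columns else "CI95"
        icc, ci = icc_two_way_random_absolute(RatingsTable(HAND_TABLE))
        assert icc == pytest.approx(ref["ICC"], abs=1e-9)
        assert ci[0] == pytest.approx(ref[ci_col][0], abs=0.01)
        assert ci[1] == pytest.approx(ref[ci_col][1], abs=0.01)

    def test_shift_invariance_of_whole_table(self):
        a, _ = icc_two_way_random_absolute(RatingsTable(HAND_TABLE))
        b, _ = icc_two_way_random_absolute(RatingsTable(HAND_TABLE + 100.0))
        assert a == pytest.approx(b, abs=1e-12)

    def test_column_shift_breaks_agreement(self):
        shifted = HAND_TABLE.copy()
        shifted[:, 1] += 5.0
        a, _ = icc_two_way_random_absolute(RatingsTable(HAND_TABLE))
        b, _ = icc_two_way_random_absolute(RatingsTable(shifted))
        assert b < a

    def test_degenerate_table_rejected(self):
        with pytest.raises(DegenerateDataError):
            icc_two_way_random_absolute(RatingsTable(np.full((5, 2), 3.0)))
        with pytest.raises(DegenerateDataError):
            RatingsTable(np.ones((2, 2)))
        with pytest.raises(DegenerateDataError):
            RatingsTable(np.array([[1.0, np.nan], [2, 2], [3, 3]]))


class TestInterpretIcc:
    @pytest.mark.parametrize("icc,band", [
        (0.95, "excellent"),
        (0.91, "excellent"),
        (0.90, "reasonable"),
        (0.80, "reasonable"),
        (0.75, "moderate"),
        (0.60, "moderate"),
        (0.50, "poor"),
        (0.30, "poor"),
        (-0.2, "poor"),
    ])
    def test_bands(self, icc, band):
        assert interpret_icc(icc) == band

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            interpret_icc(1.5)


class TestPearson:
    def test_perfect_positive_affine(self):
        x = np.array([1.0, 2, 3, 5, 8])
        r, p = pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p == 0.0

    def test_perfect_negative(self):
        x = np.array([1.0, 2, 3, 5])
        r, _ = pearson(x, -x)
        assert r == pytest.approx(-1.0)

    def test_matches_scipy_on_hand_data(self):
        x = np.array([2.0, 4.0, 5.0, 7.0, 9.0])
        y = np.array([3.1, 3.9, 6.2, 6.8, 9.5])
        r, p = pearson(x, y)
        ref = sps.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_affine_invariance(self):
        x = np.array([2.0, 4.0, 5.0, 7.0, 9.0])
        y = np.array([3.1, 3.9, 6.2, 6.8, 9.5])
        r1, _ = pearson(x, y)
        r2, _ = pearson(3.0 * x + 7.0, 0.5 * y - 2.0)
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBlandAltman:
    def test_identical_series(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        ba = bland_altman(x, x)
        assert ba["ba_bias"] == 0.0
        assert ba["ba_loa"] == (0.0, 0.0)

    def test_hand_arithmetic(self):
        # differences {1, 2, 3}: bias 2, SD 1, LoA (0.04, 3.96)
        x = np.array([2.0, 4.0, 6.0])
        y = np.array([1.0, 2.0, 3.0])
        ba = bland_altman(x, y)
        assert ba["ba_bias"] == pytest.approx(2.0)
        assert ba["ba_loa"][0] == pytest.approx(0.04, abs=1e-9)
        assert ba["ba_loa"][1] == pytest.approx(3.96, abs=1e-9)
        lo, hi = ba["ba_loa"]
        assert lo <= ba["ba_bias"] <= hi

    def test_length_mismatch_rejected(self):
        with pytest.raises(DegenerateDataError):
            bland_altman([1.0, 2.0, 3.0], [1.0, 2.0])

    def test_agree_within_verdict(self):
        x = np.array([10.0, 10.1, 9.9, 10.05, 9.95])
        res = compare_methods(x, x + np.array([0.02, -0.01, 0.0, 0.01, -0.02]))
        assert agree_within(res, 1.0)
        assert not agree_within(res, 0.001)


def test_compare_methods_bundle_consistency():
    rng = np.random.default_rng(0)
    x = rng.normal(10, 2, size=30)
    y = x + rng.normal(0, 0.1, size=30)
    res = compare_methods(x, y, label="toy")
    assert res.icc > 0.99
    assert res.pearson_r > 0.99
    assert res.icc_ci95[0] <= res.icc <= res.icc_ci95[1]
    assert res.ba_loa[0] <= res.ba_bias <= res.ba_loa[1]
    assert interpret_icc(res.icc) == "excellent"
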