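"""ICC, ANOVA mean squares, Bland-Altman and reliability labels."""

import numpy as np
import pytest

from sleepcal import (
    RatingsMatrix,
    bland_altman_stats,
    classify_icc,
    icc_single,
    two_way_mean_squares,
)


def oracle_mean_squares(x):
    """Term-by-term sums of squares straight from the definitions."""
    n, k = x.shape
    grand = x.mean()
    ss_rows = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_err = sum(
        (x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    return ss_rows / (n - 1), ss_cols / (k - 1), ss_err / ((n - 1) * (k - 1))


def oracle_icc(x, form):
    msr, msc, mse = oracle_mean_squares(x)
    n, k = x.shape
    if form == "consistency":
        return (msr - mse) / (msr + (k - 1) * mse)
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


class TestMeanSquares:
    def test_hand_anova_on_six_values(self):
        sq = two_way_mean_squares(RatingsMatrix([[1, 2], [2, 3], [3, 4]]))
        assert sq.ms_rows == pytest.approx(2.0)
        assert sq.ms_cols == pytest.approx(1.5)
        assert sq.ms_err == pytest.approx(0.0, abs=1e-12)

    def test_identical_columns_give_zero_msc_mse(self):
        x = np.array([[1.0, 1.0], [2.5, 2.5], [4.0, 4.0]])
        sq = two_way_mean_squares(RatingsMatrix(x))
        assert sq.ms_cols == pytest.approx(0.0, abs=1e-12)
        assert sq.ms_err == pytest.approx(0.0, abs=1e-12)

    def test_matches_definition_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 30))
            k = int(rng.integers(2, 5))
            x = rng.normal(size=(n, k)) * 3 + 5
            sq = two_way_mean_squares(RatingsMatrix(x))
            msr, msc, mse = oracle_mean_squares(x)
            assert sq.ms_rows == pytest.approx(msr, abs=1e-10)
            assert sq.ms_cols == pytest.approx(msc, abs=1e-10)
            assert sq.ms_err == pytest.approx(mse, abs=1e-10)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            RatingsMatrix([[1, 2], [3, 4]])

    def test_missing_cells_rejected(self):
        with pytest.raises(ValueError):
            RatingsMatrix([[1, np.nan], [3, 4], [5, 6]])


class TestICC:
    def test_perfect_agreement_is_one_with_unit_ci(self):
        x = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0], [5.0, 5.0]])
        for form in ("absolute", "consistency"):
            r = icc_single(RatingsMatrix(x), form)
            assert r.estimate == pytest.approx(1.0)
            assert r.ci_high == pytest.approx(1.0)

    def test_additive_bias_separates_the_forms(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        x = np.column_stack([base, base + 1.0])
        r_con = icc_single(RatingsMatrix(x), "consistency")
        r_abs = icc_single(RatingsMatrix(x), "absolute")
        assert r_con.estimate == pytest.approx(1.0)
        assert r_abs.estimate < 1.0

    def test_consistency_invariant_absolute_decreasing_in_bias(self, rng):
        base = rng.normal(5, 1, 20)
        noise = rng.normal(0, 0.3, 20)
        prev_abs = None
        ref_con = None
        for c in (0.0, 0.5, 1.0, 2.0):
            x = np.column_stack([base, base + noise + c])
            r_abs = icc_single(RatingsMatrix(x), "absolute").estimate
            r_con = icc_single(RatingsMatrix(x), "consistency").estimate
            if ref_con is None:
                ref_con = r_con
            assert r_con == pytest.approx(ref_con, abs=1e-10)
            if prev_abs is not None:
                assert r_abs < prev_abs
            prev_abs = r_abs

    def test_known_variance_components_at_large_n(self, rng):
        # rows sigma^2 = 4, residual sigma^2 = 1, no column effect -> ICC = 0.8
        n = 6000
        x = rng.normal(0, 2, (n, 1)) + rng.normal(0, 1, (n, 2))
        for form in ("absolute", "consistency"):
            r = icc_single(RatingsMatrix(x), form)
            assert r.estimate == pytest.approx(0.8, abs=0.02)
            assert r.ci_low <= r.estimate <= r.ci_high

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 64))
            x = rng.normal(5, 1, (n, 1)) + rng.normal(0, 0.5, (n, 2))
            for form in ("absolute", "consistency"):
                mine = icc_single(RatingsMatrix(x), form).estimate
                assert mine == pytest.approx(oracle_icc(x, form), abs=1e-10)

    def test_matches_pingouin_reference(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        for _ in range(10):
            n = int(rng.integers(4, 40))
            x = rng.normal(5, 1, (n, 1)) + rng.normal(0, 0.6, (n, 2)) \
                + np.array([0.0, float(rng.normal(0, 0.5))])
            df = pd.DataFrame({
                "t": np.repeat(np.arange(n), 2),
                "r": np.tile(["a", "b"], n),
                "s": x.ravel(),
            })
            ref = pg.intraclass_corr(df, targets="t", raters="r", ratings="s").set_index("Type")
            for form, key in (("absolute", "ICC(A,1)"), ("consistency", "ICC(C,1)")):
                mine = icc_single(RatingsMatrix(x), form)
                assert mine.estimate == pytest.approx(ref.loc[key, "ICC"], abs=1e-6)
                lo, hi = ref.loc[key, "CI95"]
                # the reference prints CIs rounded to 2 decimals
                assert mine.ci_low == pytest.approx(lo, abs=5.1e-3)
                assert mine.ci_high == pytest.approx(hi, abs=5.1e-3)

    def test_negative_lower_bound_possible(self, rng):
        # strong device offset with weak row signal drives the absolute
        # lower confidence bound below zero
        base = rng.normal(6, 0.3, 10)
        x = np.column_stack([base + rng.normal(0, 0.3, 10) - 1.0, base])
        r = icc_single(RatingsMatrix(x), "absolute")
        assert r.ci_low < 0 <= 1.0


class TestBlandAltman:
    def test_equal_pairs_all_zero(self):
        s = bland_altman_stats([(5.0, 5.0), (6.0, 6.0)])
        assert s.mean_diff == s.max_diff == s.min_diff == 0.0

    def test_hand_arithmetic(self):
        s = bland_altman_stats([(5.0, 6.0), (6.0, 6.0), (7.0, 6.0)])
        assert s.mean_diff == pytest.approx(0.0)
        assert s.max_diff == pytest.approx(1.0)
        assert s.min_diff == pytest.approx(-1.0)
        assert s.sd_diff == pytest.approx(1.0)
        assert s.loa_low == pytest.approx(-1.96)
        assert s.loa_high == pytest.approx(1.96)

    def test_order_invariant(self, rng):
        pairs = rng.normal(6, 1, (30, 2))
        s = bland_altman_stats(pairs)
        assert s.min_diff <= s.mean_diff <= s.max_diff

    def test_sign_convention_test_minus_ref(self):
        s = bland_altman_stats([(5.0, 6.0), (5.5, 6.5), (5.1, 6.2)])
        assert s.mean_diff < 0  # test underestimates -> negative

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            bland_altman_stats([(5.0, 5.0)])


@pytest.mark.parametrize(
    "value,label",
    [
        (0.49, "poor"),
        (0.5, "moderate"),
        (0.56, "moderate"),
        (0.69, "moderate"),
        (0.75, "good"),
        (0.78, "good"),
        (0.82, "good"),
        (0.9, "excellent"),
        (0.91, "excellent"),
        (0.96, "excellent"),
        (-0.2, "poor"),
    ],
)
def test_icc_labels(value, label):
    assert classify_icc(value) == label
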