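"""Method-comparison statistics: Bland-Altman, paired t, ICC, CR, relative change."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from octamag import (
    PairedSample,
    bland_altman,
    bland_altman_from_summary,
    cr_exceedance,
    evaluate_agreement,
    format_report,
    icc_absolute,
    paired_t,
    relative_change,
    report_to_dict,
)
from octamag.agreement import format_p
from octamag.errors import (
    InsufficientDataError,
    InvalidDenominatorError,
    PairingError,
    UndefinedStatisticError,
)


def _sample(a, b):
    a = np.asarray(a, dtype=float)
    return PairedSample(tuple(range(a.size)), a, np.asarray(b, dtype=float))


class TestBlandAltman:
    def test_summary_and_raw_routes_agree(self, rng):
        a = rng.normal(24.0, 1.0, 40)
        b = a + rng.normal(0.05, 0.3, 40)
        res_raw = bland_altman(_sample(a, b))
        d = a - b
        res_sum = bland_altman_from_summary(d.mean(), d.std(ddof=1), 40)
        assert res_raw.mean_diff == pytest.approx(res_sum.mean_diff, abs=1e-12)
        assert res_raw.loa_lower == pytest.approx(res_sum.loa_lower, abs=1e-12)
        assert res_raw.loa_upper_ci == pytest.approx(res_sum.loa_upper_ci, abs=1e-12)

    def test_constant_differences_collapse_loa_to_a_point(self):
        res = bland_altman(_sample([1.0, 2.0, 3.0], [0.5, 1.5, 2.5]))
        assert res.sd_diff == 0.0
        assert res.loa_lower == res.loa_upper == pytest.approx(0.5)
        assert res.loa_lower_ci == (res.loa_lower, res.loa_lower)

    def test_loa_width_is_twice_coverage_times_sd(self):
        res = bland_altman_from_summary(0.1, 0.4, 50)
        assert res.loa_width == pytest.approx(2 * 1.96 * 0.4, rel=1e-12)
        half = bland_altman_from_summary(0.1, 0.2, 50)
        assert half.loa_width == pytest.approx(res.loa_width / 2, rel=1e-12)

    @given(
        d=hnp.arrays(np.float64, st.integers(3, 30),
                     elements=st.floats(-5, 5, allow_nan=False)),
    )
    @settings(max_examples=60, deadline=None)
    def test_antisymmetry_under_method_swap(self, d):
        a = np.linspace(20, 25, d.size)
        s = _sample(a, a - d)
        res = bland_altman(s)
        res_swapped = bland_altman(s.swapped())
        assert res_swapped.mean_diff == pytest.approx(-res.mean_diff, abs=1e-10)
        assert res_swapped.loa_lower == pytest.approx(-res.loa_upper, abs=1e-10)
        assert res_swapped.loa_upper == pytest.approx(-res.loa_lower, abs=1e-10)

    def test_exact_t_intervals_are_wider_than_approx(self):
        approx = bland_altman_from_summary(0.01, 0.5, 20, ci_method="approx")
        exact = bland_altman_from_summary(0.01, 0.5, 20, ci_method="exact-t")
        assert (exact.loa_lower_ci[1] - exact.loa_lower_ci[0]) > (
            approx.loa_lower_ci[1] - approx.loa_lower_ci[0]
        )

    def test_single_pair_is_insufficient(self):
        with pytest.raises(InsufficientDataError):
            bland_altman_from_summary(0.1, 0.2, 1)


class TestPairedT:
    def test_raw_and_summary_routes_agree(self, rng):
        a = rng.normal(0.25, 0.05, 30)
        b = a + rng.normal(0.002, 0.01, 30)
        t_raw, df_raw, p_raw = paired_t(_sample(a, b))
        d = a - b
        t_sum, df_sum, p_sum = paired_t(
            mean_diff=d.mean(), sd_diff=d.std(ddof=1), n=30
        )
        assert t_raw == pytest.approx(t_sum, abs=1e-10)
        assert df_raw == df_sum == 29
        assert p_raw == pytest.approx(p_sum, abs=1e-10)

    def test_zero_mean_difference_gives_t_zero_p_one(self):
        t, df, p = paired_t(mean_diff=0.0, sd_diff=0.3, n=25)
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_zero_sd_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            paired_t(mean_diff=0.1, sd_diff=0.0, n=10)


class TestICC:
    def test_identical_methods_give_perfect_agreement(self):
        a = [0.20, 0.25, 0.31, 0.18, 0.27]
        icc, ci = icc_absolute(_sample(a, a))
        assert icc == pytest.approx(1.0, abs=1e-12)

    def test_large_constant_offset_drives_icc_toward_zero(self):
        a = np.array([0.20, 0.21, 0.22, 0.20, 0.21])
        icc, _ = icc_absolute(_sample(a, a + 5.0))
        assert icc < 0.01

    def test_matches_hand_computed_mean_squares_oracle(self):
        # 6 subjects x 2 methods; oracle computed from the two-way ANOVA
        # decomposition written out longhand below.
        a = np.array([1.2, 2.1, 3.3, 0.9, 2.5, 1.8])
        b = np.array([1.3, 2.0, 3.1, 1.1, 2.6, 1.7])
        x = np.column_stack([a, b])
        n, k = x.shape
        grand = x.mean()
        msr = k * ((x.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((x.mean(axis=0) - grand) ** 2).sum() / (k - 1)
        mse = (((x - grand) ** 2).sum()
               - k * ((x.mean(axis=1) - grand) ** 2).sum()
               - n * ((x.mean(axis=0) - grand) ** 2).sum()) / ((n - 1) * (k - 1))
        oracle = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        icc, _ = icc_absolute(_sample(a, b))
        assert icc == pytest.approx(oracle, abs=1e-8)

    def test_matches_independent_pingouin_implementation(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        a = np.array([0.21, 0.33, 0.18, 0.29, 0.24, 0.40, 0.26, 0.31])
        b = a + np.array([0.01, -0.02, 0.015, 0.0, -0.01, 0.02, -0.005, 0.01])
        icc, ci = icc_absolute(_sample(a, b))
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(8), 2),
            "rater": ["m1", "m2"] * 8,
            "value": np.column_stack([a, b]).ravel(),
        })
        tab = pingouin.intraclass_corr(long, targets="subject", raters="rater",
                                       ratings="value")
        row = tab[tab["Type"] == "ICC2"].iloc[0] if "ICC2" in set(tab["Type"]) \
            else tab[tab["Type"] == "ICC(A,1)"].iloc[0]
        assert icc == pytest.approx(row["ICC"], abs=1e-9)
        np.testing.assert_allclose(np.round(ci, 2), row["CI95"], atol=0.011)

    def test_zero_total_variance_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            icc_absolute(_sample([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]))

    def test_fewer_than_three_subjects_insufficient(self):
        with pytest.raises(InsufficientDataError):
            icc_absolute(_sample([1.0, 2.0], [1.1, 2.1]))


class TestCRExceedance:
    def test_identical_vectors_never_exceed(self):
        assert cr_exceedance([0.2, 0.3], [0.2, 0.3]) == 0.0

    def test_strict_inequality_count(self):
        ref = np.zeros(4)
        method = np.array([0.06, 0.01, 0.051, 0.053])
        assert cr_exceedance(method, ref, cr=0.052) == pytest.approx(50.0)

    def test_differences_exactly_at_cr_do_not_count(self):
        ref = np.array([0.2, 0.3, 0.4])
        assert cr_exceedance(ref + 0.052, ref, cr=0.052) == 0.0

    def test_length_mismatch_raises(self):
        with pytest.raises(PairingError):
            cr_exceedance([0.1, 0.2], [0.1])


class TestRelativeChange:
    def test_definition(self):
        res = relative_change([0.30], [0.285])
        assert res.per_pair_pct[0] == pytest.approx(5.0)

    def test_identical_values_change_zero(self):
        res = relative_change([0.2, 0.3], [0.2, 0.3])
        assert res.max_relative_pct == 0.0

    def test_per_pair_and_maxima(self):
        res = relative_change([0.2, 0.4], [0.25, 0.38])
        np.testing.assert_allclose(res.per_pair_pct, [25.0, 5.0])
        assert res.max_relative_pct == pytest.approx(25.0)
        assert res.max_absolute == pytest.approx(0.05)

    def test_nonpositive_reference_raises(self):
        with pytest.raises(InvalidDenominatorError):
            relative_change([0.0, 0.2], [0.1, 0.2])


class TestReport:
    def test_full_report_fields_and_invariants(self, rng):
        a = rng.normal(0.25, 0.06, 46)
        b = a + rng.normal(0.002, 0.012, 46)
        report = evaluate_agreement(_sample(a, b), cr=0.052)
        assert report.df == 45
        assert report.bland_altman.loa_lower <= report.bland_altman.mean_diff
        assert report.icc <= 1.0
        assert 0.0 <= report.p_value <= 1.0
        d = report_to_dict(report)
        assert set(d) >= {"mean_diff", "loa_lower_ci", "icc", "t_stat",
                          "cr_exceedance_pct", "max_relative_change_pct"}

    def test_p_value_display_floors_at_0_005(self):
        assert format_p(0.0001) == "< 0.005"
        assert format_p(0.527) == "0.527"

    def test_formatted_table_mentions_direction_and_loa(self, rng):
        a = rng.normal(24, 1, 20)
        b = a + rng.normal(0, 0.4, 20)
        text = format_report(evaluate_agreement(_sample(a, b)))
        assert "Lower LoA" in text and "Direction" in text and "ICC" in text
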