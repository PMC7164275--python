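"""Unit and property tests for the agreement indices (ICC, CV,
Bland-Altman)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rhinostat as rs
from rhinostat.errors import (
    AgreementUndefinedError,
    DesignError,
    MissingDataError,
    PositivityError,
)
from oracles import anova_oracle, icc_oracle, percentile_oracle


# ---------------------------------------------------------------------------
# repeated-measures container
# ---------------------------------------------------------------------------

def test_repeated_measures_rejects_small_and_missing():
    with pytest.raises(DesignError):
        rs.RepeatedMeasures([[1.0, 2.0]])  # single subject
    with pytest.raises(DesignError):
        rs.RepeatedMeasures([[1.0], [2.0]])  # single replicate
    with pytest.raises(MissingDataError):
        rs.RepeatedMeasures([[1.0, np.nan], [2.0, 3.0]])


def test_from_long_drops_incomplete_subjects():
    import pandas as pd

    df = pd.DataFrame({
        "subject_id": ["a", "a", "b", "b", "c"],
        "value": [1.0, 2.0, 3.0, 4.0, 5.0],
    })
    rm = rs.RepeatedMeasures.from_long(df)
    assert rm.subject_ids == ["a", "b"]
    assert rm.values.shape == (2, 2)


# ---------------------------------------------------------------------------
# one-way ANOVA
# ---------------------------------------------------------------------------

def test_anova_zero_within_spread():
    vc = rs.anova_oneway([[1, 1], [2, 2], [3, 3]])
    assert vc.ms_within == 0.0
    assert vc.sigma2_within == 0.0
    assert vc.ms_between == pytest.approx(2 * 2.0 / 2 * 1.0)  # k*var([1,2,3])


def test_anova_constant_table_degenerate():
    vc = rs.anova_oneway([[4.0] * 3] * 4)
    assert vc.ms_between == 0.0 and vc.ms_within == 0.0


def test_anova_matches_bruteforce_oracle():
    table = [[1, 2], [2, 4], [3, 6], [4, 8]]
    msb, msw = anova_oracle(table)
    vc = rs.anova_oneway(table)
    assert vc.ms_between == pytest.approx(msb, rel=1e-12)
    assert vc.ms_within == pytest.approx(msw, rel=1e-12)
    assert vc.sigma2_between == pytest.approx((msb - msw) / 2, rel=1e-12)
    assert vc.df_between == 3 and vc.df_within == 4


# ---------------------------------------------------------------------------
# ICC estimation and test
# ---------------------------------------------------------------------------

def test_icc_perfect_agreement():
    res = rs.icc_oneway([[5, 5], [7, 7], [9, 9]])
    assert res.estimate == 1.0
    assert res.p_value == 0.0
    assert np.isinf(res.f_statistic)
    assert res.benchmark == "excellent"


def test_icc_undefined_on_constant_table():
    with pytest.raises(AgreementUndefinedError):
        rs.icc_oneway([[3.0, 3.0], [3.0, 3.0]])


def test_icc_matches_integration_oracle():
    table = [[1, 3], [2, 2], [6, 4], [5, 7]]
    est, p = icc_oracle(table, rho0=0.20)
    res = rs.icc_oneway(table, rho0=0.20)
    assert res.estimate == pytest.approx(est, rel=1e-12)
    assert res.p_value == pytest.approx(p, rel=1e-8)


def test_icc_rho0_zero_is_classical_f_test():
    rng = np.random.default_rng(3)
    x = rng.normal(0, 1, (6, 4)) + rng.normal(0, 1, (6, 1))
    res = rs.icc_oneway(x, rho0=0.0)
    vc = res.components
    assert res.f_statistic == pytest.approx(vc.ms_between / vc.ms_within, rel=1e-14)


def test_icc_from_components_identity():
    rng = np.random.default_rng(4)
    x = rng.normal(5, 1, (8, 3)) + rng.normal(0, 2, (8, 1))
    res = rs.icc_oneway(x)
    vc = res.components
    assert vc.sigma2_between >= 0
    assert res.estimate == pytest.approx(
        vc.sigma2_between / (vc.sigma2_between + vc.sigma2_within), rel=1e-12
    )


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    shift=st.floats(-100, 100, allow_nan=False),
    scale=st.floats(0.01, 50, allow_nan=False),
)
def test_icc_affine_invariance(shift, scale):
    """ICC is a variance ratio: invariant to shifting and positive scaling."""
    rng = np.random.default_rng(5)
    x = rng.normal(5, 1, (7, 4)) + rng.normal(0, 1.5, (7, 1))
    base = rs.icc_oneway(x).estimate
    assert rs.icc_oneway(x * scale + shift).estimate == pytest.approx(
        base, rel=1e-9, abs=1e-9
    )


def test_icc_pvalue_decreases_with_f(
):
    """At fixed degrees of freedom, stronger subject separation (larger F)
    gives a smaller p."""
    rng = np.random.default_rng(6)
    noise = rng.normal(0, 1, (8, 3))
    subj = rng.normal(0, 1, (8, 1))
    weak = rs.icc_oneway(noise + 0.5 * subj)
    strong = rs.icc_oneway(noise + 3.0 * subj)
    assert strong.f_statistic > weak.f_statistic
    assert strong.p_value < weak.p_value


def test_icc_matches_pingouin_icc1():
    """Cross-check against an independent implementation (pingouin ICC1)."""
    pg = pytest.importorskip("pingouin")
    import pandas as pd

    rng = np.random.default_rng(1)
    x = rng.normal(5, 1, (8, 4)) + rng.normal(0, 2, (8, 1))
    df = pd.DataFrame(x).stack().reset_index()
    df.columns = ["subj", "rater", "y"]
    ref = pg.intraclass_corr(df, targets="subj", raters="rater", ratings="y")
    ref = ref.set_index("Type").loc["ICC(1,1)"]
    res = rs.icc_oneway(x, rho0=0.0)
    assert res.estimate == pytest.approx(ref["ICC"], abs=1e-10)
    assert res.f_statistic == pytest.approx(ref["F"], abs=1e-10)
    assert res.p_value == pytest.approx(ref["pval"], rel=1e-9)


def test_icc_summary_mentions_key_quantities():
    res = rs.icc_oneway([[1, 2], [4, 5], [7, 9]])
    text = res.summary()
    assert "ICC estimate" in text and "H0: ICC <= 0.20" in text


@pytest.mark.parametrize(
    "icc,label",
    [
        (0.15, "poor"),
        (-0.05, "poor"),
        (0.20, "poor"),
        (0.21, "fair"),
        (0.40, "fair"),
        (0.55, "moderate"),
        (0.60, "moderate"),
        (0.75, "substantial"),
        (0.80, "substantial"),
        (0.81, "excellent"),
        (1.0, "excellent"),
    ],
)
def test_icc_benchmark_scale(icc, label):
    assert rs.icc_benchmark(icc) == label


# ---------------------------------------------------------------------------
# CV
# ---------------------------------------------------------------------------

def test_cv_per_subject_examples():
    assert rs.cv_per_subject([4, 4, 4]) == 0.0
    assert rs.cv_per_subject([8, 12]) == pytest.approx(abs(12 - 8) / np.sqrt(2) / 10)


def test_cv_scale_invariant_shift_not():
    xs = [3.0, 4.0, 6.0]
    base = rs.cv_per_subject(xs)
    assert rs.cv_per_subject([7 * x for x in xs]) == pytest.approx(base, rel=1e-12)
    assert rs.cv_per_subject([x + 5 for x in xs]) != pytest.approx(base, rel=1e-6)
    # pooled CV: same invariances
    table = [[1.0, 3.0], [5.0, 7.0]]
    pooled = rs.cv_pooled(table)
    assert rs.cv_pooled([[7 * v for v in r] for r in table]) == pytest.approx(pooled)
    assert rs.cv_pooled([[v + 5 for v in r] for r in table]) != pytest.approx(
        pooled, rel=1e-6
    )


def test_cv_positivity_errors():
    with pytest.raises(PositivityError):
        rs.cv_per_subject([-1.0, 1.0])
    with pytest.raises(PositivityError) as exc:
        rs.cv_mean([[1.0, 2.0], [-5.0, 1.0]])
    assert exc.value.context["subject_id"] == 1
    with pytest.raises(PositivityError):
        rs.cv_pooled([[-1.0, -2.0], [-3.0, -4.0]])


def test_cv_mean_threshold_is_strict():
    # two subjects engineered to CVs 0.10 and 0.20 -> mean exactly 0.15
    def series(cv):
        # two-point series (m - d, m + d) has CV d*sqrt(2)/m
        m, d = 10.0, cv * 10.0 / np.sqrt(2)
        return [m - d, m + d]

    res = rs.cv_mean([series(0.10), series(0.20)])
    assert res.mean_cv == pytest.approx(0.15, abs=1e-12)
    assert not res.acceptable
    res0 = rs.cv_mean([[4.0, 4.0], [9.0, 9.0]])
    assert res0.mean_cv == 0.0 and res0.acceptable


def test_cv_mean_matches_rowwise_recompute():
    rng = np.random.default_rng(7)
    x = rng.lognormal(1.0, 0.4, (10, 5))
    res = rs.cv_mean(x)
    manual = [np.std(r, ddof=1) / np.mean(r) for r in x]
    assert list(res.per_subject) == pytest.approx(manual, rel=1e-12)
    assert res.mean_cv == pytest.approx(np.mean(manual), rel=1e-12)


def test_cv_pooled_hand_oracle():
    vals = [1.0, 3.0, 5.0, 7.0]
    want = np.std(vals, ddof=1) / np.mean(vals)
    assert rs.cv_pooled([[1.0, 3.0], [5.0, 7.0]]) == pytest.approx(want, rel=1e-14)
    assert rs.cv_pooled([[2.0, 2.0], [2.0, 2.0]]) == 0.0


def test_cv_pooled_delta_method_expectation():
    """Under the two-level model with gamma=10, sigma_B=sigma_W=1, the
    pooled CV concentrates near sqrt(2)/10."""
    rng = np.random.default_rng(8)
    reps = 400
    vals = []
    for _ in range(reps):
        mu = rng.normal(10, 1, (10, 1))
        x = rng.normal(mu, 1.0, (10, 5))
        vals.append(rs.cv_pooled(x))
    se = np.std(vals, ddof=1) / np.sqrt(reps)
    assert np.mean(vals) == pytest.approx(np.sqrt(2) / 10, abs=max(0.01, 4 * se))


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------

def test_bland_altman_identity_and_offset():
    x = [1.0, 2.0, 3.0, 4.0]
    res = rs.bland_altman(x, x)
    assert res.bias == 0.0 and res.loa_lower == 0.0 and res.loa_upper == 0.0
    shifted = rs.bland_altman([v + 2 for v in x], x)
    assert shifted.bias == pytest.approx(2.0)
    assert shifted.loa_lower == pytest.approx(2.0)
    assert shifted.loa_upper == pytest.approx(2.0)


def test_bland_altman_percentiles_match_sorting_oracle():
    rng = np.random.default_rng(9)
    a = rng.normal(10, 2, 20)
    b = rng.normal(10, 2, 20)
    res = rs.bland_altman(a, b)
    diffs = a - b
    assert res.loa_lower == pytest.approx(percentile_oracle(diffs, 5), rel=1e-12)
    assert res.loa_upper == pytest.approx(percentile_oracle(diffs, 95), rel=1e-12)
    assert res.bias == pytest.approx(diffs.mean(), rel=1e-12)


def test_bland_altman_parametric_limits():
    rng = np.random.default_rng(10)
    a = rng.normal(10, 2, 30)
    b = rng.normal(10, 2, 30)
    res = rs.bland_altman(a, b, mode="parametric")
    d = a - b
    assert res.loa_lower == pytest.approx(d.mean() - 1.96 * d.std(ddof=1))
    assert res.loa_upper == pytest.approx(d.mean() + 1.96 * d.std(ddof=1))


def test_bland_altman_nonparametric_bracket_coverage():
    """5th/95th percentile limits bracket >= 90% of the differences."""
    rng = np.random.default_rng(11)
    a = rng.lognormal(1, 0.5, 200)
    b = rng.lognormal(1, 0.5, 200)
    res = rs.bland_altman(a, b)
    inside = np.mean(
        (res.differences >= res.loa_lower) & (res.differences <= res.loa_upper)
    )
    # interpolation at the limits can exclude one extra point per tail
    assert inside >= 0.90 - 2.0 / 200
    assert res.loa_lower <= res.bias <= res.loa_upper


def test_bland_altman_heteroscedasticity_flag_and_log_rescue():
    """Multiplicative error makes |diff| grow with the mean; the rank test
    flags it and the log-scale rerun removes it."""
    rng = np.random.default_rng(12)
    true = rng.lognormal(1.0, 0.8, 150)
    a = true * rng.lognormal(0, 0.15, 150)
    b = true * rng.lognormal(0, 0.15, 150)
    raw = rs.bland_altman(a, b)
    assert raw.heteroscedastic
    logged = rs.bland_altman(a, b, log_scale=True)
    assert logged.hetero_p > 0.05
    assert logged.log_transformed


def test_bland_altman_input_validation():
    with pytest.raises(DesignError):
        rs.bland_altman([1, 2, 3], [1, 2])
    with pytest.raises(PositivityError):
        rs.bland_altman([1, -2, 3], [1, 2, 3], log_scale=True)
    with pytest.raises(DesignError):
        rs.bland_altman([1, 2], [1, 2])  # fewer than 3 pairs
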