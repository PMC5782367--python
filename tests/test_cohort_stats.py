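from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from legflux.cohort_stats import (
    assign_periods,
    compare_periods,
    conditional_residuals,
    fit_random_intercept,
    holm_adjust,
    mann_whitney,
    select_observations,
    sensitivity_refit,
    zero_crossing_day,
)
from legflux.config import StatsConfig
from legflux.errors import InsufficientDataError

from conftest import selection_fixture


# --------------------------------------------------------------------------
# period assignment and observation selection
# --------------------------------------------------------------------------

@pytest.mark.parametrize("day,label", [
    (9, "neither"), (10, "early"), (15, "early"), (20, "early"),
    (21, "neither"), (25, "neither"), (29, "neither"),
    (30, "late"), (40, "late"), (41, "neither")])
def test_assign_periods_closed_intervals(day, label):
    assert assign_periods([day]).iloc[0] == label


def test_both_periods_keeps_last_measurement():
    d = pd.DataFrame({"patient_id": ["A", "A"], "icu_day": [12, 32]})
    d["period"] = assign_periods(d["icu_day"]).to_numpy()
    sel = select_observations(d)
    assert list(sel["icu_day"]) == [32]


def test_twice_in_one_period_keeps_first():
    d = pd.DataFrame({"patient_id": ["A", "A"], "icu_day": [11, 19]})
    d["period"] = assign_periods(d["icu_day"]).to_numpy()
    sel = select_observations(d)
    assert list(sel["icu_day"]) == [11]


def test_protocol_fixture_reduces_to_groups_10_and_9():
    d = selection_fixture()
    d["period"] = assign_periods(d["icu_day"]).to_numpy()
    sel = select_observations(d)
    counts = sel["period"].value_counts()
    assert counts["early"] == 10
    assert counts["late"] == 9
    # never more than one observation per patient per comparison
    assert sel["patient_id"].is_unique


def test_selection_never_increases_group_sizes():
    rng = np.random.default_rng(0)
    for _ in range(50):
        n = rng.integers(2, 30)
        d = pd.DataFrame({
            "patient_id": rng.integers(0, 10, n).astype(str),
            "icu_day": rng.integers(5, 45, n)})
        d = d.drop_duplicates(["patient_id", "icu_day"])
        d["period"] = assign_periods(d["icu_day"]).to_numpy()
        sel = select_observations(d)
        for period in ("early", "late"):
            assert (sel["period"] == period).sum() <= \
                (d["period"] == period).sum()
        assert sel.groupby(["patient_id", "period"]).size().max() <= 1


# --------------------------------------------------------------------------
# Mann-Whitney
# --------------------------------------------------------------------------

def mw_enumeration_p(a, b):
    """Exhaustive two-sided Mann-Whitney p over all group assignments."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    u_obs = sum(1 for x in a for y in b if x > y)
    center = n1 * len(b) / 2
    hits = total = 0
    for idx in combinations(range(len(pooled)), n1):
        aa = pooled[list(idx)]
        bb = np.delete(pooled, list(idx))
        u = sum(1 for x in aa for y in bb if x > y)
        total += 1
        hits += abs(u - center) >= abs(u_obs - center)
    return hits / total


def test_separated_groups_exact_p_is_point_one():
    r = mann_whitney([1, 2, 3], [4, 5, 6])
    assert r.U == 0
    assert r.method == "exact"
    assert r.p_value == pytest.approx(0.1, abs=1e-12)
    assert mw_enumeration_p(np.array([1, 2, 3]), np.array([4, 5, 6])) == \
        pytest.approx(0.1, abs=1e-12)


def test_exact_p_matches_enumeration_on_random_samples():
    rng = np.random.default_rng(5)
    for _ in range(20):
        a = rng.normal(size=rng.integers(3, 6))
        b = rng.normal(size=rng.integers(3, 6))
        r = mann_whitney(a, b)
        assert r.method == "exact"
        assert r.p_value == pytest.approx(mw_enumeration_p(a, b), abs=1e-10)


def test_identical_groups_degenerate():
    r = mann_whitney([2.0, 2.0], [2.0, 2.0, 2.0])
    assert r.p_value == 1.0
    assert r.degenerate


def test_invariance_under_monotone_transform():
    rng = np.random.default_rng(9)
    a, b = rng.normal(size=10), rng.normal(1.0, 1.0, size=9)
    r1 = mann_whitney(a, b)
    r2 = mann_whitney(np.exp(a), np.exp(b))
    assert r1.U == r2.U
    assert r1.p_value == pytest.approx(r2.p_value, rel=1e-12)


def test_large_samples_use_tie_corrected_asymptotic():
    a = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 6.0]
    b = [2.0, 3.0, 3.0, 4.0, 7.0, 8.0, 9.0]
    r = mann_whitney(a, b)
    assert r.method == "asymptotic"
    assert 0 < r.p_value <= 1


def test_empty_group_rejected():
    with pytest.raises(InsufficientDataError):
        mann_whitney([], [1.0])


# --------------------------------------------------------------------------
# random-intercept model
# --------------------------------------------------------------------------

def _cohort_df(days, y, patients=None):
    return pd.DataFrame({
        "patient_id": patients if patients is not None
        else [f"P{i}" for i in range(len(days))],
        "icu_day": days, "y": y})


def test_noise_free_line_recovered_exactly():
    days = np.arange(10, 40, 3, dtype=float)
    d = _cohort_df(days, 2.0 + 0.5 * days)
    fit = fit_random_intercept(d, "y")
    assert fit.beta1 == pytest.approx(0.5, abs=1e-12)
    assert fit.beta0 == pytest.approx(2.0, abs=1e-10)
    assert fit.sigma_b == 0.0 and fit.sigma_e == 0.0
    assert fit.boundary


def test_singleton_patients_match_ols_oracle():
    # one observation per patient: the random intercept is unidentifiable
    # and the GLS fit must collapse to ordinary least squares
    rng = np.random.default_rng(21)
    days = rng.uniform(10, 40, 40)
    y = 5.0 - 0.3 * days + rng.normal(0, 2, 40)
    fit = fit_random_intercept(_cohort_df(days, y), "y")
    b1, b0 = np.polyfit(days, y, 1)
    assert fit.beta1 == pytest.approx(b1, abs=1e-6)
    assert fit.beta0 == pytest.approx(b0, abs=1e-5)


def test_two_level_day_reduces_to_group_mean_difference():
    rng = np.random.default_rng(31)
    days = np.repeat([0.0, 1.0], 15)
    y = np.where(days == 1, 3.0, 1.0) + rng.normal(0, 0.5, 30)
    fit = fit_random_intercept(_cohort_df(days, y, ), "y")
    closed_form = y[days == 1].mean() - y[days == 0].mean()
    assert fit.beta1 == pytest.approx(closed_form, abs=1e-6)


def test_repeated_measures_shrink_slope_se():
    # a true random intercept should be detected (sigma_b > 0)
    rng = np.random.default_rng(12)
    rows = []
    for i in range(25):
        b = rng.normal(0, 6)
        for day in (10.0, 20.0, 30.0):
            rows.append({"patient_id": f"P{i}", "icu_day": day,
                         "y": b + 0.5 * day + rng.normal(0, 1)})
    fit = fit_random_intercept(pd.DataFrame(rows), "y")
    assert fit.sigma_b > 2.0
    assert fit.sigma_e < 3.0
    assert fit.beta1 == pytest.approx(0.5, abs=0.1)
    assert not fit.boundary


def test_too_few_patients_rejected():
    d = _cohort_df([10.0, 20.0], [1.0, 2.0], patients=["A", "A"])
    with pytest.raises(InsufficientDataError):
        fit_random_intercept(d, "y")


# --------------------------------------------------------------------------
# sensitivity refit and zero crossing
# --------------------------------------------------------------------------

def _noisy_cohort(rng, n=20, slope=0.5):
    rows = []
    for i in range(n):
        b = rng.normal(0, 2)
        for day in (10.0, 25.0, 40.0):
            rows.append({"patient_id": f"P{i:02d}", "icu_day": day,
                         "y": b + slope * day + rng.normal(0, 1)})
    return pd.DataFrame(rows)


def test_no_outliers_refit_unchanged():
    d = _noisy_cohort(np.random.default_rng(3))
    fit = fit_random_intercept(d, "y")
    sens = sensitivity_refit(fit, d, "y")
    assert sens.removed_patient_ids == ()
    assert sens.refit is fit
    assert not sens.conclusion_changed


def test_planted_outlier_is_the_one_removed():
    d = _noisy_cohort(np.random.default_rng(3))
    fit0 = fit_random_intercept(d, "y")
    resid_sd = np.std(conditional_residuals(fit0, d, "y"), ddof=1)
    d.loc[d.index[-1], "y"] += 10 * resid_sd * 3  # way past 3 SD
    fit = fit_random_intercept(d, "y")
    sens = sensitivity_refit(fit, d, "y")
    assert sens.removed_patient_ids == ("P19",)
    assert sens.refit.n_patients == 19


def test_zero_crossing_exact_ratio():
    fit = fit_random_intercept(
        _cohort_df(np.array([10.0, 20.0, 30.0, 40.0]),
                   np.array([-25.0, -15.0, -5.0, 5.0])), "y")
    zc = zero_crossing_day(fit)
    assert zc.day == pytest.approx(35.0, abs=1e-9)
    assert not zc.undefined


def test_zero_slope_crossing_undefined():
    days = np.array([10.0, 20.0, 30.0, 40.0])
    fit = fit_random_intercept(_cohort_df(days, np.full(4, 7.0)), "y")
    assert zero_crossing_day(fit).undefined


def test_delta_method_se_matches_hand_formula():
    d = _noisy_cohort(np.random.default_rng(13), slope=0.5)
    d["y"] -= 12.0
    fit = fit_random_intercept(d, "y")
    zc = zero_crossing_day(fit)
    g = np.array([-1 / fit.beta1, fit.beta0 / fit.beta1 ** 2])
    assert zc.se == pytest.approx(float(np.sqrt(g @ fit.cov_fixed @ g)),
                                  rel=1e-12)


def test_compare_periods_end_to_end():
    rng = np.random.default_rng(6)
    d = selection_fixture()
    d["y"] = rng.normal(size=len(d))
    res = compare_periods(d, "y")
    assert (res.n_early, res.n_late) == (10, 9)
    assert 0 < res.p_value <= 1


def test_holm_adjustment_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests
    p = np.array([0.001, 0.02, 0.04, 0.2, 0.5])
    ours = holm_adjust(p)
    ref = multipletests(p, method="holm")[1]
    np.testing.assert_allclose(ours, ref, atol=1e-12)
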