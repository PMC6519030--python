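"""Optimal-reaction-norm estimation: exact arithmetic, least-squares oracles
and BCa bootstrap behaviour."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import rnevo as rn
from rnevo.optimum import bca_interval, make_periods


def env_frame(years, cue, peak, excluded=None):
    df = pd.DataFrame({"year": years, "cue_temp": cue, "peak_date": peak})
    df["optimal_laying_date"] = df["peak_date"] - 33.0
    df["excluded"] = False if excluded is None else excluded
    return df


# ---------------------------------------------------------------- LD_theta
def test_optimal_laying_date_values():
    assert rn.optimal_laying_date(120.0) == 87.0
    assert rn.optimal_laying_date(33.0) == 0.0
    assert np.array_equal(rn.optimal_laying_date(np.array([100.0, 140.0])),
                          np.array([67.0, 107.0]))


def test_optimal_laying_date_rejects_nonfinite():
    with pytest.raises(ValueError):
        rn.optimal_laying_date(float("nan"))


# ---------------------------------------------------------------- hindcast
def test_hindcast_exact_on_noise_free_line():
    years = np.arange(1985, 1995)
    cue = np.linspace(5, 9, 10)
    peak = 80 - 3.0 * cue
    env = env_frame(years, cue, peak)
    env.loc[:2, "peak_date"] = np.nan  # 1985-87 unobserved
    out = rn.hindcast_peaks(env, calibration_years=years[3:])
    assert np.allclose(out["peak_date"], 80 - 3.0 * cue)
    # observed values untouched
    assert np.array_equal(out.loc[3:, "peak_date"], peak[3:])


def test_hindcast_matches_independent_least_squares(rng):
    years = np.arange(1980, 2000)
    cue = rng.normal(7, 1.5, 20)
    peak = 75 - 2.5 * cue + rng.normal(0, 2, 20)
    env = env_frame(years, cue, peak)
    env.loc[[0, 1, 2], "peak_date"] = np.nan
    out = rn.hindcast_peaks(env, calibration_years=years[3:])
    # independent normal-equations fill
    X = np.column_stack([np.ones(17), cue[3:]])
    coef = np.linalg.solve(X.T @ X, X.T @ peak[3:])
    expect = coef[0] + coef[1] * cue[:3]
    assert np.allclose(out.loc[[0, 1, 2], "peak_date"], expect, atol=1e-9)


def test_hindcast_warns_on_extrapolation():
    years = np.arange(2000, 2008)
    cue = np.array([5, 6, 7, 8, 5.5, 6.5, 7.5, 20.0])
    peak = 80 - 3 * cue
    env = env_frame(years, cue, peak)
    env.loc[7, "peak_date"] = np.nan
    with pytest.warns(UserWarning, match="outside"):
        out = rn.hindcast_peaks(env, calibration_years=years[:7])
    assert np.isfinite(out.loc[7, "peak_date"])


def test_hindcast_needs_three_calibration_years():
    env = env_frame([2000, 2001, 2002], [5, 6, 7], [60, 58, np.nan])
    with pytest.raises(ValueError, match=">= 3"):
        rn.hindcast_peaks(env, calibration_years=[2000, 2001])


# ------------------------------------------------------------ period fits
def periods_ab():
    return make_periods([("A", 2000, 2009), ("B", 2010, 2019)])


def test_exact_shift_between_periods():
    """Noise-free data where period B = period A shifted by -5 days."""
    cue = np.tile(np.linspace(4, 9, 10), 2)
    years = np.arange(2000, 2020)
    ldo = 90 - 3.0 * cue
    ldo[10:] -= 5.0
    env = env_frame(years, cue, ldo + 33.0)
    fit = rn.fit_optimum_by_period(env, periods_ab(), n_boot=200, seed=1)
    d = fit.elevation_diff.iloc[0]
    assert d["estimate"] == pytest.approx(-5.0, abs=1e-9)
    assert d["lo"] == pytest.approx(-5.0, abs=1e-6)
    assert d["hi"] == pytest.approx(-5.0, abs=1e-6)
    fit2 = rn.fit_optimum_by_period(env, periods_ab(), common_slope=False,
                                    n_boot=200, seed=1)
    assert fit2.slope_diff.iloc[0]["estimate"] == pytest.approx(0.0, abs=1e-9)


def test_single_period_exact_line():
    years = np.arange(2000, 2010)
    cue = np.linspace(4, 9, 10)
    ldo = 100 - 3.0 * cue
    env = env_frame(years, cue, ldo + 33.0)
    fit = rn.fit_optimum_by_period(
        env, make_periods([("only", 2000, 2009)]), n_boot=150, seed=0
    )
    assert fit.slope.iloc[0]["estimate"] == pytest.approx(-3.0, abs=1e-9)
    # elevation reported at grand-mean temperature, not at T=0
    assert fit.elevation.iloc[0]["estimate"] == pytest.approx(
        100 - 3.0 * cue.mean(), abs=1e-9)


def test_excluded_years_are_dropped():
    years = np.arange(2000, 2010)
    cue = np.linspace(4, 9, 10)
    ldo = 100 - 3.0 * cue
    ldo[4] += 40.0  # a frost year with an unusable late peak
    excluded = np.zeros(10, bool)
    excluded[4] = True
    env = env_frame(years, cue, ldo + 33.0, excluded=excluded)
    fit = rn.fit_optimum_by_period(
        env, make_periods([("only", 2000, 2009)]), n_boot=150, seed=0
    )
    assert fit.excluded_years == [2004]
    assert fit.slope.iloc[0]["estimate"] == pytest.approx(-3.0, abs=1e-9)


def test_degenerate_design_raises():
    years = np.arange(2000, 2006)
    env = env_frame(years, np.full(6, 7.0), np.linspace(50, 60, 6))
    with pytest.raises(ValueError, match="degenerate|constant"):
        rn.fit_optimum_by_period(env, make_periods([("x", 2000, 2005)]),
                                 n_boot=150, seed=0)


def test_regression_matches_normal_equations(rng):
    """The period regression equals an independent normal-equations solve."""
    from rnevo.optimum import _PeriodRegression

    t = rng.normal(7, 1.5, 24)
    g = np.repeat([0, 1, 2], 8)
    y = rng.normal(60, 5, 24)
    tbar = t.mean()
    reg = _PeriodRegression(t, y, g, 3, common_slope=True, tbar=tbar)
    elev, slopes = reg.fit()
    X = np.column_stack([(g == 0), (g == 1), (g == 2), t - tbar]).astype(float)
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    assert np.allclose(elev, beta[:3], atol=1e-9)
    assert np.allclose(slopes, beta[3], atol=1e-9)


# ---------------------------------------------------------------- BCa
def test_bca_degenerate_distribution():
    with pytest.warns(UserWarning, match="degenerate"):
        lo, hi = bca_interval(3.0, np.full(500, 3.0), np.full(20, 3.0))
    assert lo == hi == 3.0


def test_bca_symmetric_close_to_percentile(rng):
    boot = rng.normal(0, 1, 20000)
    jack = rng.normal(0, 1, 50) * 0  # zero skew -> zero acceleration
    lo, hi = bca_interval(np.median(boot), boot, jack, 0.95)
    plo, phi = np.quantile(boot, [0.025, 0.975])
    width = phi - plo
    assert abs(lo - plo) < 0.02 * width
    assert abs(hi - phi) < 0.02 * width


def test_bca_close_to_t_interval_for_normal_mean(rng):
    """BCa for a normal mean tracks the analytic t-interval."""
    n = 50
    diffs = []
    for _ in range(100):
        x = rng.normal(10, 2, n)
        boots = np.array([rng.choice(x, n).mean() for _ in range(600)])
        jack = np.array([np.delete(x, i).mean() for i in range(n)])
        lo, hi = bca_interval(x.mean(), boots, jack)
        tlo, thi = stats.t.interval(0.95, n - 1, loc=x.mean(),
                                    scale=stats.sem(x))
        w = thi - tlo
        diffs.append(max(abs(lo - tlo), abs(hi - thi)) / w)
    assert np.mean(diffs) < 0.10


def test_bca_monotone_in_level(rng):
    boot = rng.gamma(3, 2, 5000)
    jack = rng.gamma(3, 2, 40)
    est = float(np.median(boot))
    lo90, hi90 = bca_interval(est, boot, jack, 0.90)
    lo99, hi99 = bca_interval(est, boot, jack, 0.99)
    assert lo99 <= lo90 and hi99 >= hi90


def test_bca_needs_enough_replicates():
    with pytest.raises(ValueError, match=">= 100"):
        bca_interval(0.0, np.zeros(50), np.zeros(10))


# ----------------------------------------------------- optimum variance
def test_variance_constant_period():
    years = np.arange(2000, 2006)
    env = env_frame(years, np.linspace(4, 9, 6), np.full(6, 88.0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = rn.optimum_variance_by_period(
            env, make_periods([("x", 2000, 2005)]), n_boot=150, seed=0)
    assert out.iloc[0]["estimate"] == 0.0


def test_variance_two_values_closed_form():
    years = [2000, 2001, 2002]
    env = env_frame(years, [5, 6, 7], np.array([80.0, 80.0, 92.0]))
    out = rn.optimum_variance_by_period(
        env, make_periods([("x", 2000, 2002)]), n_boot=150, seed=0)
    vals = env["optimal_laying_date"].to_numpy()
    assert out.iloc[0]["estimate"] == pytest.approx(np.var(vals, ddof=1))


def test_variance_recovers_truth_on_average(rng):
    """Mean estimate over replicates ~ true interannual variance."""
    true_var = 64.0
    ests = []
    for _ in range(300):
        vals = rng.normal(60, np.sqrt(true_var), 15)
        ests.append(np.var(vals, ddof=1))
    assert abs(np.mean(ests) - true_var) / true_var < 0.05


def test_period_parsing_and_overlap():
    ps = rn.make_periods()
    assert [p.label for p in ps] == ["1973-1987", "1988-2001", "2002-2016"]
    with pytest.raises(ValueError, match="overlap"):
        make_periods([("a", 2000, 2010), ("b", 2005, 2015)])
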