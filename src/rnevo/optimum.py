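"""Optimal-reaction-norm estimation.

The optimal laying date in a year (LD_theta) is the food-peak date minus the
rearing lag (default 33 days: laying to peak chick food demand).  Regressing
LD_theta on the spring cue temperature gives the *optimal reaction norm*; its
elevation (value at the grand-mean temperature) and slope are estimated per
multi-year period, and changes between periods are bootstrapped with
bias-corrected and accelerated (BCa) intervals, resampling years.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import rng_from_seed

DEFAULT_OFFSET = 33.0

#: The default periodisation: three equal-interval blocks of the study years.
DEFAULT_PERIODS = (
    ("1973-1987", 1973, 1987),
    ("1988-2001", 1988, 2001),
    ("2002-2016", 2002, 2016),
)


@dataclass(frozen=True)
class PeriodDefinition:
    label: str
    first_year: int
    last_year: int

    def __post_init__(self):
        if self.last_year < self.first_year:
            raise ValueError(f"period {self.label}: last year before first")

    def contains(self, years) -> np.ndarray:
        years = np.asarray(years)
        return (years >= self.first_year) & (years <= self.last_year)


def make_periods(spec=DEFAULT_PERIODS) -> list[PeriodDefinition]:
    """Build ordered, non-overlapping periods from (label, first, last) triples."""
    periods = [PeriodDefinition(*p) for p in spec]
    for a, b in zip(periods, periods[1:]):
        if b.first_year <= a.last_year:
            raise ValueError(f"periods {a.label} and {b.label} overlap or disorder")
    return periods


def parse_periods(text: str) -> list[PeriodDefinition]:
    """Parse '1973-1987,1988-2001,2002-2016' into period definitions."""
    spec = []
    for chunk in text.split(","):
        first, last = chunk.strip().split("-")
        spec.append((chunk.strip(), int(first), int(last)))
    return make_periods(spec)


# ---------------------------------------------------------------------- #
def optimal_laying_date(peak_date, offset: float = DEFAULT_OFFSET):
    """Optimal laying date = food-peak date minus the rearing lag (days)."""
    peak = np.asarray(peak_date, dtype=float)
    if not np.all(np.isfinite(peak)):
        raise ValueError("peak_date must be finite")
    out = peak - offset
    return float(out) if np.isscalar(peak_date) else out


def hindcast_peaks(
    environments: pd.DataFrame, calibration_years, offset: float = DEFAULT_OFFSET
) -> pd.DataFrame:
    """Fill missing peak dates by the peak-vs-cue regression on calibration years.

    Observed peaks are untouched.  Hindcast temperatures outside the
    calibration range trigger an extrapolation warning but are still filled.
    """
    env = environments.copy()
    calib = env[env["year"].isin(calibration_years) & env["peak_date"].notna()]
    if len(calib) < 3:
        raise ValueError(
            f"need >= 3 calibration years with observed peaks, got {len(calib)}"
        )
    slope, intercept = np.polyfit(calib["cue_temp"], calib["peak_date"], 1)
    missing = env["peak_date"].isna()
    t = env.loc[missing, "cue_temp"]
    lo, hi = calib["cue_temp"].min(), calib["cue_temp"].max()
    outside = (t < lo) | (t > hi)
    if outside.any():
        warnings.warn(
            f"hindcasting {int(outside.sum())} year(s) at temperatures outside "
            f"the calibration range [{lo:.2f}, {hi:.2f}] degC",
            stacklevel=2,
        )
    env.loc[missing, "peak_date"] = intercept + slope * t
    env["optimal_laying_date"] = optimal_laying_date(env["peak_date"], offset)
    return env


# ---------------------------------------------------------------------- #
def bca_interval(point_estimate, bootstrap_replicates, jackknife_replicates,
                 level: float = 0.95):
    """Bias-corrected and accelerated bootstrap interval.

    Bias correction z0 from the fraction of bootstrap replicates below the
    point estimate; acceleration a from the skewness of jackknife replicates.
    A degenerate bootstrap distribution yields a zero-width interval.
    """
    boot = np.asarray(bootstrap_replicates, dtype=float)
    if boot.size < 100:
        raise ValueError(f"need >= 100 bootstrap replicates, got {boot.size}")
    if np.ptp(boot) < 1e-12 * max(1.0, abs(float(point_estimate))):
        warnings.warn("degenerate bootstrap distribution; zero-width interval",
                      stacklevel=2)
        c = float(np.median(boot))
        return (c, c)
    prop = np.mean(boot < point_estimate) + 0.5 * np.mean(boot == point_estimate)
    prop = min(max(prop, 1.0 / (boot.size + 1)), boot.size / (boot.size + 1.0))
    z0 = stats.norm.ppf(prop)
    jack = np.asarray(jackknife_replicates, dtype=float)
    jm = jack.mean()
    num = np.sum((jm - jack) ** 3)
    den = 6.0 * np.sum((jm - jack) ** 2) ** 1.5
    a = num / den if den > 0 else 0.0
    alpha = (1.0 - level) / 2.0
    out = []
    for q in (alpha, 1.0 - alpha):
        zq = stats.norm.ppf(q)
        adj = stats.norm.cdf(z0 + (z0 + zq) / (1.0 - a * (z0 + zq)))
        out.append(float(np.quantile(boot, adj)))
    return (out[0], out[1])


@dataclass
class OptimumFit:
    """Per-period optimal-reaction-norm estimates with BCa intervals.

    Elevations are reported at the grand-mean cue temperature so that
    elevation changes are not contaminated by slope differences.
    """

    periods: list
    elevation: pd.DataFrame       # period, estimate, lo, hi
    slope: pd.DataFrame           # period (or 'common'), estimate, lo, hi
    elevation_diff: pd.DataFrame  # pair, estimate, lo, hi
    slope_diff: pd.DataFrame
    variance: pd.DataFrame        # period, estimate, lo, hi
    excluded_years: list
    grand_mean_temp: float
    common_slope: bool

    def summary(self) -> str:
        lines = ["Optimal reaction norm by period"]
        lines.append(f"  elevation at grand-mean cue T = {self.grand_mean_temp:.2f} C")
        for _, r in self.elevation.iterrows():
            lines.append(
                f"  {r['period']:>12}: elevation {r['estimate']:7.2f} "
                f"[{r['lo']:.2f}, {r['hi']:.2f}] days"
            )
        for _, r in self.slope.iterrows():
            lines.append(
                f"  {str(r['period']):>12}: slope    {r['estimate']:7.2f} "
                f"[{r['lo']:.2f}, {r['hi']:.2f}] days/C"
            )
        for _, r in self.elevation_diff.iterrows():
            lines.append(
                f"  d(elev) {r['pair']}: {r['estimate']:6.2f} "
                f"[{r['lo']:.2f}, {r['hi']:.2f}] days"
            )
        for _, r in self.variance.iterrows():
            lines.append(
                f"  var(LDtheta) {r['period']:>12}: {r['estimate']:7.2f} "
                f"[{r['lo']:.2f}, {r['hi']:.2f}] days^2"
            )
        return "\n".join(lines)

    def plot(self, environments: pd.DataFrame, ax=None):
        """Optimal laying dates vs cue temperature with per-period fits."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        env = environments[environments.get("excluded", False) != True]  # noqa: E712
        slopes = (self.slope["estimate"].to_numpy()
                  if not self.common_slope
                  else np.repeat(self.slope["estimate"].iloc[0],
                                 len(self.periods)))
        for k, p in enumerate(self.periods):
            sub = env[p.contains(env["year"])]
            pts = ax.plot(sub["cue_temp"], sub["optimal_laying_date"], "o",
                          ms=4, label=p.label)
            t = np.linspace(sub["cue_temp"].min(), sub["cue_temp"].max(), 2)
            elev = self.elevation["estimate"].iloc[k]
            ax.plot(t, elev + slopes[k] * (t - self.grand_mean_temp),
                    color=pts[0].get_color())
        ax.set_xlabel("cue temperature (degC)")
        ax.set_ylabel("optimal laying date (April days)")
        ax.legend()
        return ax


class _PeriodRegression:
    """OLS of LD_theta on centred cue temperature with period indicators."""

    def __init__(self, temps, ldo, period_idx, n_periods, common_slope, tbar):
        self.t = np.asarray(temps, float) - tbar
        self.y = np.asarray(ldo, float)
        self.g = np.asarray(period_idx, int)
        self.P = n_periods
        self.common = common_slope

    def fit(self, sel=None):
        t, y, g = self.t, self.y, self.g
        if sel is not None:
            t, y, g = t[sel], y[sel], g[sel]
        cols = [np.asarray(g == p, float) for p in range(self.P)]
        if self.common:
            cols.append(t)
        else:
            cols.extend(np.asarray(g == p, float) * t for p in range(self.P))
        X = np.column_stack(cols)
        for p in range(self.P):
            if (g == p).sum() < 2 or np.ptp(t[g == p]) < 1e-12:
                raise ValueError(
                    f"degenerate design in period {p}: constant temperature "
                    "or too few years"
                )
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        elev = beta[: self.P]
        slopes = np.full(self.P, beta[self.P]) if self.common else beta[self.P:]
        return elev, slopes


def fit_optimum_by_period(
    environments: pd.DataFrame,
    periods=None,
    common_slope: bool = True,
    n_boot: int = 1000,
    seed: int = 0,
    offset: float = DEFAULT_OFFSET,
    level: float = 0.95,
) -> OptimumFit:
    """Estimate the optimal reaction norm per period with BCa intervals.

    Years flagged ``excluded`` (e.g. frost-damage years with an unusable food
    peak) are dropped.  Bootstrap resamples years within each period,
    preserving period sizes; jackknife leaves one year out.
    """
    if periods is None:
        periods = make_periods()
    env = environments.copy()
    if "optimal_laying_date" not in env or env["optimal_laying_date"].isna().any():
        env["optimal_laying_date"] = optimal_laying_date(env["peak_date"], offset)
    excluded = list(env.loc[env.get("excluded", False) == True, "year"])  # noqa: E712
    env = env[env.get("excluded", False) != True]  # noqa: E712

    frames, pidx = [], []
    for k, p in enumerate(periods):
        sub = env[p.contains(env["year"])]
        if len(sub) < 3:
            raise ValueError(f"period {p.label} has {len(sub)} years (< 3)")
        frames.append(sub)
        pidx.extend([k] * len(sub))
    data = pd.concat(frames, ignore_index=True)
    pidx = np.array(pidx)
    tbar = float(data["cue_temp"].mean())

    reg = _PeriodRegression(
        data["cue_temp"], data["optimal_laying_date"], pidx, len(periods),
        common_slope, tbar,
    )
    elev_hat, slope_hat = reg.fit()

    rng = rng_from_seed(seed, "optimum")
    n = len(data)
    idx_by_period = [np.flatnonzero(pidx == k) for k in range(len(periods))]

    def resample():
        parts = [rng.choice(ix, size=ix.size, replace=True) for ix in idx_by_period]
        return np.concatenate(parts)

    boot_e = np.empty((n_boot, len(periods)))
    boot_s = np.empty((n_boot, len(periods)))
    for b in range(n_boot):
        try:
            e, s = reg.fit(resample())
        except ValueError:
            e, s = np.full(len(periods), np.nan), np.full(len(periods), np.nan)
        boot_e[b], boot_s[b] = e, s
    ok = ~np.isnan(boot_e).any(axis=1)
    boot_e, boot_s = boot_e[ok], boot_s[ok]

    jack_e = np.empty((n, len(periods)))
    jack_s = np.empty((n, len(periods)))
    for i in range(n):
        sel = np.ones(n, bool)
        sel[i] = False
        try:
            jack_e[i], jack_s[i] = reg.fit(sel)
        except ValueError:
            jack_e[i], jack_s[i] = elev_hat, slope_hat

    def table(stat_hat, boot, jack, labels):
        rows = []
        for k, lab in enumerate(labels):
            lo, hi = bca_interval(stat_hat[k], boot[:, k], jack[:, k], level)
            rows.append({"period": lab, "estimate": float(stat_hat[k]),
                         "lo": lo, "hi": hi})
        return pd.DataFrame(rows)

    labels = [p.label for p in periods]
    elevation = table(elev_hat, boot_e, jack_e, labels)
    if common_slope:
        slope = table(slope_hat[:1], boot_s[:, :1], jack_s[:, :1], ["common"])
    else:
        slope = table(slope_hat, boot_s, jack_s, labels)

    def diffs(stat_hat, boot, jack):
        rows = []
        for k in range(1, len(periods)):
            d = stat_hat[k] - stat_hat[0]
            lo, hi = bca_interval(
                d, boot[:, k] - boot[:, 0], jack[:, k] - jack[:, 0], level
            )
            rows.append({"pair": f"{labels[k]} - {labels[0]}",
                         "estimate": float(d), "lo": lo, "hi": hi})
        return pd.DataFrame(rows)

    elevation_diff = diffs(elev_hat, boot_e, jack_e)
    if common_slope:
        slope_diff = pd.DataFrame(columns=["pair", "estimate", "lo", "hi"])
    else:
        slope_diff = diffs(slope_hat, boot_s, jack_s)

    variance = optimum_variance_by_period(env, periods, n_boot=n_boot,
                                          seed=seed, level=level)

    return OptimumFit(
        periods=list(periods),
        elevation=elevation,
        slope=slope,
        elevation_diff=elevation_diff,
        slope_diff=slope_diff,
        variance=variance,
        excluded_years=excluded,
        grand_mean_temp=tbar,
        common_slope=common_slope,
    )


def optimum_variance_by_period(
    environments: pd.DataFrame, periods=None, n_boot: int = 1000, seed: int = 0,
    level: float = 0.95,
) -> pd.DataFrame:
    """Unbiased interannual variance of LD_theta per period, BCa over years."""
    if periods is None:
        periods = make_periods()
    env = environments[environments.get("excluded", False) != True]  # noqa: E712
    rng = rng_from_seed(seed, "optimum", "variance")
    rows = []
    for p in periods:
        vals = env.loc[p.contains(env["year"]), "optimal_laying_date"].to_numpy(float)
        if vals.size < 3:
            raise ValueError(f"period {p.label} has {vals.size} years (< 3)")
        est = float(np.var(vals, ddof=1))
        boot = np.array(
            [np.var(rng.choice(vals, vals.size, replace=True), ddof=1)
             for _ in range(n_boot)]
        )
        jack = np.array(
            [np.var(np.delete(vals, i), ddof=1) for i in range(vals.size)]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lo, hi = bca_interval(est, boot, jack, level)
        rows.append({"period": p.label, "estimate": est,
                     "lo": max(lo, 0.0), "hi": max(hi, 0.0)})
    return pd.DataFrame(rows)
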