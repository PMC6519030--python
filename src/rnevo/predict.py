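"""Reaction-norm breeder's equation.

Selection on laying date in a year with centred cue temperature x maps onto
the reaction-norm components through the environment vector (1, x): the
annual genetic change in (elevation, slope) is

    dg = G (1, x)' beta_z * p_recr * 0.5,

where G is the additive (co)variance matrix of elevation and slope, beta_z
the year's directional gradient, p_recr the fraction of the next breeding
population composed of new local recruits (a generation-time correction) and
the factor 0.5 accounts for laying date being expressed only in females.
Uncertainty in G (from posterior HPDIs via a normal approximation) and in
beta_z is propagated by first-order error-propagation rules and accumulated
across years as a root-sum-of-squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import check_psd


def map_gradients_to_rn(beta_z_by_env, env_values) -> np.ndarray:
    """Map environment-specific gradients to reaction-norm gradients.

    beta_g = Phi' beta_z with Phi rows (1, x_i): the intercept component sums
    the gradients, the slope component weights them by the environment.
    """
    b = np.asarray(beta_z_by_env, float)
    x = np.asarray(env_values, float)
    if b.shape != x.shape:
        raise ValueError("beta_z_by_env and env_values must have equal length")
    phi = np.column_stack([np.ones_like(x), x])
    return phi.T @ b


def annual_response(
    G: np.ndarray,
    x_j: float,
    beta_zj: float,
    p_recr_next: float = 1.0,
    sex_limited: bool = True,
) -> np.ndarray:
    """One year's predicted genetic change in (elevation, slope).

    dg = G (1, x_j)' beta_zj, scaled by the recruit fraction of the next
    breeding population and halved when the trait is sex-limited.
    """
    G = np.asarray(G, float)
    if G.shape != (2, 2) or not check_psd(G, tol=1e-6):
        raise ValueError("G must be a 2x2 PSD matrix")
    if not 0.0 <= p_recr_next <= 1.0:
        raise ValueError("p_recr must be in [0, 1]")
    env = np.array([1.0, float(x_j)])
    dg = G @ env * float(beta_zj) * float(p_recr_next)
    if sex_limited:
        dg = dg * 0.5
    return dg


def propagate_se(
    G: np.ndarray,
    x_j: float,
    beta_zj: float,
    se_beta: float,
    se_G: np.ndarray,
    p_recr_next: float = 1.0,
    sex_limited: bool = True,
) -> np.ndarray:
    """First-order SE of the annual response, elementwise.

    SE^2 = (G(1,x)')^2 Var(beta) + beta^2 Var(G(1,x)'), with Var(G(1,x)')
    built from the per-element SEs of G combined along (1, x); the result is
    scaled by p_recr (and 0.5 if sex-limited) exactly like the point
    estimate.
    """
    G = np.asarray(G, float)
    se_G = np.asarray(se_G, float)
    if np.any(se_G < 0) or se_beta < 0:
        raise ValueError("standard errors must be >= 0")
    env = np.array([1.0, float(x_j)])
    g_env = G @ env
    var_g_env = (se_G**2) @ env**2  # independent-element approximation
    se = np.sqrt(g_env**2 * se_beta**2 + beta_zj**2 * var_g_env)
    scale = float(p_recr_next) * (0.5 if sex_limited else 1.0)
    return se * scale


def cumulative_response(deltas, ses, level_z: float = 1.96):
    """Cumulative change and its symmetric CI across years.

    Point estimate: component-wise sum; CI half-width = z * sqrt(sum SE^2).
    """
    deltas = np.atleast_2d(np.asarray(deltas, float))
    ses = np.atleast_2d(np.asarray(ses, float))
    if deltas.shape != ses.shape or deltas.shape[0] < 1:
        raise ValueError("need >= 1 (delta, se) entries of equal shape")
    total = deltas.sum(axis=0)
    half = level_z * np.sqrt((ses**2).sum(axis=0))
    return total, total - half, total + half


def compute_p_recr(breeders: pd.DataFrame) -> pd.Series:
    """Per-year fraction of breeding females that are locally born recruits."""
    return breeders.groupby("year")["female_is_recruit"].mean()


@dataclass
class PredictionTrajectory:
    """Per-year and cumulative predicted reaction-norm evolution."""

    table: pd.DataFrame  # year, temp, x (centred), beta_z, se_beta, p_recr,
    #                      d_elev, d_slope, se_d_elev, se_d_slope, flag
    cumulative: np.ndarray       # (d_elev_total, d_slope_total)
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    sex_limited: bool
    generation_corrected: bool
    grand_mean_temp: float
    skipped_years: list = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            "Predicted reaction-norm evolution "
            f"({len(self.table)} years; sex_limited={self.sex_limited}, "
            f"generation_corrected={self.generation_corrected})",
            f"  cumulative d(elevation) = {self.cumulative[0]:+.3f} days "
            f"[{self.ci_lo[0]:+.3f}, {self.ci_hi[0]:+.3f}]",
            f"  cumulative d(slope)     = {self.cumulative[1]:+.4f} days/C "
            f"[{self.ci_lo[1]:+.4f}, {self.ci_hi[1]:+.4f}]",
        ]
        if self.skipped_years:
            lines.append(f"  skipped years (no usable gradient): "
                         f"{self.skipped_years}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Per-year predicted elevation change with +-1 SE bars."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.table
        ax.errorbar(t["year"], t["d_elev"], yerr=t["se_d_elev"], fmt="o",
                    ms=3, capsize=2)
        ax.axhline(0.0, lw=0.8, color="grey")
        ax.set_xlabel("year")
        ax.set_ylabel("predicted $\\Delta$ elevation (days)")
        return ax


def predict_trajectory(
    G: np.ndarray,
    se_G: np.ndarray,
    gradients: pd.DataFrame,
    environments: pd.DataFrame,
    p_recr: pd.Series,
    baseline_last_year: int,
    grand_mean_temp: float | None = None,
    sex_limited: bool = True,
    generation_corrected: bool = True,
) -> PredictionTrajectory:
    """Accumulate annual breeder's-equation responses after a baseline period.

    The baseline period supplies the starting reaction norm (estimated across
    its years); evolution is predicted for every later year with a usable
    gradient, using that year's centred temperature and the *next* year's
    recruit fraction.  ``generation_corrected=False`` switches to the
    uncorrected response (no recruit fraction, no halving) for the
    upper-bound contrast.

    gradients: DataFrame with year, beta_z, se columns (NaN/flagged years
    are skipped with a note).
    """
    env = environments.set_index("year")
    if grand_mean_temp is None:
        grand_mean_temp = float(env["cue_temp"].mean())
    years = [int(y) for y in env.index if y > baseline_last_year]
    if not years:
        raise ValueError("baseline period covers all years: nothing to predict")
    grad = gradients.set_index("year")

    rows, skipped = [], []
    for year in years:
        if year not in grad.index or not np.isfinite(grad.loc[year, "beta_z"]):
            skipped.append(year)
            continue
        beta = float(grad.loc[year, "beta_z"])
        se_b = float(grad.loc[year, "se"])
        x = float(env.loc[year, "cue_temp"]) - grand_mean_temp
        if generation_corrected:
            pr = float(p_recr.get(year + 1, np.nan))
            if not np.isfinite(pr):
                skipped.append(year)
                continue
        else:
            pr = 1.0
        sl = sex_limited and generation_corrected
        dg = annual_response(G, x, beta, pr, sex_limited=sl)
        se = propagate_se(G, x, beta, se_b, se_G, pr, sex_limited=sl)
        rows.append(
            {"year": year, "temp": float(env.loc[year, "cue_temp"]), "x": x,
             "beta_z": beta, "se_beta": se_b, "p_recr_next": pr,
             "d_elev": dg[0], "d_slope": dg[1],
             "se_d_elev": se[0], "se_d_slope": se[1]}
        )
    table = pd.DataFrame(rows)
    if len(table):
        total, lo, hi = cumulative_response(
            table[["d_elev", "d_slope"]].to_numpy(),
            table[["se_d_elev", "se_d_slope"]].to_numpy(),
        )
    else:
        total = lo = hi = np.zeros(2)
    return PredictionTrajectory(
        table=table, cumulative=total, ci_lo=lo, ci_hi=hi,
        sex_limited=sex_limited and generation_corrected,
        generation_corrected=generation_corrected,
        grand_mean_temp=grand_mean_temp, skipped_years=skipped,
    )
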