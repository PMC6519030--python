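"""Bayesian mixed models for reaction norms, fitted by Gibbs sampling.

Two model families are provided, both written as Model/Results pairs:

``ReactionNormAnimalModel``
    Univariate random-regression (animal) model for laying date: fixed
    effects (intercept, age class, temperature), individual
    permanent-environment intercepts and slopes, optional additive-genetic
    intercepts and slopes linked through the pedigree relationship matrix,
    year and nest-box intercepts, and heterogeneous residual variances across
    groups of years with similar temperatures.

``BivariateSelectionModel``
    Joint model of laying date (Gaussian, repeated) and lifetime reproductive
    success (overdispersed Poisson, one value per female), with individual
    reaction-norm elevation, slope and fitness intercept drawn from a 3x3
    unstructured covariance matrix.  The covariance between reaction-norm
    components and fitness measures selection on the reaction norm.

All Gaussian effects have conjugate conditional updates; covariance blocks
use inverse-Wishart conditionals; the Poisson trait's latent log-scale values
are updated by adaptive random-walk Metropolis with the residual variance
held at a fixed small value, which keeps the chain mixing while effectively
constraining the residual.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.linalg import splu

from ._utils import rng_from_seed
from .pedigree import Pedigree


# ====================================================================== #
# helpers named in the public surface
# ====================================================================== #
def center_within_individual(records: pd.DataFrame, temp_col: str = "cue_temp"):
    """Split each record's temperature into within- and between-individual parts.

    Returns ``(within, between)``: per-record T_ij - mean_i(T) and the
    individual mean, so that within + between reconstructs T exactly and the
    within component sums to zero per individual.
    """
    t = records[temp_col].astype(float)
    if t.isna().any():
        raise ValueError("every record needs a temperature")
    means = t.groupby(records["female_id"]).transform("mean")
    return (t - means).rename("t_within"), means.rename("t_between")


def default_residual_groups(n_years: int) -> int:
    """Default number of residual groups: the rounded number of years / 10."""
    return max(1, int(round(n_years / 10.0)))


def assign_residual_groups(environments: pd.DataFrame, n_groups: int) -> pd.Series:
    """Group years into ``n_groups`` rank-based temperature blocks.

    Years are sorted by cue temperature (ties broken by year) and split into
    contiguous blocks of as-equal-as-possible size; block 0 is coldest.
    """
    env = environments
    n_years = len(env)
    if not 1 <= n_groups <= n_years:
        raise ValueError(f"n_groups must be in [1, {n_years}]")
    order = env.sort_values(["cue_temp", "year"])["year"].to_numpy()
    sizes = np.full(n_groups, n_years // n_groups)
    sizes[: n_years % n_groups] += 1
    groups = np.repeat(np.arange(n_groups), sizes)
    return pd.Series(groups, index=order, name="residual_group").sort_index()


def assign_decade_groups(environments: pd.DataFrame, n_groups: int) -> pd.Series:
    """Group years into consecutive calendar blocks (decade-style grouping)."""
    env = environments
    years = np.sort(env["year"].to_numpy())
    sizes = np.full(n_groups, len(years) // n_groups)
    sizes[: len(years) % n_groups] += 1
    groups = np.repeat(np.arange(n_groups), sizes)
    return pd.Series(groups, index=years, name="residual_group").sort_index()


def hpdi(chain: np.ndarray, level: float = 0.95):
    """Shortest interval containing ``level`` of the sorted samples."""
    x = np.sort(np.asarray(chain, float))
    n = x.size
    m = max(1, int(np.ceil(level * n)))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m:] - x[: n - m]
    k = int(np.argmin(widths))
    return float(x[k]), float(x[k + m])


def effective_sample_size(chain: np.ndarray) -> float:
    """ESS from the initial-positive-sequence autocorrelation-time estimate."""
    x = np.asarray(chain, float)
    n = x.size
    if n < 4 or np.ptp(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1 :]
    acf = acf / acf[0]
    # sum of autocorrelations over initial positive pairwise sums (Geyer)
    tau = 1.0
    for k in range(1, n - 2, 2):
        pair = acf[k] + acf[k + 1]
        if pair <= 0:
            break
        tau += 2.0 * pair
    return float(min(n, n / tau))


def posterior_summary(chain: np.ndarray, level: float = 0.95):
    """(median, HPDI lo, HPDI hi, ESS) for one parameter chain."""
    x = np.asarray(chain, float)
    if x.size < 100:
        raise ValueError(f"chain too short for a summary: {x.size} < 100")
    lo, hi = hpdi(x, level)
    if np.ptp(x) == 0:
        return float(x[0]), float(x[0]), float(x[0]), float("nan")
    return float(np.median(x)), lo, hi, effective_sample_size(x)


def slope_variance_contribution(sigma2_slope, centred_temps) -> float:
    """Variance in expected trait values attributable to slope variation.

    The among-individual slope variance is converted to the trait scale by
    multiplying with the variance of the centred environmental values.
    """
    t = np.asarray(centred_temps, float)
    if not (np.all(np.isfinite(t)) and np.isfinite(sigma2_slope)):
        raise ValueError("inputs must be finite")
    return float(sigma2_slope * np.var(t))


# ====================================================================== #
# specifications and results containers
# ====================================================================== #
@dataclass
class MCMCSettings:
    """Sampler settings.  Defaults target desk-scale runs (ESS >= ~400 for
    well-mixing parameters); set ``burnin=1e5, n_iter=1.01e7, thin=1e4`` to
    mirror long reference runs."""

    n_iter: int = 1300
    burnin: int = 300
    thin: int = 2

    @property
    def n_stored(self) -> int:
        return (self.n_iter - self.burnin + self.thin - 1) // self.thin


@dataclass
class ModelSpec:
    """Structure of a reaction-norm mixed model.

    centring:   'grand-mean' (animal-model form) or 'within-individual'
                (selection-model form; adds a between-individual mean-
                temperature fixed effect).
    individual_slope: whether individuals get random slopes (I x E).
    additive:   whether pedigree-linked additive effects are included
                (intercept + slope when individual_slope is on).
    residual_grouping: 'temperature' (rank-based equal-count groups),
                'decade' (consecutive calendar blocks) or 'homogeneous'.
    """

    centring: str = "grand-mean"
    individual_slope: bool = True
    additive: bool = False
    year_effect: bool = True
    nestbox_effect: bool = True
    residual_grouping: str = "temperature"
    residual_n_groups: int | None = None  # default: round(n_years / 10)
    fixed_poisson_residual: float = 0.01  # for the fitness trait only

    def __post_init__(self):
        if self.centring not in ("grand-mean", "within-individual"):
            raise ValueError(f"unknown centring {self.centring!r}")
        if self.residual_grouping not in ("temperature", "decade", "homogeneous"):
            raise ValueError(f"unknown residual grouping {self.residual_grouping!r}")


class PosteriorFit:
    """Thinned posterior chains plus seed/settings provenance.

    ``chains`` maps parameter names to 1-D arrays (length = stored samples).
    Covariance-matrix elements are stored as e.g. ``G[intercept,slope]``.
    """

    def __init__(self, chains: dict, settings: MCMCSettings, seed,
                 meta: dict | None = None):
        self.chains = {k: np.asarray(v) for k, v in chains.items()}
        self.settings = settings
        self.seed = seed
        self.meta = meta or {}

    def __getitem__(self, name):
        return self.chains[name]

    def parameters(self):
        return list(self.chains)

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        rows = []
        for name, chain in self.chains.items():
            med, lo, hi, ess = posterior_summary(chain, level)
            rows.append(
                {"parameter": name, "median": med, "hpdi_lo": lo,
                 "hpdi_hi": hi, "ess": ess}
            )
        return pd.DataFrame(rows).set_index("parameter")

    def median(self, name: str) -> float:
        return float(np.median(self.chains[name]))

    def hpdi(self, name: str, level: float = 0.95):
        return hpdi(self.chains[name], level)

    def covariance_median(self, block: str, labels) -> np.ndarray:
        """Posterior-median covariance matrix for a named block (e.g. 'G')."""
        d = len(labels)
        out = np.empty((d, d))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                key = f"{block}[{a},{b}]" if i <= j else f"{block}[{b},{a}]"
                out[i, j] = self.median(key)
        return out

    def covariance_se(self, block: str, labels, level: float = 0.95) -> np.ndarray:
        """Normal-approximation SEs: (half the HPDI width) / 1.96 per element."""
        z = stats.norm.ppf(0.5 + level / 2.0)
        d = len(labels)
        out = np.empty((d, d))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                key = f"{block}[{a},{b}]" if i <= j else f"{block}[{b},{a}]"
                lo, hi = self.hpdi(key, level)
                out[i, j] = 0.5 * (hi - lo) / z
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.chains)


# ====================================================================== #
# internal Gibbs machinery
# ====================================================================== #
def _sample_invgamma(rng, shape, rate):
    return rate / rng.gamma(shape)


_IG_SHAPE0 = 0.501   # weak scaled-inverse-chi^2 (nu ~ 1) priors for scalars
_IG_RATE0 = 0.0005


def _sample_cov_iw(rng, S, n, dim, v0=0.002, nu_extra=0.002):
    """Inverse-Wishart conditional for a covariance block.

    Prior IW(nu0 = dim + nu_extra, V0 = v0 * I); returns one posterior draw
    given the sum-of-squares matrix ``S`` over ``n`` effect vectors.
    """
    nu0 = dim + nu_extra
    scale = v0 * np.eye(dim) + S
    scale = 0.5 * (scale + scale.T)
    df = nu0 + n
    try:
        return stats.invwishart.rvs(df=df, scale=scale, random_state=rng)
    except np.linalg.LinAlgError:
        scale = scale + 1e-8 * np.eye(dim)
        return stats.invwishart.rvs(df=df, scale=scale, random_state=rng)


def _chol2_inv_sample(rng, a, b, c, r1, r2):
    """Vectorized draw from N(M^-1 r, M^-1) for 2x2 precision blocks.

    M = [[a, b], [b, c]] per row; (r1, r2) the RHS.  Returns (x1, x2).
    """
    det = a * c - b * b
    p = c / det
    q = -b / det
    s = a / det
    mu1 = p * r1 + q * r2
    mu2 = q * r1 + s * r2
    l11 = np.sqrt(p)
    l21 = q / l11
    l22 = np.sqrt(np.maximum(s - l21**2, 1e-300))
    z1 = rng.standard_normal(a.shape)
    z2 = rng.standard_normal(a.shape)
    return mu1 + l11 * z1, mu2 + l21 * z1 + l22 * z2


def _sample_scaling(rng, Z, resid, w, dim, prior_var=625.0):
    """Draw the diagonal working-scale parameters of an expanded block.

    Given unit-scale effects entering the mean as Z @ lambda, this is a
    conjugate weighted regression with N(0, prior_var) priors (25^2, the
    usual weakly informative choice for parameter expansion).
    """
    Zw = Z * w[:, None]
    prec = Zw.T @ Z + np.eye(dim) / prior_var
    rhs = Zw.T @ resid
    chol = np.linalg.cholesky(prec)
    mean = np.linalg.solve(prec, rhs)
    return mean + np.linalg.solve(chol.T, rng.standard_normal(dim))


def _safe_inv(mat, dim):
    """Invert a covariance block, jittering the diagonal if singular.

    Returns (possibly repaired matrix, inverse, jitter count).
    """
    try:
        return mat, np.linalg.inv(mat), 0
    except np.linalg.LinAlgError:
        repaired = mat + 1e-8 * np.eye(dim)
        return repaired, np.linalg.inv(repaired), 1


def I_NF(n):
    return sparse.eye(n, format="csr")


def _level_update(rng, resid_w, w, codes, n_levels, prior_prec):
    """Conditional draw of iid Gaussian random intercepts for one factor.

    resid_w: partial residual * weight per record; w: weight per record.
    """
    sw = np.bincount(codes, weights=w, minlength=n_levels)
    sr = np.bincount(codes, weights=resid_w, minlength=n_levels)
    var = 1.0 / (sw + prior_prec)
    mean = var * sr
    return mean + np.sqrt(var) * rng.standard_normal(n_levels)


# ====================================================================== #
# the univariate random-regression (animal) model
# ====================================================================== #
class ReactionNormAnimalModel:
    """Random-regression model of laying date on temperature.

    Parameters
    ----------
    records : DataFrame with female_id, year, nestbox, laying_date, age_class.
        Records with unknown female identity are dropped (they cannot inform
        individual effects).
    environments : DataFrame with year and cue_temp.
    pedigree : optional Pedigree enabling the additive-genetic structure.
    spec : ModelSpec.
    """

    def __init__(self, records: pd.DataFrame, environments: pd.DataFrame,
                 pedigree: Pedigree | None = None, spec: ModelSpec | None = None,
                 a_inverse_method: str = "inbred"):
        spec = spec or ModelSpec(additive=pedigree is not None)
        if spec.additive and pedigree is None:
            raise ValueError("additive structure requested but no pedigree given")
        self.spec = spec
        self.pedigree = pedigree
        self.environments = environments.reset_index(drop=True)
        self._a_inverse_method = a_inverse_method

        rec = records[records["female_id"].notna()].reset_index(drop=True)
        env = self.environments.set_index("year")
        missing = set(rec["year"]) - set(env.index)
        if missing:
            raise ValueError(f"records reference years without environments: "
                             f"{sorted(missing)[:5]}")
        rec = rec.join(env["cue_temp"], on="year")
        self.records = rec
        self._build()

    # ------------------------------------------------------------------ #
    def _build(self):
        rec, spec = self.records, self.spec
        self.y = rec["laying_date"].to_numpy(float)
        n = len(rec)

        # temperature covariates
        self.grand_mean_temp = float(self.environments["cue_temp"].mean())
        if spec.centring == "grand-mean":
            self.t = rec["cue_temp"].to_numpy(float) - self.grand_mean_temp
            extra = []
            extra_names = []
        else:
            within, between = center_within_individual(rec)
            self.t = within.to_numpy(float)
            extra = [between.to_numpy(float)]
            extra_names = ["temp_between"]

        age = rec["age_class"].astype(str)
        X = [np.ones(n)]
        names = ["intercept"]
        for lvl in ("first-year", "unknown"):  # reference level: 'older'
            if (age == lvl).any():
                X.append((age == lvl).to_numpy(float))
                names.append(f"age[{lvl}]")
        X.append(self.t)
        names.append("temp")
        X.extend(extra)
        names.extend(extra_names)
        self.X = np.column_stack(X)
        self.fixed_names = names

        self.fem_codes, self.females = pd.factorize(rec["female_id"])
        self.n_fem = len(self.females)
        self.yr_codes, self.years_levels = pd.factorize(rec["year"])
        self.nb_codes, self.nb_levels = pd.factorize(rec["nestbox"])

        # residual groups per record (grouping by year)
        n_years = len(self.environments)
        n_groups = spec.residual_n_groups or default_residual_groups(n_years)
        if spec.residual_grouping == "homogeneous":
            n_groups = 1
            year_groups = pd.Series(0, index=self.environments["year"])
        elif spec.residual_grouping == "decade":
            year_groups = assign_decade_groups(self.environments, n_groups)
        else:
            year_groups = assign_residual_groups(self.environments, n_groups)
        self.n_resid_groups = n_groups
        self.resid_group = year_groups.reindex(rec["year"]).to_numpy(int)
        self.year_groups = year_groups

        if spec.additive:
            rel = self.pedigree.relationship_inverse(self._a_inverse_method)
            self.rel = rel
            self.ped_index = rel.index
            unknown = set(self.females) - set(rel.index)
            if unknown:
                raise ValueError(
                    f"records reference females missing from the pedigree: "
                    f"{sorted(unknown)[:5]}"
                )
            self.fem_ped_rows = np.array([rel.index[f] for f in self.females])

    # ------------------------------------------------------------------ #
    def fit(self, settings: MCMCSettings | None = None, seed: int = 0
            ) -> PosteriorFit:
        """Run the Gibbs sampler.

        Covariance blocks use a parameter-expanded (working-scale)
        parametrization: effects are stored as unit-scale vectors with
        covariance Psi and a diagonal scaling Lambda updated by a weighted
        regression, so that the reported block is Lambda Psi Lambda'.  This
        keeps near-zero variance components mixing, where the plain
        inverse-Wishart Gibbs step stalls.
        """
        settings = settings or MCMCSettings()
        rng = rng_from_seed(seed, "mixedmodels", "rram")
        spec = self.spec
        y, X, t = self.y, self.X, self.t
        n, p = X.shape
        nf, ng = self.n_fem, self.n_resid_groups
        slope = spec.individual_slope
        dim = 2 if slope else 1
        ones = np.ones(n)

        # state (working scale)
        beta = np.zeros(p)
        beta[0] = y.mean()
        u_pe = np.zeros((nf, dim))      # unit-scale PE effects
        psi_pe = np.eye(dim)
        lam_pe = np.full(dim, 0.5)
        u_yr = np.zeros(len(self.years_levels))
        u_nb = np.zeros(len(self.nb_levels))
        sigma2_yr = 1.0
        sigma2_nb = 1.0
        resid_var = np.full(ng, max(np.var(y) / 2.0, 1e-3))
        if spec.additive:
            M = len(self.rel.ids)
            u_a = np.zeros((M, dim))
            psi_g = np.eye(dim)
            lam_g = np.full(dim, 0.5)
            a_inv = self.rel.a_inv.tocsr()
            S_chol = self.rel.chol_factor.tocsr()
            fem_rows = self.fem_ped_rows
            rec_rows = fem_rows[self.fem_codes]

        yr_of_rec = self.yr_codes
        nb_of_rec = self.nb_codes
        fem_of_rec = self.fem_codes
        xcols = (ones, t)  # covariates multiplying (intercept, slope) effects

        store = {name: [] for name in self._param_names(dim)}
        jitter_count = 0

        def block_contrib(u, lam, rows):
            c = lam[0] * u[rows, 0]
            if dim == 2:
                c = c + lam[1] * u[rows, 1] * t
            return c

        fitted = X @ beta + u_yr[yr_of_rec] + u_nb[nb_of_rec]
        fitted += block_contrib(u_pe, lam_pe, fem_of_rec)
        if spec.additive:
            fitted += block_contrib(u_a, lam_g, rec_rows)

        for it in range(settings.n_iter):
            w = 1.0 / resid_var[self.resid_group]

            # --- fixed effects
            resid = y - fitted + X @ beta
            Xw = X * w[:, None]
            prec = Xw.T @ X + 1e-10 * np.eye(p)
            rhs = Xw.T @ resid
            chol = np.linalg.cholesky(prec)
            mean = np.linalg.solve(prec, rhs)
            new_beta = mean + np.linalg.solve(chol.T, rng.standard_normal(p))
            fitted += X @ (new_beta - beta)
            beta = new_beta

            # --- year effects
            if spec.year_effect:
                resid = y - fitted + u_yr[yr_of_rec]
                new = _level_update(rng, resid * w, w, yr_of_rec,
                                    len(u_yr), 1.0 / sigma2_yr)
                fitted += new[yr_of_rec] - u_yr[yr_of_rec]
                u_yr = new
                sigma2_yr = _sample_invgamma(
                    rng, _IG_SHAPE0 + len(u_yr) / 2.0,
                    _IG_RATE0 + 0.5 * np.sum(u_yr**2),
                )

            # --- nest-box effects
            if spec.nestbox_effect:
                resid = y - fitted + u_nb[nb_of_rec]
                new = _level_update(rng, resid * w, w, nb_of_rec,
                                    len(u_nb), 1.0 / sigma2_nb)
                fitted += new[nb_of_rec] - u_nb[nb_of_rec]
                u_nb = new
                sigma2_nb = _sample_invgamma(
                    rng, _IG_SHAPE0 + len(u_nb) / 2.0,
                    _IG_RATE0 + 0.5 * np.sum(u_nb**2),
                )

            # --- individual effects (PE, and additive when a pedigree is on)
            if spec.additive:
                # Joint draw of PE effects and breeding values: for each
                # phenotyped female the two are nearly collinear (only the
                # pedigree separates them), so sampling them in one Gaussian
                # block removes the slowest mixing direction of the chain.
                old = (block_contrib(u_pe, lam_pe, fem_of_rec)
                       + block_contrib(u_a, lam_g, rec_rows))
                resid = y - fitted + old
                psi_pe, psi_pe_inv, j1 = _safe_inv(psi_pe, dim)
                psi_g, psi_g_inv, j2 = _safe_inv(psi_g, dim)
                jitter_count += j1 + j2
                u_a, u_pe = self._sample_individual_joint(
                    rng, resid, w, t, lam_g, lam_pe, psi_g_inv, psi_pe_inv,
                    a_inv, S_chol, dim)
                fitted += (block_contrib(u_pe, lam_pe, fem_of_rec)
                           + block_contrib(u_a, lam_g, rec_rows)) - old
                psi_pe = np.atleast_2d(_sample_cov_iw(
                    rng, u_pe.T @ u_pe, nf, dim, v0=float(dim), nu_extra=0.0))
                Sg = u_a.T @ (a_inv @ u_a)
                psi_g = np.atleast_2d(_sample_cov_iw(
                    rng, Sg, M, dim, v0=float(dim), nu_extra=0.0))

                # joint working-scale update for both blocks
                old = (block_contrib(u_pe, lam_pe, fem_of_rec)
                       + block_contrib(u_a, lam_g, rec_rows))
                resid = y - fitted + old
                xc = np.column_stack(xcols[:dim])
                Z = np.column_stack([u_a[rec_rows, :] * xc,
                                     u_pe[fem_of_rec, :] * xc])
                lam_all = _sample_scaling(rng, Z, resid, w, 2 * dim)
                lam_g, lam_pe = lam_all[:dim], lam_all[dim:]
                fitted += (block_contrib(u_pe, lam_pe, fem_of_rec)
                           + block_contrib(u_a, lam_g, rec_rows)) - old
            else:
                c1 = lam_pe[0] * ones
                c2 = lam_pe[1] * t if dim == 2 else None
                old = block_contrib(u_pe, lam_pe, fem_of_rec)
                resid = y - fitted + old
                rw = resid * w
                S11 = np.bincount(fem_of_rec, weights=w * c1 * c1,
                                  minlength=nf)
                R1 = np.bincount(fem_of_rec, weights=rw * c1, minlength=nf)
                psi_pe, psi_pe_inv, j1 = _safe_inv(psi_pe, dim)
                jitter_count += j1
                if dim == 2:
                    S12 = np.bincount(fem_of_rec, weights=w * c1 * c2,
                                      minlength=nf)
                    S22 = np.bincount(fem_of_rec, weights=w * c2 * c2,
                                      minlength=nf)
                    R2 = np.bincount(fem_of_rec, weights=rw * c2,
                                     minlength=nf)
                    x1, x2 = _chol2_inv_sample(
                        rng, S11 + psi_pe_inv[0, 0], S12 + psi_pe_inv[0, 1],
                        S22 + psi_pe_inv[1, 1], R1, R2,
                    )
                    u_pe = np.column_stack([x1, x2])
                else:
                    var = 1.0 / (S11 + psi_pe_inv[0, 0])
                    u_pe = (var * R1 + np.sqrt(var)
                            * rng.standard_normal(nf))[:, None]
                fitted += block_contrib(u_pe, lam_pe, fem_of_rec) - old
                psi_pe = np.atleast_2d(_sample_cov_iw(
                    rng, u_pe.T @ u_pe, nf, dim, v0=float(dim), nu_extra=0.0))

                # working-scale update for the PE block
                old = block_contrib(u_pe, lam_pe, fem_of_rec)
                resid = y - fitted + old
                Z = u_pe[fem_of_rec, :] * np.column_stack(xcols[:dim])
                lam_pe = _sample_scaling(rng, Z, resid, w, dim)
                fitted += block_contrib(u_pe, lam_pe, fem_of_rec) - old

            # --- residual group variances
            resid = y - fitted
            for g in range(ng):
                mask = self.resid_group == g
                ssr = float(np.sum(resid[mask] ** 2))
                resid_var[g] = _sample_invgamma(
                    rng, _IG_SHAPE0 + mask.sum() / 2.0, _IG_RATE0 + 0.5 * ssr
                )

            if not np.isfinite(fitted).all():
                raise RuntimeError(
                    f"sampler diverged (non-finite state) at iteration {it}"
                )

            if it >= settings.burnin and (it - settings.burnin) % settings.thin == 0:
                L = np.diag(lam_pe)
                cov_pe = L @ psi_pe @ L
                cov_g = None
                if spec.additive:
                    Lg = np.diag(lam_g)
                    cov_g = Lg @ psi_g @ Lg
                self._store(store, beta, cov_pe, cov_g,
                            sigma2_yr, sigma2_nb, resid_var, dim)

        chains = {k: np.array(v) for k, v in store.items()}
        meta = {
            "model": "ReactionNormAnimalModel",
            "n_records": n,
            "n_females": nf,
            "grand_mean_temp": self.grand_mean_temp,
            "centred_temps": self.t.copy(),
            "residual_groups": self.year_groups.to_dict(),
            "jitter_repairs": jitter_count,
        }
        return PosteriorFit(chains, settings, seed, meta)

    # ------------------------------------------------------------------ #
    def _sample_individual_joint(self, rng, resid, w, t, lam_g, lam_pe,
                                 psi_g_inv, psi_pe_inv, a_inv, S_chol, dim):
        """One Gaussian draw of all breeding values and PE effects.

        theta ~ N(C^-1 r, C^-1) with

            C = blockdiag(kron(A^-1, Psi_G^-1), kron(I, Psi_PE^-1)) + Z'WZ,

        where Z carries each record's working-scale covariates for both its
        female's additive and PE effects.  Sampled with the perturbation
        technique: theta = C^-1 (r + e), e ~ N(0, C) assembled from the
        factorizations A^-1 = S'S and Psi^-1 = B'B, and one sparse LU solve.
        """
        M = a_inv.shape[0]
        nf = self.n_fem
        fem = self.fem_codes
        ped_rows = self.fem_ped_rows
        rec_rows = ped_rows[fem]
        nrec = len(resid)
        rw = resid * w
        d2 = 2 * dim
        ntot = (M + nf) * dim

        # per-record covariates: (additive ints, additive slopes, PE ...)
        cvec = [np.full(nrec, lam_g[0])]
        if dim == 2:
            cvec.append(lam_g[1] * t)
        cvec.append(np.full(nrec, lam_pe[0]))
        if dim == 2:
            cvec.append(lam_pe[1] * t)

        # aggregate per female: data blocks, RHS and data perturbation
        S = np.empty((nf, d2, d2))
        R = np.empty((nf, d2))
        E = np.empty((nf, d2))
        eps = rng.standard_normal(nrec) * np.sqrt(w)
        for a in range(d2):
            R[:, a] = np.bincount(fem, weights=rw * cvec[a], minlength=nf)
            E[:, a] = np.bincount(fem, weights=eps * cvec[a], minlength=nf)
            for b in range(a, d2):
                s = np.bincount(fem, weights=w * cvec[a] * cvec[b],
                                minlength=nf)
                S[:, a, b] = s
                S[:, b, a] = s

        # unknown positions per female: additive first, then PE
        pos = np.empty((nf, d2), dtype=np.int64)
        for k in range(dim):
            pos[:, k] = ped_rows * dim + k
            pos[:, dim + k] = M * dim + np.arange(nf) * dim + k

        rows = np.repeat(pos, d2, axis=1).ravel()
        cols = np.tile(pos, (1, d2)).ravel()
        D = sparse.coo_matrix((S.ravel(), (rows, cols)),
                              shape=(ntot, ntot)).tocsr()
        Q = sparse.block_diag(
            (sparse.kron(a_inv, psi_g_inv), sparse.kron(I_NF(nf), psi_pe_inv)),
            format="csr",
        )
        C = (Q + D).tocsc()

        rhs = np.zeros(ntot)
        rhs[pos.ravel()] = R.ravel()
        e_data = np.zeros(ntot)
        e_data[pos.ravel()] = E.ravel()

        # prior perturbation from the factorized precisions
        Bg = np.linalg.cholesky(psi_g_inv).T
        e_prior_g = (sparse.kron(S_chol, Bg, format="csr").T
                     @ rng.standard_normal(M * dim))
        Bpe = np.linalg.cholesky(psi_pe_inv).T
        e_prior_pe = (rng.standard_normal((nf, dim)) @ Bpe).ravel()
        e_prior = np.concatenate([e_prior_g, e_prior_pe])

        lu = splu(C, permc_spec="MMD_AT_PLUS_A",
                  options=dict(SymmetricMode=True, DiagPivotThresh=0.0))
        theta = lu.solve(rhs + e_data + e_prior)
        return (theta[: M * dim].reshape(M, dim),
                theta[M * dim:].reshape(nf, dim))

    # ------------------------------------------------------------------ #
    def _param_names(self, dim):
        names = [f"beta[{n}]" for n in self.fixed_names]
        lbl = ["intercept", "slope"][:dim]
        for blk in ["PE"] + (["G"] if self.spec.additive else []):
            for i in range(dim):
                for j in range(i, dim):
                    names.append(f"{blk}[{lbl[i]},{lbl[j]}]")
        if self.spec.year_effect:
            names.append("sigma2_year")
        if self.spec.nestbox_effect:
            names.append("sigma2_nestbox")
        names.extend(f"sigma2_resid[{g}]" for g in range(self.n_resid_groups))
        return names

    def _store(self, store, beta, cov_pe, cov_g, s_yr, s_nb, resid_var, dim):
        lbl = ["intercept", "slope"][:dim]
        k = 0
        for i, nm in enumerate(self.fixed_names):
            store[f"beta[{nm}]"].append(beta[i])
        for blk, mat in (("PE", cov_pe),) + ((("G", cov_g),) if cov_g is not None
                                             else ()):
            for i in range(dim):
                for j in range(i, dim):
                    store[f"{blk}[{lbl[i]},{lbl[j]}]"].append(mat[i, j])
        if self.spec.year_effect:
            store["sigma2_year"].append(s_yr)
        if self.spec.nestbox_effect:
            store["sigma2_nestbox"].append(s_nb)
        for g in range(self.n_resid_groups):
            store[f"sigma2_resid[{g}]"].append(resid_var[g])
        del k


# ====================================================================== #
# the bivariate laying-date / fitness model
# ====================================================================== #
def build_selection_data(records: pd.DataFrame, first_cohort: int,
                         last_cohort: int):
    """Assemble the period dataset for the selection model.

    Females are assigned to a cohort by their first observed breeding year;
    females with fewer than two breeding attempts or unknown identity are
    excluded.  LRS is the summed recruit count over all of a female's records
    (manipulated broods included).
    Returns (laying-date records, LRS series indexed by female).
    """
    rec = records[records["female_id"].notna()]
    first = rec.groupby("female_id")["year"].min()
    counts = rec.groupby("female_id").size()
    keep = first[(first >= first_cohort) & (first <= last_cohort)
                 & (counts >= 2)].index
    sub = rec[rec["female_id"].isin(keep)].copy()
    lrs = sub.groupby("female_id")["recruits"].sum()
    return sub.reset_index(drop=True), lrs


class BivariateSelectionModel:
    """Joint Gaussian/Poisson model measuring selection on the reaction norm.

    Laying date follows the within-individual-centred random-regression
    model; each female's lifetime reproductive success is overdispersed
    Poisson with an individual log-scale intercept.  The 3x3 covariance of
    (elevation, slope, fitness intercept) is the quantity of interest: a
    negative elevation-fitness covariance indicates selection for earlier
    laying across the board.
    """

    LABELS = ("LD_intercept", "LD_slope", "LRS")

    def __init__(self, records: pd.DataFrame, lrs: pd.Series,
                 environments: pd.DataFrame, spec: ModelSpec | None = None):
        self.spec = spec or ModelSpec(
            centring="within-individual", residual_n_groups=2
        )
        if self.spec.centring != "within-individual":
            raise ValueError(
                "the selection model requires within-individual centring "
                "because the between-individual mean temperature enters the "
                "fixed part"
            )
        rec = records[records["female_id"].notna()].reset_index(drop=True)
        env = environments.set_index("year")
        rec = rec.join(env["cue_temp"], on="year")
        counts = rec.groupby("female_id").size()
        if (counts < 2).any():
            bad = counts[counts < 2].index[:5]
            raise ValueError(f"females with < 2 breeding attempts: {list(bad)}")
        self.records = rec
        self.environments = environments.reset_index(drop=True)
        self.lrs = lrs.reindex(counts.index)
        if self.lrs.isna().any():
            raise ValueError("missing LRS for some females")
        self._build()

    def _build(self):
        rec = self.records
        self.y = rec["laying_date"].to_numpy(float)
        within, between = center_within_individual(rec)
        self.t = within.to_numpy(float)
        n = len(rec)
        age = rec["age_class"].astype(str)
        X = [np.ones(n)]
        names = ["intercept"]
        for lvl in ("first-year", "unknown"):
            if (age == lvl).any():
                X.append((age == lvl).to_numpy(float))
                names.append(f"age[{lvl}]")
        X.append(self.t)
        names.append("temp_within")
        X.append(between.to_numpy(float))
        names.append("temp_between")
        self.X = np.column_stack(X)
        self.fixed_names = names
        self.fem_codes, self.females = pd.factorize(rec["female_id"])
        self.n_fem = len(self.females)
        self.yr_codes, _ = pd.factorize(rec["year"])
        self.n_yr = self.yr_codes.max() + 1
        self.nb_codes, _ = pd.factorize(rec["nestbox"])
        self.n_nb = self.nb_codes.max() + 1
        self.W = self.lrs.reindex(self.females).to_numpy(float)
        ng = self.spec.residual_n_groups or 2
        years_here = self.environments[
            self.environments["year"].isin(rec["year"])
        ].reset_index(drop=True)
        groups = assign_residual_groups(years_here, ng)
        self.n_resid_groups = ng
        self.resid_group = groups.reindex(rec["year"]).to_numpy(int)

    # ------------------------------------------------------------------ #
    def fit(self, settings: MCMCSettings | None = None, seed: int = 0
            ) -> PosteriorFit:
        settings = settings or MCMCSettings(n_iter=2600, burnin=600, thin=4)
        rng = rng_from_seed(seed, "mixedmodels", "bivariate")
        y, X, t = self.y, self.X, self.t
        n, p = X.shape
        nf, ng = self.n_fem, self.n_resid_groups
        fem = self.fem_codes
        e_var = self.spec.fixed_poisson_residual

        beta = np.zeros(p)
        beta[0] = y.mean()
        u = np.zeros((nf, 3))             # unit-scale (a_i, b_i, c_i)
        psi3 = np.eye(3)
        lam = np.array([0.5, 0.3, 0.5])   # working scales (PX)
        u_yr = np.zeros(self.n_yr)
        u_nb = np.zeros(self.n_nb)
        sigma2_yr = sigma2_nb = 1.0
        resid_var = np.full(ng, max(np.var(y) / 2.0, 1e-3))
        alpha_w = float(np.log(np.mean(self.W) + 0.1))
        eta = np.full(nf, alpha_w)
        mh_scale = 0.3
        mh_scale2 = 0.5
        mh_accept = 0

        store = {name: [] for name in self._param_names()}
        ld_fit = X @ beta + u_yr[self.yr_codes] + u_nb[self.nb_codes] \
            + lam[0] * u[fem, 0] + lam[1] * u[fem, 1] * t

        for it in range(settings.n_iter):
            w = 1.0 / resid_var[self.resid_group]

            # fixed effects (laying date)
            resid = y - ld_fit + X @ beta
            Xw = X * w[:, None]
            prec = Xw.T @ X + 1e-10 * np.eye(p)
            mean = np.linalg.solve(prec, Xw.T @ resid)
            new_beta = mean + np.linalg.solve(
                np.linalg.cholesky(prec).T, rng.standard_normal(p))
            ld_fit += X @ (new_beta - beta)
            beta = new_beta

            # year / nest box
            resid = y - ld_fit + u_yr[self.yr_codes]
            new = _level_update(rng, resid * w, w, self.yr_codes, self.n_yr,
                                1.0 / sigma2_yr)
            ld_fit += new[self.yr_codes] - u_yr[self.yr_codes]
            u_yr = new
            sigma2_yr = _sample_invgamma(
                rng, _IG_SHAPE0 + self.n_yr / 2.0,
                _IG_RATE0 + 0.5 * np.sum(u_yr**2))
            resid = y - ld_fit + u_nb[self.nb_codes]
            new = _level_update(rng, resid * w, w, self.nb_codes, self.n_nb,
                                1.0 / sigma2_nb)
            ld_fit += new[self.nb_codes] - u_nb[self.nb_codes]
            u_nb = new
            sigma2_nb = _sample_invgamma(
                rng, _IG_SHAPE0 + self.n_nb / 2.0,
                _IG_RATE0 + 0.5 * np.sum(u_nb**2))

            # joint (a, b, c) blocks -- batched 3x3 Gaussian updates on the
            # unit scale (record covariates carry the working scales)
            c1 = lam[0]
            c2v = lam[1] * t
            contrib = c1 * u[fem, 0] + u[fem, 1] * c2v
            resid = y - ld_fit + contrib
            rw = resid * w
            try:
                psi3_inv = np.linalg.inv(psi3)
            except np.linalg.LinAlgError:
                psi3 = psi3 + 1e-8 * np.eye(3)
                psi3_inv = np.linalg.inv(psi3)
            Mprec = np.broadcast_to(psi3_inv, (nf, 3, 3)).copy()
            Mprec[:, 0, 0] += np.bincount(fem, weights=w * c1 * c1,
                                          minlength=nf)
            swt = np.bincount(fem, weights=w * c1 * c2v, minlength=nf)
            Mprec[:, 0, 1] += swt
            Mprec[:, 1, 0] += swt
            Mprec[:, 1, 1] += np.bincount(fem, weights=w * c2v * c2v,
                                          minlength=nf)
            Mprec[:, 2, 2] += lam[2] ** 2 / e_var
            rhs = np.zeros((nf, 3))
            rhs[:, 0] = np.bincount(fem, weights=rw * c1, minlength=nf)
            rhs[:, 1] = np.bincount(fem, weights=rw * c2v, minlength=nf)
            rhs[:, 2] = lam[2] * (eta - alpha_w) / e_var
            Mcov = np.linalg.inv(Mprec)
            mu = np.einsum("nij,nj->ni", Mcov, rhs)
            L = np.linalg.cholesky(Mcov)
            z = rng.standard_normal((nf, 3))
            new_u = mu + np.einsum("nij,nj->ni", L, z)
            ld_fit += (c1 * new_u[fem, 0] + new_u[fem, 1] * c2v) - contrib
            u = new_u
            psi3 = _sample_cov_iw(rng, u.T @ u, nf, 3, v0=3.0, nu_extra=0.0)

            # working scales: LD side informs (lam1, lam2), LRS side lam3
            contrib = c1 * u[fem, 0] + u[fem, 1] * c2v
            resid = y - ld_fit + contrib
            Z = np.column_stack([u[fem, 0], u[fem, 1] * t])
            lam12 = _sample_scaling(rng, Z, resid, w, 2)
            ld_fit += (lam12[0] * u[fem, 0]
                       + lam12[1] * u[fem, 1] * t) - contrib
            prec3 = np.sum(u[:, 2] ** 2) / e_var + 1.0 / 625.0
            mean3 = np.sum(u[:, 2] * (eta - alpha_w)) / e_var / prec3
            lam = np.array([lam12[0], lam12[1],
                            mean3 + rng.standard_normal() / np.sqrt(prec3)])

            # latent Poisson scale: adaptive random-walk Metropolis
            prop = eta + mh_scale * rng.standard_normal(nf)
            mu_eta = alpha_w + lam[2] * u[:, 2]
            logr = (
                self.W * (prop - eta) - (np.exp(prop) - np.exp(eta))
                - 0.5 * ((prop - mu_eta) ** 2 - (eta - mu_eta) ** 2) / e_var
            )
            acc = np.log(rng.random(nf)) < logr
            eta = np.where(acc, prop, eta)
            if it < settings.burnin and (it + 1) % 50 == 0:
                rate = acc.mean()
                mh_scale *= np.exp(0.5 * (rate - 0.44))
                mh_scale = float(np.clip(mh_scale, 1e-3, 2.0))
            mh_accept += acc.mean()

            # joint translation of (eta_i, c_i): the fixed tiny residual
            # variance glues them together, so move the pair along the slow
            # direction; the tight Gaussian factor is invariant under it
            if abs(lam[2]) > 1e-8:
                delta = mh_scale2 * rng.standard_normal(nf)
                u3_new = u[:, 2] + delta / lam[2]
                m_cond = (psi3[2, :2] @ np.linalg.solve(psi3[:2, :2],
                                                        u[:, :2].T))
                v_cond = psi3[2, 2] - psi3[2, :2] @ np.linalg.solve(
                    psi3[:2, :2], psi3[:2, 2])
                v_cond = max(float(v_cond), 1e-12)
                logr = (
                    self.W * delta - (np.exp(eta + delta) - np.exp(eta))
                    - 0.5 * ((u3_new - m_cond) ** 2
                             - (u[:, 2] - m_cond) ** 2) / v_cond
                )
                acc2 = np.log(rng.random(nf)) < logr
                eta = np.where(acc2, eta + delta, eta)
                u[:, 2] = np.where(acc2, u3_new, u[:, 2])
                if it < settings.burnin and (it + 1) % 50 == 0:
                    mh_scale2 *= np.exp(0.5 * (acc2.mean() - 0.44))
                    mh_scale2 = float(np.clip(mh_scale2, 1e-3, 3.0))

            # fitness intercept
            v = e_var / nf
            alpha_w = float(np.mean(eta - lam[2] * u[:, 2])
                            + np.sqrt(v) * rng.standard_normal())

            # residual groups (laying date)
            resid = y - ld_fit
            for g in range(ng):
                mask = self.resid_group == g
                resid_var[g] = _sample_invgamma(
                    rng, _IG_SHAPE0 + mask.sum() / 2.0,
                    _IG_RATE0 + 0.5 * float(np.sum(resid[mask] ** 2)))

            if not np.isfinite(ld_fit).all() or not np.isfinite(eta).all():
                raise RuntimeError(
                    f"sampler diverged (non-finite state) at iteration {it}")

            if it >= settings.burnin and (it - settings.burnin) % settings.thin == 0:
                Lm = np.diag(lam)
                self._store(store, beta, Lm @ psi3 @ Lm, alpha_w,
                            sigma2_yr, sigma2_nb, resid_var)

        chains = {k: np.array(v) for k, v in store.items()}
        meta = {
            "model": "BivariateSelectionModel",
            "n_records": n,
            "n_females": nf,
            "mh_mean_accept": mh_accept / settings.n_iter,
        }
        return PosteriorFit(chains, settings, seed, meta)

    def _param_names(self):
        names = [f"beta[{n}]" for n in self.fixed_names]
        lbl = self.LABELS
        for i in range(3):
            for j in range(i, 3):
                names.append(f"P[{lbl[i]},{lbl[j]}]")
        names += ["alpha_LRS", "sigma2_year", "sigma2_nestbox"]
        names += [f"sigma2_resid[{g}]" for g in range(self.n_resid_groups)]
        return names

    def _store(self, store, beta, cov3, alpha_w, s_yr, s_nb, resid_var):
        for i, nm in enumerate(self.fixed_names):
            store[f"beta[{nm}]"].append(beta[i])
        lbl = self.LABELS
        for i in range(3):
            for j in range(i, 3):
                store[f"P[{lbl[i]},{lbl[j]}]"].append(cov3[i, j])
        store["alpha_LRS"].append(alpha_w)
        store["sigma2_year"].append(s_yr)
        store["sigma2_nestbox"].append(s_nb)
        for g in range(self.n_resid_groups):
            store[f"sigma2_resid[{g}]"].append(resid_var[g])


# ====================================================================== #
def fit_model(records, environments, spec: ModelSpec | None = None,
              pedigree: Pedigree | None = None, lrs: pd.Series | None = None,
              settings: MCMCSettings | None = None, seed: int = 0
              ) -> PosteriorFit:
    """Functional front door: dispatches on whether an LRS series is given."""
    if lrs is not None:
        model = BivariateSelectionModel(records, lrs, environments, spec)
    else:
        model = ReactionNormAnimalModel(records, environments, pedigree, spec)
    return model.fit(settings=settings, seed=seed)
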