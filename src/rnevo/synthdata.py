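"""Synthetic breeding-population generator.

Emulates a long-term hole-nesting passerine study population: overlapping
generations in a nest-box plot of fixed capacity, immigration, spring-
temperature cues with a warming trend, a caterpillar food peak that advances
with temperature, laying-date reaction norms with permanent-environment and
additive-genetic (co)variation in elevation and slope, and annual recruit
counts under stabilizing selection around the moving optimum (food peak minus
the rearing lag).

The generator writes the same statistical structure the estimation modules
assume, so parameter recovery can be tested end to end without field data.
Laying dates are on the April-day scale: days since March 31 (April 1 = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._utils import rng_from_seed, check_psd
from .pedigree import Pedigree


class SimulationError(RuntimeError):
    pass


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study population.

    Variance components default to the posterior medians of the motivating
    system (day^2 for intercepts, (days/degC)^2 for slopes); demographic rates
    default to values that reproduce a ~44-year, ~3,000-female, ~4,900-brood
    dataset with roughly biennial generations.
    """

    # demography
    n_founders: int = 110          # breeding females supported per year
    n_years: int = 44
    year_start: int = 1973
    adult_survival: float = 0.45   # annual survival of breeders
    recruitment_rate: float = 0.60  # P(vacancy filled by a local recruit)
    sibship_shape: float = 1.0     # gamma shape of per-brood recruit weights
    mate_fidelity: float = 0.7     # P(surviving pair stays together)
    n_nestboxes: int = 170

    # environment
    mean_cue_temp: float = 6.7     # degC over the cue window
    sd_cue_temp: float = 1.2
    temp_trend: float = 0.035      # degC / year
    peak_intercept: float = 78.0   # April-days at 0 degC
    peak_slope: float = -3.15      # days / degC
    peak_resid_sd: float = 4.0
    optimum_offset: float = 33.0   # rearing lag: optimum = peak - offset

    # laying-date model (grand-mean-centred temperature)
    mean_laying_date: float = 22.0
    pop_slope: float = -3.28       # days / degC
    age_effect_first_year: float = 1.78
    age_effect_unknown: float = 1.27
    sigma2_A: float = 4.38         # additive intercept variance (day^2)
    sigma2_B: float = 0.02         # additive slope variance ((days/degC)^2)
    cov_AB: float = 0.07
    sigma2_PE_int: float = 3.24
    sigma2_PE_slope: float = 0.02
    cov_PE: float = 0.06
    sigma2_year: float = 9.65
    sigma2_nestbox: float = 1.22
    residual_sd_by_group: tuple = (3.33, 3.69, 4.38, 4.39)  # cold -> warm
    resid_temp_dependence: bool = True

    # fitness
    fitness_width: float = 12.0    # omega of stabilizing selection (days)
    fitness_max: float = 1.2       # expected recruits at the optimum
    overdispersion: float = 2.0    # NB size parameter (inf -> Poisson)

    # observation process
    unknown_id_fraction: float = 0.03
    manipulated_fraction: float = 0.10
    manipulation_effect: float = 0.8  # multiplier on expected recruits

    seed: int = 0

    # ------------------------------------------------------------------ #
    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        variances = dict(
            sigma2_A=self.sigma2_A, sigma2_B=self.sigma2_B,
            sigma2_PE_int=self.sigma2_PE_int, sigma2_PE_slope=self.sigma2_PE_slope,
            sigma2_year=self.sigma2_year, sigma2_nestbox=self.sigma2_nestbox,
        )
        for name, v in variances.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.n_years < 2:
            raise ValueError("n_years must be >= 2")
        if len(self.residual_sd_by_group) == 0:
            raise ValueError("residual_sd_by_group must be nonempty")
        for m, label in ((self.G, "G"), (self.P_pe, "permanent-environment")):
            if not check_psd(m):
                raise ValueError(f"{label} (co)variance matrix is not PSD")
        if not 0.0 <= self.adult_survival <= 1.0:
            raise ValueError("adult_survival must be in [0, 1]")
        if not 0.0 <= self.recruitment_rate <= 1.0:
            raise ValueError("recruitment_rate must be in [0, 1]")

    @property
    def G(self) -> np.ndarray:
        return np.array([[self.sigma2_A, self.cov_AB],
                         [self.cov_AB, self.sigma2_B]])

    @property
    def P_pe(self) -> np.ndarray:
        return np.array([[self.sigma2_PE_int, self.cov_PE],
                         [self.cov_PE, self.sigma2_PE_slope]])

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_start + self.n_years)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["residual_sd_by_group"] = list(self.residual_sd_by_group)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "residual_sd_by_group" in d:
            d["residual_sd_by_group"] = tuple(d["residual_sd_by_group"])
        return cls(**d)


@dataclass
class DemographyResult:
    """Pedigree plus the per-year composition of the breeding population."""

    pedigree: Pedigree
    breeders: pd.DataFrame  # year, female, male, female_is_recruit, age_class

    def p_recr(self) -> pd.Series:
        """Per-year fraction of breeding females that are locally born recruits."""
        return self.breeders.groupby("year")["female_is_recruit"].mean()


# ---------------------------------------------------------------------- #
def simulate_pedigree(config: SimulationConfig, rng=None) -> DemographyResult:
    """Simulate overlapping-generation demography in a fixed-capacity plot.

    Every year the plot supports ``n_founders`` breeding pairs.  Breeders
    survive to the next year with probability ``adult_survival``; surviving
    pairs stay together with probability ``mate_fidelity``, everyone else
    re-pairs at random.  Each vacancy is filled by a locally born recruit
    with probability ``recruitment_rate``, otherwise by an immigrant, who
    enters the pedigree as a new founder.  Recruits of a cohort choose their
    natal brood proportionally to gamma-distributed per-pair weights
    (``sibship_shape``), so recruitment clusters into full-sib families as
    it does in real nest-box populations.
    """
    if rng is None:
        rng = rng_from_seed(config.seed, "pedigree")
    K = config.n_founders
    if K <= 0:
        raise SimulationError(
            f"population extinct before year {config.year_start}: no founders"
        )

    ped_rows = []  # (id, dam, sire, cohort, sex)
    counter = {"F": 0, "M": 0}

    def new_individual(sex, cohort, dam=None, sire=None):
        counter[sex] += 1
        iid = f"{sex}{counter[sex]:05d}"
        ped_rows.append((iid, dam, sire, cohort, sex))
        return iid

    # founders: mixed (unknown) ages, cohorts before the study starts
    females = [
        new_individual("F", config.year_start - int(rng.integers(1, 6)))
        for _ in range(K)
    ]
    males = [
        new_individual("M", config.year_start - int(rng.integers(1, 6)))
        for _ in range(K)
    ]
    recruit_flags = {f: False for f in females}

    cohort_of = {r[0]: r[3] for r in ped_rows}
    breeder_rows = []
    mates_f = list(males)
    rng.shuffle(mates_f)
    pairs = list(zip(females, mates_f))

    for year in config.years:
        if len(pairs) == 0:
            raise SimulationError(f"population extinct in year {year}")
        for f, m in pairs:
            age = "first-year" if cohort_of[f] == year - 1 else "older"
            breeder_rows.append(
                {"year": year, "female": f, "male": m,
                 "female_is_recruit": recruit_flags.get(f, False),
                 "age_class": age}
            )

        # per-brood recruit weights: clustering of recruits into sibships
        brood_w = rng.gamma(config.sibship_shape, size=len(pairs))
        if brood_w.sum() <= 0:
            brood_w = np.ones(len(pairs))
        brood_p = brood_w / brood_w.sum()

        def refill(survivors, sex, target):
            flags = {}
            out = list(survivors)
            while len(out) < target:
                if rng.random() < config.recruitment_rate:
                    dam, sire = pairs[int(rng.choice(len(pairs), p=brood_p))]
                    iid = new_individual(sex, year, dam=dam, sire=sire)
                    flags[iid] = True
                else:  # immigrant: new founder born elsewhere this year
                    iid = new_individual(sex, year)
                    flags[iid] = False
                cohort_of[iid] = year
                out.append(iid)
            return out, flags

        surv_f = {f for f, _ in pairs if rng.random() < config.adult_survival}
        surv_m = {m for _, m in pairs if rng.random() < config.adult_survival}
        intact = [
            (f, m) for f, m in pairs
            if f in surv_f and m in surv_m and rng.random() < config.mate_fidelity
        ]
        taken_f = {f for f, _ in intact}
        taken_m = {m for _, m in intact}
        females, fflags = refill(sorted(surv_f - taken_f), "F", K - len(intact))
        males, _ = refill(sorted(surv_m - taken_m), "M", K - len(intact))
        recruit_flags = fflags
        recruit_flags.update({f: False for f in taken_f})
        rng.shuffle(males)
        pairs = intact + list(zip(females, males))

    ped = Pedigree(
        pd.DataFrame(ped_rows, columns=["id", "dam", "sire", "cohort", "sex"])
    )
    return DemographyResult(pedigree=ped, breeders=pd.DataFrame(breeder_rows))


def simulate_environments(config: SimulationConfig, rng=None) -> pd.DataFrame:
    """Annual cue temperatures, food-peak dates and optimal laying dates.

    cue_temp ~ N(mean + trend * (year - start), sd); the peak date is linear
    in the cue with Gaussian noise; the optimal laying date is the peak date
    minus the rearing lag.
    """
    if rng is None:
        rng = rng_from_seed(config.seed, "environments")
    years = config.years
    cue = (
        config.mean_cue_temp
        + config.temp_trend * (years - config.year_start)
        + rng.normal(0.0, config.sd_cue_temp, size=len(years))
    )
    peak = (
        config.peak_intercept
        + config.peak_slope * cue
        + rng.normal(0.0, config.peak_resid_sd, size=len(years))
    )
    return pd.DataFrame(
        {
            "year": years,
            "cue_temp": cue,
            "peak_date": peak,
            "optimal_laying_date": peak - config.optimum_offset,
            "excluded": False,
        }
    )


@dataclass
class SyntheticTruth:
    """Hidden state of a simulated dataset, for parameter-recovery tests."""

    individuals: pd.DataFrame   # id, A_int, A_slope, PE_int, PE_slope
    year_effects: pd.Series
    nestbox_effects: pd.Series
    grand_mean_temp: float
    config: SimulationConfig = field(repr=False, default=None)


def _residual_sd_for_years(environments: pd.DataFrame, config: SimulationConfig):
    """Map each year to its residual sd (temperature-grouped or pooled)."""
    from .mixedmodels import assign_residual_groups  # local: avoid cycle

    sds = np.asarray(config.residual_sd_by_group, dtype=float)
    n_groups = min(len(sds), len(environments))
    if config.resid_temp_dependence and n_groups > 1:
        # with fewer years than groups, keep the coldest/warmest extremes
        use = sds[np.round(np.linspace(0, len(sds) - 1, n_groups)).astype(int)]
        groups = assign_residual_groups(environments, n_groups)
        return {int(y): use[g] for y, g in groups.items()}
    pooled = float(np.sqrt(np.mean(sds**2)))
    return {int(y): pooled for y in environments["year"]}


def simulate_breeding_data(
    demography: DemographyResult,
    environments: pd.DataFrame,
    config: SimulationConfig,
    rng=None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Laying dates and recruit counts for every breeding attempt.

    Breeding values flow down the pedigree (founders ~ MVN(0, G), offspring =
    midparent + MVN(0, G/2)); laying date adds permanent-environment, year,
    nest-box and temperature-group residual deviations around the plastic
    fixed part; expected recruits decay as a Gaussian function of the mismatch
    with the year's optimum, realized as negative-binomial counts.
    """
    if rng is None:
        rng = rng_from_seed(config.seed, "breeding")
    env = environments.set_index("year")
    breeders = demography.breeders
    missing = set(breeders["year"]) - set(env.index)
    if missing:
        raise ValueError(f"environments missing years {sorted(missing)[:5]}")

    # breeding values down the pedigree
    ped = demography.pedigree
    order = ped.topological_order()
    idx = {i: k for k, i in enumerate(order)}
    parents = {r["id"]: (r["dam"], r["sire"]) for _, r in ped.table.iterrows()}
    G = config.G
    n = len(order)
    bv = np.empty((n, 2))
    chol_G = np.linalg.cholesky(G + 1e-12 * np.eye(2))
    chol_half = chol_G / np.sqrt(2.0)
    z_f = rng.standard_normal((n, 2))
    for k, i in enumerate(order):
        d, s = parents[i]
        if d is None and s is None:
            bv[k] = chol_G @ z_f[k]
        else:
            mid = np.zeros(2)
            for p in (d, s):
                if p is not None:
                    mid += bv[idx[p]]
            bv[k] = mid / 2.0 + chol_half @ z_f[k]

    # permanent-environment deviations for breeding females
    females = sorted(breeders["female"].unique())
    pe = rng.multivariate_normal(np.zeros(2), config.P_pe, size=len(females))
    pe_map = {f: pe[k] for k, f in enumerate(females)}

    year_eff = pd.Series(
        rng.normal(0.0, np.sqrt(config.sigma2_year), size=len(env)), index=env.index
    )
    boxes = [f"NB{k:03d}" for k in range(config.n_nestboxes)]
    nb_eff = pd.Series(
        rng.normal(0.0, np.sqrt(config.sigma2_nestbox), size=len(boxes)), index=boxes
    )

    tbar = float(env["cue_temp"].mean())
    sd_by_year = _residual_sd_for_years(environments, config)

    age_eff = {
        "first-year": config.age_effect_first_year,
        "older": 0.0,
        "unknown": config.age_effect_unknown,
    }

    yrs = breeders["year"].to_numpy(int)
    fem = breeders["female"].to_numpy(object)
    ages = breeders["age_class"].to_numpy(object)
    n_rec = len(breeders)
    fem_idx = np.array([idx[f] for f in fem])
    pe_arr = np.array([pe_map[f] for f in fem])
    tc = env["cue_temp"].reindex(yrs).to_numpy() - tbar
    box_pick = rng.integers(len(boxes), size=n_rec)
    box_ids = np.array(boxes, dtype=object)[box_pick]
    mu_z = (
        config.mean_laying_date
        + np.array([age_eff[a] for a in ages])
        + (config.pop_slope + pe_arr[:, 1] + bv[fem_idx, 1]) * tc
        + pe_arr[:, 0] + bv[fem_idx, 0]
        + year_eff.reindex(yrs).to_numpy()
        + nb_eff.to_numpy()[box_pick]
    )
    sd = np.array([sd_by_year[y] for y in yrs])
    z = mu_z + rng.normal(0.0, 1.0, size=n_rec) * sd
    theta = env["optimal_laying_date"].reindex(yrs).to_numpy()
    mu_w = config.fitness_max * np.exp(
        -((z - theta) ** 2) / (2.0 * config.fitness_width**2)
    )
    manipulated = rng.random(size=n_rec) < config.manipulated_fraction
    mu_w = np.where(manipulated, mu_w * config.manipulation_effect, mu_w)
    if np.isfinite(config.overdispersion):
        k = config.overdispersion
        recruits = rng.negative_binomial(k, k / (k + mu_w))
    else:
        recruits = rng.poisson(mu_w)
    records = pd.DataFrame(
        {
            "female_id": fem,
            "year": yrs,
            "nestbox": box_ids,
            "laying_date": z,
            "age_class": ages,
            "recruits": recruits.astype(int),
            "manipulated": manipulated,
        }
    )

    # blank a fraction of female ids, biased toward extreme laying dates
    n_unknown = int(round(config.unknown_id_fraction * len(records)))
    if n_unknown > 0:
        zs = records["laying_date"].to_numpy()
        w = 0.5 + np.abs((zs - zs.mean()) / (zs.std() + 1e-12))
        pick = rng.choice(len(records), size=n_unknown, replace=False, p=w / w.sum())
        records.loc[pick, "female_id"] = None
        records.loc[pick, "age_class"] = "unknown"

    truth = SyntheticTruth(
        individuals=pd.DataFrame(
            {
                "id": order,
                "A_int": bv[:, 0],
                "A_slope": bv[:, 1],
                "PE_int": [pe_map.get(i, (np.nan, np.nan))[0] for i in order],
                "PE_slope": [pe_map.get(i, (np.nan, np.nan))[1] for i in order],
            }
        ),
        year_effects=year_eff,
        nestbox_effects=nb_eff,
        grand_mean_temp=tbar,
        config=config,
    )
    return records, truth


@dataclass
class SyntheticDataset:
    """Everything one simulated study produces."""

    config: SimulationConfig
    pedigree: Pedigree
    breeders: pd.DataFrame
    environments: pd.DataFrame
    records: pd.DataFrame
    truth: SyntheticTruth

    def p_recr(self) -> pd.Series:
        return self.breeders.groupby("year")["female_is_recruit"].mean()


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run the full generator (pedigree -> environments -> records)."""
    demog = simulate_pedigree(config)
    env = simulate_environments(config)
    records, truth = simulate_breeding_data(demog, env, config)
    return SyntheticDataset(
        config=config,
        pedigree=demog.pedigree,
        breeders=demog.breeders,
        environments=env,
        records=records,
        truth=truth,
    )
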