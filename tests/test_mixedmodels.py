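"""Mixed-model machinery: centring, grouping, posterior summaries, the
conjugate Gaussian updates, and small end-to-end sampler checks."""

import numpy as np
import pandas as pd
import pytest

import rnevo as rn
from rnevo.mixedmodels import (
    MCMCSettings,
    ModelSpec,
    PosteriorFit,
    ReactionNormAnimalModel,
    _level_update,
    assign_decade_groups,
    default_residual_groups,
    hpdi,
    posterior_summary,
)


# ------------------------------------------------------------- centring
def test_center_within_individual_cases():
    rec = pd.DataFrame({
        "female_id": ["a", "b", "b"],
        "cue_temp": [8.0, 8.0, 10.0],
    })
    within, between = rn.center_within_individual(rec)
    assert within.tolist() == [0.0, -1.0, 1.0]
    assert between.tolist() == [8.0, 9.0, 9.0]


def test_centring_reconstructs_temperature(rng):
    rec = pd.DataFrame({
        "female_id": rng.choice(list("abcdef"), 60),
        "cue_temp": rng.normal(7, 1.5, 60),
    })
    within, between = rn.center_within_individual(rec)
    assert np.allclose(within + between, rec["cue_temp"])
    sums = within.groupby(rec["female_id"]).sum()
    assert np.allclose(sums, 0.0, atol=1e-12)


# ------------------------------------------------------------- grouping
def test_default_group_count_rule():
    assert default_residual_groups(44) == 4
    assert default_residual_groups(30) == 3
    assert default_residual_groups(7) == 1


def test_equal_count_temperature_groups():
    env = pd.DataFrame({"year": np.arange(1973, 2017),
                        "cue_temp": np.sin(np.arange(44)) * 2 + 7})
    groups = rn.assign_residual_groups(env, 4)
    assert sorted(np.bincount(groups.to_numpy())) == [11, 11, 11, 11]
    # coldest years in group 0
    coldest = env.nsmallest(11, "cue_temp")["year"]
    assert (groups.loc[coldest] == 0).all()


def test_two_groups_split_by_temperature():
    env = pd.DataFrame({"year": [1, 2, 3, 4], "cue_temp": [3.0, 5.0, 7.0, 9.0]})
    groups = rn.assign_residual_groups(env, 2)
    assert groups.loc[[1, 2]].tolist() == [0, 0]
    assert groups.loc[[3, 4]].tolist() == [1, 1]


def test_decade_groups_are_calendar_blocks():
    env = pd.DataFrame({"year": np.arange(2000, 2030),
                        "cue_temp": np.random.default_rng(0).normal(7, 1, 30)})
    groups = assign_decade_groups(env, 3)
    assert (groups.loc[2000:2009] == 0).all()
    assert (groups.loc[2020:2029] == 2).all()


# ---------------------------------------------------- posterior summaries
def test_posterior_summary_constant_chain():
    med, lo, hi, ess = posterior_summary(np.full(500, 2.5))
    assert med == lo == hi == 2.5


def test_hpdi_uniform_length():
    rng = np.random.default_rng(5)
    chain = rng.random(10_000)
    lo, hi = hpdi(chain, 0.95)
    assert (hi - lo) == pytest.approx(0.95, abs=0.02)


def test_hpdi_hugs_zero_for_exponential():
    rng = np.random.default_rng(6)
    chain = rng.exponential(1.0, 5000)
    lo, _ = hpdi(chain, 0.95)
    perc_lo = np.quantile(chain, 0.025)
    assert lo < perc_lo  # shortest interval shifts to the zero boundary
    assert lo < 0.01


def test_posterior_summary_needs_length():
    with pytest.raises(ValueError, match="too short"):
        posterior_summary(np.zeros(50))


# ------------------------------------------------- variance contribution
def test_slope_variance_contribution_cases(rng):
    assert rn.slope_variance_contribution(0.0, [1, 2, 3]) == 0.0
    temps = np.array([-2.0, 0.0, 2.0])  # population variance 8/3
    assert rn.slope_variance_contribution(1.0, temps) == pytest.approx(8 / 3)
    t = rng.normal(0, 1.3, 200)
    s2 = 0.37
    assert rn.slope_variance_contribution(s2, t) == pytest.approx(
        s2 * np.var(t))


# ------------------------------------------------- conjugate toy updates
def test_level_update_matches_closed_form_posterior(rng):
    """The Gaussian conditional draw reproduces the conjugate posterior.

    One random-intercept factor with known residual variance and fixed prior
    variance: the sampled values must match the closed-form normal posterior
    N(sum(w*y)/(sum(w)+1/v0), 1/(sum(w)+1/v0)) in mean and variance.
    """
    sigma2_e, v0 = 2.0, 4.0
    y = rng.normal(3.0, np.sqrt(sigma2_e), 40)
    codes = np.zeros(40, dtype=int)
    w = np.full(40, 1.0 / sigma2_e)
    draws = np.array([
        _level_update(rng, y * w, w, codes, 1, 1.0 / v0)[0]
        for _ in range(6000)
    ])
    prec = 40 / sigma2_e + 1 / v0
    mean = (y.sum() / sigma2_e) / prec
    assert draws.mean() == pytest.approx(mean, abs=4 * np.sqrt(1 / prec / 6000))
    assert draws.var() == pytest.approx(1 / prec, rel=0.1)


# --------------------------------------------------------- sampler checks
@pytest.fixture(scope="module")
def rram_fit(small_dataset_module):
    data = small_dataset_module
    model = ReactionNormAnimalModel(
        data.records, data.environments, data.pedigree, ModelSpec(additive=True)
    )
    return model.fit(MCMCSettings(n_iter=700, burnin=200, thin=2), seed=3), data


@pytest.fixture(scope="module")
def small_dataset_module():
    cfg = rn.SimulationConfig(n_founders=30, n_years=20, seed=42)
    return rn.simulate_dataset(cfg)


def test_covariance_chains_are_psd(rram_fit):
    fit, _ = rram_fit
    for blk in ("PE", "G"):
        v1 = fit[f"{blk}[intercept,intercept]"]
        v2 = fit[f"{blk}[slope,slope]"]
        cv = fit[f"{blk}[intercept,slope]"]
        assert (v1 >= 0).all() and (v2 >= 0).all()
        assert (v1 * v2 - cv**2 >= -1e-10).all()


def test_fit_recovers_population_slope(rram_fit):
    fit, data = rram_fit
    med = fit.median("beta[temp]")
    lo, hi = fit.hpdi("beta[temp]")
    assert lo < data.config.pop_slope < hi
    assert abs(med - data.config.pop_slope) < 1.0


def test_summary_table_invariants(rram_fit):
    fit, _ = rram_fit
    s = fit.summary()
    assert (s["hpdi_lo"] <= s["median"] + 1e-12).all()
    assert (s["median"] <= s["hpdi_hi"] + 1e-12).all()
    assert s.loc["sigma2_year", "ess"] > 50


def test_zero_variance_components_stay_near_zero():
    """With no simulated individual variation the posteriors hug zero."""
    cfg = rn.SimulationConfig(
        n_founders=40, n_years=15, seed=8,
        sigma2_A=0.0, sigma2_B=0.0, cov_AB=0.0,
        sigma2_PE_int=0.0, sigma2_PE_slope=0.0, cov_PE=0.0,
        residual_sd_by_group=(4.0,), resid_temp_dependence=False,
        unknown_id_fraction=0.0,
    )
    data = rn.simulate_dataset(cfg)
    model = ReactionNormAnimalModel(data.records, data.environments,
                                    spec=ModelSpec(additive=False))
    fit = model.fit(MCMCSettings(n_iter=600, burnin=200, thin=2), seed=4)
    lo, _ = fit.hpdi("PE[slope,slope]")
    assert lo < 0.01  # HPDI abuts zero (skewed zero-bound posterior)
    # medians stay small relative to the ~16 day^2 residual variance
    assert fit.median("PE[slope,slope]") < 1.0
    assert fit.median("PE[intercept,intercept]") < 1.5
    from rnevo.residual_sim import detect_slope_variance
    assert not detect_slope_variance(fit)


def test_doubling_iterations_stable_medians():
    """Seeded convergence: doubling iterations shifts medians < MC error."""
    cfg = rn.SimulationConfig(n_founders=30, n_years=15, seed=15)
    data = rn.simulate_dataset(cfg)
    model = ReactionNormAnimalModel(data.records, data.environments,
                                    spec=ModelSpec(additive=False))
    f1 = model.fit(MCMCSettings(n_iter=800, burnin=200, thin=2), seed=5)
    f2 = model.fit(MCMCSettings(n_iter=1400, burnin=200, thin=2), seed=6)
    for par in ("beta[temp]", "PE[intercept,intercept]", "sigma2_resid[0]"):
        m1, m2 = f1.median(par), f2.median(par)
        lo, hi = f2.hpdi(par)
        scale = (hi - lo) / 2 + 1e-6
        assert abs(m1 - m2) < 0.5 * scale


def test_requires_pedigree_for_additive(small_dataset):
    with pytest.raises(ValueError, match="pedigree"):
        ReactionNormAnimalModel(small_dataset.records,
                                small_dataset.environments,
                                spec=ModelSpec(additive=True))


def test_unknown_identity_records_are_excluded(small_dataset):
    rec = small_dataset.records.copy()
    n_unknown = rec["female_id"].isna().sum()
    model = ReactionNormAnimalModel(rec, small_dataset.environments,
                                    spec=ModelSpec(additive=False))
    assert len(model.records) == len(rec) - n_unknown


def test_selection_model_requires_repeat_breeders(small_dataset):
    rec = small_dataset.records[small_dataset.records["female_id"].notna()]
    lrs = rec.groupby("female_id")["recruits"].sum()
    with pytest.raises(ValueError, match="2 breeding attempts"):
        rn.BivariateSelectionModel(rec, lrs, small_dataset.environments)


def test_bivariate_model_recovers_selection_on_elevation():
    """A population laying after its optimum shows a negative posterior
    covariance between reaction-norm elevation and lifetime fitness."""
    from rnevo.mixedmodels import build_selection_data

    cfg = rn.SimulationConfig(n_founders=60, n_years=20, seed=5,
                              mean_laying_date=30.0, fitness_width=9.0)
    data = rn.simulate_dataset(cfg)
    sub, lrs = build_selection_data(data.records, 1973, 1992)
    model = rn.BivariateSelectionModel(sub, lrs, data.environments)
    fit = model.fit(MCMCSettings(n_iter=2600, burnin=600, thin=4), seed=2)
    med = fit.median("P[LD_intercept,LRS]")
    lo, hi = fit.hpdi("P[LD_intercept,LRS]")
    assert med < 0 and hi < 0  # clearly negative, not just the median
    # variance components positive and the LD intercept variance sensible
    assert fit.median("P[LD_intercept,LD_intercept]") > 3.0
    assert fit.median("P[LD_slope,LD_slope]") >= 0.0


def test_build_selection_data_rules(small_dataset):
    from rnevo.mixedmodels import build_selection_data

    sub, lrs = build_selection_data(small_dataset.records, 1973, 1992)
    counts = sub.groupby("female_id").size()
    assert (counts >= 2).all()
    assert sub["female_id"].notna().all()
    # LRS sums all of a female's records
    f = counts.index[0]
    all_rec = small_dataset.records
    assert lrs[f] == all_rec.loc[all_rec["female_id"] == f, "recruits"].sum()
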