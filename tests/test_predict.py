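"""Reaction-norm breeder's equation: exact arithmetic and propagation."""

import numpy as np
import pandas as pd
import pytest

import rnevo as rn

G_TABLE = np.array([[4.38, 0.07], [0.07, 0.02]])  # posterior-median defaults


# ------------------------------------------------------- gradient mapping
def test_map_single_environment():
    out = rn.map_gradients_to_rn([-0.3], [2.0])
    assert np.allclose(out, [-0.3, -0.6])


def test_map_symmetric_environments():
    out = rn.map_gradients_to_rn([0.4, 0.4], [-1.0, 1.0])
    assert np.allclose(out, [0.8, 0.0])


def test_map_matches_matrix_product(rng):
    b = rng.normal(size=10)
    x = rng.normal(size=10)
    out = rn.map_gradients_to_rn(b, x)
    phi = np.column_stack([np.ones(10), x])
    assert np.allclose(out, phi.T @ b, atol=1e-12)


# ------------------------------------------------------- annual response
def test_annual_response_identity_case():
    dg = rn.annual_response(np.eye(2), 0.0, -1.0, 1.0, sex_limited=True)
    assert np.allclose(dg, [-0.5, 0.0])


def test_annual_response_hand_arithmetic():
    # G(1,2)' = (4.52, 0.11); x beta(-0.05) x p_recr(0.4) x 0.5
    dg = rn.annual_response(G_TABLE, 2.0, -0.05, 0.4, sex_limited=True)
    assert np.allclose(dg, [-0.0452, -0.0011], atol=1e-12)


def test_annual_response_reduces_to_plain_breeders_equation(rng):
    G = G_TABLE
    x, beta = rng.normal(), rng.normal()
    dg = rn.annual_response(G, x, beta, 1.0, sex_limited=False)
    assert np.allclose(dg, G @ np.array([1.0, x]) * beta, atol=1e-12)


def test_annual_response_linearity(rng):
    x = 1.3
    d1 = rn.annual_response(G_TABLE, x, -0.1, 0.5)
    d2 = rn.annual_response(G_TABLE, x, -0.2, 0.5)
    assert np.allclose(d2, 2 * d1)
    d3 = rn.annual_response(G_TABLE, x, -0.1, 1.0)
    assert np.allclose(d3, 2 * d1)


def test_diagonal_G_mean_environment_cannot_move_slope():
    dg = rn.annual_response(np.diag([4.0, 0.1]), 0.0, -0.3, 1.0)
    assert dg[1] == 0.0


def test_sex_limitation_halves_exactly():
    a = rn.annual_response(G_TABLE, 1.5, -0.2, 0.7, sex_limited=False)
    b = rn.annual_response(G_TABLE, 1.5, -0.2, 0.7, sex_limited=True)
    assert np.allclose(b, 0.5 * a)


def test_annual_response_validates_inputs():
    with pytest.raises(ValueError, match="PSD"):
        rn.annual_response(np.array([[1.0, 2.0], [2.0, 1.0]]), 0.0, -0.1)
    with pytest.raises(ValueError, match="p_recr"):
        rn.annual_response(np.eye(2), 0.0, -0.1, 1.5)


# ------------------------------------------------------ error propagation
def test_propagate_se_collapse_cases():
    se = rn.propagate_se(G_TABLE, 2.0, -0.05, 0.02, np.zeros((2, 2)),
                         1.0, sex_limited=False)
    genv = np.abs(G_TABLE @ np.array([1.0, 2.0]))
    assert np.allclose(se, genv * 0.02)
    se0 = rn.propagate_se(G_TABLE, 2.0, 0.0, 0.0,
                          np.full((2, 2), 0.3), 1.0, sex_limited=False)
    assert np.allclose(se0, 0.0)


def test_propagate_se_scaled_like_point_estimate():
    se_G = np.array([[1.2, 0.15], [0.15, 0.04]])
    se_a = rn.propagate_se(G_TABLE, 1.0, -0.1, 0.03, se_G, 1.0, False)
    se_b = rn.propagate_se(G_TABLE, 1.0, -0.1, 0.03, se_G, 0.4, True)
    assert np.allclose(se_b, se_a * 0.2)


def test_propagate_se_close_to_monte_carlo(rng):
    """First-order SE within 10% of a 1e5-draw Monte-Carlo propagation."""
    configs = [
        (G_TABLE, 1.0, -0.05, 0.015, np.array([[1.2, 0.16], [0.16, 0.04]])),
        (G_TABLE, -2.0, -0.10, 0.02, np.array([[0.8, 0.10], [0.10, 0.03]])),
        (np.array([[6.0, 0.2], [0.2, 0.3]]), 0.5, 0.08, 0.025,
         np.array([[1.0, 0.2], [0.2, 0.08]])),
    ]
    n = 100_000
    for G, x, beta, se_b, se_G in configs:
        se = rn.propagate_se(G, x, beta, se_b, se_G, 1.0, sex_limited=False)
        env = np.array([1.0, x])
        g_env = G @ env
        se_g_env = np.sqrt((se_G**2) @ env**2)
        draws_b = rng.normal(beta, se_b, n)
        for k in range(2):
            draws_g = rng.normal(g_env[k], se_g_env[k], n)
            mc = np.std(draws_g * draws_b)
            assert abs(se[k] - mc) / mc < 0.10


# ------------------------------------------------------------ cumulative
def test_cumulative_single_year():
    total, lo, hi = rn.cumulative_response([[-0.2, -0.01]], [[0.05, 0.002]])
    assert np.allclose(total, [-0.2, -0.01])
    assert np.allclose(hi - total, 1.96 * np.array([0.05, 0.002]))


def test_cumulative_three_four_five():
    total, lo, hi = rn.cumulative_response([[1.0], [1.0]], [[3.0], [4.0]])
    assert total[0] == 2.0
    assert (hi - total)[0] == pytest.approx(1.96 * 5.0)


def test_cumulative_matches_accumulation_script(rng):
    d = rng.normal(size=(20, 2))
    s = np.abs(rng.normal(size=(20, 2)))
    total, lo, hi = rn.cumulative_response(d, s)
    assert np.allclose(total, d.sum(axis=0))
    assert np.allclose(hi, d.sum(axis=0) + 1.96 * np.sqrt((s**2).sum(axis=0)))
    assert np.allclose(total - lo, hi - total)  # symmetric CI


def test_cumulative_requires_entries():
    with pytest.raises(ValueError):
        rn.cumulative_response(np.empty((0, 2)), np.empty((0, 2)))


# ------------------------------------------------------------ trajectory
def grad_frame(years, beta, se):
    return pd.DataFrame({"year": years, "beta_z": beta, "se": se})


def env_frame(years, temps):
    return pd.DataFrame({"year": years, "cue_temp": temps})


def test_zero_gradients_zero_trajectory():
    years = np.arange(2000, 2010)
    env = env_frame(years, np.linspace(5, 8, 10))
    grads = grad_frame(years, 0.0, 0.01)
    p_recr = pd.Series(0.3, index=np.arange(2000, 2011))
    traj = rn.predict_trajectory(G_TABLE, np.zeros((2, 2)), grads, env,
                                 p_recr, baseline_last_year=2004)
    assert np.allclose(traj.cumulative, 0.0)
    assert len(traj.table) == 5


def test_uncorrected_mode_equals_plain_equation():
    years = np.arange(2000, 2006)
    env = env_frame(years, [5, 6, 7, 8, 6, 7])
    grads = grad_frame(years, -0.05, 0.01)
    p_recr = pd.Series(1.0, index=years)
    traj = rn.predict_trajectory(G_TABLE, np.zeros((2, 2)), grads, env,
                                 p_recr, 2002, generation_corrected=False)
    tbar = env["cue_temp"].mean()
    for _, row in traj.table.iterrows():
        x = row["temp"] - tbar
        expect = G_TABLE @ np.array([1.0, x]) * -0.05
        assert np.allclose([row["d_elev"], row["d_slope"]], expect)


def test_missing_gradient_years_are_skipped():
    years = np.arange(2000, 2006)
    env = env_frame(years, np.linspace(5, 8, 6))
    grads = grad_frame([2003, 2005], [-0.05, np.nan], [0.01, np.nan])
    p_recr = pd.Series(0.4, index=years)
    traj = rn.predict_trajectory(G_TABLE, np.zeros((2, 2)), grads, env,
                                 p_recr, 2002)
    assert traj.skipped_years == [2004, 2005]
    assert traj.table["year"].tolist() == [2003]


def test_baseline_covering_everything_raises():
    years = np.arange(2000, 2005)
    env = env_frame(years, np.linspace(5, 8, 5))
    with pytest.raises(ValueError, match="nothing to predict"):
        rn.predict_trajectory(G_TABLE, np.zeros((2, 2)),
                              grad_frame(years, -0.05, 0.01), env,
                              pd.Series(0.4, index=years), 2010)


def test_p_recr_uses_next_year(small_dataset):
    pr = rn.predict.compute_p_recr(small_dataset.breeders)
    years = small_dataset.environments["year"]
    grads = grad_frame(years, -0.05, 0.01)
    traj = rn.predict_trajectory(G_TABLE, np.zeros((2, 2)), grads,
                                 small_dataset.environments, pr,
                                 baseline_last_year=int(years.iloc[6]))
    row = traj.table.iloc[0]
    assert row["p_recr_next"] == pytest.approx(pr[row["year"] + 1])
    # final year has no next-year recruit fraction: skipped
    assert int(years.iloc[-1]) in traj.skipped_years
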