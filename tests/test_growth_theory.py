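"""Effective growth rate k = ∫ p(τ) ln β(τ)/τ dτ and its optima."""

import math

import numpy as np
import pytest

from phagesim.growth_theory import (
    effective_growth_rate,
    growth_rate_difference,
    growth_rate_grid,
    optimal_mean_lysis_time,
)
from phagesim.life_history import (
    BurstSizeModel,
    LysisTimeDistribution,
    default_strain,
    distribution_from_mean_std,
)

ECLIPSE = BurstSizeModel("linear_with_eclipse", {"rate": 20.0, "eclipse": 9.5})
LINEAR = BurstSizeModel("linear", {"rate": 8.82})
NORMAL = BurstSizeModel("normal", {"burst_mean": 150.0, "burst_std": 50.0})
MODELS = {"normal": NORMAL, "linear": LINEAR, "linear_with_eclipse": ECLIPSE}


def delta(tau):
    return LysisTimeDistribution("delta", {"tau": tau})


def test_delta_closed_form_and_calibration_point():
    """All three models give k = ln(150)/17 at the shared calibration."""
    expected = math.log(150.0) / 17.0
    for model in MODELS.values():
        res = effective_growth_rate(delta(17.0), model)
        beta = 150.0 if model.kind != "linear" else 149.94
        assert res.k == pytest.approx(math.log(beta) / 17.0, abs=1e-12)
        assert res.k == pytest.approx(expected, abs=1e-4)
        assert res.quadrature_abs_error == 0.0


def test_nonviable_delta_returns_sentinel():
    res = effective_growth_rate(delta(9.5), ECLIPSE)  # burst 0 at the eclipse edge
    assert res.k == -math.inf
    assert res.excluded_mass == 1.0


def test_delta_limit_oracle():
    """Vanishing-noise quadrature agrees with the closed form ln β(τ̄)/τ̄."""
    for model in MODELS.values():
        for tau in (12.0, 17.0, 25.0):
            narrow = distribution_from_mean_std("gaussian", tau, 1e-4)
            k_quad = effective_growth_rate(narrow, model).k
            k_exact = effective_growth_rate(delta(tau), model).k
            assert abs(k_quad - k_exact) < 1e-4


@pytest.mark.parametrize("model", [NORMAL, LINEAR], ids=["normal", "linear"])
def test_noise_raises_k_for_convex_models(model):
    """Symmetric lysis-time noise increases k when ln β(τ)/τ is convex."""
    for tau in np.arange(10.0, 31.0, 5.0):
        k0 = effective_growth_rate(delta(tau), model).k
        k1 = effective_growth_rate(
            distribution_from_mean_std("gaussian", tau, 2.5), model
        ).k
        assert k1 > k0


def test_noise_lowers_k_for_eclipse_model():
    k0 = effective_growth_rate(delta(17.0), ECLIPSE).k
    k1 = effective_growth_rate(distribution_from_mean_std("gaussian", 17.0, 2.5), ECLIPSE).k
    assert k1 < k0


def test_deterministic_optimum_matches_grid_scan():
    """Bounded optimization agrees with a brute-force scan of ln(m(τ−ε))/τ."""
    taus = np.arange(9.6, 60.0, 1e-3)
    ks = np.log(20.0 * (taus - 9.5)) / taus
    brute_tau = taus[np.nanargmax(ks)]
    res = optimal_mean_lysis_time(ECLIPSE, std=0.0)
    assert not res.monotone
    assert res.tau_opt == pytest.approx(brute_tau, abs=5e-3)
    assert res.k_opt == pytest.approx(np.nanmax(ks), abs=1e-6)


def test_optimum_shifts_right_and_declines_with_noise():
    stds = [0.0, 1.0, 2.0, 3.0, 4.0]
    results = [optimal_mean_lysis_time(ECLIPSE, std=s) for s in stds]
    taus = [r.tau_opt for r in results]
    ks = [r.k_opt for r in results]
    assert all(b >= a - 1e-6 for a, b in zip(taus, taus[1:]))
    assert taus[-1] > taus[0] + 0.5  # strictly rightward overall
    assert all(b <= a + 1e-9 for a, b in zip(ks, ks[1:]))


@pytest.mark.parametrize("model", [NORMAL, LINEAR], ids=["normal", "linear"])
def test_monotone_models_flagged(model):
    res = optimal_mean_lysis_time(model, std=2.5, search_interval=(10.0, 30.0))
    assert res.monotone
    assert res.tau_opt == 10.0
    # k decreasing in mean lysis time
    k_lo = effective_growth_rate(distribution_from_mean_std("gaussian", 10.0, 2.5), model).k
    k_hi = effective_growth_rate(distribution_from_mean_std("gaussian", 30.0, 2.5), model).k
    assert k_lo > k_hi


def test_degenerate_search_interval_rejected():
    with pytest.raises(ValueError):
        optimal_mean_lysis_time(ECLIPSE, std=0.0, search_interval=(20.0, 20.0))


def test_growth_rate_difference_antisymmetric():
    wt = default_strain("wildtype", "linear", 20.0, 0.0)
    mu = default_strain("mutant", "linear", 12.0, 0.0)
    expected = math.log(8.82 * 12) / 12 - math.log(8.82 * 20) / 20
    assert growth_rate_difference(mu, wt) == pytest.approx(expected, abs=1e-10)
    assert growth_rate_difference(wt, mu) == pytest.approx(-expected, abs=1e-10)
    assert growth_rate_difference(wt, wt) == 0.0


def test_growth_rate_grid_matches_closed_form_at_zero_std():
    means = np.array([12.0, 17.0, 25.0])
    grid = growth_rate_grid(ECLIPSE, means, [0.0, 2.5])
    assert grid.k.shape == (3, 2)
    for i, m in enumerate(means):
        assert grid.k[i, 0] == pytest.approx(math.log(20 * (m - 9.5)) / m, abs=1e-10)


def test_eclipse_grid_has_interior_optimum_per_std_column():
    means = np.arange(10.0, 30.5, 1.0)
    grid = growth_rate_grid(ECLIPSE, means, [0.5, 2.5, 4.0])
    for j in range(grid.k.shape[1]):
        col = grid.k[:, j]
        arg = int(np.nanargmax(col))
        assert 0 < arg < len(means) - 1


def test_single_cell_grid_reduces_to_one_call():
    grid = growth_rate_grid(NORMAL, [17.0], [2.5])
    direct = effective_growth_rate(distribution_from_mean_std("gaussian", 17.0, 2.5), NORMAL)
    assert grid.k[0, 0] == pytest.approx(direct.k, abs=1e-12)


def test_skewness_effects_at_fixed_mean_and_std():
    """Negative skew helps the convex (normal/linear) models; positive skew
    helps the eclipse model by thinning the unproductive left tail."""
    for model in (NORMAL, LINEAR):
        k_neg = effective_growth_rate(
            distribution_from_mean_std("skew_normal", 17.0, 2.5, skew_shape=-4.0), model
        ).k
        k_pos = effective_growth_rate(
            distribution_from_mean_std("skew_normal", 17.0, 2.5, skew_shape=4.0), model
        ).k
        assert k_neg > k_pos
    k_neg = effective_growth_rate(
        distribution_from_mean_std("skew_normal", 17.0, 2.5, skew_shape=-4.0), ECLIPSE
    ).k
    k_pos = effective_growth_rate(
        distribution_from_mean_std("skew_normal", 17.0, 2.5, skew_shape=4.0), ECLIPSE
    ).k
    assert k_pos > k_neg


def test_erlang_shape_orderings():
    """Low shape (large variance) favours the normal/linear models; high
    shape (small variance) favours the eclipse model, at fixed mean."""

    def k_of(model, shape):
        d = LysisTimeDistribution("erlang", {"shape": shape, "rate": shape / 17.0})
        return effective_growth_rate(d, model).k

    for model in (NORMAL, LINEAR):
        assert k_of(model, 4) > k_of(model, 16) > k_of(model, 100)
    assert k_of(ECLIPSE, 100) > k_of(ECLIPSE, 16) > k_of(ECLIPSE, 4)
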