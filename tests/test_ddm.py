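"""Wiener first-passage density, sampler, and maximum-likelihood fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from nwlchoice.ddm import (
    DDMParams,
    FitSettings,
    fit_all_conditions,
    fit_ddm,
    hit_probability,
    mean_decision_time,
    sample_wiener,
    simulate_choices,
    wiener_loglik,
    wiener_pdf,
)

valid_params = st.builds(
    DDMParams,
    boundary_sep=st.floats(0.6, 3.0),
    non_decision=st.floats(0.0, 0.5),
    bias=st.floats(0.15, 0.85),
    drift=st.floats(-2.5, 2.5),
)


def test_params_validation():
    with pytest.raises(ValueError):
        DDMParams(0.0, 0.3, 0.5, 1.0)
    with pytest.raises(ValueError):
        DDMParams(1.0, -0.1, 0.5, 1.0)
    with pytest.raises(ValueError):
        DDMParams(1.0, 0.3, 1.0, 1.0)
    with pytest.raises(ValueError):
        DDMParams(1.0, 0.3, 0.5, np.inf)


@settings(max_examples=12, deadline=None, derandomize=True)
@given(valid_params)
def test_density_normalizes_to_one(p):
    total = quad(
        lambda t: wiener_pdf(t, "upper", p) + wiener_pdf(t, "lower", p),
        p.non_decision,
        p.non_decision + 80.0,
        limit=300,
    )[0]
    assert total == pytest.approx(1.0, abs=1e-3)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(valid_params)
def test_density_reflection_symmetry(p):
    mirrored = DDMParams(p.boundary_sep, p.non_decision, 1 - p.bias, -p.drift)
    ts = p.non_decision + np.linspace(0.01, 6.0, 40)
    np.testing.assert_allclose(
        wiener_pdf(ts, "upper", p), wiener_pdf(ts, "lower", mirrored), rtol=0, atol=1e-12
    )


def test_density_zero_before_non_decision():
    p = DDMParams(1.5, 0.4, 0.5, 1.0)
    assert wiener_pdf(0.39, "upper", p) == 0.0
    assert wiener_pdf(np.array([0.1, 0.4]), "lower", p).sum() == 0.0


def test_hit_probability_limits():
    assert hit_probability(DDMParams(2.0, 0.0, 0.7, 0.0)) == pytest.approx(0.7)
    assert hit_probability(DDMParams(2.0, 0.0, 0.5, 50.0)) == pytest.approx(1.0, abs=1e-6)
    assert hit_probability(DDMParams(2.0, 0.0, 0.5, -50.0)) == pytest.approx(0.0, abs=1e-6)


def test_hit_probability_vs_simulation():
    p = DDMParams(2.0, 0.0, 0.5, 1.0)
    rng = np.random.default_rng(42)
    rt, up, cen = simulate_choices(p, 40_000, rng, dt=5e-4)
    assert cen.sum() == 0
    p_hat = up.mean()
    p_true = hit_probability(p)
    sd = np.sqrt(p_true * (1 - p_true) / up.size)
    assert abs(p_hat - p_true) < 3 * sd


def test_sampler_respects_non_decision_and_timeout():
    p = DDMParams(1.5, 0.3, 0.5, 0.5)
    rng = np.random.default_rng(0)
    rt, up, cen = simulate_choices(p, 2000, rng, timeout=4.0)
    assert np.nanmin(rt) >= 0.3
    assert np.isnan(rt[cen]).all()
    # aggressive timeout censors rather than drops
    rt2, _, cen2 = simulate_choices(p, 500, rng, timeout=0.5)
    assert cen2.any()
    assert len(rt2) == 500


def test_mean_decision_time_matches_monte_carlo():
    rng = np.random.default_rng(3)
    for alpha, drift in [(1.2, 0.8), (2.0, 1.5), (1.6, 0.2)]:
        p = DDMParams(alpha, 0.0, 0.5, drift)
        rt, _, cen = simulate_choices(p, 20_000, rng, dt=5e-4)
        mc = rt[~cen]
        se = mc.std() / np.sqrt(mc.size)
        assert abs(mc.mean() - mean_decision_time(p)) < 2 * se + 5e-4


def test_loglik_guard_and_additivity():
    p = DDMParams(1.5, 0.5, 0.5, 1.0)
    assert wiener_loglik([0.4], [True], p) < -1e9  # rt <= tau is impossible
    rts = np.array([0.8, 1.1, 0.9])
    ups = np.array([True, False, True])
    single = wiener_loglik(rts, ups, p)
    double = wiener_loglik(np.tile(rts, 2), np.tile(ups, 2), p)
    assert double == pytest.approx(2 * single, rel=1e-12)
    with pytest.raises(ValueError):
        wiener_loglik([], [], p)


def test_loglik_dominance_at_true_params():
    true = DDMParams(1.5, 0.3, 0.6, 0.8)
    rng = np.random.default_rng(9)
    rt, up, cen = simulate_choices(true, 10_000, rng)
    rt, up = rt[~cen], up[~cen]
    ll_true = wiener_loglik(rt, up, true)
    for perturbed in (
        DDMParams(1.9, 0.3, 0.6, 0.8),
        DDMParams(1.5, 0.15, 0.6, 0.8),
        DDMParams(1.5, 0.3, 0.45, 0.8),
        DDMParams(1.5, 0.3, 0.6, 1.4),
    ):
        assert ll_true > wiener_loglik(rt, up, perturbed)


def test_fit_recovers_generating_parameters():
    true = DDMParams(1.5, 0.3, 0.6, 0.8)
    rng = np.random.default_rng(7)
    rt, up, cen = simulate_choices(true, 1000, rng)
    fit = fit_ddm(rt[~cen], up[~cen], rng=np.random.default_rng(1))
    assert fit.converged
    est = fit.params
    assert est.boundary_sep == pytest.approx(true.boundary_sep, rel=0.10)
    assert est.non_decision == pytest.approx(true.non_decision, rel=0.10)
    assert est.drift == pytest.approx(true.drift, rel=0.10)
    assert abs(est.bias - true.bias) < 0.05


def test_fit_requires_min_trials():
    with pytest.raises(ValueError, match="at least"):
        fit_ddm(np.full(5, 1.0), np.ones(5, bool))


def test_refit_from_optimum_is_stable():
    true = DDMParams(1.4, 0.25, 0.55, 0.6)
    rng = np.random.default_rng(5)
    rt, up, cen = simulate_choices(true, 300, rng)
    rt, up = rt[~cen], up[~cen]
    fit = fit_ddm(rt, up, rng=np.random.default_rng(2))
    refit = fit_ddm(rt, up, init=fit.params)
    assert refit.log_likelihood >= fit.log_likelihood - 1e-6


def test_degenerate_all_healthy_condition_flagged():
    rng = np.random.default_rng(8)
    # slow, conflicted response times yet every choice healthy: the only way
    # to kill the lower-boundary mass is to push parameters to their bounds
    rt, up, cen = simulate_choices(DDMParams(1.8, 0.3, 0.5, 0.3), 60, rng)
    up[:] = True
    fit = fit_ddm(rt[~cen], up[~cen], rng=np.random.default_rng(3))
    assert fit.converged
    assert fit.at_bound


def test_fit_all_conditions_bookkeeping(small_study, small_metrics):
    import pandas as pd

    one = small_metrics[small_metrics.participant_id == "p000"]
    fits = fit_all_conditions(one, FitSettings(n_restarts=2), seed=0)
    assert len(fits) == 6
    assert set(zip(fits.context, fits.nwl_shown)) == {
        (c, s) for c in ("healthy", "typical", "unrestricted") for s in (False, True)
    }
    assert not fits.insufficient_trials.any()
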