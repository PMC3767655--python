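"""The FRAP forward model against closed-form oracles, and its fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import curve_fit

from fa_relax.frap_model import (
    ExchangeParameters,
    FRAPCurve,
    calibrate_bleach_depth,
    estimate_pools,
    fit_diffusion,
    fit_exchange,
    half_time,
    mobile_fraction,
    normalize_and_average,
    pure_diffusion_recovery,
    simulate_recovery,
)
from fa_relax.frap_model import _forward


# ---------------------------------------------------------------------------
# forward model vs oracles


def test_pde_matches_diffusion_series_in_zero_binding_limit():
    """With no exchange the PDE must reproduce the Gaussian-spot series <1%."""
    p = ExchangeParameters(d_c=1.2, k_on=0.0, k_off=0.0, k_bleach=2.2)
    t = np.linspace(0.0, 3.0, 151)
    pde = _forward(p, t)
    series = pure_diffusion_recovery(1.2, p.w, 2.2, t).intensity
    assert np.max(np.abs(pde - series)) < 0.01


def test_reaction_dominant_limit_recovers_at_k_off():
    """Fast diffusion + 90% bound: recovery ≈ 1 − C·exp(−k_off t) within 10%."""
    koff = 0.005
    p = ExchangeParameters(d_c=100.0, k_on=9 * koff, k_off=koff, k_bleach=2.2)
    t = np.linspace(0.0, 1000.0, 200)
    f = _forward(p, t)

    def model(t, c, k, a):
        return a - c * np.exp(-k * t)

    popt, _ = curve_fit(model, t[5:], f[5:], p0=[0.5, koff, 1.0])
    assert abs(popt[1] / koff - 1) < 0.10


def test_mass_conserved_after_bleach(exchange_params, frap_times):
    """Total ∬(f+b)dA is invariant under diffusion + exchange (reflecting box)."""
    _, diag = simulate_recovery(exchange_params, frap_times, full_output=True)
    mass = diag["mass"]
    assert np.ptp(mass) / mass[0] < 1e-3


@pytest.mark.parametrize("kon,koff", [(0.0, 0.0), (0.01, 0.005), (0.001, 0.01)])
def test_noiseless_recovery_is_monotone(kon, koff):
    p = ExchangeParameters(d_c=1.2, k_on=kon, k_off=koff, k_bleach=2.0)
    f = _forward(p, np.linspace(0.0, 600.0, 120))
    assert np.all(np.diff(f) > -1e-9)


def test_bleach_depth_calibration_hits_target_window():
    """K_bleach calibrated for 50–75% bleach yields F(0⁺) in [0.25, 0.5]."""
    for depth in (0.5, 0.6, 0.75):
        k = calibrate_bleach_depth(depth)
        p = ExchangeParameters(d_c=1.2, k_on=0.01, k_off=0.005, k_bleach=k)
        f0 = _forward(p, np.array([0.0]))[0]
        assert f0 == pytest.approx(1.0 - depth, abs=0.02)
        assert 0.5 <= 1.0 - f0 <= 0.76


def test_grid_too_coarse_is_rejected(exchange_params):
    with pytest.raises(ValueError, match="coarse"):
        _forward(exchange_params, np.array([0.0, 1.0]), dr=exchange_params.w / 5)


@pytest.mark.parametrize(
    "field,value",
    [("d_c", -1.0), ("k_on", -0.1), ("k_off", -0.1), ("w", 0.0), ("d_m", 0.05)],
)
def test_invalid_parameters_rejected_naming_field(field, value):
    p = ExchangeParameters(**{field: value})
    with pytest.raises(ValueError, match=field):
        p.validate()


def test_simulate_requires_prebleach_samples(exchange_params):
    with pytest.raises(ValueError, match="pre-bleach"):
        simulate_recovery(exchange_params, np.linspace(0, 10, 20))


# ---------------------------------------------------------------------------
# pure-diffusion series


def test_series_initial_value_matches_bleach_depth():
    k = 2.2
    curve = pure_diffusion_recovery(1.2, 0.385, k, np.array([-1.0, 0.0]))
    assert curve.intensity[-1] == pytest.approx((1 - np.exp(-k)) / k, rel=1e-9)


def test_series_recovers_fully_at_long_times():
    curve = pure_diffusion_recovery(1.2, 0.385, 2.2, np.array([-1.0, 1e5]))
    assert curve.intensity[-1] == pytest.approx(1.0, abs=1e-3)


@given(depth=st.floats(0.05, 0.95))
@settings(max_examples=20, deadline=None)
def test_bleach_calibration_roundtrip(depth):
    k = calibrate_bleach_depth(depth)
    f0 = (1 - np.exp(-k)) / k
    assert f0 == pytest.approx(1 - depth, abs=1e-9)


# ---------------------------------------------------------------------------
# normalization and averaging


def _raw_trace(scale=350.0, bleach_index=3, n_post=30, tau=20.0, depth=0.6, dt=1.0):
    t = np.arange(-bleach_index, n_post) * dt
    y = np.ones_like(t)
    post = t >= 0
    y[post] = 1 - depth * np.exp(-t[post] / tau)
    return FRAPCurve(t, scale * y, bleach_index)


def test_average_sets_prebleach_mean_to_one():
    avg = normalize_and_average([_raw_trace(scale=350.0)])
    assert avg.prebleach.mean() == pytest.approx(1.0, abs=1e-12)


def test_averaging_identical_curves_is_idempotent():
    tr = _raw_trace()
    avg = normalize_and_average([tr, tr, tr])
    single = normalize_and_average([tr])
    np.testing.assert_allclose(avg.intensity, single.intensity, rtol=1e-12)
    assert avg.n_averaged == 3


def test_curves_with_different_bleach_indices_align_at_bleach():
    a = _raw_trace(bleach_index=3)
    b = _raw_trace(bleach_index=6)
    avg = normalize_and_average([a, b])
    assert avg.bleach_index == 3
    assert avg.times[avg.bleach_index] == pytest.approx(0.0)
    # both traces share the same shape, so the average equals either
    np.testing.assert_allclose(avg.post_intensity, a.normalized().post_intensity, rtol=1e-12)


def test_nonpositive_prebleach_trace_excluded_then_error():
    good = _raw_trace()
    bad = FRAPCurve(good.times, np.zeros_like(good.intensity), good.bleach_index)
    with pytest.warns(UserWarning, match="excluded"):
        avg = normalize_and_average([good, bad])
    assert avg.n_averaged == 1
    with pytest.warns(UserWarning):
        with pytest.raises(ValueError, match="all traces"):
            normalize_and_average([bad])


# ---------------------------------------------------------------------------
# D_C fit (short timescale)


def _short_curve(d, w=0.385, k=2.2, dt=0.02):
    t = np.concatenate([[-0.3, -0.2, -0.1], np.arange(0.0, 3.0, dt)])
    return pure_diffusion_recovery(d, w, k, t)


def test_fit_diffusion_recovers_d_within_2pct():
    fit = fit_diffusion(_short_curve(1.2), w=0.385)
    assert fit.converged
    assert fit.d_c == pytest.approx(1.2, rel=0.02)


@pytest.mark.parametrize("d_true", [1.0, 1.25, 1.5])
def test_fit_diffusion_across_physiological_range(d_true):
    fit = fit_diffusion(_short_curve(d_true), w=0.385)
    assert 0.9 <= fit.d_c <= 1.65


def test_fit_diffusion_flat_curve_flags_nonconvergence():
    t = np.concatenate([[-0.3, -0.2, -0.1], np.arange(0.0, 3.0, 0.1)])
    flat = FRAPCurve(t, np.ones_like(t), 3)
    fit = fit_diffusion(flat, w=0.385)
    assert not fit.converged


# ---------------------------------------------------------------------------
# pool estimation


@pytest.mark.parametrize(
    "fa,adj,c,expected",
    [(1000.0, 400.0, 1.0, (1000.0, 400.0)),
     (0.0, 7.0, 2.0, (0.0, 14.0)),
     (5.0, 5.0, 3.0, (15.0, 15.0))],
)
def test_estimate_pools(fa, adj, c, expected):
    assert estimate_pools(fa, adj, c) == expected


def test_estimate_pools_rejects_negative():
    with pytest.raises(ValueError):
        estimate_pools(-1.0, 5.0, 1.0)


# ---------------------------------------------------------------------------
# exchange fit


def test_fit_exchange_recovers_rates_noiseless(noiseless_curve):
    fit = fit_exchange(noiseless_curve, d_c=1.2, n_fa=1000.0, n_c=500.0)
    assert fit.converged
    assert fit.k_on == pytest.approx(0.01, rel=0.05)
    assert fit.k_off == pytest.approx(0.005, rel=0.05)
    assert 0.0 <= fit.r_f <= 1.05
    assert fit.t_half > 0


def test_fit_exchange_invariant_to_intensity_units(frap_times):
    """Rescaling the raw trace (camera gain) must not move the fitted rates."""
    p = ExchangeParameters(d_c=1.2, k_on=0.008, k_off=0.004, k_bleach=2.0,
                           n_fa=1000.0, n_c=500.0)
    clean = simulate_recovery(p, frap_times)
    raw = FRAPCurve(clean.times, clean.intensity * 1234.5, clean.bleach_index)
    fit_a = fit_exchange(normalize_and_average([clean]), d_c=1.2, n_fa=1000.0, n_c=500.0)
    fit_b = fit_exchange(normalize_and_average([raw]), d_c=1.2, n_fa=1000.0, n_c=500.0)
    assert fit_a.k_on == pytest.approx(fit_b.k_on, rel=1e-6)
    assert fit_a.k_off == pytest.approx(fit_b.k_off, rel=1e-6)


def test_fit_exchange_symmetric_rates(frap_times):
    """A stable-state protein (k_on = k_off) fits back symmetric rates."""
    p = ExchangeParameters(d_c=1.2, k_on=0.006, k_off=0.006, k_bleach=2.0,
                           n_fa=500.0, n_c=500.0)
    curve = simulate_recovery(p, frap_times)
    fit = fit_exchange(curve, d_c=1.2, n_fa=500.0, n_c=500.0)
    assert fit.k_on == pytest.approx(fit.k_off, rel=0.10)


# ---------------------------------------------------------------------------
# recovery summary statistics


def test_mobile_fraction_full_and_none():
    t = np.concatenate([[-2.0, -1.0], np.linspace(0, 100, 60)])
    full = np.concatenate([[1.0, 1.0], 1 - 0.6 * np.exp(-np.linspace(0, 100, 60) / 3.0)])
    assert mobile_fraction(FRAPCurve(t, full, 2)) == pytest.approx(1.0, abs=0.01)
    flat = np.concatenate([[1.0, 1.0], np.full(60, 0.4)])
    with pytest.warns(UserWarning):
        assert mobile_fraction(FRAPCurve(t, flat, 2)) == 0.0


def test_half_time_matches_analytic_crossing():
    """T_half on the diffusion series agrees with root-finding on the series."""
    from scipy.optimize import brentq

    d, w, k = 1.2, 0.385, 2.2
    t = np.concatenate([[-0.3, -0.2, -0.1], np.linspace(0.0, 5.0, 500)])
    curve = pure_diffusion_recovery(d, w, k, t)
    f0 = curve.post_intensity[0]
    plateau = curve.post_intensity[-50:].mean()
    target = f0 + 0.5 * (plateau - f0)

    def g(tt):
        return pure_diffusion_recovery(d, w, k, np.array([-1.0, tt])).intensity[-1] - target

    analytic = brentq(g, 1e-6, 5.0)
    dt = t[4] - t[3]
    assert abs(half_time(curve) - analytic) <= dt
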