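"""Isotope conversions, empirical fits and the back-flux pipeline.

Frozen expected values were derived by hand/closed-form evaluation of the
chained expressions and cross-checked by finite differences.
"""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import aobflux as af
from aobflux import isotope as iso
from aobflux.constants import R_KJ, R_VPDB

RT = R_KJ * 298.0


# ---------------------------------------------------------------------------
# conversions

def test_delta_zero_is_standard_ratio():
    assert iso.delta_to_ratio(0.0) == pytest.approx(R_VPDB, abs=0)


def test_delta_minus25_ratio():
    assert iso.delta_to_ratio(-25.0) == pytest.approx(0.01095627, abs=5e-9)


@given(delta=st.floats(min_value=-999.0, max_value=5000.0))
def test_conversion_round_trip(delta):
    r = iso.delta_to_ratio(delta)
    f = iso.ratio_to_fraction(r)
    assert float(iso.ratio_to_delta(iso.fraction_to_ratio(f))) == pytest.approx(
        delta, abs=1e-9)


def test_conversion_domain_errors():
    with pytest.raises(ValueError):
        iso.delta_to_ratio(-1000.0)
    with pytest.raises(ValueError):
        iso.fraction_to_ratio(1.0)
    with pytest.raises(ValueError):
        iso.ratio_to_fraction(-0.1)


# ---------------------------------------------------------------------------
# empirical fits

def test_first_order_exact_recovery():
    t = np.arange(0, 161, 10.0)
    y = 0.1 + 5.9 * np.exp(-0.04 * t)
    fit = iso.fit_first_order(t, y)
    assert fit.c0 == pytest.approx(0.1, rel=1e-6)
    assert fit.c1 == pytest.approx(6.0, rel=1e-6)
    assert fit.lam == pytest.approx(0.04, rel=1e-6)


def test_first_order_constant_series_errors():
    t = np.arange(0, 60, 10.0)
    with pytest.raises(ValueError, match="decay|constant"):
        iso.fit_first_order(t, np.full_like(t, 3.0))


def test_first_order_noise_robustness():
    """5% multiplicative noise, 17 points: lambda lands within 10% of truth
    in the typical seed (Monte-Carlo median over 100 seeds)."""
    t = np.arange(0, 161, 10.0)
    truth = 0.1 + 5.9 * np.exp(-0.04 * t)
    errs = []
    for seed in range(100):
        rng = np.random.default_rng(seed)
        y = np.clip(truth * (1 + 0.05 * rng.standard_normal(t.size)), 1e-6, None)
        try:
            fit = iso.fit_first_order(t, y)
            errs.append(abs(fit.lam - 0.04) / 0.04)
        except ValueError:
            errs.append(np.inf)
    assert np.median(errs) < 0.10


def test_net_rate_value_and_limits(truth_fit):
    fit, _ = truth_fit
    assert float(iso.net_rate(fit, 80.0)) == pytest.approx(0.009620, abs=5e-7)
    assert float(iso.net_rate(fit, 1e6)) == pytest.approx(0.0, abs=1e-12)
    h = 1e-5
    fd = -(fit.alkane(80.0 + h) - fit.alkane(80.0 - h)) / (2 * h)
    assert float(iso.net_rate(fit, 80.0)) == pytest.approx(float(fd), rel=1e-6)
    with pytest.raises(ValueError):
        iso.net_rate(fit, -1.0)


def test_logistic_exact_recovery():
    t = np.arange(0, 161, 10.0)
    y = -25.0 + 105.0 / (1 + np.exp(-0.08 * (t - 80.0)))
    lfit = iso.fit_logistic(t, y)
    for got, want in zip((lfit.d0, lfit.d1, lfit.d2, lfit.k), (-25, 80, 80, 0.08)):
        assert got == pytest.approx(want, rel=1e-6)
    assert not lfit.degenerate


def test_logistic_flat_series_degenerate():
    t = np.arange(0, 60, 10.0)
    lfit = iso.fit_logistic(t, np.full_like(t, -25.0))
    assert lfit.degenerate
    assert lfit.d1 == pytest.approx(lfit.d0, abs=1e-6)


def test_logistic_noise_robustness():
    """1 permil noise: the plateau d1 recovers within 3 permil (median
    over 50 seeds)."""
    t = np.arange(0, 161, 10.0)
    truth = -25.0 + 105.0 / (1 + np.exp(-0.08 * (t - 80.0)))
    errs = []
    for seed in range(50):
        rng = np.random.default_rng(seed)
        lfit = iso.fit_logistic(t, truth + rng.standard_normal(t.size))
        errs.append(abs(lfit.d1 - 80.0))
    assert np.median(errs) < 3.0


# ---------------------------------------------------------------------------
# mass-balance chain (frozen derived values at t = 80 d, default truth)

def test_alkane_13c_amount(truth_fit, const):
    fit, lfit = truth_fit
    assert float(iso.alkane_13c_amount(fit, lfit, const, 80.0)) == pytest.approx(
        0.0155463, abs=2e-6)
    # vanishes with the pool
    empty = af.FirstOrderFit(c0=0.0, c1=6.0, lam=0.04)
    assert float(iso.alkane_13c_amount(empty, lfit, const, 1e5)) == pytest.approx(0.0)


def test_alkane_13c_monotone_in_delta(truth_fit, const):
    fit, _ = truth_fit
    amounts = [
        float(iso.alkane_13c_amount(
            fit, af.LogisticFit(d0=d, d1=d + 1e-6, d2=80, k=0.08), const, 80.0))
        for d in (-25.0, 0.0, 40.0, 80.0)
    ]
    assert np.all(np.diff(amounts) > 0)


def test_d13c_derivative_matches_finite_difference(truth_fit, const):
    fit, lfit = truth_fit
    for t in (5.0, 40.0, 80.0, 120.0):
        h = 1e-4
        fd = (float(iso.alkane_13c_amount(fit, lfit, const, t + h))
              - float(iso.alkane_13c_amount(fit, lfit, const, t - h))) / (2 * h)
        assert float(iso.d13c_alkane_dt(fit, lfit, const, t)) == pytest.approx(
            fd, rel=1e-6)


def test_d13c_derivative_terms(truth_fit, const):
    """At t=80 d the label-gain term is 3.1411e-5 and the net-consumption
    term n*F*v = 4.392e-4, giving -4.078e-4 mmol 13C/L/d overall."""
    fit, lfit = truth_fit
    assert float(iso.d13c_alkane_dt(fit, lfit, const, 80.0)) == pytest.approx(
        -4.0781e-4, abs=2e-8)
    # label-gain term alone: total + n*F*v
    f = float(iso.delta_to_fraction(lfit.delta(80.0)))
    gain = (float(iso.d13c_alkane_dt(fit, lfit, const, 80.0))
            + const.n * f * float(iso.net_rate(fit, 80.0)))
    assert gain == pytest.approx(3.1411e-5, abs=2e-9)


def test_d13c_derivative_vanishes_flat_and_exhausted(const):
    fit = af.FirstOrderFit(c0=0.1, c1=6.0, lam=0.04)
    flat = af.LogisticFit(d0=-25.0, d1=-25.0 + 1e-9, d2=80.0, k=1e-3)
    assert float(iso.d13c_alkane_dt(fit, flat, const, 1e4)) == pytest.approx(
        0.0, abs=1e-12)


def test_co2_13fraction_values(truth_fit, const, setup):
    fit, lfit = truth_fit
    assert float(iso.co2_13fraction(setup, fit, lfit, const, 0.0)) == pytest.approx(
        0.98000, abs=5e-5)
    assert float(iso.co2_13fraction(setup, fit, lfit, const, 80.0)) == pytest.approx(
        0.44009, abs=5e-5)


def test_co2_13fraction_mixing_limit(const):
    """All alkane consumed at natural abundance with no back flux: the DIC
    pool carries the mixed-pool abundance."""
    f_mix = 0.0112
    setup = af.LabelingSetup(atom13_dic0=f_mix,
                             delta0_alk=float(iso.fraction_to_delta(f_mix)))
    fit = af.FirstOrderFit(c0=0.0, c1=6.0, lam=0.04)
    flat = af.LogisticFit(d0=-25.0, d1=-25.0 + 1e-9, d2=80.0, k=1e-3)
    f_end = float(iso.co2_13fraction(setup, fit, flat, const, 1e5))
    assert f_end == pytest.approx(setup.c13_total / setup.c_total, rel=1e-9)


def test_labeling_setup_conserved_totals(setup):
    assert setup.c_total == pytest.approx(42.0)
    assert setup.c13_total == pytest.approx(17.9001, abs=5e-5)


# ---------------------------------------------------------------------------
# back-flux extent

def test_mu_zero_without_isotope_contrast(setup):
    """Flat d13C and alpha+ = alpha- = 1: the numerator of the explicit mu
    expression vanishes identically."""
    const = af.IsotopeConstants(alpha_plus=1.0, alpha_minus=1.0)
    fit = af.FirstOrderFit(c0=0.1, c1=6.0, lam=0.04)
    flat = af.LogisticFit(d0=-25.0, d1=-25.0 + 1e-9, d2=80.0, k=1e-3)
    traj = iso.back_flux_extent(setup, fit, flat, const, np.arange(0, 121, 10.0))
    assert np.allclose(traj.mu[traj.mask], 0.0, atol=1e-9)


def test_mu_default_value_at_80d(truth_fit, const, setup):
    fit, lfit = truth_fit
    traj = iso.back_flux_extent(setup, fit, lfit, const, np.array([80.0]))
    assert traj.mu[0] == pytest.approx(1.8375e-3, abs=2e-6)


def test_mu_bell_shape(truth_fit, const, setup):
    """mu(t) rises to an interior peak and falls off afterwards."""
    fit, lfit = truth_fit
    t = np.arange(0, 161, 5.0)
    traj = iso.back_flux_extent(setup, fit, lfit, const, t)
    mu = traj.mu
    i_peak = int(np.nanargmax(mu))
    assert 0 < i_peak < t.size - 1
    i_min = int(np.nanargmin(mu[:i_peak]))
    assert np.all(np.diff(mu[i_min:i_peak + 1]) > 0)
    assert np.all(np.diff(mu[i_peak:]) < 0)
    assert traj.mu_peak > 3 * max(mu[i_min], mu[-1])


def test_flux_identity(truth_fit, const, setup):
    """f+ - f-/n = v wherever mu is defined."""
    fit, lfit = truth_fit
    traj = iso.back_flux_extent(setup, fit, lfit, const, np.arange(0, 161, 10.0))
    m = traj.mask
    assert np.allclose(traj.f_plus[m] - traj.f_minus[m] / const.n, traj.v[m],
                       rtol=1e-12)


def test_mu_fully_masked_errors(truth_fit, const, setup):
    fit, lfit = truth_fit
    with pytest.raises(ValueError, match="no identifiable"):
        iso.back_flux_extent(setup, fit, lfit, const, np.array([1e4, 2e4]))


# ---------------------------------------------------------------------------
# Rayleigh and flux-force

def test_rayleigh_inverse_consistency():
    """Data generated from the closed-form Rayleigh relation with
    alpha=0.9975 return epsilon = -2.5 permil exactly."""
    f = np.array([1.0, 0.8, 0.5, 0.2, 0.05])
    delta0 = -25.0
    delta = (delta0 + 1000.0) * f ** (0.9975 - 1.0) - 1000.0
    alpha, eps = iso.rayleigh_alpha(np.arange(f.size), 6.0 * f, delta)
    assert alpha == pytest.approx(0.9975, abs=1e-12)
    assert eps == pytest.approx(-2.5, abs=1e-9)


def test_rayleigh_no_fractionation():
    f = np.array([1.0, 0.6, 0.3, 0.1])
    delta = np.full_like(f, -25.0)
    _, eps = iso.rayleigh_alpha(np.arange(f.size), 6.0 * f, delta)
    assert eps == pytest.approx(0.0, abs=1e-12)


def test_rayleigh_closed_form_at_half():
    """At half the substrate remaining with eps=-2.5: delta = -23.31."""
    delta = (-25.0 + 1000.0) * 0.5 ** (-0.0025) - 1000.0
    assert delta == pytest.approx(-23.31, abs=5e-3)


def test_rayleigh_domain_errors():
    with pytest.raises(ValueError):
        iso.rayleigh_alpha([0, 1, 2], [6.0, 7.0, 8.0], [-25, -25, -25])


def test_flux_force_values():
    ratio, _ = iso.flux_force(0.0)
    assert ratio == 1.0
    _, fnet = iso.flux_force(-RT * math.log(2.0))
    assert fnet == pytest.approx(1.0, rel=1e-12)
    ratio, fnet = iso.flux_force(-17.1)
    assert ratio == pytest.approx(math.exp(-17.1 / RT), rel=1e-12)
    assert ratio == pytest.approx(1.0e-3, rel=1e-2)
    assert fnet == pytest.approx(1.0e-3, rel=1e-2)
    with pytest.raises(ValueError):
        iso.flux_force(+1.0)


@given(st.floats(min_value=-60.0, max_value=-0.5))
def test_flux_force_monotone_in_dg(dg):
    """f-/f_net strictly increases as dG approaches zero from below."""
    _, a = iso.flux_force(dg)
    _, b = iso.flux_force(dg + 0.25)
    assert b > a


# ---------------------------------------------------------------------------
# overall process free energy

def test_overall_dg_unit_activities():
    out = iso.overall_delta_g(1000.0, 1000.0, 1000.0, 1000.0, dg0_overall=-300.0)
    assert out[0] == pytest.approx(-300.0)


def test_overall_dg_halving_butane():
    g1 = iso.overall_delta_g(1000.0, 1000.0, 1000.0, 1000.0, dg0_overall=-300.0)
    g2 = iso.overall_delta_g(500.0, 1000.0, 1000.0, 1000.0, dg0_overall=-300.0)
    assert g2[0] - g1[0] == pytest.approx(RT * math.log(2.0), rel=1e-12)


def test_overall_dg_monotone_on_depletion_trajectory(truth_fit):
    """dG rises toward equilibrium as butane depletes and products build."""
    fit, _ = truth_fit
    t = np.arange(0, 121, 10.0)
    butane = fit.alkane(t)
    consumed = butane[0] - butane
    sulfide = 3.25 * consumed + 1e-6
    sulfate = 28.0 - sulfide
    dic = 18.0 + 4.0 * consumed
    dg = iso.overall_delta_g(butane, sulfate, sulfide, dic, dg0_overall=-300.0)
    assert np.all(np.diff(dg) > 0)


def test_overall_dg_masks_nonpositive():
    out = iso.overall_delta_g([1000.0, 0.0], 1000.0, 1000.0, 1000.0,
                              dg0_overall=-300.0)
    assert np.isnan(out[1]) and np.isfinite(out[0])
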