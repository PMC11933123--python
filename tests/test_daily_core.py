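"""Closed-form daily integrals against the quadrature oracle, branch
continuity at a = 1, the diurnal-shape ordering, and the noon identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from tlrhm import daily_core as dc


def apar_for_shape_a(alpha, pm, daylength, a, profile):
    """Daily APAR (mol m-2) that produces saturation parameter ``a``."""
    noon = pm / (alpha * a)
    return noon * daylength / (dc.NOON_COEFF[profile] * 1e6)


@pytest.mark.parametrize("func,profile", [
    (dc.gpp_daily_sine, dc.SINE),
    (dc.gpp_daily_sinesine, dc.SQUARED_SINE),
])
def test_zero_light_gives_zero(func, profile):
    assert func(0.05, 20.0, 0.0, 12 * 3600.0) == 0.0
    assert dc.gpp_daily_numeric(0.05, 20.0, 0.0, 12 * 3600.0, profile) == 0.0


@pytest.mark.parametrize("func,profile,a_small", [
    # the sine form approaches saturation like a*ln(1/a), the squared-sine
    # form like sqrt(a), so the latter needs a far smaller a for the same
    # closeness; both limits are confirmed against quadrature elsewhere
    (dc.gpp_daily_sine, dc.SINE, 1e-4),
    (dc.gpp_daily_sinesine, dc.SQUARED_SINE, 1e-8),
])
def test_saturation_asymptote(func, profile, a_small):
    """As a -> 0 the whole day runs at Pm, so GPP -> Pm * daylength."""
    alpha, pm, d = 0.05, 20.0, 12 * 3600.0
    apar = apar_for_shape_a(alpha, pm, d, a_small, profile)
    assert func(alpha, pm, apar, d) == pytest.approx(pm * d, rel=1e-3)


@pytest.mark.parametrize("profile,func", [
    (dc.SINE, dc.gpp_daily_sine),
    (dc.SQUARED_SINE, dc.gpp_daily_sinesine),
])
def test_closed_form_matches_adaptive_quadrature_at_a2(profile, func):
    alpha, pm, d = 0.05, 20.0, 12 * 3600.0
    apar = apar_for_shape_a(alpha, pm, d, 2.0, profile)
    closed = func(alpha, pm, apar, d)
    numeric = dc.gpp_daily_numeric(alpha, pm, apar, d, profile)
    assert closed == pytest.approx(numeric, rel=1e-6)


def test_sine_branch_continuity_at_a_equals_one():
    """The a = 1 value is the limit of the a > 1 branch."""
    alpha, pm, d = 0.05, 20.0, 12 * 3600.0
    apar1 = apar_for_shape_a(alpha, pm, d, 1.0, dc.SINE)
    at_one = dc.gpp_daily_sine(alpha, pm, apar1, d)
    above = dc.gpp_daily_sine(alpha, pm,
                              apar_for_shape_a(alpha, pm, d, 1.0 + 1e-7, dc.SINE), d)
    below = dc.gpp_daily_sine(alpha, pm,
                              apar_for_shape_a(alpha, pm, d, 1.0 - 1e-7, dc.SINE), d)
    assert at_one == pytest.approx(above, rel=1e-6)
    assert at_one == pytest.approx(below, rel=1e-6)
    # and the branch value equals Pm D (1 - 2/pi)
    assert at_one == pytest.approx(pm * d * (1.0 - 2.0 / np.pi), rel=1e-9)


def test_closed_forms_match_quadrature_on_random_sweep():
    """Random (alpha, Pm, APAR, daylength) sweep including near-critical a."""
    rng = np.random.default_rng(7)
    worst = 0.0
    for _ in range(500):
        alpha = rng.uniform(0.01, 0.1)
        pm = rng.uniform(0.5, 40.0)
        d = rng.uniform(2.0, 18.0) * 3600.0
        if rng.random() < 0.2:  # exercise the neighbourhood of a = 1
            a = 1.0 + rng.uniform(-1e-5, 1e-5)
            apar = apar_for_shape_a(alpha, pm, d, a, dc.SINE)
        else:
            apar = rng.uniform(0.005, 60.0)
        for profile, func in ((dc.SINE, dc.gpp_daily_sine),
                              (dc.SQUARED_SINE, dc.gpp_daily_sinesine)):
            closed = func(alpha, pm, apar, d)
            numeric = dc.gpp_daily_numeric(alpha, pm, apar, d, profile)
            worst = max(worst, abs(closed - numeric) / numeric)
    assert worst < 1e-6


def test_simpson_oracle_converges():
    args = (0.05, 20.0, 10.0, 12 * 3600.0, dc.SINE)
    coarse = dc.gpp_daily_numeric(*args, n_steps=10_000)
    fine = dc.gpp_daily_numeric(*args, n_steps=20_000)
    assert abs(fine - coarse) / fine < 1e-8


def test_noon_radiation_identities():
    """Integrating each diurnal profile with its noon amplitude recovers the
    daily total to 1e-10 relative; the squared-sine coefficient is exactly 2."""
    d = 13.0 * 3600.0
    apar_daily = 25.0  # mol m-2 day-1
    for profile, power in ((dc.SINE, 1), (dc.SQUARED_SINE, 2)):
        noon = dc.apar_noon(apar_daily, d, profile)  # umol m-2 s-1
        integral, _ = quad(lambda t: noon * np.sin(np.pi * t / d) ** power,
                           0.0, d, epsabs=1e-13, epsrel=1e-13)
        assert integral * 1e-6 == pytest.approx(apar_daily, rel=1e-10)
    assert dc.NOON_COEFF[dc.SQUARED_SINE] == 2.0
    assert dc.NOON_COEFF[dc.SINE] == pytest.approx(np.pi / 2.0, rel=1e-15)


@given(alpha=st.floats(0.01, 0.1), pm=st.floats(0.5, 40.0),
       apar=st.floats(0.001, 60.0), hours=st.floats(2.0, 18.0))
@settings(deadline=None, max_examples=200)
def test_sine_form_never_below_sinesine_form(alpha, pm, apar, hours):
    d = hours * 3600.0
    assert dc.gpp_daily_sine(alpha, pm, apar, d) >= \
        dc.gpp_daily_sinesine(alpha, pm, apar, d) - 1e-9


@given(alpha=st.floats(0.01, 0.1), pm=st.floats(0.5, 40.0),
       apar=st.floats(0.001, 60.0), hours=st.floats(2.0, 18.0),
       bump=st.floats(1.0001, 2.0))
@settings(deadline=None, max_examples=100)
def test_daily_gpp_monotone_in_each_input(alpha, pm, apar, hours, bump):
    d = hours * 3600.0
    for func in (dc.gpp_daily_sine, dc.gpp_daily_sinesine):
        base = func(alpha, pm, apar, d)
        assert func(alpha * bump, pm, apar, d) >= base - 1e-9
        assert func(alpha, pm * bump, apar, d) >= base - 1e-9
        assert func(alpha, pm, apar * bump, d) >= base - 1e-9
        assert 0.0 <= base <= pm * d


def test_vectorised_evaluation_matches_scalar():
    alpha = np.array([0.04, 0.05, 0.06])
    pm = np.array([10.0, 20.0, 5.0])
    apar = np.array([0.0, 20.0, 5.0])
    d = np.array([10.0, 12.0, 14.0]) * 3600.0
    vec = dc.gpp_daily_sine(alpha, pm, apar, d)
    for i in range(3):
        assert vec[i] == pytest.approx(
            dc.gpp_daily_sine(alpha[i], pm[i], apar[i], d[i]), rel=1e-14)


def test_invalid_inputs_raise():
    with pytest.raises(ValueError):
        dc.gpp_daily_sine(0.05, 20.0, 10.0, 0.0)
    with pytest.raises(ValueError):
        dc.gpp_daily_numeric(0.05, 20.0, 10.0, 12 * 3600.0, n_steps=50)
    with pytest.raises(ValueError):
        dc.gpp_daily(0.05, 20.0, 10.0, 12 * 3600.0, "triangle")
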