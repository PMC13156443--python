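"""Forward-model physics: spectral densities, orientational coefficients,
exchange terms and the apparent-R1 mixture."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from thbr1 import (BiophysParams, IllConditionedModelError,
                   InvalidParameterError, decompose_contributions,
                   derived_diffusion, exchange_terms, g_coefficients,
                   lorentzian, r1_apparent, r1_bb_ldm, rate_coefficients,
                   study_field, thb_lambda_from_distance, v_functions)
from thbr1.fields import FieldContext, GAMMA_PROTON
from thbr1.params import PUBLISHED_MEANS, PUBLISHED_R1I


# ---------------------------------------------------------------------------
# Lorentzian spectral density
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("omega, tau, expected", [
    (0.0, 3e-8, 3e-8),                 # L(0) = tau
    (1.0 / 3e-8, 3e-8, 1.5e-8),        # omega*tau = 1 -> tau/2
    (100.0 / 7e-8, 7e-8, 7e-8 / 10001),  # large-argument limit
])
def test_lorentzian_values(omega, tau, expected):
    assert lorentzian(omega, tau) == pytest.approx(expected, rel=1e-12)


def test_lorentzian_monotone_and_domain():
    tau = 5e-8
    omegas = np.linspace(0, 1e10, 400)
    L = lorentzian(omegas, tau)
    assert np.all(np.diff(L) <= 0) and np.all(L > 0)
    with pytest.raises(InvalidParameterError):
        lorentzian(1.0, 0.0)


# ---------------------------------------------------------------------------
# Orientational coefficients g0, g1, g2
# ---------------------------------------------------------------------------

def test_g_coefficients_endpoints():
    assert g_coefficients(0.0) == pytest.approx((-0.25, 0.0, 1.0), abs=1e-15)
    assert g_coefficients(90.0) == pytest.approx((0.125, 0.125, 0.375),
                                                 abs=1e-15)


def test_g_sum_rule_random_angles(rng):
    """g0 + 12 g1 + 3 g2 = 11/4 for every angle."""
    theta = rng.uniform(-360, 360, size=200)
    g0, g1, g2 = g_coefficients(theta)
    np.testing.assert_allclose(g0 + 12 * g1 + 3 * g2, 2.75, atol=1e-12)
    assert np.all(g1 >= -1e-15) and np.all(g2 > 0)


def test_g0_minimum_grid_matches_analytic_root():
    """Brute-force grid minimizer of g0 agrees with cos^2(t) = 5/9."""
    theta = np.arange(0.0, 90.0005, 0.001)
    g0 = g_coefficients(theta)[0]
    t_grid = theta[np.argmin(g0)]
    t_analytic = math.degrees(math.acos(math.sqrt(5.0 / 9.0)))
    assert abs(t_grid - t_analytic) <= 0.01
    assert g0.min() == pytest.approx(-11.0 / 12.0, rel=1e-6)


@given(st.floats(-360, 360))
def test_angular_outputs_even_and_supplementary(theta):
    """f(theta) = f(-theta) = f(180 - theta) for every angular output."""
    ctx = study_field(3.0)
    p = BiophysParams(lambdaA=5e7, tauA=70e-9, **PUBLISHED_MEANS)
    for t2 in (-theta, 180.0 - theta):
        np.testing.assert_allclose(g_coefficients(theta),
                                   g_coefficients(t2), atol=1e-9)
        np.testing.assert_allclose(
            rate_coefficients(theta, ctx, 5e7, 70e-9),
            rate_coefficients(t2, ctx, 5e7, 70e-9), atol=1e-9)
        np.testing.assert_allclose(
            r1_bb_ldm(theta, ctx, 23.1, 9.1, warn=False),
            r1_bb_ldm(t2, ctx, 23.1, 9.1, warn=False), atol=1e-9)
        np.testing.assert_allclose(
            r1_apparent(p, 1.14, theta, ctx, warn=False),
            r1_apparent(p, 1.14, t2, ctx, warn=False), atol=1e-9)


# ---------------------------------------------------------------------------
# THB rate coefficients
# ---------------------------------------------------------------------------

def test_rate_coefficients_zero_coupling(fields3):
    kA, KA = rate_coefficients(33.0, fields3[3.0], 0.0, 70e-9)
    assert kA == 0 and KA == 0


def test_rate_difference_nonnegative(fields3, rng):
    theta = rng.uniform(0, 90, 100)
    kA, KA = rate_coefficients(theta, fields3[3.0], 5e7, 70e-9)
    assert np.all(kA - KA >= -1e-12)


def test_long_lifetime_limit():
    """kA -> KA as omega*tau -> infinity at fixed lambdaA*tauA."""
    tau = 70e-9
    theta = 60.0
    g0, g1, g2 = g_coefficients(theta)
    prev = None
    for wt in (1e2, 1e3, 1e4):
        ctx = FieldContext(B=3.0, omega=wt / tau)
        kA, KA = rate_coefficients(theta, ctx, 1e8, tau)
        ratio = abs(kA - KA) / abs(kA)
        bound = 3.0 * wt ** -2 * (2 * g1 + 2 * g2) / ((1 / 9) * abs(g0))
        assert ratio <= bound
        if prev is not None:
            assert ratio < prev / 10
        prev = ratio


def test_ka_most_negative_at_g0_minimum(fields3):
    """In the long-lifetime regime kA tracks g0, dipping near 41.8 deg."""
    tau = 70e-9
    ctx = FieldContext(B=3.0, omega=1e4 / tau)
    theta = np.arange(0.0, 90.001, 0.01)
    kA, _ = rate_coefficients(theta, ctx, 1e8, tau)
    assert theta[np.argmin(kA)] == pytest.approx(41.81, abs=0.1)


# ---------------------------------------------------------------------------
# Lateral-diffusion spectral functions and rate
# ---------------------------------------------------------------------------

def test_v_functions_values_and_warning(caplog):
    with caplog.at_level("WARNING", logger="thbr1.physics"):
        V0, V2 = v_functions(1.0)
    assert (V0, V2) == (0.048, 0.131)
    assert any("validity" in r.message for r in caplog.records)
    # direct arithmetic oracle at Omega = 10
    assert v_functions(10.0)[0] == pytest.approx(0.048 * 10 ** -1.10,
                                                 rel=1e-12)
    assert v_functions(10.0)[0] == pytest.approx(3.813e-3, rel=1e-3)


def test_v_functions_power_law_ratio_and_monotonicity():
    assert v_functions(25.0)[0] / v_functions(5.0)[0] == pytest.approx(
        5.0 ** -1.10, rel=1e-12)
    om = np.linspace(5, 25, 200)
    V0, V2 = v_functions(om)
    assert np.all(np.diff(V0) < 0) and np.all(np.diff(V2) < 0)
    with pytest.raises(InvalidParameterError):
        v_functions(0.0)


def _ldm_bracket_oracle(theta_deg, Omega):
    """Term-by-term arithmetic evaluation of the angular bracket."""
    t = math.radians(theta_deg)
    s2, c2 = math.sin(t) ** 2, math.cos(t) ** 2
    s4 = s2 * s2
    V0 = lambda o: 0.048 * o ** -1.10  # noqa: E731
    V2 = lambda o: 0.131 * o ** -1.31  # noqa: E731
    return (s2 * (5 + 3 * c2) * V0(Omega)
            + (16 * c2 + 6 * s4) * V0(2 * Omega)
            + (8 - 3 * s4) * V2(Omega)
            + (8 + 24 * s2 + 3 * s4) * V2(2 * Omega))


@pytest.mark.parametrize("theta", [0.0, 30.0, 41.8, 60.0, 90.0])
def test_r1_bb_ldm_matches_arithmetic_oracle(theta, fields3):
    got = r1_bb_ldm(theta, fields3[3.0], 2.0, 9.1, warn=False)
    assert got == pytest.approx(_ldm_bracket_oracle(theta, 9.1), rel=1e-9)


def test_r1_bb_ldm_endpoint_brackets(fields3):
    """Frozen oracle values for the 0 and 90 degree brackets at Omega=9.1."""
    b0 = r1_bb_ldm(0.0, fields3[3.0], 2.0, 9.1, warn=False)
    b90 = r1_bb_ldm(90.0, fields3[3.0], 2.0, 9.1, warn=False)
    assert b0 == pytest.approx(0.113074, abs=2e-4)
    assert b90 == pytest.approx(0.171768, abs=2e-4)
    assert r1_bb_ldm(37.0, fields3[3.0], 0.0, 9.1, warn=False) == 0.0


def test_r1_bb_ldm_decreases_with_field():
    for theta in (0.0, 45.0, 90.0):
        vals = [r1_bb_ldm(theta, FieldContext.from_tesla(B), 23.1, 9.1,
                          warn=False) for B in (1.5, 3.0, 7.0)]
        assert vals[0] > vals[1] > vals[2] > 0


# ---------------------------------------------------------------------------
# Exchange terms and the mixed apparent rate
# ---------------------------------------------------------------------------

def test_exchange_terms_thb_channel_off(fields3):
    p = BiophysParams(lambdaA=0.0, tauA=70e-9, **PUBLISHED_MEANS)
    theta = np.array([0.0, 30.0, 60.0, 90.0])
    pA, dR1wA, R1bA = exchange_terms(p, theta, fields3[3.0], warn=False)
    np.testing.assert_array_equal(pA, 0.0)
    np.testing.assert_array_equal(dR1wA, 0.0)
    expect = (1 - p.nbA) * r1_bb_ldm(theta, fields3[3.0], p.Lambda, p.Omega0,
                                     warn=False)
    np.testing.assert_allclose(R1bA, expect, rtol=1e-12)


def test_exchange_terms_no_coupled_water(fields3):
    p = BiophysParams(lambdaA=5e7, tauA=70e-9,
                      **{**PUBLISHED_MEANS, "nwA": 0.0})
    theta = np.array([20.0, 70.0])
    kA, _ = rate_coefficients(theta, fields3[3.0], p.lambdaA, p.tauA)
    _, dR1wA, R1bA = exchange_terms(p, theta, fields3[3.0], warn=False)
    np.testing.assert_array_equal(dR1wA, 0.0)
    r1A = r1_bb_ldm(theta, fields3[3.0], p.Lambda, p.Omega0, warn=False)
    np.testing.assert_allclose(R1bA, (1 - p.nbA) * r1A + p.nbA * kA,
                               rtol=1e-12)


@pytest.mark.parametrize("lam_scale", [1.0, 0.1])
def test_indirect_water_term_decreases_with_field(table1_params, fields3,
                                                  lam_scale):
    """dR1wA at fixed angle decreases from 1.5 T to 3 T to 7 T for the
    calibrated default coupling and below it."""
    p = table1_params.replace(lambdaA=table1_params.lambdaA * lam_scale)
    theta = np.arange(0.0, 90.1, 1.5)
    d = {t: exchange_terms(p, theta, ctx, warn=False)[1]
         for t, ctx in fields3.items()}
    assert np.all(d[1.5] > d[3.0]) and np.all(d[3.0] > d[7.0])


def test_singular_denominator_raises_with_location(fields3):
    p0 = BiophysParams(lambdaA=1e7, tauA=70e-9, **PUBLISHED_MEANS)
    theta = 30.0
    kA, _ = rate_coefficients(theta, fields3[3.0], p0.lambdaA, p0.tauA)
    r1A = r1_bb_ldm(theta, fields3[3.0], p0.Lambda, p0.Omega0, warn=False)
    den = (1 - p0.nbA) * r1A + p0.nbA * kA
    assert den > 0
    p = p0.replace(r1w=float(den))  # cancels the denominator exactly
    with pytest.raises(IllConditionedModelError, match="theta=30"):
        exchange_terms(p, theta, fields3[3.0], warn=False)
    pA, _, _ = exchange_terms(p, theta, fields3[3.0], on_singular="nan",
                              warn=False)
    assert np.isnan(pA)


def test_r1_apparent_mixing_limits(table1_params, fields3):
    theta = np.array([15.0, 45.0, 80.0])
    ctx = fields3[3.0]
    p0 = table1_params.replace(zeta=0.0)
    _, dR1wA, R1bA = exchange_terms(p0, theta, ctx, warn=False)
    np.testing.assert_allclose(r1_apparent(p0, 1.14, theta, ctx, warn=False),
                               1.14 + dR1wA, rtol=1e-12)
    p1 = table1_params.replace(zeta=1.0)
    np.testing.assert_allclose(r1_apparent(p1, 1.14, theta, ctx, warn=False),
                               exchange_terms(p1, theta, ctx, warn=False)[2],
                               rtol=1e-12)
    flat = table1_params.replace(zeta=0.0, lambdaA=0.0)
    vals = r1_apparent(flat, 1.14, np.linspace(0, 90, 50), ctx, warn=False)
    np.testing.assert_allclose(vals, 1.14, rtol=1e-14)


def test_r1_apparent_minimum_near_g0_root(table1_params, fields3):
    theta = np.arange(9.6, 90.0001, 0.1)
    r1 = r1_apparent(table1_params, PUBLISHED_R1I[3.0], theta, fields3[3.0],
                     warn=False)
    assert theta[np.argmin(r1)] == pytest.approx(41.8, abs=3.0)


def test_r1_apparent_positive_for_default_set(table1_params, fields3,
                                              published_r1i):
    theta = np.linspace(0, 90, 181)
    for t, ctx in fields3.items():
        vals = r1_apparent(table1_params, published_r1i[t], theta, ctx,
                           warn=False)
        assert np.all(vals > 0)


def test_decomposition_sums_exactly(table1_params, fields3, published_r1i):
    theta = np.arange(0, 90.1, 4.5)
    for t, ctx in fields3.items():
        iso, ind, direct = decompose_contributions(
            table1_params, published_r1i[t], theta, ctx)
        total = iso + ind + direct
        expect = r1_apparent(table1_params, published_r1i[t], theta, ctx,
                             warn=False)
        np.testing.assert_allclose(total, expect, atol=1e-12, rtol=0)
    z0 = table1_params.replace(zeta=0.0)
    _, _, direct = decompose_contributions(z0, 1.14, theta, fields3[3.0])
    np.testing.assert_array_equal(direct, 0.0)


# ---------------------------------------------------------------------------
# Parameter-level relations
# ---------------------------------------------------------------------------

def test_thb_lambda_distance_scaling():
    r = 1.6e-10
    assert thb_lambda_from_distance(2 * r) == pytest.approx(
        thb_lambda_from_distance(r) / 64.0, rel=1e-12)
    assert thb_lambda_from_distance(r) * r ** 6 == pytest.approx(
        thb_lambda_from_distance(3 * r) * (3 * r) ** 6, rel=1e-12)
    with pytest.raises(InvalidParameterError):
        thb_lambda_from_distance(0.0)


def test_derived_diffusion_correlation_time_and_roundtrip():
    ctx = study_field(3.0)
    dd = derived_diffusion(23.1, 9.1, ctx)
    # tau_d = Omega0 / (gamma * B_ref)
    assert dd.tau_d == pytest.approx(9.1 / (GAMMA_PROTON * 3.0), rel=1e-12)
    assert dd.tau_d * 1e9 == pytest.approx(11.34, abs=0.01)
    # doubling Omega0 doubles tau_d
    assert derived_diffusion(23.1, 18.2, ctx).tau_d == pytest.approx(
        2 * dd.tau_d, rel=1e-12)
    # round trip through the strength relation and tau_d = d^2 / 2D
    from thbr1.fields import HBAR
    lam_back = (9 * math.pi / (256 * dd.D * dd.d ** 4)) \
        * (HBAR * GAMMA_PROTON ** 2 / 2) ** 2
    assert lam_back == pytest.approx(23.1, rel=1e-9)
    assert dd.d ** 2 / (2 * dd.D) == pytest.approx(dd.tau_d, rel=1e-9)
    with pytest.raises(InvalidParameterError):
        derived_diffusion(0.0, 9.1, ctx)


def test_default_coupling_keeps_model_well_conditioned(table1_params,
                                                       fields3):
    """The calibrated lambdaA keeps pA finite at every angle and field."""
    theta = np.arange(0.0, 90.01, 0.25)
    for ctx in fields3.values():
        pA, _, _ = exchange_terms(table1_params, theta, ctx, warn=False)
        assert np.all(np.isfinite(pA))
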