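"""Closed-form forward model of orientation- and field-dependent apparent R1.

Two relaxation channels contribute to the apparent longitudinal rate of
white matter:

* a transient-hydrogen-bond (THB) channel, in which water protons exchange
  magnetization with lipid-bound protons through dipole-dipole coupling of
  strength ``lambdaA`` over a bond lifetime ``tauA``; its diagonal and
  cross-relaxation coefficients ``kA``/``KA`` carry the fiber-to-field angle
  through the orientational coefficients ``g0, g1, g2`` and the field
  through Lorentzian spectral densities ``L(omega*tau)``;

* a lateral-diffusion channel, in which bound protons relax through their
  two-dimensional diffusion within the bilayer; its rate ``r1A`` carries the
  angle through trigonometric weights and the field through the power-law
  functions ``V0, V2`` of the dimensionless frequency ``Omega``.

Both channels mix into a single apparent rate

    R1app = (1 - zeta) * (R1I + dR1wA) + zeta * R1bA

where ``R1I`` is the per-field isotropic rate, ``dR1wA`` the anisotropic
water contribution driven indirectly through THB exchange, and ``R1bA`` the
bound-pool rate entering directly with mixing weight ``zeta``.

All angle arguments are degrees at the interface (radians internally) and
fold into [0, 90] by the axial symmetry of the problem; every function
broadcasts over numpy arrays in both angle and parameters.

The literature source typesets several prefactors ambiguously; the adopted
readings are centralised in ``EQ_CONSTANTS`` so an alternative reading is a
one-line change.
"""

from __future__ import annotations

import logging
import math
from typing import NamedTuple

import numpy as np
from scipy.optimize import brentq

from .exceptions import IllConditionedModelError, InvalidParameterError
from .fields import GAMMA_PROTON, HBAR, FieldContext
from .params import BiophysParams

logger = logging.getLogger(__name__)

#: Adopted prefactor readings, centralised.  Keys:
#:   lambda_prefactor — 3/2 in lambda = (3/2) r^-6 (hbar gamma^2 / 2)^2
#:   rate_prefactor   — 3/4 in front of the kA/KA brackets
#:   g0_weight        — 1/9 multiplying g0*L(0) inside kA/KA
#:   g_norm           — 1/8 normalising the orientational coefficients
#:   ldm_prefactor    — 1/2 in r1A = (Lambda/2) * [...]
EQ_CONSTANTS = {
    "lambda_prefactor": 1.5,
    "rate_prefactor": 0.75,
    "g0_weight": 1.0 / 9.0,
    "g_norm": 0.125,
    "ldm_prefactor": 0.5,
}

#: Power-law approximation of the lateral-diffusion spectral functions,
#: V0(Omega) = c0 * Omega**e0, V2(Omega) = c2 * Omega**e2, valid for
#: Omega in [5, 25].
V_COEFFS = {"c0": 0.048, "e0": -1.10, "c2": 0.131, "e2": -1.31}

#: Validity band of the V0/V2 power laws.
V_VALID_RANGE = (5.0, 25.0)

#: Relative tolerance below which the pA denominator counts as singular.
PA_SINGULAR_RTOL = 1e-12


def _theta_rad(theta_deg):
    """Degrees -> radians; the model is even in cos(theta) so no explicit
    folding is needed, but inputs are accepted on the whole real line."""
    return np.deg2rad(np.asarray(theta_deg, dtype=float))


# ---------------------------------------------------------------------------
# Spectral densities and orientational coefficients
# ---------------------------------------------------------------------------

def lorentzian(omega, tau):
    """Lorentzian spectral density L(omega*tau) = tau / (1 + (omega*tau)^2).

    Parameters
    ----------
    omega : array_like
        Angular frequency [rad/s], >= 0.
    tau : array_like
        Correlation time [s], > 0.

    Returns
    -------
    ndarray or float
        L in seconds; L(0) = tau, monotonically non-increasing in omega.
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau <= 0):
        raise InvalidParameterError("tau must be positive")
    omega = np.asarray(omega, dtype=float)
    return tau / (1.0 + (omega * tau) ** 2)


def g_coefficients(theta_deg):
    """Orientational coefficients (g0, g1, g2) of the THB rates.

    g0 = (1/8)(1 - 30 cos^2 t + 27 cos^4 t)
    g1 = (1/8)(1 +  2 cos^2 t -  3 cos^4 t)
    g2 = (1/8)(3 +  2 cos^2 t +  3 cos^4 t)

    g1 >= 0 and g2 > 0 everywhere; g0 is negative on a broad band around its
    minimum at cos^2 t = 5/9 (t ~ 41.81 deg).  All three are even in
    cos(theta), so f(theta) = f(-theta) = f(180 - theta).
    """
    c2 = np.cos(_theta_rad(theta_deg)) ** 2
    c4 = c2 * c2
    n = EQ_CONSTANTS["g_norm"]
    g0 = n * (1.0 - 30.0 * c2 + 27.0 * c4)
    g1 = n * (1.0 + 2.0 * c2 - 3.0 * c4)
    g2 = n * (3.0 + 2.0 * c2 + 3.0 * c4)
    return g0, g1, g2


def rate_coefficients(theta_deg, ctx: FieldContext, lambdaA, tauA, *,
                      g0_weight_binds_g0_only: bool = True):
    """Diagonal (kA) and cross-relaxation (KA) THB coefficients [1/s].

    kA = (3/4) lambdaA [ (1/9) g0 L(0) + 2 g1 L(w tauA) + g2 L(2w tauA) ]
    KA = (3/4) lambdaA [ (1/9) g0 L(0) -              g2 L(2w tauA) ]

    ``g0_weight_binds_g0_only`` selects whether the 1/9 weight multiplies
    only the g0 L(0) term (default) or the whole KA bracket.
    """
    g0, g1, g2 = g_coefficients(theta_deg)
    L0 = lorentzian(0.0, tauA)
    Lw = lorentzian(ctx.omega, tauA)
    L2w = lorentzian(2.0 * ctx.omega, tauA)
    pre = EQ_CONSTANTS["rate_prefactor"] * np.asarray(lambdaA, dtype=float)
    w0 = EQ_CONSTANTS["g0_weight"]
    kA = pre * (w0 * g0 * L0 + 2.0 * g1 * Lw + g2 * L2w)
    if g0_weight_binds_g0_only:
        KA = pre * (w0 * g0 * L0 - g2 * L2w)
    else:
        KA = pre * w0 * (g0 * L0 - g2 * L2w)
    return kA, KA


def v_functions(Omega, *, warn: bool = True):
    """Power-law spectral functions (V0, V2) of the lateral-diffusion model.

    V0 ~ 0.048 Omega^-1.10, V2 ~ 0.131 Omega^-1.31; the approximation is
    stated for Omega in [5, 25] — outside that band the same power laws are
    evaluated and a warning is logged (``warn=False`` suppresses it for hot
    loops that have already vetted the range).
    """
    Omega = np.asarray(Omega, dtype=float)
    if np.any(Omega <= 0):
        raise InvalidParameterError("Omega must be positive")
    lo, hi = V_VALID_RANGE
    if warn and np.any((Omega < lo) | (Omega > hi)):
        logger.warning(
            "V0/V2 power laws evaluated outside their stated validity band "
            "Omega in [%g, %g]", lo, hi)
    c = V_COEFFS
    return c["c0"] * Omega ** c["e0"], c["c2"] * Omega ** c["e2"]


def _ldm_angular_weights(theta_deg):
    """The four angular weights multiplying V0(O), V0(2O), V2(O), V2(2O)."""
    t = _theta_rad(theta_deg)
    s2 = np.sin(t) ** 2
    c2 = 1.0 - s2
    s4 = s2 * s2
    a0 = s2 * (5.0 + 3.0 * c2)
    a0d = 16.0 * c2 + 6.0 * s4
    a2 = 8.0 - 3.0 * s4
    a2d = 8.0 + 24.0 * s2 + 3.0 * s4
    return a0, a0d, a2, a2d


def r1_bb_ldm(theta_deg, ctx: FieldContext, Lambda, Omega0, *,
              warn: bool = True):
    """Bound-pool lateral-diffusion relaxation rate r1A [1/s].

    r1A = (Lambda/2) [ sin^2 t (5 + 3 cos^2 t) V0(O)
                       + (16 cos^2 t + 6 sin^4 t) V0(2O)
                       + (8 - 3 sin^4 t) V2(O)
                       + (8 + 24 sin^2 t + 3 sin^4 t) V2(2O) ]

    with O = (B / B_ref) * Omega0.  Decreasing in B at fixed angle because
    V0 and V2 decrease in Omega.
    """
    Lambda = np.asarray(Lambda, dtype=float)
    if np.any(Lambda < 0):
        raise InvalidParameterError("Lambda must be >= 0")
    Omega = ctx.Omega(np.asarray(Omega0, dtype=float))
    V0, V2 = v_functions(Omega, warn=warn)
    V0d, V2d = v_functions(2.0 * Omega, warn=warn)
    a0, a0d, a2, a2d = _ldm_angular_weights(theta_deg)
    bracket = a0 * V0 + a0d * V0d + a2 * V2 + a2d * V2d
    return EQ_CONSTANTS["ldm_prefactor"] * Lambda * bracket


# ---------------------------------------------------------------------------
# Exchange-coupled rates and the apparent R1
# ---------------------------------------------------------------------------

def exchange_terms(p: BiophysParams, theta_deg, ctx: FieldContext, *,
                   eq2_grouping: str = "grouped",
                   on_singular: str = "raise",
                   warn: bool = True):
    """Exchange fraction pA, water anisotropy dR1wA and bound rate R1bA.

    pA     = KA / [ (1-nbA) r1A + nbA kA - r1w ]
    dR1wA  = nwA (kA - nbA pA KA)            (``eq2_grouping='grouped'``)
           = nwA kA - nbA pA KA              (``eq2_grouping='ungrouped'``)
    R1bA   = (1-nbA) r1A + nbA kA + nwA nbA pA KA

    With lambdaA = 0 the THB channel is off: pA = dR1wA = 0 and
    R1bA = (1-nbA) r1A.

    ``on_singular`` controls what happens when the pA denominator falls
    below ``PA_SINGULAR_RTOL`` of its leading-term magnitude: ``"raise"``
    raises :class:`IllConditionedModelError` naming the angle and field,
    ``"nan"`` marks the affected entries NaN (used by the sampler, which
    maps them to -inf log-probability).
    """
    if eq2_grouping not in ("grouped", "ungrouped"):
        raise InvalidParameterError(f"unknown eq2_grouping {eq2_grouping!r}")
    kA, KA = rate_coefficients(theta_deg, ctx, p.lambdaA, p.tauA)
    r1A = r1_bb_ldm(theta_deg, ctx, p.Lambda, p.Omega0, warn=warn)
    den = (1.0 - p.nbA) * r1A + p.nbA * kA - p.r1w
    scale = (np.abs((1.0 - p.nbA) * r1A) + np.abs(p.nbA * kA)
             + np.abs(np.asarray(p.r1w, dtype=float)))
    singular = np.abs(den) <= PA_SINGULAR_RTOL * scale
    # lambdaA == 0 forces KA == 0 and pA == 0 regardless of the denominator
    trivial = np.broadcast_to(np.asarray(KA) == 0.0, np.shape(singular))
    singular = singular & ~trivial
    if np.any(singular):
        if on_singular == "raise":
            theta_b = np.atleast_1d(np.broadcast_to(
                np.asarray(theta_deg, dtype=float), np.shape(singular)))
            bad = np.argwhere(np.atleast_1d(singular))
            th = float(theta_b[tuple(bad[0])]) if bad.size else float("nan")
            raise IllConditionedModelError(
                f"pA denominator is singular at theta={th:.3g} deg, "
                f"B={ctx.B:g} T (parameter set makes pA unbounded)")
        den = np.where(singular, np.nan, den)
    with np.errstate(invalid="ignore", divide="ignore"):
        pA = np.where(np.asarray(KA) == 0.0, 0.0, KA / den)
    cross = p.nbA * pA * KA
    if eq2_grouping == "grouped":
        dR1wA = p.nwA * (kA - cross)
    else:
        dR1wA = p.nwA * kA - cross
    R1bA = (1.0 - p.nbA) * r1A + p.nbA * kA + p.nwA * cross
    return pA, dR1wA, R1bA


def r1_apparent(p: BiophysParams, R1I, theta_deg, ctx: FieldContext, *,
                eq2_grouping: str = "grouped",
                on_singular: str = "raise",
                warn: bool = True):
    """Apparent mixed-signal rate R1app = (1-z)(R1I + dR1wA) + z R1bA [1/s]."""
    R1I = np.asarray(R1I, dtype=float)
    if np.any(R1I <= 0):
        raise InvalidParameterError("R1I must be positive")
    _, dR1wA, R1bA = exchange_terms(p, theta_deg, ctx,
                                    eq2_grouping=eq2_grouping,
                                    on_singular=on_singular, warn=warn)
    z = p.zeta
    return (1.0 - z) * (R1I + dR1wA) + z * R1bA


def decompose_contributions(p: BiophysParams, R1I, theta_deg,
                            ctx: FieldContext, *, eq2_grouping="grouped"):
    """Split R1app into (isotropic, indirect water, direct bound) terms.

    Returns the triple ((1-z) R1I, (1-z) dR1wA, z R1bA); the three sum to
    :func:`r1_apparent` exactly.
    """
    _, dR1wA, R1bA = exchange_terms(p, theta_deg, ctx,
                                    eq2_grouping=eq2_grouping)
    z = p.zeta
    iso = np.broadcast_to((1.0 - z) * np.asarray(R1I, dtype=float),
                          np.shape(dR1wA)).copy()
    return iso, (1.0 - z) * dR1wA, z * R1bA


# ---------------------------------------------------------------------------
# Parameter-level relations
# ---------------------------------------------------------------------------

def thb_lambda_from_distance(r):
    """THB coupling strength from the w-b proton distance r [m]:

    lambda = (3/2) r^-6 (hbar gamma^2 / 2)^2   [1/s^2]
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise InvalidParameterError("r must be positive")
    c = (HBAR * GAMMA_PROTON ** 2 / 2.0) ** 2
    return EQ_CONSTANTS["lambda_prefactor"] * c / r ** 6


class DerivedDiffusion(NamedTuple):
    """Lateral-diffusion quantities derived from (Lambda, Omega0)."""

    tau_d: float  # characteristic diffusion time [s]
    d: float      # minimal approach distance [m]
    D: float      # lateral diffusion coefficient [m^2/s]


def derived_diffusion(Lambda: float, Omega0: float, ctx: FieldContext,
                      gamma: float = GAMMA_PROTON) -> DerivedDiffusion:
    """Solve for (tau_d, d, D) from the fitted (Lambda, Omega0).

    tau_d = Omega0 / omega_ref with omega_ref = gamma * B_ref, then (d, D)
    solve the strength relation

        Lambda = (9 pi / (256 D d^4)) (hbar gamma^2 / 2)^2

    jointly with tau_d = d^2 / (2 D).  Substituting D gives the closed form
    d^6 = 9 pi tau_d (hbar gamma^2 / 2)^2 / (128 Lambda).
    """
    if not (Lambda > 0 and Omega0 > 0):
        raise InvalidParameterError("Lambda and Omega0 must be positive")
    omega_ref = gamma * ctx.B_ref
    tau_d = Omega0 / omega_ref
    c = (HBAR * gamma ** 2 / 2.0) ** 2
    d6 = 9.0 * math.pi * tau_d * c / (128.0 * Lambda)
    if not (d6 > 0 and math.isfinite(d6)):
        raise IllConditionedModelError("no positive real (d, D) solution")
    d = d6 ** (1.0 / 6.0)
    D = d * d / (2.0 * tau_d)
    return DerivedDiffusion(tau_d=tau_d, d=d, D=D)


def conditioning_cap_lambda(base: BiophysParams, fields=None, *,
                            margin: float = 0.25,
                            theta_step_deg: float = 0.25) -> float:
    """Largest lambdaA keeping the pA denominator safely away from zero.

    The denominator (1-nbA) r1A + nbA kA - r1w is linear in lambdaA (through
    kA) and can cross zero at high field, where r1A shrinks while the
    long-lifetime kA stays negative around the g0 minimum.  This returns the
    largest lambdaA for which the denominator retains at least ``margin``
    of its lambdaA=0 value at every angle and every supplied field.
    """
    from .fields import study_fields

    if fields is None:
        fields = study_fields().values()
    theta = np.arange(0.0, 90.0 + theta_step_deg, theta_step_deg)
    cap = np.inf
    for ctx in fields:
        r1A = r1_bb_ldm(theta, ctx, base.Lambda, base.Omega0, warn=False)
        A = (1.0 - base.nbA) * r1A - base.r1w
        kA_unit, _ = rate_coefficients(theta, ctx, 1.0, base.tauA)
        slope = base.nbA * kA_unit
        neg = slope < 0
        if np.any(neg):
            cap = min(cap, float(np.min(A[neg] * (1.0 - margin)
                                        / (-slope[neg]))))
    return cap


def calibrate_lambda(base: BiophysParams,
                     R1I_3T: float | None = None,
                     ctx3: FieldContext | None = None,
                     target_fraction: float = 0.04,
                     theta_step_deg: float = 0.25,
                     conditioning_margin: float = 0.25) -> float:
    """lambdaA making the 3 T peak-to-trough anisotropy a set fraction of R1I.

    The observed angular modulation of R1 is a few percent of the mean rate;
    lacking a printed lambdaA, the default parameter set scales it so that
    max-min of R1app over theta in [0, 90] deg at 3 T equals
    ``target_fraction * R1I``, solved by brentq.  The result is capped at
    :func:`conditioning_cap_lambda` over the three study fields: beyond the
    cap the pA denominator crosses zero at 7 T and the model is singular
    there, so a target anisotropy requiring more coupling is reduced to the
    largest well-conditioned value (logged when the cap binds).
    """
    from .fields import study_field
    from .params import PUBLISHED_R1I

    if ctx3 is None:
        ctx3 = study_field(3.0)
    if R1I_3T is None:
        R1I_3T = PUBLISHED_R1I[3.0]
    theta = np.arange(0.0, 90.0 + theta_step_deg, theta_step_deg)

    def excess(lam):
        r1 = r1_apparent(base.replace(lambdaA=float(lam)), R1I_3T, theta,
                         ctx3, warn=False)
        return (float(np.max(r1) - np.min(r1)) / R1I_3T) - target_fraction

    cap = conditioning_cap_lambda(base, margin=conditioning_margin,
                                  theta_step_deg=theta_step_deg)
    if not math.isfinite(cap):
        cap = 1e16
    if excess(cap) < 0:
        logger.info(
            "lambdaA calibration capped at %.4g 1/s^2 by the pA conditioning "
            "bound; the %g anisotropy target is not reachable with a "
            "well-conditioned model at all study fields", cap, target_fraction)
        return float(cap)
    return float(brentq(excess, 0.0, cap, xtol=1e-6, rtol=1e-12))
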