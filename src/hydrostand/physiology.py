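"""Leaf- and tissue-level physiology.

Pressure-volume relations (three-stage tissue drainage), sigmoidal xylem
vulnerability and stomatal stress curves, Ball-Berry stomatal conductance with
a water-stress multiplier, and the coupled photosynthesis-conductance solver.

The pressure-volume curve follows the classic partition into a capillary
stage (at or above full turgor, water drawn from capillary reserves), an
elastic stage between full turgor and the turgor-loss point (solute plus
pressure potential), and a post-turgor-loss stage where only the solute
potential remains.
"""
from __future__ import annotations

import warnings

import numpy as np

# ---------------------------------------------------------------------------
# Pressure-volume curve
# ---------------------------------------------------------------------------


def _pv_stage23(rwcs, pi0, eps_bulk):
    """Elastic / post-turgor-loss water potential at normalized RWC* in (0, 1]."""
    psi_solute = pi0 / rwcs
    psi_pressure = np.maximum(0.0, -pi0 + eps_bulk * (rwcs - 1.0))
    return psi_solute + psi_pressure


def pv_water_potential(rwc, pi0, eps_bulk, resid_frac, cap_frac=0.0):
    """Tissue water potential (MPa) from relative water content.

    Parameters are scalars or broadcastable arrays. ``rwc`` is the absolute
    relative water content in (resid_frac, 1]; internally it is rescaled to
    RWC* = (rwc - resid_frac)/(1 - resid_frac).

    Stage 1 (capillary, RWC* >= 1 - cap_frac): linear from 0 at RWC* = 1 to the
    full-turgor elastic value at RWC* = 1 - cap_frac. Stages 2-3: solute
    potential pi0/RWC* plus turgor max(0, -pi0 + eps_bulk*(RWC* - 1)).
    """
    rwc = np.asarray(rwc, dtype=float)
    pi0 = np.asarray(pi0, dtype=float)
    eps_bulk = np.asarray(eps_bulk, dtype=float)
    resid_frac = np.asarray(resid_frac, dtype=float)
    cap_frac = np.asarray(cap_frac, dtype=float)
    if np.any(rwc <= resid_frac):
        raise ValueError("rwc <= resid_frac: water potential undefined below "
                         "residual water content")
    if np.any(rwc > 1.0 + 1e-12):
        raise ValueError("rwc > 1")
    rwcs = (rwc - resid_frac) / (1.0 - resid_frac)
    psi_el = _pv_stage23(rwcs, pi0, eps_bulk)
    # capillary stage: linear ramp to the elastic value at the stage boundary
    with np.errstate(divide="ignore", invalid="ignore"):
        boundary = 1.0 - cap_frac
        psi_ft = _pv_stage23(np.maximum(boundary, 1e-12), pi0, eps_bulk)
        psi_cap = np.where(cap_frac > 0, psi_ft * (1.0 - rwcs) / np.maximum(cap_frac, 1e-300), 0.0)
    out = np.where((cap_frac > 0) & (rwcs >= boundary), psi_cap, psi_el)
    return out if out.ndim else float(out)


def pv_slope(rwc, pi0, eps_bulk, resid_frac, cap_frac=0.0):
    """d(psi)/d(rwc) of the pressure-volume curve (MPa per unit rwc, > 0)."""
    rwc = np.asarray(rwc, dtype=float)
    pi0 = np.asarray(pi0, dtype=float)
    eps_bulk = np.asarray(eps_bulk, dtype=float)
    resid_frac = np.asarray(resid_frac, dtype=float)
    cap_frac = np.asarray(cap_frac, dtype=float)
    rwcs = (rwc - resid_frac) / (1.0 - resid_frac)
    rwcs = np.maximum(rwcs, 1e-9)
    turgid = (-pi0 + eps_bulk * (rwcs - 1.0)) > 0.0
    dpsi_drwcs = -pi0 / rwcs**2 + np.where(turgid, eps_bulk, 0.0)
    if np.any(cap_frac > 0):
        boundary = 1.0 - cap_frac
        psi_ft = _pv_stage23(np.maximum(boundary, 1e-12), pi0, eps_bulk)
        cap_slope = -psi_ft / np.maximum(cap_frac, 1e-300)
        dpsi_drwcs = np.where((cap_frac > 0) & (rwcs >= boundary), cap_slope, dpsi_drwcs)
    out = dpsi_drwcs / (1.0 - resid_frac)
    return out if out.ndim else float(out)


def pv_rwc_from_psi(psi, pi0, eps_bulk, resid_frac, cap_frac=0.0, iters=60):
    """Invert the pressure-volume curve by bisection on rwc.

    Vectorized over broadcastable inputs; round-trip error is far below
    1e-8 MPa for the default iteration count.
    """
    psi = np.asarray(psi, dtype=float)
    shape = np.broadcast_shapes(psi.shape, np.shape(pi0), np.shape(eps_bulk),
                                np.shape(resid_frac), np.shape(cap_frac))
    psi_b = np.broadcast_to(psi, shape).astype(float)
    pi0_b = np.broadcast_to(np.asarray(pi0, float), shape)
    eps_b = np.broadcast_to(np.asarray(eps_bulk, float), shape)
    rf_b = np.broadcast_to(np.asarray(resid_frac, float), shape)
    cf_b = np.broadcast_to(np.asarray(cap_frac, float), shape)
    lo = rf_b + 1e-9 * (1.0 - rf_b)
    hi = np.ones(shape)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        val = pv_water_potential(mid, pi0_b, eps_b, rf_b, cf_b)
        too_wet = val > psi_b  # psi monotone increasing in rwc
        hi = np.where(too_wet, mid, hi)
        lo = np.where(too_wet, lo, mid)
    out = 0.5 * (lo + hi)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Vulnerability and stomatal stress sigmoids
# ---------------------------------------------------------------------------


def conductivity_fraction(psi, p50, shape):
    """Fraction of maximum xylem conductivity (1 - PLC) at water potential psi.

    Sigmoid anchored at the P50: k/kmax = [1 + (psi/p50)^shape]^-1, so
    psi = p50 gives exactly 0.5 for any positive shape. Positive psi is
    clamped to zero (supersaturation treated as no conductivity loss) with a
    warning.
    """
    psi = np.asarray(psi, dtype=float)
    p50 = np.asarray(p50, dtype=float)
    shape = np.asarray(shape, dtype=float)
    if np.any(p50 >= 0):
        raise ValueError("p50 must be strictly negative")
    if np.any(shape <= 0):
        raise ValueError("shape must be positive")
    if np.any(psi > 0):
        warnings.warn("positive water potential clamped to 0 in "
                      "conductivity_fraction", stacklevel=2)
        psi = np.minimum(psi, 0.0)
    ratio = psi / p50  # >= 0
    out = 1.0 / (1.0 + ratio**shape)
    return out if out.ndim else float(out)


def stress_factor(psi_leaf, p50_gs, a_gs):
    """Plant water-stress factor beta in (0, 1] from leaf water potential.

    beta = [1 + (psi_leaf/p50_gs)^a_gs]^-1: equal to 0.5 at the leaf water
    potential where stomatal conductance is halved (psi50gs) and tending to 1
    as the leaf relaxes toward zero potential. Positive leaf potential is
    clamped to zero.
    """
    psi_leaf = np.minimum(np.asarray(psi_leaf, dtype=float), 0.0)
    p50_gs = np.asarray(p50_gs, dtype=float)
    a_gs = np.asarray(a_gs, dtype=float)
    if np.any(p50_gs >= 0):
        raise ValueError("p50_gs must be strictly negative")
    if np.any(a_gs <= 0):
        raise ValueError("a_gs must be positive")
    out = 1.0 / (1.0 + (psi_leaf / p50_gs)**a_gs)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Ball-Berry stomatal conductance
# ---------------------------------------------------------------------------


def stomatal_conductance(an, cs, patm, hs, beta, g0, g1):
    """Ball-Berry stomatal conductance with water-stress multiplier.

    gs = g0 + g1 * (an * 1e-6) / (cs / patm) * hs * beta, floored at g0;
    non-positive net photosynthesis closes stomata to the cuticular minimum.
    ``an`` is in umol m-2 s-1, ``cs`` and ``patm`` in Pa, result mol m-2 s-1.
    """
    an = np.asarray(an, dtype=float)
    cs = np.asarray(cs, dtype=float)
    if np.any(cs <= 0):
        raise ValueError("cs must be positive")
    if np.any(np.asarray(patm) <= 0):
        raise ValueError("patm must be positive")
    gs = g0 + g1 * (an * 1e-6) / (cs / patm) * hs * beta
    gs = np.where(an <= 0, g0, np.maximum(gs, g0))
    return gs if gs.ndim else float(gs)


# ---------------------------------------------------------------------------
# Minimal Farquhar biochemistry (Rubisco/RuBP limitation)
# ---------------------------------------------------------------------------

_RGAS = 8.314  # J mol-1 K-1
KC25, HA_KC = 40.49, 79430.0        # Pa, J mol-1
KO25, HA_KO = 27840.0, 36380.0      # Pa, J mol-1
GSTAR25, HA_GSTAR = 4.332, 37830.0  # Pa, J mol-1
HA_VCMAX = 65330.0
HA_JMAX = 43540.0
HA_RD = 46390.0
O2_PA = 20900.0       # Pa, ambient O2 partial pressure
JMAX_RATIO = 1.67     # Jmax25 / Vcmax25
RD_RATIO = 0.015      # Rd25 / Vcmax25
THETA_J = 0.9         # curvature of the light response
ALPHA_Q = 0.3         # mol electrons per mol incident photons
PAR_PER_SW = 2.3      # umol photons per J shortwave (0.5 PAR fraction x 4.6)


def _arrhenius(ha, tleaf_c):
    tk = np.asarray(tleaf_c, float) + 273.15
    return np.exp(ha / _RGAS * (1.0 / 298.15 - 1.0 / tk))


def farquhar_temp_responses(tair_c):
    """Temperature-dependent biochemistry terms (vectorizable over time).

    Returns (f_vcmax, f_jmax, f_rd, kc_eff, gstar): multiply the 25 C rates
    by the f factors; kc_eff is Kc(1 + O/Ko), the effective Michaelis term.
    """
    kc = KC25 * _arrhenius(HA_KC, tair_c)
    ko = KO25 * _arrhenius(HA_KO, tair_c)
    return (_arrhenius(HA_VCMAX, tair_c), _arrhenius(HA_JMAX, tair_c),
            _arrhenius(HA_RD, tair_c), kc * (1.0 + O2_PA / ko),
            GSTAR25 * _arrhenius(HA_GSTAR, tair_c))


def _solve_leaf_core(par, cs, hs, beta, g0, g1, vcmax, jmax, rd, kc_eff,
                     gstar, patm, iters=30):
    """Bisection on ci for the coupled supply/demand/diffusion system.

    All biochemistry terms are pre-evaluated at leaf temperature; trait
    arguments may be arrays over ensemble members. Returns leaf-level
    (an, gs, ci). The bracket always contains the fixed point: below, an < 0
    pins gs at g0 and the implied ci exceeds the midpoint; above, an > 0
    pulls the implied ci below it.
    """
    i2 = ALPHA_Q * par
    bb = i2 + jmax
    j4 = (bb - np.sqrt(np.maximum(bb * bb - 4.0 * THETA_J * i2 * jmax, 0.0))) \
        / (2.0 * THETA_J) / 4.0
    inv_csp = patm / cs
    lo = np.broadcast_to(np.minimum(gstar * 0.5, cs * 0.5),
                         np.shape(beta)).astype(float)
    hi = np.broadcast_to(cs + 1.6 * rd * 1e-6 * patm / np.maximum(g0, 1e-6),
                         np.shape(beta)).astype(float)
    an = gs = mid = None
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        cip = np.maximum(mid, gstar)
        an = np.minimum(vcmax * (cip - gstar) / (cip + kc_eff),
                        j4 * (cip - gstar) / (cip + 2.0 * gstar)) - rd
        gs = g0 + g1 * (an * 1e-6) * inv_csp * hs * beta
        gs = np.where(an <= 0, g0, np.maximum(gs, g0))
        f = cs - 1.6 * an * 1e-6 * patm / gs - mid
        pos = f > 0
        lo = np.where(pos, mid, lo)
        hi = np.where(pos, hi, mid)
    return an, gs, mid


def electron_transport(par, jmax):
    """Non-rectangular hyperbola light response (umol electrons m-2 s-1)."""
    i2 = ALPHA_Q * par
    b = i2 + jmax
    disc = np.maximum(b * b - 4.0 * THETA_J * i2 * jmax, 0.0)
    return (b - np.sqrt(disc)) / (2.0 * THETA_J)


def net_photosynthesis(ci, tleaf_c, par, vcmax25):
    """Leaf net assimilation (umol m-2 s-1) at intercellular CO2 ci (Pa)."""
    vcmax = vcmax25 * _arrhenius(HA_VCMAX, tleaf_c)
    jmax = JMAX_RATIO * vcmax25 * _arrhenius(HA_JMAX, tleaf_c)
    rd = RD_RATIO * vcmax25 * _arrhenius(HA_RD, tleaf_c)
    kc = KC25 * _arrhenius(HA_KC, tleaf_c)
    ko = KO25 * _arrhenius(HA_KO, tleaf_c)
    gstar = GSTAR25 * _arrhenius(HA_GSTAR, tleaf_c)
    j = electron_transport(par, jmax)
    ci_pos = np.maximum(ci, gstar)
    ac = vcmax * (ci_pos - gstar) / (ci_pos + kc * (1.0 + O2_PA / ko))
    aj = (j / 4.0) * (ci_pos - gstar) / (ci_pos + 2.0 * gstar)
    return np.minimum(ac, aj) - rd


def canopy_scale(lai, k_ext=0.5):
    """Big-leaf scaling factor (1 - exp(-k*LAI)) / k (units of effective LAI)."""
    return (1.0 - np.exp(-k_ext * lai)) / k_ext


def solve_leaf_exchange(tair_c, swdown, rh_pct, co2_ppm, beta,
                        g0, g1, vcmax25, lai, k_ext=0.5, patm=101325.0,
                        iters=48, residual_tol=1e-6, label=""):
    """Coupled Ball-Berry / Farquhar / diffusion fixed point, big-leaf canopy.

    Solves for intercellular CO2 by bisection on the strictly decreasing
    mismatch between the diffusion-implied and assumed ci. Returns canopy-
    scaled ``(an_canopy, gs_canopy, ci)`` with an in umol CO2 m-2 ground s-1,
    gs (to water vapor) in mol m-2 ground s-1 and ci in Pa.

    All leaf/trait arguments may be (n,) arrays for a batch of assemblages;
    the meteorological arguments are scalars for one forcing step. Raises if
    any converged residual exceeds ``residual_tol`` (relative to an, floored
    at 1 umol m-2 s-1 to keep the dark limit well-posed).
    """
    beta = np.asarray(beta, dtype=float)
    g0 = np.asarray(g0, dtype=float)
    cs = co2_ppm * 1e-6 * patm
    if cs <= 0:
        raise ValueError("cs must be positive (co2_ppm > 0)")
    par = max(swdown, 0.0) * PAR_PER_SW
    hs = min(max(rh_pct / 100.0, 0.05), 1.0)
    scale = canopy_scale(lai, k_ext)

    rd = RD_RATIO * np.asarray(vcmax25, float) * _arrhenius(HA_RD, tair_c)
    if par <= 1e-9:
        # dark limit: respiration only, stomata at the cuticular minimum
        an = -rd
        gs = np.broadcast_to(g0, an.shape if an.ndim else ()).astype(float)
        ci = cs - 1.6 * an * 1e-6 * patm / np.maximum(gs, 1e-12)
        out = (an * scale, gs * scale, ci)
        return tuple(o if np.ndim(o) else float(o) for o in out)

    fv, fj, fr, kc_eff, gstar = farquhar_temp_responses(tair_c)
    vcmax = np.asarray(vcmax25, float) * fv
    jmax = JMAX_RATIO * np.asarray(vcmax25, float) * fj
    an, gs, ci = _solve_leaf_core(par, cs, hs, beta, g0, np.asarray(g1, float),
                                  vcmax, jmax, rd, kc_eff, gstar, patm,
                                  iters=iters)
    # diffusion-closure residual, expressed as an assimilation error
    f = cs - 1.6 * an * 1e-6 * patm / gs - ci
    dan = np.abs(net_photosynthesis(ci + f, tair_c, par, vcmax25)
                 - net_photosynthesis(ci, tair_c, par, vcmax25))
    rel = dan / np.maximum(np.abs(an), 1.0)
    if np.any(rel > residual_tol):
        raise RuntimeError(
            f"leaf exchange solver did not converge{' at ' + label if label else ''}: "
            f"max relative residual {float(np.max(rel)):.3e}")
    out = (an * scale, gs * scale, ci)
    return tuple(o if np.ndim(o) else float(o) for o in out)


def leaf_exchange_residuals(an_canopy, gs_canopy, ci, tair_c, swdown, rh_pct,
                            co2_ppm, beta, g0, g1, vcmax25, lai, k_ext=0.5,
                            patm=101325.0):
    """Residuals of the three coupled equations for a converged solution.

    Returns (supply, demand, diffusion) as relative errors: the Ball-Berry
    supply curve gs(an), the biochemical demand curve an(ci), and the
    diffusion closure ci = cs - 1.6 an Patm / gs (relative to cs). Together
    they are the independent check that a solution satisfies the whole
    coupled system.
    """
    scale = canopy_scale(lai, k_ext)
    an = np.asarray(an_canopy, float) / scale
    gs = np.asarray(gs_canopy, float) / scale
    cs = co2_ppm * 1e-6 * patm
    hs = min(max(rh_pct / 100.0, 0.05), 1.0)
    par = max(swdown, 0.0) * PAR_PER_SW
    gs_bb = stomatal_conductance(an, cs, patm, hs, beta, g0, g1)
    supply = np.abs(gs_bb - gs) / np.maximum(np.abs(gs), 1e-12)
    an_bio = net_photosynthesis(ci, tair_c, par, vcmax25)
    demand = np.abs(an_bio - an) / np.maximum(np.abs(an), 1.0)
    diffusion = np.abs(cs - 1.6 * an * 1e-6 * patm / np.maximum(gs, 1e-12)
                       - ci) / cs
    return supply, demand, diffusion
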