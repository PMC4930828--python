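"""Particle–liquid exchange: dissolution, size-bin cascade, drag and slip.

Food particles are represented as fixed-diameter size classes ("bins")
j = 2..6.  Acidic dissolution moves particle mass into the dissolved
components in proportion to the particle composition; the shrinking of
partially dissolved particles is modelled as a mass cascade from each bin to
the next smaller one.  The smallest bin (nondigestible fibre) neither
dissolves nor cascades.  Momentum exchange uses a Wen–Yu-type drag law valid
for particle Reynolds numbers up to ~1000; the full per-phase momentum
balance is reduced to an algebraic terminal-slip (drift-flux) closure.
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)

#: Mass exchange stops in neutral/alkaline surroundings.
DISSOLUTION_PH_CUTOFF = 7.0
_RE_LIMIT = 1000.0
_re_warned = False


def dissolution_coefficient(pH, k_phys, a, b):
    """Mass-transfer coefficient k = k_phys * a * pH**b, kg/(m^2 s).

    The power law is an empirical fit for carrot tissue; ``k_phys`` is the
    transfer coefficient at the reference gastric acidity (f(1.8) ~ 1).
    Clamped to zero at pH >= 7 — no dissolution in a neutral or alkaline
    environment.
    """
    pH = np.asarray(pH, dtype=float)
    if np.any(pH <= 0):
        raise ValueError("pH must be positive")
    k = np.where(pH < DISSOLUTION_PH_CUTOFF, k_phys * a * pH ** b, 0.0)
    return k if k.ndim else float(k)


def particle_to_solution_flux(alpha_j, d_j, k, beta_i, dissolvable=True):
    """Dissolution mass flux m'(j)(i) = beta_i * 6 k alpha_j / d_j, kg/(m^3 s).

    ``6 alpha / d`` is the specific surface of spheres at diameter ``d``;
    ``beta_i`` partitions the dissolved mass over the particle components.
    Zero for the nondigestible smallest bin.
    """
    alpha_j = np.asarray(alpha_j, dtype=float)
    d_j = np.asarray(d_j, dtype=float)
    if np.any(d_j <= 0):
        raise ValueError("particle diameter must be positive")
    if np.any(alpha_j < 0):
        raise ValueError("volume fraction must be nonnegative")
    flux = np.asarray(beta_i) * 6.0 * np.asarray(k) * alpha_j / d_j
    flux = np.where(dissolvable, flux, 0.0)
    return flux if flux.ndim else float(flux)


def bin_cascade_flux(alpha_j, d_j, d_next, k, dissolvable=True):
    """Size-cascade flux m''(j)(j+1), kg/(m^3 s): mass of bin-j particles
    reclassified into the next smaller bin as dissolution shrinks them::

        m'' = 6 d_next^3 k alpha_j / (d_j (d_j^3 - d_next^3))

    The geometric factor follows from spherical volume ratios at fixed bin
    diameters; it is zero for the last (nondigestible) bin and there is no
    cascade into the largest bin.
    """
    d_j = np.asarray(d_j, dtype=float)
    d_next = np.asarray(d_next, dtype=float)
    if np.any(d_next <= 0) or np.any(d_j <= d_next):
        raise ValueError("diameters must satisfy d_j > d_next > 0")
    alpha_j = np.asarray(alpha_j, dtype=float)
    flux = 6.0 * d_next ** 3 * np.asarray(k) * alpha_j / (d_j * (d_j ** 3 - d_next ** 3))
    flux = np.where(dissolvable, flux, 0.0)
    return flux if flux.ndim else float(flux)


def _drag_correction(Re):
    global _re_warned
    Re = np.asarray(Re, dtype=float)
    if np.any(Re > _RE_LIMIT) and not _re_warned:
        logger.warning("particle Reynolds number exceeds %g; the low-Re drag "
                       "closure is extrapolated", _RE_LIMIT)
        _re_warned = True
    return 1.0 + 0.15 * Re ** 0.687


def drag_coefficient_particle_liquid(alpha_j, alpha_1, eta_1, d_j, slip, rho_1):
    """Interphase drag K(j)(1) = 18 alpha_j alpha_1 eta_1 / d_j^2 * (1 + 0.15 Re^0.687),
    Re = rho_1 |slip| d_j / eta_1.  Units kg/(m^3 s)."""
    Re = np.asarray(rho_1) * np.abs(np.asarray(slip)) * np.asarray(d_j) / np.asarray(eta_1)
    K = (18.0 * np.asarray(alpha_j) * np.asarray(alpha_1) * np.asarray(eta_1)
         / np.asarray(d_j) ** 2 * _drag_correction(Re))
    return K if K.ndim else float(K)


def drag_coefficient_particle_particle(alpha_j, alpha_q, eta_j, d_j, d_q, slip, rho_j):
    """Symmetric particle–particle drag
    K(j)(q) = 72 alpha_j alpha_q eta_j / (d_j + d_q)^2 * (1 + 0.15 Re^0.687),
    Re = 0.5 rho_j |slip| (d_j + d_q) / eta_j."""
    dsum = np.asarray(d_j) + np.asarray(d_q)
    Re = 0.5 * np.asarray(rho_j) * np.abs(np.asarray(slip)) * dsum / np.asarray(eta_j)
    K = (72.0 * np.asarray(alpha_j) * np.asarray(alpha_q) * np.asarray(eta_j)
         / dsum ** 2 * _drag_correction(Re))
    return K if K.ndim else float(K)


def slip_velocity(alpha_j, alpha_1, rho_j, rho_mix, d_j, eta_1, rho_1, g_axis,
                  tol=1e-10, max_iter=100, v_max=None):
    """Terminal sedimentation slip v_j - v_1 along the centerline, m/s.

    Balances drag against buoyancy, K(j)(1) (v1 - vj) + alpha_j (rho_j -
    rho_mix) g_axis = 0, and solves the implicit dependence of K on the slip
    (through Re) by damped fixed-point iteration.  ``g_axis`` is the gravity
    component along +x (signed).  Neutral buoyancy gives zero slip; denser
    particles drift toward the gravity vector (settling).  All arguments
    broadcast.
    """
    alpha_j, alpha_1, rho_j, rho_mix, d_j, g_axis = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in
          (alpha_j, alpha_1, rho_j, rho_mix, d_j, g_axis)))
    scalar = alpha_j.ndim == 0
    # buoyancy per unit volume over the alpha_j-independent part of the drag
    stokes_coeff = 18.0 * np.maximum(np.asarray(alpha_1, dtype=float), 1e-6) \
        * eta_1 / d_j ** 2
    forcing = (rho_j - rho_mix) * g_axis  # alpha_j cancels against K's alpha_j
    v = forcing / stokes_coeff  # Stokes (Re=0) first guess
    for _ in range(max_iter):
        Re = rho_1 * np.abs(v) * d_j / eta_1
        v_new = forcing / (stokes_coeff * _drag_correction(Re))
        v_new = 0.5 * (v + v_new)  # damping for stability at high Re
        if np.all(np.abs(v_new - v) <= tol):
            v = v_new
            break
        v = v_new
    if v_max is not None:
        v = np.clip(v, -v_max, v_max)
    return float(v) if scalar else v
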