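"""Homogeneous chemistry of the liquid phase.

Covers molar concentrations, the pH diagnostic, acid–bicarbonate
neutralization (NaHCO3 + HCl -> NaCl + H2O + CO2, bimolecular with a large
rate constant), and pepsin proteolysis of dissolved protein in
Michaelis–Menten form with a quadratic pH modifier.

Unit conventions: volume fractions dimensionless, densities kg/m^3, molar
concentrations kmol/m^3 (numerically equal to mol/L, so pH needs no unit
conversion), reaction rates kg/(m^3 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import (BICARB, HCL, PEPSIN, POLYPEPTIDE, PRODUCT, PROTEIN,
                     WATER, ComponentRegistry, ReactionParams)

#: Acid concentration floor (kmol/m^3) for the pH diagnostic; pure water and
#: the alkaline duodenal lumen report the pH 8 cap rather than +inf.  The
#: model carries no hydroxide/carbonate speciation, so pH is meaningful only
#: on the acidic side.
PH_FLOOR_CONC = 1e-8
PH_CAP = 8.0


@dataclass
class MixtureState:
    """Intensive state of the liquid phase at one point (or per cell)."""

    alpha1: np.ndarray          # liquid volume fraction
    rho1: float                 # liquid density, kg/m^3
    Y: np.ndarray               # mass fractions, last axis = component
    registry: ComponentRegistry = field(default_factory=ComponentRegistry)

    def __post_init__(self) -> None:
        Y = np.asarray(self.Y, dtype=float)
        if np.any(Y < -1e-12):
            raise ValueError("mass fractions must be nonnegative")
        if np.any(np.abs(Y.sum(axis=-1) - 1.0) > 1e-9):
            raise ValueError("mass fractions must sum to 1")
        a1 = np.asarray(self.alpha1, dtype=float)
        if np.any((a1 < 0) | (a1 > 1)):
            raise ValueError("liquid volume fraction must lie in [0, 1]")

    @property
    def concentrations(self) -> np.ndarray:
        """C_i = alpha1 * Y_i * rho1 / M_i per component, kmol/m^3."""
        Y = np.asarray(self.Y)
        a1 = np.asarray(self.alpha1)
        if Y.ndim == a1.ndim + 1:
            a1 = a1[..., None]
        return molar_concentration(a1, Y, self.rho1,
                                   self.registry.molar_masses)

    @property
    def pH(self) -> np.ndarray:
        return ph(self.concentrations[..., HCL])


def molar_concentration(alpha1, Y_i, rho1, M_i):
    """Molar concentration C_i = alpha1 * Y_i * rho1 / M_i (kmol/m^3)."""
    M_i = np.asarray(M_i, dtype=float)
    if np.any(M_i <= 0):
        raise ValueError("molar mass must be positive")
    return np.asarray(alpha1) * np.asarray(Y_i) * np.asarray(rho1) / M_i


def ph(C0):
    """pH from the hydrochloric-acid molar concentration (full dissociation).

    kmol/m^3 is numerically mol/L; the concentration is floored at 1e-8 so an
    acid-free liquid reports the cap pH 8, consistent with the alkaline
    duodenal range of the model.
    """
    C0 = np.asarray(C0, dtype=float)
    if np.any(C0 < 0):
        raise ValueError("acid concentration must be nonnegative")
    out = -np.log10(np.maximum(C0, PH_FLOOR_CONC))
    return out if out.ndim else float(out)


def neutralization_rates(C0, C2, k02, registry: ComponentRegistry) -> dict:
    """Mass-source intensities of the acid/bicarbonate neutralization.

    The molar rate is k02 * C0 * C2; per component, |R_i| = k02 M_i C0 C2,
    negative for the reagents (HCl, NaHCO3) and positive for the products
    (NaCl + CO2, water).  Returns a mapping component index -> kg/(m^3 s).
    The four rates sum to zero because M0 + M2 = M1 + M9.
    """
    C0 = np.asarray(C0, dtype=float)
    C2 = np.asarray(C2, dtype=float)
    if np.any(C0 < 0) or np.any(C2 < 0):
        raise ValueError("concentrations must be nonnegative")
    molar = k02 * C0 * C2
    M = registry.molar_masses
    return {
        HCL: -M[HCL] * molar,
        BICARB: -M[BICARB] * molar,
        PRODUCT: M[PRODUCT] * molar,
        WATER: M[WATER] * molar,
    }


def pepsin_ph_modifier(pH, a37, b37, c37):
    """Quadratic pepsin-activity factor f(pH) = max(0, a pH^2 + b pH + c).

    With the published coefficients the parabola peaks at pH 2.32 and the
    activity vanishes above pH 4.45 (and below pH 0.19).
    """
    pH = np.asarray(pH, dtype=float)
    out = np.maximum(0.0, a37 * pH ** 2 + b37 * pH + c37)
    return out if out.ndim else float(out)


def proteolysis_rates(state: MixtureState, params: ReactionParams):
    """Pepsin-catalysed conversion of dissolved protein into polypeptides.

    Michaelis–Menten in the protein concentration, linear in the enzyme, and
    modulated by the quadratic pH factor::

        |R| = k37 f(pH) (alpha1 rho1)^2 Y3 Y7 / M7
              / (k37' + alpha1 rho1 Y3 / M3)

    which is a mass rate in kg/(m^3 s) as written: the Y7 factor carries the
    molar enzyme concentration and the Y3 factor a mass concentration, so the
    saturated limit is k37 f C7 M3 — protein mass loss is M3 times the molar
    turnover with no extra scaling.  Returns ``(R3, R8)`` with R3 <= 0,
    R8 = -R3 (the polypeptide pool gains exactly the protein mass lost).
    """
    M = state.registry.molar_masses
    a1 = np.asarray(state.alpha1, dtype=float)
    Y = np.asarray(state.Y, dtype=float)
    conc_mass = a1 * state.rho1  # kg liquid per m^3 mixture
    f = pepsin_ph_modifier(state.pH, params.a37, params.b37, params.c37)
    numer = params.k37 * f * conc_mass ** 2 * Y[..., PROTEIN] * Y[..., PEPSIN] / M[PEPSIN]
    denom = params.k37_lim + conc_mass * Y[..., PROTEIN] / M[PROTEIN]
    rate = np.where(denom > 0, numer / np.where(denom > 0, denom, 1.0), 0.0)
    return -rate, +rate
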