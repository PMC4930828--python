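"""Wall-region mass sources: gland secretion and absorption into blood.

Acid (upper antrum, l = 2), pepsin (l = 2) and sodium bicarbonate
(l = 3, 4, 5) enter the liquid phase in the wall-adjacent layer of their
region, with saturable Michaelis-type dependence on the near-wall
concentrations that drive each gland (dissolved nutrients for acid and
pepsin, luminal acid for bicarbonate — the neutralization feedback).  Water
is co-secreted at a fixed mass ratio so the gland fluids have constant
composition.  Chemicals (lead) are absorbed across every wall region at a
rate proportional to the cavity–blood concentration difference.  All outputs
scale linearly with the functionality F of the region: F = 0 silences the
gland, F = 1 is the undamaged rate.

Functions return volumetric source intensities in kg/(m^3 s) referred to the
wall-layer volume V(l); multiplying by V(l) recovers the total gland output
in kg/s, which is how the transport solver applies them.
"""

from __future__ import annotations

import numpy as np

from .params import SecretionParams, ParameterError, CARB, FAT, PROTEIN


def _require_fraction(F: float, name: str) -> None:
    if not 0.0 <= F <= 1.0:
        raise ParameterError(f"{name} must lie in [0, 1]")


def _region_volume(params: SecretionParams, l: int) -> float:
    try:
        return params.region_volumes[l]
    except KeyError:
        raise ParameterError(
            f"region volume V({l}) not set; derive it from the geometry "
            "before evaluating volumetric secretion rates") from None


def acid_secretion(region_conc, params: SecretionParams, F21: float) -> dict:
    """Acid source S(0)(2) in the upper antrum, kg/(m^3 s).

    ``region_conc`` maps component index -> mean near-wall mass concentration
    [rho1 alpha1 Y_i] (kg/m^3) for the dissolved nutrients i in {3, 4, 5}.
    Saturable stimulation on top of the basal rate::

        S = F21 * (s0 + sum_i s_i c_i / (s' + sum_i c_i)) / V(2)

    Water is co-secreted at ``water_acid_ratio`` times the acid rate.
    Returns ``{"acid": S, "water": s92 * S}``.
    """
    _require_fraction(F21, "F(2)(1)")
    total = 0.0
    weighted = 0.0
    for i in (PROTEIN, FAT, CARB):
        c = float(region_conc.get(i, 0.0))
        if c < 0:
            raise ParameterError("concentrations must be nonnegative")
        total += c
        weighted += params.acid_stim[i] * c
    rate_total = params.acid_basal + (weighted / (params.acid_limit + total)
                                      if total > 0 else 0.0)
    S = F21 * rate_total / _region_volume(params, 2)
    return {"acid": S, "water": params.water_acid_ratio * S}


def pepsin_secretion(protein_conc: float, params: SecretionParams,
                     F21: float) -> float:
    """Pepsin source S(7)(2), kg/(m^3 s): saturable in the near-wall dissolved
    protein concentration alone."""
    _require_fraction(F21, "F(2)(1)")
    if protein_conc < 0:
        raise ParameterError("concentrations must be nonnegative")
    stim = params.pepsin_stim * protein_conc / (params.pepsin_limit + protein_conc)
    return F21 * (params.pepsin_basal + stim) / _region_volume(params, 2)


def bicarbonate_secretion(acid_conc: float, params: SecretionParams,
                          F_l1: float, l: int) -> dict:
    """Bicarbonate source S(2)(l) for l in {3, 4, 5}, kg/(m^3 s).

    Saturable in the near-wall acid concentration — the experimentally known
    feedback by which acid output recruits alkaline secretion downstream.
    Water is co-secreted at the region's ``water_bicarb_ratio``.
    Returns ``{"bicarb": S, "water": s9l * S}``.
    """
    if l not in (3, 4, 5):
        raise ParameterError("bicarbonate is secreted in regions l = 3, 4, 5")
    _require_fraction(F_l1, f"F({l})(1)")
    if acid_conc < 0:
        raise ParameterError("concentrations must be nonnegative")
    stim = (params.bicarb_stim[l] * acid_conc
            / (params.bicarb_limit[l] + acid_conc))
    S = F_l1 * (params.bicarb_basal[l] + stim) / _region_volume(params, l)
    return {"bicarb": S, "water": params.water_bicarb_ratio[l] * S}


def absorption_flux(chem_conc, params: SecretionParams, F_l2: float,
                    l: int):
    """Chemical (lead) wall absorption S(6)(l) = -F s(6)(l) (c - h6 C6_blood),
    kg/(m^3 s); nonpositive whenever the cavity concentration exceeds the
    blood equilibrium level.  Local (per cell), not region-averaged."""
    if l not in (2, 3, 4, 5):
        raise ParameterError("absorption occurs across wall regions l = 2..5")
    _require_fraction(F_l2, f"F({l})(2)")
    chem_conc = np.asarray(chem_conc, dtype=float)
    out = -F_l2 * params.absorption_rate[l] * (
        chem_conc - params.partition_h6 * params.blood_conc)
    return out if out.ndim else float(out)
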