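"""Registries, parameter tables, scenarios and unit-conversion derivations.

All quantities are SI unless stated.  The ten dissolved components of the
first (liquid) phase are indexed ``i = 0..9``; the five food-particle size
classes are phases ``j = 2..6`` (phase 1 is the liquid).  Secretion constants
are stored as *total* gland outputs in kg/s; the volumetric source densities
used by the transport solver are obtained by dividing by the wall-layer
volume ``V(l)`` of the secreting region, which is derived from the configured
geometry (the tract anatomy fixes it, not the rate data).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from .geometry import (GeometryConfig, PyloricGate, WaveParams,
                       antral_wave_defaults, duodenal_wave_defaults)

__all__ = [
    "ParameterError", "ConfigError", "Component", "ComponentRegistry",
    "ParticleBin", "PhaseRegistry", "SecretionParams", "ReactionParams",
    "Scenario", "FunctionalityMap", "NumericsConfig", "Config",
    "derive_acid_mass_rate", "derive_water_coupling", "derive_basal_rate",
    "load_scenario", "SCENARIOS",
]


class ParameterError(ValueError):
    """A physical parameter is outside its admissible range."""


class ConfigError(ValueError):
    """A configuration file or scenario selection is invalid."""


# ---------------------------------------------------------------------------
# component registry (first phase, i = 0..9)
# ---------------------------------------------------------------------------

# component indices
HCL, PRODUCT, BICARB, PROTEIN, FAT, CARB, CHEMICAL, PEPSIN, POLYPEPTIDE, WATER = \
    range(10)

N_COMPONENTS = 10
N_BINS = 5  # particle phases j = 2..6


@dataclass(frozen=True)
class Component:
    name: str
    molar_mass: float      # kg/kmol
    diffusion: float       # m^2/s


# Molar masses: HCl, NaHCO3 and water from standard chemistry; the NaCl+CO2
# reaction product carries M = 58.44 + 44.01 so the neutralization
# NaHCO3 + HCl -> NaCl + H2O + CO2 conserves mass exactly.  Protein is the
# synthetic dipeptide substrate (354.4) and pepsin 35000; fats/carbohydrates/
# polypeptides get nominal values (triolein, glucose, a short peptide) — they
# enter no molar-rate expression.  The exemplar chemical is lead (207.2).
_DEFAULT_COMPONENTS = (
    Component("hydrochloric acid", 36.46, 1e-9),
    Component("reaction product (NaCl + CO2)", 102.45, 1e-9),
    Component("sodium bicarbonate", 84.01, 1e-9),
    Component("solute proteins", 354.4, 1e-9),
    Component("solute fats", 885.4, 1e-9),
    Component("solute carbohydrates", 180.16, 1e-9),
    Component("chemicals (lead)", 207.2, 5.12e-10),
    Component("pepsin", 35000.0, 1e-9),
    Component("polypeptides", 1000.0, 1e-9),
    Component("water", 18.02, 1e-9),
)


@dataclass
class ComponentRegistry:
    """The ten dissolved components of the liquid phase, in fixed order."""

    components: tuple = _DEFAULT_COMPONENTS

    def __post_init__(self) -> None:
        if len(self.components) != N_COMPONENTS:
            raise ParameterError("exactly 10 first-phase components required")
        if any(c.molar_mass <= 0 for c in self.components):
            raise ParameterError("molar masses must be positive")

    @property
    def molar_masses(self) -> np.ndarray:
        return np.array([c.molar_mass for c in self.components])

    @property
    def diffusion(self) -> np.ndarray:
        return np.array([c.diffusion for c in self.components])

    @property
    def names(self) -> list:
        return [c.name for c in self.components]


# ---------------------------------------------------------------------------
# particle phases (j = 2..6)
# ---------------------------------------------------------------------------

@dataclass
class ParticleBin:
    j: int
    diameter: float          # m, representative ("medium") size
    density: float = 1040.0  # kg/m^3
    viscosity: float = 1.0   # Pa s (particle phases modelled as viscous fluid)
    dissolvable: bool = True


@dataclass
class PhaseRegistry:
    """Liquid phase plus the five fixed-diameter particle size classes.

    ``beta`` is the mass composition of a (carrot) food particle over the
    dissolvable components {protein, fat, carbohydrate, chemical, water};
    it is shared by all bins and sums to one.
    """

    bins: list = field(default_factory=lambda: [
        ParticleBin(2, 3.6e-3),
        ParticleBin(3, 2.8e-3),
        ParticleBin(4, 1.7e-3),
        ParticleBin(5, 0.7e-3),
        ParticleBin(6, 0.2e-3, dissolvable=False),
    ])
    beta: dict = field(default_factory=lambda: {
        PROTEIN: 0.013,
        FAT: 0.001,
        CARB: 0.093 - 0.28e-6,
        CHEMICAL: 0.28e-6,
        WATER: 0.893,
    })
    liquid_density: float = 1000.0   # kg/m^3
    liquid_viscosity: float = 1e-3   # Pa s (water)

    def __post_init__(self) -> None:
        d = self.diameters
        if not np.all(np.diff(d) < 0) or d[-1] <= 0:
            raise ParameterError("bin diameters must be strictly decreasing and positive")
        if abs(sum(self.beta.values()) - 1.0) > 1e-9:
            raise ParameterError("particle composition fractions must sum to 1")
        if self.bins[-1].dissolvable:
            raise ParameterError("the smallest size class is nondigestible")

    @property
    def diameters(self) -> np.ndarray:
        return np.array([b.diameter for b in self.bins])

    @property
    def densities(self) -> np.ndarray:
        return np.array([b.density for b in self.bins])

    @property
    def viscosities(self) -> np.ndarray:
        return np.array([b.viscosity for b in self.bins])

    @property
    def dissolvable(self) -> np.ndarray:
        return np.array([b.dissolvable for b in self.bins])

    def beta_array(self) -> np.ndarray:
        """Composition as a length-10 vector over all components."""
        out = np.zeros(N_COMPONENTS)
        for i, b in self.beta.items():
            out[i] = b
        return out

    def with_density(self, rho: float) -> "PhaseRegistry":
        bins = [dataclasses.replace(b, density=rho) for b in self.bins]
        return dataclasses.replace(self, bins=bins)


# ---------------------------------------------------------------------------
# secretion / absorption constants
# ---------------------------------------------------------------------------

@dataclass
class SecretionParams:
    """Gland output constants.

    Rates are total region outputs in kg/s (the numerators of the published
    per-volume constants); saturation ("limiting") constants are near-wall
    mass concentrations in kg/m^3.  ``water_*`` couplings are dimensionless
    mass-rate ratios fixing the water content of the secreted fluid.
    ``region_volumes`` maps wall region l -> wall-layer volume V(l) (m^3);
    left empty it is derived from the geometry by the solver.
    """

    acid_basal: float = 0.404e-7                      # s(0)(2)^0 * V(2)
    acid_stim: dict = field(default_factory=lambda: {  # s(0)(2)(i) * V(2)
        PROTEIN: 1.616e-7, FAT: 1.315e-7, CARB: 1.54e-7})
    acid_limit: float = 12.66                          # s(0)(2)' kg/m^3
    water_acid_ratio: float = 171.3                    # s(9)(2)

    pepsin_basal: float = 0.416e-8
    pepsin_stim: float = 1.664e-8
    pepsin_limit: float = 12.66

    bicarb_basal: dict = field(default_factory=lambda: {
        3: 1.75e-8, 4: 0.278e-8, 5: 1.972e-7})
    bicarb_stim: dict = field(default_factory=lambda: {
        3: 7.0e-8, 4: 1.112e-8, 5: 7.888e-7})
    bicarb_limit: dict = field(default_factory=lambda: {3: 0.5, 4: 0.5, 5: 0.5})
    water_bicarb_ratio: dict = field(default_factory=lambda: {
        3: 395.5, 4: 395.5, 5: 78.3})

    absorption_rate: dict = field(default_factory=lambda: {
        2: 3.34e-3, 3: 3.34e-3, 4: 3.34e-3, 5: 3.34e-3})  # s(6)(l), 1/s
    partition_h6: float = 1.0       # cavity/blood critical concentration ratio
    blood_conc: float = 0.0         # C(6)^b, kg/m^3

    region_volumes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        rates = [self.acid_basal, self.pepsin_basal, self.pepsin_stim,
                 *self.acid_stim.values(), *self.bicarb_basal.values(),
                 *self.bicarb_stim.values(), *self.absorption_rate.values()]
        if any(r < 0 for r in rates):
            raise ParameterError("secretion/absorption rate constants must be >= 0")
        if any(v <= 0 for v in self.region_volumes.values()):
            raise ParameterError("region volumes must be positive")


@dataclass
class ReactionParams:
    """Homogeneous chemistry and particle-dissolution constants."""

    k02: float = 1e4          # neutralization, m^3/(kmol s); near-instantaneous
    k37: float = 0.038        # proteolysis turnover, 1/s
    k37_lim: float = 1.4e-3   # proteolysis half-saturation, kmol/m^3
    a37: float = -5.786       # pepsin pH modifier: a*pH^2 + b*pH + c
    b37: float = 26.819
    c37: float = -4.857
    diss_a: float = 3.246     # dissolution pH law f(pH) = a * pH^b
    diss_b: float = -2.092
    k_phys: float = 2.72e-4   # kg/(m^2 s) at the reference gastric acidity

    def __post_init__(self) -> None:
        if self.k02 < 1e4:
            raise ParameterError("ion exchange is near-instantaneous: k02 >= 1e4")
        if self.a37 >= 0:
            raise ParameterError("pepsin pH modifier must be a downward parabola")


# ---------------------------------------------------------------------------
# scenarios and functionality
# ---------------------------------------------------------------------------

@dataclass
class Scenario:
    """One functional-disorder configuration.

    ``acid_functionality`` is F(2)(1); ``alkaline_functionality`` applies to
    l = 3..5; absorption F(l)(2) and motor F(l)(3) default to the undamaged
    value 1.  ``particle_density`` is shared by all size classes.
    """

    id: int
    acid_functionality: float = 1.0
    alkaline_functionality: float = 1.0
    absorption_functionality: float = 1.0
    motor_functionality: float = 1.0
    particle_density: float = 1040.0

    def __post_init__(self) -> None:
        for f in (self.acid_functionality, self.alkaline_functionality,
                  self.absorption_functionality, self.motor_functionality):
            if not 0.0 <= f <= 1.0:
                raise ParameterError("functionality values lie in [0, 1]")

    def functionality_map(self) -> "FunctionalityMap":
        fmap = {}
        for l in (2, 3, 4, 5):
            fmap[(l, 1)] = (self.acid_functionality if l == 2
                            else self.alkaline_functionality)
            fmap[(l, 2)] = self.absorption_functionality
            fmap[(l, 3)] = self.motor_functionality
        return FunctionalityMap(fmap)


@dataclass
class FunctionalityMap:
    """(l, m) -> F in [0,1]; l = 2..5 wall regions, m = 1 secretion,
    2 absorption, 3 motor.  F = 1 means no disorder."""

    values: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(not 0.0 <= v <= 1.0 for v in self.values.values()):
            raise ParameterError("functionality values lie in [0, 1]")

    def get(self, l: int, m: int) -> float:
        return self.values.get((l, m), 1.0)

    def motor_by_region(self) -> dict:
        return {l: self.get(l, 3) for l in (2, 3, 4, 5)}


SCENARIOS = {
    1: Scenario(1, 1.0, 1.0),
    2: Scenario(2, 0.5, 1.0),
    3: Scenario(3, 0.2, 1.0),
    4: Scenario(4, 1.0, 0.5),
    5: Scenario(5, 1.0, 0.2),
    6: Scenario(6, 1.0, 1.0, particle_density=1005.0),
}


def load_scenario(scenario_id: int) -> Scenario:
    """Return one of the six functional-disorder scenarios."""
    try:
        return SCENARIOS[int(scenario_id)]
    except (KeyError, ValueError, TypeError):
        raise ConfigError(
            f"unknown scenario {scenario_id!r}; valid ids are 1..6") from None


# ---------------------------------------------------------------------------
# unit-conversion derivations fixing the secretion constants
# ---------------------------------------------------------------------------

def derive_acid_mass_rate(molar_rate: float, molar_mass: float) -> float:
    """Convert a gland output in kmol/h to kg/s.

    The maximal gastric HCl output of 20 mmol/h corresponds to
    20e-6 kmol/h * 36.46 kg/kmol / 3600 s = 2.03e-7 kg/s.
    """
    if molar_rate <= 0 or molar_mass <= 0:
        raise ParameterError("molar rate and molar mass must be positive")
    return molar_rate * molar_mass / 3600.0


def derive_water_coupling(acid_mass_fraction: float) -> float:
    """Water:acid mass-rate ratio so acid makes up fraction ``w`` of the
    secreted fluid: (1 - w) / w.  w = 0.58% gives the 171 ratio of gastric
    juice."""
    if not 0.0 < acid_mass_fraction < 1.0:
        raise ParameterError("acid mass fraction must lie in (0, 1)")
    return (1.0 - acid_mass_fraction) / acid_mass_fraction


def derive_basal_rate(maximal_rate: float, factor: float) -> float:
    """Basal (resting) secretion as maximal / factor; gastric acid rests at
    about one fifth of its food-stimulated maximum."""
    if factor <= 0:
        raise ParameterError("reduction factor must be positive")
    return maximal_rate / factor


# ---------------------------------------------------------------------------
# numerics + top-level configuration
# ---------------------------------------------------------------------------

@dataclass
class NumericsConfig:
    """Finite-volume discretization controls."""

    dx: float = 2e-3            # m
    dt: float = 0.02            # s, base step (substepped under CFL)
    cfl: float = 0.9
    diffusion: bool = True
    clip_tol: float = 1e-6      # kg cumulative clipped mass before abort
    max_substeps: int = 200
    slip_max: float = 0.1       # m/s cap on sedimentation slip
    packing_limit: float = 0.62  # max total particle volume fraction for slip influx
    accommodation_tau: float = 8.0  # s, discharge time of stored wall-tone volume
    # axial dispersion closure for the cross-sectional recirculation the 1D
    # reduction cannot resolve (cm/s eddies over a cm-scale lumen)
    mixing_dispersion: float = 5e-5  # m^2/s

    def __post_init__(self) -> None:
        if not 0 < self.cfl <= 0.9:
            raise ParameterError("CFL number must lie in (0, 0.9]")


@dataclass
class Config:
    """Complete model configuration with the published defaults baked in."""

    components: ComponentRegistry = field(default_factory=ComponentRegistry)
    phases: PhaseRegistry = field(default_factory=PhaseRegistry)
    secretion: SecretionParams = field(default_factory=SecretionParams)
    reaction: ReactionParams = field(default_factory=ReactionParams)
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    antral_wave: WaveParams = field(default_factory=antral_wave_defaults)
    duodenal_wave: WaveParams = None  # type: ignore[assignment]
    gate: PyloricGate = None          # type: ignore[assignment]
    numerics: NumericsConfig = field(default_factory=NumericsConfig)

    def __post_init__(self) -> None:
        if self.duodenal_wave is None:
            self.duodenal_wave = duodenal_wave_defaults(self.geometry.pylorus_end)
        if self.gate is None:
            self.gate = PyloricGate(open_radius=self.geometry.pylorus_radius)

    # -- YAML round trip -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["components"]["components"] = list(d["components"]["components"])
        d["phases"]["beta"] = {int(k): float(v)
                               for k, v in d["phases"]["beta"].items()}
        return d

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "Config":
        def intkeys(m):
            return {int(k): v for k, v in m.items()}

        kw = {}
        if "components" in d:
            kw["components"] = ComponentRegistry(tuple(
                Component(**c) for c in d["components"]["components"]))
        if "phases" in d:
            p = d["phases"]
            kw["phases"] = PhaseRegistry(
                bins=[ParticleBin(**b) for b in p["bins"]],
                beta=intkeys(p["beta"]),
                liquid_density=p["liquid_density"],
                liquid_viscosity=p["liquid_viscosity"])
        if "secretion" in d:
            s = dict(d["secretion"])
            for key in ("acid_stim", "bicarb_basal", "bicarb_stim",
                        "bicarb_limit", "water_bicarb_ratio",
                        "absorption_rate", "region_volumes"):
                if key in s:
                    s[key] = intkeys(s[key])
            kw["secretion"] = SecretionParams(**s)
        if "reaction" in d:
            kw["reaction"] = ReactionParams(**d["reaction"])
        if "geometry" in d:
            kw["geometry"] = GeometryConfig(**d["geometry"])
        if "antral_wave" in d:
            kw["antral_wave"] = WaveParams(**d["antral_wave"])
        if d.get("duodenal_wave") is not None:
            kw["duodenal_wave"] = WaveParams(**d["duodenal_wave"])
        if d.get("gate") is not None:
            kw["gate"] = PyloricGate(**d["gate"])
        if "numerics" in d:
            kw["numerics"] = NumericsConfig(**d["numerics"])
        try:
            return cls(**kw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, source) -> "Config":
        if hasattr(source, "read"):
            text = source.read()
        else:
            with open(source) as fh:
                text = fh.read()
        d = yaml.safe_load(text)
        if not isinstance(d, dict):
            raise ConfigError("configuration file must be a YAML mapping")
        return cls.from_dict(d)
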