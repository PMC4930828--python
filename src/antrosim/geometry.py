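"""Quasi-1D geometry and motility of the antroduodenal tract.

The three-dimensional antrum/pylorus/duodenum lumen is reduced to a tube of
circular cross-section around the centerline arclength coordinate ``x`` in
``[0, L]``.  Peristalsis enters as travelling squared-sinusoid indentations of
the baseline radius profile ``R0(x)``; the pyloric sphincter is a periodic
binary gate between the gastric and duodenal segments.  Wall regions carry the
labels used for secretion/absorption sources:

====  =============================================
l     wall region
====  =============================================
2     upper antrum (acid and pepsin secreting)
3     lower antrum, adjacent to the gastric outlet
4     gastric outlet and proximal duodenum
5     central/distal duodenum (pancreatic inflow)
====  =============================================

Motor functionality ``F(l,3)`` in ``[0, 1]`` scales the local wave amplitude;
``F = 1`` is the undamaged tract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

G_STANDARD = 9.81  # m/s^2

REGION_NONE = 0
REGION_UPPER_ANTRUM = 2
REGION_LOWER_ANTRUM = 3
REGION_OUTLET_DUODENUM = 4
REGION_MID_DUODENUM = 5
WALL_REGIONS = (2, 3, 4, 5)


@dataclass
class WaveParams:
    """A family of travelling peristaltic contraction waves.

    A new wave is born at ``origin`` every ``period`` seconds, travels at
    ``speed`` (m/s) in ``direction`` (+1 distal) and persists for ``duration``
    seconds.  ``amplitude`` (m) is the maximal radial indentation, ``width``
    (m) the spatial support of the squared-sinusoid bump.  Contractions
    start shallow and deepen as they propagate: the indentation grows
    linearly over ``growth_time`` seconds after birth (antral contractions
    reach full depth around the mid-antrum) and decays over ``ramp`` seconds
    before death so the enclosed volume is continuous in time.
    """

    period: float = 18.0
    width: float = 0.02
    amplitude: float = 0.009
    speed: float = 0.0022
    duration: float = 38.0
    origin: float = 0.0
    direction: int = 1
    ramp: float = 2.0
    growth_time: float = 19.0

    def __post_init__(self) -> None:
        for name in ("period", "width", "amplitude", "speed", "duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"wave parameter {name!r} must be positive")


def antral_wave_defaults() -> WaveParams:
    """Antral wave: 18 s period, 0.02 m width, 0.009 m amplitude, 0.0022 m/s, 38 s."""
    return WaveParams()


def duodenal_wave_defaults(origin: float) -> WaveParams:
    """Duodenal wave: 9 s period, 0.04 m width, 0.0035 m amplitude, 0.005 m/s, 36 s."""
    return WaveParams(period=9.0, width=0.04, amplitude=0.0035, speed=0.005,
                      duration=36.0, origin=origin, growth_time=2.0)


@dataclass
class PyloricGate:
    """Periodic pyloric sphincter: open for ``open_duration`` s every ``period`` s.

    ``phase`` is the time within a cycle at which the gate opens; ``None``
    defers to the motility object, which synchronizes the opening with the
    arrival of the antral wave at the mid-antrum.
    """

    period: float = 18.0
    open_duration: float = 2.0
    open_radius: float = 0.004
    closed_radius: float = 0.0
    phase: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.open_duration < self.period:
            raise ValueError("gate open duration must lie in (0, period)")


@dataclass
class GeometryConfig:
    """Baseline dimensions of the reduced antroduodenal tract.

    The antrum is a bulge tapering from ``antrum_radius`` at the proximal
    (esophageal-side, closed) end down to ``pylorus_radius`` at the sphincter;
    the duodenum is a tube of radius ``duodenum_radius``.  ``*_gravity_cos``
    give the cosine of the angle between gravity and the +x centerline
    direction for an upright posture: negative in the antrum (the bulge is the
    lowest point, so dense material drifts toward x = 0).
    """

    antrum_length: float = 0.084
    pylorus_length: float = 0.008
    duodenum_length: float = 0.18
    antrum_radius: float = 0.035
    pylorus_radius: float = 0.004
    duodenum_radius: float = 0.010
    duodenum_taper: float = 0.010
    radius_floor: float = 0.002
    acid_region_fraction: float = 0.5
    proximal_duodenum_fraction: float = 0.3
    antrum_gravity_cos: float = -0.5
    duodenum_gravity_cos: float = 0.0
    wall_layer_fraction: float = 0.1
    # collapse all wall labels onto one region (degenerate configuration used
    # to compare the transport solver against the well-mixed reactor)
    region_override: int | None = None

    @property
    def total_length(self) -> float:
        return self.antrum_length + self.pylorus_length + self.duodenum_length

    @property
    def pylorus_start(self) -> float:
        return self.antrum_length

    @property
    def pylorus_end(self) -> float:
        return self.antrum_length + self.pylorus_length


@dataclass
class Grid:
    """Uniform finite-volume grid over the tract centerline."""

    x: np.ndarray            # cell centers, m
    dx: float
    region: np.ndarray       # wall-region label per cell
    gravity_cos: np.ndarray  # cosine of gravity vs +x per cell
    gate_interface: int      # interface index separating stomach from bowel

    @property
    def n_cells(self) -> int:
        return self.x.size

    @property
    def x_faces(self) -> np.ndarray:
        return np.concatenate(([self.x[0] - 0.5 * self.dx],
                               self.x + 0.5 * self.dx))

    def stomach_mask(self) -> np.ndarray:
        """Cells on the gastric side of the pyloric gate."""
        return np.arange(self.n_cells) < self.gate_interface


class TractGeometry:
    """Realized geometry: baseline radius, regions and gravity along ``x``."""

    def __init__(self, config: GeometryConfig | None = None,
                 table: pd.DataFrame | None = None) -> None:
        self.config = config or GeometryConfig()
        self._table = table  # optional (x, R0, region, gravity_cos) override

    # -- baseline profile ---------------------------------------------------

    def baseline_radius(self, x):
        """R0(x): antrum bulge -> pyloric constriction -> duodenal tube."""
        x = np.asarray(x, dtype=float)
        if self._table is not None:
            return np.interp(x, self._table["x"].values, self._table["R0"].values)
        c = self.config
        r = np.full(x.shape, c.pylorus_radius)
        ant = x < c.pylorus_start
        r[ant] = c.pylorus_radius + (c.antrum_radius - c.pylorus_radius) * np.cos(
            0.5 * np.pi * x[ant] / c.antrum_length) ** 2
        duo = x >= c.pylorus_end
        xi = x[duo] - c.pylorus_end
        taper = np.minimum(xi / max(c.duodenum_taper, 1e-12), 1.0)
        r[duo] = c.duodenum_radius + (c.pylorus_radius - c.duodenum_radius) * np.cos(
            0.5 * np.pi * taper) ** 2
        return r

    def region_label(self, x):
        x = np.asarray(x, dtype=float)
        if self._table is not None:
            idx = np.searchsorted(self._table["x"].values, x)
            idx = np.clip(idx, 0, len(self._table) - 1)
            return self._table["region"].values[idx].astype(int)
        c = self.config
        if c.region_override is not None:
            return np.full(x.shape, int(c.region_override), dtype=int)
        lab = np.full(x.shape, REGION_NONE, dtype=int)
        lab[x < c.antrum_length * c.acid_region_fraction] = REGION_UPPER_ANTRUM
        lower = (x >= c.antrum_length * c.acid_region_fraction) & (x < c.pylorus_start)
        lab[lower] = REGION_LOWER_ANTRUM
        prox_end = c.pylorus_end + c.proximal_duodenum_fraction * c.duodenum_length
        lab[(x >= c.pylorus_start) & (x < prox_end)] = REGION_OUTLET_DUODENUM
        lab[x >= prox_end] = REGION_MID_DUODENUM
        return lab

    def gravity_cosine(self, x):
        x = np.asarray(x, dtype=float)
        if self._table is not None:
            return np.interp(x, self._table["x"].values,
                             self._table["gravity_cos"].values)
        c = self.config
        g = np.full(x.shape, c.duodenum_gravity_cos)
        g[x < c.pylorus_start] = c.antrum_gravity_cos
        g[(x >= c.pylorus_start) & (x < c.pylorus_end)] = 0.0
        return g

    def is_pylorus(self, x):
        x = np.asarray(x, dtype=float)
        c = self.config
        return (x >= c.pylorus_start) & (x < c.pylorus_end)

    # -- grid ---------------------------------------------------------------

    def make_grid(self, dx: float) -> Grid:
        c = self.config
        n = int(round(c.total_length / dx))
        x = (np.arange(n) + 0.5) * dx
        gate_iface = int(round((c.pylorus_start + 0.5 * c.pylorus_length) / dx))
        return Grid(x=x, dx=dx, region=self.region_label(x),
                    gravity_cos=self.gravity_cosine(x), gate_interface=gate_iface)

    # -- plain-text geometry table ------------------------------------------

    def to_table(self, n: int = 200) -> pd.DataFrame:
        x = np.linspace(0.0, self.config.total_length, n)
        return pd.DataFrame({
            "x": x,
            "R0": self.baseline_radius(x),
            "region": self.region_label(x),
            "gravity_cos": self.gravity_cosine(x),
        })

    def save(self, path, n: int = 200) -> None:
        self.to_table(n).to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path, config: GeometryConfig | None = None) -> "TractGeometry":
        table = pd.read_csv(path, sep="\t")
        required = {"x", "R0", "region", "gravity_cos"}
        if not required.issubset(table.columns):
            raise ValueError(f"geometry table must have columns {sorted(required)}")
        return cls(config=config, table=table)


class Motility:
    """Wall motion: baseline geometry + waves + gate + motor functionality."""

    def __init__(self, geometry: TractGeometry,
                 antral_wave: WaveParams | None = None,
                 duodenal_wave: WaveParams | None = None,
                 gate: PyloricGate | None = None,
                 motor_functionality=None) -> None:
        self.geometry = geometry
        c = geometry.config
        self.antral_wave = antral_wave or antral_wave_defaults()
        self.duodenal_wave = duodenal_wave or duodenal_wave_defaults(c.pylorus_end)
        self.gate = gate or PyloricGate(open_radius=c.pylorus_radius)
        # F(l,3) per wall region; mapping l -> value in [0,1]
        self.motor_functionality = dict(motor_functionality or {})

    # -- gate ----------------------------------------------------------------

    @property
    def gate_phase(self) -> float:
        """Opening time within a cycle, synchronized with the antral wave
        reaching the mid-antrum."""
        if self.gate.phase is not None:
            return self.gate.phase
        c = self.geometry.config
        w = self.antral_wave
        arrival = (0.5 * c.antrum_length - w.origin) / w.speed
        return arrival % self.gate.period

    def gate_open(self, t) -> np.ndarray | bool:
        """True while the pyloric sphincter is open (2 s every 18 s by default)."""
        t = np.asarray(t, dtype=float)
        out = ((t - self.gate_phase) % self.gate.period) < self.gate.open_duration
        return bool(out) if out.ndim == 0 else out

    def next_gate_event(self, t: float) -> float:
        """Time of the next opening or closing transition strictly after ``t``."""
        tau = (t - self.gate_phase) % self.gate.period
        if tau < self.gate.open_duration:
            dt = self.gate.open_duration - tau
        else:
            dt = self.gate.period - tau
        return t + max(dt, 1e-12)

    # -- wall motion ---------------------------------------------------------

    def _motor_factor(self, region: np.ndarray) -> np.ndarray:
        f = np.ones(region.shape)
        for l, val in self.motor_functionality.items():
            f[region == l] = val
        return f

    def _wave_deviation(self, x: np.ndarray, t: float, wave: WaveParams,
                        x_min: float, x_max: float) -> np.ndarray:
        dev = np.zeros_like(x)
        if t < 0:
            return dev
        n_last = int(t // wave.period)
        for n in range(max(0, n_last - int(wave.duration // wave.period) - 1),
                       n_last + 1):
            age = t - n * wave.period
            if age < 0 or age > wave.duration:
                continue
            env = min(1.0, age / wave.growth_time, (wave.duration - age) / wave.ramp)
            xw = wave.origin + wave.direction * wave.speed * age
            arg = (x - xw) / wave.width
            support = (np.abs(arg) < 0.5) & (x >= x_min) & (x <= x_max)
            dev[support] += (wave.amplitude * env
                             * np.cos(np.pi * arg[support]) ** 2)
        return dev

    def radius(self, x, t: float) -> np.ndarray:
        """R(x, t): baseline minus superposed wave indentations, scaled by the
        motor functionality of the local wall region; the pylorus reflects the
        gate state."""
        scalar = np.ndim(x) == 0
        x = np.atleast_1d(np.asarray(x, dtype=float))
        c = self.geometry.config
        r0 = self.geometry.baseline_radius(x)
        dev = self._wave_deviation(x, t, self.antral_wave, 0.0, c.pylorus_start)
        dev += self._wave_deviation(x, t, self.duodenal_wave, c.pylorus_end,
                                    c.total_length)
        dev *= self._motor_factor(self.geometry.region_label(x))
        r = np.maximum(r0 - dev, c.radius_floor)
        pyl = self.geometry.is_pylorus(x)
        if np.any(pyl):
            r[pyl] = (self.gate.open_radius if self.gate_open(t)
                      else self.gate.closed_radius)
        return float(r[0]) if scalar else r

    # -- finite-volume geometry ----------------------------------------------

    def cell_radius(self, grid: Grid, t: float) -> np.ndarray:
        """Radius per cell as the FV solver sees it: the pyloric lumen keeps
        its open-gate radius (gating acts on interface fluxes, not volumes)."""
        x = grid.x
        c = self.geometry.config
        r0 = self.geometry.baseline_radius(x)
        dev = self._wave_deviation(x, t, self.antral_wave, 0.0, c.pylorus_start)
        dev += self._wave_deviation(x, t, self.duodenal_wave, c.pylorus_end,
                                    c.total_length)
        dev *= self._motor_factor(grid.region)
        r = np.maximum(r0 - dev, c.radius_floor)
        pyl = self.geometry.is_pylorus(x)
        r[pyl] = self.gate.open_radius
        return r

    def cell_volumes(self, grid: Grid, t: float, return_derivative: bool = False):
        """Cell volumes V = pi R(x,t)^2 dx and, optionally, their (central
        finite-difference) time derivatives."""
        r = self.cell_radius(grid, t)
        v = np.pi * r ** 2 * grid.dx
        if not return_derivative:
            return v
        eps = 1e-4
        vp = np.pi * self.cell_radius(grid, t + eps) ** 2 * grid.dx
        vm = np.pi * self.cell_radius(grid, max(t - eps, 0.0)) ** 2 * grid.dx
        dvdt = (vp - vm) / (eps + min(t, eps))
        return v, dvdt

    def face_areas(self, grid: Grid, t: float) -> np.ndarray:
        """Cross-section area at interior interfaces (arithmetic radius mean)."""
        r = self.cell_radius(grid, t)
        rf = np.empty(grid.n_cells + 1)
        rf[1:-1] = 0.5 * (r[:-1] + r[1:])
        rf[0], rf[-1] = r[0], r[-1]
        return np.pi * rf ** 2


# -- spec-level convenience wrappers -----------------------------------------

def radius(x, t: float, motility: Motility, motor_functionality=None) -> np.ndarray:
    """Functional form of :meth:`Motility.radius` with an explicit motor map."""
    if motor_functionality is not None:
        motility = Motility(motility.geometry, motility.antral_wave,
                            motility.duodenal_wave, motility.gate,
                            motor_functionality)
    return motility.radius(x, t)


def gate_open(t, motility: Motility):
    return motility.gate_open(t)


def cell_volumes(t: float, grid: Grid, motility: Motility,
                 return_derivative: bool = False):
    return motility.cell_volumes(grid, t, return_derivative=return_derivative)
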