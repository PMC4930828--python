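"""Time integration of the coupled digestion model.

Two integrators share one source-term implementation:

* :class:`BatchReactor` — a well-mixed (0D) reactor.  With secretion active it
  behaves as a CSTR: the secreted fluid volume displaces an equal volume of
  mixed content, which is exactly the limit of the 1D solver under spatially
  uniform forcing.  With sources off it is a closed box and conserves mass to
  round-off, which makes it the conservation/stoichiometry oracle.

* :class:`Solver1D` — a quasi-1D finite-volume solver on the moving-wall
  tract.  Per (sub)step: wall motion fixes the new cell volumes; the mixture
  velocity follows from 1D incompressibility (discrete telescoping of volume
  fluxes from the closed esophageal end, with the pyloric gate as an
  interface switch); phases advect first-order upwind with a drift-flux
  sedimentation slip; local sources (dissolution, cascade, proteolysis,
  secretion, absorption) are applied; the stiff acid-bicarbonate
  neutralization is integrated exactly (bimolecular closed form); solute
  diffusion closes the step.

The discrete volume ledger is exact by construction: interface volume fluxes
are solved so that every cell satisfies V^{n+1} = V^n + dt (F_in - F_out) + Q
with Q the source volume, hence volume fractions sum to one without
renormalization.  A closed antral compartment squeezed by a peristaltic wave
cannot satisfy the prescribed wall motion exactly in 1D; the prescribed
volumes are relaxed by a uniform factor (receptive-relaxation analogue) so
the compartment volume ledger closes, see docs/methods.md.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import interphase, kinetics, secretion as secretion_mod
from .geometry import G_STANDARD, Grid, Motility, TractGeometry, WALL_REGIONS
from .params import (BICARB, CARB, CHEMICAL, FAT, HCL, N_BINS, N_COMPONENTS,
                     PEPSIN, POLYPEPTIDE, PRODUCT, PROTEIN, WATER, Config,
                     Scenario)


class SolverAbort(RuntimeError):
    """Raised when clipped (non-physical) mass exceeds the tolerance."""


def _blank_ledger() -> dict:
    return {
        "secreted": np.zeros(N_COMPONENTS),
        "absorbed": 0.0,
        "evac_comp": np.zeros(N_COMPONENTS),
        "evac_bin": np.zeros(N_BINS),
        "gate_comp": np.zeros(N_COMPONENTS),
        "gate_bin": np.zeros(N_BINS),
        "clipped_abs": 0.0,
        "clipped_net": 0.0,
        "initial_mass": 0.0,
        # cumulative secreted/absorbed mass per wall region
        "by_region": {},
    }


def _accumulate_region_ledger(ledger: dict, by_region: dict, dt: float) -> None:
    for l, v in by_region.items():
        reg = ledger["by_region"].setdefault(l, {"secreted": 0.0,
                                                 "absorbed": 0.0})
        reg["secreted"] += dt * v["secreted"]
        reg["absorbed"] += dt * v["absorbed"]


@dataclass
class SimState:
    """Finite-volume state: per-cell component and size-class masses (kg)."""

    t: float
    V: np.ndarray          # (N,) cell volumes, m^3
    comp_mass: np.ndarray  # (N, 10) liquid-phase component masses
    bin_mass: np.ndarray   # (N, 5) particle masses per size class
    rho1: float
    bin_rho: np.ndarray    # (5,)
    ledger: dict = field(default_factory=_blank_ledger)

    def copy(self) -> "SimState":
        import copy as _copy
        return SimState(self.t, self.V.copy(), self.comp_mass.copy(),
                        self.bin_mass.copy(), self.rho1, self.bin_rho.copy(),
                        _copy.deepcopy(self.ledger))

    # -- derived fields ------------------------------------------------------

    @property
    def liquid_mass(self) -> np.ndarray:
        return self.comp_mass.sum(axis=-1)

    @property
    def alpha1(self) -> np.ndarray:
        return self.liquid_mass / self.rho1 / self.V

    @property
    def alpha_bins(self) -> np.ndarray:
        return self.bin_mass / self.bin_rho / self.V[..., None]

    @property
    def Y(self) -> np.ndarray:
        m = self.liquid_mass
        return self.comp_mass / np.where(m > 0, m, 1.0)[..., None]

    @property
    def total_mass(self) -> float:
        return float(self.comp_mass.sum() + self.bin_mass.sum())

    def concentration(self, i: int) -> np.ndarray:
        """Mass concentration rho1 alpha1 Y_i = m_i / V, kg/m^3."""
        return self.comp_mass[..., i] / self.V

    def pH(self, molar_mass_acid: float = 36.46) -> np.ndarray:
        return kinetics.ph(np.maximum(self.concentration(HCL), 0.0)
                           / molar_mass_acid)

    def mass_closure(self) -> float:
        """Relative residual of the global ledger: in-domain + evacuated +
        absorbed - secreted - clipped vs the initial load."""
        led = self.ledger
        total = (self.total_mass + led["evac_comp"].sum() + led["evac_bin"].sum()
                 + led["absorbed"] - led["secreted"].sum() - led["clipped_net"])
        return (total - led["initial_mass"]) / led["initial_mass"]


# ---------------------------------------------------------------------------
# shared source terms
# ---------------------------------------------------------------------------

class _SourceEngine:
    """Local (per-cell) source rates shared by the 0D and 1D integrators.

    ``region_weights`` maps wall region l -> (cells, deposit weights) where
    the weights distribute the total gland output of region l over its wall
    cells; near-wall mean concentrations are volume-weighted over the same
    cells.
    """

    def __init__(self, config: Config, scenario: Scenario,
                 region_weights: dict, region_volumes: dict) -> None:
        self.config = config
        self.scenario = scenario
        self.fmap = scenario.functionality_map()
        self.phases = config.phases.with_density(scenario.particle_density)
        self.registry = config.components
        self.M = self.registry.molar_masses
        self.region_weights = region_weights
        self.secretion = dataclasses.replace(
            config.secretion,
            region_volumes={**region_volumes,
                            **config.secretion.region_volumes})
        self.reaction = config.reaction
        self.beta = self.phases.beta_array()
        d = self.phases.diameters
        self.diam = d
        self.dissolvable = self.phases.dissolvable.astype(float)
        # cascade geometric factors between consecutive bins (kg/(m^3 s) per
        # unit k alpha); zero out of the last bin
        self.casc_geom = np.zeros(N_BINS)
        self.casc_geom[:-1] = 6.0 * d[1:] ** 3 / (d[:-1] * (d[:-1] ** 3 - d[1:] ** 3))
        self.casc_geom *= self.dissolvable
        self.diss_geom = 6.0 / d * self.dissolvable

    def rates(self, state: SimState, dt: float) -> dict:
        """Positivity-limited source rates (kg/s per cell) for a step ``dt``.

        Returns per-cell component and bin mass rates, the net source volume
        rate (m^3/s) and the ledger rates (secreted per component, absorbed).
        """
        V = state.V
        n = V.size
        rho1 = state.rho1
        dm_c = np.zeros((n, N_COMPONENTS))
        dm_b = np.zeros((n, N_BINS))
        secreted = np.zeros((n, N_COMPONENTS))
        pH = state.pH(self.M[HCL])

        # -- dissolution and size cascade (kg/s per cell/bin) ---------------
        k = interphase.dissolution_coefficient(
            np.maximum(pH, 1e-3), self.reaction.k_phys,
            self.reaction.diss_a, self.reaction.diss_b)
        alpha_b = state.alpha_bins
        diss = k[:, None] * self.diss_geom * alpha_b * V[:, None]   # to solution
        casc = k[:, None] * self.casc_geom * alpha_b * V[:, None]   # to next bin
        out_rate = diss + casc
        with np.errstate(divide="ignore", invalid="ignore"):
            limit = np.where(out_rate * dt > 0,
                             np.minimum(1.0, state.bin_mass / np.maximum(out_rate * dt, 1e-300)),
                             1.0)
        diss *= limit
        casc *= limit
        dm_b -= diss + casc
        dm_b[:, 1:] += casc[:, :-1]
        diss_total = diss.sum(axis=1)
        dm_c += diss_total[:, None] * self.beta

        # -- proteolysis -----------------------------------------------------
        Yc = np.clip(state.Y, 0.0, None)
        Yc /= np.maximum(Yc.sum(axis=-1), 1e-300)[:, None]
        mix = kinetics.MixtureState(np.clip(state.alpha1, 0.0, 1.0), rho1, Yc,
                                    self.registry)
        r3, r8 = kinetics.proteolysis_rates(mix, self.reaction)
        prot = -r3 * V  # kg/s consumed
        prot = np.minimum(prot, np.maximum(state.comp_mass[:, PROTEIN], 0.0) / dt)
        dm_c[:, PROTEIN] -= prot
        dm_c[:, POLYPEPTIDE] += prot

        # -- secretion (total gland outputs distributed over wall cells) ----
        conc_cell = state.comp_mass / V[:, None]  # rho1 alpha1 Y_i
        params = self.secretion
        for l, (cells, w) in self.region_weights.items():
            if cells.size == 0:
                continue
            v_l = params.region_volumes[l]
            mean_conc = state.comp_mass[cells].sum(axis=0) / V[cells].sum()
            if l == 2:
                F = self.fmap.get(2, 1)
                acid = secretion_mod.acid_secretion(
                    {i: mean_conc[i] for i in (PROTEIN, FAT, CARB)}, params, F)
                peps = secretion_mod.pepsin_secretion(mean_conc[PROTEIN], params, F)
                secreted[cells, HCL] += acid["acid"] * v_l * w
                secreted[cells, WATER] += acid["water"] * v_l * w
                secreted[cells, PEPSIN] += peps * v_l * w
            else:
                F = self.fmap.get(l, 1)
                bic = secretion_mod.bicarbonate_secretion(
                    max(mean_conc[HCL], 0.0), params, F, l)
                secreted[cells, BICARB] += bic["bicarb"] * v_l * w
                secreted[cells, WATER] += bic["water"] * v_l * w
        dm_c += secreted

        # -- absorption of chemicals (local, per cell) -----------------------
        absorbed = np.zeros(n)
        by_region = {}
        for l, (cells, _) in self.region_weights.items():
            F = self.fmap.get(l, 2)
            S = secretion_mod.absorption_flux(conc_cell[cells, CHEMICAL],
                                              params, F, l)
            rate = -S * V[cells]  # kg/s removed (S <= 0 when cavity > blood)
            rate = np.minimum(rate, np.maximum(state.comp_mass[cells, CHEMICAL], 0.0) / dt)
            dm_c[cells, CHEMICAL] -= rate
            absorbed[cells] = rate
            by_region[l] = {"secreted": float(secreted[cells].sum()),
                            "absorbed": float(rate.sum())}

        # -- net source volume (m^3/s per cell) ------------------------------
        q = (secreted.sum(axis=1) - absorbed) / rho1 \
            + diss_total * (1.0 / rho1 - 1.0 / self.phases.densities[0])
        return {"dm_comp": dm_c, "dm_bin": dm_b, "volume": q,
                "secreted": secreted, "absorbed": absorbed,
                "by_region": by_region}

    # -- stiff neutralization, exact bimolecular integration -----------------

    def neutralize(self, state: SimState, dt: float) -> None:
        """Advance NaHCO3 + HCl -> products by ``dt`` with the closed-form
        solution of the bimolecular rate law (the reaction is near
        instantaneous relative to transport, so explicit stepping would need
        sub-millisecond steps)."""
        M = self.M
        n0 = np.maximum(state.comp_mass[:, HCL], 0.0) / M[HCL]
        n2 = np.maximum(state.comp_mass[:, BICARB], 0.0) / M[BICARB]
        active = (n0 > 0) & (n2 > 0)
        if not np.any(active):
            return
        kappa = self.reaction.k02 / state.V[active]   # 1/(kmol s)
        a = np.maximum(n0[active], n2[active])
        b = np.minimum(n0[active], n2[active])
        delta = a - b
        arg = np.minimum(kappa * delta * dt, 700.0)
        with np.errstate(over="ignore"):
            b_new = np.where(
                delta > 1e-300 * np.maximum(a, 1.0),
                delta * b / np.maximum(a * np.exp(arg) - b, 1e-300),
                b / (1.0 + kappa * b * dt))
        x = np.maximum(b - b_new, 0.0)  # kmol consumed
        consumed = np.zeros(state.V.size)
        consumed[active] = x
        state.comp_mass[:, HCL] -= consumed * M[HCL]
        state.comp_mass[:, BICARB] -= consumed * M[BICARB]
        state.comp_mass[:, PRODUCT] += consumed * M[PRODUCT]
        state.comp_mass[:, WATER] += consumed * M[WATER]

    def clip(self, state: SimState, tol: float) -> None:
        """Zero out round-off negatives, moving the deficit to the ledger."""
        for arr in (state.comp_mass, state.bin_mass):
            neg = arr < 0
            if np.any(neg):
                deficit = -arr[neg].sum()
                state.ledger["clipped_abs"] += deficit
                state.ledger["clipped_net"] += deficit
                arr[neg] = 0.0
        if state.ledger["clipped_abs"] > tol:
            raise SolverAbort(
                f"cumulative clipped mass {state.ledger['clipped_abs']:.3e} kg "
                f"exceeds tolerance {tol:.1e}; the run is invalid")


# ---------------------------------------------------------------------------
# 0D batch / CSTR reactor
# ---------------------------------------------------------------------------

class BatchReactor:
    """Well-mixed reactor over a fixed volume.

    ``regions`` lists the wall regions whose glands feed the box (all four by
    default); their total outputs are the same as in 1D.  When secretion is
    active the secreted fluid volume leaves as mixed outflow (CSTR) so the
    box volume is constant; with ``regions=()`` the box is closed.
    """

    def __init__(self, config: Config, scenario: Scenario, volume: float,
                 regions=WALL_REGIONS, outflow: bool | None = None) -> None:
        self.config = config
        self.scenario = scenario
        self.volume = float(volume)
        # a box without wall sources is closed: no balancing outflow
        self.outflow = bool(regions) if outflow is None else outflow
        layer = config.geometry.wall_layer_fraction
        cells = np.array([0])
        weights = {l: (cells, np.array([1.0])) for l in regions}
        volumes = {l: layer * volume for l in regions}
        self.engine = _SourceEngine(config, scenario, weights, volumes)

    def initial_state(self, alpha_bins=None, Y=None) -> SimState:
        """Water-filled box, optionally loaded with particle fractions."""
        phases = self.engine.phases
        rho1 = phases.liquid_density
        a_b = np.zeros(N_BINS) if alpha_bins is None else np.asarray(alpha_bins, float)
        a1 = 1.0 - a_b.sum()
        comp = np.zeros((1, N_COMPONENTS))
        if Y is None:
            comp[0, WATER] = a1 * rho1 * self.volume
        else:
            comp[0] = np.asarray(Y, float) * a1 * rho1 * self.volume
        bins = (a_b * phases.densities * self.volume)[None, :]
        state = SimState(0.0, np.array([self.volume]), comp, bins, rho1,
                         phases.densities.copy())
        state.ledger["initial_mass"] = state.total_mass
        return state

    def step(self, state: SimState, dt: float) -> SimState:
        """Advance the reactor by ``dt`` (explicit, positivity-limited, with
        exact neutralization); returns the same state object."""
        rates = self.engine.rates(state, dt)
        # CSTR outflow of pre-step mixed content making room for the net
        # source volume the step is about to add (matching the transport
        # solver, whose outlet carries start-of-step composition); the box
        # volume is restored exactly once the sources land
        if self.outflow:
            content = (state.comp_mass.sum() / state.rho1
                       + (state.bin_mass / state.bin_rho).sum())
            frac = np.clip((content - self.volume
                            + rates["volume"].sum() * dt) / content, -0.5, 0.5)
            state.ledger["evac_comp"] += state.comp_mass[0] * frac
            state.ledger["evac_bin"] += state.bin_mass[0] * frac
            state.comp_mass *= (1.0 - frac)
            state.bin_mass *= (1.0 - frac)
        state.comp_mass += rates["dm_comp"] * dt
        state.bin_mass += rates["dm_bin"] * dt
        state.ledger["secreted"] += rates["secreted"].sum(axis=0) * dt
        state.ledger["absorbed"] += rates["absorbed"].sum() * dt
        _accumulate_region_ledger(state.ledger, rates["by_region"], dt)
        self.engine.neutralize(state, dt)
        self.engine.clip(state, self.config.numerics.clip_tol)
        state.t += dt
        return state


def step_batch(reactor: BatchReactor, state: SimState, dt: float) -> SimState:
    return reactor.step(state, dt)


# ---------------------------------------------------------------------------
# quasi-1D finite-volume solver
# ---------------------------------------------------------------------------

class Solver1D:
    """Finite-volume integrator of the reduced antroduodenal model."""

    def __init__(self, config: Config, scenario: Scenario,
                 geometry: TractGeometry | None = None) -> None:
        self.config = config
        self.scenario = scenario
        self.fmap = scenario.functionality_map()
        self.geometry = geometry or TractGeometry(config.geometry)
        self.motility = Motility(self.geometry, config.antral_wave,
                                 config.duodenal_wave, config.gate,
                                 self.fmap.motor_by_region())
        self.grid: Grid = self.geometry.make_grid(config.numerics.dx)
        self.phases = config.phases.with_density(scenario.particle_density)
        self.registry = config.components
        self.M = self.registry.molar_masses
        self.Kdiff = self.registry.diffusion

        # wall-layer region volumes and deposit weights (wall area ~ R0 dx)
        V0 = self.motility.cell_volumes(self.grid, 0.0)
        r0 = self.geometry.baseline_radius(self.grid.x)
        layer = config.geometry.wall_layer_fraction
        weights, volumes = {}, {}
        for l in WALL_REGIONS:
            cells = np.where(self.grid.region == l)[0]
            if cells.size:
                w = r0[cells] / r0[cells].sum()
                weights[l] = (cells, w)
                volumes[l] = layer * V0[cells].sum()
        self.engine = _SourceEngine(config, scenario, weights, volumes)
        # accommodation stretch of each compartment's prescribed volumes
        self.stretch_ant = 1.0
        self.stretch_duo = 1.0

    # -- states --------------------------------------------------------------

    def blank_state(self) -> SimState:
        """All-water domain at t = 0 (before any food fill is applied)."""
        V = self.motility.cell_volumes(self.grid, 0.0)
        rho1 = self.phases.liquid_density
        comp = np.zeros((self.grid.n_cells, N_COMPONENTS))
        comp[:, WATER] = rho1 * V
        bins = np.zeros((self.grid.n_cells, N_BINS))
        state = SimState(0.0, V, comp, bins, rho1, self.phases.densities.copy())
        state.ledger["initial_mass"] = state.total_mass
        return state

    # -- kinematics ----------------------------------------------------------

    def slip_velocities(self, state: SimState) -> np.ndarray:
        """Terminal drift-flux slip of each size class per cell, m/s."""
        num = self.config.numerics
        rho_mix = (state.comp_mass.sum(axis=1) + state.bin_mass.sum(axis=1)) / state.V
        g_axis = G_STANDARD * self.grid.gravity_cos
        return interphase.slip_velocity(
            state.alpha_bins, np.maximum(state.alpha1, 1e-6)[:, None],
            state.bin_rho[None, :], rho_mix[:, None], self.phases.diameters[None, :],
            self.phases.liquid_viscosity, state.rho1, g_axis[:, None],
            v_max=num.slip_max)

    def volume_fluxes(self, state: SimState, dt: float, q_rate: np.ndarray,
                      gate_is_open: bool):
        """Interface volume fluxes (m^3/s) satisfying the discrete volume
        ledger against the prescribed wall motion.

        Telescopes from the closed esophageal end.  A closed compartment
        cannot follow the prescribed wall motion exactly in 1D (incompressible
        content, no radial degree of freedom); each segment therefore carries
        a uniform *accommodation stretch* multiplying its prescribed volumes.
        While the gate is shut the gastric stretch absorbs the wave's
        displaced volume; while the compartment can drain it relaxes toward 1
        with time constant ``accommodation_tau``, releasing the stored volume
        as a smooth antral-pump discharge instead of an instantaneous snap.
        Relaxation is one-sided: an emptied compartment (stretch < 1) is not
        re-inflated.  The outlet is an open zero-gradient boundary: outflow
        leaves the domain and transient inflow re-entrains material at the
        boundary-cell composition (a dying peristaltic wave refills from the
        bowel side), with the evacuation ledger tracking the net flux.
        Returns ``(F, V_new, stretches)`` without mutating solver state; the
        caller commits the stretch factors.
        """
        grid = self.grid
        num = self.config.numerics
        V_old = state.V
        raw = self.motility.cell_volumes(grid, state.t + dt)
        Q = q_rate * dt
        n = grid.n_cells
        gi = grid.gate_interface
        F = np.zeros(n + 1)
        V_new = np.empty(n)
        decay = float(np.exp(-dt / num.accommodation_tau))

        def relax(stretch):
            return 1.0 + (stretch - 1.0) * decay if stretch > 1.0 else stretch

        if gate_is_open:
            s_ant = relax(self.stretch_ant)
            s_duo = relax(self.stretch_duo)
            tgt = raw.copy()
            tgt[:gi] *= s_ant
            tgt[gi:] *= s_duo
            F[1:] = -np.cumsum(tgt - V_old - Q) / dt
            V_new[:] = tgt
        else:
            # antrum: closed-closed; the stretch absorbs the wave volume
            s_ant = (V_old[:gi].sum() + Q[:gi].sum()) / raw[:gi].sum()
            V_new[:gi] = s_ant * raw[:gi]
            F[1:gi + 1] = -np.cumsum(V_new[:gi] - V_old[:gi] - Q[:gi]) / dt
            F[gi] = 0.0
            # duodenum: closed-left, open-right
            s_duo = relax(self.stretch_duo)
            V_new[gi:] = s_duo * raw[gi:]
            F[gi + 1:] = -np.cumsum(V_new[gi:] - V_old[gi:] - Q[gi:]) / dt
        return F, V_new, (s_ant, s_duo)

    def mixture_velocity(self, state: SimState, dt: float, gate_is_open=None):
        """Interface mixture velocities u = F/A for diagnostic use."""
        if gate_is_open is None:
            gate_is_open = bool(self.motility.gate_open(state.t))
        rates = self.engine.rates(state, dt)
        F, _, _ = self.volume_fluxes(state, dt, rates["volume"], gate_is_open)
        A = self.motility.face_areas(self.grid, state.t)
        return F / A

    # -- one integration step ------------------------------------------------

    def step(self, state: SimState, dt: float) -> SimState:
        """Advance by ``dt`` with CFL-driven substepping; substeps are aligned
        with pyloric gate transitions so the gate state is unambiguous."""
        num = self.config.numerics
        t_end = state.t + dt
        guard = 0
        while state.t < t_end - 1e-12:
            guard += 1
            if guard > max(num.max_substeps, 10 * int(dt / num.dt + 1)):
                raise SolverAbort("substep limit exceeded")
            dt_try = min(num.dt, t_end - state.t,
                         self.motility.next_gate_event(state.t) - state.t)
            self._substep(state, dt_try)
        return state

    def _substep(self, state: SimState, dt_try: float) -> None:
        num = self.config.numerics
        grid = self.grid
        n = grid.n_cells
        gate_is_open = bool(self.motility.gate_open(state.t + 0.5 * dt_try))

        rates = self.engine.rates(state, dt_try)
        v_slip = self.slip_velocities(state)
        A = self.motility.face_areas(grid, state.t)

        # CFL: shrink the step until the combined advective Courant number fits
        dt_sub = dt_try
        for _ in range(30):
            F, V_new, stretches = self.volume_fluxes(state, dt_sub,
                                                     rates["volume"],
                                                     gate_is_open)
            vmax = np.abs(v_slip).max() if v_slip.size else 0.0
            courant = (np.abs(F / A).max() + vmax) * dt_sub / grid.dx
            if courant <= num.cfl or dt_sub < 1e-6:
                break
            dt_sub = max(dt_sub * 0.85 * num.cfl / courant, 1e-7)
        dt = dt_sub
        self.stretch_ant, self.stretch_duo = stretches

        # -- upwind advection -------------------------------------------------
        alpha_b = state.alpha_bins
        alpha1 = state.alpha1
        Y = state.Y
        rho_b = state.bin_rho

        # drift-flux slip at interior faces, volume-mean removed so the total
        # volume flux at a face is exactly F
        vf = 0.5 * (v_slip[:-1] + v_slip[1:])                    # (n-1, 5)
        ab_face = 0.5 * (alpha_b[:-1] + alpha_b[1:])
        vd = vf - (ab_face * vf).sum(axis=1, keepdims=True)
        donor_s = np.where(vd > 0, np.arange(n - 1)[:, None],
                           np.arange(1, n)[:, None])
        G = np.zeros((n + 1, N_BINS))
        G[1:n] = A[1:n, None] * np.take_along_axis(alpha_b, donor_s, axis=0) * vd
        # no sedimentation flux into a packed cell, through the closed gate,
        # or across the domain ends
        recv = np.where(vd > 0, np.arange(1, n)[:, None],
                        np.arange(n - 1)[:, None])
        packed = alpha_b.sum(axis=1) >= num.packing_limit
        G[1:n][packed[recv]] = 0.0
        if not gate_is_open:
            G[grid.gate_interface] = 0.0
        G[0] = G[n] = 0.0
        G1 = -G.sum(axis=1)

        up = np.where(F >= 0, np.arange(-1, n), np.arange(0, n + 1))
        up = np.clip(up, 0, n - 1)
        bin_vol_flux = F[:, None] * alpha_b[up] + G
        liq_vol_flux = F * alpha1[up] + G1
        dl = np.where(liq_vol_flux >= 0, np.arange(-1, n), np.arange(0, n + 1))
        dl = np.clip(dl, 0, n - 1)
        comp_flux = liq_vol_flux[:, None] * state.rho1 * Y[dl]
        bin_flux = rho_b[None, :] * bin_vol_flux
        comp_flux[0] = 0.0
        bin_flux[0] = 0.0

        state.comp_mass -= dt * (comp_flux[1:] - comp_flux[:-1])
        state.bin_mass -= dt * (bin_flux[1:] - bin_flux[:-1])
        led = state.ledger
        led["evac_comp"] += dt * comp_flux[n]
        led["evac_bin"] += dt * bin_flux[n]
        led["gate_comp"] += dt * comp_flux[grid.gate_interface]
        led["gate_bin"] += dt * bin_flux[grid.gate_interface]

        # the advected masses are consistent with the new cell volumes from
        # here on; later stages must see those volumes
        state.V = V_new

        # -- sources, stiff chemistry, diffusion ------------------------------
        state.comp_mass += dt * rates["dm_comp"]
        state.bin_mass += dt * rates["dm_bin"]
        led["secreted"] += dt * rates["secreted"].sum(axis=0)
        led["absorbed"] += dt * rates["absorbed"].sum()
        _accumulate_region_ledger(led, rates["by_region"], dt)

        self.engine.neutralize(state, dt)

        if num.mixing_dispersion > 0:
            self._disperse(state, dt, A, gate_is_open)
        if num.diffusion:
            self._diffuse(state, dt, A, gate_is_open)

        self.engine.clip(state, num.clip_tol)
        state.t += dt

    def _disperse(self, state: SimState, dt: float, A: np.ndarray,
                  gate_is_open: bool) -> None:
        """Axial dispersion closure for the unresolved cross-sectional
        recirculation: adjacent cells exchange equal volumes down the
        gradients of the phase volume fractions and the liquid-borne
        concentrations, which is exactly volume-neutral because the
        fractions sum to one.  Substepped for explicit stability."""
        grid = self.grid
        num = self.config.numerics
        D = num.mixing_dispersion
        dt_stab = 0.4 * grid.dx ** 2 / D
        n_sub = max(1, int(np.ceil(dt / dt_stab)))
        h = dt / n_sub
        coef = D * A[1:-1] / grid.dx  # m^3/s exchange per unit gradient
        if not gate_is_open and 0 < grid.gate_interface < grid.n_cells:
            coef = coef.copy()
            coef[grid.gate_interface - 1] = 0.0
        rho_b = state.bin_rho
        for _ in range(n_sub):
            V = state.V
            conc = state.comp_mass / V[:, None]          # kg/m^3 of mixture
            alpha_b = state.bin_mass / rho_b / V[:, None]
            fc = -coef[:, None] * (conc[1:] - conc[:-1])
            fb = -coef[:, None] * rho_b * (alpha_b[1:] - alpha_b[:-1])
            state.comp_mass[:-1] -= h * fc
            state.comp_mass[1:] += h * fc
            state.bin_mass[:-1] -= h * fb
            state.bin_mass[1:] += h * fb

    def _diffuse(self, state: SimState, dt: float, A: np.ndarray,
                 gate_is_open: bool) -> None:
        """Explicit Fickian diffusion of the dissolved solutes relative to the
        solvent: water carries the compensating counter-flux so diffusion is
        exactly volume-neutral per cell (the liquid density is constant)."""
        grid = self.grid
        Y = state.Y
        a1f = 0.5 * (state.alpha1[:-1] + state.alpha1[1:])
        grad = (Y[1:, :9] - Y[:-1, :9]) / grid.dx
        flux = -A[1:-1, None] * a1f[:, None] * state.rho1 * self.Kdiff[None, :9] * grad
        if not gate_is_open and 0 < grid.gate_interface < grid.n_cells:
            flux[grid.gate_interface - 1] = 0.0
        full = np.zeros((grid.n_cells + 1, N_COMPONENTS))
        full[1:-1, :9] = flux
        full[1:-1, WATER] = -flux.sum(axis=1)
        state.comp_mass -= dt * (full[1:] - full[:-1])

    # -- scenario run ----------------------------------------------------------

    def run(self, state: SimState, T: float, output_dt: float = 3.0) -> "RunResult":
        """Integrate to ``t = T`` recording a diagnostic row every
        ``output_dt`` seconds (the initial state is row 0)."""
        if T < 0:
            raise ValueError("T must be nonnegative")
        rows = [self.diagnostics(state)]
        n_out = int(round(T / output_dt)) if T > 0 else 0
        for k in range(1, n_out + 1):
            self.step(state, min(k * output_dt, T) - state.t)
            rows.append(self.diagnostics(state))
        if state.t < T - 1e-9:
            self.step(state, T - state.t)
            rows.append(self.diagnostics(state))
        return RunResult(pd.DataFrame(rows), state, self)

    def diagnostics(self, state: SimState) -> dict:
        grid = self.grid
        stomach = grid.stomach_mask()
        bowel = ~stomach
        pH = state.pH(self.M[HCL])
        led = state.ledger
        row = {"time": state.t}
        for jj in range(N_BINS):
            j = jj + 2
            row[f"bin{j}_stomach_kg"] = state.bin_mass[stomach, jj].sum()
            row[f"bin{j}_bowel_kg"] = state.bin_mass[bowel, jj].sum()
            row[f"bin{j}_total_kg"] = state.bin_mass[:, jj].sum()
            row[f"gate_bin{j}_kg"] = led["gate_bin"][jj]
            row[f"evac_bin{j}_kg"] = led["evac_bin"][jj]
        for i in range(N_COMPONENTS):
            row[f"comp{i}_kg"] = state.comp_mass[:, i].sum()
        row["ph_stomach_min"] = pH[stomach].min()
        row["ph_stomach_mean"] = pH[stomach].mean()
        row["ph_bowel_min"] = pH[bowel].min()
        row["ph_bowel_mean"] = pH[bowel].mean()
        row["absorbed_kg"] = led["absorbed"]
        row["secreted_kg"] = led["secreted"].sum()
        for l in sorted(led["by_region"]):
            row[f"secreted_region{l}_kg"] = led["by_region"][l]["secreted"]
            row[f"absorbed_region{l}_kg"] = led["by_region"][l]["absorbed"]
        row["evacuated_kg"] = led["evac_comp"].sum() + led["evac_bin"].sum()
        row["clipped_kg"] = led["clipped_abs"]
        row["closure_residual"] = state.mass_closure()
        return row


def step_1d(solver: Solver1D, state: SimState, dt: float) -> SimState:
    return solver.step(state, dt)


@dataclass
class RunResult:
    """Time series plus final state of one scenario run."""

    timeseries: pd.DataFrame
    state: SimState
    solver: Solver1D

    def save_csv(self, path) -> None:
        self.timeseries.to_csv(path, index=False)

    def ph_profile(self) -> pd.DataFrame:
        """Final-time pH along the centerline."""
        s = self.state
        return pd.DataFrame({"x": self.solver.grid.x,
                             "pH": s.pH(self.solver.M[HCL])})

    def evacuated_bin_fraction(self, j: int) -> float:
        """Net gate-crossing mass of size class j over its initial load."""
        ts = self.timeseries
        initial = ts[f"bin{j}_total_kg"].iloc[0]
        if initial <= 0:
            return 0.0
        return float(self.state.ledger["gate_bin"][j - 2] / initial)
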