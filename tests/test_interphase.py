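"""Dissolution, size-bin cascade, drag and sedimentation slip."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from antrosim import (BatchReactor, Config, Scenario, bin_cascade_flux,
                      dissolution_coefficient, drag_coefficient_particle_liquid,
                      drag_coefficient_particle_particle,
                      particle_to_solution_flux, slip_velocity)
from antrosim.interphase import _drag_correction
from antrosim.params import PROTEIN, ReactionParams

RP = ReactionParams()


class TestDissolutionCoefficient:
    @pytest.mark.parametrize("pH, expected", [
        (1.0, 2.72e-4 * 3.246),            # pH^b = 1
        (2.0, 2.72e-4 * 3.246 * 2 ** -2.092),
        (7.5, 0.0),                        # alkaline clamp
    ])
    def test_power_law_and_clamp(self, pH, expected):
        k = dissolution_coefficient(pH, RP.k_phys, RP.diss_a, RP.diss_b)
        assert k == pytest.approx(expected, rel=1e-10)

    def test_reference_magnitudes(self):
        assert dissolution_coefficient(1.0, RP.k_phys, RP.diss_a, RP.diss_b) \
            == pytest.approx(8.83e-4, rel=1e-3)
        assert dissolution_coefficient(2.0, RP.k_phys, RP.diss_a, RP.diss_b) \
            == pytest.approx(2.071e-4, rel=1e-3)

    def test_near_unity_at_reference_acidity(self):
        """f(1.8) ~ 1: k_phys is the transfer coefficient at normal gastric pH."""
        f = RP.diss_a * 1.8 ** RP.diss_b
        assert f == pytest.approx(1.0, rel=0.06)


class TestParticleFluxes:
    def test_dissolution_flux_reference(self):
        k = 2.071e-4
        m = particle_to_solution_flux(0.088, 7e-4, k, 0.013)
        assert m == pytest.approx(2.03e-3, rel=2e-3)

    def test_zero_loading_zero_flux(self):
        assert particle_to_solution_flux(0.0, 7e-4, 1e-4, 0.013) == 0.0

    def test_nondigestible_bin_never_dissolves(self):
        m = particle_to_solution_flux(0.1, 2e-4, 1e-3, 0.5, dissolvable=False)
        assert m == 0.0

    def test_composition_partition_sums_to_total(self):
        """Summing the per-component fluxes over the particle composition
        recovers 6 k alpha / d exactly (the fractions sum to one)."""
        cfg = Config()
        beta = cfg.phases.beta_array()
        k, alpha, d = 2.071e-4, 0.088, 7e-4
        fluxes = particle_to_solution_flux(alpha, d, k, beta)
        assert fluxes.sum() == pytest.approx(6 * k * alpha / d, rel=1e-14)

    def test_cascade_flux_reference(self):
        m = bin_cascade_flux(0.088, 7e-4, 2e-4, 2.071e-4)
        assert m == pytest.approx(3.73e-3, rel=2e-3)

    def test_cascade_boundaries(self):
        assert bin_cascade_flux(0.0, 7e-4, 2e-4, 1e-4) == 0.0
        assert bin_cascade_flux(0.1, 7e-4, 2e-4, 1e-4, dissolvable=False) == 0.0
        with pytest.raises(ValueError):
            bin_cascade_flux(0.1, 2e-4, 7e-4, 1e-4)  # must shrink


class TestDrag:
    def test_stokes_reference_value(self):
        K = drag_coefficient_particle_liquid(0.1, 0.9, 1e-3, 1e-3,
                                             slip=0.0, rho_1=1000.0)
        assert K == pytest.approx(1620.0, rel=1e-12)

    def test_vanishes_without_particles(self):
        assert drag_coefficient_particle_liquid(0.0, 1.0, 1e-3, 1e-3,
                                                0.01, 1000.0) == 0.0

    @settings(derandomize=True, max_examples=100)
    @given(aj=st.floats(0.0, 0.5), aq=st.floats(0.0, 0.5),
           dj=st.floats(1e-4, 5e-3), dq=st.floats(1e-4, 5e-3),
           slip=st.floats(0.0, 0.1))
    def test_particle_particle_symmetry(self, aj, aq, dj, dq, slip):
        """K(j)(q) = K(q)(j): swapping the phases (including their volume
        fractions and diameters) leaves the interaction coefficient
        unchanged."""
        Kjq = drag_coefficient_particle_particle(aj, aq, 1.0, dj, dq, slip,
                                                 1040.0)
        Kqj = drag_coefficient_particle_particle(aq, aj, 1.0, dq, dj, slip,
                                                 1040.0)
        assert Kjq == pytest.approx(Kqj, rel=1e-12, abs=1e-300)


class TestSlipVelocity:
    ETA1, RHO1 = 1e-3, 1000.0

    def test_neutral_buoyancy_means_no_slip(self):
        v = slip_velocity(0.1, 0.9, 1040.0, 1040.0, 1e-3, self.ETA1,
                          self.RHO1, -4.9)
        assert v == 0.0

    def test_dense_particles_settle_toward_the_bulge(self):
        """Gravity pointing toward x = 0 (the gastric bulge) drives denser
        particles to negative slip: settling into the stomach's lowest part."""
        v = slip_velocity(0.1, 0.9, 1040.0, 1004.0, 1e-3, self.ETA1,
                          self.RHO1, -4.9)
        assert v < 0

    def test_lighter_particles_slip_less(self):
        common = dict(alpha_j=0.1, alpha_1=0.9, rho_mix=1000.0, d_j=1e-3,
                      eta_1=self.ETA1, rho_1=self.RHO1, g_axis=-4.9)
        v_dense = slip_velocity(rho_j=1040.0, **common)
        v_light = slip_velocity(rho_j=1005.0, **common)
        assert abs(v_light) < abs(v_dense)

    def test_fixed_point_matches_bisection_oracle(self, rng):
        """The damped fixed-point solve of the implicit terminal balance
        agrees with a brute-force bisection on the residual to 1e-8 m/s on
        random states."""
        for _ in range(20):
            rho_j = rng.uniform(1001.0, 1100.0)
            rho_mix = rng.uniform(995.0, rho_j)
            d = rng.uniform(1e-4, 4e-3)
            a1 = rng.uniform(0.4, 1.0)
            g = rng.uniform(-9.81, 9.81)
            v = slip_velocity(0.1, a1, rho_j, rho_mix, d, self.ETA1,
                              self.RHO1, g, tol=1e-12)

            def residual(u):
                Re = self.RHO1 * abs(u) * d / self.ETA1
                return (18 * a1 * self.ETA1 / d ** 2 * _drag_correction(Re) * u
                        - (rho_j - rho_mix) * g)

            lo, hi = -10.0, 10.0
            for _ in range(200):
                mid = 0.5 * (lo + hi)
                if residual(lo) * residual(mid) <= 0:
                    hi = mid
                else:
                    lo = mid
            assert v == pytest.approx(0.5 * (lo + hi), abs=1e-8)

    def test_velocity_cap_applies(self):
        v = slip_velocity(0.1, 1.0, 2000.0, 1000.0, 5e-3, self.ETA1,
                          self.RHO1, 9.81, v_max=0.05)
        assert abs(v) == pytest.approx(0.05)


class TestCascadeConservation:
    def test_closed_box_mass_conserved_over_1000_steps(self):
        """Dissolution plus the size cascade in an acidified closed box: the
        total of particle and dissolved mass is invariant."""
        cfg = Config()
        reactor = BatchReactor(cfg, Scenario(1), volume=1e-4, regions=())
        state = reactor.initial_state(
            alpha_bins=[0.044, 0.110, 0.344, 0.088, 0.014])
        # pre-acidify so dissolution is active (pH ~ 2)
        state.comp_mass[0, 0] = 0.01 * 36.46 * 0.4 * 1e-4
        state.comp_mass[0, 9] -= state.comp_mass[0, 0]
        state.ledger["initial_mass"] = state.total_mass
        m0 = state.total_mass
        for _ in range(1000):
            reactor.step(state, 0.05)
        assert state.total_mass == pytest.approx(m0, rel=1e-9)
        # mass actually moved between pools
        assert state.comp_mass[0, PROTEIN] > 0
        assert state.bin_mass[0, -1] > 0.014 * 1040 * 1e-4  # smallest bin grew
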