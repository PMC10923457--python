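"""RANS solver: closed-form operations, 1-D oracles, conservation."""

import math

import numpy as np
import pytest

import theatresmoke as ts
from theatresmoke.scene import Patch
from theatresmoke.solver import (GasProperties, SolverSettings,
                                 TurbulenceConstants, assemble_source,
                                 effective_viscosity, inlet_turbulence,
                                 mass_balance, production_Gk,
                                 solve_conv_diff_1d, wall_treatment,
                                 SolverFault)


class TestInletTurbulence:
    def test_published_inlet_values(self):
        k, eps = inlet_turbulence(0.096, 0.037, 0.07 * 2.4)
        assert k == pytest.approx(1.8925e-5, rel=1e-4)
        assert eps == pytest.approx(8.05e-8, rel=1e-3)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            inlet_turbulence(0.096, 0.0, 0.168)
        with pytest.raises(ValueError):
            inlet_turbulence(0.096, 0.037, 0.0)


class TestEffectiveViscosity:
    def test_laminar_limit(self):
        props, const = GasProperties(), TurbulenceConstants()
        mu_eff = effective_viscosity(np.array([1e-30]), np.array([1.0]), props, const)
        assert mu_eff[0] == pytest.approx(props.mu)

    def test_arithmetic_example(self):
        props = GasProperties(mu=0.0, pressure=101325.0)
        # rho = 1.2 via a tuned reference temperature
        props = GasProperties(mu=0.0, T_ref=props.pressure * props.molar_mass
                              / (8.314462618 * 1.2))
        const = TurbulenceConstants()
        mu_t = effective_viscosity(1e-4, 1e-6, props, const)
        assert mu_t == pytest.approx(1.08e-3, rel=1e-3)

    def test_quadratic_scaling_in_k(self):
        props, const = GasProperties(), TurbulenceConstants()
        a = effective_viscosity(1e-4, 1e-6, props, const) - props.mu
        b = effective_viscosity(2e-4, 1e-6, props, const) - props.mu
        assert b / a == pytest.approx(4.0)

    def test_nonpositive_dissipation_faults(self):
        with pytest.raises(SolverFault):
            effective_viscosity(np.array([1e-4]), np.array([0.0]),
                                GasProperties(), TurbulenceConstants())


class TestProductionGk:
    d = (0.1, 0.1, 0.1)

    def _grid(self):
        return np.zeros((8, 8, 8))

    def test_uniform_flow_zero_production(self):
        u = np.full((8, 8, 8), 1.3)
        g = production_Gk(u, u, u, self.d, mu_t=1.0)
        assert np.allclose(g, 0.0)

    def test_pure_shear_closed_form(self):
        S = 2.5
        z = (np.arange(8) + 0.5) * self.d[2]
        u = np.broadcast_to(S * z, (8, 8, 8)).copy()
        g = production_Gk(u, self._grid(), self._grid(), self.d, mu_t=3.0)
        assert np.allclose(g[:, :, 1:-1], 3.0 * S ** 2, rtol=1e-12)

    def test_rigid_rotation_zero_production(self):
        omega = 1.7
        x = (np.arange(8) + 0.5) * self.d[0]
        y = (np.arange(8) + 0.5) * self.d[1]
        u = np.broadcast_to(-omega * y[None, :, None], (8, 8, 8)).copy()
        v = np.broadcast_to(omega * x[:, None, None], (8, 8, 8)).copy()
        g = production_Gk(u, v, self._grid(), self.d, mu_t=1.0)
        assert np.allclose(g[1:-1, 1:-1], 0.0, atol=1e-12)


class TestWallTreatment:
    def test_zero_velocity_zero_shear(self):
        tau, _, _ = wall_treatment(0.0, 1e-4, 0.05, GasProperties(),
                                   TurbulenceConstants())
        assert tau == 0.0

    def test_log_linear_blend_continuity(self):
        """At y+ = 11.63 the linear and log laws agree within ~1%."""
        kappa, E = 0.41, 9.8
        yplus = 11.63
        u_log = math.log(E * yplus) / kappa
        assert u_log == pytest.approx(yplus, rel=0.01)

    def test_near_wall_dissipation_formula(self):
        const = TurbulenceConstants()
        k, y = 2e-4, 0.05
        _, _, eps = wall_treatment(0.1, k, y, GasProperties(), const)
        assert eps == pytest.approx(const.Cmu ** 0.75 * k ** 1.5 / (0.41 * y))


class TestAssembleSource:
    def test_mass_rate_from_stp_flow(self, coarse_mesh):
        spec = ts.make_source_spec(500.0)
        src = assemble_source(spec, coarse_mesh)
        rho_stp = 101325.0 * 0.02896 / (8.314462618 * 273.15)
        assert src.mdot == pytest.approx(rho_stp * 5.1532e-5, rel=1e-6)
        assert src.temperature == pytest.approx(773.15)
        assert src.cell == (20, 15, 4)

    def test_species_split_by_mass_fractions(self, coarse_mesh):
        spec = ts.make_source_spec(500.0)
        src = assemble_source(spec, coarse_mesh)
        total = sum(src.species_mass_fractions.values())
        assert 0 < total <= 1.0

    def test_source_in_solid_cell_rejected(self, coarse_mesh):
        spec = ts.make_source_spec(500.0, position=(4.0, 3.0, 0.5))  # inside table
        with pytest.raises(ValueError, match="solid"):
            assemble_source(spec, coarse_mesh)


class TestOneDimensionalOracles:
    @pytest.mark.parametrize("pe", [1.0, 5.0, 20.0])
    def test_advection_diffusion_matches_exponential_solution(self, pe):
        """The discrete operator reproduces the analytic Peclet profile
        phi = (exp(Pe x/L)-1)/(exp(Pe)-1) to < 1% L2 on a fine grid."""
        L, gamma = 1.0, 1.0e-2
        rho_u = pe * gamma / L
        n = 800
        x, phi = solve_conv_diff_1d(n, L, rho_u, gamma, 0.0, 1.0)
        exact = (np.exp(pe * x / L) - 1.0) / (np.exp(pe) - 1.0)
        err = np.linalg.norm(phi - exact) / np.linalg.norm(exact)
        assert err < 0.01

    def test_pure_diffusion_linear_profile(self):
        x, phi = solve_conv_diff_1d(50, 2.0, 0.0, 0.5, 10.0, 30.0)
        assert np.allclose(phi, 10.0 + 10.0 * x, rtol=1e-10)


class TestUnforcedRoom:
    """Zero-source, isothermal-exterior room: the pure ventilation flow."""

    def test_converges(self, unforced_isothermal_state):
        assert unforced_isothermal_state.converged

    def test_temperature_stays_ambient(self, unforced_isothermal_state):
        assert np.allclose(unforced_isothermal_state.T_celsius, 27.0, atol=1e-2)

    def test_species_identically_zero(self, unforced_isothermal_state):
        for f in unforced_isothermal_state.species.values():
            assert np.all(f == 0.0)

    def test_global_mass_balance(self, unforced_isothermal_state):
        bal = mass_balance(unforced_isothermal_state)
        assert bal["relative_imbalance"] < 1e-3

    def test_downflow_at_inlet(self, unforced_isothermal_state):
        st = unforced_isothermal_state
        mesh = st.mesh
        inlet_faces = mesh.fz[:, :, -1] == Patch.INLET
        assert (st.fluxes[2][:, :, -1][inlet_faces] < 0).all()

    def test_turbulence_fields_positive(self, unforced_isothermal_state):
        st = unforced_isothermal_state
        assert (st.k[st.mesh.fluid] > 0).all()
        assert (st.eps[st.mesh.fluid] > 0).all()


class TestDiffusionOnlyLimit:
    def test_conduction_between_robin_walls(self):
        """With convection frozen (no inlet flow solved; fluxes zero) the
        energy equation reduces to 1-D conduction between the two Robin
        side walls; the discrete profile must match the exact resistance-
        network solution to < 1%."""
        from theatresmoke.solver import RansSolver, BoundaryConditionSet

        mesh = ts.build_mesh(ts.TheatreScene(), (12, 10, 10))
        bc = BoundaryConditionSet(wall_exterior_temp=50.0)
        # huge pseudo_dt: no inertial damping, pure steady diffusion solve
        s = RansSolver(mesh, bc, None,
                       SolverSettings(tolerance=1e-10, max_iterations=1,
                                      pseudo_dt=1e9, relax_scalar=1.0))
        # zero all fluxes (quiescent gas), solve energy repeatedly
        s.Fx[:] = 0.0
        s.Fy[:] = 0.0
        s.Fz[:] = 0.0
        s.inlet_cells = {k: np.zeros(mesh.n, dtype=bool)
                         for k in s.inlet_cells}   # seal the inlet
        mu_t = np.zeros(mesh.n)
        for _ in range(600):
            s._energy(mu_t)
        # uniform equilibrium: both exteriors at 50 degC and no other sink
        assert np.allclose(s.T[mesh.fluid] - 273.15, 50.0, atol=0.5)


def test_settings_validation():
    with pytest.raises(ValueError):
        SolverSettings(relax_momentum=0.0)
    with pytest.raises(ValueError):
        SolverSettings(tolerance=-1.0)
    with pytest.raises(ValueError):
        SolverSettings(pseudo_dt=0.0)


def test_boundary_conditions_validation():
    with pytest.raises(ValueError):
        ts.BoundaryConditionSet(inlet_velocity=0.0)
    with pytest.raises(ValueError):
        ts.BoundaryConditionSet(turb_intensity=1.5)
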