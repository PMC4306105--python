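"""Flow solver: dimensionless-group utilities and verification oracles."""

import numpy as np
import pytest
from scipy.integrate import solve_bvp

from stentflow import (
    FluidProperties,
    InletSpec,
    SolverSettings,
    make_fixture,
    reynolds_number,
    solve_flow,
    velocity_for_reynolds,
)


class TestReynolds:
    def test_printed_constants(self, fluid):
        # rho v d / mu with the study constants
        assert reynolds_number(fluid, 0.22, 0.003) == pytest.approx(198.9, abs=0.05)

    @pytest.mark.parametrize("Re,v", [(200, 0.22), (400, 0.44),
                                      (600, 0.66), (800, 0.88)])
    def test_velocity_table(self, fluid, Re, v):
        assert velocity_for_reynolds(fluid, Re, 0.003) == pytest.approx(v, abs=5e-3)

    def test_zero_velocity(self, fluid):
        assert reynolds_number(fluid, 0.0, 0.003) == 0.0

    def test_linearity_and_roundtrip(self, fluid):
        r1 = reynolds_number(fluid, 0.1, 0.003)
        assert reynolds_number(fluid, 0.2, 0.003) == pytest.approx(2 * r1, rel=1e-14)
        v = velocity_for_reynolds(fluid, r1, 0.003)
        assert v == pytest.approx(0.1, rel=1e-14)

    def test_validation(self, fluid):
        with pytest.raises(ValueError):
            reynolds_number(fluid, 1.0, -1.0)
        with pytest.raises(ValueError):
            velocity_for_reynolds(fluid, -5.0, 0.003)
        with pytest.raises(ValueError):
            FluidProperties(rho=-1.0)
        with pytest.raises(ValueError):
            InletSpec(v_char=0.0)


class TestSettings:
    def test_relaxation_bounds(self):
        with pytest.raises(ValueError):
            SolverSettings(alpha_u=0.0)
        with pytest.raises(ValueError):
            SolverSettings(convection_scheme="quick")


class TestPoiseuilleOracle:
    def test_parabolic_profile(self, straight_case):
        geo, mesh, flow = straight_case
        i = np.searchsorted(mesh.s_c, 0.5 * mesh.s_faces[-1])
        jl = mesh.j_lumen
        n = mesh.n_c[jl]
        u = flow.u_cell[i, jl]
        a = geo.lumen_diameter / 2
        exact = 1.5 * 0.22 * (1 - (n / a) ** 2)
        err = np.linalg.norm(u - exact) / np.linalg.norm(exact)
        assert err < 0.01

    def test_centreline_is_1p5_mean(self, straight_case):
        geo, mesh, flow = straight_case
        i = np.searchsorted(mesh.s_c, 0.5 * mesh.s_faces[-1])
        jl = mesh.j_lumen
        u = flow.u_cell[i, jl]
        mean = (u * mesh.dn[jl]).sum() / mesh.dn[jl].sum()
        assert u.max() / mean == pytest.approx(1.5, rel=5e-3)

    def test_no_slip_in_solid(self, straight_case):
        _, mesh, flow = straight_case
        wall = mesh.region != 0
        assert np.all(flow.u_cell[wall] == 0.0)
        assert np.all(flow.v_cell[wall] == 0.0)


def curved_channel_exact(fluid, r_inner, r_outer, r_eval):
    """Fully developed azimuthal flow between concentric arcs, unit angular
    pressure gradient: integrate the exact radial ODE as a BVP."""
    def ode(r, y):   # y = [r*u, z] with z = (1/r) d(ru)/dr
        return np.vstack([r * y[1], -1.0 / (fluid.mu * r)])

    def bc(ya, yb):
        return np.array([ya[0], yb[0]])

    grid = np.linspace(r_inner, r_outer, 200)
    sol = solve_bvp(ode, bc, grid, np.zeros((2, grid.size)), tol=1e-10)
    assert sol.success
    return sol.sol(r_eval)[0] / r_eval


class TestCurvedChannelOracle:
    def test_fully_developed_bend_profile(self, bend_case, fluid):
        geo, mesh, flow = bend_case
        i = int(np.argmin(np.abs(mesh.s_c - 0.5 * sum(mesh.bend_span))))
        jl = mesh.j_lumen
        r = geo.bend_radius + mesh.n_c[jl]
        u = flow.u_cell[i, jl]
        oracle = curved_channel_exact(fluid, geo.bend_radius - geo.lumen_diameter / 2,
                                      geo.bend_radius + geo.lumen_diameter / 2, r)
        oracle *= (u * mesh.dn[jl]).sum() / (oracle * mesh.dn[jl]).sum()
        err = np.linalg.norm(u - oracle) / np.linalg.norm(oracle)
        assert err < 0.02


class TestConservation:
    def test_inlet_outlet_flux_match(self, straight_case, bend_case):
        for (_, mesh, flow) in (straight_case, bend_case):
            Fs, _ = flow.face_fluxes()
            q_in = Fs[0].sum()
            q_out = Fs[-1].sum()
            assert abs(q_out - q_in) / q_in < 1e-6

    def test_every_cross_section_carries_inlet_flux(self, bend_case):
        _, mesh, flow = bend_case
        Fs, _ = flow.face_fluxes()
        q = Fs.sum(axis=1)
        assert np.abs(q - q[0]).max() / q[0] < 1e-6

    def test_cellwise_mass_closure(self, stented_straight_case):
        _, mesh, flow, _ = stented_straight_case
        assert flow.continuity_error() < 1e-6


class TestGridConvergence:
    def test_refinement_differences_shrink(self, fluid):
        """L2 distance between successive refinements of the mid-bend
        profile decreases (solutions converge with the mesh)."""
        profiles = {}
        for res in (4, 8, 16):
            _, mesh = make_fixture("bare_bend", resolution=res)
            flow = solve_flow(mesh, fluid, InletSpec(v_char=0.05))
            i = int(np.argmin(np.abs(mesh.s_c - 0.5 * sum(mesh.bend_span))))
            jl = mesh.j_lumen
            profiles[res] = (mesh.n_c[jl], flow.u_cell[i, jl])

        def dist(coarse, fine):
            nc, uc = profiles[coarse]
            nf, uf = profiles[fine]
            ui = np.interp(nf, nc, uc)
            return np.linalg.norm(ui - uf) / np.linalg.norm(uf)

        assert dist(8, 16) < dist(4, 8)


class TestErrorsAndDeterminism:
    def test_turbulent_regime_rejected(self, fluid):
        _, mesh = make_fixture("straight_channel", resolution=5)
        with pytest.raises(ValueError, match="2000"):
            solve_flow(mesh, fluid, InletSpec(v_char=3.0))

    def test_nonconvergence_carries_history(self, fluid):
        from stentflow import NonConvergenceError
        _, mesh = make_fixture("straight_channel", resolution=5)
        with pytest.raises(NonConvergenceError) as exc:
            solve_flow(mesh, fluid, InletSpec(v_char=0.22),
                       SolverSettings(max_outer_iterations=8))
        assert len(exc.value.history) == 8

    def test_bit_identical_rerun(self, fluid):
        _, mesh = make_fixture("straight_channel", resolution=5)
        f1 = solve_flow(mesh, fluid, InletSpec(v_char=0.22))
        f2 = solve_flow(mesh, fluid, InletSpec(v_char=0.22))
        assert np.array_equal(f1.u, f2.u)
        assert np.array_equal(f1.p, f2.p)
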