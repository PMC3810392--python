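"""Laminar flow solver: closed-form gates, conservation and scaling laws."""

import numpy as np
import pytest

from rhinoflow import (AIR, FlowConfig, FluidProperties, PhantomSpec,
                       SetupError, box_phantom, build_mesh, cross_section,
                       reynolds_number, solve_flow)
from rhinoflow import deposition_analysis as da
from rhinoflow.flow_solver import average_speed, grid_independence


class TestReynoldsNumber:
    def test_rectangular_inlet_arithmetic(self):
        # 512 mL/min through a 2 mm x 3 mm duct
        q = 512e-6 / 60
        re, d_in = reynolds_number(q, 2e-3 * 3e-3,
                                   2 * (2e-3 + 3e-3),
                                   FluidProperties(1.184, 1.849e-5))
        assert d_in == pytest.approx(2.4e-3)
        assert re == pytest.approx(218.6, rel=1e-3)

    def test_linearity_in_flow_rate(self):
        re1, _ = reynolds_number(1e-6, 1e-6, 4e-3)
        re2, _ = reynolds_number(2e-6, 1e-6, 4e-3)
        assert re2 == pytest.approx(2 * re1, rel=1e-14)

    def test_default_phantom_is_laminar_at_paper_rates(self):
        mesh = build_mesh(PhantomSpec(), 50)
        for q_ml in (128.0, 256.0, 512.0):
            re, _ = reynolds_number(FlowConfig(q_ml_min=q_ml).q_m3_s,
                                    mesh.inlet_area, mesh.inlet_perimeter)
            assert re < 600


class TestSolveFlow:
    def test_zero_flow_is_trivial_and_immediate(self):
        mesh = build_mesh(box_phantom(5_000, 1_000), 100)
        sol = solve_flow(mesh, AIR, FlowConfig(q_ml_min=0.0))
        assert sol.converged and len(sol.residuals) == 1
        assert np.all(sol.u == 0) and np.all(sol.v == 0)
        assert np.ptp(sol.p) == 0

    def test_poiseuille_profile_and_pressure_drop(self, channel_case):
        c = channel_case
        sol, mesh = c["flow"], c["mesh"]
        assert sol.converged
        u_mean = c["config"].q_m3_s / (c["h"] * c["depth"])
        nx, ny = mesh.active.shape
        prof = sol.u[[mesh.cell_id[3 * nx // 4, j] for j in range(ny)]]
        assert prof.max() / u_mean == pytest.approx(1.5, rel=0.01)
        dp_ref = 12 * AIR.viscosity * u_mean * c["L"] / c["h"] ** 2
        assert sol.pressure_drop == pytest.approx(dp_ref, rel=0.02)
        assert average_speed(sol) == pytest.approx(u_mean, rel=0.01)

    def test_global_mass_conservation(self, channel_case):
        assert channel_case["flow"].mass_imbalance() < 1e-3

    def test_discrete_continuity_per_cell(self, channel_case):
        sol, mesh = channel_case["flow"], channel_case["mesh"]
        imb = np.zeros(mesh.n_cells)
        np.add.at(imb, mesh.int_owner, sol.q_int)
        np.add.at(imb, mesh.int_neigh, -sol.q_int)
        np.add.at(imb, mesh.b_owner, sol.q_b)
        assert np.abs(imb).max() < 1e-6 * sol.inlet_flux

    def test_stokes_linearity(self):
        mesh = build_mesh(box_phantom(10_000, 1_000), 100)
        a = solve_flow(mesh, AIR, FlowConfig(q_ml_min=0.5))
        b = solve_flow(mesh, AIR, FlowConfig(q_ml_min=0.25))
        scale = np.max(np.abs(a.u))
        assert np.max(np.abs(2 * b.u - a.u)) / scale < 0.005
        assert np.max(np.abs(2 * b.v - a.v)) / scale < 0.005

    def test_uniform_plug_average(self):
        # at the inlet face row the velocity is the prescribed plug
        mesh = build_mesh(box_phantom(10_000, 1_000), 100)
        sol = solve_flow(mesh, AIR, FlowConfig(q_ml_min=1.0))
        u_in = FlowConfig(q_ml_min=1.0).q_m3_s / mesh.inlet_area
        assert sol.inlet_flux == pytest.approx(u_in * mesh.inlet_area,
                                               rel=1e-12)

    def test_nonconvergence_returns_best_iterate(self):
        mesh = build_mesh(box_phantom(10_000, 1_000), 100)
        with pytest.warns(UserWarning, match="did not converge"):
            sol = solve_flow(mesh, AIR,
                             FlowConfig(q_ml_min=128.0, max_iterations=5))
        assert not sol.converged
        assert len(sol.residuals) == 5

    def test_no_outlet_is_setup_error(self):
        mesh = build_mesh(box_phantom(10_000, 1_000), 100)
        mesh.b_type[mesh.outlet_faces] = 1    # wall off the outlet
        with pytest.raises(SetupError):
            solve_flow(mesh, AIR, FlowConfig(q_ml_min=1.0))


class TestFlowSplit:
    def test_lubrication_conductance_ratio(self):
        # two long parallel slots, Stokes regime: Q ratio follows w^3
        spec = PhantomSpec(total_length=20_000, inlet_height=1_800,
                           dorsal_width=500, ventral_width=1_000,
                           fin_start=2_500, fin_end=17_500,
                           fin_thickness=300, squamous_end=2_500,
                           respiratory_end=5_000, olfactory_end=17_000,
                           depth=5_000)
        mesh = build_mesh(spec, 50)
        sol = solve_flow(mesh, AIR, FlowConfig(q_ml_min=0.5))
        frac = da.flow_fraction(sol, cross_section(mesh, 10e-3))
        lub = 100 * 0.5 ** 3 / (0.5 ** 3 + 1.0 ** 3)
        assert abs(frac - lub) < 2.0

    def test_symmetric_channels_split_evenly(self):
        spec = PhantomSpec(total_length=10_000, inlet_height=1_700,
                           dorsal_width=700, ventral_width=700,
                           fin_start=1_500, fin_end=8_500,
                           fin_thickness=300, squamous_end=1_500,
                           respiratory_end=2_500, olfactory_end=8_000,
                           depth=5_000)
        mesh = build_mesh(spec, 50)
        sol = solve_flow(mesh, AIR, FlowConfig(q_ml_min=64.0))
        frac = da.flow_fraction(sol, cross_section(mesh, 5e-3))
        assert abs(frac - 50.0) < 1.0


class TestGridIndependence:
    def test_poiseuille_converges_at_first_level(self):
        # tolerance set above the slowly-converging inlet-corner pressure
        # contribution; the developed-flow quantities agree at every level
        spec = box_phantom(30_000, 1_000)
        table, level = grid_independence(spec, 1000 / 16, AIR,
                                         FlowConfig(q_ml_min=1.0),
                                         levels=(1, 2, 3), tol_percent=2.0,
                                         x_cell_um=500.0)
        u_mean = FlowConfig(q_ml_min=1.0).q_m3_s / (1e-3 * 5e-3)
        assert np.allclose(table["average_velocity_m_s"], u_mean, rtol=0.01)
        assert level == 1

    def test_degenerate_tolerance_declares_coarsest(self):
        spec = box_phantom(10_000, 1_000)
        table, level = grid_independence(spec, 1000 / 8, AIR,
                                         FlowConfig(q_ml_min=1.0),
                                         levels=(1, 2, 3), tol_percent=100.0)
        assert level == 1

    def test_needs_three_levels(self):
        with pytest.raises(ValueError):
            grid_independence(box_phantom(10_000, 1_000), 125, AIR,
                              FlowConfig(q_ml_min=1.0), levels=(1, 2))
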