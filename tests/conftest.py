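"""Shared fixtures: session-scoped solves reused across test modules."""

import numpy as np
import pytest

from rhinoflow import (AIR, FlowConfig, MucusModel, PhantomSpec, StudyConfig,
                       box_phantom, build_mesh, get_odorant, run_paired_study,
                       solve_flow, solve_odorant)
from rhinoflow import deposition_analysis as da

from oracles import marching_uptake


@pytest.fixture(scope="session")
def channel_case():
    """Plane Poiseuille channel: 1 mm gap x 30 mm, 32 cells across, Stokes
    regime (development length negligible next to the channel length)."""
    spec = box_phantom(30_000, 1_000, depth_um=10_000)
    mesh = build_mesh(spec, 1000 / 32, x_cell_um=250)
    cfg = FlowConfig(q_ml_min=1.0)
    sol = solve_flow(mesh, AIR, cfg)
    return {"spec": spec, "mesh": mesh, "config": cfg, "flow": sol,
            "h": 1e-3, "L": 30e-3, "depth": 1e-2}


@pytest.fixture(scope="session")
def robin_channel_cases():
    """Uptake in a mucus-walled channel with a 5 mm zero-flux entrance zone,
    for all three odorants at all three inspiratory flow rates, paired with
    the parabolized marching oracle at 4x cross-channel resolution."""
    h, depth, L = 1e-3, 1e-2, 30e-3
    x_abs = 5e-3
    spec = box_phantom(30_000, 1_000, depth_um=10_000,
                       squamous_end_um=5_000)
    mesh = build_mesh(spec, 1000 / 32, x_cell_um=250)
    mucus = MucusModel()
    cases = {}
    for q in (128.0, 256.0, 512.0):
        cfg = FlowConfig(q_ml_min=q)
        sol = solve_flow(mesh, AIR, cfg)
        u_mean = cfg.q_m3_s / (h * depth)
        for name in ("carvone", "amyl_acetate", "octane"):
            od = get_odorant(name)
            conc = solve_odorant(mesh, sol, od, mucus)
            flux = da.wall_flux(conc)
            uptake = da.total_deposition(flux, "whole") / (1.0 * cfg.q_m3_s)
            oracle = marching_uptake(h, L - x_abs, u_mean,
                                     od.diffusivity_air, mucus.k_m(od),
                                     ny=32 * 4)
            cases[(q, name)] = {"flow": sol, "conc": conc, "flux": flux,
                                "uptake": uptake, "oracle": oracle}
    return cases


@pytest.fixture(scope="session")
def default_study(tmp_path_factory):
    """The full paired narrow-vs-widened study at the default configuration
    (delta = 34 µm, three flow rates, three odorants, grid levels 1/2/3)."""
    out = tmp_path_factory.mktemp("study")
    return run_paired_study(StudyConfig(), out_dir=out)


@pytest.fixture(scope="session")
def small_study_config():
    """A short phantom for smoke/reproducibility runs of the study driver."""
    spec = PhantomSpec(total_length=6_000, inlet_height=2_000,
                       dorsal_width=560, ventral_width=1_160,
                       fin_start=1_500, fin_end=5_500, fin_thickness=280,
                       squamous_end=1_500, respiratory_end=2_500,
                       olfactory_end=5_300, slice_thickness=200,
                       pixel_spacing=50, depth=3_000)
    return StudyConfig(spec=spec, delta_um=0.0, flow_rates_ml_min=(128.0,),
                       odorants=("octane",), target_cell_um=70.0,
                       grid_levels=(1, 2, 3), render_flux_maps=True)
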