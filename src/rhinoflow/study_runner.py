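"""Orchestrate the paired narrow-vs-widened airway study.

One call runs the whole comparative experiment on the synthetic phantom:
generate the narrow and uniformly widened geometries, mesh both at matched
resolution, solve the flow at every configured inspiratory flow rate, solve
odorant transport for every configured odorant, and reduce everything to the
comparison tables (flow-split table, regional deposition table, average-
velocity/percentage-difference table), per-case odorant mass-balance checks,
a grid-independence table, wall flux maps and a machine-readable summary.

The pipeline is fully deterministic: re-running with the same configuration
byte-reproduces every CSV.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import airway_geometry as ag
from . import deposition_analysis as da
from .flow_solver import (AIR, FlowConfig, FlowSolution, FluidProperties,
                          grid_independence, reynolds_number, solve_flow)
from .meshing import Mesh, build_mesh, cross_section
from .odorant_transport import (MucusModel, TransportConfig, get_odorant,
                                solve_odorant)

__all__ = ["StudyConfig", "StudyResult", "run_paired_study",
           "render_flux_map"]

log = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"


@dataclass
class StudyConfig:
    """Full configuration of the paired study (lengths in µm)."""

    spec: ag.PhantomSpec = field(default_factory=ag.PhantomSpec)
    delta_um: float = 34.0
    widening_mode: str = "total-width"
    flow_rates_ml_min: tuple = (128.0, 256.0, 512.0)
    odorants: tuple = ("carvone", "amyl_acetate", "octane")
    mucus_um: float = 30.0
    inlet_concentration: float = 1.0
    target_cell_um: float = 50.0
    wall_layers: int = 0
    growth_ratio: float = 1.2
    grid_levels: tuple = (1, 2, 3)
    flow_tolerance: float = 1e-4
    transport_tolerance: float = 1e-6
    max_flow_iterations: int = 5000
    widen_upsample: int = 8
    dorsal_section_um: float | None = None   # default: mid-respiratory zone
    oe_section_um: float | None = None       # default: mid-olfactory zone
    render_flux_maps: bool = True
    use_cache: bool = True
    log_level: str = "INFO"

    def __post_init__(self):
        if not self.flow_rates_ml_min or not self.odorants:
            raise ValueError("need at least one flow rate and one odorant")
        if self.delta_um < 0:
            raise ValueError("delta must be >= 0")
        if self.dorsal_section_um is None:
            self.dorsal_section_um = 0.5 * (self.spec.squamous_end
                                            + self.spec.respiratory_end)
        if self.oe_section_um is None:
            self.oe_section_um = 0.5 * (self.spec.olfactory_start
                                        + min(self.spec.fin_end,
                                              self.spec.total_length))

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        spec = ag.PhantomSpec(**raw.pop("spec", {}))
        for key in ("flow_rates_ml_min", "odorants", "grid_levels"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(spec=spec, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["spec"] = self.spec.to_dict()
        return d


@dataclass
class StudyResult:
    """In-memory bundle mirroring the files written to the output directory."""

    config: StudyConfig
    reports: dict                 # (model, Q, odorant) -> RegionReport
    comparisons: dict             # (Q, odorant) -> ComparisonReport
    flow_fraction_table: pd.DataFrame
    deposition_table: pd.DataFrame
    velocity_table: pd.DataFrame
    mass_balance_table: pd.DataFrame
    grid_table: pd.DataFrame
    grid_converged_level: int | None
    geometry_table: pd.DataFrame
    summary: dict
    out_dir: Path | None

    @property
    def all_converged(self) -> bool:
        return all(r.converged for r in self.reports.values())


def _case_label(model: str, q: float, odorant: str) -> str:
    return f"{model}_q{q:g}_{odorant}"


def run_paired_study(config: StudyConfig, out_dir=None) -> StudyResult:
    """Run the full paired experiment; write the report bundle if ``out_dir``.

    Any stage error is re-raised annotated with the case label (model, flow
    rate, odorant).  Cached flow fields under ``out_dir/cache`` make the
    default 18-case study re-entrant.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(out_dir) if out_dir is not None else None
    cache = None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        if config.use_cache:
            cache = out / "cache"
            cache.mkdir(exist_ok=True)

    narrow_spec = config.spec
    wide_spec = narrow_spec.widened(config.delta_um, config.widening_mode)
    specs = {"narrow": narrow_spec, "wide": wide_spec}

    geometry_table = _geometry_metrics(config, specs)

    # matched per-interval y cell counts (taken from the narrow geometry) so
    # paired discretization errors cancel in the narrow-vs-wide differences
    y_counts = None
    if config.wall_layers == 0 and narrow_spec.has_fin:
        y_counts = tuple(max(int(round(w / config.target_cell_um)), 1)
                         for w in (narrow_spec.ventral_width,
                                   narrow_spec.fin_thickness,
                                   narrow_spec.dorsal_width))
    meshes = {m: build_mesh(s, config.target_cell_um,
                            wall_layers=config.wall_layers,
                            growth_ratio=config.growth_ratio,
                            y_counts=y_counts)
              for m, s in specs.items()}
    sections = {m: {
        "dorsal": cross_section(meshes[m], config.dorsal_section_um * ag.UM),
        "oe": cross_section(meshes[m], config.oe_section_um * ag.UM),
    } for m in meshes}

    mucus = MucusModel(config.mucus_um * 1e-6)
    tconf = TransportConfig(tolerance=config.transport_tolerance,
                            inlet_concentration=config.inlet_concentration)

    reports, comparisons, flux_fields = {}, {}, {}
    q_max = max(config.flow_rates_ml_min)
    for q in config.flow_rates_ml_min:
        fconf = FlowConfig(q_ml_min=q, tolerance=config.flow_tolerance,
                           max_iterations=config.max_flow_iterations)
        flows = {}
        for model, mesh in meshes.items():
            try:
                flows[model] = _solve_flow_cached(mesh, fconf, cache,
                                                  f"{model}_q{q:g}")
            except Exception as err:
                raise RuntimeError(
                    f"flow stage failed for case ({model}, {q} mL/min)"
                ) from err
        for od_name in config.odorants:
            odorant = get_odorant(od_name)
            for model, mesh in meshes.items():
                label = _case_label(model, q, od_name)
                try:
                    conc = solve_odorant(mesh, flows[model], odorant, mucus,
                                         tconf)
                    flux = da.wall_flux(conc)
                    reports[(model, q, od_name)] = da.region_report(
                        model, flows[model], conc, flux, sections[model])
                    flux_fields[(model, q, od_name)] = flux
                except Exception as err:
                    raise RuntimeError(
                        f"transport stage failed for case {label}") from err
            comparisons[(q, od_name)] = da.compare_models(
                reports[("narrow", q, od_name)],
                reports[("wide", q, od_name)])

    grid_table, grid_level = grid_independence(
        narrow_spec, config.target_cell_um,
        AIR, FlowConfig(q_ml_min=config.flow_rates_ml_min[0],
                        tolerance=config.flow_tolerance,
                        max_iterations=config.max_flow_iterations),
        levels=config.grid_levels, wall_layers=config.wall_layers,
        growth_ratio=config.growth_ratio)

    tables = _build_tables(config, meshes, reports, comparisons)
    summary = _summary(config, meshes, reports, comparisons, grid_table,
                       grid_level)
    result = StudyResult(config, reports, comparisons, *tables,
                         grid_table, grid_level, geometry_table, summary, out)
    if out is not None:
        _write_bundle(result, flux_fields, q_max)
    return result


def _geometry_metrics(config: StudyConfig, specs: dict) -> pd.DataFrame:
    """Airway metrics of the narrow stack and its image-widened counterpart
    (the stack-based analog of the model-geometry table), plus the widened
    spec rasterized directly for cross-checking."""
    rows = []
    narrow_stack = ag.generate_phantom(specs["narrow"])
    m = ag.airway_metrics(narrow_stack)
    rows.append({"model": "narrow", "source": "stack",
                 "volume_m3": m["volume_m3"], "surface_m2": m["surface_m2"]})
    if config.delta_um > 0:
        widened_stack = ag.widen_airway(narrow_stack, config.delta_um,
                                        config.widening_mode,
                                        config.widen_upsample)
        m = ag.airway_metrics(widened_stack)
        rows.append({"model": "wide", "source": "stack_widened",
                     "volume_m3": m["volume_m3"],
                     "surface_m2": m["surface_m2"]})
    m = ag.airway_metrics(ag.generate_phantom(specs["wide"]))
    rows.append({"model": "wide", "source": "stack_from_widened_spec",
                 "volume_m3": m["volume_m3"], "surface_m2": m["surface_m2"]})
    return pd.DataFrame(rows)


def _solve_flow_cached(mesh: Mesh, fconf: FlowConfig, cache: Path | None,
                       label: str) -> FlowSolution:
    path = cache / f"flow_{label}.npz" if cache is not None else None
    if path is not None and path.exists():
        with np.load(path) as z:
            if z["n_cells"] == mesh.n_cells:
                res = pd.DataFrame({"u": z["res_u"], "v": z["res_v"],
                                    "continuity": z["res_c"]})
                res.index = pd.RangeIndex(1, len(res) + 1, name="iteration")
                return FlowSolution(mesh, z["u"], z["v"], z["p"], z["q_int"],
                                    z["q_b"], float(z["pressure_drop"]),
                                    res, bool(z["converged"]), fconf, AIR)
    sol = solve_flow(mesh, AIR, fconf)
    if path is not None:
        np.savez_compressed(path, n_cells=mesh.n_cells, u=sol.u, v=sol.v,
                            p=sol.p, q_int=sol.q_int, q_b=sol.q_b,
                            pressure_drop=sol.pressure_drop,
                            converged=sol.converged,
                            res_u=sol.residuals["u"].to_numpy(),
                            res_v=sol.residuals["v"].to_numpy(),
                            res_c=sol.residuals["continuity"].to_numpy())
    return sol


def _build_tables(config, meshes, reports, comparisons):
    frac_rows, dep_rows, vel_rows, mb_rows = [], [], [], []
    od0 = config.odorants[0]
    for q in config.flow_rates_ml_min:
        for model in meshes:
            rep = reports[(model, q, od0)]
            for sec_name, frac in rep.flow_fractions.items():
                frac_rows.append({"section": sec_name, "model": model,
                                  "q_ml_min": q, "dorsal_flow_pct": frac})
        for od in config.odorants:
            for model in meshes:
                rep = reports[(model, q, od)]
                for region in da.REGIONS:
                    dep_rows.append({
                        "odorant": od, "model": model, "q_ml_min": q,
                        "region": region,
                        "deposition_kg_s": rep.deposition[region],
                        "uptake_fraction": rep.uptake_fraction[region],
                        "wall_area_m2": rep.wall_area[region]})
                mb_rows.append({"odorant": od, "model": model, "q_ml_min": q,
                                "mass_closure_rel": rep.mass_closure,
                                "converged": rep.converged})
        comp = comparisons[(q, od0)]
        for region_key in ("whole", "oe"):
            vel_rows.append({
                "q_ml_min": q, "region": region_key,
                "narrow_m_s": comp.narrow.average_velocity[region_key],
                "wide_m_s": comp.wide.average_velocity[region_key],
                "diff_pct": comp.velocity_diff_pct.get(region_key, np.nan)})
    return (pd.DataFrame(frac_rows), pd.DataFrame(dep_rows),
            pd.DataFrame(vel_rows), pd.DataFrame(mb_rows))


def _summary(config, meshes, reports, comparisons, grid_table, grid_level):
    q_list = list(config.flow_rates_ml_min)
    mesh_n = meshes["narrow"]
    re_in, d_in = reynolds_number(FlowConfig(q_ml_min=max(q_list)).q_m3_s,
                                  mesh_n.inlet_area, mesh_n.inlet_perimeter)
    headline = {
        "inlet_concentration_kg_m3": config.inlet_concentration,
        "delta_um": config.delta_um,
        "hydraulic_diameter_m": d_in,
        "max_inlet_reynolds": re_in,
        "cells": {m: meshes[m].n_cells for m in meshes},
        "grid_converged_level": grid_level,
        "all_converged": all(r.converged for r in reports.values()),
    }
    for q in q_list:
        comp = comparisons[(q, config.odorants[0])]
        headline[f"velocity_diff_pct_whole_q{q:g}"] = \
            comp.velocity_diff_pct.get("whole")
        headline[f"velocity_diff_pct_oe_q{q:g}"] = \
            comp.velocity_diff_pct.get("oe")
        headline[f"oe_flow_fraction_diff_points_q{q:g}"] = \
            comp.flow_fraction_diff_points.get("oe")
        for od in config.odorants:
            c = comparisons[(q, od)]
            headline[f"oe_deposition_diff_pct_{od}_q{q:g}"] = \
                c.deposition_diff_pct["olfactory"]
            headline[f"oe_deposition_diff_abs_kg_s_{od}_q{q:g}"] = \
                c.deposition_diff_abs["olfactory"]
    return headline


def _write_bundle(result: StudyResult, flux_fields: dict, q_max: float):
    out = result.out_dir
    result.flow_fraction_table.to_csv(out / "table3_flow_fractions.csv",
                                      index=False, float_format=FLOAT_FMT)
    result.deposition_table.to_csv(out / "table4_deposition.csv",
                                   index=False, float_format=FLOAT_FMT)
    result.velocity_table.to_csv(out / "fig5_average_velocity.csv",
                                 index=False, float_format=FLOAT_FMT)
    result.mass_balance_table.to_csv(out / "mass_balance.csv", index=False,
                                     float_format=FLOAT_FMT)
    result.grid_table.to_csv(out / "grid_independence.csv", index=False,
                             float_format=FLOAT_FMT)
    result.geometry_table.to_csv(out / "geometry_metrics.csv", index=False,
                                 float_format=FLOAT_FMT)
    header = {"config": _jsonable(result.config.to_dict()),
              "summary": _jsonable(result.summary)}
    (out / "summary.json").write_text(json.dumps(header, indent=1,
                                                 sort_keys=True))
    if result.config.render_flux_maps:
        map_dir = out / "flux_maps"
        map_dir.mkdir(exist_ok=True)
        for (model, q, od), flux in flux_fields.items():
            if q != q_max:
                continue
            render_flux_map(flux,
                            out_path=map_dir / f"flux_{model}_{od}.png")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    return obj


# ------------------------------------------------------------------ flux map

_WALL_GROUPS = ("outer_dorsal", "fin_dorsal_side", "axial_steps",
                "fin_ventral_side", "outer_ventral")


def render_flux_map(flux: "da.WallFluxField", region: str = "whole",
                    cap: float | None = None, n_bins: int = 100,
                    out_path=None):
    """Axial-position vs wall raster of the deposition flux j.

    Wall faces are grouped into the dorsal outer wall, the two septum-fin
    sides, the ventral outer wall and axial step faces; j is area-averaged
    into ``n_bins`` axial bins.  Values above ``cap`` saturate at the top of
    the color scale (the cap is the plotted vmax).  Returns (figure, binned
    array).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mask = flux.region_mask(region)
    if not mask.any():
        raise ValueError(f"no wall faces selected for region {region!r}")
    mesh = flux.mesh
    ids = flux.face_ids[mask]
    j = flux.j[mask]
    area = flux.area[mask]
    x = flux.x[mask]
    fin_mid = mesh.meta.get("regions", {}).get(
        "fin_midline_m", 0.5 * (mesh.y_edges[0] + mesh.y_edges[-1]))
    axis = mesh.b_axis[ids]
    sign = mesh.b_sign[ids]
    y = mesh.b_y[ids]
    group = np.full(ids.size, 2)                     # axial steps
    yfaces = axis == 1
    group[yfaces & (sign == 1) & (y > fin_mid)] = 0   # outer dorsal wall
    group[yfaces & (sign == -1) & (y >= fin_mid)] = 1  # fin, dorsal side
    group[yfaces & (sign == 1) & (y <= fin_mid)] = 3   # fin, ventral side
    group[yfaces & (sign == -1) & (y < fin_mid)] = 4   # outer ventral wall

    edges = np.linspace(mesh.x_edges[0], mesh.x_edges[-1], n_bins + 1)
    xbin = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
    num = np.zeros((5, n_bins))
    den = np.zeros((5, n_bins))
    np.add.at(num, (group, xbin), j * area)
    np.add.at(den, (group, xbin), area)
    img = np.divide(num, den, out=np.full_like(num, np.nan), where=den > 0)

    fig, ax = plt.subplots(figsize=(8, 3))
    im = ax.imshow(img, aspect="auto", origin="upper", cmap="jet",
                   vmin=0.0, vmax=cap,
                   extent=[0, mesh.x_edges[-1] * 1e3, 4.5, -0.5])
    ax.set_yticks(range(5), _WALL_GROUPS)
    ax.set_xlabel("axial position (mm)")
    ax.set_title(f"wall flux j (kg/m²·s), {flux.mesh.meta.get('build', {}).get('source', '')} mesh")
    fig.colorbar(im, ax=ax, label="j (kg/m²·s)")
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=110)
        plt.close(fig)
    return fig, img
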