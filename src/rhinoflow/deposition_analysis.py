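"""Wall fluxes, regional deposition doses and narrow-vs-wide comparisons.

This is the quantitative reporting surface of the paired-airway study: the
odorant wall flux j = k_m·c_w·C_in (kg/m²·s) integrates over epithelium
regions into deposition rates J (kg/s) and concentration-scale-free uptake
fractions J/(C_in·Q); the flow field yields volume-averaged velocities per
region and dorsal/ventral volumetric-flow fractions through coronal sections;
and paired narrow/widened cases reduce to signed percentage differences
(baseline = the narrow model).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .meshing import (Mesh, Section, OLFACTORY, RESPIRATORY, SQUAMOUS,
                      REGION_NAMES)
from .flow_solver import FlowSolution
from .odorant_transport import ConcentrationField

__all__ = [
    "WallFluxField", "RegionReport", "ComparisonReport",
    "wall_flux", "total_deposition", "mass_balance", "average_velocity",
    "flow_fraction", "percentage_difference", "compare_models",
    "REGIONS",
]

REGIONS = ("whole", "squamous", "respiratory", "olfactory")


@dataclass
class WallFluxField:
    """Per-wall-face odorant mass flux j (kg/m²·s) with region labels."""

    mesh: Mesh
    face_ids: np.ndarray          # boundary-face indices of the wall faces
    j: np.ndarray
    area: np.ndarray
    region: np.ndarray
    x: np.ndarray
    y: np.ndarray
    c_in: float
    warnings: list = field(default_factory=list)

    def region_mask(self, region: str) -> np.ndarray:
        if region == "whole":
            return np.ones(self.face_ids.size, bool)
        code = {v: k for k, v in REGION_NAMES.items()}.get(region)
        if code is None:
            raise ValueError(f"unknown region {region!r}")
        return self.region == code


@dataclass
class RegionReport:
    """One model × flow rate × odorant: the rows of the study tables."""

    model: str
    q_ml_min: float
    odorant: str
    wall_area: dict               # m² per region
    deposition: dict              # J, kg/s per region
    uptake_fraction: dict         # J / (C_in · Q) per region
    average_velocity: dict        # m/s, keys 'whole' and 'oe'
    flow_fractions: dict          # % dorsal per named section
    mass_closure: float           # relative odorant mass-balance error
    pressure_drop: float
    converged: bool


@dataclass
class ComparisonReport:
    """Paired narrow/wide differences (baseline = narrow)."""

    q_ml_min: float
    odorant: str
    narrow: RegionReport
    wide: RegionReport
    velocity_diff_pct: dict       # keys 'whole', 'oe'
    flow_fraction_diff_points: dict
    deposition_diff_pct: dict     # per region (NaN where baseline is 0)
    deposition_diff_abs: dict     # kg/s, wide − narrow


def wall_flux(conc: ConcentrationField, c_in: float | None = None
              ) -> WallFluxField:
    """j = k_m·c_w·C_in on mucus-coated faces, 0 on squamous faces.

    By construction of the Robin balance this equals the air-side diffusive
    flux D_a·C_in·(c_P − c_w)/δn on every mucosal face.
    """
    mesh = conc.mesh
    if c_in is None:
        c_in = conc.config.inlet_concentration if conc.config else 1.0
    ids = mesh.wall_faces
    region = mesh.b_region[ids]
    j = np.zeros(ids.size)
    mucosal = region != SQUAMOUS
    if np.isinf(conc.k_m):
        D_a = conc.odorant.diffusivity_air
        j[mucosal] = D_a * c_in * conc.c[mesh.b_owner[ids[mucosal]]] \
            / mesh.b_dist[ids[mucosal]]
    else:
        j[mucosal] = conc.k_m * conc.c_wall[ids[mucosal]] * c_in
    warn = []
    if not conc.converged:
        warn.append("concentration field did not converge")
        warnings.warn(warn[-1], stacklevel=2)
    return WallFluxField(mesh, ids, j, mesh.b_area[ids], region,
                         mesh.b_x[ids], mesh.b_y[ids], c_in, warn)


def total_deposition(flux: WallFluxField, region: str = "whole") -> float:
    """J = Σ j · face area over the region's wall faces (kg/s)."""
    mask = flux.region_mask(region)
    if not mask.any():
        warnings.warn(f"region {region!r} has no wall faces; J = 0",
                      stacklevel=2)
        return 0.0
    return float((flux.j[mask] * flux.area[mask]).sum())


def mass_balance(conc: ConcentrationField, flow: FlowSolution,
                 flux: WallFluxField) -> float:
    """Relative odorant mass-balance closure error.

    closure = |ṁ_in − ṁ_out − J_total| / ṁ_in, with ṁ_in the advective plus
    diffusive odorant mass rate through the inlet and ṁ_out the advective
    rate through the outlet (outlet diffusion is zero by the outflow
    condition).
    """
    mesh = conc.mesh
    c_in = flux.c_in
    D_a = conc.odorant.diffusivity_air
    inlet = mesh.inlet_faces
    outlet = mesh.outlet_faces
    q_in = -flow.q_b[inlet]
    cp = conc.c[mesh.b_owner[inlet]]
    m_in = float((q_in * 1.0 * c_in).sum()
                 + (D_a * mesh.b_area[inlet] / mesh.b_dist[inlet]
                    * (1.0 - cp) * c_in).sum())
    m_out = float((flow.q_b[outlet] * conc.c[mesh.b_owner[outlet]]
                   * c_in).sum())
    j_total = total_deposition(flux, "whole")
    if m_in == 0:
        return 0.0
    return abs(m_in - m_out - j_total) / m_in


def average_velocity(flow: FlowSolution, region: str = "whole",
                     weighting: str = "volume") -> float:
    """Mean velocity magnitude over a region's cells.

    ``weighting='volume'`` (default) is the volume-weighted mean of the
    speed; ``'flux'`` weights additionally by the local speed (a
    throughput-weighted alternative, reported for sensitivity only).
    """
    cells = flow.mesh.region_cells(region)
    if cells.size == 0:
        raise ValueError(f"region {region!r} is empty")
    s = flow.speed[cells]
    w = flow.mesh.cell_vol[cells]
    if weighting == "flux":
        w = w * s
        if w.sum() == 0:
            return 0.0
    elif weighting != "volume":
        raise ValueError("weighting must be 'volume' or 'flux'")
    return float((s * w).sum() / w.sum())


def flow_fraction(flow: FlowSolution, section: Section,
                  subset: str = "dorsal") -> float:
    """Percent of the section's volumetric flow carried by a subsection."""
    q = flow.q_int[section.face_ids]
    total = q.sum()
    if total == 0:
        raise ZeroDivisionError("section carries no net flow")
    mask = section.dorsal if subset == "dorsal" else section.ventral
    return float(100.0 * q[mask].sum() / total)


def percentage_difference(narrow_value: float, wide_value: float) -> float:
    """Signed percent change of the wide model relative to the narrow one."""
    if narrow_value == 0:
        raise ZeroDivisionError("narrow baseline is zero")
    return 100.0 * (wide_value - narrow_value) / narrow_value


def region_report(model: str, flow: FlowSolution, conc: ConcentrationField,
                  flux: WallFluxField,
                  sections: dict[str, Section] | None = None) -> RegionReport:
    """Assemble the per-case dosimetry/velocity/flow-split summary."""
    mesh = flow.mesh
    q_m3_s = flow.config.q_m3_s
    wall_area = {r: float(flux.area[flux.region_mask(r)].sum())
                 for r in REGIONS}
    dep = {r: total_deposition(flux, r) for r in REGIONS}
    denom = flux.c_in * q_m3_s
    uptake = {r: (dep[r] / denom if denom else np.nan) for r in REGIONS}
    avg = {"whole": average_velocity(flow, "whole")}
    try:
        avg["oe"] = average_velocity(flow, "oe")
    except ValueError:
        avg["oe"] = np.nan
    fracs = {}
    for name, sec in (sections or {}).items():
        fracs[name] = flow_fraction(flow, sec, "dorsal")
    closure = mass_balance(conc, flow, flux)
    return RegionReport(model, flow.config.q_ml_min, conc.odorant.name,
                        wall_area, dep, uptake, avg, fracs, closure,
                        flow.pressure_drop,
                        bool(flow.converged and conc.converged))


def compare_models(narrow: RegionReport, wide: RegionReport
                   ) -> ComparisonReport:
    """Paired percentage differences (velocities, flow splits, deposition).

    Swapping the arguments negates the velocity differences up to the change
    of baseline; the sign convention is wide-relative-to-narrow throughout.
    """
    if narrow.q_ml_min != wide.q_ml_min or narrow.odorant != wide.odorant:
        raise ValueError("paired reports must share flow rate and odorant")
    vel = {k: percentage_difference(narrow.average_velocity[k],
                                    wide.average_velocity[k])
           for k in narrow.average_velocity
           if np.isfinite(narrow.average_velocity[k])
           and narrow.average_velocity[k] != 0}
    frac = {k: wide.flow_fractions[k] - narrow.flow_fractions[k]
            for k in narrow.flow_fractions}
    dep_pct = {}
    dep_abs = {}
    for r in REGIONS:
        dep_abs[r] = wide.deposition[r] - narrow.deposition[r]
        dep_pct[r] = (percentage_difference(narrow.deposition[r],
                                            wide.deposition[r])
                      if narrow.deposition[r] != 0 else np.nan)
    return ComparisonReport(narrow.q_ml_min, narrow.odorant, narrow, wide,
                            vel, frac, dep_pct, dep_abs)
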