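"""Steady incompressible laminar flow on masked FV meshes.

The solver uses SIMPLE pressure–velocity coupling on a collocated grid with
Rhie–Chow face-flux interpolation, deferred-correction second-order upwind
convection and central diffusion.  Boundary conditions follow the nasal-airway
setup: uniform velocity inlet (Q / inlet area), no-slip rigid walls, and an
outflow outlet (zero normal gradient, with the pressure-correction equation
anchored by a zero-correction outlet reference so global mass balance is
enforced to machine precision each iteration).

Momentum u/v share one matrix factorization per iteration; the
pressure-correction matrix is refrozen every few iterations with its face
coefficients reused consistently in the flux correction, so per-cell
continuity after each correction is exact regardless of coefficient age.
Residuals (u, v momentum and continuity imbalance) are RMS norms over cells,
each normalized by its first-iteration value.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import splu

from .meshing import Mesh, build_mesh
from .airway_geometry import PhantomSpec, ImageStack

__all__ = [
    "FluidProperties", "FlowConfig", "FlowSolution", "SetupError",
    "solve_flow", "reynolds_number", "grid_independence", "AIR",
]

log = logging.getLogger(__name__)

ML_MIN = 1e-6 / 60.0  # m³/s per mL/min


class SetupError(RuntimeError):
    """The case is ill-posed (e.g. no outlet: singular pressure system)."""


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian fluid: density (kg/m³) and dynamic viscosity (Pa·s)."""

    density: float = 1.184
    viscosity: float = 1.849e-5

    def __post_init__(self):
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("density and viscosity must be positive")


#: Air at 25 °C and 1 atm.
AIR = FluidProperties()


@dataclass(frozen=True)
class FlowConfig:
    q_ml_min: float = 128.0
    tolerance: float = 1e-4
    max_iterations: int = 5000
    alpha_u: float = 0.7
    alpha_p: float = 0.3
    refactor_every: int = 10
    log_every: int = 100

    def __post_init__(self):
        if self.q_ml_min < 0:
            raise ValueError("flow rate must be >= 0")
        if not 0 < self.tolerance <= 1e-2:
            raise ValueError("tolerance must lie in (0, 1e-2]")

    @property
    def q_m3_s(self) -> float:
        return self.q_ml_min * ML_MIN


@dataclass
class FlowSolution:
    """Converged (or best-iterate) velocity/pressure fields on a mesh."""

    mesh: Mesh
    u: np.ndarray
    v: np.ndarray
    p: np.ndarray
    q_int: np.ndarray            # interior-face volumetric flux, owner->neigh (m³/s)
    q_b: np.ndarray              # boundary-face volumetric flux, outward (m³/s)
    pressure_drop: float         # area-weighted inlet minus outlet pressure (Pa)
    residuals: pd.DataFrame
    converged: bool
    config: FlowConfig = None
    fluid: FluidProperties = None

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.u, self.v)

    @property
    def inlet_flux(self) -> float:
        return float(-self.q_b[self.mesh.inlet_faces].sum())

    @property
    def outlet_flux(self) -> float:
        return float(self.q_b[self.mesh.outlet_faces].sum())

    def mass_imbalance(self) -> float:
        """|inlet − outlet| / inlet volumetric flux (0 for a zero-flow case)."""
        if self.inlet_flux == 0:
            return 0.0
        return abs(self.inlet_flux - self.outlet_flux) / self.inlet_flux

    def save(self, path) -> None:
        np.savez_compressed(
            path, u=self.u, v=self.v, p=self.p, q_int=self.q_int, q_b=self.q_b,
            pressure_drop=self.pressure_drop, converged=self.converged,
            res_index=self.residuals.index.to_numpy(),
            res_cols=np.array(self.residuals.columns, dtype="U32"),
            res_vals=self.residuals.to_numpy())


def reynolds_number(q_m3_s: float, inlet_area: float, inlet_perimeter: float,
                    fluid: FluidProperties = AIR) -> tuple[float, float]:
    """Inlet Reynolds number and hydraulic diameter ``d_in = 4 A / P``.

    ``d_in`` is also the reference length used by the nondimensional wall
    uptake parameter K in the transport layer.
    """
    if inlet_area <= 0 or inlet_perimeter <= 0:
        raise ValueError("area and perimeter must be positive")
    d_in = 4.0 * inlet_area / inlet_perimeter
    mean_u = q_m3_s / inlet_area
    re = fluid.density * mean_u * d_in / fluid.viscosity
    return re, d_in


# --------------------------------------------------------------------- solver

class _Assembler:
    """Per-mesh static arrays shared by momentum/pressure/scalar assembly."""

    def __init__(self, mesh: Mesh):
        self.m = mesh
        self.n = mesh.n_cells
        self.o = mesh.int_owner
        self.nb = mesh.int_neigh
        self.w = mesh.int_wf
        self.axis = mesh.int_axis
        self.ax0 = self.axis == 0
        self.inlet = mesh.inlet_faces
        self.outlet = mesh.outlet_faces
        self.wall = mesh.wall_faces

    def green_gauss(self, phi: np.ndarray, outlet_value: float | None = None
                    ) -> np.ndarray:
        """Cell gradient (n, 2) with zero-gradient boundary extrapolation
        (``outlet_value`` overrides the outlet-face value when given)."""
        m = self.m
        grad = np.zeros((self.n, 2))
        phi_f = self.w * phi[self.o] + (1 - self.w) * phi[self.nb]
        fa = phi_f * m.int_area
        for ax in (0, 1):
            sel = self.axis == ax
            np.add.at(grad[:, ax], self.o[sel], fa[sel])
            np.add.at(grad[:, ax], self.nb[sel], -fa[sel])
        phi_b = phi[m.b_owner].copy()
        if outlet_value is not None:
            phi_b[self.outlet] = outlet_value
        ba = phi_b * m.b_area * m.b_sign
        for ax in (0, 1):
            sel = m.b_axis == ax
            np.add.at(grad[:, ax], m.b_owner[sel], ba[sel])
        return grad / m.cell_vol[:, None]

    def sou_correction(self, phi: np.ndarray, q_int: np.ndarray,
                       limit: bool = True) -> np.ndarray:
        """Face-value correction (SOU − first-order upwind) per interior face."""
        m = self.m
        pos = q_int >= 0
        up = np.where(pos, self.o, self.nb)
        dn = np.where(pos, self.nb, self.o)
        uu = np.where(pos, m.int_uu_pos, m.int_uu_neg)
        g = np.where(pos, m.int_g_pos, m.int_g_neg)
        ok = uu >= 0
        corr = np.zeros_like(phi, shape=q_int.shape)
        corr[ok] = g[ok] * (phi[up[ok]] - phi[uu[ok]])
        if limit:
            face = phi[up] + corr
            lo = np.minimum(phi[up], phi[dn])
            hi = np.maximum(phi[up], phi[dn])
            corr = np.clip(face, lo, hi) - phi[up]
        return corr


def solve_flow(mesh: Mesh, fluid: FluidProperties = AIR,
               config: FlowConfig = FlowConfig(),
               initial: dict | None = None) -> FlowSolution:
    """SIMPLE solve of the steady laminar flow at the configured flow rate.

    ``initial`` may carry ``u``, ``v``, ``p`` arrays (e.g. prolonged from a
    coarser mesh) to warm-start the iteration.
    """
    if mesh.outlet_faces.size == 0:
        raise SetupError("mesh has no outlet: pressure system is singular")
    if mesh.inlet_faces.size == 0:
        raise SetupError("mesh has no inlet")
    rho, mu = fluid.density, fluid.viscosity
    q_target = config.q_m3_s
    u_in = q_target / mesh.inlet_area
    re, _ = reynolds_number(q_target, mesh.inlet_area, mesh.inlet_perimeter,
                            fluid)
    if re >= 600:
        warnings.warn(f"inlet Reynolds number {re:.0f} >= 600: outside the "
                      "laminar regime this model assumes", stacklevel=2)

    a = _Assembler(mesh)
    n = mesh.n_cells
    nf = mesh.int_owner.size
    if q_target == 0.0:
        residuals = pd.DataFrame({"u": [0.0], "v": [0.0], "continuity": [0.0]},
                                 index=pd.RangeIndex(1, 2, name="iteration"))
        return FlowSolution(mesh, np.zeros(n), np.zeros(n), np.zeros(n),
                            np.zeros(nf), np.zeros(mesh.b_owner.size), 0.0,
                            residuals, True, config, fluid)
    D_int = mu * mesh.int_area / mesh.int_delta
    D_b = mu * mesh.b_area / mesh.b_dist
    inlet, outlet, wall = a.inlet, a.outlet, a.wall
    q_in_face = u_in * mesh.b_area[inlet]          # fixed inflow per face

    u = np.zeros(n); v = np.zeros(n); p = np.zeros(n)
    q_int = np.zeros(nf)
    q_b = np.zeros(mesh.b_owner.size)
    q_b[inlet] = -q_in_face
    if initial:
        u = np.array(initial["u"], float); v = np.array(initial["v"], float)
        p = np.array(initial["p"], float)
        phi_f = np.where(a.ax0, a.w * u[a.o] + (1 - a.w) * u[a.nb],
                         a.w * v[a.o] + (1 - a.w) * v[a.nb])
        q_int = phi_f * mesh.int_area
        q_b[outlet] = np.maximum(u[mesh.b_owner[outlet]], 0.0) \
            * mesh.b_area[outlet]

    raw = {"u": [], "v": [], "continuity": []}
    # absolute fallback scales: per-cell shares of the inlet momentum and
    # mass fluxes, so a warm-started run near the solution can still be
    # declared converged even though its first-iteration residual is tiny
    mom_ref = rho * q_target * u_in / n
    cont_ref = rho * q_target / n
    abs_ref = {"u": mom_ref, "v": mom_ref, "continuity": cont_ref}
    converged = False
    lu_p = None
    lu_m = None
    cb_frozen = None

    for it in range(1, config.max_iterations + 1):
        refreeze = lu_p is None or (it - 1) % config.refactor_every == 0
        F = rho * q_int
        Fpos = np.maximum(F, 0.0)
        Fneg = np.minimum(F, 0.0)

        diag = np.zeros(n)
        rows = np.concatenate([a.o, a.nb])
        cols = np.concatenate([a.nb, a.o])
        vals = np.concatenate([-D_int + Fneg, -D_int - Fpos])
        np.add.at(diag, a.o, D_int + Fpos)
        np.add.at(diag, a.nb, D_int - Fneg)

        bu = np.zeros(n); bv = np.zeros(n)
        # inlet: Dirichlet (u_in, 0) with convective inflow
        Fb_in = rho * q_b[inlet]                   # negative
        np.add.at(diag, mesh.b_owner[inlet], D_b[inlet])
        np.add.at(bu, mesh.b_owner[inlet], (D_b[inlet] - Fb_in) * u_in)
        # walls: no slip
        np.add.at(diag, mesh.b_owner[wall], D_b[wall])
        # outlet: zero-gradient, convective outflow only
        Fb_out = np.maximum(rho * q_b[outlet], 0.0)
        np.add.at(diag, mesh.b_owner[outlet], Fb_out)

        # deferred-correction second-order upwind
        cu = a.sou_correction(u, q_int)
        cv = a.sou_correction(v, q_int)
        np.add.at(bu, a.o, -F * cu); np.add.at(bu, a.nb, F * cu)
        np.add.at(bv, a.o, -F * cv); np.add.at(bv, a.nb, F * cv)

        # pressure-gradient source (outlet face pressure anchored at the
        # zero reference, consistent with the pressure-correction system)
        grad_p = a.green_gauss(p, outlet_value=0.0)
        bu -= grad_p[:, 0] * mesh.cell_vol
        bv -= grad_p[:, 1] * mesh.cell_vol

        # implicit under-relaxation
        diag_rel = diag / config.alpha_u
        bu_rel = bu + (diag_rel - diag) * u
        bv_rel = bv + (diag_rel - diag) * v

        A = sparse.coo_matrix(
            (np.concatenate([vals, diag_rel]),
             (np.concatenate([rows, np.arange(n)]),
              np.concatenate([cols, np.arange(n)]))),
            shape=(n, n)).tocsr()

        ru = bu - _matvec_offdiag(rows, cols, vals, u, n) - diag * u
        rv = bv - _matvec_offdiag(rows, cols, vals, v, n) - diag * v
        res_u = float(np.sqrt(np.mean(ru ** 2)))
        res_v = float(np.sqrt(np.mean(rv ** 2)))

        # momentum solved by defect correction against a periodically
        # refrozen LU; refactorize at once if the stale factor stops
        # contracting the linear residual (coefficients drifted too far)
        if refreeze:
            lu_m = splu(A.tocsc())
        for _ in range(2):
            u = u + lu_m.solve(bu_rel - A @ u)
            v = v + lu_m.solve(bv_rel - A @ v)
        rlin = bu_rel - A @ u
        if not np.isfinite(rlin).all() or \
                np.sqrt(np.mean(rlin ** 2)) > 0.1 * max(res_u, 1e-300):
            lu_m = splu(A.tocsc())
            u = lu_m.solve(bu_rel)
            v = lu_m.solve(bv_rel)
        d_cell = mesh.cell_vol / diag_rel

        # Rhie–Chow face fluxes (grad_p from the momentum assembly is current)
        phi_f = np.where(a.ax0, a.w * u[a.o] + (1 - a.w) * u[a.nb],
                         a.w * v[a.o] + (1 - a.w) * v[a.nb])
        d_f = a.w * d_cell[a.o] + (1 - a.w) * d_cell[a.nb]
        gp_f = np.where(a.ax0,
                        a.w * grad_p[a.o, 0] + (1 - a.w) * grad_p[a.nb, 0],
                        a.w * grad_p[a.o, 1] + (1 - a.w) * grad_p[a.nb, 1])
        q_int = mesh.int_area * (phi_f + d_f * (gp_f - (p[a.nb] - p[a.o])
                                                / mesh.int_delta))
        q_b[outlet] = u[mesh.b_owner[outlet]] * mesh.b_area[outlet]

        # pressure correction (coefficients frozen between refactorizations)
        if refreeze:
            d_frozen = d_f.copy()
            cb_frozen = mesh.b_area[outlet] * d_cell[mesh.b_owner[outlet]] \
                / mesh.b_dist[outlet]
            c_int = mesh.int_area * d_frozen / mesh.int_delta
            diag_p = np.zeros(n)
            np.add.at(diag_p, a.o, c_int)
            np.add.at(diag_p, a.nb, c_int)
            np.add.at(diag_p, mesh.b_owner[outlet], cb_frozen)
            Ap = sparse.coo_matrix(
                (np.concatenate([-c_int, -c_int, diag_p]),
                 (np.concatenate([a.o, a.nb, np.arange(n)]),
                  np.concatenate([a.nb, a.o, np.arange(n)]))),
                shape=(n, n)).tocsc()
            lu_p = splu(Ap)
            c_int_frozen = c_int

        imb = np.zeros(n)
        np.add.at(imb, a.o, q_int)
        np.add.at(imb, a.nb, -q_int)
        np.add.at(imb, mesh.b_owner, q_b)
        res_c = float(rho * np.sqrt(np.mean(imb ** 2)))

        pc = lu_p.solve(-imb)
        q_int -= c_int_frozen * (pc[a.nb] - pc[a.o])
        q_b[outlet] += cb_frozen * pc[mesh.b_owner[outlet]]
        p += config.alpha_p * pc
        grad_pc = a.green_gauss(pc, outlet_value=0.0)
        u -= d_cell * grad_pc[:, 0]
        v -= d_cell * grad_pc[:, 1]

        last = {}
        for key, r in (("u", res_u), ("v", res_v), ("continuity", res_c)):
            raw[key].append(r)
            norm0 = max(max(raw[key][:5]), 1e-300)
            last[key] = min(r / norm0, r / max(abs_ref[key], 1e-300))
        if it % config.log_every == 0:
            log.info("iter %d: u=%.3e v=%.3e cont=%.3e", it,
                     last["u"], last["v"], last["continuity"])
        if it >= 2 and max(last.values()) < config.tolerance:
            converged = True
            break

    hist = {}
    for key, series in raw.items():
        norm0 = max(max(series[:5]), 1e-300)
        hist[key] = [min(r / norm0, r / max(abs_ref[key], 1e-300))
                     for r in series]
    residuals = pd.DataFrame(hist,
                             index=pd.RangeIndex(1, len(hist["u"]) + 1,
                                                 name="iteration"))
    p_in = _area_mean(p[mesh.b_owner[inlet]], mesh.b_area[inlet])
    p_out = _area_mean(p[mesh.b_owner[outlet]], mesh.b_area[outlet])
    sol = FlowSolution(mesh, u, v, p, q_int, q_b, p_in - p_out, residuals,
                       converged, config, fluid)
    if not converged:
        warnings.warn(f"flow solver did not converge in "
                      f"{config.max_iterations} iterations "
                      f"(final residual {max(hist['u'][-1], hist['v'][-1], hist['continuity'][-1]):.2e})",
                      stacklevel=2)
    return sol


def _matvec_offdiag(rows, cols, vals, x, n):
    out = np.zeros(n)
    np.add.at(out, rows, vals * x[cols])
    return out


def _area_mean(values, areas) -> float:
    return float((values * areas).sum() / areas.sum())


# --------------------------------------------------- grid-independence study

def average_speed(sol: FlowSolution, region: str = "whole") -> float:
    """Volume-weighted mean velocity magnitude over a mesh region."""
    cells = sol.mesh.region_cells(region)
    w = sol.mesh.cell_vol[cells]
    return float((sol.speed[cells] * w).sum() / w.sum())


def prolong(coarse: Mesh, sol: FlowSolution, fine: Mesh) -> dict:
    """Nearest-cell injection of a coarse solution onto a finer mesh."""
    ix = np.clip(np.searchsorted(coarse.x_edges, fine.cell_x, "right") - 1,
                 0, coarse.active.shape[0] - 1)
    iy = np.clip(np.searchsorted(coarse.y_edges, fine.cell_y, "right") - 1,
                 0, coarse.active.shape[1] - 1)
    src = coarse.cell_id[ix, iy]
    ok = src >= 0
    out = {}
    for name, f in (("u", sol.u), ("v", sol.v), ("p", sol.p)):
        arr = np.zeros(fine.n_cells)
        arr[ok] = f[src[ok]]
        out[name] = arr
    return out


def grid_independence(geometry: PhantomSpec | ImageStack,
                      target_cell_um: float,
                      fluid: FluidProperties = AIR,
                      config: FlowConfig = FlowConfig(),
                      levels: tuple = (1, 2, 3),
                      tol_percent: float = 1.0,
                      wall_layers: int = 0, growth_ratio: float = 1.2,
                      depth_um: float | None = None,
                      x_cell_um: float | None = None,
                      warm_start: bool = True) -> tuple[pd.DataFrame, int | None]:
    """Solve the same case on successively refined meshes.

    Each level ``k`` rebuilds the mesh at ``target_cell_um / k``.  Convergence
    is declared at the first level whose whole-domain average velocity and
    pressure drop both change by less than ``tol_percent`` relative to the
    next finer level.  A non-monotone refinement sequence is reported
    (``monotone`` column) and no level is declared.
    """
    if len(levels) < 3:
        raise ValueError("grid independence needs at least 3 levels")
    rows = []
    prev = None
    for lev in levels:
        mesh = build_mesh(geometry, target_cell_um / lev,
                          wall_layers=wall_layers, growth_ratio=growth_ratio,
                          depth_um=depth_um,
                          x_cell_um=None if x_cell_um is None
                          else x_cell_um / lev)
        init = prolong(prev[0], prev[1], mesh) if (warm_start and prev) else None
        sol = solve_flow(mesh, fluid, config, initial=init)
        rows.append({"level": lev, "cells": mesh.n_cells,
                     "average_velocity_m_s": average_speed(sol),
                     "pressure_drop_pa": sol.pressure_drop,
                     "converged": sol.converged})
        prev = (mesh, sol)
    table = pd.DataFrame(rows)
    dv = np.abs(np.diff(table["average_velocity_m_s"])) \
        / table["average_velocity_m_s"].to_numpy()[1:] * 100
    dp = np.abs(np.diff(table["pressure_drop_pa"])) \
        / np.abs(table["pressure_drop_pa"].to_numpy()[1:]) * 100
    table["delta_velocity_pct"] = np.append(dv, np.nan)
    table["delta_pressure_pct"] = np.append(dp, np.nan)
    # a refinement sequence is non-monotone only if it reverses direction by
    # more than the tolerance (plateau wiggles at convergence don't count)
    diffs = np.diff(table["average_velocity_m_s"])
    significant = dv > tol_percent
    signs = np.sign(diffs)[significant]
    monotone = bool(signs.size == 0 or np.all(signs == signs[0]))
    table.attrs["monotone"] = monotone
    converged_level = None
    for k in range(len(levels) - 1):
        if dv[k] < tol_percent and dp[k] < tol_percent:
            converged_level = int(levels[k])
            break
    if not monotone:
        log.warning("non-monotone grid-refinement sequence; no level declared")
        converged_level = None
    return table, converged_level
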