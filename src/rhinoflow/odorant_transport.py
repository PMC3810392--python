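"""Steady odorant advection–diffusion with an air–mucus uptake wall condition.

The nondimensional concentration c (inlet value 1) is transported by the
frozen flow field and absorbed at mucus-coated walls through a quasi-steady
film balance: odorant partitions into the mucus (equilibrium coefficient β,
air/mucus), diffuses across a film of thickness H_m with c = 0 at the
mucus/tissue base, giving a Robin condition in which the air-side diffusive
flux equals k_m·c_w with the mass-transfer coefficient

    k_m = D_m / (β · H_m)        [m/s]

and the nondimensional uptake parameter K = k_m·d_in/D_a (d_in the inlet
hydraulic diameter).  Small β (a highly mucus-soluble odorant such as
carvone) gives fast uptake; β → ∞ recovers an insoluble, zero-flux wall.
Squamous walls are zero-flux; the outlet is an outflow boundary.

Discretization mirrors the flow solver: deferred-correction second-order
upwind convection (with face-value limiting, preserving 0 ≤ c ≤ 1), central
diffusion, and the Robin wall folded into the wall-adjacent cell through
c_w = c_P / (1 + k_m·δn/D_a).  The linear first-order system is factorized
once; outer iterations update only the second-order correction and stop when
the RMS concentration change per iteration falls below the tolerance.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import splu

from .flow_solver import FlowSolution, _Assembler
from .meshing import Mesh, SQUAMOUS

__all__ = [
    "OdorantProperties", "MucusModel", "TransportConfig", "ConcentrationField",
    "odorant_registry", "get_odorant", "mass_transfer_coefficient",
    "solve_odorant",
]


@dataclass(frozen=True)
class OdorantProperties:
    """Odorant physical constants at 25 °C, 1 atm.

    ``diffusivity_air``/``diffusivity_mucus`` in m²/s; ``partition`` is the
    dimensionless air/mucus equilibrium partition coefficient β.
    """

    name: str
    diffusivity_air: float
    diffusivity_mucus: float
    partition: float

    def __post_init__(self):
        if min(self.diffusivity_air, self.diffusivity_mucus,
               self.partition) <= 0:
            raise ValueError("odorant constants must be positive")


def odorant_registry() -> pd.DataFrame:
    """The shipped three-odorant constant table (indexed by name)."""
    with importlib.resources.files("rhinoflow.data") \
            .joinpath("odorants.tsv").open() as fh:
        table = pd.read_csv(fh, sep="\t", comment="#").set_index("name")
    return table


def get_odorant(name: str) -> OdorantProperties:
    table = odorant_registry()
    key = name.lower().replace(" ", "_")
    if key not in table.index:
        raise KeyError(f"unknown odorant {name!r}; registry has "
                       f"{list(table.index)}")
    row = table.loc[key]
    return OdorantProperties(key, row["D_a_m2_s"], row["D_m_m2_s"],
                             row["beta"])


@dataclass(frozen=True)
class MucusModel:
    """Uniform mucus film of thickness ``thickness_m`` (default 30 µm)."""

    thickness_m: float = 30e-6

    def __post_init__(self):
        if self.thickness_m <= 0:
            raise ValueError("mucus thickness must be positive")

    def k_m(self, odorant: OdorantProperties) -> float:
        return odorant.diffusivity_mucus / (odorant.partition
                                            * self.thickness_m)


def mass_transfer_coefficient(odorant: OdorantProperties, mucus: MucusModel,
                              d_in: float) -> tuple[float, float]:
    """(k_m [m/s], nondimensional K = k_m·d_in/D_a)."""
    k_m = mucus.k_m(odorant)
    return k_m, k_m * d_in / odorant.diffusivity_air


@dataclass(frozen=True)
class TransportConfig:
    tolerance: float = 1e-6
    max_iterations: int = 500
    inlet_concentration: float = 1.0     # C_in, kg/m³ (dimensionalizes fluxes)

    def __post_init__(self):
        if not 0 < self.tolerance <= 1e-4:
            raise ValueError("tolerance must lie in (0, 1e-4]")


@dataclass
class ConcentrationField:
    """Nondimensional odorant concentration and its wall trace."""

    mesh: Mesh
    c: np.ndarray                 # cell-centered, in [0, 1]
    c_wall: np.ndarray            # per boundary face (c_P on non-wall faces)
    k_m: float
    odorant: OdorantProperties
    mucus: MucusModel
    residuals: pd.DataFrame = None
    converged: bool = True
    config: TransportConfig = None
    flow: FlowSolution = field(default=None, repr=False)

    def save(self, path) -> None:
        np.savez_compressed(path, c=self.c, c_wall=self.c_wall, k_m=self.k_m,
                            converged=self.converged,
                            odorant=self.odorant.name)


def solve_odorant(mesh: Mesh, flow: FlowSolution,
                  odorant: OdorantProperties,
                  mucus: MucusModel = MucusModel(),
                  config: TransportConfig = TransportConfig(),
                  k_m_override: float | None = None) -> ConcentrationField:
    """Solve steady odorant transport on a converged flow field.

    ``k_m_override`` replaces the film-model coefficient (useful for the
    zero-uptake and perfectly-absorbing limits); ``np.inf`` imposes the
    Dirichlet c_w = 0 limit.
    """
    if flow.mesh is not mesh:
        raise ValueError("flow was solved on a different mesh")
    if not flow.converged:
        warnings.warn("transport driven by an unconverged flow field",
                      stacklevel=2)
    D_a = odorant.diffusivity_air
    k_m = mucus.k_m(odorant) if k_m_override is None else float(k_m_override)
    if k_m < 0:
        raise ValueError("k_m must be >= 0")

    a = _Assembler(mesh)
    n = mesh.n_cells
    q = flow.q_int
    qpos = np.maximum(q, 0.0)
    qneg = np.minimum(q, 0.0)
    D_int = D_a * mesh.int_area / mesh.int_delta
    D_b = D_a * mesh.b_area / mesh.b_dist

    diag = np.zeros(n)
    b0 = np.zeros(n)
    rows = np.concatenate([a.o, a.nb])
    cols = np.concatenate([a.nb, a.o])
    vals = np.concatenate([-D_int + qneg, -D_int - qpos])
    np.add.at(diag, a.o, D_int + qpos)
    np.add.at(diag, a.nb, D_int - qneg)

    inlet, outlet, wall = a.inlet, a.outlet, a.wall
    # inlet: Dirichlet c = 1 (convective inflow + diffusion)
    q_in = -flow.q_b[inlet]                       # positive into the domain
    np.add.at(diag, mesh.b_owner[inlet], D_b[inlet])
    np.add.at(b0, mesh.b_owner[inlet], (D_b[inlet] + q_in) * 1.0)
    # outlet: outflow (zero normal gradient, convection only)
    np.add.at(diag, mesh.b_owner[outlet],
              np.maximum(flow.q_b[outlet], 0.0))
    # walls: Robin uptake on mucus-coated faces, zero flux on squamous
    mucosal = wall[mesh.b_region[wall] != SQUAMOUS]
    if k_m > 0:
        # series resistance of the mucus film and the half-cell air gap
        film = 0.0 if np.isinf(k_m) else 1.0 / k_m
        a_wall = mesh.b_area[mucosal] / (film + mesh.b_dist[mucosal] / D_a)
        np.add.at(diag, mesh.b_owner[mucosal], a_wall)

    A = sparse.coo_matrix(
        (np.concatenate([vals, diag]),
         (np.concatenate([rows, np.arange(n)]),
          np.concatenate([cols, np.arange(n)]))), shape=(n, n)).tocsc()
    lu = splu(A)

    c = np.clip(lu.solve(b0), 0.0, 1.0)
    res_hist = []
    converged = False
    for _ in range(config.max_iterations):
        corr = a.sou_correction(c, q, limit=True)
        b = b0.copy()
        np.add.at(b, a.o, -q * corr)
        np.add.at(b, a.nb, q * corr)
        c_new = lu.solve(b)
        res = float(np.sqrt(np.mean((c_new - c) ** 2)))
        res_hist.append(res)
        c = c_new
        if res < config.tolerance:
            converged = True
            break
    if not converged:
        warnings.warn("transport solver did not converge "
                      f"(final RMS change {res_hist[-1]:.2e})", stacklevel=2)

    c_wall = c[mesh.b_owner].copy()
    if np.isinf(k_m):
        c_wall[mucosal] = 0.0
    elif k_m > 0:
        c_wall[mucosal] = c[mesh.b_owner[mucosal]] \
            / (1.0 + k_m * mesh.b_dist[mucosal] / D_a)
    residuals = pd.DataFrame(
        {"rms_delta_c": res_hist},
        index=pd.RangeIndex(1, len(res_hist) + 1, name="iteration"))
    return ConcentrationField(mesh, c, c_wall, k_m, odorant, mucus,
                              residuals, converged, config, flow)
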