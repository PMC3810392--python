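"""Masked structured 2D finite-volume meshes of the airway mid-sagittal plane.

A mesh is a tensor-product Cartesian grid (x anterior -> posterior,
y ventral -> dorsal, SI meters) with an active-cell mask and a constant unit
depth that carries all areas and volumes into SI.  Two construction paths:

* from a :class:`~rhinoflow.airway_geometry.PhantomSpec` — grid lines conform
  exactly to the channel walls and the septum fin, with optional geometric
  grading of the first off-wall cell rows (the stand-in for near-wall prism
  layers);
* from a binary :class:`~rhinoflow.airway_geometry.ImageStack` — the mid-
  sagittal section is sampled at cell centers (stair-step walls).

Boundary faces are tagged inlet (anterior open end), outlet (posterior open
end) or wall; wall faces carry an epithelium region label (squamous /
respiratory / olfactory) used by the transport and dosimetry layers.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .airway_geometry import UM, ImageStack, PhantomSpec, ResolutionError

__all__ = [
    "Mesh", "Section", "build_mesh", "refine_mesh", "cross_section",
    "INTERIOR", "WALL", "INLET", "OUTLET",
    "SQUAMOUS", "RESPIRATORY", "OLFACTORY", "REGION_NAMES",
    "EmptySectionError", "MeshSizeError",
]

INTERIOR, WALL, INLET, OUTLET = 0, 1, 2, 3
SQUAMOUS, RESPIRATORY, OLFACTORY = 0, 1, 2
REGION_NAMES = {SQUAMOUS: "squamous", RESPIRATORY: "respiratory",
                OLFACTORY: "olfactory"}
MAX_CELLS = 5_000_000


class EmptySectionError(ValueError):
    """Requested cross-section lies in solid tissue."""


class MeshSizeError(ValueError):
    """Refinement would exceed the cell-count guard."""


@dataclass
class Mesh:
    """Masked Cartesian FV mesh; all geometry in meters."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    depth: float
    active: np.ndarray           # bool (nx, ny)
    meta: dict = field(default_factory=dict)

    # derived, filled by _finalize
    cell_id: np.ndarray = None
    cell_i: np.ndarray = None
    cell_j: np.ndarray = None
    cell_x: np.ndarray = None
    cell_y: np.ndarray = None
    cell_vol: np.ndarray = None

    def __post_init__(self):
        self.x_edges = np.asarray(self.x_edges, float)
        self.y_edges = np.asarray(self.y_edges, float)
        self.active = np.asarray(self.active, bool)
        self._finalize()

    # ------------------------------------------------------------------ core
    def _finalize(self):
        nx, ny = self.active.shape
        assert self.x_edges.size == nx + 1 and self.y_edges.size == ny + 1
        self.dx = np.diff(self.x_edges)
        self.dy = np.diff(self.y_edges)
        self.xc = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        self.yc = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        self._drop_unreachable()
        self.cell_id = np.full((nx, ny), -1, dtype=np.int64)
        ii, jj = np.nonzero(self.active)
        self.cell_id[ii, jj] = np.arange(ii.size)
        self.cell_i, self.cell_j = ii, jj
        self.cell_x = self.xc[ii]
        self.cell_y = self.yc[jj]
        self.cell_vol = self.dx[ii] * self.dy[jj] * self.depth
        if ii.size == 0:
            raise ValueError("mesh has no active cells")
        self._build_faces()

    def _drop_unreachable(self):
        """Keep only cells 4-connected to the inlet column (mesh invariant)."""
        lab, n = ndimage.label(self.active)
        if n <= 1:
            return
        inlet_labels = set(np.unique(lab[0, :][self.active[0, :]]).tolist())
        keep = np.isin(lab, sorted(inlet_labels)) & self.active
        dropped = int(self.active.sum() - keep.sum())
        if dropped:
            warnings.warn(f"dropping {dropped} active cells unreachable from "
                          "the inlet", stacklevel=3)
            self.active = keep

    def _build_faces(self):
        nx, ny = self.active.shape
        act, cid = self.active, self.cell_id
        io, ineigh, iax, iarea, idelta, iwf = [], [], [], [], [], []
        ixf, iyf, iuup, igp, iuun, ign = [], [], [], [], [], []
        bo, bax, bsign, barea, bdist, btype, bx, by = [], [], [], [], [], [], [], []

        # x-normal faces -----------------------------------------------------
        for i in range(nx + 1):
            left = act[i - 1, :] if i > 0 else np.zeros(ny, bool)
            right = act[i, :] if i < nx else np.zeros(ny, bool)
            both = left & right
            jj = np.nonzero(both)[0]
            if jj.size:
                o = cid[i - 1, jj]
                n_ = cid[i, jj]
                io.append(o); ineigh.append(n_)
                iax.append(np.zeros(jj.size, np.int8))
                a = self.dy[jj] * self.depth
                iarea.append(a)
                d = self.xc[i] - self.xc[i - 1]
                idelta.append(np.full(jj.size, d))
                iwf.append(np.full(jj.size, (self.xc[i] - self.x_edges[i]) / d))
                ixf.append(np.full(jj.size, self.x_edges[i])); iyf.append(self.yc[jj])
                # far-upwind neighbours for the second-order scheme
                up = np.full(jj.size, -1, np.int64); gp = np.zeros(jj.size)
                if i >= 2:
                    ok = act[i - 2, jj]
                    up[ok] = cid[i - 2, jj[ok]]
                    gp[ok] = (self.x_edges[i] - self.xc[i - 1]) / (self.xc[i - 1] - self.xc[i - 2])
                un = np.full(jj.size, -1, np.int64); gn = np.zeros(jj.size)
                if i + 1 <= nx - 1:
                    ok = act[i + 1, jj]
                    un[ok] = cid[i + 1, jj[ok]]
                    gn[ok] = (self.xc[i] - self.x_edges[i]) / (self.xc[i + 1] - self.xc[i])
                iuup.append(up); igp.append(gp); iuun.append(un); ign.append(gn)
            # boundary faces on this grid line
            only_left = left & ~right
            jj = np.nonzero(only_left)[0]
            if jj.size:
                bo.append(cid[i - 1, jj]); bax.append(np.zeros(jj.size, np.int8))
                bsign.append(np.ones(jj.size, np.int8))
                barea.append(self.dy[jj] * self.depth)
                bdist.append(np.full(jj.size, self.x_edges[i] - self.xc[i - 1]))
                btype.append(np.full(jj.size, OUTLET if i == nx else WALL, np.int8))
                bx.append(np.full(jj.size, self.x_edges[i])); by.append(self.yc[jj])
            only_right = right & ~left
            jj = np.nonzero(only_right)[0]
            if jj.size:
                bo.append(cid[i, jj]); bax.append(np.zeros(jj.size, np.int8))
                bsign.append(-np.ones(jj.size, np.int8))
                barea.append(self.dy[jj] * self.depth)
                bdist.append(np.full(jj.size, self.xc[i] - self.x_edges[i]))
                btype.append(np.full(jj.size, INLET if i == 0 else WALL, np.int8))
                bx.append(np.full(jj.size, self.x_edges[i])); by.append(self.yc[jj])

        # y-normal faces -----------------------------------------------------
        for j in range(ny + 1):
            low = act[:, j - 1] if j > 0 else np.zeros(nx, bool)
            high = act[:, j] if j < ny else np.zeros(nx, bool)
            both = low & high
            ii = np.nonzero(both)[0]
            if ii.size:
                o = cid[ii, j - 1]; n_ = cid[ii, j]
                io.append(o); ineigh.append(n_)
                iax.append(np.ones(ii.size, np.int8))
                iarea.append(self.dx[ii] * self.depth)
                d = self.yc[j] - self.yc[j - 1]
                idelta.append(np.full(ii.size, d))
                iwf.append(np.full(ii.size, (self.yc[j] - self.y_edges[j]) / d))
                ixf.append(self.xc[ii]); iyf.append(np.full(ii.size, self.y_edges[j]))
                up = np.full(ii.size, -1, np.int64); gp = np.zeros(ii.size)
                if j >= 2:
                    ok = act[ii, j - 2]
                    up[ok] = cid[ii[ok], j - 2]
                    gp[ok] = (self.y_edges[j] - self.yc[j - 1]) / (self.yc[j - 1] - self.yc[j - 2])
                un = np.full(ii.size, -1, np.int64); gn = np.zeros(ii.size)
                if j + 1 <= ny - 1:
                    ok = act[ii, j + 1]
                    un[ok] = cid[ii[ok], j + 1]
                    gn[ok] = (self.yc[j] - self.y_edges[j]) / (self.yc[j + 1] - self.yc[j])
                iuup.append(up); igp.append(gp); iuun.append(un); ign.append(gn)
            only_low = low & ~high
            ii = np.nonzero(only_low)[0]
            if ii.size:
                bo.append(cid[ii, j - 1]); bax.append(np.ones(ii.size, np.int8))
                bsign.append(np.ones(ii.size, np.int8))
                barea.append(self.dx[ii] * self.depth)
                bdist.append(np.full(ii.size, self.y_edges[j] - self.yc[j - 1]))
                btype.append(np.full(ii.size, WALL, np.int8))
                bx.append(self.xc[ii]); by.append(np.full(ii.size, self.y_edges[j]))
            only_high = high & ~low
            ii = np.nonzero(only_high)[0]
            if ii.size:
                bo.append(cid[ii, j]); bax.append(np.ones(ii.size, np.int8))
                bsign.append(-np.ones(ii.size, np.int8))
                barea.append(self.dx[ii] * self.depth)
                bdist.append(np.full(ii.size, self.yc[j] - self.y_edges[j]))
                btype.append(np.full(ii.size, WALL, np.int8))
                bx.append(self.xc[ii]); by.append(np.full(ii.size, self.y_edges[j]))

        cat = lambda parts, dt=float: (np.concatenate(parts).astype(dt)
                                       if parts else np.empty(0, dt))
        self.int_owner = cat(io, np.int64); self.int_neigh = cat(ineigh, np.int64)
        self.int_axis = cat(iax, np.int8); self.int_area = cat(iarea)
        self.int_delta = cat(idelta); self.int_wf = cat(iwf)
        self.int_x = cat(ixf); self.int_y = cat(iyf)
        self.int_uu_pos = cat(iuup, np.int64); self.int_g_pos = cat(igp)
        self.int_uu_neg = cat(iuun, np.int64); self.int_g_neg = cat(ign)
        self.b_owner = cat(bo, np.int64); self.b_axis = cat(bax, np.int8)
        self.b_sign = cat(bsign, np.int8); self.b_area = cat(barea)
        self.b_dist = cat(bdist); self.b_type = cat(btype, np.int8)
        self.b_x = cat(bx); self.b_y = cat(by)
        self.b_region = self._label_wall_regions()

    def _label_wall_regions(self) -> np.ndarray:
        region = np.full(self.b_owner.size, -1, np.int8)
        wall = self.b_type == WALL
        if not wall.any():
            return region
        g = self.meta.get("regions", {})
        squam_end = g.get("squamous_end_m", 0.0)
        olf_start = g.get("olfactory_start_m", np.inf)
        olf_end = g.get("olfactory_end_m", np.inf)
        fin_mid = g.get("fin_midline_m", np.inf)
        x, y = self.b_x, self.b_y
        reg = np.full(x.size, RESPIRATORY, np.int8)
        reg[x < squam_end - 1e-12] = SQUAMOUS
        reg[(x >= olf_start - 1e-12) & (x <= olf_end + 1e-12)
            & (y >= fin_mid - 1e-12)] = OLFACTORY
        region[wall] = reg[wall]
        return region

    # ------------------------------------------------------------- accessors
    @property
    def n_cells(self) -> int:
        return self.cell_x.size

    @property
    def inlet_faces(self) -> np.ndarray:
        return np.nonzero(self.b_type == INLET)[0]

    @property
    def outlet_faces(self) -> np.ndarray:
        return np.nonzero(self.b_type == OUTLET)[0]

    @property
    def wall_faces(self) -> np.ndarray:
        return np.nonzero(self.b_type == WALL)[0]

    @property
    def inlet_area(self) -> float:
        return float(self.b_area[self.inlet_faces].sum())

    @property
    def outlet_area(self) -> float:
        return float(self.b_area[self.outlet_faces].sum())

    @property
    def inlet_perimeter(self) -> float:
        """Wetted perimeter of the (rectangular, depth-extruded) inlet."""
        h = self.b_area[self.inlet_faces].sum() / self.depth
        return 2.0 * (h + self.depth)

    def total_volume(self) -> float:
        return float(self.cell_vol.sum())

    def region_cells(self, region: str) -> np.ndarray:
        """Cell ids of a velocity-averaging region ('whole' or 'oe')."""
        if region == "whole":
            return np.arange(self.n_cells)
        if region == "oe":
            g = self.meta.get("regions", {})
            olf_start = g.get("olfactory_start_m")
            fin_mid = g.get("fin_midline_m")
            if olf_start is None or fin_mid is None:
                raise ValueError("mesh carries no olfactory-region metadata")
            sel = (self.cell_x >= olf_start) \
                & (self.cell_x <= g.get("olfactory_end_m", np.inf)) \
                & (self.cell_y >= fin_mid)
            if not sel.any():
                raise ValueError("olfactory region contains no cells")
            return np.nonzero(sel)[0]
        raise ValueError(f"unknown region {region!r}")

    # ---------------------------------------------------------- persistence
    def save(self, path) -> None:
        header = json.dumps({"depth": self.depth, "meta": self.meta})
        np.savez_compressed(path, x_edges=self.x_edges, y_edges=self.y_edges,
                            active=self.active, header=np.bytes_(header.encode()))

    @classmethod
    def load(cls, path) -> "Mesh":
        with np.load(path) as z:
            header = json.loads(bytes(z["header"]).decode())
            return cls(z["x_edges"], z["y_edges"], header["depth"],
                       z["active"], header.get("meta", {}))


@dataclass
class Section:
    """Interior faces crossed by a coronal cut, split at the fin midline."""

    x: float
    face_ids: np.ndarray      # indices into the mesh's interior-face arrays
    dorsal: np.ndarray        # boolean mask over face_ids
    areas: np.ndarray
    split_y: float

    @property
    def ventral(self) -> np.ndarray:
        return ~self.dorsal

    @property
    def area(self) -> float:
        return float(self.areas.sum())


# -------------------------------------------------------------- construction

def _graded_heights(length: float, target: float, layers: int,
                    ratio: float) -> np.ndarray:
    """Cell heights across one wall-bounded interval, graded at both ends."""
    n_uniform = max(int(round(length / target)), 1)
    if layers <= 0:
        return np.full(n_uniform, length / n_uniform)
    h1 = target / ratio ** (layers - 1)
    g = h1 * ratio ** np.arange(layers)
    core = length - 2 * g.sum()
    if core < target:                       # interval too thin to grade
        return np.full(n_uniform, length / n_uniform)
    n_core = max(int(round(core / target)), 1)
    heights = np.concatenate([g, np.full(n_core, core / n_core), g[::-1]])
    return heights * (length / heights.sum())


def _segment_edges(breaks: np.ndarray, target: float) -> np.ndarray:
    """Uniform subdivision of each segment between breakpoints."""
    edges = [breaks[0]]
    for a, b in zip(breaks[:-1], breaks[1:]):
        if b - a <= 1e-15:
            continue
        n = max(int(round((b - a) / target)), 1)
        edges.extend(np.linspace(a, b, n + 1)[1:])
    return np.asarray(edges)


def build_mesh(geometry: PhantomSpec | ImageStack, target_cell_um: float,
               wall_layers: int = 0, growth_ratio: float = 1.2,
               depth_um: float | None = None,
               x_cell_um: float | None = None,
               y_counts: tuple | None = None) -> Mesh:
    """Build a masked FV mesh from a phantom spec or a mask stack section.

    ``target_cell_um`` is the nominal cell size across channels (y); every
    channel must be resolved by at least 8 cells across its width.
    ``x_cell_um`` optionally sets a coarser axial cell size (long straight
    passages resolve axial gradients at much larger steps).  ``y_counts``
    pins the cell count of each y interval (ventral channel, fin, dorsal
    channel) so that paired geometries can be meshed at matched counts; it
    applies to ungraded (wall_layers = 0) spec meshes only.
    """
    if isinstance(geometry, PhantomSpec):
        return _mesh_from_spec(geometry, target_cell_um, wall_layers,
                               growth_ratio, depth_um, x_cell_um, y_counts)
    if isinstance(geometry, ImageStack):
        return _mesh_from_stack(geometry, target_cell_um, depth_um)
    raise TypeError("geometry must be a PhantomSpec or an ImageStack")


def _mesh_from_spec(spec: PhantomSpec, target_um: float, wall_layers: int,
                    growth_ratio: float, depth_um: float | None,
                    x_cell_um: float | None = None,
                    y_counts: tuple | None = None) -> Mesh:
    t = target_um * UM
    tx = (x_cell_um if x_cell_um is not None else target_um) * UM
    depth = (spec.depth if depth_um is None else depth_um) * UM
    channels = {"lumen": spec.inlet_height}
    if spec.has_fin:
        channels = {"dorsal": spec.dorsal_width, "ventral": spec.ventral_width}
    for name, w in channels.items():
        if w / target_um < 8 - 1e-9:
            raise ResolutionError(
                f"{name} channel ({w} µm) resolved by fewer than 8 cells "
                f"at target {target_um} µm")
    if y_counts is not None and spec.has_fin \
            and min(y_counts[0], y_counts[-1]) < 8:
        raise ResolutionError("y_counts resolve a channel with fewer than "
                              "8 cells")

    xb = np.unique(np.array([0.0, spec.squamous_end, spec.respiratory_end,
                             spec.olfactory_end, spec.fin_start, spec.fin_end,
                             spec.total_length]) * UM)
    x_edges = _segment_edges(xb, tx)

    if spec.has_fin:
        intervals = [(0.0, spec.fin_bottom), (spec.fin_bottom, spec.fin_top),
                     (spec.fin_top, spec.inlet_height)]
    else:
        intervals = [(0.0, spec.inlet_height)]
    if y_counts is not None and len(y_counts) != len(intervals):
        raise ValueError("y_counts must give one cell count per y interval")
    y_parts = [np.array([0.0])]
    for k, (a, b) in enumerate(intervals):
        if y_counts is not None and wall_layers == 0:
            n = int(y_counts[k])
            h = np.full(n, (b - a) * UM / n)
        else:
            h = _graded_heights((b - a) * UM, t, wall_layers, growth_ratio)
        y_parts.append(a * UM + np.cumsum(h))
    y_edges = np.unique(np.concatenate(y_parts))

    xc = 0.5 * (x_edges[:-1] + x_edges[1:])
    yc = 0.5 * (y_edges[:-1] + y_edges[1:])
    active = spec.contains(xc[:, None] / UM, yc[None, :] / UM)
    meta = {
        "build": {"target_cell_um": target_um, "wall_layers": wall_layers,
                  "growth_ratio": growth_ratio, "depth_um": depth / UM,
                  "x_cell_um": tx / UM,
                  "y_counts": list(y_counts) if y_counts is not None else None,
                  "source": "spec"},
        "spec": spec.to_dict(),
        # dorsal walls posterior of olfactory_end (the merged nasopharynx
        # tube) count as respiratory epithelium
        "regions": {"squamous_end_m": spec.squamous_end * UM,
                    "olfactory_start_m": spec.olfactory_start * UM,
                    "olfactory_end_m": spec.olfactory_end * UM,
                    "fin_midline_m": spec.fin_midline * UM},
    }
    return Mesh(x_edges, y_edges, depth, active, meta)


def _mesh_from_stack(stack: ImageStack, target_um: float,
                     depth_um: float | None) -> Mesh:
    mask, dx_um, dy_um = stack.mid_sagittal()
    margin = stack.meta.get("margin_px", 0)
    y0_um = -margin * dy_um                      # raster-bottom y in spec frame
    nx_pix, ny_pix = mask.shape
    length_um = nx_pix * dx_um
    height_um = ny_pix * dy_um

    x_edges = _segment_edges(np.array([0.0, length_um * UM]), target_um * UM)
    y_edges = _segment_edges(np.array([y0_um, y0_um + height_um]) * UM,
                             target_um * UM)
    xc = 0.5 * (x_edges[:-1] + x_edges[1:])
    yc = 0.5 * (y_edges[:-1] + y_edges[1:])
    pi = np.clip((xc / (dx_um * UM)).astype(int), 0, nx_pix - 1)
    pj = np.clip(((yc - y0_um * UM) / (dy_um * UM)).astype(int), 0, ny_pix - 1)
    active = mask[pi[:, None], pj[None, :]]

    runs = _min_channel_run(active)
    if runs < 8:
        raise ResolutionError(
            f"a channel is resolved by only {runs} cells at target "
            f"{target_um} µm")

    meta = {"build": {"target_cell_um": target_um, "wall_layers": 0,
                      "growth_ratio": 1.0,
                      "depth_um": depth_um, "source": "stack"}}
    spec_d = stack.meta.get("spec")
    if spec_d is not None:
        meta["spec"] = spec_d
        meta["regions"] = {
            "squamous_end_m": spec_d["squamous_end"] * UM,
            "olfactory_start_m": spec_d["respiratory_end"] * UM,
            "olfactory_end_m": spec_d["olfactory_end"] * UM,
            "fin_midline_m": (spec_d["ventral_width"]
                              + spec_d["fin_thickness"] / 2) * UM,
        }
        if depth_um is None:
            meta["build"]["depth_um"] = spec_d["depth"]
    if meta["build"]["depth_um"] is None:
        raise ValueError("depth_um required for stacks without spec metadata")
    return Mesh(x_edges, y_edges, meta["build"]["depth_um"] * UM, active, meta)


def _min_channel_run(active: np.ndarray) -> int:
    """Shortest vertical run of active cells over all grid columns."""
    best = np.inf
    for col in active:
        if not col.any():
            continue
        padded = np.concatenate([[0], col.view(np.int8), [0]])
        d = np.diff(padded)
        runs = np.nonzero(d == -1)[0] - np.nonzero(d == 1)[0]
        best = min(best, runs.min())
    return int(best)


def refine_mesh(mesh: Mesh, factor: int) -> Mesh:
    """Rebuild the mesh at ``target_cell_size / factor`` (same geometry)."""
    if factor not in (2, 3, 4):
        raise ValueError("factor must be in {2, 3, 4}")
    build = mesh.meta.get("build")
    if build is None or build.get("source") != "spec":
        raise ValueError("only spec-derived meshes can be refined")
    if mesh.n_cells * factor ** 2 > MAX_CELLS:
        raise MeshSizeError(
            f"refinement would exceed {MAX_CELLS} cells")
    spec = PhantomSpec.from_dict(mesh.meta["spec"])
    yc = build.get("y_counts")
    return _mesh_from_spec(spec, build["target_cell_um"] / factor,
                           build["wall_layers"], build["growth_ratio"],
                           build["depth_um"],
                           build.get("x_cell_um", build["target_cell_um"])
                           / factor,
                           tuple(n * factor for n in yc) if yc else None)


def cross_section(mesh: Mesh, x: float, split_y: float | None = None) -> Section:
    """Interior x-normal faces at the grid line nearest ``x`` (strictly
    inside the domain), partitioned into dorsal/ventral at ``split_y``
    (default: the fin midline from the mesh metadata)."""
    if not (mesh.x_edges[0] < x < mesh.x_edges[-1]):
        raise ValueError("section position must be strictly inside the domain")
    k = int(np.argmin(np.abs(mesh.x_edges[1:-1] - x))) + 1
    x_line = mesh.x_edges[k]
    ids = np.nonzero((mesh.int_axis == 0)
                     & (np.abs(mesh.int_x - x_line) < 1e-12))[0]
    if ids.size == 0:
        raise EmptySectionError(f"no lumen at x = {x} m")
    if split_y is None:
        split_y = mesh.meta.get("regions", {}).get("fin_midline_m")
        if split_y is None:
            split_y = 0.5 * (mesh.y_edges[0] + mesh.y_edges[-1])
    dorsal = mesh.int_y[ids] >= split_y
    return Section(x_line, ids, dorsal, mesh.int_area[ids], split_y)
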