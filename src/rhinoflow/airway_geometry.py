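"""Synthetic airway phantoms as binary image stacks.

The phantom emulates a segmented left nasal airway at desk scale: a single
anterior inlet lumen (squamous-lined), a passage splitting around a septum fin
into a narrow dorsal "olfactory" channel and a wider ventral "respiratory"
channel, and a merged posterior outlet.  Geometry is carried either as an
analytic :class:`PhantomSpec` or as a rasterized binary :class:`ImageStack`
(ordered coronal slices with physical pixel spacing), the same substrate an
MRI segmentation pipeline would produce.

The uniform sub-pixel airway widening operation works on stacks: each slice is
upsampled (nearest-neighbour, labels only), and the airway is grown by
thresholding the Euclidean distance transform of the tissue side, so every
boundary point moves outward along its in-plane normal by a prescribed
micrometer distance.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import measure

__all__ = [
    "PhantomSpec",
    "ImageStack",
    "GeometryError",
    "ResolutionError",
    "generate_phantom",
    "widen_airway",
    "read_stack",
    "write_stack",
    "airway_metrics",
    "box_phantom",
]

UM = 1e-6  # meters per micrometer


class GeometryError(ValueError):
    """Phantom specification is geometrically inconsistent."""


class ResolutionError(ValueError):
    """Requested raster/mesh resolution cannot resolve a channel."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric two-channel airway phantom.  All lengths in micrometers.

    The lumen occupies ``0 <= y <= inlet_height`` (y runs ventral -> dorsal).
    Over the fin's axial extent a septum fin of ``fin_thickness`` separates a
    dorsal channel of width ``dorsal_width`` (top) from a ventral channel of
    width ``ventral_width`` (bottom); the three must tile the lumen height.
    ``region_bounds`` gives the axial extents of the squamous, respiratory and
    olfactory epithelium zones, tiling ``[0, total_length]``.
    """

    total_length: float = 20_000.0
    inlet_height: float = 1_700.0
    dorsal_width: float = 400.0
    ventral_width: float = 1_000.0
    fin_start: float = 2_500.0
    fin_end: float = 19_000.0
    fin_thickness: float = 300.0
    squamous_end: float = 2_500.0
    respiratory_end: float = 5_000.0
    olfactory_end: float = 18_500.0
    pixel_spacing: float = 50.0
    slice_thickness: float = 200.0
    depth: float = 5_000.0
    widening_delta: float = 34.0
    widening_mode: str = "total-width"

    def __post_init__(self) -> None:
        for name in ("total_length", "inlet_height", "dorsal_width",
                     "ventral_width", "fin_thickness", "pixel_spacing",
                     "slice_thickness", "depth"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")
        if self.widening_delta < 0:
            raise GeometryError("widening_delta must be >= 0")
        if self.widening_mode not in ("total-width", "per-wall"):
            raise GeometryError(f"unknown widening_mode {self.widening_mode!r}")
        if not (0 <= self.squamous_end <= self.respiratory_end
                <= self.olfactory_end <= self.total_length):
            raise GeometryError("region bounds must tile [0, total_length]")
        if not (0 <= self.fin_start <= self.fin_end <= self.total_length):
            raise GeometryError("fin axial extent out of range")
        if self.has_fin:
            want = self.dorsal_width + self.ventral_width + self.fin_thickness
            if abs(want - self.inlet_height) > 1e-9 * self.inlet_height:
                raise GeometryError(
                    "dorsal_width + ventral_width + fin_thickness must equal "
                    f"inlet_height (got {want} vs {self.inlet_height})")
            if self.dorsal_width > self.ventral_width:
                raise GeometryError("the dorsal (olfactory) channel must not "
                                    "be wider than the ventral one")
            if self.pixel_spacing > min(self.dorsal_width, self.ventral_width) / 5:
                raise ResolutionError(
                    "pixel_spacing must be <= min channel width / 5")

    @property
    def has_fin(self) -> bool:
        return self.fin_end > self.fin_start

    @property
    def fin_bottom(self) -> float:
        """y of the fin's ventral face (µm)."""
        return self.ventral_width

    @property
    def fin_top(self) -> float:
        return self.ventral_width + self.fin_thickness

    @property
    def fin_midline(self) -> float:
        """y separating the dorsal from the ventral subsection (µm)."""
        if self.has_fin:
            return 0.5 * (self.fin_bottom + self.fin_top)
        return 0.5 * self.inlet_height

    @property
    def olfactory_start(self) -> float:
        return self.respiratory_end

    def widened(self, delta: float | None = None, mode: str | None = None) -> "PhantomSpec":
        """Analytically widened spec: every wall recedes by ``delta`` (per-wall
        mode) or ``delta/2`` (total-width mode, so each channel gains ``delta``).

        The lumen grows at its outer walls and the fin thins from both faces
        and both axial ends; epithelium region bounds are unchanged (they name
        tissue zones, not lumen surfaces).
        """
        d = self.widening_delta if delta is None else float(delta)
        m = self.widening_mode if mode is None else mode
        if d < 0:
            raise GeometryError("delta must be >= 0")
        r = d if m == "per-wall" else d / 2.0  # recession per wall
        if self.has_fin and self.fin_thickness - 2 * r <= 0:
            raise GeometryError("widening would consume the septum fin")
        return dataclasses.replace(
            self,
            inlet_height=self.inlet_height + 2 * r,
            dorsal_width=self.dorsal_width + 2 * r,
            ventral_width=self.ventral_width + 2 * r,
            fin_thickness=self.fin_thickness - 2 * r,
            fin_start=min(self.fin_start + r, self.fin_end - r),
            fin_end=max(self.fin_end - r, self.fin_start + r),
        )

    # lumen occupancy test used by the rasterizer and the mesher -------------
    def contains(self, x_um: np.ndarray, y_um: np.ndarray) -> np.ndarray:
        """Boolean airway membership for broadcastable µm coordinates."""
        x = np.asarray(x_um, dtype=float)
        y = np.asarray(y_um, dtype=float)
        inside = (x >= 0) & (x <= self.total_length) & \
                 (y >= 0) & (y <= self.inlet_height)
        if self.has_fin:
            in_fin = (x >= self.fin_start) & (x <= self.fin_end) & \
                     (y > self.fin_bottom) & (y < self.fin_top)
            inside &= ~in_fin
        return inside

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        return cls(**d)


@dataclass
class ImageStack:
    """Ordered binary coronal rasters with physical spacing.

    Axis convention: ``slices[s, r, c]`` with slice index ``s`` anterior ->
    posterior (x), raster row ``r`` dorsal -> ventral (descending y), column
    ``c`` lateral (z).  Values are 0 (tissue) / 1 (airway) at pixel centers;
    spacings in micrometers.
    """

    slices: np.ndarray
    pixel_spacing: float
    slice_thickness: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices)
        if self.slices.ndim != 3:
            raise ValueError("slices must be a (n_slices, rows, cols) array")
        if not np.isin(self.slices, (0, 1)).all():
            bad = [i for i, s in enumerate(self.slices)
                   if not np.isin(s, (0, 1)).all()]
            raise ValueError(f"non-binary pixel values in slices {bad}")
        if self.pixel_spacing <= 0 or self.slice_thickness <= 0:
            raise ValueError("spacings must be positive")
        if self.slices.sum() == 0:
            raise ValueError("airway voxel count must be positive")
        self.slices = self.slices.astype(np.uint8)

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]

    @property
    def shape(self) -> tuple:
        return self.slices.shape

    def mid_sagittal(self) -> tuple[np.ndarray, float, float]:
        """(mask[x, y], axial spacing µm, vertical spacing µm) of the central
        lateral column, with y ascending ventral -> dorsal."""
        col = self.slices.shape[2] // 2
        sect = self.slices[:, ::-1, col]  # flip rows so index 1 ascends in y
        return sect.astype(bool), self.slice_thickness, self.pixel_spacing


def generate_phantom(spec: PhantomSpec) -> ImageStack:
    """Rasterize a phantom spec into a binary coronal image stack.

    Deterministic: pixel centers are tested against the analytic lumen.  The
    lumen spans a fixed lateral band of ``spec.depth`` µm centered in the
    slice, with a two-pixel tissue margin on every side.
    """
    p = spec.pixel_spacing
    n_slices = int(round(spec.total_length / spec.slice_thickness))
    if n_slices < 1:
        raise GeometryError("slice_thickness exceeds total_length")
    margin = 2
    n_rows = int(np.ceil(spec.inlet_height / p)) + 2 * margin
    n_cols = int(np.ceil(spec.depth / p)) + 2 * margin
    if spec.has_fin and (spec.dorsal_width < 2 * p or spec.ventral_width < 2 * p):
        raise ResolutionError("channels unresolvable at given pixel_spacing")

    # pixel-center coordinates
    x = (np.arange(n_slices) + 0.5) * spec.slice_thickness
    y = (np.arange(n_rows)[::-1] + 0.5 - margin) * p  # row 0 = dorsal-most
    mask2d = spec.contains(x[:, None], y[None, :])     # (slice, row)
    slices = np.repeat(mask2d[:, :, None], n_cols, axis=2)
    # lateral margins are tissue
    slices[:, :, :margin] = False
    slices[:, :, n_cols - margin:] = False
    meta = {"spec": spec.to_dict(), "margin_px": margin}
    return ImageStack(slices.astype(np.uint8), p, spec.slice_thickness, meta)


def widen_airway(stack: ImageStack, delta_um: float, mode: str = "total-width",
                 upsample_factor: int = 1) -> ImageStack:
    """Uniformly widen the airway of a mask stack by ``delta_um``.

    Each slice is upsampled ``upsample_factor``-fold (nearest neighbour), then
    the airway is dilated in-plane by thresholding the Euclidean distance
    transform of the tissue side at the per-wall recession distance:
    ``delta_um`` in per-wall mode, ``delta_um / 2`` in total-width mode (the
    local channel width then grows by ``delta_um``).  Output pixel spacing is
    ``stack.pixel_spacing / upsample_factor``; slice thickness is unchanged
    (the operation is slice-wise, like slice-by-slice segmentation editing).

    If the dilation merges previously distinct airway components in any slice
    (e.g. across the septum), a topology-change warning is recorded in the
    result's ``meta['topology_warnings']`` and emitted via ``warnings``.
    """
    if delta_um < 0:
        raise ValueError("delta must be >= 0")
    if mode not in ("total-width", "per-wall"):
        raise ValueError(f"unknown widening mode {mode!r}")
    if int(upsample_factor) != upsample_factor or upsample_factor < 1:
        raise ValueError("upsample_factor must be an integer >= 1")
    upsample_factor = int(upsample_factor)
    out_spacing = stack.pixel_spacing / upsample_factor
    recession = delta_um if mode == "per-wall" else delta_um / 2.0
    if delta_um > 0 and out_spacing > delta_um / 4:
        raise ResolutionError(
            f"upsampled pixel spacing {out_spacing} µm exceeds delta/4; "
            "increase upsample_factor")

    if delta_um == 0 and upsample_factor == 1:
        return ImageStack(stack.slices.copy(), stack.pixel_spacing,
                          stack.slice_thickness, dict(stack.meta))

    out = np.empty((stack.n_slices,
                    stack.shape[1] * upsample_factor,
                    stack.shape[2] * upsample_factor), dtype=np.uint8)
    topo_warnings: list[str] = []
    for s in range(stack.n_slices):
        sl = np.repeat(np.repeat(stack.slices[s], upsample_factor, axis=0),
                       upsample_factor, axis=1)
        if recession > 0:
            n0, _ = _component_count(sl)
            dist = ndimage.distance_transform_edt(sl == 0,
                                                  sampling=out_spacing)
            sl = ((sl == 1) | (dist <= recession)).astype(np.uint8)
            n1, _ = _component_count(sl)
            if 0 < n1 < n0:
                topo_warnings.append(
                    f"slice {s}: airway components merged ({n0} -> {n1})")
        out[s] = sl
    meta = dict(stack.meta)
    meta["widened_by_um"] = meta.get("widened_by_um", 0.0) + delta_um
    meta["widening_mode"] = mode
    if topo_warnings:
        meta["topology_warnings"] = topo_warnings
        warnings.warn("airway widening changed slice topology: "
                      + "; ".join(topo_warnings), stacklevel=2)
    return ImageStack(out, out_spacing, stack.slice_thickness, meta)


def _component_count(mask: np.ndarray) -> tuple[int, np.ndarray]:
    lab, n = ndimage.label(mask)
    return n, lab


# ---------------------------------------------------------------------- I/O

_SIDECAR = "stack.json"


def write_stack(stack: ImageStack, path: str | Path, fmt: str = "png") -> Path:
    """Write a stack as numbered single-channel rasters + a JSON sidecar."""
    import imageio.v3 as iio

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if fmt not in ("png", "tif", "tiff"):
        raise ValueError(f"unsupported raster format {fmt!r}")
    width = len(str(stack.n_slices - 1))
    names = []
    for i, sl in enumerate(stack.slices):
        name = f"slice_{i:0{width}d}.{fmt}"
        iio.imwrite(path / name, (sl * 255).astype(np.uint8))
        names.append(name)
    sidecar = {
        "pixel_spacing_um": stack.pixel_spacing,
        "slice_thickness_um": stack.slice_thickness,
        "axis_order": "slice=anterior->posterior, row=dorsal->ventral, col=lateral",
        "slices": names,
        "meta": _jsonable(stack.meta),
    }
    (path / _SIDECAR).write_text(json.dumps(sidecar, indent=1))
    return path


def read_stack(path: str | Path) -> ImageStack:
    """Read a stack directory written by :func:`write_stack`.

    Round-trips bitwise, including spacings.  Raises on a missing sidecar,
    non-binary pixel values (listing offending slices) or mismatched shapes.
    """
    import imageio.v3 as iio

    path = Path(path)
    sidecar_path = path / _SIDECAR
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    for key in ("pixel_spacing_um", "slice_thickness_um", "slices"):
        if key not in sidecar:
            raise ValueError(f"sidecar missing required key {key!r}")
    if sidecar["pixel_spacing_um"] <= 0 or sidecar["slice_thickness_um"] <= 0:
        raise ValueError("sidecar declares non-positive spacing")
    arrays, bad, shapes = [], [], set()
    for name in sidecar["slices"]:
        img = np.asarray(iio.imread(path / name))
        if img.ndim != 2:
            raise ValueError(f"slice {name} is not single-channel")
        vals = set(np.unique(img).tolist())
        if not vals <= {0, 255} and not vals <= {0, 1}:
            bad.append(name)
        arrays.append((img > 0).astype(np.uint8))
        shapes.add(img.shape)
    if bad:
        raise ValueError(f"non-binary pixel values in slices: {bad}")
    if len(shapes) > 1:
        raise ValueError(f"slice shape mismatch: {sorted(shapes)}")
    return ImageStack(np.stack(arrays), sidecar["pixel_spacing_um"],
                      sidecar["slice_thickness_um"], sidecar.get("meta", {}))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


# ------------------------------------------------------------------ metrics

def airway_metrics(stack: ImageStack) -> dict:
    """Per-slice area, total volume and wall-surface estimate, in SI units.

    area[s] = airway pixel count × pixel area; volume = Σ area × slice
    thickness; surface = marching-squares contour perimeter of each slice ×
    slice thickness, summed (in-plane walls only, consistent with the
    slice-extruded geometry).
    """
    p_m = stack.pixel_spacing * UM
    t_m = stack.slice_thickness * UM
    counts = stack.slices.reshape(stack.n_slices, -1).sum(axis=1)
    areas = counts.astype(float) * p_m * p_m
    volume = float(areas.sum() * t_m)
    if counts.sum() == 0:  # unreachable through the constructor, kept for API
        warnings.warn("empty airway: zero metrics")
        return {"slice_areas_m2": areas, "volume_m3": 0.0, "surface_m2": 0.0}
    perim = 0.0
    for sl in stack.slices:
        padded = np.pad(sl, 1).astype(float)
        for contour in measure.find_contours(padded, 0.5):
            d = np.diff(contour, axis=0)
            perim += float(np.hypot(d[:, 0], d[:, 1]).sum()) * p_m
    return {
        "slice_areas_m2": areas,
        "volume_m3": volume,
        "surface_m2": perim * t_m,
    }


def box_phantom(length_um: float, height_um: float, *,
                pixel_spacing_um: float = 50.0,
                slice_thickness_um: float = 200.0,
                depth_um: float = 5_000.0,
                squamous_end_um: float = 0.0,
                mucus_walls: bool = True) -> PhantomSpec:
    """A finless rectangular-lumen phantom (validation channel).

    With ``mucus_walls`` the whole wall is respiratory epithelium (uniform
    mass-transfer walls); otherwise everything is squamous (zero-flux).
    """
    squam = squamous_end_um if mucus_walls else length_um
    return PhantomSpec(
        total_length=length_um, inlet_height=height_um,
        dorsal_width=height_um / 3, ventral_width=height_um / 3,
        fin_start=0.0, fin_end=0.0, fin_thickness=height_um / 3,
        squamous_end=squam, respiratory_end=length_um,
        olfactory_end=length_um,
        pixel_spacing=pixel_spacing_um, slice_thickness=slice_thickness_um,
        depth=depth_um, widening_delta=0.0)
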