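"""Synthetic cardiac-tissue phantoms: label volumes and pseudo-confocal stacks.

The generator emulates the microstructure the analysis pipeline assumes:

* myocytes as rectangular rods along the y (fiber) axis, 14 μm tall,
  staggered half a lattice period per layer (a brick-wall packing — the
  voxelized analogue of hexagonal rod packing), separated by interstitial
  extracellular space;
* laminae of ``layers_per_lamina`` ∈ {3, 4, 5} myocyte layers, separated
  by planar interlaminar clefts normal to z; the cleft-plane spacing is
  ``n·height + (n−1)·interstitial`` — 48, 65 and 82 μm at the default
  height 14 μm and interstitial thickness 3 μm;
* capillaries as cylinders along y seeded in interstitial corridors;
* fibroblasts / myofibroblasts as ellipsoidal cells with DAPI nucleus
  cores, seeded in the interstitium.

Volume-fraction targets are met by steering the brick width and cleft
slab thickness against direct voxel counts (bisection), to within ±2
percentage points; infeasible targets raise
:class:`PhantomInfeasibleError` with an achieved-vs-target table.

Because lattice centers are fixed and steering only widens the
extracellular set, two phantoms that differ only in their extracellular
targets have *nested* conductive sets — the basis for exact monotonicity
checks on homogenized conductivities.

Rendering (:func:`render_channels`) assigns per-domain intensity levels
to the five channels, overlays the WGA-bright glycocalyx shell on every
myocyte surface, nuclei, Cx43 puncta and perivascular signal, then
applies anisotropic PSF blur, exponential depth attenuation and noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.ndimage as ndi

from .volumes import (
    BACKGROUND,
    CLEFT,
    EXTRACELLULAR,
    FIBROBLAST,
    MYOCYTE,
    MYOFIBROBLAST,
    VESSEL,
    ChannelStack,
    LabelVolume,
)

DOMAIN_KEYS = ("myocyte", "extracellular", "cleft", "vessel", "fibroblast",
               "myofibroblast")

#: Group-mean volume-fraction profiles (percent) used as steering targets.
CONTROL_FRACTIONS: Dict[str, float] = {
    "myocyte": 65.03, "extracellular": 24.68, "cleft": 3.95,
    "vessel": 7.71, "fibroblast": 2.48, "myofibroblast": 0.09,
}
REGION1_FRACTIONS: Dict[str, float] = {
    "myocyte": 46.80, "extracellular": 40.53, "cleft": 5.14,
    "vessel": 3.64, "fibroblast": 5.00, "myofibroblast": 4.03,
}
REGION2_FRACTIONS: Dict[str, float] = {
    "myocyte": 50.68, "extracellular": 39.06, "cleft": 5.56,
    "vessel": 3.65, "fibroblast": 4.12, "myofibroblast": 2.48,
}
REGION3_FRACTIONS: Dict[str, float] = {
    "myocyte": 54.51, "extracellular": 35.12, "cleft": 12.84,
    "vessel": 5.87, "fibroblast": 2.69, "myofibroblast": 1.81,
}

#: Base channel intensity level per tissue domain (arbitrary units).
CHANNEL_LEVELS: Dict[str, Dict[int, float]] = {
    "WGA": {BACKGROUND: 0, MYOCYTE: 20, EXTRACELLULAR: 200, CLEFT: 40,
            VESSEL: 25, FIBROBLAST: 35, MYOFIBROBLAST: 35},
    "DAPI": {BACKGROUND: 0, MYOCYTE: 5, EXTRACELLULAR: 5, CLEFT: 5,
             VESSEL: 5, FIBROBLAST: 5, MYOFIBROBLAST: 5},
    "Cx43": {BACKGROUND: 0, MYOCYTE: 2, EXTRACELLULAR: 0, CLEFT: 0,
             VESSEL: 0, FIBROBLAST: 0, MYOFIBROBLAST: 0},
    "aSMA": {BACKGROUND: 0, MYOCYTE: 0, EXTRACELLULAR: 0, CLEFT: 0,
             VESSEL: 0, FIBROBLAST: 0, MYOFIBROBLAST: 130},
    "vimentin": {BACKGROUND: 0, MYOCYTE: 0, EXTRACELLULAR: 0, CLEFT: 0,
                 VESSEL: 0, FIBROBLAST: 150, MYOFIBROBLAST: 150},
}
#: WGA level of the glycocalyx shell lining every myocyte surface.
WGA_RIM_LEVEL = 200.0
#: WGA level of the 1-voxel interface bleed just inside the myocyte surface.
WGA_BLEED_LEVEL = 120.0
#: WGA / aSMA / vimentin levels of the capillary wall (endothelium, pericytes).
VESSEL_WALL_LEVELS = {"WGA": 90.0, "aSMA": 120.0, "vimentin": 100.0}
PERIVASCULAR_VIMENTIN = 80.0
DAPI_NUCLEUS_LEVEL = 180.0
CX43_PUNCTUM_LEVEL = 150.0


class PhantomInfeasibleError(ValueError):
    """Raised when fraction targets cannot be met by the phantom geometry."""

    def __init__(self, message: str, table: Dict[str, Dict[str, float]]):
        super().__init__(message + "\n" + "\n".join(
            f"  {k}: target {v['target']:.2f}%, achieved {v['achieved']:.2f}%"
            for k, v in table.items()))
        self.table = table


def cleft_spacing(layers_per_lamina: int, myocyte_height: float = 14.0,
                  interstitial_thickness: float = 3.0) -> float:
    """Cleft-plane spacing (μm): n·height + (n−1)·interstitial.

    At the defaults this gives one cleft every 48 μm (3 layers per
    lamina) up to one every 82 μm (5 layers).
    """
    n = layers_per_lamina
    if n < 1:
        raise ValueError("layers_per_lamina must be >= 1")
    return n * myocyte_height + (n - 1) * interstitial_thickness


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic tissue phantom.

    Lengths in μm unless noted; ``voxel_size`` in nm.  ``target_fractions``
    maps the six domain names to percentages; the five top-level domains
    (cleft excluded — it is nested inside extracellular) must sum to 100.
    """

    grid_shape: Tuple[int, int, int] = (96, 96, 96)
    voxel_size: float = 200.0  # nm
    target_fractions: Dict[str, float] = field(
        default_factory=lambda: dict(CONTROL_FRACTIONS))
    myocyte_height: float = 14.0
    myocyte_width: float = 20.0
    interstitial_thickness: float = 3.0
    layers_per_lamina: int = 3
    capillary_radius: float = 2.0
    fibroblast_axes: Tuple[float, float, float] = (2.5, 5.0, 2.0)  # semi-axes
    rotation_angle: float = 0.0  # degrees, fiber axis in the x–y plane
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be three positive integers")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.layers_per_lamina not in (3, 4, 5):
            raise ValueError("layers_per_lamina must be one of {3, 4, 5}")
        tf = self.target_fractions
        unknown = set(tf) - set(DOMAIN_KEYS)
        if unknown:
            raise ValueError(f"unknown target domains: {sorted(unknown)}")
        top = sum(tf.get(k, 0.0) for k in DOMAIN_KEYS if k != "cleft")
        if abs(top - 100.0) > 0.01:
            raise ValueError(
                f"top-level targets (cleft excluded) sum to {top:.4f}, not 100")
        if tf.get("cleft", 0.0) > tf.get("extracellular", 0.0) + 1e-9:
            raise ValueError("cleft target exceeds extracellular target")
        if any(v < 0 for v in tf.values()):
            raise ValueError("targets must be non-negative")

    @property
    def spacing(self) -> float:
        """Cleft-plane spacing (μm) implied by the lamina model."""
        return cleft_spacing(self.layers_per_lamina, self.myocyte_height,
                             self.interstitial_thickness)


# ----------------------------------------------------------------------
# label generation
# ----------------------------------------------------------------------

def _z_structure(spec: PhantomSpec) -> Dict[str, np.ndarray]:
    """Per-z-slice layer membership, global layer index and cleft distance."""
    nz = spec.grid_shape[2]
    vs = spec.voxel_size * 1e-3  # μm
    z = (np.arange(nz) + 0.5) * vs
    s = spec.spacing
    z_extent = nz * vs
    z_off = z_extent / 2.0  # a cleft plane sits mid-window
    h, g, n = spec.myocyte_height, spec.interstitial_thickness, spec.layers_per_lamina

    rel = z - z_off
    period = np.floor(rel / s).astype(np.int64)
    u = rel - period * s  # in [0, s)
    i_layer = np.minimum((u / (h + g)).astype(np.int64), n - 1)
    in_layer = (u - i_layer * (h + g)) < h
    global_layer = period * n + i_layer
    cleft_dist = np.minimum(u, s - u)
    cleft_centers = z_off + np.arange(
        np.ceil(-z_off / s), np.floor((z_extent - z_off) / s) + 1) * s
    return {
        "z": z, "u": u, "in_layer": in_layer, "global_layer": global_layer,
        "cleft_dist": cleft_dist, "z_extent": z_extent,
        "cleft_centers": cleft_centers, "z_off": z_off,
    }


def _myocyte_cross_section(spec: PhantomSpec, width: float,
                           zs: Dict[str, np.ndarray]) -> np.ndarray:
    """Boolean (nx, nz) cross-section of the myocyte bricks at given width."""
    nx = spec.grid_shape[0]
    vs = spec.voxel_size * 1e-3
    x = (np.arange(nx) + 0.5) * vs
    period = spec.myocyte_width + spec.interstitial_thickness

    def in_brick(offset: float) -> np.ndarray:
        # quarter-voxel lattice shift: the two brick edges then cross voxel
        # centers at different widths, halving the steering quantization
        v = (x - offset - 0.25 * vs) % period
        return (v >= (period - width) / 2.0) & (v < (period + width) / 2.0)

    brick = np.stack([in_brick(0.0), in_brick(period / 2.0)])  # parity 0 / 1
    parity = (zs["global_layer"] % 2).astype(np.int64)
    return zs["in_layer"][None, :] & brick[parity].T  # (nx, nz)


def _broadcast_xz(mask2d: np.ndarray, shape: Tuple[int, int, int]) -> np.ndarray:
    return np.broadcast_to(mask2d[:, None, :], shape)


#: Capillary segments span this fraction of the y window.  Finite segments
#: (rather than rods crossing the whole stack) mirror the interrupted
#: capillary network and keep interstitial sheets percolating around them.
_VESSEL_LENGTH_FRACTION = 0.8


@dataclass
class _Cylinder:
    cx: float
    cz: float
    r: float
    y0: float = 0.0
    y1: float = np.inf


@dataclass
class _Ellipsoid:
    center: Tuple[float, float, float]
    axes: Tuple[float, float, float]
    code: int


def _corridor_center_x(x: float, parity: int, period: float) -> float:
    offset = parity * period / 2.0
    return offset + period * round((x - offset) / period)


def _sample_vessels(spec: PhantomSpec, zs: Dict[str, np.ndarray],
                    rng: np.random.Generator,
                    cleft_thickness: float = 0.0) -> List[_Cylinder]:
    tf = spec.target_fractions
    target = tf.get("vessel", 0.0)
    if target <= 0:
        return []
    vs = spec.voxel_size * 1e-3
    nx, ny, nz = spec.grid_shape
    X, Y, Z = nx * vs, ny * vs, zs["z_extent"]
    r0 = spec.capillary_radius
    seg_len = _VESSEL_LENGTH_FRACTION * Y
    target_vol = target / 100.0 * X * Y * Z
    n_vessels = max(1, int(round(target_vol / (np.pi * r0 ** 2 * seg_len))))
    r = float(np.sqrt(target_vol / (n_vessels * np.pi * seg_len)))
    period = spec.myocyte_width + spec.interstitial_thickness
    h, g = spec.myocyte_height, spec.interstitial_thickness
    s = spec.spacing

    placed: List[_Cylinder] = []
    attempts = 0
    max_attempts = 400 * n_vessels
    while len(placed) < n_vessels and attempts < max_attempts:
        attempts += 1
        pinned = attempts < max_attempts // 2
        cz = float(rng.uniform(r, max(Z - r, r)))
        # stay clear of the cleft slabs (half thickness plus a margin)
        clear = r + cleft_thickness / 2.0 + 2.0 * vs
        if np.min(np.abs(zs["cleft_centers"] - cz)) < clear:
            continue
        cx = float(rng.uniform(0, X))
        if pinned:
            rel = cz - zs["z_off"]
            per = np.floor(rel / s)
            u = rel - per * s
            layer = min(int(u // (h + g)), spec.layers_per_lamina - 1)
            parity = int((per * spec.layers_per_lamina + layer) % 2)
            cx = _corridor_center_x(cx, parity, period)
        if not (r * 0.5 <= cx <= X - r * 0.5):
            continue
        if any((c.cx - cx) ** 2 + (c.cz - cz) ** 2 < (2 * r + vs) ** 2
               for c in placed):
            continue
        y0 = float(rng.uniform(0.0, Y - seg_len)) if Y > seg_len else 0.0
        placed.append(_Cylinder(cx=cx, cz=cz, r=r, y0=y0, y1=y0 + seg_len))
    if len(placed) < n_vessels:
        warnings.warn(
            f"placed only {len(placed)}/{n_vessels} capillaries; "
            "vessel fraction may fall short of target")
    return placed


def _cell_geometry(spec: PhantomSpec, zs: Dict[str, np.ndarray],
                   target: float) -> Tuple[int, Tuple[float, float, float]]:
    """Cell count and (scaled) semi-axes meeting a fraction target."""
    vs = spec.voxel_size * 1e-3
    nx, ny, nz = spec.grid_shape
    total_vol = nx * vs * ny * vs * zs["z_extent"]
    ax0 = np.array(spec.fibroblast_axes, dtype=float)
    cell_vol = 4.0 / 3.0 * np.pi * np.prod(ax0)
    target_vol = target / 100.0 * total_vol
    n_cells = max(1, int(round(target_vol / cell_vol)))
    scale = (target_vol / (n_cells * cell_vol)) ** (1.0 / 3.0)
    return n_cells, tuple(float(a) for a in ax0 * scale)


def _sample_cells(spec: PhantomSpec, zs: Dict[str, np.ndarray],
                  vessels: Sequence[_Cylinder], rng: np.random.Generator,
                  code: int, n_cells: int, axes: Tuple[float, float, float],
                  existing: Sequence[_Ellipsoid] = (),
                  cleft_thickness: float = 0.0) -> List[_Ellipsoid]:
    if n_cells <= 0:
        return []
    vs = spec.voxel_size * 1e-3
    nx, ny, nz = spec.grid_shape
    X, Y, Z = nx * vs, ny * vs, zs["z_extent"]
    period = spec.myocyte_width + spec.interstitial_thickness
    h, g = spec.myocyte_height, spec.interstitial_thickness
    s = spec.spacing

    placed: List[_Ellipsoid] = list(existing)
    n_target = len(placed) + n_cells
    attempts = 0
    max_attempts = 400 * n_cells
    while len(placed) < n_target and attempts < max_attempts:
        attempts += 1
        # after many failures, stop pinning cells to corridor centerlines
        pinned = attempts < max_attempts // 2
        cz = float(rng.uniform(min(axes[2], Z / 2), max(Z - axes[2], Z / 2)))
        clear_z = axes[2] + cleft_thickness / 2.0 + 1.0 * vs
        if np.min(np.abs(zs["cleft_centers"] - cz)) < clear_z:
            continue
        cx = float(rng.uniform(0, X))
        if pinned:
            rel = cz - zs["z_off"]
            per = np.floor(rel / s)
            u = rel - per * s
            layer = min(int(u // (h + g)), spec.layers_per_lamina - 1)
            parity = int((per * spec.layers_per_lamina + layer) % 2)
            cx = _corridor_center_x(cx, parity, period)
        if not (axes[0] * 0.5 <= cx <= X - axes[0] * 0.5):
            continue
        cy = float(rng.uniform(min(axes[1], Y / 2), max(Y - axes[1], Y / 2)))
        # fibroblasts / myofibroblasts are the non-vessel-associated cells:
        # keep their nuclei clearly beyond vessel-proximity range
        clearance = 4.0  # μm beyond the vessel surface
        if any((v.cx - cx) ** 2 + (v.cz - cz) ** 2 < (v.r + clearance) ** 2
               for v in vessels):
            continue
        ok = True
        for c in placed:
            d = np.array([cx, cy, cz]) - np.array(c.center)
            # same-type cells may abut; different types must stay clearly
            # separate so marker-based classification sees distinct bodies
            min_sep = 0.9 if c.code == code else 1.5
            if np.sum((d / (np.array(axes) + np.array(c.axes))) ** 2) < min_sep:
                ok = False
                break
        if not ok:
            continue
        placed.append(_Ellipsoid(center=(cx, cy, cz), axes=axes, code=code))
    new = placed[len(existing):]
    if len(new) < n_cells:
        warnings.warn(
            f"placed only {len(new)}/{n_cells} cells of code {code}; "
            "fraction may fall short of target")
    return new


def _carve_cylinders(labels: np.ndarray, vessels: Sequence[_Cylinder],
                     spec: PhantomSpec, cleft_z: np.ndarray) -> None:
    if not vessels:
        return
    nx, ny, nz = labels.shape
    vs = spec.voxel_size * 1e-3
    x = (np.arange(nx) + 0.5) * vs
    y = (np.arange(ny) + 0.5) * vs
    z = (np.arange(nz) + 0.5) * vs
    for v in vessels:
        mask2d = ((x[:, None] - v.cx) ** 2
                  + (z[None, :] - v.cz) ** 2) <= v.r ** 2
        mask2d &= ~cleft_z[None, :]
        span = (y >= v.y0) & (y < v.y1)
        sub = labels[:, span, :]
        sub[np.broadcast_to(mask2d[:, None, :], sub.shape)] = VESSEL
        labels[:, span, :] = sub


def _carve_ellipsoids(labels: np.ndarray, cells: Sequence[_Ellipsoid],
                      spec: PhantomSpec) -> None:
    vs = spec.voxel_size * 1e-3
    for c in cells:
        lo = [max(0, int((c.center[i] - c.axes[i]) / vs) - 1) for i in range(3)]
        hi = [min(labels.shape[i], int((c.center[i] + c.axes[i]) / vs) + 2)
              for i in range(3)]
        if any(l >= h for l, h in zip(lo, hi)):
            continue
        grids = np.meshgrid(*[(np.arange(lo[i], hi[i]) + 0.5) * vs
                              for i in range(3)], indexing="ij")
        d2 = sum(((grids[i] - c.center[i]) / c.axes[i]) ** 2 for i in range(3))
        box = tuple(slice(l, h) for l, h in zip(lo, hi))
        sub = labels[box]
        sel = (d2 <= 1.0) & (sub != VESSEL) & (sub != CLEFT)
        sub[sel] = c.code
        labels[box] = sub


def _measure(labels: np.ndarray) -> Dict[str, float]:
    counts = np.bincount(labels.ravel(), minlength=7)
    total = counts[1:].sum()
    pct = 100.0 * counts / max(total, 1)
    return {
        "myocyte": pct[MYOCYTE],
        "extracellular": pct[EXTRACELLULAR] + pct[CLEFT],
        "cleft": pct[CLEFT],
        "vessel": pct[VESSEL],
        "fibroblast": pct[FIBROBLAST],
        "myofibroblast": pct[MYOFIBROBLAST],
    }


def generate_labels(
    spec: PhantomSpec,
    tolerance: float = 2.0,
    return_report: bool = False,
):
    """Generate a label volume meeting the spec's fraction targets.

    Deterministic for a fixed spec (including its seed).  The brick width
    is steered by bisection against direct voxel counts until the myocyte
    fraction matches its target; the cleft slab thickness is set from the
    cleft target and the number of cleft planes inside the window.
    Achieved fractions outside ``tolerance`` percentage points of any
    target raise :class:`PhantomInfeasibleError`.
    """
    tf = {k: float(spec.target_fractions.get(k, 0.0)) for k in DOMAIN_KEYS}

    # Degenerate single-domain phantom.
    for key, code in (("myocyte", MYOCYTE), ("extracellular", EXTRACELLULAR),
                      ("vessel", VESSEL), ("fibroblast", FIBROBLAST),
                      ("myofibroblast", MYOFIBROBLAST)):
        if tf[key] >= 100.0 - 1e-9:
            labels = np.full(spec.grid_shape, code, dtype=np.uint8)
            vol = LabelVolume(labels=labels, voxel_size=spec.voxel_size,
                              meta={"spec": spec, "achieved": _measure(labels)})
            return (vol, vol.meta["achieved"]) if return_report else vol

    zs = _z_structure(spec)
    vs = spec.voxel_size * 1e-3
    rng = np.random.default_rng(spec.seed)

    # Cleft slab thickness from the cleft target and planes in the window.
    n_planes = len(zs["cleft_centers"])
    if tf["cleft"] > 0 and n_planes > 0:
        t_c = tf["cleft"] / 100.0 * zs["z_extent"] / n_planes
        t_c = max(t_c, vs)  # at least one voxel
    else:
        t_c = 0.0
    cleft_z = zs["cleft_dist"] < t_c / 2.0

    vessels = _sample_vessels(spec, zs, rng, cleft_thickness=t_c)
    n_f, axes_f = _cell_geometry(spec, zs, tf["fibroblast"])
    n_m, axes_m = _cell_geometry(spec, zs, tf["myofibroblast"])
    fibros = _sample_cells(spec, zs, vessels, rng, FIBROBLAST,
                           n_f if tf["fibroblast"] > 0 else 0, axes_f,
                           cleft_thickness=t_c)
    myofibros = _sample_cells(spec, zs, vessels, rng, MYOFIBROBLAST,
                              n_m if tf["myofibroblast"] > 0 else 0, axes_m,
                              existing=fibros, cleft_thickness=t_c)

    def build(width: float) -> np.ndarray:
        myo2d = _myocyte_cross_section(spec, width, zs)
        labels = np.where(_broadcast_xz(myo2d, spec.grid_shape), MYOCYTE,
                          EXTRACELLULAR).astype(np.uint8)
        if cleft_z.any():
            labels[:, :, cleft_z] = CLEFT
        _carve_cylinders(labels, vessels, spec, cleft_z)
        _carve_ellipsoids(labels, fibros + myofibros, spec)
        return labels

    period = spec.myocyte_width + spec.interstitial_thickness
    target_myo = tf["myocyte"]

    def steer() -> Tuple[float, np.ndarray]:
        lo, hi = 0.0, period
        f_hi = _measure(build(hi))["myocyte"]
        if f_hi < target_myo - tolerance:
            achieved = _measure(build(hi))
            raise PhantomInfeasibleError(
                "myocyte target exceeds the geometric maximum of this packing",
                {k: {"target": tf[k], "achieved": achieved[k]}
                 for k in DOMAIN_KEYS})
        width = hi
        if f_hi > target_myo:
            for _ in range(40):
                width = 0.5 * (lo + hi)
                if _measure(build(width))["myocyte"] > target_myo:
                    hi = width
                else:
                    lo = width
                if hi - lo < 0.2 * vs:
                    break
            width = 0.5 * (lo + hi)
        return width, build(width)

    # Steer the brick width, then top up cell counts where carving overlap
    # losses leave fibroblast / myofibroblast fractions short, and re-steer.
    total_vox = float(np.prod(spec.grid_shape))
    for _round in range(4):
        width, labels = steer()
        achieved = _measure(labels)
        topped_up = False
        for code, cells, axes_c, key in (
                (FIBROBLAST, fibros, axes_f, "fibroblast"),
                (MYOFIBROBLAST, myofibros, axes_m, "myofibroblast")):
            deficit = tf[key] - achieved[key]
            if tf[key] > 0 and deficit > 0.5 * tolerance:
                pct_per_cell = (4.0 / 3.0 * np.pi * np.prod(axes_c)
                                / (vs ** 3) / total_vox * 100.0)
                extra = int(np.ceil(deficit / pct_per_cell))
                new = _sample_cells(spec, zs, vessels, rng, code, extra,
                                    axes_c, existing=fibros + myofibros,
                                    cleft_thickness=t_c)
                cells.extend(new)
                topped_up = topped_up or bool(new)
        if not topped_up:
            break
    if spec.rotation_angle != 0.0:
        labels = ndi.rotate(labels, spec.rotation_angle, axes=(0, 1),
                            reshape=False, order=0, mode="constant",
                            cval=BACKGROUND)
    achieved = _measure(labels)
    table = {k: {"target": tf[k], "achieved": achieved[k]} for k in DOMAIN_KEYS}
    if spec.rotation_angle == 0.0:
        off = {k: abs(tf[k] - achieved[k]) for k in DOMAIN_KEYS}
        if max(off.values()) > tolerance:
            raise PhantomInfeasibleError(
                "fraction targets not reachable within tolerance", table)

    vol = LabelVolume(labels=labels, voxel_size=spec.voxel_size,
                      meta={"spec": spec, "achieved": achieved,
                            "brick_width": width, "cleft_thickness": t_c})
    return (vol, achieved) if return_report else vol


def cleft_plane_positions(labels: LabelVolume) -> np.ndarray:
    """Sorted z positions (μm) of the cleft planes (component centroids)."""
    cleft = labels.mask(CLEFT)
    comp, n = ndi.label(cleft, structure=ndi.generate_binary_structure(3, 1))
    if n == 0:
        return np.array([])
    vs = labels.voxel_size * 1e-3
    centers = ndi.center_of_mass(cleft, comp, index=np.arange(1, n + 1))
    return np.sort([(c[2] + 0.5) * vs for c in centers])


# ----------------------------------------------------------------------
# channel rendering
# ----------------------------------------------------------------------

def _draw_spheres(img: np.ndarray, centers_vox: Sequence[Tuple[float, float, float]],
                  radius_vox: float, level: float) -> None:
    r = radius_vox
    for c in centers_vox:
        lo = [max(0, int(c[i] - r) - 1) for i in range(3)]
        hi = [min(img.shape[i], int(c[i] + r) + 2) for i in range(3)]
        if any(l >= h for l, h in zip(lo, hi)):
            continue
        grids = np.meshgrid(*[np.arange(lo[i], hi[i]) for i in range(3)],
                            indexing="ij")
        d2 = sum((grids[i] - c[i]) ** 2 for i in range(3))
        box = tuple(slice(l, h) for l, h in zip(lo, hi))
        img[box] = np.where(d2 <= r * r, np.maximum(img[box], level), img[box])


def render_channels(
    labels: LabelVolume,
    attenuation_rate: float = 0.0,  # per μm of depth
    psf_sigma: Tuple[float, float, float] = (0.0, 0.0, 0.0),  # μm per axis
    noise_sd: float = 0.0,
    shot_noise: bool = False,
    seed: int = 0,
    vessel_wall: float = 1.0,  # μm
    nucleus_radius: float = 1.5,  # μm
) -> ChannelStack:
    """Render a pseudo-confocal five-channel stack from a label volume.

    With ``attenuation_rate`` 0, PSF widths 0 and ``noise_sd`` 0 the output
    is piecewise constant at the documented per-domain levels (plus the
    structured overlays: glycocalyx shell, vessel walls, nuclei, puncta).
    Deterministic for a fixed seed.
    """
    if any(s < 0 for s in psf_sigma):
        raise ValueError("PSF widths must be non-negative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")

    lab = labels.labels
    vs = labels.voxel_size * 1e-3  # μm
    rng = np.random.default_rng(seed)
    struct = ndi.generate_binary_structure(3, 1)

    chans: Dict[str, np.ndarray] = {}
    for name, levels in CHANNEL_LEVELS.items():
        lut = np.zeros(7)
        for code, lvl in levels.items():
            lut[code] = lvl
        chans[name] = lut[lab].astype(np.float64)

    myo = lab == MYOCYTE
    if myo.any() and not myo.all():
        dil = ndi.binary_dilation(myo, structure=struct)
        rim = dil & ~myo
        bleed = myo & ndi.binary_dilation(~myo, structure=struct)
        chans["WGA"][rim] = WGA_RIM_LEVEL
        chans["WGA"][bleed] = WGA_BLEED_LEVEL

    ves = lab == VESSEL
    nucleus_centers: List[Tuple[float, float, float]] = []
    if ves.any():
        edt_in = ndi.distance_transform_edt(ves) * vs
        wall = ves & (edt_in <= vessel_wall)
        for cname, lvl in VESSEL_WALL_LEVELS.items():
            chans[cname][wall] = np.maximum(chans[cname][wall], lvl)
        edt_out = ndi.distance_transform_edt(~ves) * vs
        peri = (lab == EXTRACELLULAR) & (edt_out <= vessel_wall)
        chans["vimentin"][peri] = np.maximum(chans["vimentin"][peri],
                                             PERIVASCULAR_VIMENTIN)
        # endothelial / pericyte nuclei on the vessel wall
        wall_idx = np.flatnonzero(wall.ravel())
        n_wall_nuc = max(1, int(wall.sum() * (vs ** 3) / 400.0))
        if wall_idx.size:
            pick = rng.choice(wall_idx, size=min(n_wall_nuc, wall_idx.size),
                              replace=False)
            nucleus_centers += [tuple(np.unravel_index(i, lab.shape))
                                for i in pick]

    # nucleus cores of fibroblasts / myofibroblasts (one per cell component)
    for code in (FIBROBLAST, MYOFIBROBLAST):
        mask = lab == code
        if mask.any():
            comp, n = ndi.label(mask, structure=struct)
            nucleus_centers += ndi.center_of_mass(mask, comp,
                                                  index=np.arange(1, n + 1))

    # sparse myocyte nuclei
    if myo.any():
        myo_idx = np.flatnonzero(myo.ravel())
        n_myo_nuc = max(1, int(myo.sum() * (vs ** 3) / 8000.0))
        pick = rng.choice(myo_idx, size=min(n_myo_nuc, myo_idx.size),
                          replace=False)
        nucleus_centers += [tuple(np.unravel_index(i, lab.shape)) for i in pick]
        # Cx43 puncta at myocyte-myocyte contact sites
        n_punct = max(1, int(myo.sum() * (vs ** 3) / 4000.0))
        pick = rng.choice(myo_idx, size=min(n_punct, myo_idx.size),
                          replace=False)
        _draw_spheres(chans["Cx43"],
                      [tuple(np.unravel_index(i, lab.shape)) for i in pick],
                      max(0.4 / vs, 1.0), CX43_PUNCTUM_LEVEL)

    _draw_spheres(chans["DAPI"], nucleus_centers, nucleus_radius / vs,
                  DAPI_NUCLEUS_LEVEL)

    sig_vox = tuple(s / vs for s in psf_sigma)
    for name in chans:
        if any(s > 0 for s in sig_vox):
            chans[name] = ndi.gaussian_filter(chans[name], sigma=sig_vox)
        if attenuation_rate > 0:
            z_um = (np.arange(lab.shape[2]) + 0.5) * vs
            chans[name] = chans[name] * np.exp(-attenuation_rate * z_um)[None, None, :]
        if shot_noise:
            chans[name] = rng.poisson(np.clip(chans[name], 0, None)).astype(float)
        if noise_sd > 0:
            chans[name] = chans[name] + rng.normal(0.0, noise_sd, lab.shape)
        chans[name] = np.clip(chans[name], 0.0, None)

    return ChannelStack(channels=chans, voxel_size=labels.voxel_size)


# ----------------------------------------------------------------------
# ensembles
# ----------------------------------------------------------------------

def conduction_ensemble_specs(
    n: int = 20,
    seed: int = 0,
    grid_shape: Tuple[int, int, int] = (72, 64, 120),
    voxel_size: float = 400.0,
    ve_minus_cleft: Tuple[float, float] = (17.0, 39.0),
    cleft_range: Tuple[float, float] = (2.0, 6.0),
) -> List[PhantomSpec]:
    """Phantom specs spanning V_e ≈ 20–45% for conductivity regressions.

    The non-cleft extracellular fraction increases linearly across the
    ensemble while the cleft fraction follows a jittered-but-monotone
    ramp: both extracellular parameters grow from one phantom to the
    next, so (with cells and vessels absent) the conductive sets are
    nested and homogenized conductivities are provably non-decreasing in
    V_e; the jitter decorrelates V_cleft from V_e − V_cleft enough for
    the regression contrasts.
    """
    if n < 2:
        raise ValueError("ensemble needs n >= 2")
    rng = np.random.default_rng(seed)
    vem = np.linspace(*ve_minus_cleft, n)
    ramp = (np.arange(n) + rng.uniform(-0.45, 0.45, n)) / (n - 1)
    vc = cleft_range[0] + (cleft_range[1] - cleft_range[0]) * ramp
    specs = []
    for i in range(n):
        ve = float(vem[i] + vc[i])
        specs.append(PhantomSpec(
            grid_shape=grid_shape,
            voxel_size=voxel_size,
            target_fractions={
                "myocyte": 100.0 - ve, "extracellular": ve,
                "cleft": float(vc[i]), "vessel": 0.0,
                "fibroblast": 0.0, "myofibroblast": 0.0,
            },
            seed=int(seed + 1000 + i),
        ))
    return specs
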