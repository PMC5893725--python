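"""Reconstruction of the six tissue domains from channel stacks.

Myocytes are segmented by a marker-based watershed on the WGA channel
(WGA ridges are cell boundaries; seeds come from the distance transform
of the low-WGA phase).  Capillaries are elongated low-WGA tubes, dilated
to include their walls.  Fibroblasts and myofibroblasts are DAPI nuclei
outside myocytes and away from vessels, classified by the vimentin /
α-SMA content of their surrounding vimentin-positive region.  The
extracellular space is the residual after excluding all cell domains,
and interlaminar clefts are large connected low-WGA regions inside it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import scipy.ndimage as ndi
from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.segmentation import watershed

from .volumes import (
    CLEFT,
    EXTRACELLULAR,
    FIBROBLAST,
    MYOCYTE,
    MYOFIBROBLAST,
    VESSEL,
    ChannelStack,
    LabelVolume,
)

_STRUCT = ndi.generate_binary_structure(3, 1)


@dataclass
class SegmentationParams:
    """Tunable segmentation parameters (lengths μm, volumes μm³)."""

    voxel_size: float = 200.0  # nm
    wga_interface_k: float = 1.0  # SD multiplier for the mode+k·SD threshold
    low_wga_threshold: Optional[float] = None  # seed threshold; None → auto
    wga_mask_threshold: Optional[float] = None  # growth threshold; None → auto
    seed_edt_min: float = 0.4  # μm; erosion depth for watershed seeds
    min_myocyte_volume: float = 500.0  # μm³
    min_myocyte_half_thickness: float = 3.0  # μm
    capillary_radius: float = 2.0  # μm
    capillary_scale: float = 1.6  # tube if half-thickness ≤ scale·radius
    max_tube_cross: float = 10.0  # μm; rejects planar clefts as tubes
    min_tube_length: float = 12.0  # μm
    min_tube_aspect: float = 2.5  # length / cross extent; rejects cell bodies
    vessel_max_vimentin_fraction: float = 0.8  # lumina are vimentin-dim inside
    tube_cross_symmetry: float = 0.4  # min/max cross extent; rejects ribbons
    vessel_dilation: float = 0.0  # μm
    nucleus_min_volume: float = 4.0  # μm³
    proximity_radius: float = 2.0  # μm; vessel-association distance
    marker_k: float = 1.0  # SD multiplier for DAPI/vimentin/α-SMA thresholds
    asma_positive_fraction: float = 0.1
    cleft_wga_threshold: Optional[float] = None  # absolute; None → ECS mode
    cleft_min_volume: float = 50.0  # μm³
    cleft_rim_margin: int = 1  # voxels; re-attach the glycocalyx shell

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.wga_interface_k < 0 or self.marker_k < 0:
            raise ValueError("threshold multipliers must be >= 0")
        for name in ("min_myocyte_volume", "nucleus_min_volume",
                     "cleft_min_volume", "proximity_radius",
                     "capillary_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def vs_um(self) -> float:
        return self.voxel_size * 1e-3

    def um3_to_vox(self, v: float) -> float:
        return v / self.vs_um ** 3


def mode_sd_threshold(image: np.ndarray, k: float = 1.0,
                      bins: int = 256) -> float:
    """Histogram mode (over the observed range) plus k standard deviations."""
    img = np.asarray(image, dtype=float)
    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        warnings.warn("flat histogram: threshold set to the maximum value")
        return hi
    hist, edges = np.histogram(img, bins=bins, range=(lo, hi))
    mode = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
    return mode + k * float(img.std())


def _wga_thresholds(wga: np.ndarray,
                    params: SegmentationParams) -> Tuple[float, float]:
    """(seed, mask) thresholds separating the WGA histogram's classes.

    Cell interiors, clefts and lumina are darkest; interface signal
    (membrane bleed, vessel walls) intermediate; the collagen/glycocalyx
    matrix brightest.  Seeds come from the darkest class; instances may
    grow through the intermediate class but never into the matrix.
    Defaults via three-class multi-Otsu, falling back to plain Otsu for
    images with too few distinct levels.
    """
    t_seed, t_mask = params.low_wga_threshold, params.wga_mask_threshold
    if t_seed is not None and t_mask is not None:
        return t_seed, t_mask
    if wga.max() <= wga.min():
        auto = (float(wga.min()), float(wga.min()))  # flat: empty low phase
    else:
        try:
            lo, hi = threshold_multiotsu(wga, classes=3)
            auto = (float(lo), float(hi))
        except ValueError:
            t = float(threshold_otsu(wga))
            auto = (t, t)
    return (t_seed if t_seed is not None else auto[0],
            t_mask if t_mask is not None else auto[1])


def segment_myocytes(wga: np.ndarray,
                     params: SegmentationParams) -> np.ndarray:
    """Watershed myocyte instance segmentation on the WGA channel.

    Returns an integer instance-label volume (0 = not myocyte).  The
    low-WGA phase is flooded from distance-transform cores; candidate
    instances must exceed a minimum volume and a minimum half-thickness
    (which rejects thin clefts and narrow capillary lumina), and voxels
    at extracellular-level WGA are never kept inside an instance.
    """
    wga = np.asarray(wga, dtype=float)
    t_seed, t_mask = _wga_thresholds(wga, params)
    low = wga < t_seed
    if not low.any():
        warnings.warn("empty low-WGA phase: no myocytes found")
        return np.zeros(wga.shape, dtype=np.int32)
    mask = wga < t_mask

    edt_low = ndi.distance_transform_edt(low) * params.vs_um
    cores = low & (edt_low >= params.seed_edt_min)
    markers, n = ndi.label(cores, structure=_STRUCT)
    if n == 0:
        warnings.warn("no watershed seeds survive erosion: no myocytes found")
        return np.zeros(wga.shape, dtype=np.int32)
    ws = watershed(wga, markers=markers, mask=mask)

    ids = np.arange(1, n + 1)
    vols = ndi.sum_labels(np.ones_like(ws), ws, index=ids)
    edt = ndi.distance_transform_edt(mask) * params.vs_um
    half = ndi.maximum(edt, labels=ws, index=ids)
    keep = (vols >= params.um3_to_vox(params.min_myocyte_volume)) & \
           (half >= params.min_myocyte_half_thickness)
    lut = np.zeros(n + 1, dtype=np.int32)
    lut[ids[keep]] = np.arange(1, int(keep.sum()) + 1)
    return lut[ws]


def segment_vessels(wga: np.ndarray, myocyte_mask: np.ndarray,
                    params: SegmentationParams,
                    vimentin: Optional[np.ndarray] = None) -> np.ndarray:
    """Capillaries: elongated low-WGA, non-myocyte tubes, plus walls.

    A low-WGA component qualifies as a capillary lumen when it is thin
    (half-thickness ≤ capillary_scale · capillary_radius), of limited
    cross-section (rejecting planar clefts) and elongated along the
    fiber axis.  When the vimentin channel is supplied, candidates that
    are vimentin-positive throughout are rejected — a capillary is
    vimentin-dim in its lumen, unlike an elongated fibroblast body.
    The detected tube is dilated by ``vessel_dilation`` to absorb
    endothelium and pericytes; myocyte voxels are never absorbed.
    """
    wga = np.asarray(wga, dtype=float)
    _, t_mask = _wga_thresholds(wga, params)
    cand = (wga < t_mask) & ~myocyte_mask
    if not cand.any():
        return np.zeros(wga.shape, dtype=bool)
    vim_pos = None
    if vimentin is not None:
        vimentin = np.asarray(vimentin, dtype=float)
        if vimentin.max() > vimentin.min():
            vim_pos = vimentin >= mode_sd_threshold(vimentin, params.marker_k)
    edt = ndi.distance_transform_edt(cand) * params.vs_um
    comp, n = ndi.label(cand, structure=_STRUCT)
    vessel = np.zeros(wga.shape, dtype=bool)
    objects = ndi.find_objects(comp)
    vs = params.vs_um
    for i, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        region = comp[sl] == i
        half = float(edt[sl][region].max())
        if half > params.capillary_scale * params.capillary_radius:
            continue
        ext = [(s.stop - s.start) * vs for s in sl]
        if max(ext[0], ext[2]) > params.max_tube_cross:
            continue  # planar (cleft-like) or blob-like, not a tube
        if ext[1] < max(params.min_tube_length,
                        params.min_tube_aspect * max(ext[0], ext[2])):
            continue  # not elongated along the fiber axis
        if min(ext[0], ext[2]) < params.tube_cross_symmetry * max(ext[0],
                                                                  ext[2]):
            continue  # flat ribbon cross-section, not a round lumen
        if vim_pos is not None:
            if float(vim_pos[sl][region].mean()) >= \
                    params.vessel_max_vimentin_fraction:
                continue  # uniformly vimentin-positive: a cell body
        vessel[sl] |= region
    if params.vessel_dilation > 0 and vessel.any():
        dist = ndi.distance_transform_edt(~vessel) * vs
        vessel = dist <= params.vessel_dilation
    return vessel & ~myocyte_mask


def classify_fibro_myofibro(
    dapi: np.ndarray,
    vimentin: np.ndarray,
    asma: np.ndarray,
    myocyte_mask: np.ndarray,
    vessel_mask: np.ndarray,
    params: SegmentationParams,
) -> Tuple[np.ndarray, np.ndarray]:
    """Fibroblast / myofibroblast masks from nucleus-anchored cell bodies.

    Nuclei are thresholded DAPI components above a minimum volume,
    excluding those inside myocytes or within ``proximity_radius`` of a
    vessel.  Each remaining nucleus claims its surrounding
    vimentin-positive connected region (clipped to non-myocyte,
    non-vessel space): α-SMA-negative regions are fibroblasts,
    α-SMA-positive ones myofibroblasts.
    """
    dapi = np.asarray(dapi, dtype=float)
    if dapi.max() <= dapi.min():
        return (np.zeros(dapi.shape, dtype=bool),
                np.zeros(dapi.shape, dtype=bool))
    t_dapi = mode_sd_threshold(dapi, params.marker_k)
    nuclei, n_nuc = ndi.label(dapi >= t_dapi, structure=_STRUCT)
    if n_nuc == 0:
        return (np.zeros(dapi.shape, dtype=bool),
                np.zeros(dapi.shape, dtype=bool))

    if vessel_mask.any():
        vessel_dist = ndi.distance_transform_edt(~vessel_mask) * params.vs_um
    else:
        vessel_dist = np.full(dapi.shape, np.inf)

    def positive(img: np.ndarray) -> np.ndarray:
        img = np.asarray(img, dtype=float)
        if img.max() <= img.min():
            return np.zeros(img.shape, dtype=bool)  # flat channel: no signal
        return img >= mode_sd_threshold(img, params.marker_k)

    vim_pos = positive(vimentin)
    cell_space = vim_pos & ~myocyte_mask & ~vessel_mask
    vim_comp, _ = ndi.label(cell_space, structure=_STRUCT)
    asma_pos = positive(asma)

    min_nuc = params.um3_to_vox(params.nucleus_min_volume)
    fibro = np.zeros(dapi.shape, dtype=bool)
    myofibro = np.zeros(dapi.shape, dtype=bool)
    claimed: set = set()
    for i, sl in enumerate(ndi.find_objects(nuclei), start=1):
        if sl is None:
            continue
        nuc = nuclei[sl] == i
        if nuc.sum() < min_nuc:
            continue
        inside_myo = (myocyte_mask[sl][nuc]).mean() > 0.5
        if inside_myo:
            continue
        if float(vessel_dist[sl][nuc].min()) <= params.proximity_radius:
            continue
        cids = np.unique(vim_comp[sl][nuc])
        cids = cids[cids > 0]
        for cid in cids:
            if cid in claimed:
                continue
            claimed.add(cid)
            region = vim_comp == cid
            frac = float(asma_pos[region].mean())
            if frac >= params.asma_positive_fraction:
                myofibro |= region
            else:
                fibro |= region
    return fibro, myofibro


def extracellular_residual(myocyte_mask: np.ndarray, vessel_mask: np.ndarray,
                           fibro_mask: np.ndarray,
                           myofibro_mask: np.ndarray) -> np.ndarray:
    """Residual space after excluding all segmented cell domains.

    Inputs must be pairwise disjoint; the union of the five domains then
    covers the volume exactly.
    """
    masks = [myocyte_mask, vessel_mask, fibro_mask, myofibro_mask]
    overlap = (sum(m.astype(np.int8) for m in masks) > 1)
    if overlap.any():
        raise ValueError(
            f"domain masks overlap on {int(overlap.sum())} voxels")
    union = masks[0] | masks[1] | masks[2] | masks[3]
    return ~union


def detect_clefts(extracellular_mask: np.ndarray, wga: np.ndarray,
                  params: SegmentationParams) -> np.ndarray:
    """Interlaminar clefts: large connected low-WGA extracellular regions.

    The default threshold is the WGA histogram mode within the
    extracellular space (clefts sit well below it because of their
    reduced collagen density).  Components above ``cleft_min_volume``
    are kept and grown by ``cleft_rim_margin`` voxels inside the
    extracellular mask to re-attach the WGA-bright glycocalyx shell
    lining the adjacent myocyte surfaces.  The result is always a subset
    of the extracellular mask, and a higher threshold never shrinks it.
    """
    if not extracellular_mask.any():
        raise ValueError("extracellular mask is empty")
    wga = np.asarray(wga, dtype=float)
    if params.cleft_wga_threshold is not None:
        thr = params.cleft_wga_threshold
    else:
        ecs_wga = wga[extracellular_mask]
        lo, hi = float(ecs_wga.min()), float(ecs_wga.max())
        if hi <= lo:
            return np.zeros(wga.shape, dtype=bool)
        hist, edges = np.histogram(ecs_wga, bins=256, range=(lo, hi))
        thr = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
    cand = extracellular_mask & (wga < thr)
    if not cand.any():
        return np.zeros(wga.shape, dtype=bool)
    comp, n = ndi.label(cand, structure=_STRUCT)
    ids = np.arange(1, n + 1)
    vols = ndi.sum_labels(np.ones_like(comp), comp, index=ids)
    keep = ids[vols >= params.um3_to_vox(params.cleft_min_volume)]
    cleft = np.isin(comp, keep)
    for _ in range(params.cleft_rim_margin):
        cleft = ndi.binary_dilation(cleft, structure=_STRUCT) & extracellular_mask
    return cleft


def refine_interface(myocyte_mask: np.ndarray, wga: np.ndarray,
                     k: float = 1.0) -> np.ndarray:
    """WGA-bright voxels inside myocytes, for the conductivity model.

    Thresholds the WGA image at mode + k·SD and flags myocyte voxels at
    or above it — conservatively preserving the extracellular interface
    (and transverse tubules) when the conductive mask is assembled.
    """
    wga = np.asarray(wga, dtype=float)
    thr = mode_sd_threshold(wga, k)
    addition = myocyte_mask & (wga >= thr)
    if not addition.any():
        warnings.warn("interface refinement: no myocyte voxels above threshold")
    return addition


def segment_volume(stack: ChannelStack,
                   params: Optional[SegmentationParams] = None) -> LabelVolume:
    """Full six-domain segmentation of a preprocessed channel stack."""
    if params is None:
        params = SegmentationParams(voxel_size=stack.voxel_size)
    wga = stack["WGA"]
    instances = segment_myocytes(wga, params)
    myo = instances > 0
    vessel = segment_vessels(wga, myo, params,
                             vimentin=stack.channels.get("vimentin"))
    fibro, myofibro = classify_fibro_myofibro(
        stack["DAPI"], stack["vimentin"], stack["aSMA"], myo, vessel, params)
    fibro &= ~vessel
    myofibro &= ~vessel
    ecs = extracellular_residual(myo, vessel, fibro, myofibro)
    cleft = detect_clefts(ecs, wga, params)

    labels = np.full(stack.shape, EXTRACELLULAR, dtype=np.uint8)
    labels[cleft] = CLEFT
    labels[myo] = MYOCYTE
    labels[vessel] = VESSEL
    labels[fibro] = FIBROBLAST
    labels[myofibro] = MYOFIBROBLAST
    return LabelVolume(labels=labels, voxel_size=stack.voxel_size,
                       meta={"myocyte_instances": int(instances.max()),
                             "params": params})
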