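"""Anatomical and functional seed / evaluation ROI builders.

Anatomical seeds (aROIs) are carved from gyrus masks: the hand area is
the 10 x 2 mm axial slab centred on the hand-knob landmark intersected
with the pre- (motor) or post-central (sensory) gyrus; the foot area is
the whole paracentral lobule; the mouth area is the ventral precentral
gyrus between the Sylvian fissure and the inferior limit of the knob.
Functional seeds (fROIs) are 6 mm spheres centred on the contralateral
task-activation peak. Evaluation masks are built by iterated 6-connected
binary dilation ("dilated by k voxels" = k iterations with the
city-block structuring element), with the iteration count kept as
provenance on the mask.

Gyrus masks are plain NIfTI inputs (atlas-derived or phantom); no atlas
fetching happens here. All coordinates entering these builders are world
mm; voxel indices never leave the module.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .images import RoiMask, StatMap, require_same_grid, voxel_to_world, world_to_voxel

__all__ = [
    "HandRoiSpec",
    "build_hand_aroi",
    "build_foot_aroi",
    "build_mouth_aroi",
    "build_froi",
    "dilate_mask",
    "mirror_mask",
]

from dataclasses import dataclass


@dataclass(frozen=True)
class HandRoiSpec:
    """Hand-area slab rule: n_slices of slice_thickness_mm around the knob."""

    knob_centre_mm: tuple[float, float, float]
    n_slices: int = 10
    slice_thickness_mm: float = 2.0
    gyrus: str = "precentral"

    def __post_init__(self) -> None:
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.slice_thickness_mm <= 0:
            raise ValueError("slice_thickness_mm must be > 0")
        if self.gyrus not in ("precentral", "postcentral"):
            raise ValueError("gyrus must be precentral or postcentral")


def _world_z(mask: RoiMask) -> np.ndarray:
    """World z coordinate of every voxel centre (3D array)."""
    idx = np.indices(mask.shape3, dtype=float)
    aff = mask.affine
    return (aff[2, 0] * idx[0] + aff[2, 1] * idx[1]
            + aff[2, 2] * idx[2] + aff[2, 3])


def build_hand_aroi(gyrus_mask: RoiMask, spec: HandRoiSpec) -> RoiMask:
    """Intersect the gyrus with the axial slab centred on the knob z.

    The slab is the symmetric half-open interval
    [z_knob - h/2, z_knob + h/2) with h = n_slices * thickness.
    """
    if gyrus_mask.is_empty:
        raise ValueError("gyrus mask is empty")
    ijk = world_to_voxel(gyrus_mask.affine, spec.knob_centre_mm)
    if np.any(ijk < -0.5) or np.any(ijk > np.asarray(gyrus_mask.shape3) - 0.5):
        raise ValueError("knob centre lies outside the grid")
    half = spec.n_slices * spec.slice_thickness_mm / 2.0
    z0 = spec.knob_centre_mm[2]
    wz = _world_z(gyrus_mask)
    slab = (wz >= z0 - half) & (wz < z0 + half)
    zmin, zmax = wz.min(), wz.max()
    if z0 - half < zmin or z0 + half > zmax:
        warnings.warn("hand-area slab clipped at the grid edge")
    out = gyrus_mask.values & slab
    if not out.any():
        raise ValueError("hand aROI is empty (slab does not meet the gyrus)")
    return RoiMask(out, gyrus_mask.affine, label=f"hand_aROI_{spec.gyrus}")


def build_foot_aroi(paracentral_mask: RoiMask) -> RoiMask:
    """The foot area is the whole paracentral lobule."""
    if paracentral_mask.is_empty:
        raise ValueError("paracentral mask is empty")
    return RoiMask(paracentral_mask.values.copy(), paracentral_mask.affine,
                   label="foot_aROI")


def build_mouth_aroi(precentral_mask: RoiMask, sylvian_z_mm: float,
                     knob_inferior_z_mm: float) -> RoiMask:
    """Ventral precentral gyrus between the Sylvian fissure and the
    inferior limit of the hand knob: z in [sylvian, knob_inferior)."""
    if sylvian_z_mm >= knob_inferior_z_mm:
        raise ValueError("sylvian_z_mm must lie below knob_inferior_z_mm")
    if precentral_mask.is_empty:
        raise ValueError("precentral mask is empty")
    wz = _world_z(precentral_mask)
    out = precentral_mask.values & (wz >= sylvian_z_mm) & (wz < knob_inferior_z_mm)
    if not out.any():
        raise ValueError("mouth aROI is empty in the given z window")
    return RoiMask(out, precentral_mask.affine, label="mouth_aROI")


def build_froi(contralateral_tmap: StatMap, search_mask: RoiMask,
               radius_mm: float = 6.0) -> RoiMask:
    """Sphere of ``radius_mm`` centred on the peak of the map within the
    search mask (voxel included if its centre is within the radius).

    Equal maxima break toward the lowest linear voxel index (logged).
    """
    require_same_grid(contralateral_tmap, search_mask, "t map and search mask")
    if search_mask.is_empty:
        raise ValueError("search mask is empty")
    vals = np.where(search_mask.values, contralateral_tmap.values, -np.inf)
    if not np.isfinite(vals).any():
        raise ValueError("no finite map values inside the search mask")
    peak_flat = int(np.argmax(vals))
    n_max = int((vals == vals.flat[peak_flat]).sum())
    if n_max > 1:
        warnings.warn(f"{n_max} equal peak voxels; lowest linear index chosen")
    peak_ijk = np.unravel_index(peak_flat, vals.shape)
    centre = voxel_to_world(contralateral_tmap.affine, np.asarray(peak_ijk))
    idx = np.indices(search_mask.shape3, dtype=float).reshape(3, -1).T
    coords = voxel_to_world(contralateral_tmap.affine, idx)
    dist = np.linalg.norm(coords - centre, axis=1).reshape(search_mask.shape3)
    return RoiMask(dist <= radius_mm, contralateral_tmap.affine, label="fROI")


_STRUCT6 = ndimage.generate_binary_structure(3, 1)  # 6-connected


def dilate_mask(mask: RoiMask, n_iter: int) -> RoiMask:
    """``n_iter`` iterations of 6-connected binary dilation (city-block
    ball); provenance updated on the returned mask."""
    if n_iter < 0:
        raise ValueError("n_iter must be >= 0")
    if n_iter == 0:
        out = mask.values.copy()
    else:
        out = ndimage.binary_dilation(mask.values, _STRUCT6, iterations=n_iter)
    return RoiMask(out, mask.affine, label=mask.label,
                   dilation_voxels=mask.dilation_voxels + n_iter)


def mirror_mask(mask: RoiMask, midline_x_mm: float = 0.0) -> RoiMask:
    """Reflect the mask about the sagittal plane ``x = midline_x_mm``.

    Used to transfer seeds defined on the healthy hemisphere to the
    lesioned one. Voxels whose reflection leaves the grid are clipped
    with a warning.
    """
    ijk = np.argwhere(mask.values)
    out = np.zeros(mask.shape3, dtype=bool)
    if len(ijk) == 0:
        return RoiMask(out, mask.affine, label=f"{mask.label}_mirrored",
                       dilation_voxels=mask.dilation_voxels)
    xyz = voxel_to_world(mask.affine, ijk.astype(float))
    xyz = np.atleast_2d(xyz)
    xyz[:, 0] = 2.0 * midline_x_mm - xyz[:, 0]
    back = np.atleast_2d(world_to_voxel(mask.affine, xyz))
    back = np.round(back).astype(int)
    inside = np.all((back >= 0) & (back < np.asarray(mask.shape3)), axis=1)
    if not inside.all():
        warnings.warn(f"{int((~inside).sum())} mirrored voxels left the grid; clipped")
    kept = back[inside]
    out[kept[:, 0], kept[:, 1], kept[:, 2]] = True
    return RoiMask(out, mask.affine, label=f"{mask.label}_mirrored",
                   dilation_voxels=mask.dilation_voxels)
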