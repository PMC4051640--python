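"""Core in-memory containers for volumetric fMRI data.

Three containers are shared by every stage of the pipeline:

``BoldSeries``
    A 4D BOLD time series (x, y, z, t) with its voxel-to-world affine and
    repetition time.

``StatMap``
    A 3D statistical map (t or z score per voxel) with provenance recording
    which mapping method produced it.

``RoiMask``
    A labelled binary 3D mask (anatomical region, seed, lesion, brain,
    ground-truth activation) that remembers how many dilation iterations
    were applied to it.

All containers carry a 4x4 RAS+ affine; world coordinates are always in mm.
NIfTI-1 serialization goes through nibabel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

__all__ = [
    "BoldSeries",
    "StatMap",
    "RoiMask",
    "voxel_to_world",
    "world_to_voxel",
    "read_bold",
    "read_statmap",
    "read_mask",
    "write_volume",
]


class DimensionError(ValueError):
    """Raised when grids or affines of combined volumes disagree."""


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine is singular")
    return affine


def same_grid(a, b) -> bool:
    return a.shape3 == b.shape3 and np.allclose(a.affine, b.affine, atol=1e-6)


def require_same_grid(a, b, what: str = "volumes") -> None:
    if not same_grid(a, b):
        raise DimensionError(
            f"{what} are on different grids: {a.shape3}/{b.shape3} or affines differ"
        )


@dataclass
class BoldSeries:
    """4D BOLD series: ``data[x, y, z, t]`` plus affine and TR in seconds."""

    data: np.ndarray
    affine: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD series must be 4D, got {self.data.ndim}D")
        if self.data.shape[3] < 2:
            raise ValueError("BOLD series needs at least 2 time points")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD series contains non-finite values")
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        self.affine = _check_affine(self.affine)

    @property
    def shape3(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def with_data(self, data: np.ndarray) -> "BoldSeries":
        return replace(self, data=np.asarray(data, dtype=float))


@dataclass
class StatMap:
    """3D statistical map (t or z)."""

    values: np.ndarray
    affine: np.ndarray
    stat_kind: str = "t"  # "t" or "z"
    dof: int | None = None
    provenance: str = ""  # one of tb / aROI / fROI / ICA (free-form allowed)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"StatMap must be 3D, got {self.values.ndim}D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("StatMap contains non-finite values")
        if self.stat_kind not in ("t", "z"):
            raise ValueError(f"stat_kind must be 't' or 'z', got {self.stat_kind!r}")
        self.affine = _check_affine(self.affine)

    @property
    def shape3(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class RoiMask:
    """Labelled binary 3D mask with dilation provenance."""

    values: np.ndarray
    affine: np.ndarray
    label: str = ""
    dilation_voxels: int = 0

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 3:
            raise ValueError(f"RoiMask must be 3D, got {arr.ndim}D")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask {self.label!r} is not binary (values {uniq[:5]})")
        self.values = arr.astype(bool)
        self.affine = _check_affine(self.affine)

    @property
    def shape3(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    @property
    def is_empty(self) -> bool:
        return not self.values.any()

    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def volume_ml(self) -> float:
        return self.n_voxels * self.voxel_volume_mm3() / 1000.0

    def with_values(self, values: np.ndarray, **updates) -> "RoiMask":
        return replace(self, values=values, **updates)


def voxel_to_world(affine: np.ndarray, ijk: np.ndarray) -> np.ndarray:
    """Map voxel indices (n x 3 or 3,) to world mm via the affine."""
    ijk = np.asarray(ijk, dtype=float)
    squeeze = ijk.ndim == 1
    out = np.atleast_2d(ijk) @ np.asarray(affine)[:3, :3].T + np.asarray(affine)[:3, 3]
    return out[0] if squeeze else out


def world_to_voxel(affine: np.ndarray, xyz: np.ndarray) -> np.ndarray:
    """Map world mm coordinates to (fractional) voxel indices."""
    inv = np.linalg.inv(np.asarray(affine))
    xyz = np.asarray(xyz, dtype=float)
    squeeze = xyz.ndim == 1
    out = np.atleast_2d(xyz) @ inv[:3, :3].T + inv[:3, 3]
    return out[0] if squeeze else out


# ---------------------------------------------------------------------------
# NIfTI round trips


def _load(path) -> nib.Nifti1Image:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - message re-raise
        raise ValueError(f"cannot read {path} as NIfTI: {exc}") from exc
    if not isinstance(img, (nib.Nifti1Image, nib.Nifti2Image)):
        raise ValueError(f"{path} is not a NIfTI image")
    return img


def read_bold(path, tr: float | None = None) -> BoldSeries:
    img = _load(path)
    if tr is None:
        tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
    if tr <= 0:
        raise ValueError(f"{path}: TR not stored in header; pass tr explicitly")
    return BoldSeries(np.asarray(img.dataobj, dtype=float), img.affine, tr)


def read_statmap(path, stat_kind: str = "t", provenance: str = "") -> StatMap:
    img = _load(path)
    descrip = img.header["descrip"].tobytes().decode(errors="ignore").rstrip("\x00")
    return StatMap(
        np.asarray(img.dataobj, dtype=float),
        img.affine,
        stat_kind=stat_kind,
        provenance=provenance or descrip,
    )


def read_mask(path, label: str = "") -> RoiMask:
    img = _load(path)
    arr = np.asarray(img.dataobj, dtype=float)
    uniq = np.unique(arr)
    if not np.all(np.isin(uniq, (0.0, 1.0))):
        raise ValueError(f"{path}: mask has non-binary values {uniq[:5]}")
    return RoiMask(arr.astype(bool), img.affine, label=label or str(path))


def write_volume(obj, path) -> None:
    """Write a BoldSeries / StatMap / RoiMask as NIfTI-1."""
    if isinstance(obj, BoldSeries):
        img = nib.Nifti1Image(obj.data.astype(np.float32), obj.affine)
        zooms = list(img.header.get_zooms())
        zooms[3] = obj.tr
        img.header.set_zooms(zooms)
    elif isinstance(obj, StatMap):
        img = nib.Nifti1Image(obj.values.astype(np.float32), obj.affine)
        img.header["descrip"] = obj.provenance.encode()[:79]
    elif isinstance(obj, RoiMask):
        img = nib.Nifti1Image(obj.values.astype(np.uint8), obj.affine)
        img.header["descrip"] = f"{obj.label};dil={obj.dilation_voxels}".encode()[:79]
    else:
        raise TypeError(f"cannot serialize {type(obj).__name__}")
    nib.save(img, str(path))
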