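"""Thresholding, overlap, centre-of-mass and stimulation-site concordance.

This module carries the study's quantitative deliverables:

* AMPLE thresholding — "activation mapping as percentage of local
  excitation": the threshold is 50% of the highest t/z score found in
  the motor cortex ipsilateral to the lesion, and is then applied to the
  whole map. Supra-threshold is non-strict (>=), so the peak is always
  included.
* Overlap sensitivity/specificity — within a (dilated) motor-cortex
  evaluation mask, alpha = V_overlap / V_tb measures how much of the
  task activation the resting-state map captures, and
  beta = V_overlap / V_rs how much of the resting-state map lies inside
  the task activation.
* Centres of mass — supra-threshold voxels inside the anatomical mask,
  averaged in world mm with t-score weights (all clusters pooled); the
  lesion CoM is the unweighted centroid.
* ECS scoring — stimulation sites are projected onto the cortex
  (nearest cortex voxel centre), and each site's distance to the nearest
  supra-threshold voxel is computed per method; 0 means the site falls
  inside the activation. Sites and maps "match" when the distance is
  below a 7 or 10 mm cutoff.
* Aggregation — per-task and grand mean/SD rows (sample SD, n-1;
  single-value groups report SD 0) over per-case tables with explicit
  missing markers, mirroring the reporting conventions of clinical
  concordance studies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .images import RoiMask, StatMap, require_same_grid, voxel_to_world, world_to_voxel
from .phantom import EcsSite

__all__ = [
    "ThresholdedMap",
    "OverlapResult",
    "CentreOfMass",
    "MatchCriteria",
    "UndefinedResultError",
    "ample_threshold",
    "fixed_threshold",
    "overlap_alpha_beta",
    "weighted_com",
    "lesion_com",
    "com_distance",
    "project_site_to_cortex",
    "ecs_distance",
    "match_rate",
    "aggregate_summary",
]

MISSING = "-"  # map unavailable
MISSING_REF = "- -"  # comparison impossible (reference map absent)


class UndefinedResultError(ValueError):
    """A comparison has no defined value (mirrors '-'/'- -' table cells)."""


@dataclass
class ThresholdedMap:
    """A statistical map with its threshold and supra-threshold voxel set."""

    source: StatMap
    threshold: float
    policy: str = "ample"  # "ample" | "fixed"

    def __post_init__(self) -> None:
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")
        self.supra = self.source.values >= self.threshold

    @property
    def n_supra(self) -> int:
        return int(self.supra.sum())

    @property
    def affine(self) -> np.ndarray:
        return self.source.affine

    @property
    def shape3(self):
        return self.source.shape3


def ample_threshold(stat_map: StatMap,
                    ipsilateral_motor_mask: RoiMask) -> ThresholdedMap:
    """Threshold at 50% of the in-mask maximum; supra set spans the whole map."""
    require_same_grid(stat_map, ipsilateral_motor_mask, "map and motor mask")
    if ipsilateral_motor_mask.is_empty:
        raise ValueError("motor mask is empty")
    peak = float(stat_map.values[ipsilateral_motor_mask.values].max())
    if peak <= 0:
        raise ValueError("no excitable peak: in-mask maximum is not positive")
    return ThresholdedMap(stat_map, threshold=0.5 * peak, policy="ample")


def fixed_threshold(stat_map: StatMap, threshold: float) -> ThresholdedMap:
    """Operator-style fixed threshold."""
    return ThresholdedMap(stat_map, threshold=float(threshold), policy="fixed")


@dataclass
class OverlapResult:
    """Supra-threshold volumes and the derived alpha / beta overlap indices."""

    v_tb: int
    v_rs: int
    v_overlap: int
    mask_label: str = ""

    def __post_init__(self) -> None:
        if self.v_overlap > min(self.v_tb, self.v_rs):
            raise ValueError("V_overlap cannot exceed either volume")

    @property
    def alpha(self) -> float:
        """Sensitivity of the rs map with respect to the tb map."""
        return self.v_overlap / self.v_tb

    @property
    def beta(self) -> float:
        """Specificity of the rs map with respect to the tb map."""
        return self.v_overlap / self.v_rs


def overlap_alpha_beta(tb: ThresholdedMap, rs: ThresholdedMap,
                       eval_mask: RoiMask) -> OverlapResult:
    """Count supra-threshold voxels within the evaluation mask and derive
    alpha = V_overlap/V_tb, beta = V_overlap/V_rs."""
    require_same_grid(tb, rs, "tb and rs maps")
    require_same_grid(tb, eval_mask, "maps and evaluation mask")
    if eval_mask.is_empty:
        raise ValueError("evaluation mask is empty")
    m = eval_mask.values
    v_tb = int((tb.supra & m).sum())
    v_rs = int((rs.supra & m).sum())
    if v_tb == 0 or v_rs == 0:
        raise UndefinedResultError(
            "alpha/beta undefined: no supra-threshold voxels in the mask for "
            + ("tb" if v_tb == 0 else "rs")
        )
    v_overlap = int((tb.supra & rs.supra & m).sum())
    return OverlapResult(v_tb=v_tb, v_rs=v_rs, v_overlap=v_overlap,
                         mask_label=eval_mask.label)


@dataclass
class CentreOfMass:
    """World-mm centre of mass of a set of contributing voxels."""

    xyz_mm: np.ndarray
    weighted: bool
    n_voxels: int

    def __post_init__(self) -> None:
        self.xyz_mm = np.asarray(self.xyz_mm, dtype=float)


def weighted_com(tmap: ThresholdedMap, anatomical_mask: RoiMask) -> CentreOfMass:
    """t-weighted CoM of supra-threshold voxels inside the anatomical mask.

    All supra-threshold voxels are pooled with no cluster pre-selection,
    which makes the measure insensitive to fragmentation of activity.
    """
    require_same_grid(tmap, anatomical_mask, "map and anatomical mask")
    sel = tmap.supra & anatomical_mask.values
    if not sel.any():
        raise UndefinedResultError("no supra-threshold voxels inside the mask")
    ijk = np.argwhere(sel).astype(float)
    xyz = np.atleast_2d(voxel_to_world(tmap.affine, ijk))
    w = tmap.source.values[sel]
    com = (w[:, None] * xyz).sum(axis=0) / w.sum()
    return CentreOfMass(com, weighted=True, n_voxels=int(sel.sum()))


def lesion_com(lesion_mask: RoiMask) -> CentreOfMass:
    """Unweighted centroid of the lesion voxels, world mm."""
    if lesion_mask.is_empty:
        raise ValueError("lesion mask is empty")
    ijk = np.argwhere(lesion_mask.values).astype(float)
    xyz = np.atleast_2d(voxel_to_world(lesion_mask.affine, ijk))
    return CentreOfMass(xyz.mean(axis=0), weighted=False, n_voxels=len(ijk))


def com_distance(a: CentreOfMass, b: CentreOfMass) -> float:
    """Euclidean distance between two centres of mass, mm."""
    return float(np.linalg.norm(a.xyz_mm - b.xyz_mm))


# ---------------------------------------------------------------------------
# ECS concordance


@dataclass(frozen=True)
class MatchCriteria:
    """Distance cutoffs (mm) below which a site counts as matched."""

    cutoffs_mm: tuple[float, ...] = (7.0, 10.0)

    def __post_init__(self) -> None:
        if not self.cutoffs_mm or any(c <= 0 for c in self.cutoffs_mm):
            raise ValueError("cutoffs must be positive")
        if list(self.cutoffs_mm) != sorted(self.cutoffs_mm):
            raise ValueError("cutoffs must be ascending")


def project_site_to_cortex(site: EcsSite, cortex_mask: RoiMask) -> EcsSite:
    """Cartesian projection onto the cortical surface: a site already
    inside a cortex voxel is kept, otherwise it moves to the centre of
    the nearest cortex voxel (ties -> lowest linear index, logged)."""
    if cortex_mask.is_empty:
        raise ValueError("cortex mask is empty")
    p = np.asarray(site.xyz_mm, dtype=float)
    ijk = np.round(world_to_voxel(cortex_mask.affine, p)).astype(int)
    if (np.all(ijk >= 0) and np.all(ijk < np.asarray(cortex_mask.shape3))
            and cortex_mask.values[tuple(ijk)]):
        site.projected_xyz_mm = tuple(p)
        return site
    vox = np.argwhere(cortex_mask.values).astype(float)
    centres = np.atleast_2d(voxel_to_world(cortex_mask.affine, vox))
    d = np.linalg.norm(centres - p, axis=1)
    dmin = d.min()
    winners = np.flatnonzero(np.isclose(d, dmin, rtol=0, atol=1e-9))
    if len(winners) > 1:
        warnings.warn(f"{len(winners)} equidistant cortex voxels; "
                      "lowest linear index chosen")
    site.projected_xyz_mm = tuple(centres[winners[0]])
    return site


def ecs_distance(site: EcsSite, activation: ThresholdedMap) -> float:
    """Shortest distance (mm) from the projected site to the activation.

    0 when the projected site lies within a supra-threshold voxel, else
    the Euclidean distance to the nearest supra-threshold voxel centre.
    """
    if activation.n_supra == 0:
        raise UndefinedResultError("activation map has no supra-threshold voxels")
    p = np.asarray(site.projected_xyz_mm
                   if site.projected_xyz_mm is not None else site.xyz_mm,
                   dtype=float)
    ijk = np.round(world_to_voxel(activation.affine, p)).astype(int)
    if (np.all(ijk >= 0) and np.all(ijk < np.asarray(activation.shape3))
            and activation.supra[tuple(ijk)]):
        return 0.0
    vox = np.argwhere(activation.supra).astype(float)
    centres = np.atleast_2d(voxel_to_world(activation.affine, vox))
    return float(cKDTree(centres).query(p)[0])


def match_rate(distances_mm, cutoff_mm: float) -> float:
    """Percent of distances strictly below the cutoff."""
    distances_mm = np.asarray(list(distances_mm), dtype=float)
    if distances_mm.size == 0:
        raise ValueError("no distances supplied")
    return 100.0 * float((distances_mm < cutoff_mm).mean())


# ---------------------------------------------------------------------------
# Aggregation of per-case tables


def _sd(values: np.ndarray) -> float:
    """Sample SD (ddof=1); single observations report 0."""
    return float(np.std(values, ddof=1)) if len(values) >= 2 else 0.0


def aggregate_summary(per_case: pd.DataFrame, value_columns=None,
                      group_by: str = "task") -> pd.DataFrame:
    """Per-group and grand mean/SD rows over a per-case table.

    ``per_case`` holds one row per case with a grouping column (e.g.
    task) and numeric value columns in which missing cells are NaN or
    the string markers '-' / '- -'. Missing cells are excluded from
    means; all-missing groups are omitted with a warning. Returns a
    table indexed by (group, statistic) with statistics mean, sd and n,
    plus a final ('all', ...) grand block pooling every available cell.
    """
    df = per_case.copy()
    if value_columns is None:
        value_columns = [c for c in df.columns if c != group_by]
    for c in value_columns:
        df[c] = pd.to_numeric(
            df[c].replace({MISSING: np.nan, MISSING_REF: np.nan, "--": np.nan}),
            errors="coerce",
        )
    rows = []
    groups = list(dict.fromkeys(df[group_by]))  # preserve order
    for g in groups:
        sub = df.loc[df[group_by] == g, value_columns]
        if sub.notna().sum().sum() == 0:
            warnings.warn(f"group {g!r} has no available cells; omitted")
            continue
        for stat in ("mean", "sd", "n"):
            row = {"group": g, "stat": stat}
            for c in value_columns:
                vals = sub[c].dropna().to_numpy()
                if len(vals) == 0:
                    row[c] = np.nan
                elif stat == "mean":
                    row[c] = float(np.mean(vals))
                elif stat == "sd":
                    row[c] = _sd(vals)
                else:
                    row[c] = len(vals)
            rows.append(row)
    for stat in ("mean", "sd", "n"):
        row = {"group": "all", "stat": stat}
        for c in value_columns:
            vals = df[c].dropna().to_numpy()
            if len(vals) == 0:
                row[c] = np.nan
            elif stat == "mean":
                row[c] = float(np.mean(vals))
            elif stat == "sd":
                row[c] = _sd(vals)
            else:
                row[c] = len(vals)
        rows.append(row)
    return pd.DataFrame(rows).set_index(["group", "stat"])
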