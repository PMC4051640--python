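"""Orchestration: I/O dispatch, packaged fixture tables, pipeline runs.

``run_phantom_case`` drives the whole chain on the synthetic phantom —
simulate, preprocess, map (task GLM, seed-based aROI/fROI, ICA),
AMPLE-threshold, then overlap, centre-of-mass and stimulation-site
concordance — and returns a :class:`CaseRecord` of per-method metrics.
Any method that fails at some stage is marked unavailable ('-'
semantics) and the run continues.

``load_fixture_tables`` exposes the packaged per-case tables of the
multi-patient clinical comparison (overlap, centre-of-mass and
stimulation-site distances under both operator-chosen and AMPLE
thresholds); ``table_summaries`` aggregates them into the headline
group-level statistics.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import concord, mapping, phantom, preprocess, rois
from .images import (BoldSeries, RoiMask, StatMap, read_bold, read_mask,
                     read_statmap, write_volume)

__all__ = [
    "CaseRecord",
    "PipelineConfig",
    "read_volume",
    "write_volume",
    "load_fixture_tables",
    "table_summaries",
    "dice",
    "run_phantom_case",
]

log = logging.getLogger("motormap")

METHODS = ("tb", "aROI", "fROI", "ICA")
FIXTURE_FILES = {
    "overlap_operator": "table4_overlap_operator.tsv",
    "overlap_ample": "table5_overlap_ample.tsv",
    "com_operator": "table6_com_operator.tsv",
    "ecs_operator": "table8_ecs_operator.tsv",
    "ecs_ample": "table9_ecs_ample.tsv",
}


def read_volume(path, kind: str | None = None, tr: float | None = None):
    """Read a NIfTI file as BoldSeries (4D), RoiMask (3D binary) or StatMap.

    ``kind`` may force 'bold', 'mask' or 'statmap'; by default 4D data
    become a BoldSeries and 3D data a RoiMask when strictly binary, else
    a StatMap.
    """
    import nibabel as nib

    img = nib.load(str(path))
    ndim = len(img.shape)
    if kind == "bold" or (kind is None and ndim == 4):
        return read_bold(path, tr=tr)
    if ndim != 3:
        raise ValueError(f"{path}: expected 3D or 4D image, got {ndim}D")
    if kind == "mask":
        return read_mask(path)
    if kind == "statmap":
        return read_statmap(path)
    arr = np.asarray(img.dataobj, dtype=float)
    if np.all(np.isin(np.unique(arr), (0.0, 1.0))):
        return read_mask(path)
    return read_statmap(path)


# ---------------------------------------------------------------------------
# Packaged fixture tables


def load_fixture_tables() -> dict[str, pd.DataFrame]:
    """Load the packaged per-case tables, verifying their checksums.

    Missing cells keep their markers: '-' (map unavailable) and '- -'
    (comparison impossible because the reference task map is absent).
    """
    pkg = resources.files("motormap") / "data"
    sums = json.loads((pkg / "checksums.json").read_text())
    out: dict[str, pd.DataFrame] = {}
    for key, fname in FIXTURE_FILES.items():
        raw = (pkg / fname).read_bytes()
        digest = hashlib.sha256(raw).hexdigest()
        if digest != sums[fname]:
            raise ValueError(f"fixture {fname} checksum mismatch")
        out[key] = pd.read_csv(pkg / fname, sep="\t", dtype=str)
    return out


def _num(df: pd.DataFrame, cols) -> pd.DataFrame:
    sub = df[cols].replace({"-": np.nan, "- -": np.nan, "--": np.nan})
    return sub.apply(pd.to_numeric)


def table_summaries() -> dict[str, float]:
    """Headline group-level statistics recomputed from the per-case tables.

    Percentages are on the 0-100 scale; alpha/beta on 0-1; distances mm.
    """
    t = load_fixture_tables()
    out: dict[str, float] = {}

    def grand_mean(df, col):
        agg = concord.aggregate_summary(df[["task", col]], [col], group_by="task")
        return float(agg.loc[("all", "mean"), col])

    def task_mean(df, col, task):
        agg = concord.aggregate_summary(df[["task", col]], [col], group_by="task")
        return float(agg.loc[(task, "mean"), col])

    op, am = t["overlap_operator"], t["overlap_ample"]
    out["alpha_aroi_grand_operator"] = grand_mean(op, "alpha_aroi")
    out["beta_froi_grand_operator"] = grand_mean(op, "beta_froi")
    out["alpha_aroi_foot_operator"] = task_mean(op, "alpha_aroi", "foot")
    out["alpha_froi_grand_ample"] = grand_mean(am, "alpha_froi")
    out["beta_froi_grand_ample"] = grand_mean(am, "beta_froi")

    for key, col, name in (
        ("ecs_operator", "d_tb", "ecs_mean_tb_operator"),
        ("ecs_operator", "d_aroi", "ecs_mean_aroi_operator"),
        ("ecs_operator", "d_froi", "ecs_mean_froi_operator"),
        ("ecs_operator", "d_ica", "ecs_mean_ica_operator"),
        ("ecs_ample", "d_tb", "ecs_mean_tb_ample"),
        ("ecs_ample", "d_aroi", "ecs_mean_aroi_ample"),
        ("ecs_ample", "d_ica", "ecs_mean_ica_ample"),
    ):
        vals = _num(t[key], [col])[col].dropna()
        out[name] = float(vals.mean())

    for key, name in (("ecs_operator", "ecs_match10_ica_operator"),
                      ("ecs_ample", "ecs_match10_ica_ample")):
        vals = _num(t[key], ["d_ica"])["d_ica"].dropna()
        out[name] = concord.match_rate(vals, 10.0)

    lesion_cols = ["dles_tb", "dles_aroi", "dles_froi", "dles_ica"]
    pooled = _num(t["com_operator"], lesion_cols).to_numpy().ravel()
    out["lesion_distance_grand_operator"] = float(np.nanmean(pooled))
    return out


# ---------------------------------------------------------------------------
# End-to-end phantom pipeline


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient of two boolean volumes."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    s = a.sum() + b.sum()
    if s == 0:
        raise ValueError("both sets are empty")
    return 2.0 * float((a & b).sum()) / float(s)


@dataclass
class PipelineConfig:
    """Configuration of a phantom pipeline run."""

    seed: int = 0
    methods: tuple[str, ...] = ("aROI", "fROI", "ICA")
    threshold_policy: str = "ample"  # "ample" or "fixed:<t>"
    n_components: int = 20
    ica_z_thr: float = 2.0
    eval_dilation_voxels: int = 2
    ecs_n_sites: int = 6
    ecs_offset_mm: float = 5.0
    preprocess: preprocess.PreprocessConfig = field(
        default_factory=preprocess.PreprocessConfig)
    rest_spec: phantom.PhantomSpec | None = None
    task_spec: phantom.PhantomSpec | None = None
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.methods:
            raise ValueError("at least one rs-fMRI method is required")
        bad = set(self.methods) - {"aROI", "fROI", "ICA"}
        if bad:
            raise ValueError(f"unknown methods {sorted(bad)}")


@dataclass
class CaseRecord:
    """Per-case results: availability flags plus metric rows per method."""

    case_id: str
    available: dict[str, bool]
    metrics: dict[str, dict[str, float]]
    dice_truth: dict[str, float] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)
    seed: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for method in METHODS:
            row: dict[str, object] = {"case": self.case_id, "method": method,
                                      "available": self.available.get(method, False)}
            row.update(self.metrics.get(method, {}))
            if method in self.dice_truth:
                row["dice_truth"] = self.dice_truth[method]
            rows.append(row)
        return pd.DataFrame(rows)


def _threshold(policy: str, stat_map: StatMap,
               motor_mask: RoiMask) -> concord.ThresholdedMap:
    if policy == "ample":
        return concord.ample_threshold(stat_map, motor_mask)
    if policy.startswith("fixed:"):
        return concord.fixed_threshold(stat_map, float(policy.split(":", 1)[1]))
    raise ValueError(f"unknown threshold policy {policy!r}")


def run_phantom_case(config: PipelineConfig, case_id: str = "phantom") -> CaseRecord:
    """Simulate one phantom case and run the full comparison chain.

    Steps: hand-task run -> smoothing + GLM (tb map); resting run ->
    denoising chain -> aROI/fROI seed maps and ICA component map;
    AMPLE (or fixed) thresholding with the motor mask ipsilateral to the
    lesion; overlap alpha/beta in the dilated bilateral motor mask; CoM
    and lesion distances; ECS sites placed at a known offset and scored
    per method.
    """
    seed = int(config.seed)
    task_spec = config.task_spec or phantom.default_task_spec(seed=seed)
    rest_spec = config.rest_spec or phantom.default_rest_spec(seed=seed + 1)
    truth = phantom.make_phantom(task_spec)
    design = phantom.default_block_design(task_spec.n_volumes, task_spec.tr)
    fwhm = config.preprocess.fwhm_mm

    record = CaseRecord(case_id=case_id, available={}, metrics={}, seed=seed)

    # --- task-based map -------------------------------------------------
    # each hemisphere follows only its own side's blocks, so left and
    # right regressors enter the design separately (each is the nuisance
    # of the other); the bilateral map is the voxel-wise max of the two
    # one-sided t maps. Cubic drift terms are modelled as confounds.
    task_run = phantom.simulate_task_bold(task_spec, design, truth, task="hand")
    task_run = preprocess.gaussian_smooth(task_run, fwhm)
    reg_l = mapping.build_task_regressor(design, side="left")
    reg_r = mapping.build_task_regressor(design, side="right")
    drift = preprocess._poly_basis(task_spec.n_volumes, 3)[:, 1:]
    t_left = mapping.glm_tmap(task_run, reg_l,
                              confounds=np.column_stack([reg_r, drift]))
    t_right = mapping.glm_tmap(task_run, reg_r,
                               confounds=np.column_stack([reg_l, drift]))
    tb_vals = np.maximum(t_left.values, t_right.values)
    tb_vals[~truth.brain_mask.values] = 0.0  # non-parenchymal voxels removed
    tb_map = StatMap(tb_vals, task_spec.affine, stat_kind="t",
                     dof=t_left.dof, provenance="tb")

    # lesion sits in the right hemisphere by construction: AMPLE peak
    # search uses the ipsilateral (right) motor strip
    g = truth.gyrus_masks
    aff = task_spec.affine
    motor_ipsi = RoiMask(g["precentral_R"].values | g["postcentral_R"].values,
                         aff, label="motor_ipsilateral")
    motor_bilat = RoiMask(
        g["precentral_L"].values | g["postcentral_L"].values
        | g["precentral_R"].values | g["postcentral_R"].values,
        aff, label="motor_bilateral")
    eval_mask = rois.dilate_mask(motor_bilat, config.eval_dilation_voxels)

    tb_thr = _threshold(config.threshold_policy, tb_map, motor_ipsi)
    record.available["tb"] = True
    record.metrics["tb"] = {
        "threshold": tb_thr.threshold,
        "volume_ml": float(tb_thr.supra.sum()) * eval_mask.voxel_volume_mm3() / 1e3,
    }
    record.dice_truth["tb"] = dice(tb_thr.supra,
                                   truth.activation("hand", "both").values)

    # --- resting-state maps ---------------------------------------------
    rest_truth = phantom.make_phantom(rest_spec)
    rest_run = phantom.simulate_rest_bold(rest_spec, rest_truth)
    rest_clean = preprocess.preprocess_rest(rest_run, truth.brain_mask,
                                            config.preprocess)

    def _brain_masked(stat: StatMap) -> StatMap:
        vals = stat.values.copy()
        vals[~truth.brain_mask.values] = 0.0
        return StatMap(vals, stat.affine, stat_kind=stat.stat_kind,
                       dof=stat.dof, provenance=stat.provenance)

    rs_maps: dict[str, StatMap] = {}
    if "aROI" in config.methods:
        try:
            knob = task_spec.regions["hand_knob_L"].center
            knob_mm = (np.asarray(knob) @ aff[:3, :3].T + aff[:3, 3])
            seed_roi = rois.build_hand_aroi(
                g["precentral_L"],
                rois.HandRoiSpec(knob_centre_mm=tuple(knob_mm), n_slices=10,
                                 slice_thickness_mm=2.0))
            tc = mapping.seed_timecourse(rest_clean, seed_roi)
            rs_maps["aROI"] = _brain_masked(
                mapping.sba_tmap(rest_clean, tc, provenance="aROI"))
        except Exception as exc:  # '-' semantics: carry on without the map
            record.notes.append(f"aROI unavailable: {exc}")
    if "fROI" in config.methods:
        try:
            motor_contra = RoiMask(
                g["precentral_L"].values | g["postcentral_L"].values, aff,
                label="motor_contralateral")
            froi = rois.build_froi(tb_map, motor_contra, radius_mm=6.0)
            tc = mapping.seed_timecourse(rest_clean, froi)
            rs_maps["fROI"] = _brain_masked(
                mapping.sba_tmap(rest_clean, tc, provenance="fROI"))
        except Exception as exc:
            record.notes.append(f"fROI unavailable: {exc}")
    if "ICA" in config.methods:
        try:
            dec = mapping.spatial_ica(rest_clean, truth.brain_mask,
                                      n_components=config.n_components,
                                      seed=seed + 2)
            rs_maps["ICA"] = mapping.select_sensorimotor_component(
                dec, motor_bilat, z_thr=config.ica_z_thr)
        except Exception as exc:
            record.notes.append(f"ICA unavailable: {exc}")

    # --- concordance -----------------------------------------------------
    les_com = concord.lesion_com(truth.lesion_mask)
    tb_com = concord.weighted_com(tb_thr, eval_mask)
    record.metrics["tb"]["lesion_distance_mm"] = concord.com_distance(tb_com,
                                                                      les_com)
    sites = phantom.place_ecs_sites(truth, n=config.ecs_n_sites,
                                    offset_mm=config.ecs_offset_mm,
                                    seed=seed + 3, task="hand")
    cortex = truth.network_mask
    for s in sites:
        concord.project_site_to_cortex(s, cortex)
        s.distances_mm["tb"] = concord.ecs_distance(s, tb_thr)
    record.metrics["tb"]["ecs_mean_mm"] = float(
        np.mean([s.distances_mm["tb"] for s in sites]))

    for method, rs_map in rs_maps.items():
        try:
            rs_thr = _threshold(config.threshold_policy, rs_map, motor_ipsi)
            ov = concord.overlap_alpha_beta(tb_thr, rs_thr, eval_mask)
            rs_com = concord.weighted_com(rs_thr, eval_mask)
            for s in sites:
                s.distances_mm[method] = concord.ecs_distance(s, rs_thr)
            record.available[method] = True
            record.metrics[method] = {
                "threshold": rs_thr.threshold,
                "volume_ml": float(rs_thr.supra.sum())
                * eval_mask.voxel_volume_mm3() / 1e3,
                "alpha": ov.alpha,
                "beta": ov.beta,
                "com_distance_mm": concord.com_distance(rs_com, tb_com),
                "lesion_distance_mm": concord.com_distance(rs_com, les_com),
                "ecs_mean_mm": float(
                    np.mean([s.distances_mm[method] for s in sites])),
            }
            record.dice_truth[method] = dice(rs_thr.supra,
                                             truth.network_mask.values)
        except Exception as exc:
            record.available[method] = False
            record.notes.append(f"{method} comparison unavailable: {exc}")

    for m in METHODS:
        record.available.setdefault(m, False)

    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        record.to_frame().to_csv(outdir / f"{case_id}_metrics.tsv",
                                 sep="\t", index=False)
        payload = {"case": case_id, "seed": seed,
                   "metrics": record.metrics, "dice_truth": record.dice_truth,
                   "notes": record.notes}
        (outdir / f"{case_id}_metrics.json").write_text(
            json.dumps(payload, indent=1, sort_keys=True))
        write_volume(tb_map, outdir / f"{case_id}_tb_tmap.nii.gz")
        for method, rs_map in rs_maps.items():
            write_volume(rs_map, outdir / f"{case_id}_{method}_map.nii.gz")
    return record
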