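"""Synthetic BOLD phantom with known ground truth.

Generates a parametric "head": brain ellipsoid, pre/post-central gyrus
slabs with a knob-like hand-area protrusion, paracentral lobules, a
ventral mouth strip, a lesion ellipsoid and a white-matter core — plus
block-design task runs and resting-state runs on that anatomy. All
geometry is analytic (boxes, ellipsoids, slabs), so every downstream
stage of the pipeline can be tested against exact ground truth without
any atlas or download.

Signal model
------------
A voxel time course is

    baseline + drift(t) + global_amp * g(t) + signal(t) + noise

where ``drift`` is a polynomial up to order 3 in normalized time,
``g(t)`` a brain-wide fluctuation shared by all voxels, ``signal`` is
either a boxcar-convolved-with-HRF response (task runs, restricted to
the task's activation region) or a band-limited (<0.1 Hz) fluctuation
shared by the sensorimotor network (rest runs), and the noise is i.i.d.
Gaussian. Amplitudes are expressed in percent of baseline. One RNG
stream per operation, derived from ``spec.seed`` plus a fixed offset, so
adding operations never perturbs existing draws.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .hrf import double_gamma_hrf
from .images import BoldSeries, RoiMask

__all__ = [
    "RegionDef",
    "PhantomSpec",
    "GroundTruth",
    "BlockDesign",
    "EcsSite",
    "default_regions",
    "default_rest_spec",
    "default_task_spec",
    "default_block_design",
    "make_phantom",
    "simulate_task_bold",
    "simulate_rest_bold",
    "place_ecs_sites",
]

# RNG stream offsets (per operation; never reuse)
_STREAM_TASK_NOISE = 1
_STREAM_REST_NOISE = 2
_STREAM_NETWORK_SOURCE = 3
_STREAM_GLOBAL_TASK = 4
_STREAM_GLOBAL_REST = 5


class ConfigurationError(ValueError):
    """Raised for invalid phantom specifications."""


@dataclass(frozen=True)
class RegionDef:
    """Analytic region: axis-aligned box or ellipsoid in voxel coordinates.

    ``center`` is the region centre (voxel units, may be fractional);
    ``size`` holds per-axis half-widths (box) or semi-axes (ellipsoid).
    """

    kind: str  # "box" | "ellipsoid"
    center: tuple[float, float, float]
    size: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.kind not in ("box", "ellipsoid"):
            raise ConfigurationError(f"unknown region kind {self.kind!r}")
        if any(s < 0 for s in self.size):
            raise ConfigurationError("region size must be non-negative")

    def rasterize(self, grid_shape: tuple[int, int, int]) -> np.ndarray:
        """Boolean membership grid; a voxel belongs if its index-centre does."""
        idx = np.indices(grid_shape, dtype=float)
        d = [idx[a] - self.center[a] for a in range(3)]
        if self.kind == "box":
            return np.logical_and.reduce(
                [np.abs(d[a]) <= self.size[a] for a in range(3)]
            )
        if any(s == 0 for s in self.size):  # degenerate ellipsoid is empty
            return np.zeros(grid_shape, dtype=bool)
        q = sum((d[a] / self.size[a]) ** 2 for a in range(3))
        return q <= 1.0

    def bounds_ok(self, grid_shape: tuple[int, int, int]) -> bool:
        return all(
            self.center[a] - self.size[a] >= -0.5
            and self.center[a] + self.size[a] <= grid_shape[a] - 0.5
            for a in range(3)
        )


def default_regions(grid_shape=(48, 54, 42)) -> dict[str, RegionDef]:
    """Default anatomy for the standard 48 x 54 x 42 grid (2.5 mm voxels).

    Axis convention: x left->right (midline between i=23 and 24), y
    posterior->anterior, z inferior->superior. The precentral slabs sit
    anterior to a two-row central sulcus; each carries an ellipsoidal
    knob protruding posteriorly at the hand-area level (z=28) so the
    hand-knob slice rule has a real landmark to work on. The brain is
    sized so the sensorimotor network occupies roughly a tenth of it —
    the spatial sparsity that makes resting-state networks separable
    components in the first place.
    """
    if tuple(grid_shape) != (48, 54, 42):
        raise ConfigurationError(
            "default_regions is laid out for a 48x54x42 grid; "
            "supply explicit regions for other grids"
        )
    r: dict[str, RegionDef] = {}
    r["brain"] = RegionDef("ellipsoid", (23.5, 26.5, 20.5), (22.0, 25.0, 19.5))
    # gyrus slabs: 9 voxels wide per hemisphere, 5 rows thick, 19 slices tall
    r["precentral_L"] = RegionDef("box", (11, 31, 24), (4, 2, 9))
    r["precentral_R"] = RegionDef("box", (36, 31, 24), (4, 2, 9))
    r["postcentral_L"] = RegionDef("box", (11, 24, 24), (4, 2, 9))
    r["postcentral_R"] = RegionDef("box", (36, 24, 24), (4, 2, 9))
    # knob-like posterior protrusion of the precentral slab at hand level
    r["hand_knob_L"] = RegionDef("ellipsoid", (11, 28, 28), (2.5, 1.4, 2.5))
    r["hand_knob_R"] = RegionDef("ellipsoid", (36, 28, 28), (2.5, 1.4, 2.5))
    # medial-wall paracentral lobules (foot area)
    r["paracentral_L"] = RegionDef("box", (21, 26, 33), (2, 5, 3))
    r["paracentral_R"] = RegionDef("box", (26, 26, 33), (2, 5, 3))
    # lesion anterior to the right precentral gyrus, clear of the slabs
    r["lesion"] = RegionDef("ellipsoid", (33, 38, 22), (3, 3, 3))
    # deep white-matter core (network regions are carved out in make_phantom)
    r["white_matter"] = RegionDef("ellipsoid", (23.5, 26.5, 16), (9.0, 11.0, 7.0))
    return r


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic acquisition; fixed seed => bit-identical output."""

    grid_shape: tuple[int, int, int] = (48, 54, 42)
    voxel_size: float = 2.5  # mm, isotropic
    n_volumes: int = 200
    tr: float = 2.8  # seconds
    regions: dict[str, RegionDef] = field(default_factory=default_regions)
    network_amplitude: float = 2.0  # % of baseline
    task_effect: float = 2.0  # % of baseline
    noise_sd: float = 20.0  # signal units
    drift_coeffs: tuple[float, ...] = (0.0, 8.0, -5.0, 3.0)  # signal units
    global_amp: float = 2.0  # % of baseline
    baseline: float = 1000.0  # signal units
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.grid_shape) or len(self.grid_shape) != 3:
            raise ConfigurationError("grid_shape must be three positive ints")
        if self.voxel_size <= 0:
            raise ConfigurationError("voxel_size must be > 0")
        if self.tr <= 0:
            raise ConfigurationError("tr must be > 0")
        if self.n_volumes < 2:
            raise ConfigurationError("n_volumes must be >= 2")
        if len(self.drift_coeffs) > 4:
            raise ConfigurationError("drift polynomial order is at most 3")
        for name, reg in self.regions.items():
            if not reg.bounds_ok(self.grid_shape):
                raise ConfigurationError(f"region {name!r} extends outside the grid")

    @property
    def affine(self) -> np.ndarray:
        """RAS+ affine with the grid centre at the world origin."""
        aff = np.eye(4)
        aff[:3, :3] = np.eye(3) * self.voxel_size
        aff[:3, 3] = -self.voxel_size * (np.asarray(self.grid_shape) - 1) / 2.0
        return aff

    def replace(self, **kw) -> "PhantomSpec":
        return dataclasses.replace(self, **kw)


def default_rest_spec(seed: int = 0, **kw) -> PhantomSpec:
    """200 volumes at TR 2.8 s — the resting-state acquisition length."""
    return PhantomSpec(n_volumes=200, tr=2.8, seed=seed, **kw)


def default_task_spec(seed: int = 0, **kw) -> PhantomSpec:
    """144 volumes at TR 3.0 s, matching the default 18-block design."""
    return PhantomSpec(n_volumes=144, tr=3.0, seed=seed, **kw)


# ---------------------------------------------------------------------------
# Block design


@dataclass(frozen=True)
class BlockDesign:
    """Ordered block layout tiling ``[0, n_volumes)`` without overlap.

    Each block is ``(condition, onset_volume, duration_volumes)`` with
    condition one of ``active_left``, ``active_right``, ``rest``.
    """

    n_volumes: int
    tr: float
    blocks: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ConfigurationError("tr must be > 0")
        covered = np.zeros(self.n_volumes, dtype=bool)
        for cond, onset, dur in self.blocks:
            if cond not in ("active_left", "active_right", "rest"):
                raise ConfigurationError(f"unknown condition {cond!r}")
            if onset < 0 or dur <= 0 or onset + dur > self.n_volumes:
                raise ConfigurationError(f"block {(cond, onset, dur)} outside run")
            if covered[onset : onset + dur].any():
                raise ConfigurationError("blocks overlap")
            covered[onset : onset + dur] = True
        if not covered.all():
            raise ConfigurationError("blocks do not tile the run")

    def boxcar(self, side: str) -> np.ndarray:
        """Indicator time course for ``left``/``right``/``both`` active blocks."""
        conds = {
            "left": ("active_left",),
            "right": ("active_right",),
            "both": ("active_left", "active_right"),
        }[side]
        box = np.zeros(self.n_volumes)
        for cond, onset, dur in self.blocks:
            if cond in conds:
                box[onset : onset + dur] = 1.0
        return box


def default_block_design(n_volumes: int = 144, tr: float = 3.0) -> BlockDesign:
    """12 active blocks (6 per side) and 6 rest blocks, in rest-L-R cycles."""
    if n_volumes % 18 != 0:
        raise ConfigurationError("default design needs n_volumes divisible by 18")
    dur = n_volumes // 18
    blocks = []
    onset = 0
    for _ in range(6):
        for cond in ("rest", "active_left", "active_right"):
            blocks.append((cond, onset, dur))
            onset += dur
    return BlockDesign(n_volumes=n_volumes, tr=tr, blocks=tuple(blocks))


# ---------------------------------------------------------------------------
# Ground truth


@dataclass
class GroundTruth:
    """All masks of the phantom on the spec grid."""

    activation_masks: dict[str, RoiMask]  # keys: hand_L, hand_R, foot_L, ...
    network_mask: RoiMask
    lesion_mask: RoiMask
    brain_mask: RoiMask
    white_matter_mask: RoiMask
    gyrus_masks: dict[str, RoiMask]  # precentral_L/R, postcentral_L/R, paracentral_L/R
    spec: PhantomSpec

    def activation(self, task: str, side: str = "both") -> RoiMask:
        """Bilateral or single-hemisphere activation mask for a task."""
        if side in ("L", "R"):
            return self.activation_masks[f"{task}_{side}"]
        union = (
            self.activation_masks[f"{task}_L"].values
            | self.activation_masks[f"{task}_R"].values
        )
        return RoiMask(union, self.spec.affine, label=f"{task}_bilateral")


def make_phantom(spec: PhantomSpec) -> GroundTruth:
    """Rasterize the spec's regions into mutually consistent masks."""
    shape = spec.grid_shape
    aff = spec.affine
    reg = spec.regions

    def need(name: str) -> np.ndarray:
        if name not in reg:
            raise ConfigurationError(f"spec.regions is missing {name!r}")
        return reg[name].rasterize(shape)

    brain = need("brain")
    # cortical regions are clipped to the brain so the signal model, the
    # brain-restricted noise and the ground-truth masks stay consistent
    gyrus_arrays: dict[str, np.ndarray] = {}
    for hemi in ("L", "R"):
        knob = need(f"hand_knob_{hemi}") & brain
        gyrus_arrays[f"precentral_{hemi}"] = (need(f"precentral_{hemi}") & brain) | knob
        gyrus_arrays[f"postcentral_{hemi}"] = need(f"postcentral_{hemi}") & brain
        gyrus_arrays[f"paracentral_{hemi}"] = need(f"paracentral_{hemi}") & brain

    activation: dict[str, RoiMask] = {}
    for hemi in ("L", "R"):
        pre = gyrus_arrays[f"precentral_{hemi}"]
        knob_def = reg[f"hand_knob_{hemi}"]
        kx, _, kz = knob_def.center
        idx = np.indices(shape, dtype=float)
        # hand area: knob plus the precentral neighbourhood of the knob
        hand = (need(f"hand_knob_{hemi}") & brain) | (
            pre & (np.abs(idx[2] - kz) <= 3) & (np.abs(idx[0] - kx) <= 4)
        )
        mouth = pre & (idx[2] >= 15) & (idx[2] <= 19)
        foot = gyrus_arrays[f"paracentral_{hemi}"]
        for task, arr in (("hand", hand), ("foot", foot), ("mouth", mouth)):
            if not arr.any():
                raise ConfigurationError(f"{task}_{hemi} activation region is empty")
            activation[f"{task}_{hemi}"] = RoiMask(arr, aff, label=f"{task}_{hemi}")

    network = np.zeros(shape, dtype=bool)
    for name in ("precentral_L", "precentral_R", "postcentral_L", "postcentral_R",
                 "paracentral_L", "paracentral_R"):
        network |= gyrus_arrays[name]
    if not network.any():
        raise ConfigurationError("network mask is empty")

    wm = need("white_matter") & ~network
    lesion = need("lesion")

    return GroundTruth(
        activation_masks=activation,
        network_mask=RoiMask(network, aff, label="sensorimotor_network"),
        lesion_mask=RoiMask(lesion, aff, label="lesion"),
        brain_mask=RoiMask(brain, aff, label="brain"),
        white_matter_mask=RoiMask(wm, aff, label="white_matter"),
        gyrus_masks={k: RoiMask(v, aff, label=k) for k, v in gyrus_arrays.items()},
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Signal synthesis


def _drift(spec: PhantomSpec) -> np.ndarray:
    tau = np.linspace(-1.0, 1.0, spec.n_volumes)
    out = np.zeros(spec.n_volumes)
    for k, c in enumerate(spec.drift_coeffs):
        out += c * tau**k
    return out


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def _band_limited_source(n: int, tr: float, cutoff_hz: float, rng) -> np.ndarray:
    """White noise brick-wall low-passed below ``cutoff_hz``, then z-scored."""
    x = rng.standard_normal(n)
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, d=tr)
    spec[freqs > cutoff_hz] = 0.0
    return _zscore(np.fft.irfft(spec, n))


def _nuisance(spec: PhantomSpec, series: np.ndarray, brain: np.ndarray,
              global_stream: int) -> None:
    """Add baseline, drift and global fluctuation in place (brain voxels)."""
    rng = np.random.default_rng(spec.seed + global_stream)
    g = _zscore(rng.standard_normal(spec.n_volumes))
    nuis = spec.baseline + _drift(spec) + spec.global_amp / 100.0 * spec.baseline * g
    series[brain] += nuis[None, :]


def simulate_task_bold(
    spec: PhantomSpec,
    design: BlockDesign,
    truth: GroundTruth,
    task: str = "hand",
) -> BoldSeries:
    """Block-design run: activation confined to the task's motor subregions.

    ``active_left`` blocks drive the right-hemisphere region and vice
    versa (movement activates the contralateral cortex).
    """
    if design.n_volumes != spec.n_volumes:
        raise ConfigurationError(
            f"design has {design.n_volumes} volumes, spec has {spec.n_volumes}"
        )
    for hemi in ("L", "R"):
        key = f"{task}_{hemi}"
        if key not in truth.activation_masks:
            raise ConfigurationError(f"unknown task {task!r}")
        if truth.activation_masks[key].shape3 != spec.grid_shape:
            raise ValueError("activation mask grid does not match spec grid")

    h = double_gamma_hrf(spec.tr)
    amp = spec.task_effect / 100.0 * spec.baseline
    series = np.zeros(spec.grid_shape + (spec.n_volumes,))
    for side, hemi in (("left", "R"), ("right", "L")):
        resp = np.convolve(design.boxcar(side), h)[: spec.n_volumes]
        mask = truth.activation_masks[f"{task}_{hemi}"].values
        series[mask] += amp * resp[None, :]

    brain = truth.brain_mask.values
    _nuisance(spec, series, brain, _STREAM_GLOBAL_TASK)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed + _STREAM_TASK_NOISE)
        series[brain] += rng.normal(0, spec.noise_sd, (int(brain.sum()), spec.n_volumes))
    return BoldSeries(series, spec.affine, spec.tr)


def simulate_rest_bold(spec: PhantomSpec, truth: GroundTruth) -> BoldSeries:
    """Resting run: network voxels share one <0.1 Hz band-limited source."""
    if truth.network_mask.shape3 != spec.grid_shape:
        raise ValueError("network mask grid does not match spec grid")
    rng_src = np.random.default_rng(spec.seed + _STREAM_NETWORK_SOURCE)
    source = _band_limited_source(spec.n_volumes, spec.tr, 0.1, rng_src)
    amp = spec.network_amplitude / 100.0 * spec.baseline

    series = np.zeros(spec.grid_shape + (spec.n_volumes,))
    series[truth.network_mask.values] += amp * source[None, :]
    brain = truth.brain_mask.values
    _nuisance(spec, series, brain, _STREAM_GLOBAL_REST)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed + _STREAM_REST_NOISE)
        series[brain] += rng.normal(0, spec.noise_sd, (int(brain.sum()), spec.n_volumes))
    return BoldSeries(series, spec.affine, spec.tr)


# ---------------------------------------------------------------------------
# ECS site placement


@dataclass
class EcsSite:
    """A cortical stimulation point in world mm."""

    id: str
    xyz_mm: tuple[float, float, float]
    response: str = "hand"
    projected_xyz_mm: tuple[float, float, float] | None = None
    distances_mm: dict[str, float] = field(default_factory=dict)


def _distance_to_mask(point: np.ndarray, mask: RoiMask,
                      centres: np.ndarray, inv_affine: np.ndarray) -> float:
    """0 if the containing voxel is in the mask, else distance to the
    nearest mask-voxel centre (world mm)."""
    ijk = np.round(point @ inv_affine[:3, :3].T + inv_affine[:3, 3]).astype(int)
    if np.all(ijk >= 0) and np.all(ijk < mask.shape3) and mask.values[tuple(ijk)]:
        return 0.0
    return float(np.min(np.linalg.norm(centres - point, axis=1)))


def place_ecs_sites(
    truth: GroundTruth,
    n: int,
    offset_mm: float,
    seed: int,
    task: str = "hand",
) -> list[EcsSite]:
    """Sample ``n`` sites at the stated Euclidean offset from the
    activation-mask surface, reproducibly under a fixed seed.

    ``offset_mm == 0`` places sites on surface voxel centres (inside the
    mask, so the distance reads 0); otherwise each site is moved outward
    along the ray from the mask centroid through a random surface voxel
    and bisected until its nearest-voxel distance equals ``offset_mm``.
    """
    if n < 1:
        raise ValueError("need at least one ECS site")
    mask = truth.activation(task, "both")
    if mask.is_empty:
        raise ValueError("activation mask is empty")
    from scipy import ndimage

    aff = mask.affine
    inv = np.linalg.inv(aff)
    ijk = np.argwhere(mask.values)
    centres = ijk @ aff[:3, :3].T + aff[:3, 3]
    eroded = ndimage.binary_erosion(mask.values)
    surface = np.argwhere(mask.values & ~eroded)
    rng = np.random.default_rng(seed)
    picks = surface[rng.integers(0, len(surface), size=n)]
    centroid = centres.mean(axis=0)

    sites: list[EcsSite] = []
    for i, vox in enumerate(picks):
        p0 = vox @ aff[:3, :3].T + aff[:3, 3]
        if offset_mm == 0:
            sites.append(EcsSite(id=f"site{i + 1}", xyz_mm=tuple(p0),
                                 response=task))
            continue
        u = p0 - centroid
        nu = np.linalg.norm(u)
        u = u / nu if nu > 0 else np.array([0.0, 0.0, 1.0])
        # bracket: distance along the ray is continuous and unbounded above
        lo, hi = 0.0, offset_mm + 1.0
        while _distance_to_mask(p0 + hi * u, mask, centres, inv) < offset_mm:
            hi *= 2.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if _distance_to_mask(p0 + mid * u, mask, centres, inv) < offset_mm:
                lo = mid
            else:
                hi = mid
        sites.append(EcsSite(id=f"site{i + 1}",
                             xyz_mm=tuple(p0 + hi * u), response=task))
    return sites
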