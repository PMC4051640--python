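import numpy as np
import pandas as pd
import pytest

from motormap.concord import (MISSING, MISSING_REF, CentreOfMass,
                              MatchCriteria, OverlapResult,
                              UndefinedResultError, aggregate_summary,
                              ample_threshold, com_distance, ecs_distance,
                              fixed_threshold, lesion_com, match_rate,
                              overlap_alpha_beta, project_site_to_cortex,
                              weighted_com)
from motormap.images import RoiMask, StatMap
from motormap.phantom import EcsSite

VOX = 2.0
AFF = np.diag([VOX, VOX, VOX, 1.0])
AFF[:3, 3] = (-10.0, -10.0, -10.0)
SHAPE = (11, 11, 11)


def _mask(values=None):
    if values is None:
        values = np.ones(SHAPE, bool)
    return RoiMask(values, AFF)


def _map(values):
    return StatMap(np.asarray(values, dtype=float), AFF)


# --- AMPLE thresholding -----------------------------------------------------


def test_threshold_is_half_the_in_mask_peak(rng):
    vals = np.zeros(SHAPE)
    vals[5, 5, 5] = 10.0
    thr = ample_threshold(_map(vals), _mask())
    assert thr.threshold == 5.0
    assert thr.supra[5, 5, 5]  # peak always supra


def test_constant_map_keeps_all_mask_voxels():
    vals = np.full(SHAPE, 4.0)
    thr = ample_threshold(_map(vals), _mask())
    assert thr.threshold == 2.0
    assert thr.supra.all()


def test_out_of_mask_global_maximum_ignored(rng):
    vals = rng.random(SHAPE)
    vals[0, 0, 0] = 20.0  # global max outside the mask
    inside = np.zeros(SHAPE, bool)
    inside[4:8, 4:8, 4:8] = True
    vals[6, 6, 6] = 8.0
    thr = ample_threshold(_map(vals), _mask(inside))
    # oracle: brute-force masked maximum
    assert thr.threshold == 0.5 * max(
        vals[i, j, k] for i, j, k in np.argwhere(inside))
    assert thr.threshold == 4.0


def test_non_positive_peak_rejected():
    vals = -np.ones(SHAPE)
    with pytest.raises(ValueError, match="no excitable peak"):
        ample_threshold(_map(vals), _mask())


# --- overlap ----------------------------------------------------------------


def _thr_from_bool(supra):
    vals = np.where(supra, 1.0, -1.0)
    return fixed_threshold(_map(vals), 0.5)


def test_overlap_trivial_and_forced_cases(rng):
    a = rng.random(SHAPE) > 0.5
    same = overlap_alpha_beta(_thr_from_bool(a), _thr_from_bool(a), _mask())
    assert same.alpha == 1.0 and same.beta == 1.0

    b = ~a
    with np.errstate(all="ignore"):
        disjoint = overlap_alpha_beta(_thr_from_bool(a), _thr_from_bool(b),
                                      _mask())
    assert disjoint.alpha == 0.0 and disjoint.beta == 0.0

    forced = OverlapResult(v_tb=50, v_rs=100, v_overlap=25)
    assert forced.alpha == 0.5 and forced.beta == 0.25


def test_overlap_swapping_maps_swaps_alpha_and_beta(rng):
    a = rng.random(SHAPE) > 0.4
    b = rng.random(SHAPE) > 0.6
    ab = overlap_alpha_beta(_thr_from_bool(a), _thr_from_bool(b), _mask())
    ba = overlap_alpha_beta(_thr_from_bool(b), _thr_from_bool(a), _mask())
    assert ab.alpha == ba.beta and ab.beta == ba.alpha
    assert ab.v_overlap <= min(ab.v_tb, ab.v_rs)


def test_raising_threshold_never_increases_overlap(rng):
    vals_a = rng.random(SHAPE)
    vals_b = rng.random(SHAPE)
    prev = None
    for thr in (0.2, 0.4, 0.6):
        ov = overlap_alpha_beta(fixed_threshold(_map(vals_a), thr),
                                fixed_threshold(_map(vals_b), 0.3), _mask())
        if prev is not None:
            assert ov.v_overlap <= prev
        prev = ov.v_overlap


def test_empty_masked_volume_is_undefined(rng):
    a = np.zeros(SHAPE, bool)
    a[0, 0, 0] = True
    b = rng.random(SHAPE) > 0.5
    inside = np.zeros(SHAPE, bool)
    inside[5:, 5:, 5:] = True  # excludes all of a
    with pytest.raises(UndefinedResultError):
        overlap_alpha_beta(_thr_from_bool(a), _thr_from_bool(b), _mask(inside))


# --- centres of mass --------------------------------------------------------


def test_single_voxel_com_is_its_centre():
    vals = np.zeros(SHAPE)
    vals[5, 5, 5] = 3.0
    com = weighted_com(fixed_threshold(_map(vals), 1.0), _mask())
    assert np.allclose(com.xyz_mm, (0.0, 0.0, 0.0))


def test_two_voxel_weighted_mean():
    vals = np.zeros(SHAPE)
    vals[5, 5, 5] = 1.0   # x = 0
    vals[10, 5, 5] = 3.0  # x = 10
    com = weighted_com(fixed_threshold(_map(vals), 0.5), _mask())
    assert com.xyz_mm[0] == pytest.approx(7.5)


def test_weighted_com_matches_exhaustive_sum_oracle(rng):
    vals = rng.random((10, 10, 10)) * 4.0
    aff = AFF
    smap = StatMap(vals, aff)
    thr = fixed_threshold(smap, 2.0)
    mask = RoiMask(rng.random((10, 10, 10)) > 0.3, aff)
    num = np.zeros(3)
    den = 0.0
    for i in range(10):
        for j in range(10):
            for k in range(10):
                if vals[i, j, k] >= 2.0 and mask.values[i, j, k]:
                    xyz = aff[:3, :3] @ (i, j, k) + aff[:3, 3]
                    num += vals[i, j, k] * xyz
                    den += vals[i, j, k]
    com = weighted_com(thr, mask)
    assert np.max(np.abs(com.xyz_mm - num / den)) < 1e-10


def test_lesion_com_unweighted_centroid(rng):
    vals = rng.random(SHAPE) > 0.7
    if not vals.any():
        vals[3, 3, 3] = True
    mask = _mask(vals)
    com = lesion_com(mask)
    centres = np.argwhere(vals) @ AFF[:3, :3].T + AFF[:3, 3]
    assert np.allclose(com.xyz_mm, centres.mean(axis=0))
    assert not com.weighted


def test_com_distance_euclidean_and_symmetric():
    a = CentreOfMass((0.0, 0.0, 0.0), True, 1)
    b = CentreOfMass((3.0, 4.0, 0.0), True, 1)
    assert com_distance(a, b) == 5.0
    assert com_distance(b, a) == 5.0
    assert com_distance(a, a) == 0.0


# --- ECS --------------------------------------------------------------------


def test_projection_keeps_inside_sites_and_snaps_outside_ones():
    cortex = np.zeros(SHAPE, bool)
    cortex[:, :, 5] = True  # flat slab at world z = 0
    mask = _mask(cortex)
    inside = EcsSite("a", (0.0, 0.0, 0.0))
    project_site_to_cortex(inside, mask)
    assert inside.projected_xyz_mm == (0.0, 0.0, 0.0)

    above = EcsSite("b", (0.0, 0.0, 5.0))
    project_site_to_cortex(above, mask)
    assert np.allclose(above.projected_xyz_mm, (0.0, 0.0, 0.0))
    assert np.linalg.norm(np.subtract(above.projected_xyz_mm,
                                      above.xyz_mm)) == pytest.approx(5.0)


def test_ecs_distance_matches_brute_force_scan(rng):
    vals = rng.random(SHAPE)
    thr = fixed_threshold(_map(vals), 0.8)
    site = EcsSite("s", (7.3, -4.1, 9.9))
    got = ecs_distance(site, thr)
    # oracle: containing-voxel check then full scan over supra centres
    inv = np.linalg.inv(AFF)
    ijk = np.round(np.array(site.xyz_mm) @ inv[:3, :3].T + inv[:3, 3]).astype(int)
    if thr.supra[tuple(ijk)]:
        expected = 0.0
    else:
        centres = np.argwhere(thr.supra) @ AFF[:3, :3].T + AFF[:3, 3]
        expected = np.min(np.linalg.norm(centres - site.xyz_mm, axis=1))
    assert got == pytest.approx(expected, abs=1e-10)


def test_site_inside_activation_scores_zero():
    vals = np.zeros(SHAPE)
    vals[5, 5, 5] = 2.0
    thr = fixed_threshold(_map(vals), 1.0)
    assert ecs_distance(EcsSite("s", (0.4, -0.4, 0.2)), thr) == 0.0
    with pytest.raises(UndefinedResultError):
        ecs_distance(EcsSite("s", (0, 0, 0)), fixed_threshold(_map(vals), 99.0))


def test_match_rate_examples():
    assert match_rate([0.0, 0.0, 0.0], 10.0) == 100.0
    assert match_rate([12.0, 15.0], 10.0) == 0.0
    table9_ica = [38, 41.4, 0, 2.8, 30.8, 7.2, 24.5, 26, 16.5, 16.5]
    assert match_rate(table9_ica, 10.0) == pytest.approx(30.0)
    with pytest.raises(ValueError):
        match_rate([], 10.0)
    with pytest.raises(ValueError):
        MatchCriteria(cutoffs_mm=(10.0, 7.0))


# --- aggregation ------------------------------------------------------------


def test_aggregate_summary_handles_missing_and_single_values():
    df = pd.DataFrame({
        "task": ["hand", "hand", "foot", "foot", "mouth"],
        "alpha": ["0.50", "0.70", MISSING, "0.30", MISSING_REF],
    })
    out = aggregate_summary(df, ["alpha"])
    assert out.loc[("hand", "mean"), "alpha"] == pytest.approx(0.60)
    assert out.loc[("hand", "sd"), "alpha"] == pytest.approx(
        np.std([0.5, 0.7], ddof=1))
    assert out.loc[("foot", "mean"), "alpha"] == pytest.approx(0.30)
    assert out.loc[("foot", "sd"), "alpha"] == 0.0  # single value
    assert out.loc[("all", "n"), "alpha"] == 3
    assert ("mouth", "mean") not in out.index or np.isnan(
        out.loc[("mouth", "mean"), "alpha"])


def test_all_missing_group_is_omitted_with_warning():
    df = pd.DataFrame({"task": ["hand", "foot"], "v": ["1.0", MISSING]})
    with pytest.warns(UserWarning, match="omitted"):
        out = aggregate_summary(df, ["v"])
    assert ("foot", "mean") not in out.index
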