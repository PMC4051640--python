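import numpy as np
import pytest

from motormap.images import BoldSeries, RoiMask
from motormap.preprocess import (PreprocessConfig, detrend_polynomial,
                                 gaussian_smooth, global_signal_regress,
                                 lowpass_filter, preprocess_rest,
                                 regress_confounds, temporal_snr)

AFF = np.diag([2.0, 2.0, 2.0, 1.0])


def _series(data, tr=2.8):
    return BoldSeries(np.asarray(data, dtype=float), AFF, tr=tr)


def _grid_series(rng, shape=(4, 4, 3), t=60, tr=2.8):
    return _series(rng.standard_normal(shape + (t,)), tr=tr)


# --- confound regression ----------------------------------------------------


def test_confound_equal_to_voxel_course_removes_it(rng):
    conf = rng.standard_normal((40, 1))
    data = np.tile(conf[:, 0], (2, 2, 2, 1))
    out = regress_confounds(_series(data), conf)
    assert np.max(np.abs(out.data)) < 1e-10


def test_residuals_orthogonal_to_all_confounds(rng):
    series = _grid_series(rng, t=80)
    conf = rng.standard_normal((80, 6))
    out = regress_confounds(series, conf)
    flat = out.data.reshape(-1, 80)
    corr = flat @ conf / 80
    assert np.max(np.abs(corr)) < 1e-10


def test_orthogonal_confound_changes_only_the_mean(rng):
    t = np.arange(64)
    voxel = np.sin(2 * np.pi * t / 16)
    conf = np.cos(2 * np.pi * t / 16)[:, None]  # orthogonal over full periods
    data = voxel.reshape(1, 1, 1, -1)
    out = regress_confounds(_series(data), conf)
    assert np.max(np.abs(out.data[0, 0, 0] - (voxel - voxel.mean()))) < 1e-10


def test_rank_deficient_design_warns(rng):
    series = _grid_series(rng, t=30)
    conf = np.ones((30, 2))  # duplicates the intercept twice
    with pytest.warns(UserWarning, match="rank-deficient"):
        regress_confounds(series, conf)


# --- detrending -------------------------------------------------------------


def test_cubic_course_removed_exactly(rng):
    tau = np.linspace(-1, 1, 100)
    coeffs = rng.standard_normal((3, 4))
    data = np.stack([c[0] + c[1] * tau + c[2] * tau**2 + c[3] * tau**3
                     for c in coeffs]).reshape(3, 1, 1, 100)
    out = detrend_polynomial(_series(data), 3)
    assert np.max(np.abs(out.data)) < 1e-8


def test_order_zero_removes_mean_only(rng):
    series = _grid_series(rng)
    out = detrend_polynomial(series, 0)
    assert np.max(np.abs(out.data.mean(axis=3))) < 1e-10
    centred = series.data - series.data.mean(axis=3, keepdims=True)
    assert np.max(np.abs(out.data - centred)) < 1e-10


def test_detrend_preserves_orthogonal_oscillation(rng):
    tau = np.linspace(-1, 1, 120)
    sine = np.sin(2 * np.pi * 15 * tau)
    data = (2.0 - tau + 0.5 * tau**3 + sine).reshape(1, 1, 1, -1)
    out = detrend_polynomial(_series(data), 3)
    r = np.corrcoef(out.data[0, 0, 0], sine)[0, 1]
    assert r > 0.999
    # least-squares oracle: residual equals sine minus its own projection
    basis = np.column_stack([tau**k for k in range(4)])
    proj = basis @ np.linalg.lstsq(basis, sine, rcond=None)[0]
    assert np.max(np.abs(out.data[0, 0, 0] - (sine - proj))) < 1e-8


def test_negative_order_rejected(rng):
    with pytest.raises(ValueError):
        detrend_polynomial(_grid_series(rng), -1)


# --- low-pass filter --------------------------------------------------------


def _amplitude_ratio(freq_hz, tr=2.8, cutoff=0.1, n=400):
    t = np.arange(n) * tr
    wave = np.sin(2 * np.pi * freq_hz * t)
    out = lowpass_filter(_series(wave.reshape(1, 1, 1, -1), tr=tr), cutoff)
    return np.sqrt(np.mean(out.data**2) / np.mean(wave**2))


def test_constant_series_passes_unchanged():
    data = np.full((2, 2, 2, 50), 7.0)
    out = lowpass_filter(_series(data), 0.1)
    assert np.max(np.abs(out.data - 7.0)) < 1e-10


def test_passband_and_stopband_behaviour():
    assert _amplitude_ratio(0.05) >= 0.95
    assert _amplitude_ratio(0.2) <= 0.05


def test_zero_phase_preserves_waveform_alignment():
    t = np.arange(300) * 2.8
    wave = np.sin(2 * np.pi * 0.03 * t)
    out = lowpass_filter(_series(wave.reshape(1, 1, 1, -1)), 0.1).data[0, 0, 0]
    lag = np.argmax(np.correlate(out, wave, mode="full")) - (len(wave) - 1)
    assert lag == 0


def test_cutoff_above_nyquist_rejected(rng):
    with pytest.raises(ValueError, match="Nyquist"):
        lowpass_filter(_grid_series(rng, tr=2.8), 0.2)


# --- global signal regression -----------------------------------------------


def test_identical_voxels_zeroed(rng):
    course = rng.standard_normal(50)
    data = np.tile(course, (3, 3, 2, 1))
    mask = RoiMask(np.ones((3, 3, 2), bool), AFF)
    out = global_signal_regress(_series(data), mask)
    assert np.max(np.abs(out.data)) < 1e-10


def test_post_gsr_correlations_vanish(rng):
    series = _grid_series(rng, shape=(5, 5, 4), t=100)
    mask = RoiMask(np.ones((5, 5, 4), bool), AFF)
    g = series.data[mask.values].mean(axis=0)
    out = global_signal_regress(series, mask)
    gc = (g - g.mean()) / g.std()
    flat = out.data.reshape(-1, 100)
    corr = flat @ gc / 100 / np.maximum(flat.std(axis=1), 1e-30)
    assert np.max(np.abs(corr)) < 1e-10
    g_out = out.data[mask.values].mean(axis=0)
    assert g_out.var() < 1e-6 * g.var()


def test_empty_mask_rejected(rng):
    series = _grid_series(rng)
    with pytest.raises(ValueError, match="empty"):
        global_signal_regress(series, RoiMask(np.zeros((4, 4, 3), bool), AFF))


# --- smoothing --------------------------------------------------------------


def test_fwhm_zero_is_identity(rng):
    arr = rng.standard_normal((8, 8, 8))
    assert np.array_equal(gaussian_smooth(arr, 0.0, 2.0), arr)


def test_delta_response_matches_closed_form_gaussian():
    vox = 2.0
    arr = np.zeros((41, 41, 41))
    arr[20, 20, 20] = 1.0
    out = gaussian_smooth(arr, 8.0, vox)
    sigma = 8.0 / (2 * np.sqrt(2 * np.log(2)))
    ratio = out[21, 20, 20] / out[20, 20, 20]
    assert ratio == pytest.approx(np.exp(-(vox**2) / (2 * sigma**2)), abs=1e-3)
    assert out.sum() == pytest.approx(1.0, abs=1e-6)  # interior mass conserved


def test_series_smoothing_is_volume_wise(rng):
    series = _grid_series(rng, shape=(8, 8, 8), t=4)
    out = gaussian_smooth(series, 6.0)
    for t in range(4):
        vol = gaussian_smooth(series.data[..., t], 6.0, 2.0)
        assert np.allclose(out.data[..., t], vol)


# --- tSNR -------------------------------------------------------------------


def test_tsnr_single_and_two_voxel_examples():
    t = 64
    rng = np.random.default_rng(0)
    aff = AFF
    base = np.zeros((2, 1, 1, t))
    course = rng.standard_normal(t)
    course = (course - course.mean()) / course.std(ddof=0)
    base[0, 0, 0] = 100 + 0.5 * course  # tSNR 200
    base[1, 0, 0] = 100 + 1.0 * course  # tSNR 100
    one = RoiMask(np.array([[[True]], [[False]]]), aff)
    both = RoiMask(np.ones((2, 1, 1), bool), aff)
    series = BoldSeries(base, aff, tr=2.0)
    assert temporal_snr(series, one) == pytest.approx(200.0, rel=1e-9)
    assert temporal_snr(series, both) == pytest.approx(150.0, rel=1e-9)


def test_tsnr_on_phantom_white_matter(small_spec, small_truth):
    from motormap.phantom import simulate_rest_bold

    spec = small_spec.replace(drift_coeffs=(0.0,), global_amp=0.0)
    series = simulate_rest_bold(spec, small_truth)
    expected = spec.baseline / spec.noise_sd
    got = temporal_snr(series, small_truth.white_matter_mask)
    assert got == pytest.approx(expected, rel=0.05)


def test_zero_variance_voxels_excluded_with_warning():
    data = np.zeros((2, 1, 1, 10))
    data[0, 0, 0] = 100.0  # constant -> zero variance
    data[1, 0, 0] = 100 + np.sin(np.arange(10))
    series = BoldSeries(data, AFF, tr=2.0)
    mask = RoiMask(np.ones((2, 1, 1), bool), AFF)
    with pytest.warns(UserWarning, match="zero-variance"):
        temporal_snr(series, mask)


# --- full chain -------------------------------------------------------------


def test_null_configuration_is_identity_on_band_limited_data(rng):
    # zero-mean data whose spectrum lies fully below the filter's
    # pass-band edge: every chain step is then a no-op in its null config
    raw = rng.standard_normal((4, 4, 3, 100))
    spec = np.fft.rfft(raw, axis=3)
    freqs = np.fft.rfftfreq(100, d=2.8)
    spec[..., freqs > 0.05] = 0.0
    data = np.fft.irfft(spec, 100, axis=3)
    data -= data.mean(axis=3, keepdims=True)
    series = _series(data)
    mask = RoiMask(np.ones((4, 4, 3), bool), AFF)
    cfg = PreprocessConfig(poly_order=0, lowpass_hz=0.1, fwhm_mm=0.0,
                           do_gsr=False)
    out = preprocess_rest(series, mask, cfg)
    assert np.max(np.abs(out.data - data)) < 1e-10


def test_invalid_configs_rejected(rng):
    series = _grid_series(rng, tr=2.8)
    mask = RoiMask(np.ones((4, 4, 3), bool), AFF)
    with pytest.raises(ValueError):
        preprocess_rest(series, mask, PreprocessConfig(lowpass_hz=0.5))
    with pytest.raises(ValueError):
        preprocess_rest(series, mask, PreprocessConfig(fwhm_mm=-1.0))
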