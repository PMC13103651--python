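import numpy as np
import pytest
from hypothesis import given, strategies as st

from thalatarget.errors import ArgumentError
from thalatarget.geometry import make_grid
from thalatarget.preprocess import (FWHM_TO_SIGMA, BoldRun, bandpass,
                                    build_confounds_36p, build_confounds_gsr,
                                    censor, drop_initial_frames,
                                    framewise_displacement, regress_out, smooth)
from thalatarget.synth import MotionParams


def _run(data, tr=2.0):
    data = np.asarray(data, dtype=float)
    return BoldRun(data, tr, np.ones(data.shape[0], dtype=bool))


# ---------------------------------------------------------------- frames ---

def test_drop_initial_frames_240_to_230():
    run = _run(np.random.default_rng(0).normal(size=(240, 4)))
    out = drop_initial_frames(run, 10)
    assert out.n_frames == 230
    assert np.array_equal(out.data, run.data[10:])


def test_drop_zero_is_identity_and_full_drop_errors():
    run = _run(np.arange(12, dtype=float).reshape(6, 2))
    assert np.array_equal(drop_initial_frames(run, 0).data, run.data)
    with pytest.raises(ArgumentError):
        drop_initial_frames(run, 6)


# ---------------------------------------------------------------- FD -------

def test_fd_constant_parameters_is_zero():
    fd = framewise_displacement(MotionParams(np.ones((10, 6))))
    assert np.allclose(fd, 0.0)


def test_fd_translation_step():
    params = np.zeros((5, 6))
    params[3:, 1] = 0.3
    fd = framewise_displacement(MotionParams(params))
    assert fd[3] == pytest.approx(0.3)
    assert fd[[0, 1, 2, 4]].max() == 0.0


def test_fd_rotation_arc_length_conversion():
    params = np.zeros((4, 6))
    params[2:, 4] = 0.01  # radians
    fd = framewise_displacement(MotionParams(params), head_radius_mm=50.0)
    assert fd[2] == pytest.approx(0.5)  # 50 mm * 0.01 rad


# ---------------------------------------------------------------- censor ---

def test_censor_strictly_greater_than_threshold():
    run = _run(np.zeros((3, 2)))
    out = censor(run, np.array([0.1, 0.6, 0.4]), 0.5)
    assert out.mask.tolist() == [True, False, True]
    exactly = censor(run, np.array([0.5, 0.5, 0.5]), 0.5)
    assert exactly.mask.all()  # FD exactly at threshold is retained
    assert np.array_equal(out.data, run.data)  # censoring is logical only


@given(st.lists(st.floats(0, 2), min_size=4, max_size=30),
       st.floats(0.05, 1.0), st.floats(0.05, 1.0))
def test_censor_monotone_in_threshold(fd, thr_a, thr_b):
    lo, hi = sorted([thr_a, thr_b])
    run = _run(np.zeros((len(fd), 1)))
    n_lo = censor(run, np.array(fd), lo).n_retained
    n_hi = censor(run, np.array(fd), hi).n_retained
    assert n_lo <= n_hi


# ---------------------------------------------------------------- 36P ------

def test_confounds_have_36_ordered_columns(rng):
    motion = MotionParams(rng.normal(size=(20, 6)))
    tissue = rng.normal(size=(20, 3))
    conf = build_confounds_36p(motion, tissue)
    assert conf.values.shape == (20, 36)
    assert conf.columns[:6] == ("trans_x", "trans_y", "trans_z",
                                "rot_x", "rot_y", "rot_z")
    assert conf.columns[6:9] == ("global_signal", "white_matter", "csf")
    assert all(c.endswith("_derivative1") for c in conf.columns[9:18])
    assert all(c.endswith("_power2") for c in conf.columns[18:36])


def test_confounds_zero_input_and_constant_motion():
    conf = build_confounds_36p(MotionParams(np.zeros((8, 6))), np.zeros((8, 3)))
    assert np.all(conf.values == 0.0)
    motion = MotionParams(np.full((8, 6), 1.5))
    conf = build_confounds_36p(motion, np.zeros((8, 3)))
    deriv = conf.values[:, 9]  # trans_x_derivative1
    square = conf.values[:, 18]  # trans_x_power2
    assert np.allclose(deriv, 0.0)
    assert np.allclose(square, 1.5**2)
    # backward difference: first element defined as 0
    ramp = MotionParams(np.outer(np.arange(8.0), np.ones(6)))
    conf = build_confounds_36p(ramp, np.zeros((8, 3)))
    assert conf.values[0, 9] == 0.0
    assert np.allclose(conf.values[1:, 9], 1.0)


def test_gsr_recipe_has_28_columns(rng):
    conf = build_confounds_gsr(MotionParams(rng.normal(size=(12, 6))),
                               rng.normal(size=12))
    assert conf.values.shape == (12, 28)


# ---------------------------------------------------------------- OLS ------

def test_regression_toy_residuals_by_hand():
    # data [1,2,3,4] on regressor [1,1,2,2] + intercept: group means 1.5, 3.5
    from thalatarget.preprocess import ConfoundMatrix

    run = _run(np.array([[1.0], [2.0], [3.0], [4.0]]))
    conf = ConfoundMatrix(np.array([[1.0], [1.0], [2.0], [2.0]]), ("reg",))
    out = regress_out(run, conf)
    assert np.allclose(out.data[:, 0], [-0.5, 0.5, -0.5, 0.5])


def test_residuals_orthogonal_to_confounds(rng):
    data = rng.normal(size=(60, 5))
    motion = MotionParams(rng.normal(size=(60, 6)) * 0.1)
    tissue = rng.normal(size=(60, 3))
    conf = build_confounds_36p(motion, tissue)
    out = regress_out(_run(data), conf)
    for j in range(conf.values.shape[1]):
        c = conf.values[:, j] - conf.values[:, j].mean()
        r = out.data
        num = np.abs(c @ r)
        den = np.linalg.norm(c) * np.linalg.norm(r, axis=0)
        assert np.all(num / np.where(den == 0, 1, den) < 1e-8)


def test_regression_idempotent(rng):
    data = rng.normal(size=(50, 4))
    conf = build_confounds_36p(MotionParams(rng.normal(size=(50, 6))),
                               rng.normal(size=(50, 3)))
    once = regress_out(_run(data), conf)
    twice = regress_out(once, conf)
    assert np.allclose(once.data, twice.data, atol=1e-10)


def test_regression_drops_collinear_columns(rng, caplog):
    # duplicate tissue columns make the design rank-deficient
    motion = MotionParams(rng.normal(size=(40, 6)))
    tissue = rng.normal(size=(40, 3))
    tissue[:, 2] = tissue[:, 1]
    conf = build_confounds_36p(motion, tissue)
    out = regress_out(_run(rng.normal(size=(40, 2))), conf)
    assert np.all(np.isfinite(out.data))


def test_regression_interpolates_censored_frames(rng):
    from thalatarget.preprocess import ConfoundMatrix

    data = rng.normal(size=(30, 3))
    mask = np.ones(30, dtype=bool)
    mask[10] = False
    run = BoldRun(data, 2.0, mask)
    conf = ConfoundMatrix(rng.normal(size=(30, 2)), ("a", "b"))
    out = regress_out(run, conf)
    assert np.allclose(out.data[10], (out.data[9] + out.data[11]) / 2)
    assert not out.mask[10]


# ---------------------------------------------------------------- filter ---

def _amplitude_ratio(freq_hz, tr=2.0, n=600):
    t = np.arange(n) * tr
    x = np.sin(2 * np.pi * freq_hz * t)
    out = bandpass(_run(x[:, None], tr=tr)).data[:, 0]
    mid = slice(n // 4, 3 * n // 4)
    return np.sqrt(np.mean(out[mid] ** 2) / np.mean(x[mid] ** 2))


def test_bandpass_removes_dc():
    out = bandpass(_run(np.full((230, 2), 7.0))).data
    assert np.abs(out).max() < 0.01 * 7.0  # >= 99% attenuation


def test_bandpass_passband_and_stopband():
    assert _amplitude_ratio(0.05) >= 0.8   # passband centre retained
    assert _amplitude_ratio(0.2) <= 0.2    # stopband attenuated


def test_bandpass_rejects_band_outside_nyquist():
    with pytest.raises(ArgumentError):
        bandpass(_run(np.zeros((40, 1)), tr=2.0), 0.01, 0.3)


# ---------------------------------------------------------------- smooth ---

def test_smoothing_sigma_in_voxels():
    assert 6.0 * FWHM_TO_SIGMA / 2.0 == pytest.approx(1.2740, abs=1e-4)


def test_smooth_constant_volume_unchanged():
    grid = make_grid(12, 2.0)
    vals = np.full(grid.n_voxels, 3.25)
    out = smooth(vals, 6.0, space=grid)
    assert np.allclose(out, 3.25)


def test_smooth_impulse_matches_analytic_kernel():
    grid = make_grid(21, 2.0)
    vals = np.zeros(grid.n_voxels)
    center = (10 * 21 + 10) * 21 + 10
    vals[center] = 1.0
    out = smooth(vals, 6.0, space=grid)
    sigma = 6.0 * FWHM_TO_SIGMA / 2.0
    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    k /= k.sum()
    assert out[center] == pytest.approx(float(k.max() ** 3), rel=1e-10)
    assert out.sum() == pytest.approx(1.0, abs=1e-6)  # mass conserved


def test_smooth_constant_surface_unchanged(small_mesh):
    vals = np.full(small_mesh.n_vertices, -1.5)
    assert np.allclose(smooth(vals, 6.0, space=small_mesh), -1.5)


def test_smooth_rejects_nonpositive_fwhm(small_mesh):
    with pytest.raises(ArgumentError):
        smooth(np.zeros(small_mesh.n_vertices), 0.0, space=small_mesh)
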