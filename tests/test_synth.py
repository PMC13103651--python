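import numpy as np
import pytest

from thalatarget.errors import ArgumentError
from thalatarget.fc import correlation_map
from thalatarget.preprocess import framewise_displacement
from thalatarget.synth import (ConnectivityField, GroupSpec,
                               effective_dof_inflation, simulate_bold,
                               simulate_cohort, simulate_longitudinal,
                               simulate_motion, spherical_harmonic_basis)


def _measured_r(run, s):
    return correlation_map(run, s).values


# --------------------------------------------------------------- fields ----

def test_connectivity_field_invariants(small_truth):
    f = small_truth.surface_field()
    assert np.abs(f.rho).max() < 1.0
    assert f.rho[f.neg_peak] == f.rho.min()
    assert f.rho[f.pos_peak] == f.rho.max()
    assert f.neg_peak == small_truth.neg_vertex
    bad = f.rho.copy()
    bad[f.neg_peak] = 0.0  # the planted minimum no longer is one
    with pytest.raises(ArgumentError):
        ConnectivityField(bad, f.space, f.neg_peak, f.pos_peak)


def test_volume_field_excludes_seed_from_peaks(small_truth):
    f = small_truth.volume_field()
    seed = small_truth.grid.flat_labels() > 0
    assert np.all(f.rho[seed] == small_truth.seed_rho)
    assert not seed[f.neg_peak] and not seed[f.pos_peak]


def test_spherical_harmonic_basis_uniform_variance(small_mesh):
    basis = spherical_harmonic_basis(small_mesh.unit_directions(), 4)
    assert basis.shape == (small_mesh.n_vertices, 24)
    persum = (basis**2).sum(axis=1)
    assert np.allclose(persum, 24 / (4 * np.pi), rtol=1e-10)


# --------------------------------------------------------------- bold ------

def test_simulate_bold_is_deterministic(small_truth):
    f = small_truth.surface_field()
    a, sa = simulate_bold(f, 40, 2.0, 123)
    b, sb = simulate_bold(f, 40, 2.0, 123)
    assert np.array_equal(a.data, b.data)
    assert np.array_equal(sa, sb)
    c, _ = simulate_bold(f, 40, 2.0, 124)
    assert not np.array_equal(a.data, c.data)


def test_simulate_bold_near_unit_rho_tracks_seed(small_truth):
    rho = np.zeros(small_truth.mesh.n_vertices)
    rho[5] = 0.999999
    rho[0] = -0.5
    f = ConnectivityField(rho, small_truth.mesh, 0, 5)
    run, s = simulate_bold(f, 230, 2.0, 7)
    r = _measured_r(run, s)
    assert r[5] > 0.999


def test_simulate_bold_null_sampling_bound(small_truth):
    """With rho = 0 everywhere the null Pearson spread matches the
    autocorrelation-corrected bound 2 sqrt(kappa / n) (the generator noise is
    band-limited, so the white-noise 2 / sqrt(n) bound does not apply)."""
    n_frames = 230
    kappa = effective_dof_inflation(n_frames, 2.0)
    assert 2.0 < kappa < 5.0
    rho = np.zeros(small_truth.mesh.n_vertices)
    rho[1] = 1e-9  # a strict maximum to satisfy the field invariant
    rho[0] = -1e-9
    f = ConnectivityField(rho, small_truth.mesh, 0, 1)
    bound = 2.0 * np.sqrt(kappa / n_frames)
    inside = []
    for seed in range(5):
        run, s = simulate_bold(f, n_frames, 2.0, seed)
        inside.append(np.abs(_measured_r(run, s)) < bound)
    assert np.mean(inside) >= 0.92  # ~95% expected for a +/-2 SD bound


def test_simulate_bold_rejects_short_runs_and_unit_rho(small_truth):
    f = small_truth.surface_field()
    with pytest.raises(ArgumentError):
        simulate_bold(f, 10, 2.0, 0)
    rho = np.zeros(4)
    rho[0] = -1.0
    with pytest.raises(ArgumentError):
        ConnectivityField(rho, small_truth.mesh, 0, 1)


def test_generator_fidelity_over_seeds(small_truth):
    """Mean(sample r - rho) within +/-0.02 and spread within 20% of the
    autocorrelation-corrected Pearson sampling SD, over 20 seeds."""
    f = small_truth.surface_field()
    n_frames = 230
    kappa = effective_dof_inflation(n_frames, 2.0)
    errors = []
    for seed in range(20):
        run, s = simulate_bold(f, n_frames, 2.0, seed)
        errors.append(_measured_r(run, s) - f.rho)
    errors = np.asarray(errors)
    assert abs(errors.mean()) < 0.02
    theory_sd = float(np.mean((1.0 - f.rho**2) * np.sqrt(kappa / n_frames)))
    assert theory_sd * 0.8 < errors.std() < theory_sd * 1.2


# --------------------------------------------------------------- motion ----

def test_motion_spike_produces_fd_step():
    m = simulate_motion(50, [20], 0.6, seed=0, drift_sd_mm=0.0)
    fd = framewise_displacement(m)
    assert fd[20] >= 0.6
    assert fd[[10, 30]].max() < 1e-12


def test_motion_no_spikes_zero_drift_is_zero():
    m = simulate_motion(30, [], 0.5, seed=0, drift_sd_mm=0.0)
    assert np.all(m.params == 0.0)


def test_motion_is_seeded_and_validates_spikes():
    a = simulate_motion(40, [5, 12], 0.7, seed=3)
    b = simulate_motion(40, [5, 12], 0.7, seed=3)
    assert np.array_equal(a.params, b.params)
    with pytest.raises(ArgumentError):
        simulate_motion(40, [40], 0.7, seed=3)


# --------------------------------------------------------------- cohort ----

def test_cohort_constant_scores_when_uncoupled(small_truth):
    import copy
    truth = copy.deepcopy(small_truth)
    truth.groups["patient"] = GroupSpec(fs14_mean=9.6, fs14_sd=0.0,
                                        fs14_coupling_r=None, fs14_slope=0.0,
                                        fs14_noise_sd=0.0)
    cohort = simulate_cohort(truth, 5, n_frames=40, seed=1,
                             groups=("patient",), space="surface")
    assert cohort.phenotypes["fs14"].tolist() == [10] * 5  # round(9.6)


def test_cohort_deterministic_linear_coupling(small_truth):
    import copy
    truth = copy.deepcopy(small_truth)
    truth.groups["patient"] = GroupSpec(fs14_mean=8.0, fs14_sd=2.0,
                                        fs14_coupling_r=None, fs14_slope=-30.0,
                                        fs14_noise_sd=0.0)
    cohort = simulate_cohort(truth, 30, n_frames=40, seed=2,
                             groups=("patient",), space="surface")
    r = np.corrcoef(cohort.z_neg_true, cohort.phenotypes["fs14_cont"])[0, 1]
    assert r == pytest.approx(-1.0)


def test_cohort_scores_respect_scale_bounds(small_truth):
    cohort = simulate_cohort(small_truth, 40, n_frames=40, seed=3,
                             space="surface")
    assert cohort.phenotypes["fs14"].between(0, 14).all()
    assert cohort.phenotypes["hamd"].between(0, 88).all()


def test_cohort_planted_coupling_is_exact_before_rounding(small_truth):
    cohort = simulate_cohort(small_truth, 50, n_frames=40, seed=4,
                             groups=("patient",), space="surface")
    r = np.corrcoef(cohort.z_neg_true, cohort.phenotypes["fs14_cont"])[0, 1]
    assert r == pytest.approx(-0.3, abs=1e-10)
    # rounding + clipping attenuate only slightly
    r_obs = np.corrcoef(cohort.z_neg_true, cohort.phenotypes["fs14"])[0, 1]
    assert abs(r_obs + 0.3) < 0.08


def test_cohort_fully_deterministic_including_order(small_truth):
    a = simulate_cohort(small_truth, 4, n_frames=40, seed=9, space="surface")
    b = simulate_cohort(small_truth, 4, n_frames=40, seed=9, space="surface")
    assert a.phenotypes.equals(b.phenotypes)
    assert np.array_equal(a.jitter_coefs, b.jitter_coefs)
    ra = a.subject_run(2)
    rb = b.subject_run(2)
    assert np.array_equal(ra.bold.data, rb.bold.data)
    assert np.array_equal(ra.motion.params, rb.motion.params)


def test_cohort_requires_three_per_group(small_truth):
    with pytest.raises(ArgumentError):
        simulate_cohort(small_truth, 2, n_frames=40, seed=0)


# ---------------------------------------------------------- longitudinal ---

def test_longitudinal_zero_effect_is_flat(small_truth):
    import copy
    truth = copy.deepcopy(small_truth)
    truth.delta_mean_z = 0.0
    truth.delta_sd_z = 0.0
    truth.dfs14_coupling_r = 0.0
    truth.dfs14_sd = 0.0
    truth.dfs14_mean = 0.0
    cohort = simulate_longitudinal(truth, 5, n_frames=40, seed=1)
    assert np.all(cohort.delta_z == 0.0)
    assert np.all(cohort.true_region_delta() == 0.0)
    assert (cohort.phenotypes["fs14_post"] == cohort.phenotypes["fs14"]).all()
    pre = cohort.subject_pre_run(0)
    post = cohort.subject_post_run(0)
    assert np.array_equal(pre.field.rho, post.field.rho)


def test_longitudinal_planted_delta_coupling_is_exact(small_truth):
    cohort = simulate_longitudinal(small_truth, 35, n_frames=40, seed=2)
    d_fs = (cohort.phenotypes["fs14_post_cont"]
            - cohort.phenotypes["fs14_cont"]).to_numpy()
    r = np.corrcoef(cohort.true_region_delta(), d_fs)[0, 1]
    assert r == pytest.approx(-0.4, abs=1e-10)


def test_longitudinal_pre_arm_matches_cohort_generator(small_truth):
    """The pre-treatment arm uses the same per-subject generator as the
    cross-sectional cohort: same field construction, same phenotype rule."""
    cohort = simulate_longitudinal(small_truth, 6, n_frames=40, seed=3)
    pre = cohort.subject_pre_run(0)
    assert pre.bold.n_frames == 40
    assert pre.group == "patient"
    assert cohort.phenotypes["fs14"].between(0, 14).all()
    # true z at the planted peak follows the same jitter construction
    basis = small_truth.surface_jitter_basis()[small_truth.neg_vertex]
    expected = (small_truth.surface_z("patient")[small_truth.neg_vertex]
                + small_truth.jitter_sd * cohort.jitter_coefs @ basis)
    assert np.allclose(cohort.z_neg_true, expected)
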