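"""Synthetic resting-state cohorts with planted, recoverable ground truth.

The generator emulates the statistical structure the targeting analysis
assumes, on a spherical stand-in cortex:

* a smooth thalamic-seed connectivity field with one planted negative and
  one planted positive peak (Gaussian bumps on the sphere, Fisher-z scale,
  squashed through tanh so correlations stay in (-1, 1));
* per-subject fields = group field + a smooth between-subject jitter field
  (random low-order spherical harmonics), so individual peaks scatter while
  the cohort average recovers the planted peaks;
* BOLD runs built by the mixing rule y_v = rho_v * s + sqrt(1 - rho_v^2) * eta_v
  with unit-variance band-limited (0.01-0.08 Hz) noise, so the expected
  Pearson correlation of location v with the seed signal s equals rho_v;
* motion with censorable spikes, tissue signals, and additive confound
  contamination lying exactly in the 36-parameter span, so nuisance
  regression provably removes it;
* fatigue scores (FS14, 0-14 Chalder-style totals) coupled to the subject's
  true Fisher z at the planted negative peak, with the planted correlation
  imposed exactly in-sample before rounding/clipping;
* a longitudinal arm in which a treatment shifts connectivity inside a
  target region and the FS14 change is anticorrelated with the true
  connectivity change.

Everything is deterministic given one master seed: subjects own named
SeedSequence substreams, and any subject's run can be regenerated in
isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.special import sph_harm_y

from .errors import ArgumentError, DataError
from .geometry import (SurfaceMesh, VolumeGrid, add_thalamic_seed, make_grid,
                       make_mesh)
from .preprocess import (BoldRun, TISSUE_COLUMNS, build_confounds_36p,
                         butter_bandpass_gain)

__all__ = [
    "MotionParams",
    "ConnectivityField",
    "GroupSpec",
    "CohortTruth",
    "SubjectRecord",
    "Cohort",
    "LongitudinalCohort",
    "make_truth",
    "make_default_study",
    "simulate_bold",
    "simulate_motion",
    "simulate_cohort",
    "simulate_longitudinal",
    "band_limited_noise",
    "effective_dof_inflation",
    "spherical_harmonic_basis",
    "GENERATOR_BAND_HZ",
]

logger = logging.getLogger(__name__)

#: generator noise band (Hz): inside the analysis band-pass so denoising
#: does not destroy planted correlations
GENERATOR_BAND_HZ = (0.01, 0.08)


# --------------------------------------------------------------------------
# low-level pieces
# --------------------------------------------------------------------------

def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def band_limited_noise(rng: np.random.Generator, n_frames: int, n_series: int,
                       tr: float, band=GENERATOR_BAND_HZ) -> np.ndarray:
    """Unit-variance noise with power confined to ``band``.

    White noise is shaped by the zero-phase 4th-order Butterworth gain of the
    band (applied spectrally, which is equivalent to filtering up to the
    circular boundary) and standardized per series.
    """
    freqs = np.fft.rfftfreq(n_frames, tr)
    gain = butter_bandpass_gain(freqs, band[0], band[1], 1.0 / tr)
    draws = rng.standard_normal((len(freqs), n_series, 2))
    spec = (draws[..., 0] + 1j * draws[..., 1]) * gain[:, None]
    spec[0] = 0.0
    if n_frames % 2 == 0:
        spec[-1] = spec[-1].real
    x = np.fft.irfft(spec, n=n_frames, axis=0)
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return x / sd


def effective_dof_inflation(n_frames: int, tr: float,
                            band=GENERATOR_BAND_HZ) -> float:
    """Autocorrelation inflation kappa = sum_k rho(k)^2 of the generator
    noise: the null variance of a Pearson correlation between two such
    series is approximately kappa / n instead of the white-noise 1 / n."""
    freqs = np.fft.rfftfreq(n_frames, tr)
    gain = butter_bandpass_gain(freqs, band[0], band[1], 1.0 / tr)
    power = gain**2
    power[0] = 0.0
    # fold the one-sided spectrum back to a full (two-sided) normalized one
    full = np.concatenate([power, power[-2:0:-1]]) if n_frames % 2 == 0 else \
        np.concatenate([power, power[:0:-1]])
    full = full / full.sum()
    return float(n_frames * np.sum(full**2))


def spherical_harmonic_basis(directions: np.ndarray, lmax: int) -> np.ndarray:
    """Real orthonormal spherical harmonics Y_lm for l = 1..lmax, (N, lmax(lmax+2)).

    By the addition theorem the per-point sum of squares is
    sum_l (2l+1)/(4 pi), independent of direction, so coefficient draws give
    a jitter field with spatially uniform variance.
    """
    d = np.asarray(directions, dtype=float)
    theta = np.arccos(np.clip(d[:, 2], -1.0, 1.0))
    phi = np.arctan2(d[:, 1], d[:, 0])
    cols = []
    for ell in range(1, lmax + 1):
        for m in range(-ell, ell + 1):
            y = sph_harm_y(ell, abs(m), theta, phi)
            if m > 0:
                cols.append(np.sqrt(2.0) * (-1.0) ** m * y.real)
            elif m < 0:
                cols.append(np.sqrt(2.0) * (-1.0) ** m * y.imag)
            else:
                cols.append(y.real)
    return np.column_stack(cols)


def _jitter_amplitude(jitter_sd: float, lmax: int) -> float:
    total = lmax * (lmax + 2)  # sum of (2l+1) for l=1..lmax
    return jitter_sd / np.sqrt(total / (4.0 * np.pi))


def _plant_correlation(x: np.ndarray, target_r: float, sd: float, mean: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Continuous scores with *exact* in-sample correlation ``target_r``
    against x (Gram-Schmidt construction), sample SD ``sd``, mean ``mean``."""
    n = len(x)
    if n < 3:
        raise ArgumentError("planting a correlation needs at least 3 subjects")
    eps = rng.standard_normal(n)
    if target_r != 0.0 and np.ptp(x) == 0:
        logger.warning("field value is constant across subjects; the requested "
                       "coupling r=%.2f cannot be planted and is dropped", target_r)
        target_r = 0.0
    if np.ptp(x) > 0:
        xs = (x - x.mean()) / x.std()
        eps = eps - eps.mean() - xs * np.dot(eps - eps.mean(), xs) / n
    else:
        xs = np.zeros(n)
        eps = eps - eps.mean()
    eps_sd = eps.std()
    eps = eps / eps_sd if eps_sd > 0 else eps
    y = target_r * xs + np.sqrt(max(0.0, 1.0 - target_r**2)) * eps
    return mean + sd * y


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class MotionParams:
    """Per-frame rigid-body parameters: 3 translations (mm), 3 rotations (rad)."""

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ArgumentError("motion parameters must be frames x 6")
        if not np.all(np.isfinite(self.params)):
            raise DataError("motion parameters must be finite")

    @property
    def n_frames(self) -> int:
        return len(self.params)


@dataclass
class ConnectivityField:
    """True per-location seed correlation rho in (-1, 1) with planted peaks.

    ``exclude`` flags locations (e.g. the seed voxels themselves) that are
    not part of the cortical field; peak invariants hold over the rest.
    """

    rho: np.ndarray
    space: SurfaceMesh | VolumeGrid
    neg_peak: int
    pos_peak: int
    exclude: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        if np.abs(self.rho).max() >= 1.0:
            raise ArgumentError("|rho| must be < 1 everywhere")
        keep = np.ones(len(self.rho), dtype=bool)
        if self.exclude is not None:
            self.exclude = np.asarray(self.exclude, dtype=bool)
            keep = ~self.exclude
        if self.exclude is not None and self.exclude.shape != self.rho.shape:
            raise ArgumentError("exclude flags must match the field cardinality")
        vals = self.rho[keep]
        if self.rho[self.neg_peak] != vals.min():
            raise ArgumentError("rho at the planted negative peak must be the minimum")
        if self.rho[self.pos_peak] != vals.max():
            raise ArgumentError("rho at the planted positive peak must be the maximum")

    @property
    def n_locations(self) -> int:
        return len(self.rho)


@dataclass
class GroupSpec:
    """Phenotype generator for one group.

    If ``fs14_coupling_r`` is set, FS14 is planted with exactly that
    in-sample correlation against the subject's true Fisher z at the
    planted negative peak (before rounding/clipping). Otherwise the direct
    linear rule fs14 = intercept + slope * z + noise is used.
    """

    fs14_mean: float
    fs14_sd: float
    fs14_coupling_r: float | None = None
    fs14_slope: float = 0.0
    fs14_noise_sd: float = 0.0
    hamd_mean: float = 5.0
    hamd_sd: float = 4.0
    neg_amp_shift_z: float = 0.0


@dataclass
class CohortTruth:
    """All planted parameters of a synthetic study.

    The connectivity field is defined on the sphere in Fisher-z units:
    z(u) = pos_amp * G(u; pos_dir) - neg_amp * G(u; neg_dir), with G a
    Gaussian bump of angular width ``bump_sigma_rad``; per-subject fields
    add a smooth jitter field of SD ``jitter_sd`` (z units). Volume fields
    apply a radial taper centred on the cortical shell, and the thalamic
    seed voxels carry rho = ``seed_rho``.
    """

    mesh: SurfaceMesh
    grid: VolumeGrid
    scalp: SurfaceMesh
    neg_dir: np.ndarray
    pos_dir: np.ndarray
    neg_amp_z: float = 0.5
    pos_amp_z: float = 0.5
    bump_sigma_rad: float = 0.25
    jitter_sd: float = 0.4
    jitter_lmax: int = 4
    seed_rho: float = 0.9
    taper_sd_mm: float = 8.0
    shell_radius_mm: float = 50.0
    contamination_amp: float = 0.7
    spike_rate: float = 3.0
    spike_mm: float = 0.7
    drift_sd_mm: float = 0.005
    groups: dict[str, GroupSpec] = dc_field(default_factory=dict)
    delta_mean_z: float = 0.15
    delta_sd_z: float = 0.20
    region_sigma_rad: float = 0.4
    dfs14_coupling_r: float = -0.4
    dfs14_sd: float = 2.5
    dfs14_mean: float = -3.0
    band_hz: tuple[float, float] = GENERATOR_BAND_HZ
    master_seed: int = 0

    def __post_init__(self) -> None:
        self.neg_dir = np.asarray(self.neg_dir, dtype=float)
        self.neg_dir = self.neg_dir / np.linalg.norm(self.neg_dir)
        self.pos_dir = np.asarray(self.pos_dir, dtype=float)
        self.pos_dir = self.pos_dir / np.linalg.norm(self.pos_dir)
        if self.jitter_sd < 0 or self.bump_sigma_rad <= 0:
            raise ArgumentError("jitter_sd must be >= 0 and bump_sigma_rad > 0")
        for name, g in self.groups.items():
            if g.fs14_sd < 0 or g.hamd_sd < 0:
                raise ArgumentError(f"group {name!r}: noise SDs must be >= 0")
        # planted vertices: mesh vertices nearest the bump directions; the
        # bump centres are then snapped to those directions so the analytic
        # field attains its extrema exactly at mesh vertices.
        dirs = self.mesh.unit_directions()
        self.neg_vertex = int(np.argmax(dirs @ self.neg_dir))
        self.pos_vertex = int(np.argmax(dirs @ self.pos_dir))
        self.neg_dir = dirs[self.neg_vertex]
        self.pos_dir = dirs[self.pos_vertex]
        self._surface_basis: np.ndarray | None = None
        self._volume_basis: np.ndarray | None = None

    # ---- analytic fields ------------------------------------------------

    def angular_z(self, directions: np.ndarray, group: str | None = None) -> np.ndarray:
        """Group-level Fisher-z field as a function of unit direction."""
        d = np.asarray(directions, dtype=float)
        neg_amp = self.neg_amp_z
        if group is not None:
            neg_amp = neg_amp - self.groups[group].neg_amp_shift_z
        cos_n = np.clip(d @ self.neg_dir, -1.0, 1.0)
        cos_p = np.clip(d @ self.pos_dir, -1.0, 1.0)
        th_n = np.arccos(cos_n)
        th_p = np.arccos(cos_p)
        s2 = 2.0 * self.bump_sigma_rad**2
        return (self.pos_amp_z * np.exp(-th_p**2 / s2)
                - neg_amp * np.exp(-th_n**2 / s2))

    def surface_z(self, group: str | None = None) -> np.ndarray:
        return self.angular_z(self.mesh.unit_directions(), group)

    def surface_field(self, group: str | None = None) -> ConnectivityField:
        rho = np.tanh(self.surface_z(group))
        return ConnectivityField(rho, self.mesh, self.neg_vertex, self.pos_vertex)

    def _volume_geometry(self):
        centers = self.grid.voxel_centers_mm()
        radii = np.linalg.norm(centers, axis=1)
        safe = np.where(radii == 0, 1.0, radii)
        dirs = centers / safe[:, None]
        taper = np.exp(-0.5 * ((radii - self.shell_radius_mm) / self.taper_sd_mm) ** 2)
        taper[radii == 0] = 0.0
        return dirs, taper

    def volume_z(self, group: str | None = None) -> np.ndarray:
        dirs, taper = self._volume_geometry()
        return taper * self.angular_z(dirs, group)

    def volume_field(self, group: str | None = None) -> ConnectivityField:
        rho = np.tanh(self.volume_z(group))
        seed_mask = self.grid.flat_labels() > 0
        rho[seed_mask] = self.seed_rho
        keep = ~seed_mask
        neg = int(np.flatnonzero(keep)[np.argmin(rho[keep])])
        pos = int(np.flatnonzero(keep)[np.argmax(rho[keep])])
        return ConnectivityField(rho, self.grid, neg, pos, exclude=seed_mask)

    # ---- jitter bases ---------------------------------------------------

    @property
    def n_jitter_coefs(self) -> int:
        return self.jitter_lmax * (self.jitter_lmax + 2)

    def surface_jitter_basis(self) -> np.ndarray:
        if self._surface_basis is None:
            amp = _jitter_amplitude(1.0, self.jitter_lmax)
            self._surface_basis = amp * spherical_harmonic_basis(
                self.mesh.unit_directions(), self.jitter_lmax)
        return self._surface_basis

    def volume_jitter_basis(self) -> np.ndarray:
        if self._volume_basis is None:
            dirs, taper = self._volume_geometry()
            amp = _jitter_amplitude(1.0, self.jitter_lmax)
            self._volume_basis = taper[:, None] * (
                amp * spherical_harmonic_basis(dirs, self.jitter_lmax))
        return self._volume_basis

    def region_weights(self) -> np.ndarray:
        """Treatment-region weights on the surface: a Gaussian bump around the
        planted negative peak with angular width ``region_sigma_rad``."""
        d = self.mesh.unit_directions()
        th = np.arccos(np.clip(d @ self.neg_dir, -1.0, 1.0))
        return np.exp(-th**2 / (2.0 * self.region_sigma_rad**2))


def make_truth(mesh: SurfaceMesh, grid: VolumeGrid, scalp: SurfaceMesh,
               **overrides) -> CohortTruth:
    """Study truth with field defaults and Table-1-style phenotype groups.

    The planted negative bump points toward the left lateral occipital
    direction and the positive bump toward the anterior midline, matching
    the kind of thalamocortical topography the targeting analysis expects.
    """
    groups = overrides.pop("groups", None)
    if groups is None:
        groups = {
            "patient": GroupSpec(fs14_mean=10.35, fs14_sd=2.90,
                                 fs14_coupling_r=-0.3,
                                 hamd_mean=5.81, hamd_sd=4.97),
            "control": GroupSpec(fs14_mean=4.73, fs14_sd=3.96,
                                 fs14_coupling_r=0.0,
                                 hamd_mean=4.96, hamd_sd=3.54),
        }
    return CohortTruth(
        mesh=mesh, grid=grid, scalp=scalp,
        neg_dir=np.array([-51.0, -77.5, 7.0]),
        pos_dir=np.array([2.8, 29.7, 26.5]),
        groups=groups,
        **overrides,
    )


def make_default_study(subdivisions: int = 4, radius_mm: float = 50.0,
                       scalp_radius_mm: float = 60.0, grid_shape: int = 16,
                       voxel_mm: float = 7.0, **overrides) -> CohortTruth:
    """Desk-scale study geometry: icosphere cortex + scalp, labelled grid."""
    mesh = make_mesh(subdivisions, radius_mm)
    scalp = make_mesh(max(2, subdivisions - 2), scalp_radius_mm)
    grid = add_thalamic_seed(make_grid(grid_shape, voxel_mm))
    return make_truth(mesh, grid, scalp, shell_radius_mm=radius_mm, **overrides)


# --------------------------------------------------------------------------
# simulators
# --------------------------------------------------------------------------

def simulate_bold(field: ConnectivityField, n_frames: int, tr_seconds: float,
                  seed) -> tuple[BoldRun, np.ndarray]:
    """BOLD run realizing the field's correlations with a shared seed signal.

    y_v = rho_v * s + sqrt(1 - rho_v^2) * eta_v with s, eta_v independent
    unit-variance band-limited noise; identical seeds give identical output.
    """
    if n_frames < 20:
        raise ArgumentError("n_frames must be at least 20")
    if tr_seconds <= 0:
        raise ArgumentError("tr_seconds must be positive")
    rho = field.rho
    if np.abs(rho).max() >= 1.0:
        raise ArgumentError("|rho| must be < 1 everywhere")
    rng = _rng(seed)
    noise = band_limited_noise(rng, n_frames, len(rho) + 1, tr_seconds)
    s = noise[:, 0]
    eta = noise[:, 1:]
    data = rho[None, :] * s[:, None] + np.sqrt(1.0 - rho**2)[None, :] * eta
    run = BoldRun(data, tr_seconds, np.ones(n_frames, dtype=bool), field.space)
    return run, s


def simulate_motion(n_frames: int, spike_frames, spike_mm: float, seed,
                    drift_sd_mm: float = 0.005) -> MotionParams:
    """Small random-walk drift plus sustained translation steps at spikes.

    Each spike adds a step of ``spike_mm`` on one translation axis (axes
    cycle), so framewise displacement at the spike frame is >= spike_mm.
    """
    if n_frames <= 0:
        raise ArgumentError("n_frames must be positive")
    spikes = sorted(int(k) for k in spike_frames)
    if spikes and (spikes[0] < 0 or spikes[-1] >= n_frames):
        raise ArgumentError("spike frames must lie in [0, n_frames)")
    if spike_mm <= 0:
        raise ArgumentError("spike_mm must be positive")
    rng = _rng(seed)
    steps = np.zeros((n_frames, 6))
    if drift_sd_mm > 0:
        steps = rng.normal(0.0, drift_sd_mm, (n_frames, 6))
        steps[:, 3:] /= 50.0  # rotations drift in rad, ~drift_sd at 50 mm
        steps[0] = 0.0
    params = np.cumsum(steps, axis=0)
    for j, k in enumerate(spikes):
        params[k:, j % 3] += spike_mm
    return MotionParams(params)


@dataclass
class SubjectRecord:
    """One simulated acquisition: signal, motion, tissue series, truth."""

    subject_id: str
    group: str
    bold: BoldRun
    motion: MotionParams
    tissue: pd.DataFrame
    seed_signal: np.ndarray
    field: ConnectivityField


class _SubjectFactory:
    """Deterministic per-subject generation shared by cohort flavours."""

    def __init__(self, truth: CohortTruth, space: str, n_frames: int, tr: float,
                 contaminate: bool):
        if space not in ("volume", "surface"):
            raise ArgumentError("space must be 'volume' or 'surface'")
        self.truth = truth
        self.space = space
        self.n_frames = n_frames
        self.tr = tr
        self.contaminate = contaminate
        t = truth
        if space == "surface":
            self.base_z = {g: t.surface_z(g) for g in t.groups}
            self.basis = t.surface_jitter_basis()
        else:
            self.base_z = {g: t.volume_z(g) for g in t.groups}
            self.basis = t.volume_jitter_basis()
            self.seed_mask = t.grid.flat_labels() > 0

    def field_for(self, group: str, coefs: np.ndarray,
                  extra_z: np.ndarray | None = None) -> ConnectivityField:
        t = self.truth
        z = self.base_z[group] + t.jitter_sd * (self.basis @ coefs)
        if extra_z is not None:
            z = z + extra_z
        rho = np.tanh(z)
        if self.space == "volume":
            rho[self.seed_mask] = t.seed_rho
            keep = ~self.seed_mask
            idx = np.flatnonzero(keep)
            return ConnectivityField(rho, t.grid, int(idx[np.argmin(rho[keep])]),
                                     int(idx[np.argmax(rho[keep])]),
                                     exclude=self.seed_mask)
        neg = int(np.argmin(rho))
        pos = int(np.argmax(rho))
        return ConnectivityField(rho, t.mesh, neg, pos)

    def run_for(self, subject_id: str, group: str, coefs: np.ndarray,
                run_seed: np.random.SeedSequence,
                extra_z: np.ndarray | None = None) -> SubjectRecord:
        t = self.truth
        rng = np.random.default_rng(run_seed)
        fld = self.field_for(group, coefs, extra_z)
        bold, s = simulate_bold(fld, self.n_frames, self.tr, rng)
        n_spikes = rng.poisson(t.spike_rate)
        spike_frames = rng.choice(self.n_frames, size=min(n_spikes, self.n_frames),
                                  replace=False) if n_spikes else []
        motion = simulate_motion(self.n_frames, spike_frames, t.spike_mm, rng,
                                 drift_sd_mm=t.drift_sd_mm)
        tissue_arr = band_limited_noise(rng, self.n_frames, 3, self.tr)
        tissue = pd.DataFrame(tissue_arr, columns=list(TISSUE_COLUMNS))
        if self.contaminate and t.contamination_amp > 0:
            conf = build_confounds_36p(motion, tissue).values
            sd = conf.std(axis=0)
            scaled = conf / np.where(sd == 0, 1.0, sd)
            weights = rng.standard_normal((scaled.shape[1], bold.n_locations))
            weights *= t.contamination_amp / np.sqrt(scaled.shape[1])
            bold = BoldRun(bold.data + scaled @ weights, bold.tr, bold.mask,
                           bold.space)
        return SubjectRecord(subject_id, group, bold, motion, tissue, s, fld)


@dataclass
class Cohort:
    """A cross-sectional cohort; subject runs regenerate deterministically."""

    truth: CohortTruth
    space: str
    n_frames: int
    tr: float
    phenotypes: pd.DataFrame
    jitter_coefs: np.ndarray
    z_neg_true: np.ndarray
    z_pos_true: np.ndarray
    _factory: _SubjectFactory
    _run_seeds: list

    def __len__(self) -> int:
        return len(self.phenotypes)

    def subject_run(self, i: int) -> SubjectRecord:
        row = self.phenotypes.iloc[i]
        return self._factory.run_for(row["subject_id"], row["group"],
                                     self.jitter_coefs[i], self._run_seeds[i])

    def subject_field(self, i: int) -> ConnectivityField:
        """The subject's true connectivity field (no acquisition simulated)."""
        row = self.phenotypes.iloc[i]
        return self._factory.field_for(row["group"], self.jitter_coefs[i])

    def iter_subjects(self):
        for i in range(len(self)):
            yield self.subject_run(i)

    def group_index(self, group: str) -> np.ndarray:
        return np.flatnonzero((self.phenotypes["group"] == group).to_numpy())


def _phenotype_scores(z_peak: np.ndarray, spec: GroupSpec,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """FS14 totals (continuous and clipped/rounded) for one group."""
    n = len(z_peak)
    if spec.fs14_coupling_r is not None:
        cont = _plant_correlation(z_peak, spec.fs14_coupling_r, spec.fs14_sd,
                                  spec.fs14_mean, rng)
    else:
        eps = rng.normal(0.0, spec.fs14_noise_sd, n) if spec.fs14_noise_sd > 0 else 0.0
        cont = spec.fs14_mean + spec.fs14_slope * z_peak + eps
        cont = np.asarray(cont, dtype=float) * np.ones(n)
    fs14 = np.clip(np.round(cont), 0, 14).astype(int)
    return cont, fs14


def simulate_cohort(truth: CohortTruth, n_per_group: int, n_frames: int = 240,
                    tr: float = 2.0, seed: int = 0, space: str = "volume",
                    contaminate: bool = True,
                    groups: tuple[str, ...] | None = None) -> Cohort:
    """Cross-sectional cohort with planted FC fields and coupled phenotypes.

    FS14_i = clip(round(a + b * z_i(neg peak) + eps_i), 0, 14), with the
    coupling planted exactly in-sample when the group specifies a target r.
    """
    if n_per_group < 3:
        raise ArgumentError("n_per_group must be at least 3")
    groups = tuple(groups) if groups is not None else tuple(truth.groups)
    unknown = set(groups) - set(truth.groups)
    if unknown:
        raise ArgumentError(f"unknown group(s): {sorted(unknown)}")
    factory = _SubjectFactory(truth, space, n_frames, tr, contaminate)
    n_total = n_per_group * len(groups)
    ss = np.random.SeedSequence(seed)
    subject_seeds = ss.spawn(n_total)
    group_seeds = ss.spawn(len(groups))
    coefs = np.empty((n_total, truth.n_jitter_coefs))
    run_seeds = []
    for i, child in enumerate(subject_seeds):
        meta, run = child.spawn(2)
        coefs[i] = np.random.default_rng(meta).standard_normal(truth.n_jitter_coefs)
        run_seeds.append(run)

    # true (noise-free) Fisher z at the planted surface peaks drives phenotypes
    basis_neg = truth.surface_jitter_basis()[truth.neg_vertex]
    basis_pos = truth.surface_jitter_basis()[truth.pos_vertex]
    rows = []
    z_neg = np.empty(n_total)
    z_pos = np.empty(n_total)
    fs14_cont_all = np.empty(n_total)
    for gi, g in enumerate(groups):
        idx = np.arange(gi * n_per_group, (gi + 1) * n_per_group)
        base = truth.surface_z(g)
        z_neg[idx] = base[truth.neg_vertex] + truth.jitter_sd * (coefs[idx] @ basis_neg)
        z_pos[idx] = base[truth.pos_vertex] + truth.jitter_sd * (coefs[idx] @ basis_pos)
        grng = np.random.default_rng(group_seeds[gi])
        spec = truth.groups[g]
        cont, fs14 = _phenotype_scores(z_neg[idx], spec, grng)
        fs14_cont_all[idx] = cont
        hamd = np.clip(np.round(grng.normal(spec.hamd_mean, spec.hamd_sd,
                                            n_per_group)), 0, 88).astype(int)
        for j, i in enumerate(idx):
            rows.append({"subject_id": f"sub-{i + 1:03d}", "group": g,
                         "fs14": int(fs14[j]), "hamd": int(hamd[j])})
    phen = pd.DataFrame(rows)
    phen["fs14_cont"] = fs14_cont_all
    return Cohort(truth, space, n_frames, tr, phen, coefs, z_neg, z_pos,
                  factory, run_seeds)


@dataclass
class LongitudinalCohort:
    """Paired pre/post cohort of patients under a planted treatment effect.

    The treatment shifts each subject's Fisher-z field by delta_i * g(u)
    inside the target region g; the FS14 change is planted against delta_i
    (equivalently the region-mean true Delta z, which is proportional).
    """

    truth: CohortTruth
    space: str
    n_frames: int
    tr: float
    phenotypes: pd.DataFrame
    jitter_coefs: np.ndarray
    delta_z: np.ndarray
    z_neg_true: np.ndarray
    _factory: _SubjectFactory
    _pre_seeds: list
    _post_seeds: list
    _region_z: np.ndarray

    def __len__(self) -> int:
        return len(self.phenotypes)

    def subject_pre_run(self, i: int) -> SubjectRecord:
        row = self.phenotypes.iloc[i]
        return self._factory.run_for(row["subject_id"], row["group"],
                                     self.jitter_coefs[i], self._pre_seeds[i])

    def subject_post_run(self, i: int) -> SubjectRecord:
        row = self.phenotypes.iloc[i]
        return self._factory.run_for(row["subject_id"], row["group"],
                                     self.jitter_coefs[i], self._post_seeds[i],
                                     extra_z=self.delta_z[i] * self._region_z)

    def true_region_delta(self) -> np.ndarray:
        """Per-subject mean true Fisher-z change over the target region."""
        return self.delta_z * float(self._region_z.mean())


def simulate_longitudinal(truth: CohortTruth, n: int, n_frames: int = 240,
                          tr: float = 2.0, seed: int = 0,
                          space: str = "surface", contaminate: bool = True,
                          group: str = "patient") -> LongitudinalCohort:
    """Paired pre/post patient cohort with a planted Delta-Delta coupling.

    DeltaFS14_i = c * delta_i + noise with c calibrated so the in-sample
    correlation equals ``truth.dfs14_coupling_r`` before rounding/clipping.
    """
    if n < 3:
        raise ArgumentError("n must be at least 3")
    if group not in truth.groups:
        raise ArgumentError(f"unknown group {group!r}")
    factory = _SubjectFactory(truth, space, n_frames, tr, contaminate)
    ss = np.random.SeedSequence(seed)
    subject_seeds = ss.spawn(n)
    pheno_seed, delta_seed = ss.spawn(2)
    coefs = np.empty((n, truth.n_jitter_coefs))
    pre_seeds, post_seeds = [], []
    for i, child in enumerate(subject_seeds):
        meta, pre, post = child.spawn(3)
        coefs[i] = np.random.default_rng(meta).standard_normal(truth.n_jitter_coefs)
        pre_seeds.append(pre)
        post_seeds.append(post)
    basis_neg = truth.surface_jitter_basis()[truth.neg_vertex]
    base = truth.surface_z(group)
    z_neg = base[truth.neg_vertex] + truth.jitter_sd * (coefs @ basis_neg)
    grng = np.random.default_rng(pheno_seed)
    spec = truth.groups[group]
    fs14_cont, fs14 = _phenotype_scores(z_neg, spec, grng)
    drng = np.random.default_rng(delta_seed)
    delta = drng.normal(truth.delta_mean_z, truth.delta_sd_z, n)
    dfs14_cont = _plant_correlation(delta, truth.dfs14_coupling_r,
                                    truth.dfs14_sd, truth.dfs14_mean, drng)
    fs14_post = np.clip(np.round(fs14_cont + dfs14_cont), 0, 14).astype(int)
    rows = [{"subject_id": f"sub-{i + 1:03d}", "group": group,
             "fs14": int(fs14[i]), "fs14_post": int(fs14_post[i])}
            for i in range(n)]
    phen = pd.DataFrame(rows)
    phen["fs14_cont"] = fs14_cont
    phen["fs14_post_cont"] = fs14_cont + dfs14_cont
    if space == "surface":
        region = truth.region_weights()
    else:
        dirs, taper = truth._volume_geometry()
        th = np.arccos(np.clip(dirs @ truth.neg_dir, -1.0, 1.0))
        region = taper * np.exp(-th**2 / (2.0 * truth.region_sigma_rad**2))
    return LongitudinalCohort(truth, space, n_frames, tr, phen, coefs, delta,
                              z_neg, factory, pre_seeds, post_seeds, region)
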