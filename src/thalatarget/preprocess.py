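"""Denoising chain for standard-space BOLD runs.

The chain mirrors a scrubbing-compatible confound pipeline: drop initial
frames, censor frames by framewise displacement (FD), regress 36 nuisance
parameters (6 motion + 3 tissue means, their temporal derivatives, and the
squares of all of those) on the retained frames, interpolate the residuals
across censored frames so a zero-phase band-pass can run, re-apply the
censoring mask, and smooth spatially. Anatomical steps (registration,
segmentation, surface reconstruction) are assumed done upstream: inputs are
already co-registered, standard-space time series.

Conventions fixed here because published pipelines vary:

* FD is Power's backward-difference sum, rotations converted to arc length
  at a 50 mm head radius.
* Censoring is strict: a frame is removed only when FD *exceeds* the
  threshold.
* The nuisance design always includes an intercept (37 columns total), so
  residuals are mean-free; collinear columns are dropped with a warning.
* The band-pass is a zero-phase 4th-order Butterworth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage, signal

from .errors import ArgumentError, DataError
from .geometry import SurfaceMesh, VolumeGrid

__all__ = [
    "BoldRun",
    "ConfoundMatrix",
    "drop_initial_frames",
    "framewise_displacement",
    "censor",
    "build_confounds_36p",
    "build_confounds_gsr",
    "regress_out",
    "bandpass",
    "smooth",
    "denoise_run",
    "FWHM_TO_SIGMA",
    "MOTION_COLUMNS",
    "TISSUE_COLUMNS",
]

logger = logging.getLogger(__name__)

#: fwhm = sigma * 2 sqrt(2 ln 2)
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")
TISSUE_COLUMNS = ("global_signal", "white_matter", "csf")


@dataclass
class BoldRun:
    """One subject-run: frames x locations signal matrix plus its space.

    ``mask`` flags retained frames; censored frames keep their rows (possibly
    interpolated for filtering continuity) but never enter statistics.
    """

    data: np.ndarray
    tr: float
    mask: np.ndarray
    space: SurfaceMesh | VolumeGrid | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ArgumentError("BOLD data must be a frames x locations matrix")
        if not np.all(np.isfinite(self.data)):
            raise DataError("BOLD data contain non-finite values")
        if self.tr <= 0:
            raise ArgumentError("tr must be positive")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (self.data.shape[0],):
            raise ArgumentError("retained-frame mask length must equal the frame count")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_locations(self) -> int:
        return self.data.shape[1]

    @property
    def n_retained(self) -> int:
        return int(self.mask.sum())

    def retained(self) -> np.ndarray:
        return self.data[self.mask]


@dataclass
class ConfoundMatrix:
    """Frames x 36 nuisance matrix with fixed column order.

    Order: 6 motion, 3 tissue means, their 9 backward-difference derivatives
    (first element 0), then the 18 squares of all of the preceding.
    """

    values: np.ndarray
    columns: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.columns):
            raise ArgumentError("confound values/column mismatch")
        if not np.all(np.isfinite(self.values)):
            raise DataError("confounds contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


def _motion_array(motion) -> np.ndarray:
    arr = np.asarray(getattr(motion, "params", motion), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 6:
        raise ArgumentError("motion parameters must be a frames x 6 array")
    return arr


def drop_initial_frames(run: BoldRun, n: int, confounds: ConfoundMatrix | None = None):
    """Remove the first ``n`` frames from the run (and paired confounds)."""
    if n < 0:
        raise ArgumentError("n must be non-negative")
    if n >= run.n_frames:
        raise ArgumentError(f"cannot drop {n} of {run.n_frames} frames")
    out = BoldRun(run.data[n:], run.tr, run.mask[n:], run.space)
    if confounds is None:
        return out
    if confounds.n_frames != run.n_frames:
        raise ArgumentError("confound frame count must match the run")
    return out, ConfoundMatrix(confounds.values[n:], confounds.columns)


def framewise_displacement(motion, head_radius_mm: float = 50.0) -> np.ndarray:
    """Power's FD: sum of absolute backward differences of the 6 parameters,
    rotations converted to mm as ``head_radius * delta_angle``. FD_0 = 0."""
    arr = _motion_array(motion)
    if len(arr) < 2:
        raise ArgumentError("framewise displacement needs at least 2 frames")
    if not np.all(np.isfinite(arr)):
        raise DataError("motion parameters contain non-finite values")
    if head_radius_mm <= 0:
        raise ArgumentError("head_radius_mm must be positive")
    d = np.abs(np.diff(arr, axis=0))
    d[:, 3:] *= head_radius_mm
    fd = np.zeros(len(arr))
    fd[1:] = d.sum(axis=1)
    return fd


def censor(run: BoldRun, fd: np.ndarray, threshold_mm: float = 0.5) -> BoldRun:
    """Flag frames whose FD strictly exceeds the threshold as censored.

    Only the retained-frame mask changes; data are untouched. A frame at
    exactly the threshold is retained.
    """
    fd = np.asarray(fd, dtype=float)
    if fd.shape != (run.n_frames,):
        raise ArgumentError("fd length must equal the frame count")
    if threshold_mm <= 0:
        raise ArgumentError("threshold_mm must be positive")
    return BoldRun(run.data, run.tr, run.mask & (fd <= threshold_mm), run.space)


def _derivative(x: np.ndarray) -> np.ndarray:
    d = np.zeros_like(x)
    d[1:] = np.diff(x, axis=0)
    return d


def _expand_confounds(base: np.ndarray, names: list[str]) -> ConfoundMatrix:
    deriv = _derivative(base)
    first = np.hstack([base, deriv])
    values = np.hstack([first, first**2])
    columns = (
        names
        + [f"{c}_derivative1" for c in names]
        + [f"{c}_power2" for c in names]
        + [f"{c}_derivative1_power2" for c in names]
    )
    return ConfoundMatrix(values, tuple(columns))


def build_confounds_36p(motion, tissue_means) -> ConfoundMatrix:
    """36-parameter family: motion + global/WM/CSF means, derivatives, squares."""
    arr = _motion_array(motion)
    tissue = np.asarray(
        tissue_means[list(TISSUE_COLUMNS)] if hasattr(tissue_means, "columns") else tissue_means,
        dtype=float,
    )
    if tissue.ndim != 2 or tissue.shape[1] != 3:
        raise ArgumentError("tissue_means must provide exactly 3 series (global, WM, CSF)")
    if len(tissue) != len(arr):
        raise ArgumentError("motion and tissue series must have equal frame counts")
    return _expand_confounds(np.hstack([arr, tissue]),
                             list(MOTION_COLUMNS) + list(TISSUE_COLUMNS))


def build_confounds_gsr(motion, global_signal) -> ConfoundMatrix:
    """Reduced recipe for normative-style denoising: motion + global signal,
    derivatives and squares (28 columns). Kept distinct from the 36P recipe;
    the two are deliberately not harmonized."""
    arr = _motion_array(motion)
    g = np.asarray(global_signal, dtype=float).reshape(-1, 1)
    if len(g) != len(arr):
        raise ArgumentError("motion and global signal must have equal frame counts")
    return _expand_confounds(np.hstack([arr, g]), list(MOTION_COLUMNS) + ["global_signal"])


def _drop_collinear(design: np.ndarray, columns: list[str]) -> tuple[np.ndarray, list[str]]:
    """Keep a maximal independent column subset via pivoted QR."""
    rank = np.linalg.matrix_rank(design)
    if rank == design.shape[1]:
        return design, columns
    from scipy.linalg import qr

    _, _, piv = qr(design, mode="economic", pivoting=True)
    keep = np.sort(piv[:rank])
    dropped = [columns[i] for i in range(design.shape[1]) if i not in set(keep.tolist())]
    logger.warning("dropping %d collinear confound column(s): %s", len(dropped), dropped)
    return design[:, keep], [columns[i] for i in keep]


def _interpolate_censored(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Linear interpolation of censored rows from retained rows (edges clamp)."""
    if mask.all():
        return values
    out = values.copy()
    t = np.arange(len(mask))
    ret = t[mask]
    cen = t[~mask]
    left = np.searchsorted(ret, cen, side="right") - 1
    right = np.clip(left + 1, 0, len(ret) - 1)
    left = np.clip(left, 0, len(ret) - 1)
    t0, t1 = ret[left], ret[right]
    w = np.where(t1 > t0, (cen - t0) / np.where(t1 > t0, t1 - t0, 1), 0.0)
    out[cen] = (1 - w)[:, None] * values[t0] + w[:, None] * values[t1]
    return out


def regress_out(run: BoldRun, confounds: ConfoundMatrix) -> BoldRun:
    """OLS nuisance regression on retained frames, intercept always included.

    Residuals at censored frames are filled by linear interpolation from
    retained residuals so a zero-phase filter can be applied downstream;
    the censoring mask itself is preserved.
    """
    if confounds.n_frames != run.n_frames:
        raise ArgumentError("confound frame count must match the run")
    mask = run.mask
    n_ret = int(mask.sum())
    if n_ret < confounds.values.shape[1] + 2:
        raise DataError("too few retained frames for the nuisance design")
    design = np.column_stack([np.ones(n_ret), confounds.values[mask]])
    names = ["intercept"] + list(confounds.columns)
    design, _ = _drop_collinear(design, names)
    gram = design.T @ design
    beta = np.linalg.solve(gram, design.T @ run.data[mask])
    resid_ret = run.data[mask] - design @ beta
    resid = np.zeros_like(run.data)
    resid[mask] = resid_ret
    resid = _interpolate_censored(resid, mask)
    return BoldRun(resid, run.tr, mask, run.space)


def butter_bandpass_gain(freqs_hz: np.ndarray, low_hz: float, high_hz: float,
                         fs_hz: float, order: int = 4) -> np.ndarray:
    """Zero-phase (forward-backward) gain |H(f)|^2 of an order-``order``
    Butterworth band-pass, evaluated at ``freqs_hz``. This is the documented
    frequency response of the pipeline band-pass."""
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs_hz,
                        output="sos")
    _, h = signal.sosfreqz(sos, worN=np.asarray(freqs_hz, dtype=float), fs=fs_hz)
    return np.abs(h) ** 2


def zero_phase_bandpass(data: np.ndarray, tr: float, low_hz: float,
                        high_hz: float, order: int = 4) -> np.ndarray:
    """Apply the zero-phase Butterworth band-pass gain along time.

    Implemented in the frequency domain (circular boundary), so the realized
    response equals ``butter_bandpass_gain`` exactly at the DFT frequencies.
    """
    n = data.shape[0]
    freqs = np.fft.rfftfreq(n, tr)
    gain = butter_bandpass_gain(freqs, low_hz, high_hz, 1.0 / tr, order)
    spec = np.fft.rfft(data, axis=0)
    shape = (len(freqs),) + (1,) * (data.ndim - 1)
    return np.fft.irfft(spec * gain.reshape(shape), n=n, axis=0)


def bandpass(run: BoldRun, low_hz: float = 0.01, high_hz: float = 0.1) -> BoldRun:
    """Zero-phase 4th-order Butterworth band-pass along time.

    Assumes censored rows were already interpolated (regress_out does this);
    censored frames stay flagged and never re-enter statistics.
    """
    nyquist = 1.0 / (2.0 * run.tr)
    if not (0.0 < low_hz < high_hz < nyquist):
        raise ArgumentError(
            f"band ({low_hz}, {high_hz}) Hz must lie strictly inside (0, {nyquist}) Hz"
        )
    filtered = zero_phase_bandpass(run.data, run.tr, low_hz, high_hz)
    return BoldRun(filtered, run.tr, run.mask, run.space)


def _gaussian_kernel_1d(sigma: float) -> np.ndarray:
    # same truncation rule as scipy.ndimage (truncate=4)
    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def _smooth_volume(data: np.ndarray, grid: VolumeGrid, fwhm_mm: float) -> np.ndarray:
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / grid.voxel_sizes()
    if data.ndim == 1:
        vol = data.reshape(grid.shape)
        return ndimage.gaussian_filter(vol, sigma=sigma_vox, mode="nearest").reshape(-1)
    vols = data.reshape((data.shape[0],) + grid.shape)
    out = ndimage.gaussian_filter(vols, sigma=(0.0, *sigma_vox), mode="nearest")
    return out.reshape(data.shape)


def surface_smoothing_iterations(mesh: SurfaceMesh, fwhm_mm: float) -> int:
    """Iteration count for neighbour-averaging smoothing, calibrated so the
    accumulated spatial variance approximates (fwhm / 2.3548)^2.

    One uniform step over self + neighbours spreads variance by roughly
    deg/(deg+1) * mean squared edge length. This is an approximate, surface-
    mode extension; the reference pipeline smooths in volume space.
    """
    e = mesh.edges()
    mean_sq_edge = float(
        (np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1) ** 2).mean()
    )
    mean_deg = 2.0 * len(e) / mesh.n_vertices
    step_var = mean_sq_edge * mean_deg / (mean_deg + 1.0)
    target_var = (fwhm_mm * FWHM_TO_SIGMA) ** 2
    return max(1, int(round(target_var / step_var)))


def _surface_averaging_operator(mesh: SurfaceMesh):
    from scipy import sparse as sp

    g = mesh.edge_graph().copy()
    g.data = np.ones_like(g.data)
    g = g + sp.eye(mesh.n_vertices, format="csr")
    inv_deg = 1.0 / np.asarray(g.sum(axis=1)).reshape(-1)
    return sp.diags(inv_deg) @ g


def _smooth_surface(data: np.ndarray, mesh: SurfaceMesh, fwhm_mm: float) -> np.ndarray:
    w = _surface_averaging_operator(mesh)
    k = surface_smoothing_iterations(mesh, fwhm_mm)
    out = data.T if data.ndim == 2 else data
    for _ in range(k):
        out = w @ out
    return out.T if data.ndim == 2 else out


def smooth(obj, fwhm_mm: float = 6.0, space=None):
    """Gaussian smoothing of a run or map; constant input is unchanged.

    Volume spaces use a separable Gaussian with sigma = fwhm / (2 sqrt(2 ln 2));
    surface spaces use iterative neighbour averaging calibrated to the FWHM.
    """
    if fwhm_mm <= 0:
        raise ArgumentError("fwhm_mm must be positive")
    from .fc import FCMap  # local import to avoid a cycle

    if isinstance(obj, BoldRun):
        sp_obj = space if space is not None else obj.space
        if isinstance(sp_obj, VolumeGrid):
            out = _smooth_volume(obj.data, sp_obj, fwhm_mm)
        elif isinstance(sp_obj, SurfaceMesh):
            out = _smooth_surface(obj.data, sp_obj, fwhm_mm)
        else:
            raise ArgumentError("smoothing requires a volume grid or surface mesh space")
        return BoldRun(out, obj.tr, obj.mask, obj.space)
    if isinstance(obj, FCMap):
        sp_obj = space if space is not None else obj.space
        if isinstance(sp_obj, VolumeGrid):
            out = _smooth_volume(obj.values, sp_obj, fwhm_mm)
        elif isinstance(sp_obj, SurfaceMesh):
            out = _smooth_surface(obj.values, sp_obj, fwhm_mm)
        else:
            raise ArgumentError("smoothing requires a volume grid or surface mesh space")
        return replace(obj, values=out)
    arr = np.asarray(obj, dtype=float)
    if isinstance(space, VolumeGrid):
        return _smooth_volume(arr, space, fwhm_mm)
    if isinstance(space, SurfaceMesh):
        return _smooth_surface(arr, space, fwhm_mm)
    raise ArgumentError("pass a BoldRun, FCMap, or an array with an explicit space")


def denoise_run(
    run: BoldRun,
    motion,
    tissue_means,
    *,
    drop_frames: int = 10,
    fd_threshold_mm: float = 0.5,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
    fwhm_mm: float | None = 6.0,
    recipe: str = "36p",
    head_radius_mm: float = 50.0,
) -> tuple[BoldRun, dict]:
    """Full denoising chain; returns the denoised run and a provenance record.

    ``recipe`` selects the nuisance family: "36p" (default, in-house data) or
    "gsr" (motion + global signal family, normative-style runs).
    """
    arr = _motion_array(motion)
    tissue = np.asarray(
        tissue_means[list(TISSUE_COLUMNS)] if hasattr(tissue_means, "columns") else tissue_means,
        dtype=float,
    )
    if drop_frames:
        run = drop_initial_frames(run, drop_frames)
        arr = arr[drop_frames:]
        tissue = tissue[drop_frames:]
    fd = framewise_displacement(arr, head_radius_mm)
    run = censor(run, fd, fd_threshold_mm)
    if recipe == "36p":
        conf = build_confounds_36p(arr, tissue)
    elif recipe == "gsr":
        conf = build_confounds_gsr(arr, tissue[:, 0])
    else:
        raise ArgumentError(f"unknown denoising recipe {recipe!r}")
    run = regress_out(run, conf)
    run = bandpass(run, low_hz, high_hz)
    if fwhm_mm is not None:
        run = smooth(run, fwhm_mm)
    record = {
        "frames_dropped": int(drop_frames),
        "frames_censored": int((~run.mask).sum()),
        "fd_threshold_mm": fd_threshold_mm,
        "band_hz": [low_hz, high_hz],
        "fwhm_mm": fwhm_mm,
        "recipe": recipe,
        "n_confounds": conf.values.shape[1],
    }
    return run, record
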