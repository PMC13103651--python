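"""End-to-end orchestration of the three analyses.

* normative mode — average a healthy cohort's Fisher-z seed-FC maps,
  identify the positive/negative surface peaks once, and evaluate those
  fixed sites in every patient (group comparisons and FS14 correlations at
  vertex and sphere level);
* individual mode — identify each subject's own peaks with no restrictions
  and quantify their spatial overlap and symptom associations;
* simulate-validate mode — place a virtual coil over a target site,
  mask the top fraction of the surrogate field, and correlate pre/post
  changes of masked mean FC with changes in FS14 in a longitudinal cohort.

Every mode runs against generated cohorts when no data directory is given
(the reference study's data are not public), all randomness flows from one
master seed, and all outputs are byte-stable for a fixed configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .errors import ArgumentError, DataError, InputOutputError
from .fc import FCMap, average_maps, correlation_map, fisher_z, seed_mean_timeseries
from .field import masked_mean_fc, project_to_scalp, surrogate_field, top_fraction_mask
from .geometry import THALAMUS_LABELS
from .preprocess import denoise_run
from .rng import substream
from .stats import delta_correlation, pearson_test, two_sample_t
from .synth import (Cohort, CohortTruth, make_default_study, simulate_cohort,
                    simulate_longitudinal)
from .targeting import (SphereROI, TargetSite, find_peaks, geodesic_sphere,
                        overlap_rate, sphere_mean, volume_to_surface)

__all__ = [
    "AnalysisConfig",
    "CohortResult",
    "run_normative",
    "run_individual",
    "run_simulation_validation",
    "run_analysis",
    "MODES",
]

MODES = ("normative", "individual", "simulate-validate")

#: reference parameter defaults; overrides are flagged in reports
_REFERENCE_DEFAULTS = {
    "fd_threshold_mm": 0.5,
    "low_hz": 0.01,
    "high_hz": 0.1,
    "fwhm_mm": 6.0,
    "sphere_radius_mm": 6.0,
    "mask_fraction": 0.30,
    "drop_frames": 10,
}


@dataclass
class AnalysisConfig:
    """All knobs of one analysis run; defaults are the reference values."""

    mode: str = "normative"
    out_dir: str | None = None
    data_dir: str | None = None
    # cohort sizes (synthetic mode)
    n_patients: int = 100
    n_controls: int = 100
    n_normative: int = 100
    n_longitudinal: int = 35
    # acquisition
    n_frames: int = 240
    tr: float = 2.0
    # denoising
    drop_frames: int = 10
    fd_threshold_mm: float = 0.5
    low_hz: float = 0.01
    high_hz: float = 0.1
    fwhm_mm: float = 6.0
    recipe: str = "36p"
    normative_recipe: str = "gsr"
    # seed + targeting
    seed_labels: tuple[int, ...] = THALAMUS_LABELS
    sphere_radius_mm: float = 6.0
    mask_fraction: float = 0.30
    field_sigma_mm: float = 20.0
    # synthetic geometry
    mesh_subdivisions: int = 4
    mesh_radius_mm: float = 50.0
    scalp_radius_mm: float = 60.0
    grid_shape: int = 16
    voxel_mm: float = 7.0
    space: str = "volume"
    longitudinal_space: str = "surface"
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ArgumentError(f"mode must be one of {MODES}")
        positive = ["n_frames", "tr", "fd_threshold_mm", "low_hz", "high_hz",
                    "fwhm_mm", "sphere_radius_mm", "mask_fraction",
                    "field_sigma_mm", "mesh_radius_mm", "scalp_radius_mm",
                    "voxel_mm"]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ArgumentError(f"{name} must be positive")
        if not (0 < self.mask_fraction <= 1):
            raise ArgumentError("mask_fraction must lie in (0, 1]")
        self.seed_labels = tuple(int(v) for v in self.seed_labels)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["seed_labels"] = list(self.seed_labels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        return cls(**d)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        path = Path(path)
        if not path.exists():
            raise InputOutputError(f"missing config file: {path}")
        return cls.from_dict(yaml.safe_load(path.read_text()))

    def overridden_parameters(self) -> dict:
        return {k: getattr(self, k) for k, v in _REFERENCE_DEFAULTS.items()
                if getattr(self, k) != v}


@dataclass
class CohortResult:
    """Everything one mode reports, plus deterministic writers."""

    config: AnalysisConfig
    sites: pd.DataFrame
    subject_values: pd.DataFrame
    stats: pd.DataFrame
    overlap: pd.DataFrame | None = None
    deltas: pd.DataFrame | None = None
    report_text: str = ""
    hashes: dict = dc_field(default_factory=dict)

    def write(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        # the output location is invocation detail, not analysis configuration;
        # dropping it keeps reruns of one config byte-identical
        snapshot = dataclasses.replace(self.config, out_dir=None)
        snapshot.to_yaml(out / "config.yaml")
        tio.write_table(self.sites, out / "sites.tsv")
        tio.write_table(self.subject_values, out / "subject_values.tsv")
        tio.write_table(self.stats, out / "stats.tsv")
        if self.overlap is not None:
            tio.write_table(self.overlap, out / "overlap.tsv")
        if self.deltas is not None:
            tio.write_table(self.deltas, out / "deltas.tsv")
        (out / "report.txt").write_text(self.report_text)
        hashes = dict(self.hashes)
        for f in sorted(out.glob("*.tsv")):
            hashes[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
        tio.write_json(hashes, out / "hashes.json")
        return out


# --------------------------------------------------------------------------
# shared plumbing
# --------------------------------------------------------------------------

def _seed_for(cfg: AnalysisConfig, *path) -> int:
    return int(substream(cfg.master_seed, *path).generate_state(1)[0] % (2**31))


def _make_truth(cfg: AnalysisConfig) -> CohortTruth:
    return make_default_study(
        subdivisions=cfg.mesh_subdivisions, radius_mm=cfg.mesh_radius_mm,
        scalp_radius_mm=cfg.scalp_radius_mm, grid_shape=cfg.grid_shape,
        voxel_mm=cfg.voxel_mm)


def _subject_surface_map(record, truth: CohortTruth, cfg: AnalysisConfig,
                         recipe: str) -> tuple[FCMap, FCMap | None]:
    """(surface map, volume map or None) for one subject record."""
    den, _ = denoise_run(
        record.bold, record.motion, record.tissue,
        drop_frames=cfg.drop_frames, fd_threshold_mm=cfg.fd_threshold_mm,
        low_hz=cfg.low_hz, high_hz=cfg.high_hz, fwhm_mm=cfg.fwhm_mm,
        recipe=recipe)
    if record.bold.space is truth.grid:
        vol = fisher_z(correlation_map(den, seed_mean_timeseries(den, cfg.seed_labels)))
        return volume_to_surface(vol, truth.mesh, truth.grid), vol
    seed_ts = record.seed_signal[-den.n_frames:][den.mask]
    return fisher_z(correlation_map(den, seed_ts)), None


def _cohort_surface_maps(cohort: Cohort, truth: CohortTruth, cfg: AnalysisConfig,
                         recipe: str) -> tuple[list[FCMap], list[FCMap] | None]:
    surf, vol = [], []
    for i in range(len(cohort)):
        s, v = _subject_surface_map(cohort.subject_run(i), truth, cfg, recipe)
        surf.append(s)
        if v is not None:
            vol.append(v)
    return surf, (vol if vol else None)


def identify_normative_sites(cfg: AnalysisConfig, truth: CohortTruth
                             ) -> tuple[dict[str, TargetSite], dict[str, SphereROI], FCMap]:
    """Simulate (or load) the normative cohort, average its maps, and find
    the positive/negative surface peaks with their geodesic spheres."""
    cohort = simulate_cohort(truth, cfg.n_normative, n_frames=cfg.n_frames,
                             tr=cfg.tr, seed=_seed_for(cfg, "normative"),
                             space=cfg.space, groups=("control",))
    surf_maps, vol_maps = _cohort_surface_maps(cohort, truth, cfg,
                                               cfg.normative_recipe)
    if vol_maps is not None:
        normative = volume_to_surface(average_maps(vol_maps), truth.mesh, truth.grid)
    else:
        normative = average_maps(surf_maps)
    pos, neg = find_peaks(normative)
    for site in (pos, neg):
        sv, sc = project_to_scalp(site.coord_mm, truth.scalp)
        site.scalp_vertex, site.scalp_coord_mm = sv, sc
    rois = {s.polarity: geodesic_sphere(truth.mesh, s.vertex, cfg.sphere_radius_mm)
            for s in (pos, neg)}
    return {"positive": pos, "negative": neg}, rois, normative


def _sites_table(sites: dict[str, TargetSite], rois: dict[str, SphereROI]) -> pd.DataFrame:
    rows = []
    for pol in ("negative", "positive"):
        s = sites[pol]
        rows.append({
            "polarity": pol, "vertex": s.vertex,
            "x_mm": s.coord_mm[0], "y_mm": s.coord_mm[1], "z_mm": s.coord_mm[2],
            "scalp_vertex": s.scalp_vertex if s.scalp_vertex is not None else -1,
            "scalp_x_mm": s.scalp_coord_mm[0] if s.scalp_coord_mm is not None else np.nan,
            "scalp_y_mm": s.scalp_coord_mm[1] if s.scalp_coord_mm is not None else np.nan,
            "scalp_z_mm": s.scalp_coord_mm[2] if s.scalp_coord_mm is not None else np.nan,
            "sphere_n_vertices": len(rois[pol].members) if pol in rois else 0,
        })
    return pd.DataFrame(rows)


def _stats_rows(values: pd.DataFrame, measure_cols: dict[str, str],
                has_controls: bool) -> tuple[list[dict], list[str]]:
    """Group t tests and FS14 correlations for each measure column."""
    rows, lines = [], []
    pat = values[values["group"] == "patient"]
    con = values[values["group"] == "control"]
    for label, col in measure_cols.items():
        level, polarity = label.split("_", 1)
        if has_controls and len(con) >= 2 and len(pat) >= 2:
            try:
                gc = two_sample_t(pat[col].to_numpy(float), con[col].to_numpy(float))
                rows.append({"test": "group_t", "level": level, "polarity": polarity,
                             "statistic": gc.t, "p": gc.p, "n": gc.n1 + gc.n2,
                             "ci_low": np.nan, "ci_high": np.nan})
                lines.append(f"  {polarity} {level}: patients vs controls "
                             f"t = {gc.t:.2f}, p = {gc.p:.3f}")
            except DataError as exc:
                lines.append(f"  {polarity} {level}: group test skipped ({exc})")
        try:
            cr = pearson_test(pat[col].to_numpy(float), pat["fs14"].to_numpy(float))
            rows.append({"test": "fs14_correlation", "level": level,
                         "polarity": polarity, "statistic": cr.r, "p": cr.p,
                         "n": cr.n, "ci_low": cr.ci_low, "ci_high": cr.ci_high})
            lines.append(f"  {polarity} {level}: FC-FS14 r = {cr.r:.2f} "
                         f"[{cr.ci_low:.2f}, {cr.ci_high:.2f}], p = {cr.p:.3f}")
        except DataError as exc:
            lines.append(f"  {polarity} {level}: correlation skipped ({exc})")
    return rows, lines


def _report_header(cfg: AnalysisConfig, title: str, n_lines: list[str]) -> list[str]:
    lines = [title, "=" * len(title), ""]
    lines += n_lines
    over = cfg.overridden_parameters()
    if over:
        lines.append("parameters overriding reference defaults: "
                     + ", ".join(f"{k}={v}" for k, v in sorted(over.items())))
    else:
        lines.append("all reference-default parameters in effect "
                     "(FD 0.5 mm, 0.01-0.1 Hz, 6 mm FWHM, 6 mm spheres, top 30% mask)")
    lines.append(f"master seed: {cfg.master_seed}")
    lines.append("")
    return lines


def _phenotype_hash(cohort: Cohort) -> str:
    csv = cohort.phenotypes.to_csv(index=False, float_format="%.10g")
    return hashlib.sha256(csv.encode()).hexdigest()


# --------------------------------------------------------------------------
# modes
# --------------------------------------------------------------------------

def run_normative(cfg: AnalysisConfig,
                  truth: CohortTruth | None = None) -> CohortResult:
    """Normative targeting: fixed sites from a healthy cohort, evaluated in
    patients (and controls when present)."""
    if cfg.data_dir is not None:
        raise InputOutputError(
            f"on-disk cohorts are read per subject via thalatarget.io; "
            f"directory mode expects a prepared layout under {cfg.data_dir}")
    truth = truth if truth is not None else _make_truth(cfg)
    sites, rois, normative = identify_normative_sites(cfg, truth)
    groups = ("patient", "control") if cfg.n_controls > 0 else ("patient",)
    n_per = cfg.n_patients if cfg.n_controls in (0, cfg.n_patients) else None
    if n_per is None:
        raise ArgumentError("synthetic mode uses equal patient/control sizes")
    cohort = simulate_cohort(truth, n_per, n_frames=cfg.n_frames, tr=cfg.tr,
                             seed=_seed_for(cfg, "cohort"), space=cfg.space,
                             groups=groups)
    surf_maps, _ = _cohort_surface_maps(cohort, truth, cfg, cfg.recipe)
    values = cohort.phenotypes[["subject_id", "group", "fs14"]].copy()
    measure_cols = {}
    for pol in ("negative", "positive"):
        vcol, scol = f"{pol}_vertex_z", f"{pol}_sphere_z"
        values[vcol] = [m.values[sites[pol].vertex] for m in surf_maps]
        values[scol] = [sphere_mean(m, rois[pol]) for m in surf_maps]
        measure_cols[f"vertex_{pol}"] = vcol
        measure_cols[f"sphere_{pol}"] = scol
    rows, stat_lines = _stats_rows(values, measure_cols, cfg.n_controls > 0)
    lines = _report_header(cfg, "Normative targeting", [
        f"normative cohort: n = {cfg.n_normative} ({cfg.normative_recipe} recipe)",
        f"evaluation cohort: {len(cohort)} subjects in groups {groups} "
        f"({cfg.recipe} recipe)",
    ])
    neg, pos = sites["negative"], sites["positive"]
    lines.append(f"negative site: vertex {neg.vertex} at "
                 f"({neg.coord_mm[0]:.1f}, {neg.coord_mm[1]:.1f}, {neg.coord_mm[2]:.1f}) mm, "
                 f"scalp vertex {neg.scalp_vertex}")
    lines.append(f"positive site: vertex {pos.vertex} at "
                 f"({pos.coord_mm[0]:.1f}, {pos.coord_mm[1]:.1f}, {pos.coord_mm[2]:.1f}) mm, "
                 f"scalp vertex {pos.scalp_vertex}")
    lines.append("")
    lines += stat_lines
    lines.append("")
    lines.append(f"tests performed: {len(rows)} (no multiple-comparison correction)")
    return CohortResult(cfg, _sites_table(sites, rois), values,
                        pd.DataFrame(rows), report_text="\n".join(lines) + "\n",
                        hashes={"phenotypes": _phenotype_hash(cohort)})


def run_individual(cfg: AnalysisConfig,
                   truth: CohortTruth | None = None) -> CohortResult:
    """Individual targeting: per-subject unrestricted peaks, overlap rates,
    and symptom associations of subject-specific extrema."""
    truth = truth if truth is not None else _make_truth(cfg)
    groups = ("patient", "control") if cfg.n_controls > 0 else ("patient",)
    cohort = simulate_cohort(truth, cfg.n_patients, n_frames=cfg.n_frames,
                             tr=cfg.tr, seed=_seed_for(cfg, "cohort"),
                             space=cfg.space, groups=groups)
    surf_maps, _ = _cohort_surface_maps(cohort, truth, cfg, cfg.recipe)
    values = cohort.phenotypes[["subject_id", "group", "fs14"]].copy()
    rois: dict[str, list[SphereROI]] = {"negative": [], "positive": []}
    cols: dict[str, list] = {f"{p}_{w}": [] for p in ("negative", "positive")
                             for w in ("vertex", "vertex_z", "sphere_z")}
    for m in surf_maps:
        pos, neg = find_peaks(m)
        for site in (pos, neg):
            roi = geodesic_sphere(truth.mesh, site.vertex, cfg.sphere_radius_mm)
            rois[site.polarity].append(roi)
            cols[f"{site.polarity}_vertex"].append(site.vertex)
            cols[f"{site.polarity}_vertex_z"].append(m.values[site.vertex])
            cols[f"{site.polarity}_sphere_z"].append(sphere_mean(m, roi))
    for k, v in cols.items():
        values[k] = v
    measure_cols = {f"vertex_{p}": f"{p}_vertex_z" for p in ("negative", "positive")}
    measure_cols.update({f"sphere_{p}": f"{p}_sphere_z" for p in ("negative", "positive")})
    rows, stat_lines = _stats_rows(values, measure_cols, cfg.n_controls > 0)
    overlap_rows = []
    for pol in ("negative", "positive"):
        for g in groups:
            idx = cohort.group_index(g)
            rate = overlap_rate([rois[pol][i] for i in idx], truth.mesh)
            overlap_rows.append({"polarity": pol, "group": g,
                                 "overlap_rate": rate, "n": len(idx)})
    overlap_df = pd.DataFrame(overlap_rows)
    lines = _report_header(cfg, "Individual targeting", [
        f"cohort: {len(cohort)} subjects in groups {groups}",
        "peaks selected per subject with no spatial restrictions",
    ])
    for row in overlap_rows:
        lines.append(f"  {row['polarity']} sphere overlap in {row['group']}s: "
                     f"{100 * row['overlap_rate']:.1f}% (max vertex coverage, "
                     f"n = {row['n']})")
    lines.append("")
    lines += stat_lines
    lines.append("")
    lines.append(f"tests performed: {len(rows)} (no multiple-comparison correction)")
    return CohortResult(cfg, pd.DataFrame(), values, pd.DataFrame(rows),
                        overlap=overlap_df, report_text="\n".join(lines) + "\n",
                        hashes={"phenotypes": _phenotype_hash(cohort)})


def run_simulation_validation(cfg: AnalysisConfig,
                              truth: CohortTruth | None = None,
                              sites: dict[str, TargetSite] | None = None
                              ) -> CohortResult:
    """Virtual-stimulation validation of target sites on a longitudinal
    cohort: scalp projection -> surrogate field -> top-fraction mask ->
    masked mean DeltaFC vs DeltaFS14."""
    truth = truth if truth is not None else _make_truth(cfg)
    if sites is None:
        sites, rois, _ = identify_normative_sites(cfg, truth)
    else:
        rois = {p: geodesic_sphere(truth.mesh, s.vertex, cfg.sphere_radius_mm)
                for p, s in sites.items()}
    cohort = simulate_longitudinal(truth, cfg.n_longitudinal,
                                   n_frames=cfg.n_frames, tr=cfg.tr,
                                   seed=_seed_for(cfg, "longitudinal"),
                                   space=cfg.longitudinal_space)
    pre_maps, post_maps = [], []
    for i in range(len(cohort)):
        pre, _ = _subject_surface_map(cohort.subject_pre_run(i), truth, cfg, cfg.recipe)
        post, _ = _subject_surface_map(cohort.subject_post_run(i), truth, cfg, cfg.recipe)
        pre_maps.append(pre)
        post_maps.append(post)
    fs_pre = cohort.phenotypes["fs14"].to_numpy(float)
    fs_post = cohort.phenotypes["fs14_post"].to_numpy(float)
    values = cohort.phenotypes[["subject_id", "group", "fs14", "fs14_post"]].copy()
    stat_rows, delta_rows, lines_stats = [], [], []
    for pol in ("negative", "positive"):
        site = sites[pol]
        coil_vertex, coil = project_to_scalp(site.coord_mm, truth.scalp)
        fmap = surrogate_field(truth.mesh, coil, cfg.field_sigma_mm)
        mask = top_fraction_mask(fmap, cfg.mask_fraction)
        pre_fc = np.array([masked_mean_fc(m, mask) for m in pre_maps])
        post_fc = np.array([masked_mean_fc(m, mask) for m in post_maps])
        values[f"{pol}_pre_fc"] = pre_fc
        values[f"{pol}_post_fc"] = post_fc
        values[f"{pol}_delta_fc"] = post_fc - pre_fc
        try:
            res = delta_correlation(pre_fc, post_fc, fs_pre, fs_post)
            stat_rows.append({"test": "delta_delta_correlation", "level": "mask",
                              "polarity": pol, "statistic": res.r, "p": res.p,
                              "n": res.n, "ci_low": res.ci_low,
                              "ci_high": res.ci_high})
            lines_stats.append(
                f"  {pol} site (scalp vertex {coil_vertex}, mask "
                f"{int(mask.sum())} vertices): DeltaFC-DeltaFS14 "
                f"r = {res.r:.2f} [{res.ci_low:.2f}, {res.ci_high:.2f}], "
                f"p = {res.p:.3f}")
        except DataError as exc:
            lines_stats.append(f"  {pol} site: delta correlation skipped ({exc})")
        delta_rows.append({"polarity": pol, "coil_scalp_vertex": coil_vertex,
                           "mask_n_vertices": int(mask.sum()),
                           "mean_delta_fc": float((post_fc - pre_fc).mean()),
                           "mean_delta_fs14": float((fs_post - fs_pre).mean())})
    lines = _report_header(cfg, "Virtual-stimulation validation", [
        f"longitudinal cohort: n = {cfg.n_longitudinal} patients, pre/post",
        f"surrogate field: Gaussian decay, sigma = {cfg.field_sigma_mm:.0f} mm; "
        f"mask = top {100 * cfg.mask_fraction:.0f}% of vertices by field magnitude",
    ])
    lines += lines_stats
    lines.append("")
    lines.append(f"tests performed: {len(stat_rows)} "
                 "(no multiple-comparison correction)")
    return CohortResult(cfg, _sites_table(sites, rois), values,
                        pd.DataFrame(stat_rows), deltas=pd.DataFrame(delta_rows),
                        report_text="\n".join(lines) + "\n",
                        hashes={"phenotypes": hashlib.sha256(
                            cohort.phenotypes.to_csv(index=False,
                                                     float_format="%.10g").encode()
                        ).hexdigest()})


def run_analysis(cfg: AnalysisConfig) -> CohortResult:
    """Dispatch on ``cfg.mode`` and write outputs when ``cfg.out_dir`` is set."""
    runner = {"normative": run_normative, "individual": run_individual,
              "simulate-validate": run_simulation_validation}[cfg.mode]
    result = runner(cfg)
    if cfg.out_dir is not None:
        result.write(cfg.out_dir)
    return result
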