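"""Seed-based functional-connectivity maps.

A seed region's mean time series is correlated (Pearson) with every
location; the r map is variance-stabilized with the Fisher r-to-z
transform, and z maps are averaged across subjects to build a normative
map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ArgumentError, DataError
from .geometry import SurfaceMesh, VolumeGrid, THALAMUS_LABELS
from .preprocess import BoldRun

__all__ = [
    "FCMap",
    "seed_mean_timeseries",
    "correlation_map",
    "fisher_z",
    "average_maps",
    "R_CLIP",
]

logger = logging.getLogger(__name__)

#: correlations are clipped to +/-(1 - R_CLIP) before atanh so z stays finite
R_CLIP = 1e-7


def _n_locations(space) -> int:
    if isinstance(space, SurfaceMesh):
        return space.n_vertices
    if isinstance(space, VolumeGrid):
        return space.n_voxels
    raise ArgumentError("space must be a SurfaceMesh or VolumeGrid")


@dataclass
class FCMap:
    """Per-location connectivity values tied to a space.

    ``kind`` distinguishes raw Pearson r ("r") from Fisher z ("z");
    ``flags`` optionally marks locations with degraded provenance (e.g.
    vertices sampled outside the volume grid).
    """

    values: np.ndarray
    space: SurfaceMesh | VolumeGrid
    provenance: str = ""
    kind: str = "r"
    flags: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("r", "z"):
            raise ArgumentError("kind must be 'r' or 'z'")
        if self.values.shape != (_n_locations(self.space),):
            raise ArgumentError("map cardinality must equal the space's location count")
        if not np.all(np.isfinite(self.values)):
            raise DataError("FC map contains non-finite values")
        if self.flags is not None:
            self.flags = np.asarray(self.flags, dtype=bool)
            if self.flags.shape != self.values.shape:
                raise ArgumentError("flags must match the map cardinality")

    @property
    def n_locations(self) -> int:
        return len(self.values)


def seed_mean_timeseries(run: BoldRun, seed_labels=THALAMUS_LABELS) -> np.ndarray:
    """Unweighted mean signal over seed-labelled locations, retained frames only."""
    if not isinstance(run.space, VolumeGrid):
        raise ArgumentError("label-based seeds require a volume-space run")
    labels = run.space.flat_labels()
    mask = np.isin(labels, np.asarray(list(seed_labels)))
    if not mask.any():
        raise ArgumentError("no location carries a seed label")
    return run.data[run.mask][:, mask].mean(axis=1)


def correlation_map(run: BoldRun, seed_ts: np.ndarray) -> FCMap:
    """Pearson correlation of every location with the seed series.

    ``seed_ts`` may be given over retained frames (length ``n_retained``) or
    over all frames (length ``n_frames``; it is masked here). Constant
    locations get r = 0 with a logged warning; a constant seed is an error.
    """
    seed_ts = np.asarray(seed_ts, dtype=float)
    if seed_ts.ndim != 1:
        raise ArgumentError("seed series must be one-dimensional")
    if len(seed_ts) == run.n_frames:
        seed_ts = seed_ts[run.mask]
    elif len(seed_ts) != run.n_retained:
        raise ArgumentError("seed series length matches neither all nor retained frames")
    if run.n_retained < 3:
        raise ArgumentError("need at least 3 retained frames")
    s = seed_ts - seed_ts.mean()
    s_norm = np.linalg.norm(s)
    if s_norm == 0:
        raise DataError("seed series is constant")
    y = run.retained()
    constant = np.ptp(y, axis=0) == 0
    y = y - y.mean(axis=0)
    y[:, constant] = 0.0
    y_norm = np.linalg.norm(y, axis=0)
    if constant.any():
        logger.warning("%d constant location(s); their correlation is set to 0",
                       int(constant.sum()))
    y_norm[constant] = 1.0
    r = (y.T @ s) / (y_norm * s_norm)
    r[constant] = 0.0
    r = np.clip(r, -1.0, 1.0)
    return FCMap(r, run.space, kind="r")


def fisher_z(fc_map: FCMap) -> FCMap:
    """Fisher r-to-z: z = atanh(r), with r clipped to +/-(1 - 1e-7) first."""
    if fc_map.kind != "r":
        raise ArgumentError("fisher_z expects a raw-r map")
    r = np.clip(fc_map.values, -(1.0 - R_CLIP), 1.0 - R_CLIP)
    return FCMap(np.arctanh(r), fc_map.space, fc_map.provenance, kind="z",
                 flags=fc_map.flags)


def _same_space(a, b) -> bool:
    if a is b:
        return True
    if isinstance(a, SurfaceMesh) and isinstance(b, SurfaceMesh):
        return (a.vertices.shape == b.vertices.shape
                and np.array_equal(a.triangles, b.triangles)
                and np.allclose(a.vertices, b.vertices))
    if isinstance(a, VolumeGrid) and isinstance(b, VolumeGrid):
        return a.shape == b.shape and np.allclose(a.affine, b.affine)
    return False


def average_maps(maps: list[FCMap], provenance: str = "normative") -> FCMap:
    """Element-wise arithmetic mean of Fisher-z maps sharing one space."""
    if not maps:
        raise ArgumentError("need at least one map")
    first = maps[0]
    for m in maps:
        if m.kind != "z":
            raise ArgumentError("average_maps expects Fisher-z maps")
        if not _same_space(m.space, first.space):
            raise ArgumentError("all maps must share one space")
    stacked = np.stack([m.values for m in maps])
    return FCMap(stacked.mean(axis=0), first.space, provenance, kind="z")
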