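"""Distance-decay surrogate for the stimulation electric field.

A finite-element E-field solver (tissue conductivities, coil windings) is
out of scope here; what the downstream analysis needs is the *masking
logic*: place the coil on the scalp over a cortical target, compute a
field-magnitude map that decays with distance from the coil, keep the
top fraction of cortical vertices as the stimulation mask, and average FC
inside the mask. The surrogate field is an isotropic Gaussian decay
exp(-d^2 / (2 sigma^2)); sigma defaults to 20 mm so the top-30% mask is a
contiguous patch at realistic head scale. Field units are arbitrary
stand-ins for V/m.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np

from .errors import ArgumentError
from .fc import FCMap
from .geometry import SurfaceMesh

__all__ = [
    "FieldMap",
    "project_to_scalp",
    "surrogate_field",
    "top_fraction_mask",
    "masked_mean_fc",
]


@dataclass
class FieldMap:
    """Per-vertex non-negative field magnitude for one coil placement."""

    values: np.ndarray
    coil_position_mm: np.ndarray
    sigma_mm: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.coil_position_mm = np.asarray(self.coil_position_mm, dtype=float)
        if (self.values < 0).any():
            raise ArgumentError("field magnitudes must be non-negative")
        if self.sigma_mm <= 0:
            raise ArgumentError("sigma_mm must be positive")


def project_to_scalp(point_mm: np.ndarray, scalp: SurfaceMesh) -> tuple[int, np.ndarray]:
    """Nearest scalp vertex to a point (Euclidean); ties break to the lowest
    index. Returns (vertex index, vertex coordinate)."""
    if scalp.n_vertices == 0:
        raise ArgumentError("scalp mesh is empty")
    point = np.asarray(point_mm, dtype=float)
    d = np.linalg.norm(scalp.vertices - point, axis=1)
    idx = int(np.argmin(d))
    return idx, scalp.vertices[idx].copy()


def surrogate_field(cortex: SurfaceMesh, coil_position_mm: np.ndarray,
                    sigma_mm: float = 20.0) -> FieldMap:
    """Gaussian distance-decay field over cortical vertices.

    field_v = exp(-d_v^2 / (2 sigma^2)) with d_v the Euclidean distance from
    vertex v to the coil position; strictly decreasing in d.
    """
    if sigma_mm <= 0:
        raise ArgumentError("sigma_mm must be positive")
    coil = np.asarray(coil_position_mm, dtype=float)
    d = np.linalg.norm(cortex.vertices - coil, axis=1)
    return FieldMap(np.exp(-0.5 * (d / sigma_mm) ** 2), coil, sigma_mm)


def top_fraction_mask(field: FieldMap, fraction: float = 0.30) -> np.ndarray:
    """Boolean mask of the ceil(fraction * N) highest-field vertices.

    Ties at the cut are admitted lowest-index-first until the cardinality is
    met, so the mask size is always exactly ceil(fraction * N).
    """
    if not (0.0 < fraction <= 1.0):
        raise ArgumentError("fraction must lie in (0, 1]")
    n = len(field.values)
    k = ceil(fraction * n)
    order = np.argsort(-field.values, kind="stable")
    mask = np.zeros(n, dtype=bool)
    mask[order[:k]] = True
    return mask


def masked_mean_fc(fc_map: FCMap, mask: np.ndarray) -> float:
    """Unweighted mean FC (z) within a vertex mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (fc_map.n_locations,):
        raise ArgumentError("mask must be one boolean per map location")
    if not mask.any():
        raise ArgumentError("mask is empty")
    return float(fc_map.values[mask].mean())
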