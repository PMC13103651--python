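"""Spatial carriers: triangulated surfaces and labelled volume grids.

The synthetic stand-in for a cortical (or scalp) surface is an icosphere;
the stand-in for standard 2 mm MNI volume space is a small isotropic grid
with an integer seed-label image (thalamic labels 231-246 by convention).
Coordinates are millimetres, RAS+.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .errors import ArgumentError

__all__ = [
    "SurfaceMesh",
    "VolumeGrid",
    "make_mesh",
    "make_grid",
    "add_thalamic_seed",
    "THALAMUS_LABELS",
]

#: Brainnetome bilateral thalamus label range used as the default seed.
THALAMUS_LABELS = tuple(range(231, 247))


@dataclass
class SurfaceMesh:
    """Triangulated surface: vertex coordinates (mm) plus triangle indices.

    ``exclusion`` optionally flags vertices (e.g. a medial wall) that peak
    search must ignore; it is empty (all False) by default.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    exclusion: np.ndarray | None = None
    _edge_graph: sparse.csr_matrix | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ArgumentError("vertices must be an (V, 3) array of mm coordinates")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ArgumentError("triangles must be an (F, 3) array of vertex indices")
        if not np.all(np.isfinite(self.vertices)):
            raise ArgumentError("vertex coordinates must be finite")
        if self.triangles.size:
            if self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices):
                raise ArgumentError("triangle indices out of range")
        if self.exclusion is not None:
            self.exclusion = np.asarray(self.exclusion, dtype=bool)
            if self.exclusion.shape != (len(self.vertices),):
                raise ArgumentError("exclusion flags must be one boolean per vertex")
        graph = self.edge_graph()
        if graph.nnz and graph.data.min() <= 0:
            raise ArgumentError("mesh contains a zero-length edge")
        n_comp, _ = connected_components(graph, directed=False)
        if len(self.vertices) > 1 and n_comp != 1:
            raise ArgumentError("mesh edge graph must be connected")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def edges(self) -> np.ndarray:
        """Unique undirected edges, (E, 2), each row sorted."""
        tri = self.triangles
        pairs = np.concatenate([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]])
        pairs = np.sort(pairs, axis=1)
        return np.unique(pairs, axis=0)

    def edge_graph(self) -> sparse.csr_matrix:
        """Sparse symmetric graph weighted by Euclidean edge length (mm)."""
        if self._edge_graph is None:
            e = self.edges()
            w = np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)
            n = self.n_vertices
            g = sparse.coo_matrix(
                (np.concatenate([w, w]), (np.concatenate([e[:, 0], e[:, 1]]),
                                          np.concatenate([e[:, 1], e[:, 0]]))),
                shape=(n, n),
            )
            self._edge_graph = g.tocsr()
        return self._edge_graph

    def mean_edge_length(self) -> float:
        e = self.edges()
        return float(np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1).mean())

    def unit_directions(self) -> np.ndarray:
        """Vertex directions from the origin (used by the spherical generators)."""
        norms = np.linalg.norm(self.vertices, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return self.vertices / norms


@dataclass
class VolumeGrid:
    """Regular voxel grid with an affine from 0-based indices to mm (RAS+).

    ``labels`` is an integer image (0 = background); the thalamic seed is a
    set of non-zero labels inside it. Flattened-location order is C order.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise ArgumentError("shape must be three positive integers")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ArgumentError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ArgumentError("affine must be invertible")
        if self.labels is None:
            self.labels = np.zeros(self.shape, dtype=np.int32)
        else:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != self.shape:
                raise ArgumentError("label image shape must match grid shape")
            if self.labels.min() < 0:
                raise ArgumentError("seed labels must be non-negative")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def voxel_sizes(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_centers_mm(self) -> np.ndarray:
        """(N, 3) mm coordinates of voxel centres in C (flattened) order."""
        idx = np.indices(self.shape).reshape(3, -1)
        homo = np.vstack([idx, np.ones(idx.shape[1])])
        return (self.affine @ homo)[:3].T

    def world_to_voxel(self, points_mm: np.ndarray) -> np.ndarray:
        """Continuous 0-based voxel coordinates of mm points, (N, 3)."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        inv = np.linalg.inv(self.affine)
        homo = np.hstack([pts, np.ones((len(pts), 1))])
        return (inv @ homo.T)[:3].T

    def flat_labels(self) -> np.ndarray:
        return self.labels.reshape(-1)


def make_mesh(subdivisions: int, radius_mm: float) -> SurfaceMesh:
    """Icosphere of the requested radius.

    subdivisions=0 is the icosahedron (12 vertices / 20 triangles); each
    subdivision multiplies the face count by 4 (V' = V + E).
    """
    if subdivisions < 0:
        raise ArgumentError("subdivisions must be non-negative")
    if subdivisions > 6:
        raise ArgumentError("subdivisions > 6 exceeds desk scale")
    if radius_mm <= 0:
        raise ArgumentError("radius_mm must be positive")
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius_mm)
    return SurfaceMesh(np.asarray(ico.vertices), np.asarray(ico.faces))


def make_grid(shape: int | tuple[int, int, int], voxel_mm: float,
              center_mm: np.ndarray | tuple[float, float, float] = (0.0, 0.0, 0.0)) -> VolumeGrid:
    """Isotropic axis-aligned grid centred on ``center_mm``."""
    if isinstance(shape, int):
        shape = (shape, shape, shape)
    if voxel_mm <= 0:
        raise ArgumentError("voxel_mm must be positive")
    shape = tuple(int(s) for s in shape)
    aff = np.eye(4)
    aff[:3, :3] *= voxel_mm
    center = np.asarray(center_mm, dtype=float)
    aff[:3, 3] = center - voxel_mm * (np.asarray(shape) - 1) / 2.0
    return VolumeGrid(shape, aff)


def add_thalamic_seed(grid: VolumeGrid, labels: tuple[int, ...] = THALAMUS_LABELS,
                      center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)) -> VolumeGrid:
    """Assign the seed labels to the voxels nearest ``center_mm``, one per label.

    Mimics a small bilateral thalamic label block at the centre of the head.
    """
    centers = grid.voxel_centers_mm()
    d = np.linalg.norm(centers - np.asarray(center_mm), axis=1)
    order = np.argsort(d, kind="stable")[: len(labels)]
    lab = grid.labels.reshape(-1).copy()
    lab[order] = np.asarray(labels, dtype=lab.dtype)
    return VolumeGrid(grid.shape, grid.affine, lab.reshape(grid.shape))
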