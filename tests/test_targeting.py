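import networkx as nx
import numpy as np
import pytest
from hypothesis import given, strategies as st

from thalatarget.errors import ArgumentError, DataError
from thalatarget.fc import FCMap
from thalatarget.geometry import SurfaceMesh, make_grid
from thalatarget.targeting import (find_peaks, geodesic_sphere, overlap_rate,
                                   sphere_mean, volume_to_surface)


def _surface_map(values, mesh, kind="z"):
    return FCMap(np.asarray(values, dtype=float), mesh, kind=kind)


def _path_mesh(n=6, spacing=1.0):
    """Degenerate 'path' surface: a thin triangle strip along x."""
    top = np.column_stack([np.arange(n) * spacing, np.zeros(n), np.zeros(n)])
    bottom = np.column_stack([np.arange(n) * spacing, np.full(n, 100.0),
                              np.zeros(n)])
    verts = np.vstack([top, bottom])
    tris = []
    for i in range(n - 1):
        tris.append([i, i + 1, n + i])
        tris.append([i + 1, n + i + 1, n + i])
    return SurfaceMesh(verts, np.array(tris))


# ------------------------------------------------------ volume to surface --

def test_volume_to_surface_constant_volume(small_mesh):
    grid = make_grid(16, 7.0)
    vol = FCMap(np.full(grid.n_voxels, 1.7), grid, kind="z")
    surf = volume_to_surface(vol, small_mesh, grid)
    assert np.allclose(surf.values, 1.7)
    assert surf.kind == "z"


def test_volume_to_surface_exact_at_voxel_center():
    grid = make_grid(9, 2.0)
    vals = np.arange(grid.n_voxels, dtype=float)
    centers = grid.voxel_centers_mm()
    # a tiny mesh whose first vertex sits exactly on a voxel centre
    target = 4 * 81 + 4 * 9 + 6
    verts = np.array([centers[target],
                      centers[target] + [0.5, 0, 0],
                      centers[target] + [0, 0.5, 0]])
    mesh = SurfaceMesh(verts, np.array([[0, 1, 2]]))
    surf = volume_to_surface(FCMap(vals, grid, kind="z"), mesh, grid)
    assert surf.values[0] == pytest.approx(vals[target])


def test_volume_to_surface_midpoint_is_mean_of_neighbours():
    grid = make_grid(9, 2.0)
    vals = np.arange(grid.n_voxels, dtype=float)
    centers = grid.voxel_centers_mm()
    a = 4 * 81 + 4 * 9 + 4
    b = a + 1  # neighbour along the last axis
    mid = (centers[a] + centers[b]) / 2
    mesh = SurfaceMesh(np.array([mid, mid + [0.5, 0, 0], mid + [0, 0.5, 0]]),
                       np.array([[0, 1, 2]]))
    surf = volume_to_surface(FCMap(vals, grid, kind="z"), mesh, grid)
    assert surf.values[0] == pytest.approx((vals[a] + vals[b]) / 2)


def test_volume_to_surface_flags_outside_vertices():
    grid = make_grid(4, 2.0)
    mesh = SurfaceMesh(np.array([[0, 0, 0], [500.0, 0, 0], [0, 500.0, 0]]),
                       np.array([[0, 1, 2]]))
    surf = volume_to_surface(FCMap(np.ones(grid.n_voxels), grid, kind="z"),
                             mesh, grid)
    assert surf.flags.tolist() == [False, True, True]


# ----------------------------------------------------------------- peaks ---

def test_find_peaks_small_example():
    mesh = _path_mesh(3)
    vals = [0.1, 0.9, -0.7, 0.0, 0.0, 0.0]
    pos, neg = find_peaks(_surface_map(vals, mesh))
    assert pos.vertex == 1 and pos.polarity == "positive"
    assert neg.vertex == 2 and neg.polarity == "negative"
    assert np.allclose(pos.coord_mm, mesh.vertices[1])


def test_find_peaks_tie_breaks_to_lowest_index():
    mesh = _path_mesh(4)
    vals = np.zeros(8)
    vals[[4, 7]] = 1.0  # tie at the maximum
    vals[1] = -1.0
    pos, neg = find_peaks(_surface_map(vals, mesh))
    assert pos.vertex == 4
    assert neg.vertex == 1


def test_find_peaks_respects_exclusion_and_errors():
    mesh = _path_mesh(3)
    vals = [0.1, 0.9, -0.7, 0.0, 0.0, 0.0]
    pos, neg = find_peaks(_surface_map(vals, mesh),
                          exclusion=np.array([0, 1, 0, 0, 0, 0], dtype=bool))
    assert pos.vertex != 1
    with pytest.raises(DataError):
        find_peaks(_surface_map(vals, mesh), exclusion=np.ones(6, dtype=bool))
    with pytest.raises(DataError):
        find_peaks(_surface_map(np.zeros(6), mesh))


# ---------------------------------------------------------------- sphere ---

def test_geodesic_sphere_radius_zero_is_center_only(small_mesh):
    roi = geodesic_sphere(small_mesh, 17, 0.0)
    assert roi.members.tolist() == [17]
    with pytest.raises(ArgumentError):
        geodesic_sphere(small_mesh, 17, -1.0)


def test_geodesic_sphere_on_path_graph():
    mesh = _path_mesh(6, spacing=1.0)
    roi = geodesic_sphere(mesh, 0, 2.5)
    along_path = sorted(v for v in roi.members if v < 6)
    assert along_path == [0, 1, 2]  # unit edges: <= 2 hops


def test_geodesic_sphere_matches_exhaustive_shortest_path(small_mesh):
    # independent oracle: networkx Dijkstra on the same weighted edge graph
    g = nx.Graph()
    for (a, b) in small_mesh.edges():
        w = float(np.linalg.norm(small_mesh.vertices[a] - small_mesh.vertices[b]))
        g.add_edge(int(a), int(b), weight=w)
    for center in [0, 17, 80, 161]:
        for radius in [6.0, 15.0, 40.0]:
            roi = geodesic_sphere(small_mesh, center, radius)
            lengths = nx.single_source_dijkstra_path_length(g, center,
                                                            weight="weight")
            expected = sorted(v for v, d in lengths.items() if d <= radius)
            assert roi.members.tolist() == expected
            for v, d in zip(roi.members, roi.distances):
                assert d == pytest.approx(lengths[int(v)])


@given(st.integers(0, 161), st.floats(0.0, 30.0), st.floats(0.0, 30.0))
def test_geodesic_sphere_monotone_in_radius(center, r1, r2):
    mesh = _monotone_mesh()
    lo, hi = sorted([r1, r2])
    small = set(geodesic_sphere(mesh, center, lo).members.tolist())
    large = set(geodesic_sphere(mesh, center, hi).members.tolist())
    assert small <= large


_cached_mesh = None


def _monotone_mesh():
    global _cached_mesh
    if _cached_mesh is None:
        from thalatarget.geometry import make_mesh

        _cached_mesh = make_mesh(2, 50.0)
    return _cached_mesh


# ------------------------------------------------------------ sphere mean --

def test_sphere_mean_examples(small_mesh):
    vals = np.zeros(small_mesh.n_vertices)
    vals[:3] = [1.0, 2.0, 3.0]
    fc = _surface_map(vals, small_mesh)
    single = geodesic_sphere(small_mesh, 5, 0.0)
    assert sphere_mean(fc, single) == vals[5]
    from thalatarget.targeting import SphereROI
    roi = SphereROI(0, 99.0, np.array([0, 1, 2]), np.array([0.0, 1.0, 2.0]))
    assert sphere_mean(fc, roi) == pytest.approx(2.0)


def test_sphere_mean_of_full_mesh_is_global_mean(small_mesh, rng):
    vals = rng.normal(size=small_mesh.n_vertices)
    fc = _surface_map(vals, small_mesh)
    whole = geodesic_sphere(small_mesh, 0, 1e6)
    assert len(whole.members) == small_mesh.n_vertices
    assert sphere_mean(fc, whole) == pytest.approx(float(vals.mean()))


# ---------------------------------------------------------------- overlap --

def test_overlap_rate_examples(small_mesh):
    same = [geodesic_sphere(small_mesh, 10, 6.0) for _ in range(5)]
    assert overlap_rate(same, small_mesh) == 1.0
    disjoint = [geodesic_sphere(small_mesh, c, 0.0) for c in (1, 50, 100)]
    assert overlap_rate(disjoint, small_mesh) == pytest.approx(1 / 3)


def test_overlap_rate_counts_double_coverage():
    mesh = _path_mesh(8)
    from thalatarget.targeting import SphereROI

    def roi(members):
        m = np.array(members)
        return SphereROI(members[0], 10.0, m, np.zeros(len(m)))

    rois = [roi([0, 1]), roi([1, 2]), roi([5])]  # vertex 1 covered twice
    assert overlap_rate(rois, mesh) == pytest.approx(2 / 3)


def test_overlap_rate_needs_two_subjects(small_mesh):
    with pytest.raises(ArgumentError):
        overlap_rate([geodesic_sphere(small_mesh, 0, 6.0)], small_mesh)
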