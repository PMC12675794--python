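"""Mesh container, I/O round trips, axis and generalized-radius tests."""

import numpy as np
import pytest

import osteofract as of
from osteofract.errors import DegeneracyError, EmptyBandError, FormatError
from osteofract.mesh_core import (
    Axis,
    CorticalBoneModel,
    TriangleMesh,
    compute_long_axis,
    generalized_radius,
    read_mesh,
    validate_mesh,
    write_mesh,
)

# a unit cube as an indexed triangle mesh (12 faces, volume 1)
_CUBE_V = np.array([
    [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
    [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
], dtype=float)
_CUBE_F = np.array([
    [0, 2, 1], [0, 3, 2], [4, 5, 6], [4, 6, 7],
    [0, 1, 5], [0, 5, 4], [1, 2, 6], [1, 6, 5],
    [2, 3, 7], [2, 7, 6], [3, 0, 4], [3, 4, 7],
])


@pytest.fixture
def cube():
    return TriangleMesh(_CUBE_V.copy(), _CUBE_F.copy())


def test_cube_volume_and_watertightness(cube):
    assert cube.signed_volume() == pytest.approx(1.0, abs=1e-12)
    rep = validate_mesh(cube)
    assert rep.watertight and rep.orientable
    assert rep.n_degenerate == 0 and rep.n_nonmanifold_edges == 0


def test_mesh_invariants_enforced():
    with pytest.raises(ValueError):
        TriangleMesh(_CUBE_V, np.array([[0, 1, 99]]))
    with pytest.raises(ValueError):
        TriangleMesh(_CUBE_V, np.array([[0, 1, 1]]))


@pytest.mark.parametrize("fmt,binary", [
    ("stl", False), ("stl", True),
    ("obj", False),
    ("ply", False), ("ply", True),
])
def test_io_round_trip(cube, tmp_path, fmt, binary):
    """write_mesh -> read_mesh preserves geometry and topology."""
    path = tmp_path / f"cube.{fmt}"
    write_mesh(cube, path, binary=binary)
    back = read_mesh(path)
    assert back.n_faces == 12
    # STL re-indexes by first appearance; compare the per-face corner
    # coordinates, which every format must preserve
    tol = 1e-6 if (fmt == "stl" and binary) else 0.0
    orig = np.sort(cube.vertices[cube.faces].reshape(-1, 9), axis=0)
    got = np.sort(back.vertices[back.faces].reshape(-1, 9), axis=0)
    assert np.allclose(orig, got, atol=tol)
    assert back.signed_volume() == pytest.approx(1.0, abs=1e-5)


def test_ply_round_trip_exact_with_labels(cube, tmp_path):
    cube.face_labels = np.arange(12) % 3
    for binary in (False, True):
        path = tmp_path / f"c{int(binary)}.ply"
        write_mesh(cube, path, binary=binary)
        back = read_mesh(path)
        assert np.array_equal(back.vertices, cube.vertices)
        assert np.array_equal(back.faces, cube.faces)
        assert np.array_equal(back.face_labels, cube.face_labels)


def test_ascii_stl_unit_cube_from_text(tmp_path):
    """A hand-written ASCII STL parses to the documented face count."""
    mesh = TriangleMesh(_CUBE_V, _CUBE_F)
    path = tmp_path / "cube.stl"
    write_mesh(mesh, path)
    assert path.read_text().startswith("solid")
    back = read_mesh(path)
    assert back.n_faces == 12
    assert back.signed_volume() == pytest.approx(1.0, abs=1e-12)


def test_degenerate_facet_flagged(tmp_path):
    v = np.concatenate([_CUBE_V, [[2.0, 0.0, 0.0], [3.0, 0.0, 0.0], [4.0, 0.0, 0.0]]])
    f = np.concatenate([_CUBE_F, [[8, 9, 10]]])
    mesh = TriangleMesh(v, f)
    rep = validate_mesh(mesh)
    assert rep.n_degenerate == 1


def test_read_errors(tmp_path):
    with pytest.raises(FormatError):
        read_mesh(tmp_path / "missing.stl")
    bad = tmp_path / "bad.obj"
    bad.write_text("not a mesh at all")
    with pytest.raises((FormatError, of.errors.EmptyInputError)):
        read_mesh(bad)


def test_watertightness_detects_missing_face(tube_model):
    mesh = tube_model.mesh
    holed = TriangleMesh(mesh.vertices, mesh.faces[1:],
                         mesh.face_labels[1:])
    rep = validate_mesh(holed)
    assert not rep.watertight
    assert rep.n_boundary_edges == 3


def test_nonmanifold_edge_counted():
    """Two tetrahedra sharing one edge: brute-force degree oracle."""
    v = np.array([
        [0, 0, 0], [1, 0, 0],             # shared edge
        [0.5, 1, 0], [0.5, 0.5, 1],       # tet A
        [0.5, -1, 0], [0.5, -0.5, 1],     # tet B
    ], dtype=float)
    f = np.array([
        [0, 1, 2], [0, 3, 1], [0, 2, 3], [1, 3, 2],
        [0, 4, 1], [0, 1, 5], [0, 5, 4], [1, 4, 5],
    ])
    mesh = TriangleMesh(v, f)
    # oracle: count undirected edges bordering != 2 faces
    from collections import Counter
    deg = Counter()
    for face in f:
        for a, b in ((face[0], face[1]), (face[1], face[2]), (face[2], face[0])):
            deg[tuple(sorted((a, b)))] += 1
    expected = sum(1 for c in deg.values() if c > 2)
    rep = validate_mesh(mesh)
    assert expected >= 1
    assert rep.n_nonmanifold_edges == expected


def test_long_axis_of_tube(tube_model):
    axis = compute_long_axis(tube_model.mesh)
    assert np.allclose(axis.direction, [0, 0, 1], atol=1e-6)


def test_long_axis_rotation_equivariance(tube_model):
    theta = np.radians(30)
    R = np.array([
        [1, 0, 0],
        [0, np.cos(theta), -np.sin(theta)],
        [0, np.sin(theta), np.cos(theta)],
    ])
    rotated = TriangleMesh(tube_model.mesh.vertices @ R.T, tube_model.mesh.faces)
    axis = compute_long_axis(rotated)
    expected = R @ np.array([0, 0, 1.0])
    assert np.allclose(axis.direction, expected, atol=1e-6)


def test_long_axis_translation_and_scale_invariance(tube_model):
    mesh = tube_model.mesh
    moved = TriangleMesh(mesh.vertices * 2.5 + np.array([10, -4, 7.0]), mesh.faces)
    a0 = compute_long_axis(mesh)
    a1 = compute_long_axis(moved)
    assert np.allclose(a0.direction, a1.direction, atol=1e-9)


def test_long_axis_isotropic_error():
    rng = np.random.default_rng(0)
    pts = rng.normal(size=(300, 3))
    pts /= np.linalg.norm(pts, axis=1)[:, None]  # points on a sphere
    from scipy.spatial import ConvexHull
    hull = ConvexHull(pts)
    mesh = TriangleMesh(pts, hull.simplices)
    with pytest.raises(DegeneracyError):
        compute_long_axis(mesh)


def test_signed_volume_rigid_invariance(tube_model):
    mesh = tube_model.mesh
    v0 = mesh.signed_volume()
    theta = 0.77
    R = np.array([
        [np.cos(theta), -np.sin(theta), 0],
        [np.sin(theta), np.cos(theta), 0],
        [0, 0, 1],
    ])
    moved = TriangleMesh(mesh.vertices @ R.T + np.array([3.0, -8.0, 12.0]),
                         mesh.faces)
    assert abs(moved.signed_volume() - v0) / v0 < 1e-9


def test_generalized_radius_tube(tube_model):
    r = generalized_radius(tube_model, 0.0, 5.0)
    assert r == pytest.approx(10.0, abs=1e-9)


def test_generalized_radius_frustum():
    """Linear frustum 5 -> 15 mm: band mean at mid-height vs brute force."""
    spec = of.BoneSpec(outer_radius_profile=[(0.0, 5.0), (100.0, 15.0)],
                       cortical_thickness_profile=2.0)
    model = of.generate_long_bone(spec)
    got = generalized_radius(model, 0.0, 5.0)
    # brute-force oracle over the model's own outer vertices
    mask = model.outer_vertex_mask()
    pts = model.mesh.vertices[mask]
    h = model.axis.axial_coord(pts)
    sel = (h >= -5.0) & (h <= 5.0)
    expected = model.axis.radial_distance(pts[sel]).mean()
    assert got == pytest.approx(expected, rel=1e-12)
    assert got == pytest.approx(10.0, rel=0.02)


def test_generalized_radius_band_outside(tube_model):
    with pytest.raises(EmptyBandError):
        generalized_radius(tube_model, 500.0, 2.0)
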