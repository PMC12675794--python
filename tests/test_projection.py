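"""Cylinder fitting, band unwrapping, placement and cut-point tests."""

import numpy as np
import pytest

import osteofract as of
from osteofract.errors import (
    BandError,
    EmptyBandError,
    OpenLineError,
    ScaleInfeasibleError,
)
from osteofract.mesh_core import LABEL_INNER, LABEL_OUTER, TriangleMesh
from osteofract.pattern import Polyline
from osteofract.projection import (
    PlacedLine,
    UnwrappedLayer,
    compute_cut_points,
    fit_projection_cylinder,
    place_pattern,
    unwrap_band,
)


@pytest.fixture(scope="module")
def cyl(tube_model):
    return fit_projection_cylinder(tube_model, 0.7, 20.0)


def test_cylinder_radius_and_axis(tube_model, cyl):
    assert cyl.radius == pytest.approx(10.0, abs=1e-6)
    assert np.allclose(np.abs(cyl.axis.direction), [0, 0, 1], atol=1e-6)


def test_cylinder_radius_on_frustum():
    spec = of.BoneSpec(outer_radius_profile=[(0, 5.0), (100, 15.0)],
                       cortical_thickness_profile=2.0)
    model = of.generate_long_bone(spec)
    c = fit_projection_cylinder(model, 0.0, 5.0)
    # brute-force band mean of outer vertices
    mask = model.outer_vertex_mask()
    pts = model.mesh.vertices[mask]
    h = c.axis.axial_coord(pts)
    sel = (h >= -5) & (h <= 5)
    assert c.radius == pytest.approx(
        c.axis.radial_distance(pts[sel]).mean(), rel=1e-9
    )


def test_cylinder_at_cap_rejected(tube_model):
    with pytest.raises(EmptyBandError):
        fit_projection_cylinder(tube_model, 49.0, 5.0)


def test_unwrap_coordinates_closed_form(tube_model, cyl):
    """A vertex at angle pi/2 on a radius-10 cylinder unwraps to x = 5 pi."""
    uw = unwrap_band(tube_model, cyl, LABEL_OUTER)
    v = tube_model.mesh.vertices
    ids = np.unique(uw.faces)
    target = ids[np.argmin(np.abs(v[ids, 0]) + np.abs(v[ids, 1] - 10.0))]
    assert v[target, 0] == pytest.approx(0.0, abs=1e-9)
    assert uw.vert_xy[target, 0] == pytest.approx(5 * np.pi, abs=1e-9)


def test_unwrap_rewrap_identity(tube_model, cyl):
    uw = unwrap_band(tube_model, cyl, LABEL_OUTER)
    ids = np.unique(uw.faces)
    for vid in ids[:: max(1, len(ids) // 64)]:
        x, y = uw.vert_xy[vid]
        back = uw.wrap_point(x, y)
        assert np.linalg.norm(back - tube_model.mesh.vertices[vid]) < 1e-9


def test_unwrapped_area_matches_band_area(tube_model, cyl):
    """Seam-crossing faces appear once; total 2D area equals the 3D
    lateral band area within cylindrical discretization error."""
    uw = unwrap_band(tube_model, cyl, LABEL_OUTER)
    tris = np.stack([uw.face_xy(i) for i in range(len(uw.faces))])
    e1 = tris[:, 1] - tris[:, 0]
    e2 = tris[:, 2] - tris[:, 0]
    area2d = 0.5 * np.abs(e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]).sum()
    area3d = tube_model.mesh.face_areas()[uw.face_ids].sum()
    assert area2d == pytest.approx(area3d, rel=2e-3)
    # no 2D face may span more than half the circumference
    spans = tris[:, :, 0].max(axis=1) - tris[:, :, 0].min(axis=1)
    assert spans.max() < cyl.circumference / 4


def test_place_pattern_scales_u_by_circumference(cyl):
    pat = of.generate_parametric_pattern("transverse", {"v0": 0.0})
    placed = place_pattern(pat, cyl, 0.7)
    line = placed.outer[0]
    # u = 0.5 maps to x = pi R = 10 pi
    uu = pat.lines_outer[0].unwrapped_u()
    k = int(np.argmin(np.abs(uu - (uu[0] + 0.5))))
    assert line.points_xy[k, 0] - line.points_xy[0, 0] == pytest.approx(
        0.5 * cyl.circumference, rel=1e-9
    )


def test_aspect_limit_feasible_and_infeasible(cyl):
    """Radius 9.23 source onto radius 10 bone: ratio ok; onto a radius-2
    bone the distortion exceeds 2 and placement must fail."""
    pat = of.generate_parametric_pattern("transverse", {"v0": 0.0})
    pat.meta["source_circumference"] = 2 * np.pi * 9.23
    placed = place_pattern(pat, cyl, 0.7, aspect_limit=2.0)  # 10/9.23 = 1.08
    assert placed.outer

    thin = of.generate_long_bone(of.BoneSpec(
        outer_radius_profile=2.0, cortical_thickness_profile=0.6))
    thin_cyl = fit_projection_cylinder(thin, 0.7, 20.0)
    ratio = 9.23 / thin_cyl.radius
    assert ratio > 2.0
    with pytest.raises(ScaleInfeasibleError):
        place_pattern(pat, thin_cyl, 0.7, aspect_limit=2.0)


def test_pattern_exceeding_band_rejected(tube_model):
    small = fit_projection_cylinder(tube_model, 0.7, 4.0)
    pat = of.generate_parametric_pattern("oblique", {"angle_deg": 30.0})
    with pytest.raises(BandError):
        place_pattern(pat, small, 0.7)


# ---------------------------------------------------------------------------
# planar cut-point fixtures (period=None exercises the core intersection
# machinery against brute-force oracles)
# ---------------------------------------------------------------------------

def _unit_square_layer():
    v = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
    f = np.array([[0, 1, 2], [0, 2, 3]])
    return UnwrappedLayer(
        vertices3d=v, faces=f, face_ids=np.arange(2),
        vert_xy=v[:, :2].copy(), layer=LABEL_OUTER, period=None,
    )


def _line(points, closed=False):
    return PlacedLine(points_xy=np.asarray(points, dtype=float),
                      closed=closed, line_id=0, winding=0)


def test_horizontal_segment_cuts_three_edges():
    """y=0.5 from x=-0.1 to 1.1: left edge, diagonal, right edge.

    Oracle: brute-force segment-segment intersection over all 5 edges.
    """
    uw = _unit_square_layer()
    chains = compute_cut_points(uw, [_line([[-0.1, 0.5], [1.1, 0.5]])])
    pts = chains[0].points
    assert len(pts) == 3
    xs = sorted(p.xy[0] for p in pts)
    assert np.allclose(xs, [0.0, 0.5, 1.0], atol=1e-12)
    assert len(chains[0].pair_faces) == 2


def test_segment_outside_yields_nothing():
    uw = _unit_square_layer()
    chains = compute_cut_points(uw, [_line([[-0.5, 2.0], [1.5, 2.0]])])
    assert chains[0].points == []


def test_vertex_hit_deduplicated_with_snap_tolerance():
    """A segment through the shared corner (1,1) gives ONE on-vertex point."""
    uw = _unit_square_layer()
    chains = compute_cut_points(
        uw, [_line([[0.5, 1.5], [1.5, 0.5]])], snap_tolerance=0.1
    )
    on_vertex = [p for p in chains[0].points if p.on_vertex]
    assert len(on_vertex) == 1
    assert on_vertex[0].vertex() == 2


def test_open_line_inside_band_rejected():
    uw = _unit_square_layer()
    with pytest.raises(OpenLineError):
        compute_cut_points(uw, [_line([[-0.1, 0.4], [0.6, 0.4]])])


# ---------------------------------------------------------------------------
# cylinder-band properties
# ---------------------------------------------------------------------------

def test_transverse_cut_points_lie_in_plane(tube_model, cyl):
    pat = of.generate_parametric_pattern("transverse", {"v0": 0.0})
    placed = place_pattern(pat, cyl, 0.7)
    uw = unwrap_band(tube_model, cyl, LABEL_OUTER)
    (chain,) = compute_cut_points(uw, placed.outer)
    z = np.array([p.position3d[2] for p in chain.points])
    assert np.allclose(z, 50.7, atol=1e-9)
    # one point per undirected edge
    keys = [(p.v0, p.v1) for p in chain.points]
    assert len(keys) == len(set(keys))


def test_cut_points_lie_on_mesh_chords(tube_model, cyl):
    pat = of.generate_parametric_pattern("oblique", {"angle_deg": 30.0}, seed=1)
    placed = place_pattern(pat, fit_projection_cylinder(tube_model, 0.7, 40.0), 0.7)
    uw = unwrap_band(tube_model, fit_projection_cylinder(tube_model, 0.7, 40.0),
                     LABEL_INNER)
    (chain,) = compute_cut_points(uw, placed.inner)
    v = tube_model.mesh.vertices
    for p in chain.points:
        chord = v[p.v0] + p.t * (v[p.v1] - v[p.v0])
        assert np.linalg.norm(chord - p.position3d) < 1e-9


def test_crossing_parity_is_even_for_closed_lines(tube_model):
    """A closed line crosses any layer's edge set an even number of times
    per region boundary; total crossing count is even."""
    cylw = fit_projection_cylinder(tube_model, 0.7, 40.0)
    uw = unwrap_band(tube_model, cylw, LABEL_OUTER)
    for seed in range(4):
        pat = of.generate_parametric_pattern(
            "transverse", {"waviness": 2.0, "n_waves": 3}, seed=seed)
        placed = place_pattern(pat, cylw, 0.7)
        (chain,) = compute_cut_points(uw, placed.outer)
        assert len(chain.points) % 2 == 0
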