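"""Fracture-surface triangulation, perturbation and fragment assembly."""

import numpy as np
import pytest

import osteofract as of
from osteofract.errors import ContourError, WeldError
from osteofract.fracture_surface import (
    FractureContours,
    PerturbationConfig,
    _zipper,
    assemble_fragment,
    chain_fracture_edges,
    perturb_surface,
    triangulate_fracture_zone,
)
from osteofract.mesh_core import LABEL_FRACTURE

from conftest import fracture_tube


def _concentric_contours(r_out=10.0, r_in=7.0, n=64, z=0.0):
    th = 2 * np.pi * np.arange(n) / n
    outer = np.stack([r_out * np.cos(th), r_out * np.sin(th),
                      np.full(n, z)], axis=1)
    inner = np.stack([r_in * np.cos(th), r_in * np.sin(th),
                      np.full(n, z)], axis=1)
    vertices = np.concatenate([outer, inner])
    return FractureContours(outer=list(range(n)),
                            inner=list(range(n, 2 * n))), vertices


def test_cdt_annulus_area_and_hole():
    """Concentric circles 10/7 with 64 points: triangulated area matches
    the analytic annulus within 1%, and no triangle enters the canal."""
    contours, v = _concentric_contours()
    faces = triangulate_fracture_zone(contours, v)
    a, b, c = v[faces[:, 0]], v[faces[:, 1]], v[faces[:, 2]]
    areas = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)
    assert areas.sum() == pytest.approx(np.pi * (100 - 49), rel=0.01)
    centroids = (a + b + c) / 3
    inside_hole = np.hypot(centroids[:, 0], centroids[:, 1]) < 7.0 - 1e-9
    # polygon test: hole vertices form a convex circle, radial test suffices
    assert inside_hole.sum() == 0


def test_cdt_boundary_equals_input_loops():
    contours, v = _concentric_contours(n=48)
    faces = triangulate_fracture_zone(contours, v)
    from collections import Counter
    und = Counter()
    for f in faces:
        for e in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            und[tuple(sorted(e))] += 1
    boundary = {e for e, cnt in und.items() if cnt == 1}
    loops = set()
    for loop in (contours.outer, contours.inner):
        for a, b in zip(loop, loop[1:] + loop[:1]):
            loops.add(tuple(sorted((a, b))))
    assert boundary == loops


def test_zipper_strip_between_offset_loops():
    """Coincident-projection loops (wedge-wall-like) get a ribbon whose
    boundary is exactly the two loops."""
    n = 24
    th = 2 * np.pi * np.arange(n) / n
    outer3 = np.stack([10 * np.cos(th), 10 * np.sin(th), np.zeros(n)], axis=1)
    inner3 = np.stack([7 * np.cos(th), 7 * np.sin(th), np.full(n, 0.3)], axis=1)
    v = np.concatenate([outer3, inner3])
    faces = np.asarray(_zipper(list(range(n)), list(range(n, 2 * n)), v))
    assert len(faces) == 2 * n
    from collections import Counter
    und = Counter()
    for f in faces:
        for e in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            und[tuple(sorted(e))] += 1
    assert sum(1 for cnt in und.values() if cnt == 1) == 2 * n


def test_chain_fracture_edges_detects_open_loop():
    edges = {(0, 1), (1, 2), (2, 3)}  # open chain
    with pytest.raises(ContourError):
        chain_fracture_edges(edges)
    loop = chain_fracture_edges({(0, 1), (1, 2), (2, 0)})
    assert sorted(loop) == [0, 1, 2]


def test_perturb_surface_centroid_fan():
    """Method B: triangle count exactly triples, boundary untouched,
    displacements bounded by tau, reruns bit-identical."""
    contours, v = _concentric_contours(n=40)
    surf = triangulate_fracture_zone(contours, v)
    cfg = PerturbationConfig(method="post_triangulation", tau=0.5, seed=21)
    v1, s1 = perturb_surface(v, surf, cfg, line_id=0)
    v2, s2 = perturb_surface(v, surf, cfg, line_id=0)
    assert len(s1) == 3 * len(surf)
    assert np.array_equal(v1, v2) and np.array_equal(s1, s2)
    # boundary vertices (the original loops) unchanged
    assert np.array_equal(v1[: len(v)], v)
    # every centroid displaced by at most tau
    parents = v[surf].mean(axis=1)
    disp = np.linalg.norm(v1[len(v):] - parents, axis=1)
    assert disp.max() <= 0.5 + 1e-12
    assert disp.max() > 0  # it actually perturbs


def test_perturbation_tau_zero_identity():
    contours, v = _concentric_contours(n=32)
    surf = triangulate_fracture_zone(contours, v)
    cfg = PerturbationConfig(method="post_triangulation", tau=0.0, seed=3)
    v1, s1 = perturb_surface(v, surf, cfg)
    parents = v[surf].mean(axis=1)
    assert np.allclose(v1[len(v):], parents)


def test_method_a_bounded_and_deterministic():
    _, _, _, emb1, frags1 = fracture_tube(
        "transverse", "subdivision", perturb="pre_triangulation", tau=0.4,
        seed=9)
    _, _, _, emb2, frags2 = fracture_tube(
        "transverse", "subdivision", perturb="pre_triangulation", tau=0.4,
        seed=9)
    assert np.array_equal(emb1.mesh.vertices, emb2.mesh.vertices)
    _, _, _, emb0, _ = fracture_tube("transverse", "subdivision",
                                     perturb="none", seed=9)
    moved = np.linalg.norm(emb1.mesh.vertices - emb0.mesh.vertices, axis=1)
    assert moved.max() <= 0.4 + 1e-12
    assert moved.max() > 0


@pytest.mark.parametrize("ftype,expected", [
    ("transverse", 2), ("oblique", 2), ("wedge", 3),
])
def test_fragments_watertight_and_volume_conserved(ftype, expected):
    _, _, _, emb, frags = fracture_tube(ftype, "hybrid",
                                        perturb="post_triangulation",
                                        tau=0.3, seed=5)
    assert len(frags) == expected
    total = sum(f.volume for f in frags)
    shell = emb.mesh.signed_volume()
    assert abs(total - shell) / shell < 1e-9
    for f in frags:
        assert f.volume > 0
        rep = of.validate_mesh(f.mesh)
        assert rep.watertight and rep.orientable


def test_mating_surfaces_are_shared():
    """Both fragments of a transverse fracture carry identical fracture
    surfaces with opposite orientation."""
    _, _, _, _, frags = fracture_tube("transverse", "subdivision", seed=5)
    surfs = []
    for f in frags:
        mask = f.mesh.face_labels == LABEL_FRACTURE
        surfs.append({frozenset(t) for t in f.mesh.faces[mask].tolist()})
    assert surfs[0] == surfs[1]


def test_assemble_rejects_boundary_mismatch():
    _, _, _, emb, frags = fracture_tube("transverse", "subdivision", seed=5)
    f0 = frags[0]
    shell_mask = f0.mesh.face_labels != LABEL_FRACTURE
    surf = f0.mesh.faces[~shell_mask]
    with pytest.raises(WeldError):
        assemble_fragment(
            f0.mesh.vertices,
            f0.mesh.faces[shell_mask],
            f0.mesh.face_labels[shell_mask],
            [surf[:-2]],  # two triangles missing: boundaries cannot match
        )


def test_perturbation_config_validation():
    with pytest.raises(of.errors.ConfigError):
        PerturbationConfig(method="jitter")
    with pytest.raises(of.errors.ConfigError):
        PerturbationConfig(tau=1.5)
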