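"""Shared fixtures: synthetic bones, fracture pipeline helper."""

import numpy as np
import pytest

import osteofract as of
from osteofract.mesh_core import LABEL_INNER, LABEL_OUTER
from osteofract import projection as pj
from osteofract.fragmentation import CutStrategy, embed_cuts
from osteofract.fracture_surface import PerturbationConfig, split_into_fragments


@pytest.fixture(scope="session")
def tube_model():
    """Default synthetic bone: L=100, R=10, wall 3 mm, 64x50 grid."""
    return of.generate_long_bone(of.BoneSpec())


@pytest.fixture(scope="session")
def fine_tube_model():
    return of.generate_long_bone(of.BoneSpec(n_theta=128, n_z=50))


def fracture_tube(
    fracture_type="transverse",
    strategy="subdivision",
    threshold=0.10,
    perturb="none",
    tau=0.3,
    seed=5,
    n_theta=64,
    pattern_params=None,
    inner_offset=0.5,
    inner_noise=0.2,
    fracture_height=0.7,
    band=40.0,
):
    """Run the full fracture pipeline on a synthetic tube.

    Returns (model, cylinder, placed pattern, embedded mesh, fragments).
    """
    model = of.generate_long_bone(of.BoneSpec(n_theta=n_theta))
    cyl = pj.fit_projection_cylinder(model, fracture_height, band)
    pattern = of.generate_parametric_pattern(
        fracture_type, pattern_params, inner_offset=inner_offset,
        inner_noise=inner_noise, seed=seed,
    )
    placed = pj.place_pattern(pattern, cyl, fracture_height)
    chains = (
        pj.compute_cut_points(pj.unwrap_band(model, cyl, LABEL_OUTER), placed.outer)
        + pj.compute_cut_points(pj.unwrap_band(model, cyl, LABEL_INNER), placed.inner)
    )
    embedded = embed_cuts(model.mesh, chains, CutStrategy(strategy, threshold))
    fragments = split_into_fragments(
        embedded, cyl, placed,
        PerturbationConfig(method=perturb, tau=tau, seed=seed),
    )
    return model, cyl, placed, embedded, fragments


def wrap_hausdorff(a, b, period, step=0.3):
    """Symmetric Hausdorff distance between two polylines on a cylinder
    band, brute-force over densified samples with wrap in x."""
    from scipy.spatial import cKDTree

    def densify(pts):
        out = []
        for p, q in zip(pts[:-1], pts[1:]):
            n = max(int(np.linalg.norm(q - p) / step), 1)
            out.append(p + (q - p) * np.linspace(0, 1, n, endpoint=False)[:, None])
        out.append(pts[-1:])
        return np.concatenate(out)

    A, B = densify(np.asarray(a)), densify(np.asarray(b))

    def one_sided(P, Q):
        best = np.full(len(P), np.inf)
        for k in (-1, 0, 1):
            d, _ = cKDTree(Q + np.array([k * period, 0.0])).query(P)
            best = np.minimum(best, d)
        return best.max()

    return max(one_sided(A, B), one_sided(B, A))


def line_to_xy(polyline, circumference):
    """Polyline (u, v) -> continuous (x, y) mm coordinates."""
    uu = polyline.unwrapped_u()
    return np.stack([uu * circumference, polyline.points[:, 1]], axis=1)
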