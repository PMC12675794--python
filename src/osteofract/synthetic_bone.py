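"""Deterministic generator of two-layer cortical long-bone shells.

Clinical fracture-simulation pipelines start from CT-segmented femora,
fibulae or humeri.  This module replaces those inputs with a parametric
stand-in: two concentric tubular surfaces (outer cortical wall and the
wall of the medullary canal) closed by annular caps, with optional
piecewise-linear radius/thickness profiles, a bow (curvature of the
diaphysis) and smooth seeded surface noise emulating anatomical
undulation.  Every output is bit-reproducible for a fixed spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

from .errors import ConfigError
from .mesh_core import (
    Axis,
    CorticalBoneModel,
    LABEL_INNER,
    LABEL_OUTER,
    TriangleMesh,
)

Profile = Union[float, Sequence[tuple[float, float]]]


def _eval_profile(profile: Profile, z: np.ndarray, length: float) -> np.ndarray:
    """Evaluate a constant or piecewise-linear (z, value) profile at z."""
    if np.isscalar(profile):
        return np.full_like(z, float(profile))
    pts = np.asarray(profile, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ConfigError("profile must be a scalar or a list of (z, value) pairs")
    order = np.argsort(pts[:, 0])
    return np.interp(z, pts[order, 0], pts[order, 1])


@dataclass
class BoneSpec:
    """Geometry of a synthetic two-layer long bone.

    Parameters
    ----------
    length : float
        Axial length (mm); the bone runs from z=0 to z=length along +Z.
    outer_radius_profile : float or list of (z, r) pairs
        Outer cortical radius as a function of axial position (mm).
    cortical_thickness_profile : float or list of (z, t) pairs
        Cortical wall thickness (mm); inner radius = outer - thickness.
    n_theta, n_z : int
        Circumferential and axial segment counts.
    curvature : float
        Bow amplitude (mm): the tube centreline is offset by
        ``curvature * sin(pi * z / length)`` along +X.
    seed : int
        Reserved for seeded features of derived fixtures.
    """

    length: float = 100.0
    outer_radius_profile: Profile = 10.0
    cortical_thickness_profile: Profile = 3.0
    n_theta: int = 64
    n_z: int = 50
    curvature: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.length <= 0:
            raise ConfigError("length must be > 0")
        if self.n_theta < 8:
            raise ConfigError("n_theta must be >= 8")
        if self.n_z < 4:
            raise ConfigError("n_z must be >= 4")
        z = np.linspace(0.0, self.length, 200)
        r = _eval_profile(self.outer_radius_profile, z, self.length)
        t = _eval_profile(self.cortical_thickness_profile, z, self.length)
        if (t <= 0).any():
            raise ConfigError("cortical thickness must be > 0 everywhere")
        if (r - t <= 0).any():
            raise ConfigError(
                "inner radius (outer - thickness) must be > 0 everywhere"
            )


def generate_long_bone(spec: BoneSpec) -> CorticalBoneModel:
    """Build a watertight two-layer shell from a :class:`BoneSpec`.

    The outer tube, inner tube and two annular end caps share ring
    vertices, so the result is a single closed, consistently oriented
    surface whose signed volume equals the cortical-shell volume.  Faces
    are labelled outer/inner; caps carry the outer label (they stand in
    for the machined bone ends, which diaphyseal fractures never touch).
    """
    spec.validate()
    nt, nz = spec.n_theta, spec.n_z
    z = np.linspace(0.0, spec.length, nz + 1)
    r_out = _eval_profile(spec.outer_radius_profile, z, spec.length)
    r_in = r_out - _eval_profile(spec.cortical_thickness_profile, z, spec.length)
    theta = 2.0 * np.pi * np.arange(nt) / nt
    bow = spec.curvature * np.sin(np.pi * z / spec.length)

    def rings(radii: np.ndarray) -> np.ndarray:
        # (nz+1, nt, 3) vertex grid
        x = radii[:, None] * np.cos(theta)[None, :] + bow[:, None]
        y = radii[:, None] * np.sin(theta)[None, :]
        zz = np.broadcast_to(z[:, None], x.shape)
        return np.stack([x, y, zz], axis=-1)

    outer = rings(r_out).reshape(-1, 3)
    inner = rings(r_in).reshape(-1, 3)
    vertices = np.concatenate([outer, inner])
    n_ring = nt

    def vid(layer: int, k: int, i: int) -> int:
        return layer * (nz + 1) * n_ring + k * n_ring + (i % n_ring)

    faces = []
    labels = []

    # Outer wall: outward normals (CCW seen from outside the tube).
    for k in range(nz):
        for i in range(nt):
            a = vid(0, k, i)
            b = vid(0, k, i + 1)
            c = vid(0, k + 1, i + 1)
            d = vid(0, k + 1, i)
            faces += [[a, b, c], [a, c, d]]
            labels += [LABEL_OUTER, LABEL_OUTER]
    # Inner wall: the solid lies outside this tube, so outward normals of
    # the shell point toward the axis (reversed winding).
    for k in range(nz):
        for i in range(nt):
            a = vid(1, k, i)
            b = vid(1, k, i + 1)
            c = vid(1, k + 1, i + 1)
            d = vid(1, k + 1, i)
            faces += [[a, c, b], [a, d, c]]
            labels += [LABEL_INNER, LABEL_INNER]
    # Bottom cap (z=0, normal -Z) and top cap (z=L, normal +Z).
    for i in range(nt):
        o0, o1 = vid(0, 0, i), vid(0, 0, i + 1)
        i0, i1 = vid(1, 0, i), vid(1, 0, i + 1)
        faces += [[o0, i0, i1], [o0, i1, o1]]
        labels += [LABEL_OUTER, LABEL_OUTER]
    for i in range(nt):
        o0, o1 = vid(0, nz, i), vid(0, nz, i + 1)
        i0, i1 = vid(1, nz, i), vid(1, nz, i + 1)
        faces += [[o0, i1, i0], [o0, o1, i1]]
        labels += [LABEL_OUTER, LABEL_OUTER]

    mesh = TriangleMesh(
        vertices,
        np.asarray(faces, dtype=np.int64),
        np.asarray(labels, dtype=np.int64),
    )
    axis = Axis(origin=np.array([bow.mean(), 0.0, spec.length / 2.0]),
                direction=np.array([0.0, 0.0, 1.0]))
    return CorticalBoneModel(mesh=mesh, axis=axis, length=spec.length)


def perturb_surface_noise(
    model: CorticalBoneModel, amplitude: float, seed: int
) -> CorticalBoneModel:
    """Radially displace both layers by smooth seeded noise.

    The displacement field is a low-order sinusoidal mixture in (theta, z)
    with seeded random phases, normalised so the maximum |displacement| is
    at most ``amplitude`` (mm).  Smooth noise mimics anatomical undulation
    without creating degenerate triangles; white noise would.  The inner
    layer is clamped so the local wall thickness never drops below 10% of
    its nominal value, so layers cannot cross.
    """
    if amplitude < 0:
        raise ConfigError("amplitude must be >= 0")
    if amplitude == 0:
        return CorticalBoneModel(model.mesh.copy(), model.axis, model.length)
    rng = np.random.default_rng(seed)
    modes = [(m, k, rng.uniform(0, 2 * np.pi), rng.uniform(0, 2 * np.pi),
              rng.uniform(0.5, 1.0))
             for m in (2, 3, 5) for k in (1, 2, 3)]

    mesh = model.mesh.copy()
    axis = model.axis
    p = mesh.vertices - axis.origin
    h = p @ axis.direction
    radial = p - h[:, None] * axis.direction
    r = np.linalg.norm(radial, axis=1)
    # theta measured in a fixed frame perpendicular to the axis
    e1, e2 = _axis_frame(axis.direction)
    theta = np.arctan2(p @ e2, p @ e1)
    span = h.max() - h.min()

    field_ = np.zeros_like(r)
    for m, k, ph1, ph2, w in modes:
        field_ += w * np.sin(m * theta + ph1) * np.sin(
            k * np.pi * (h - h.min()) / span + ph2
        )
    field_ *= amplitude / np.abs(field_).max()

    # identify layer per vertex from face labels (outer wins at caps)
    outer_mask = model.outer_vertex_mask()
    inner_mask = ~outer_mask
    new_r = r + field_
    # clamp inner layer: thickness >= 10% nominal, estimated per height
    if inner_mask.any() and outer_mask.any():
        nominal_t = np.median(r[outer_mask]) - np.median(r[inner_mask])
        order = np.argsort(h[outer_mask])
        ho, ro = h[outer_mask][order], new_r[outer_mask][order]
        local_outer = np.interp(h[inner_mask], ho, ro)
        cap = local_outer - 0.1 * nominal_t
        new_r[inner_mask] = np.minimum(new_r[inner_mask], cap)
    safe = r > 1e-12
    scale = np.ones_like(r)
    scale[safe] = new_r[safe] / r[safe]
    mesh.vertices = axis.origin + h[:, None] * axis.direction + radial * scale[:, None]
    return CorticalBoneModel(mesh=mesh, axis=axis, length=model.length)


def _axis_frame(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal frame (e1, e2) perpendicular to the axis."""
    d = np.asarray(direction, dtype=np.float64)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(d @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = helper - (helper @ d) * d
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return e1, e2
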