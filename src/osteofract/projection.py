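"""Cylindrical projection: enclosing cylinder, band unwrapping, pattern
placement (the transform T with P' = T(P)) and cut-point computation.

The target band of the bone is enclosed in a cylinder whose radius is the
generalized outer radius at the fracture height.  Both cortical layers are
unwrapped in the SAME cylinder frame — ``x = theta * R`` (mm along the
circumference), ``y`` = axial coordinate — so outer and inner patterns
share a coordinate frame while their cut points are computed
independently.  The unwrap is angular, not conformal: the cylinder
approximation of a diaphysis justifies radial projection.

Triangles crossing the seam ``theta = 0`` are handled by per-face/per-edge
local unwrapping (the seam-adjacent coordinates are shifted by one
circumference), so every 2D triangle is seam-free.  Intersection tests use
sign-of-orientation predicates with an exact rational fallback near zero,
which keeps seam-adjacent and near-vertex geometry robust.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional

import numpy as np

from .errors import (
    BandError,
    EmptyBandError,
    GeometryError,
    OpenLineError,
    ScaleInfeasibleError,
)
from .mesh_core import (
    Axis,
    CorticalBoneModel,
    LABEL_INNER,
    LABEL_OUTER,
    compute_long_axis,
    generalized_radius,
)
from .pattern import FracturePattern2D
from .synthetic_bone import _axis_frame


# ---------------------------------------------------------------------------
# Cylinder
# ---------------------------------------------------------------------------

@dataclass
class ProjectionCylinder:
    """Enclosing cylinder: axis, radius (mm) and axial band (mm)."""

    axis: Axis
    radius: float
    band: tuple[float, float]

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("cylinder radius must be > 0")
        if self.band[0] >= self.band[1]:
            raise ValueError("band must satisfy v_min < v_max")

    @property
    def circumference(self) -> float:
        return 2.0 * np.pi * self.radius


def fit_projection_cylinder(
    model: CorticalBoneModel, fracture_height: float, band_halfwidth: float
) -> ProjectionCylinder:
    """Fit the enclosing cylinder for a fracture at a given height.

    The axis is recomputed from the mesh (principal direction of the
    vertex cloud); the radius is the band-averaged generalized outer
    radius at the fracture height.  Heights are measured along the axis
    from the vertex centroid, so mid-shaft is height 0.

    Raises :class:`EmptyBandError` if the band reaches the bone ends
    (diaphyseal fractures must not touch the caps).
    """
    axis = compute_long_axis(model.mesh)
    h = axis.axial_coord(model.mesh.vertices)
    lo, hi = fracture_height - band_halfwidth, fracture_height + band_halfwidth
    margin = 0.02 * (h.max() - h.min())
    if lo <= h.min() + margin or hi >= h.max() - margin:
        raise EmptyBandError(
            f"band [{lo:g}, {hi:g}] mm reaches the bone ends "
            f"(axial extent [{h.min():g}, {h.max():g}] mm)"
        )
    radius = generalized_radius(
        CorticalBoneModel(model.mesh, axis, model.length),
        fracture_height, band_halfwidth,
    )
    return ProjectionCylinder(axis=axis, radius=radius, band=(lo, hi))


# ---------------------------------------------------------------------------
# Unwrapped band
# ---------------------------------------------------------------------------

@dataclass
class UnwrappedLayer:
    """One cortical layer's band faces with their 2D unwrapping.

    ``vert_xy`` holds ``(x, y)`` per model vertex (NaN outside the band);
    seam-crossing faces/edges are locally shifted by the period on the
    fly.  ``period`` is the cylinder circumference, or ``None`` for a
    planar (non-wrapping) 2D mesh, which the cut-point routine also
    accepts — handy for small planar fixtures.
    """

    vertices3d: np.ndarray
    faces: np.ndarray          # (m, 3) model-vertex ids, band faces only
    face_ids: np.ndarray       # (m,) indices into the model's face array
    vert_xy: np.ndarray        # (n_model_vertices, 2), NaN outside band
    layer: int = LABEL_OUTER
    period: Optional[float] = None
    cylinder: Optional[ProjectionCylinder] = None

    def face_xy(self, fi: int) -> np.ndarray:
        """(3, 2) locally unwrapped coordinates of band face ``fi``."""
        xy = self.vert_xy[self.faces[fi]].copy()
        if self.period is not None:
            x = xy[:, 0]
            if x.max() - x.min() > self.period / 2.0:
                x[x < self.period / 2.0] += self.period
        return xy

    def edge_xy(self, a: int, b: int) -> np.ndarray:
        """(2, 2) locally unwrapped coordinates of edge (a, b)."""
        xy = self.vert_xy[[a, b]].copy()
        if self.period is not None:
            x = xy[:, 0]
            if abs(x[0] - x[1]) > self.period / 2.0:
                x[np.argmin(x)] += self.period
        return xy

    def unique_edges(self) -> np.ndarray:
        e = np.concatenate([
            self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]
        ])
        return np.unique(np.sort(e, axis=1), axis=0)

    def edge_faces(self) -> dict:
        """Map sorted edge tuple -> list of band face indices (local)."""
        out: dict = {}
        for i, f in enumerate(self.faces):
            for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
                key = (min(a, b), max(a, b))
                out.setdefault(key, []).append(i)
        return out

    def wrap_point(self, x: float, y: float) -> np.ndarray:
        """Map 2D band coordinates back to the cylinder surface in 3D."""
        cyl = self.cylinder
        if cyl is None:
            return np.array([x, y, 0.0])
        e1, e2 = _axis_frame(cyl.axis.direction)
        th = x / cyl.radius
        return (cyl.axis.origin + cyl.radius * (np.cos(th) * e1 + np.sin(th) * e2)
                + y * cyl.axis.direction)


def unwrap_band(
    model: CorticalBoneModel, cylinder: ProjectionCylinder, layer: int
) -> UnwrappedLayer:
    """Unwrap one cortical layer's band faces to 2D.

    A band face is a face of the requested layer whose three vertices all
    have axial coordinates inside the (slightly padded) band.  Faces whose
    angular span exceeds pi/2 after seam adjustment indicate a mesh too
    coarse (or containing the axis) and raise :class:`GeometryError`.
    """
    mesh = model.mesh
    axis = cylinder.axis
    e1, e2 = _axis_frame(axis.direction)
    p = mesh.vertices - axis.origin
    h = p @ axis.direction
    theta = np.arctan2(p @ e2, p @ e1) % (2.0 * np.pi)
    x = theta * cylinder.radius
    vert_xy = np.stack([x, h], axis=1)

    lo, hi = cylinder.band
    pad = 0.02 * (hi - lo)
    in_band_v = (h >= lo - pad) & (h <= hi + pad)
    if mesh.face_labels is None:
        layer_mask = np.ones(mesh.n_faces, dtype=bool)
    else:
        layer_mask = mesh.face_labels == layer
    face_in = in_band_v[mesh.faces].all(axis=1) & layer_mask
    face_ids = np.where(face_in)[0]
    if len(face_ids) == 0:
        raise EmptyBandError(f"no layer-{layer} faces inside the band")
    faces = mesh.faces[face_ids]

    # seam sanity: no face may span more than pi/2 in angle
    th_f = theta[faces]
    span = th_f.max(axis=1) - th_f.min(axis=1)
    span = np.minimum(span, 2.0 * np.pi - span)
    if (span > np.pi / 2.0).any():
        raise GeometryError(
            "a band face spans more than pi/2 in angle; mesh too coarse "
            "for cylindrical unwrapping"
        )
    out = UnwrappedLayer(
        vertices3d=mesh.vertices, faces=faces, face_ids=face_ids,
        vert_xy=vert_xy, layer=layer, period=cylinder.circumference,
        cylinder=cylinder,
    )
    return out


# ---------------------------------------------------------------------------
# Pattern placement: P' = T(P)
# ---------------------------------------------------------------------------

@dataclass
class PlacedLine:
    """One fracture line in unwrapped mm coordinates (x continuous)."""

    points_xy: np.ndarray
    closed: bool
    line_id: int
    winding: int


@dataclass
class PlacedPattern:
    outer: list
    inner: list
    cylinder: ProjectionCylinder
    fracture_type: str


def place_pattern(
    pattern: FracturePattern2D,
    cylinder: ProjectionCylinder,
    fracture_height: float,
    aspect_limit: float = 2.0,
    longitudinal_scale: float = 1.0,
) -> PlacedPattern:
    """Scale and position a pattern in the unwrapped band (``P' = T(P)``).

    ``u`` is scaled by the circumference ``2 pi R``; ``v`` is optionally
    rescaled and translated so the pattern's longitudinal centroid sits at
    ``fracture_height``.  If the pattern records the circumference it was
    extracted at (``meta['source_circumference']``), the implied
    transverse/longitudinal distortion is checked against ``aspect_limit``
    — transplanting a fibula-scale pattern onto a much thinner bone fails
    here rather than producing a distorted fracture.
    """
    C = cylinder.circumference
    distortion = longitudinal_scale if longitudinal_scale >= 1 else 1.0 / longitudinal_scale
    src_c = pattern.meta.get("source_circumference")
    if src_c:
        f_t = C / float(src_c)
        f_l = longitudinal_scale
        distortion = max(f_t / f_l, f_l / f_t)
    if distortion > aspect_limit:
        raise ScaleInfeasibleError(
            f"pattern placement implies aspect distortion {distortion:.2f} "
            f"> limit {aspect_limit:g}; adjust the pattern or the target bone"
        )

    vmin, vmax = pattern.v_extent()
    v_mid = 0.5 * (vmin + vmax)

    def _place(lines, base_id):
        placed = []
        for j, ln in enumerate(lines):
            uu = ln.unwrapped_u()
            x = uu * C
            y = (ln.points[:, 1] - v_mid) * longitudinal_scale + fracture_height
            xy = np.stack([x, y], axis=1)
            if ln.closed:
                # explicit closure point: the closing segment continues with
                # the minimal wrap step instead of jumping back across the band
                duc = ln.points[0, 0] - ln.points[-1, 0]
                duc -= np.round(duc)
                xy = np.concatenate([xy, [[x[-1] + duc * C, y[0]]]])
            placed.append(PlacedLine(
                points_xy=xy, closed=ln.closed,
                line_id=base_id + j, winding=ln.winding(),
            ))
        return placed

    outer = _place(pattern.lines_outer, 0)
    inner = _place(pattern.lines_inner, 0)

    lo, hi = cylinder.band
    for pl in outer + inner:
        ys = pl.points_xy[:, 1]
        if ys.min() < lo or ys.max() > hi:
            raise BandError(
                f"placed pattern v-extent [{ys.min():.2f}, {ys.max():.2f}] mm "
                f"exceeds the projection band [{lo:.2f}, {hi:.2f}] mm"
            )
    return PlacedPattern(outer=outer, inner=inner, cylinder=cylinder,
                         fracture_type=pattern.fracture_type)


# ---------------------------------------------------------------------------
# Cut points
# ---------------------------------------------------------------------------

@dataclass
class CutPoint:
    """Intersection of a placed pattern segment with a mesh edge.

    ``v0 < v1`` are model-vertex ids of the undirected edge; ``t`` is the
    parametric position from ``v0``.  A hit within ``snap_tolerance`` of
    an endpoint is flagged ``on_vertex`` (and hits through a shared vertex
    are deduplicated to a single flagged point).
    """

    v0: int
    v1: int
    t: float
    layer: int
    line_id: int
    on_vertex: bool
    xy: np.ndarray
    position3d: np.ndarray

    def vertex(self) -> Optional[int]:
        if not self.on_vertex:
            return None
        return self.v0 if self.t < 0.5 else self.v1


@dataclass
class CutChain:
    """Ordered cut points of one fracture line on one layer.

    ``pair_faces[i]`` is the band-face (model face id) crossed between
    points ``i`` and ``i+1`` (wrapping for closed chains).
    """

    points: list
    pair_faces: list
    closed: bool
    line_id: int
    layer: int
    winding: int


def _orient(ax, ay, bx, by, cx, cy) -> int:
    """Sign of the orientation of (a, b, c); exact near degeneracy.

    The float determinant is trusted outside a conservative error bound;
    inside it the sign is recomputed with rational arithmetic, so
    collinear and near-collinear configurations are classified exactly.
    """
    det = (bx - ax) * (cy - ay) - (by - ay) * (cx - ax)
    err = 1e-12 * (abs(bx - ax) * (abs(cy) + abs(ay)) +
                   abs(by - ay) * (abs(cx) + abs(ax)) + 1e-300)
    if abs(det) > err:
        return 1 if det > 0 else -1
    d = (Fraction(bx) - Fraction(ax)) * (Fraction(cy) - Fraction(ay)) - \
        (Fraction(by) - Fraction(ay)) * (Fraction(cx) - Fraction(ax))
    return (d > 0) - (d < 0)


def _point_in_triangle(p, tri) -> bool:
    s = [_orient(tri[i][0], tri[i][1], tri[(i + 1) % 3][0], tri[(i + 1) % 3][1],
                 p[0], p[1]) for i in range(3)]
    return all(x > 0 for x in s) or all(x < 0 for x in s)


def compute_cut_points(
    unwrapped: UnwrappedLayer,
    placed_lines: list,
    snap_tolerance: float = 0.0,
) -> list:
    """Intersect placed fracture lines with the unwrapped band edges.

    Returns one :class:`CutChain` per line, with exactly one
    :class:`CutPoint` per undirected mesh edge crossing (deduplicated
    across the two faces sharing each edge and across seam copies), points
    ordered along the line, and the crossed face recorded for every
    consecutive pair.

    Raises :class:`OpenLineError` if a non-closed line terminates strictly
    inside the band — a fracture must traverse the band or close on
    itself, otherwise it cannot separate fragments.
    """
    edges = unwrapped.unique_edges()
    edge_faces = unwrapped.edge_faces()
    period = unwrapped.period

    exy = np.stack(
        [unwrapped.edge_xy(a, b) for a, b in edges]
    )  # (E, 2, 2)
    e_lo = exy.min(axis=1)
    e_hi = exy.max(axis=1)
    e_cx = exy[:, :, 0].mean(axis=1)

    chains = []
    for pl in placed_lines:
        pts = pl.points_xy  # closed lines carry an explicit closure point
        segs = np.stack([pts[:-1], pts[1:]], axis=1)

        if not pl.closed:
            for endpoint in (pts[0], pts[-1]):
                q = _mod_point(endpoint, period)
                for fi in range(len(unwrapped.faces)):
                    tri = unwrapped.face_xy(fi)
                    for shift in _shifts(q[0], tri[:, 0], period):
                        if _point_in_triangle((q[0] + shift, q[1]), tri):
                            raise OpenLineError(
                                "open fracture line terminates inside the "
                                "band; it must traverse the band or close"
                            )

        raw_hits = []  # (seg_idx, s, edge_key, t, xy)
        for si, (P, Q) in enumerate(segs):
            seg_cx = 0.5 * (P[0] + Q[0])
            if period is not None:
                k = np.round((seg_cx - e_cx) / period)
                shift = k * period
            else:
                shift = np.zeros(len(edges))
            lo_x = e_lo[:, 0] + shift
            hi_x = e_hi[:, 0] + shift
            cand = ~(
                (np.maximum(P[0], Q[0]) < lo_x - 1e-12)
                | (np.minimum(P[0], Q[0]) > hi_x + 1e-12)
                | (np.maximum(P[1], Q[1]) < e_lo[:, 1] - 1e-12)
                | (np.minimum(P[1], Q[1]) > e_hi[:, 1] + 1e-12)
            )
            for ei in np.where(cand)[0]:
                A = exy[ei, 0].copy()
                B = exy[ei, 1].copy()
                A[0] += shift[ei]
                B[0] += shift[ei]
                hit = _segment_edge_hit(P, Q, A, B)
                if hit is None:
                    continue
                s, t = hit
                a, b = int(edges[ei, 0]), int(edges[ei, 1])
                if a > b:
                    a, b = b, a
                    t = 1.0 - t
                    A, B = B, A
                xy = np.array([A[0] + t * (B[0] - A[0]),
                               A[1] + t * (B[1] - A[1])])
                raw_hits.append((si, s, (a, b), t, xy))

        raw_hits.sort(key=lambda h: (h[0], h[1]))
        chain_pts = _dedupe_hits(raw_hits, unwrapped, pl, snap_tolerance)
        pair_faces = _pair_faces(chain_pts, pl.closed, edge_faces, unwrapped)
        chains.append(CutChain(
            points=chain_pts, pair_faces=pair_faces, closed=pl.closed,
            line_id=pl.line_id, layer=unwrapped.layer, winding=pl.winding,
        ))
    return chains


def _mod_point(p, period):
    if period is None:
        return p
    return np.array([p[0] % period, p[1]])


def _shifts(x, tri_x, period):
    if period is None:
        return [0.0]
    k = round((tri_x.mean() - x) / period)
    return [k * period]


def _segment_edge_hit(P, Q, A, B):
    """Proper or endpoint crossing of segment PQ with edge AB.

    Returns (s, t) parameters or None.  Segment endpoints exactly on the
    edge count at s=0 but not s=1 (the next segment catches its own
    start), so polyline joints yield exactly one hit.
    """
    o1 = _orient(P[0], P[1], Q[0], Q[1], A[0], A[1])
    o2 = _orient(P[0], P[1], Q[0], Q[1], B[0], B[1])
    if o1 == o2 and o1 != 0:
        return None
    if o1 == 0 and o2 == 0:
        return None  # collinear overlap: treated as no transversal crossing
    o3 = _orient(A[0], A[1], B[0], B[1], P[0], P[1])
    o4 = _orient(A[0], A[1], B[0], B[1], Q[0], Q[1])
    if o3 == o4 and o3 != 0:
        return None
    if o4 == 0 and o3 != 0:
        return None  # Q on edge: counted by the next segment's P
    d1 = Q - P
    d2 = B - A
    denom = d1[0] * d2[1] - d1[1] * d2[0]
    if denom == 0:
        return None
    t = ((P[0] - A[0]) * d1[1] - (P[1] - A[1]) * d1[0]) / -denom
    s = ((A[0] - P[0]) * d2[1] - (A[1] - P[1]) * d2[0]) / denom
    return float(np.clip(s, 0.0, 1.0)), float(np.clip(t, 0.0, 1.0))


def _dedupe_hits(raw_hits, unwrapped, pl, snap_tol):
    """Collapse duplicate hits (seam copies, shared vertices) into points."""
    pts: list[CutPoint] = []
    keys: list = []
    for si, s, (a, b), t, xy in raw_hits:
        if snap_tol > 0:
            on_vertex = t <= snap_tol + 1e-12 or t >= 1.0 - snap_tol - 1e-12
        else:
            on_vertex = t == 0.0 or t == 1.0
        if on_vertex:
            key = ("v", a if t < 0.5 else b)
        else:
            # the parametric position distinguishes two genuine crossings
            # of the same edge from one crossing found twice (seam copies,
            # the two faces sharing the edge)
            key = ("e", a, b, round(t, 6))
        if keys and keys[-1] == key:
            continue
        v3a = unwrapped.vertices3d[a]
        v3b = unwrapped.vertices3d[b]
        pts.append(CutPoint(
            v0=a, v1=b, t=t, layer=unwrapped.layer, line_id=pl.line_id,
            on_vertex=on_vertex, xy=xy,
            position3d=v3a + t * (v3b - v3a),
        ))
        keys.append(key)
    if pl.closed and len(pts) > 1 and keys[0] == keys[-1]:
        pts.pop()
        keys.pop()
    # collapse repeated edge keys anywhere consecutive after wrap handled
    return pts


def _pair_faces(chain_pts, closed, edge_faces, unwrapped):
    """Crossed model face id for each consecutive cut-point pair."""
    n = len(chain_pts)
    if n < 2:
        return []
    pairs = list(zip(range(n - 1), range(1, n)))
    if closed:
        pairs.append((n - 1, 0))
    out = []
    for i, j in pairs:
        fi = _common_face(chain_pts[i], chain_pts[j], edge_faces, unwrapped)
        out.append(fi)
    return out


def _faces_of_point(cp: CutPoint, edge_faces, unwrapped) -> set:
    if cp.on_vertex:
        v = cp.vertex()
        return {fi for (a, b), fs in edge_faces.items() if v in (a, b)
                for fi in fs}
    return set(edge_faces.get((cp.v0, cp.v1), []))


def _common_face(cp1, cp2, edge_faces, unwrapped):
    common = _faces_of_point(cp1, edge_faces, unwrapped) & \
        _faces_of_point(cp2, edge_faces, unwrapped)
    if not common:
        raise GeometryError(
            "consecutive cut points do not share a face; the pattern is "
            "finer than the mesh or crosses outside the band"
        )
    if len(common) > 1:
        # vertex hits can touch several faces; choose the face the segment
        # midpoint lies in, falling back to the smallest id
        mid = 0.5 * (cp1.xy + cp2.xy)
        for fi in sorted(common):
            tri = unwrapped.face_xy(fi)
            shift = _shifts(mid[0], tri[:, 0], unwrapped.period)[0]
            if _point_in_triangle((mid[0] + shift, mid[1]), tri):
                return int(unwrapped.face_ids[fi])
        return int(unwrapped.face_ids[min(common)])
    return int(unwrapped.face_ids[common.pop()])


# ---------------------------------------------------------------------------
# Debug SVG dump
# ---------------------------------------------------------------------------

def dump_svg(unwrapped: UnwrappedLayer, placed_lines: list, path) -> None:
    """Write the unwrapped band plus placed pattern as an SVG for visual
    inspection of seam handling and cut geometry."""
    tris = [unwrapped.face_xy(i) for i in range(len(unwrapped.faces))]
    allxy = np.concatenate(tris + [pl.points_xy for pl in placed_lines])
    lo = allxy.min(axis=0) - 2
    hi = allxy.max(axis=0) + 2
    w, h = hi - lo
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" viewBox="{lo[0]} {-hi[1]} {w} {h}">'
    ]
    for t in tris:
        pts = " ".join(f"{p[0]},{-p[1]}" for p in t)
        parts.append(
            f'<polygon points="{pts}" fill="none" stroke="#999" stroke-width="0.05"/>'
        )
    for pl in placed_lines:
        pts = " ".join(f"{p[0]},{-p[1]}" for p in pl.points_xy)
        tag = "polygon" if pl.closed else "polyline"
        parts.append(
            f'<{tag} points="{pts}" fill="none" stroke="#c00" stroke-width="0.15"/>'
        )
    parts.append("</svg>")
    from pathlib import Path as _P
    _P(path).write_text("\n".join(parts))
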