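"""Embed fracture lines into the mesh and identify fragments.

Cut points are integrated by one of three strategies: *approximation*
moves every cut point to the nearest vertex of its edge (topology
preserved, geometry approximated), *subdivision* inserts every cut point
as a new vertex (geometry exact, new triangles), and *hybrid* snaps only
cut points within an approximation threshold of an edge endpoint —
defaulting to 10% of the edge length — and subdivides the rest.  The two
pure strategies are the threshold's limits: hybrid(0) is subdivision and
hybrid(0.5) is approximation.

Where a face is split, the re-triangulation is chosen among the valid
diagonals to maximize the mean triangle quality ``q = R / (2 r)``
(circumradius over twice the inradius), the normalized radius-ratio
metric whose optimum, 1, is attained exactly by equilateral triangles.

Fragments are then found by region growing over face adjacency, never
crossing an embedded fracture edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import (
    ConfigError,
    DegeneracyError,
    RefinementRequestError,
    TopologyError,
)
from .mesh_core import TriangleMesh

#: Area below which triangle_quality refuses to evaluate (mm^2).
_QUALITY_AREA_TOL = 1e-12


# ---------------------------------------------------------------------------
# Triangle quality
# ---------------------------------------------------------------------------

@dataclass
class TriangleQuality:
    r: float   # inradius, mm
    R: float   # circumradius, mm
    q: float   # R / (2 r), dimensionless, >= 1, == 1 iff equilateral


def triangle_quality(p0, p1, p2) -> TriangleQuality:
    """Radius-ratio quality of one triangle.

    ``r = area / s`` (s the semiperimeter), ``R = abc / (4 area)`` and
    ``q = R / (2 r)``: for any triangle ``R >= 2 r`` with equality exactly
    for the equilateral, so q is 1 at the optimum with range [1, inf).
    Values up to about 1.3 are considered well-shaped.
    """
    p0 = np.asarray(p0, dtype=np.float64)
    p1 = np.asarray(p1, dtype=np.float64)
    p2 = np.asarray(p2, dtype=np.float64)
    a = np.linalg.norm(p1 - p2)
    b = np.linalg.norm(p0 - p2)
    c = np.linalg.norm(p0 - p1)
    cross = np.cross(p1 - p0, p2 - p0)
    area = 0.5 * (np.linalg.norm(cross) if cross.ndim else abs(cross))
    if area < _QUALITY_AREA_TOL:
        raise DegeneracyError("collinear points have no triangle quality")
    s = 0.5 * (a + b + c)
    r = area / s
    R = a * b * c / (4.0 * area)
    return TriangleQuality(r=float(r), R=float(R), q=float(R / (2.0 * r)))


def mesh_quality(mesh: TriangleMesh) -> np.ndarray:
    """Vectorized q for every face (degenerate faces get +inf)."""
    v0, v1, v2 = mesh.face_corners()
    a = np.linalg.norm(v1 - v2, axis=1)
    b = np.linalg.norm(v0 - v2, axis=1)
    c = np.linalg.norm(v0 - v1, axis=1)
    area = 0.5 * np.linalg.norm(np.cross(v1 - v0, v2 - v0), axis=1)
    ok = area > _QUALITY_AREA_TOL
    q = np.full(len(a), np.inf)
    r = area[ok] / (0.5 * (a + b + c)[ok])
    R = (a * b * c)[ok] / (4.0 * area[ok])
    q[ok] = R / (2.0 * r)
    return q


# ---------------------------------------------------------------------------
# Cut strategies
# ---------------------------------------------------------------------------

@dataclass
class CutStrategy:
    """Cut-embedding strategy; ``threshold`` is the snapping band as a
    fraction of the cut edge's length (scale-invariant)."""

    mode: str = "hybrid"
    threshold: float = 0.10

    def __post_init__(self):
        if self.mode not in ("approximation", "subdivision", "hybrid"):
            raise ConfigError(f"unknown cut strategy {self.mode!r}")
        if not (0.0 <= self.threshold <= 0.5):
            raise ConfigError("threshold must lie in [0, 0.5]")

    def effective_threshold(self) -> float:
        if self.mode == "approximation":
            return 0.5
        if self.mode == "subdivision":
            return 0.0
        return self.threshold


# ---------------------------------------------------------------------------
# Embedding
# ---------------------------------------------------------------------------

@dataclass
class EmbeddedMesh:
    """Mesh with fracture lines realized as edges.

    ``fracture_edges`` maps sorted vertex pairs to the set of
    ``(line_id, layer)`` interfaces running along them; ``contours`` holds
    the ordered resolved vertex loop per interface (in pattern order).
    """

    mesh: TriangleMesh
    fracture_edges: dict
    contours: dict
    n_snapped: int = 0
    n_subdivided: int = 0

    def edges_of(self, line_id: int, layer: int) -> set:
        return {e for e, tags in self.fracture_edges.items()
                if (line_id, layer) in tags}


def embed_cuts(
    mesh: TriangleMesh, chains: list, strategy: CutStrategy
) -> EmbeddedMesh:
    """Embed ordered cut chains into the mesh under a cut strategy.

    Each cut point is either snapped to the nearest endpoint of its edge
    (if its parametric distance to that endpoint is within the strategy's
    effective threshold) or inserted as a new vertex splitting the edge.
    Every face crossed by a chain is re-triangulated so the segment
    between its two resolved cut vertices becomes a mesh edge; among the
    valid re-triangulations the one maximizing mean q is used.
    """
    thr = strategy.effective_threshold()
    vertices = [mesh.vertices]
    next_vid = mesh.n_vertices
    edge_inserts: dict = {}   # (a,b) sorted -> list of (t, vid)
    resolved: dict = {}       # id(cut point) -> vertex id
    n_snap = n_sub = 0

    for chain in chains:
        for cp in chain.points:
            key = (cp.v0, cp.v1)
            if cp.on_vertex:
                resolved[id(cp)] = cp.v0 if cp.t < 0.5 else cp.v1
                n_snap += 1
                continue
            d = min(cp.t, 1.0 - cp.t)
            if d <= thr:
                if cp.t < 0.5:
                    target = cp.v0
                elif cp.t > 0.5:
                    target = cp.v1
                else:
                    target = min(cp.v0, cp.v1)
                taken = {vid for _, vid in edge_inserts.get(key, [])}
                if target in taken:
                    pass  # snapping would merge two cuts; fall through
                else:
                    resolved[id(cp)] = target
                    n_snap += 1
                    continue
            vid = next_vid
            next_vid += 1
            vertices.append(cp.position3d[None, :])
            edge_inserts.setdefault(key, []).append((cp.t, vid))
            resolved[id(cp)] = vid
            n_sub += 1

    all_vertices = np.concatenate(vertices)

    # gather the required fracture diagonal(s) per crossed face
    face_pairs: dict = {}  # face id -> list of (rv_i, rv_j, line_id, layer)
    for chain in chains:
        pts = chain.points
        n = len(pts)
        if n == 0:
            continue
        pair_idx = list(zip(range(n - 1), range(1, n)))
        if chain.closed:
            pair_idx.append((n - 1, 0))
        for (i, j), face in zip(pair_idx, chain.pair_faces):
            ri, rj = resolved[id(pts[i])], resolved[id(pts[j])]
            face_pairs.setdefault(face, []).append(
                (ri, rj, chain.line_id, chain.layer)
            )

    fracture_edges: dict = {}
    for face, pairs in face_pairs.items():
        distinct = {frozenset((a, b)) for a, b, _, _ in pairs if a != b}
        if len(distinct) > 6:
            # segments of a simple line never cross, so several per face
            # embed fine as non-crossing diagonals; past this density the
            # pattern is finer than the mesh can represent
            raise RefinementRequestError(
                f"face {face} is crossed by {len(distinct)} fracture "
                "segments; refine the mesh or simplify the pattern"
            )
        for a, b, lid, layer in pairs:
            if a != b:
                e = (min(a, b), max(a, b))
                fracture_edges.setdefault(e, set()).add((lid, layer))

    # rebuild crossed faces (and any face adjacent to a split edge)
    affected = set(face_pairs)
    edge_to_faces: dict = {}
    for fi, f in enumerate(mesh.faces):
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            edge_to_faces.setdefault((min(a, b), max(a, b)), []).append(fi)
    for e in edge_inserts:
        affected.update(edge_to_faces.get(e, []))

    new_faces = []
    new_labels = []
    keep = np.ones(mesh.n_faces, dtype=bool)
    for face in affected:
        keep[face] = False
        corners = mesh.faces[face]
        poly = []
        for k in range(3):
            a, b = corners[k], corners[(k + 1) % 3]
            poly.append(int(a))
            key = (min(a, b), max(a, b))
            ins = edge_inserts.get(key, [])
            if ins:
                ins_sorted = sorted(ins, key=lambda it: it[0] if a < b else -it[0])
                poly.extend(vid for _, vid in ins_sorted)
        required = []
        for a, b, _, _ in face_pairs.get(face, []):
            if a != b and (a, b) not in required and (b, a) not in required:
                required.append((a, b))
        tris = _triangulate_polygon(poly, all_vertices, required)
        label = None if mesh.face_labels is None else mesh.face_labels[face]
        for t in tris:
            new_faces.append(t)
            new_labels.append(label)

    faces = np.concatenate([
        mesh.faces[keep],
        np.asarray(new_faces, dtype=np.int64).reshape(-1, 3),
    ]) if new_faces else mesh.faces[keep]
    labels = None
    if mesh.face_labels is not None:
        labels = np.concatenate([
            mesh.face_labels[keep],
            np.asarray(new_labels, dtype=np.int64),
        ]) if new_labels else mesh.face_labels[keep]

    out_mesh = TriangleMesh(all_vertices, faces, labels)

    # ordered contour per interface, with degenerate steps collapsed
    contours: dict = {}
    for chain in chains:
        ids = [resolved[id(cp)] for cp in chain.points]
        dedup = [v for k, v in enumerate(ids) if k == 0 or v != ids[k - 1]]
        if chain.closed and len(dedup) > 1 and dedup[0] == dedup[-1]:
            dedup.pop()
        if chain.closed and len(dedup) < 3:
            raise TopologyError(
                f"fracture line {chain.line_id} collapsed to fewer than 3 "
                "vertices after snapping"
            )
        contours[(chain.line_id, chain.layer)] = (dedup, chain.closed)

    return EmbeddedMesh(
        mesh=out_mesh, fracture_edges=fracture_edges, contours=contours,
        n_snapped=n_snap, n_subdivided=n_sub,
    )


def _triangulate_polygon(poly, vertices, required):
    """Triangulate a convex small polygon, forcing required diagonals.

    The polygon is an original mesh triangle with points inserted on its
    edges, so it is convex up to floating error and every diagonal is
    valid.  ``required`` lists fracture diagonals that must appear as
    edges; the polygon is split recursively along them, and each
    remaining sub-polygon is fan-triangulated choosing the fan whose mean
    quality q is best (closest to 1).
    """
    n = len(poly)
    if n == 3:
        return [list(poly)]
    required = [r for r in (required or [])
                if r[0] in poly and r[1] in poly]
    for a, b in required:
        i, j = poly.index(a), poly.index(b)
        if i > j:
            i, j = j, i
        if j - i in (1, n - 1):
            continue  # already a boundary edge of this (sub-)polygon
        side1 = poly[i:j + 1]
        side2 = poly[j:] + poly[:i + 1]
        rem = [r for r in required if r != (a, b)]
        r1 = [r for r in rem if r[0] in side1 and r[1] in side1]
        r2 = [r for r in rem if r[0] in side2 and r[1] in side2]
        return (_triangulate_polygon(side1, vertices, r1)
                + _triangulate_polygon(side2, vertices, r2))
    # no (usable) required diagonal: pick the fan whose mean q is closest
    # to the equilateral optimum (q = 1 is ideal, larger is worse).
    # Degenerate candidate triangles (clustered edge inserts) score a
    # huge penalty rather than disqualifying the fan: a zero-area sliver
    # still welds watertight, and some fan must be returned.
    best, best_q = None, np.inf
    for k in range(n):
        rot = poly[k:] + poly[:k]
        tris = [[rot[0], rot[m], rot[m + 1]] for m in range(1, n - 1)]
        qs = []
        for t in tris:
            try:
                qs.append(triangle_quality(*vertices[t]).q)
            except DegeneracyError:
                qs.append(1e12)
        mean_q = float(np.mean(qs))
        if mean_q < best_q:
            best_q, best = mean_q, tris
    return best


# ---------------------------------------------------------------------------
# Fragment identification
# ---------------------------------------------------------------------------

@dataclass
class FragmentLabeling:
    face_labels: np.ndarray
    n_fragments: int
    fracture_edges: set


def identify_fragments(mesh: TriangleMesh, fracture_edges) -> FragmentLabeling:
    """Label faces by region growing that never crosses a fracture edge.

    Seeded flood fill over the face-adjacency graph; the partition is
    independent of seed choice because connectivity is symmetric.
    """
    blocked = set(fracture_edges)
    edge_to_faces: dict = {}
    for fi, f in enumerate(mesh.faces):
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            edge_to_faces.setdefault((min(a, b), max(a, b)), []).append(fi)

    parent = np.arange(mesh.n_faces)

    def find(x):
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    for e, fs in edge_to_faces.items():
        if e in blocked or len(fs) < 2:
            continue
        r0 = find(fs[0])
        for other in fs[1:]:
            r = find(other)
            if r != r0:
                parent[r] = r0
    roots = np.array([find(i) for i in range(mesh.n_faces)])
    uniq, labels = np.unique(roots, return_inverse=True)
    return FragmentLabeling(
        face_labels=labels, n_fragments=len(uniq), fracture_edges=blocked
    )
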