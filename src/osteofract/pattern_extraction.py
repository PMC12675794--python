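"""Detect fracture zones on fragment meshes and recover 2D patterns.

This is the inverse of the simulation pipeline: given a (real or
simulated) fractured fragment, find the points where the smooth cortical
wall meets the rough fracture face, classify them into outer/inner
cortical layers, and convert them through the cylindrical unwrap into a
:class:`~osteofract.pattern.FracturePattern2D` that can be re-applied to
an intact bone.

The detector is a simplified oriented-bounding-box / grid-sweep scheme:
the fragment's principal-axis bounding box is swept in columns parallel
to its long axis, and candidate points are vertices of edges whose
dihedral angle exceeds a crease threshold (default 35 deg) — the sharp
break between cortical wall and fracture face.  Flat, axis-normal patches
("machined ends", e.g. the annular caps of synthetic bones, which are
geometrically indistinguishable from a perfectly flat transverse fracture)
are excluded; consequently detection needs either an inclined fracture
or non-zero surface roughness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import AmbiguityError
from .mesh_core import TriangleMesh
from .pattern import FracturePattern2D, Polyline
from .projection import ProjectionCylinder
from .synthetic_bone import _axis_frame

logger = logging.getLogger("osteofract")

#: Faces whose normal is within this many degrees of the sweep axis are
#: candidates for the machined-end exclusion.
_END_CONE_DEG = 10.0
#: Coplanarity tolerance (mm) for a machined-end patch.
_END_PLANAR_TOL = 0.02


@dataclass
class FractureZonePoints:
    """Candidate fracture points with cortical-layer tags."""

    points: np.ndarray          # (n, 3) mm
    layers: np.ndarray          # (n,) 0 = outer, 1 = inner
    source_vertices: np.ndarray  # (n,) vertex ids in the fragment mesh
    sweep_axis: np.ndarray = field(default_factory=lambda: np.zeros(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @property
    def empty(self) -> bool:
        return len(self.points) == 0


def detect_fracture_zone(
    fragment: TriangleMesh,
    grid_columns: int = 100,
    dihedral_threshold_deg: float = 35.0,
) -> FractureZonePoints:
    """Find fracture-zone points on a closed fragment mesh.

    The principal-axis oriented bounding box supplies the sweep axis (its
    long edge); the box cross-section is discretized into columns of
    width ``long_edge / grid_columns``.  Candidate vertices come from
    crease edges (dihedral above threshold) not bordering a machined-end
    patch, and are classified outer/inner by radial distance against the
    local (per-column) or global mid-thickness.

    An empty result (no candidates) is returned with a logged warning,
    not raised: an intact bone simply has no fracture zone.
    """
    v = fragment.vertices
    centroid = v.mean(axis=0)
    _, _, vt = np.linalg.svd(v - centroid, full_matrices=False)
    sweep = vt[0]
    a1, a2 = vt[1], vt[2]

    fn = fragment.face_normals()

    # machined-end patches: connected flat face sets with axis-normal
    # orientation (|n . sweep| within the cone) and coplanar vertices
    axial = np.abs(fn @ sweep) > np.cos(np.radians(_END_CONE_DEG))
    end_faces = _coplanar_axial_patches(fragment, fn, axial, sweep)

    # wall/fracture face classification by normal deviation from the
    # local radial direction: cortical walls are radial, fracture faces
    # are not.  The fracture contour is the crease between the two.
    fc = (v[fragment.faces[:, 0]] + v[fragment.faces[:, 1]]
          + v[fragment.faces[:, 2]]) / 3.0
    rel_c = fc - centroid
    rad = rel_c - (rel_c @ sweep)[:, None] * sweep
    rad_norm = np.linalg.norm(rad, axis=1)
    ok = rad_norm > 1e-9
    rad[ok] /= rad_norm[ok, None]
    signed_dev = np.einsum("ij,ij->i", fn, rad)
    dev = np.abs(signed_dev)
    wallish = dev > np.cos(np.radians(40.0))
    fracish = dev < np.cos(np.radians(50.0))

    # crease edges between a wall face and a fracture face.  The wall
    # face also classifies the layer: its outward normal points away from
    # the axis on the outer cortical surface and toward it on the canal
    # wall — a signed test that, unlike radial-distance thresholds, is
    # insensitive to the axis tilt an asymmetric fragment induces.
    edge_faces: dict = {}
    for fi, f in enumerate(fragment.faces):
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            edge_faces.setdefault((min(a, b), max(a, b)), []).append(fi)
    cos_thr = np.cos(np.radians(dihedral_threshold_deg))
    votes: dict = {}
    incidence: dict = {}
    for (a, b), fs in edge_faces.items():
        if len(fs) != 2:
            continue
        f1, f2 = fs
        if end_faces[f1] or end_faces[f2]:
            continue
        if fn[f1] @ fn[f2] >= cos_thr:
            continue
        if wallish[f1] and fracish[f2]:
            wall = f1
        elif wallish[f2] and fracish[f1]:
            wall = f2
        else:
            continue
        vote = 1 if signed_dev[wall] > 0 else -1
        for vid in (int(a), int(b)):
            votes[vid] = votes.get(vid, 0) + vote
            incidence[vid] = incidence.get(vid, 0) + 1
    # the contour passes THROUGH its vertices: true fracture-line points
    # have at least two incident crease edges, stray crease endpoints one
    cand_vertices = {v for v, c in incidence.items() if c >= 2}

    if not cand_vertices:
        logger.warning("no fracture-zone candidates found (intact mesh?)")
        return FractureZonePoints(
            points=np.empty((0, 3)), layers=np.empty(0, dtype=int),
            source_vertices=np.empty(0, dtype=int),
            sweep_axis=sweep, origin=centroid,
        )

    ids = np.array(sorted(cand_vertices))
    pts = v[ids]
    rel = pts - centroid

    # grid sweep: columns across the box cross-section; isolated
    # single-candidate columns are treated as noise and dropped
    long_extent = (v - centroid) @ sweep
    col_w = (long_extent.max() - long_extent.min()) / max(grid_columns, 1)
    cu = np.floor((rel @ a1) / max(col_w, 1e-9)).astype(int)
    cv = np.floor((rel @ a2) / max(col_w, 1e-9)).astype(int)
    col_count: dict = {}
    for key in zip(cu.tolist(), cv.tolist()):
        col_count[key] = col_count.get(key, 0) + 1
    keep = np.array([col_count[(a, b)] > 1
                     for a, b in zip(cu.tolist(), cv.tolist())])
    ids = ids[keep]
    pts = pts[keep]

    layers = np.array([0 if votes[int(i)] > 0 else 1 for i in ids], dtype=int)
    return FractureZonePoints(
        points=pts, layers=layers, source_vertices=ids,
        sweep_axis=sweep, origin=centroid,
    )


def _coplanar_axial_patches(fragment, fn, axial, sweep) -> np.ndarray:
    """Boolean mask of faces belonging to flat, axis-normal patches."""
    out = np.zeros(fragment.n_faces, dtype=bool)
    if not axial.any():
        return out
    # group axial faces into connected patches
    edge_faces: dict = {}
    for fi in np.where(axial)[0]:
        f = fragment.faces[fi]
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            edge_faces.setdefault((min(a, b), max(a, b)), []).append(int(fi))
    parent = {int(fi): int(fi) for fi in np.where(axial)[0]}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for fs in edge_faces.values():
        for other in fs[1:]:
            ra, rb = find(fs[0]), find(other)
            if ra != rb:
                parent[rb] = ra
    groups: dict = {}
    for fi in parent:
        groups.setdefault(find(fi), []).append(fi)
    v = fragment.vertices
    for members in groups.values():
        vids = np.unique(fragment.faces[members])
        # coplanarity against the patch's own mean normal (the sweep axis
        # may be slightly tilted by an asymmetric fracture)
        n = fn[members].mean(axis=0)
        norm = np.linalg.norm(n)
        if norm == 0:
            continue
        h = v[vids] @ (n / norm)
        if h.max() - h.min() < _END_PLANAR_TOL:
            out[members] = True
    return out


def extract_pattern(
    zone: FractureZonePoints,
    cylinder: ProjectionCylinder,
    simplify: Optional[float] = None,
) -> FracturePattern2D:
    """Convert fracture-zone points to a 2D pattern via the cylinder.

    Points of each layer are unwrapped to (u, v), chained into a polyline
    by nearest-neighbour continuation (wrap-aware), and simplified with a
    Douglas-Peucker tolerance of half the median point spacing (or the
    explicit ``simplify`` value in mm).  If the inner layer is empty it
    is filled with a copy of the outer line and a warning is logged.
    """
    if zone.empty:
        raise AmbiguityError("cannot extract a pattern from an empty zone")
    axis = cylinder.axis
    e1, e2 = _axis_frame(axis.direction)
    C = cylinder.circumference

    lines = {}
    for layer in (0, 1):
        sel = zone.layers == layer
        if not sel.any():
            continue
        p = zone.points[sel] - axis.origin
        h = p @ axis.direction
        theta = np.arctan2(p @ e2, p @ e1) % (2 * np.pi)
        x = theta * cylinder.radius
        lines[layer] = _chain_points(np.stack([x, h], axis=1), C, simplify)

    # a fracture line must separate fragments, so only closed chains are
    # usable; open chainlets are detector noise or partial coverage
    for layer in list(lines):
        lines[layer] = [lc for lc in lines[layer] if lc[1]]

    if 0 not in lines or not lines[0]:
        raise AmbiguityError(
            "no closed outer-layer fracture line could be reconstructed"
        )
    if 1 not in lines or not lines[1]:
        logger.warning("no usable inner-layer line; copying the outer line")
        lines[1] = [(xy.copy(), closed) for xy, closed in lines[0]]

    def to_polylines(chains):
        out = []
        for xy, closed in chains:
            u = (xy[:, 0] / C) % 1.0
            out.append(Polyline(np.stack([u, xy[:, 1]], axis=1), closed=closed))
        return out

    return FracturePattern2D(
        lines_outer=to_polylines(lines[0]),
        lines_inner=to_polylines(lines[1]),
        fracture_type="transverse",  # type is not inferred; caller may set
        source="extracted",
        meta={"source_circumference": float(C)},
    )


def _chain_points(xy: np.ndarray, period: float, simplify) -> list:
    """Greedy nearest-neighbour chaining with wrap-aware metric.

    The cloud is first thinned (subdivision can leave clusters of
    near-coincident crease vertices whose spacing would defeat a naive
    jump tolerance), then chained; the jump tolerance is a small multiple
    of the thinned spacing.  Returns a list of (n, 2) arrays with x
    continuous (may exceed the period), longest first.
    """
    if len(xy) < 2:
        return [xy]

    def wdist(a, b):
        dx = np.abs(a[0] - b[:, 0])
        dx = np.minimum(dx, period - dx)
        return np.hypot(dx, a[1] - b[:, 1])

    nn = []
    for s in xy[:: max(1, len(xy) // 300)]:
        d = wdist(s, xy)
        d[d == 0] = np.inf
        nn.append(d.min())
    spacing = float(np.percentile(nn, 90))
    # the sparsest stretch of the contour sets the connectivity scale
    link = float(np.max(nn))

    # thin: greedily drop points closer than a fraction of the spacing
    keep: list[int] = []
    for i in np.lexsort((xy[:, 1], xy[:, 0])):
        if not keep or wdist(xy[i], xy[np.array(keep)]).min() > 0.35 * spacing:
            keep.append(int(i))
    xy = xy[np.array(keep)]
    n = len(xy)
    max_jump = 2.5 * link

    # split into connected components of the link graph, then order each
    # component along the curve by a nearest-neighbour cycle refined with
    # 2-opt (curve reconstruction; greedy walks alone scramble the order
    # near junctions)
    dmat = _wrap_distance_matrix(xy, period)
    comp_labels = _components(dmat <= max_jump)
    min_len = max(6, int(0.03 * n))
    closed_chains = []
    open_chains = []
    for comp in np.unique(comp_labels):
        idx = np.where(comp_labels == comp)[0]
        if len(idx) < min_len:
            continue
        sub = dmat[np.ix_(idx, idx)]
        candidates = [_order_cycle(sub)]
        # a component winding the whole circumference is usually a graph
        # over x: plain circumferential sorting cannot weave
        cx = xy[idx, 0]
        if cx.max() - cx.min() > 0.8 * period or len(idx) > 3:
            candidates.append(np.argsort(cx).tolist())
        best_order, best_len = None, np.inf
        for order in candidates:
            length = sum(sub[order[i], order[(i + 1) % len(order)]]
                         for i in range(len(order)))
            if length < best_len:
                best_len, best_order = length, order
        order = best_order
        pts = xy[idx[order]].copy()
        hops = np.array([
            sub[order[i], order[(i + 1) % len(order)]]
            for i in range(len(order))
        ])
        k = int(np.argmax(hops))
        if hops[k] <= 3.0 * link:
            closed_chains.append(pts)
        else:
            # open chain: cut the cycle at its outlier hop
            open_chains.append(np.roll(pts, -(k + 1), axis=0))

    # detection can leave gaps larger than the link scale (e.g. along a
    # sparsely creased seam); re-join the ordered open chains at their
    # closest endpoints
    open_chains = _merge_open_chains(open_chains, period,
                                     max_gap=0.15 * period)

    out = []
    for pts, was_closed in ([(c, True) for c in closed_chains]
                            + [(c, False) for c in open_chains]):
        # unwrap x continuously along the chain
        pts = pts.copy()
        dx = np.diff(pts[:, 0])
        dx -= np.round(dx / period) * period
        pts[1:, 0] = pts[0, 0] + np.cumsum(dx)
        if was_closed:
            closed = True
        else:
            gap_dx = abs(pts[0, 0] - pts[-1, 0])
            gap_dx = min(gap_dx % period, period - gap_dx % period)
            gap = np.hypot(gap_dx, pts[0, 1] - pts[-1, 1])
            # the ends meet, or the chain winds the full circumference
            # and closes via the seam
            closed = (gap <= 3.0 * link
                      or pts[:, 0].max() - pts[:, 0].min() > 0.8 * period)
        if len(pts) < min_len:
            continue
        # a closed loop smaller than a few link lengths is detector noise,
        # not a fracture line
        diag = np.hypot(pts[:, 0].max() - pts[:, 0].min(),
                        pts[:, 1].max() - pts[:, 1].min())
        if closed and diag < 4.0 * link:
            continue
        if pts[:, 0].max() - pts[:, 0].min() > 0.8 * period:
            # winding line: collapse the detected band to a graph over
            # the circumference (median height per bin) — simple by
            # construction, so re-embedding cannot self-intersect
            pts = _monotone_resample(pts, spacing)
        elif len(pts) > 4:
            # light smoothing kills mesh-scale zigzag
            sm = pts.copy()
            sm[1:-1] = (pts[:-2] + pts[1:-1] + pts[2:]) / 3.0
            pts = sm
        tol = simplify if simplify is not None else 0.5 * link
        pts = _simplify_simple(pts, closed, tol, period)
        out.append((pts, closed))
    # longest chain first: it is the principal fracture line
    out.sort(key=lambda p: -len(p[0]))
    return out


def _monotone_resample(pts, spacing):
    """Median height per circumferential bin (strictly increasing x)."""
    x, y = pts[:, 0], pts[:, 1]
    width = max(spacing, 1e-6)
    nbins = max(int(np.ceil((x.max() - x.min()) / width)), 8)
    edges = np.linspace(x.min(), x.max() + 1e-9, nbins + 1)
    out = []
    for i in range(nbins):
        sel = (x >= edges[i]) & (x < edges[i + 1])
        if sel.any():
            out.append([x[sel].mean(), float(np.median(y[sel]))])
    return np.asarray(out)


def _simplify_simple(pts, closed, tol, period):
    """Douglas-Peucker simplification that yields a non-self-intersecting
    line; the tolerance is doubled until the (wrap-closed) ring is simple.
    A fracture line that crosses itself cannot be re-embedded."""
    import shapely

    if len(pts) <= 4:
        return pts
    for _ in range(7):
        if tol > 0:
            ls = shapely.LineString(pts).simplify(
                tol, preserve_topology=False)
            cand = np.asarray(ls.coords)
        else:
            cand = pts
        if closed:
            duc = cand[0, 0] - cand[-1, 0]
            duc -= np.round(duc / period) * period
            ring = np.concatenate(
                [cand, [[cand[-1, 0] + duc, cand[0, 1]]]]
            )
            probe = shapely.LineString(ring)
            ok = probe.is_simple and _no_wrap_crossing(ring, period)
        else:
            probe = shapely.LineString(cand)
            ok = probe.is_simple
        if ok or len(cand) <= 4:
            return cand
        tol = max(tol, 0.1) * 2.0
    return cand


def _no_wrap_crossing(ring, period):
    """True iff the line does not cross its own wrap copy (segments one
    period apart in continuous x are neighbours in wrapped space)."""
    import shapely

    a = shapely.LineString(ring)
    b = shapely.LineString(ring + np.array([period, 0.0]))
    inter = a.intersection(b)
    if inter.is_empty:
        return True
    # a winding ring legitimately touches its copy at the closure point
    if inter.geom_type == "Point":
        end = ring[-1]
        return np.hypot(inter.x - end[0], inter.y - end[1]) < 1e-9 or \
            np.hypot(inter.x - (ring[0, 0] + period),
                     inter.y - ring[0, 1]) < 1e-9
    return False


def _merge_open_chains(chains, period, max_gap):
    """Join ordered open chains at their closest endpoints."""

    def edist(a, b):
        dx = abs(a[0] - b[0])
        dx = min(dx % period, period - dx % period)
        return float(np.hypot(dx, a[1] - b[1]))

    chains = [np.asarray(c) for c in chains]
    while len(chains) > 1:
        best = (np.inf, None)
        for i in range(len(chains)):
            for j in range(i + 1, len(chains)):
                for ei in (0, -1):
                    for ej in (0, -1):
                        d = edist(chains[i][ei], chains[j][ej])
                        if d < best[0]:
                            best = (d, (i, j, ei, ej))
        if best[1] is None or best[0] > max_gap:
            break
        i, j, ei, ej = best[1]
        a, b = chains[i], chains[j]
        if ei == -1 and ej == 0:
            merged = np.concatenate([a, b])
        elif ei == -1 and ej == -1:
            merged = np.concatenate([a, b[::-1]])
        elif ei == 0 and ej == 0:
            merged = np.concatenate([a[::-1], b])
        else:
            merged = np.concatenate([b, a])
        chains = [c for k, c in enumerate(chains) if k not in (i, j)]
        chains.append(merged)
    return chains


def _wrap_distance_matrix(xy: np.ndarray, period: float) -> np.ndarray:
    dx = np.abs(xy[:, 0][:, None] - xy[:, 0][None, :])
    dx = np.minimum(dx, period - dx)
    dy = xy[:, 1][:, None] - xy[:, 1][None, :]
    return np.hypot(dx, dy)


def _components(adj: np.ndarray) -> np.ndarray:
    import scipy.sparse
    import scipy.sparse.csgraph
    n_comp, labels = scipy.sparse.csgraph.connected_components(
        scipy.sparse.csr_matrix(adj), directed=False
    )
    return labels


def _order_cycle(d: np.ndarray, max_passes: int = 25) -> list:
    """Nearest-neighbour tour + 2-opt: order points along a closed curve."""
    n = len(d)
    unvisited = set(range(1, n))
    tour = [0]
    while unvisited:
        cur = tour[-1]
        nxt = min(unvisited, key=lambda j: d[cur, j])
        tour.append(nxt)
        unvisited.remove(nxt)
    tour = np.asarray(tour)
    for _ in range(max_passes):
        improved = False
        pos = tour
        nxt = np.roll(pos, -1)
        for i in range(n - 1):
            a, b = pos[i], nxt[i]
            # vectorized gain of reversing segment (i+1 .. j)
            cs = pos[i + 1:]
            ds = np.roll(pos, -1)[i + 1:]
            gain = (d[a, b] + d[cs, ds]) - (d[a, cs] + d[b, ds])
            j = int(np.argmax(gain))
            if gain[j] > 1e-12:
                lo, hi = i + 1, i + 1 + j
                tour[lo:hi + 1] = tour[lo:hi + 1][::-1]
                improved = True
                pos = tour
                nxt = np.roll(pos, -1)
        if not improved:
            break
    return tour.tolist()
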