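"""Close fragments across the cortical thickness and assemble solids.

After cut embedding, each fracture interface is a pair of closed loops:
the fracture line on the outer cortical layer and its counterpart on the
inner layer.  The fracture surface spanning the cortical wall between
them is triangulated with a constrained Delaunay scheme on the loops'
best-fit plane, the inner loop bounding a hole so the medullary canal
stays open.  Where the planar projection degenerates (spiral fractures,
wedge side walls, whose two loops nearly coincide in projection) a ribbon
("zipper") triangulation between corresponding loop points is used
instead.

Roughness is added by one of two perturbation methods: displacement of
the contour vertices along their shell-vertex normals *before*
triangulation (pre_triangulation), or displacement of an auxiliary
centroid point per surface triangle along its face normal *after*
triangulation (post_triangulation, tripling the triangle count).  Random
draws are uniform in [-tau, +tau] mm (optionally one-sided [0, tau]).

Each interface's surface is computed ONCE and attached to both adjacent
fragments with opposite orientation — mating fracture surfaces are
geometrically identical, which makes the fragment-volume sum equal the
intact shell volume exactly up to float summation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import shapely

from .errors import (
    ConfigError,
    ContourError,
    GeometryError,
    LayerError,
    PerturbationError,
    WeldError,
)
from .fragmentation import EmbeddedMesh, identify_fragments
from .mesh_core import (
    Axis,
    LABEL_FRACTURE,
    LABEL_INNER,
    LABEL_OUTER,
    TriangleMesh,
    validate_mesh,
)
from .projection import ProjectionCylinder
from .synthetic_bone import _axis_frame


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PerturbationConfig:
    """Fracture-surface roughness parameters.

    ``method`` is ``"pre_triangulation"`` (contour-vertex displacement,
    a.k.a. Method A), ``"post_triangulation"`` (centroid-fan displacement,
    Method B) or ``"none"``.  ``tau`` is the maximum displacement in mm;
    the anatomically sensible range is 0.1-1.0 mm.
    """

    method: str = "none"
    tau: float = 0.3
    seed: int = 0
    one_sided: bool = False

    def __post_init__(self):
        if self.method not in ("none", "pre_triangulation", "post_triangulation"):
            raise ConfigError(f"unknown perturbation method {self.method!r}")
        if not (0.0 <= self.tau <= 1.0):
            raise ConfigError("tau must lie in [0, 1] mm")


# ---------------------------------------------------------------------------
# Contours
# ---------------------------------------------------------------------------

@dataclass
class FractureContours:
    """Ordered closed fracture loops of one interface, per layer."""

    outer: list   # vertex ids, ordered, closed (no repeated endpoint)
    inner: list
    line_id: int = 0


def chain_fracture_edges(edge_set) -> list:
    """Chain an undirected edge set into one closed ordered loop.

    Raises :class:`ContourError` if the edges form an open chain, branch,
    or split into several loops.
    """
    adj: dict = {}
    for a, b in edge_set:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    bad = [v for v, ns in adj.items() if len(ns) != 2]
    if bad:
        raise ContourError(
            f"fracture edges do not close into a simple loop (vertices with "
            f"degree != 2: {sorted(bad)[:5]} ...)"
        )
    start = min(adj)
    loop = [start]
    prev, cur = None, start
    while True:
        nxt = [n for n in adj[cur] if n != prev]
        step = nxt[0] if nxt else prev  # 2-vertex loop guard
        if step == start:
            break
        loop.append(step)
        prev, cur = cur, step
        if len(loop) > len(adj) + 1:
            raise ContourError("fracture-edge chaining did not terminate")
    if len(loop) != len(adj):
        raise ContourError("fracture edges split into several loops")
    return loop


def _remove_spikes(loop: list) -> list:
    """Delete zero-width excursions (.., a, b, a, ..) from a closed loop."""
    changed = True
    while changed and len(loop) > 3:
        changed = False
        n = len(loop)
        for i in range(n):
            if loop[(i - 1) % n] == loop[(i + 1) % n]:
                # drop the spike tip and the duplicated return vertex
                drop = sorted({i, (i + 1) % n}, reverse=True)
                for k in drop:
                    del loop[k]
                changed = True
                break
        if loop:
            dedup = [v for k, v in enumerate(loop)
                     if v != loop[(k - 1) % len(loop)]]
            if len(dedup) != len(loop):
                loop = dedup
                changed = True
    if len(loop) < 3 or len(set(loop)) != len(loop):
        raise ContourError(
            "fracture loop remains self-touching after spike removal"
        )
    return loop


def extract_fracture_contours(
    embedded: EmbeddedMesh, line_id: int, axis: Axis,
    cylinder: Optional[ProjectionCylinder] = None,
) -> FractureContours:
    """Extract and consistently orient both layers' loops of an interface.

    Both loops are oriented counter-clockwise when viewed along the bone
    axis; for wall loops (contractible, near-zero plan-view area) the
    orientation is fixed in the unwrapped frame instead, with the inner
    loop matched to the outer loop's sense.
    """
    loops = {}
    for layer in (LABEL_OUTER, LABEL_INNER):
        edges = embedded.edges_of(line_id, layer)
        if not edges:
            raise LayerError(
                f"interface {line_id} has no fracture edges on layer {layer}"
            )
        try:
            loops[layer] = chain_fracture_edges(edges)
        except ContourError:
            # snapping can fold the path back on itself ("spikes"); the
            # ordered resolved chain recovers the loop with spikes removed
            ordered = embedded.contours.get((line_id, layer))
            if ordered is None or not ordered[1]:
                raise
            loops[layer] = _remove_spikes(list(ordered[0]))

    verts = embedded.mesh.vertices
    e1, e2 = _axis_frame(axis.direction)

    def plan_area(loop):
        p = verts[loop] - axis.origin
        x, y = p @ e1, p @ e2
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    a_out = plan_area(loops[LABEL_OUTER])
    a_in = plan_area(loops[LABEL_INNER])
    scale = max(np.abs(verts[loops[LABEL_OUTER]]).max(), 1.0)
    if abs(a_out) > 1e-3 * scale**2:
        # winding loops: both CCW in plan view
        if a_out < 0:
            loops[LABEL_OUTER].reverse()
        if a_in < 0:
            loops[LABEL_INNER].reverse()
    else:
        # wall loops: orient by the unwrapped frame, then match senses
        if cylinder is not None:
            def unwrapped_area(loop):
                p = verts[loop] - axis.origin
                h = p @ axis.direction
                th = np.unwrap(np.arctan2(p @ e2, p @ e1))
                x = th * cylinder.radius
                return 0.5 * float(np.sum(x * np.roll(h, -1) - np.roll(x, -1) * h))
            if unwrapped_area(loops[LABEL_OUTER]) < 0:
                loops[LABEL_OUTER].reverse()
            if unwrapped_area(loops[LABEL_INNER]) < 0:
                loops[LABEL_INNER].reverse()
    return FractureContours(
        outer=loops[LABEL_OUTER], inner=loops[LABEL_INNER], line_id=line_id
    )


# ---------------------------------------------------------------------------
# Triangulation of the fracture zone
# ---------------------------------------------------------------------------

def triangulate_fracture_zone(
    contours: FractureContours, vertices: np.ndarray,
    forbidden_edges: Optional[set] = None,
) -> np.ndarray:
    """Triangulate the cortical cross-section between the two loops.

    Primary path: project both loops on their combined best-fit plane
    (total least squares) and run a constrained Delaunay triangulation of
    the annulus, the inner loop marked as a hole, so the medullary canal
    is never meshed.  The triangulation adds no vertices, so the surface
    boundary is exactly the two input loops.

    If the planar projection is degenerate or self-intersecting (spiral
    fractures, wedge side walls), a ribbon triangulation marching along
    corresponding points of the two loops is used instead.

    Returns (k, 3) vertex indices into ``vertices``.
    """
    outer, inner = contours.outer, contours.inner
    pts = np.concatenate([vertices[outer], vertices[inner]])
    center = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - center, full_matrices=False)
    e1, e2 = vt[0], vt[1]

    def proj(loop):
        p = vertices[loop] - center
        return np.stack([p @ e1, p @ e2], axis=1)

    o2d, i2d = proj(outer), proj(inner)
    faces = _cdt_annulus(o2d, i2d, outer, inner)
    if faces is not None and forbidden_edges:
        # a Delaunay chord may coincide with an existing shell edge (the
        # snapped contour can have mesh-adjacent, loop-non-adjacent
        # vertices); welding it would create a non-manifold edge
        for f in faces:
            for e in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
                if (min(e), max(e)) in forbidden_edges:
                    faces = None
                    break
            if faces is None:
                break
    if faces is None:
        faces = _zipper(outer, inner, vertices)
    return np.asarray(faces, dtype=np.int64)


def _cdt_annulus(o2d, i2d, outer_ids, inner_ids):
    """Constrained Delaunay triangulation of a projected annulus, or None
    if the projection does not form a valid polygon-with-hole."""
    try:
        shell = shapely.Polygon(o2d)
        hole = shapely.Polygon(i2d)
        if not (shell.is_valid and hole.is_valid):
            return None
        if not shell.contains(hole):
            return None
        annulus = shapely.Polygon(o2d, [i2d[::-1]])
        if not annulus.is_valid or annulus.area <= 0:
            return None
        tris = shapely.constrained_delaunay_triangles(annulus)
    except Exception:  # noqa: BLE001 - GEOS failures route to the fallback
        return None
    coord_to_id = {}
    for loop2d, ids in ((o2d, outer_ids), (i2d, inner_ids)):
        for xy, vid in zip(loop2d, ids):
            coord_to_id[(float(xy[0]), float(xy[1]))] = vid
    faces = []
    for geom in tris.geoms:
        xy = list(geom.exterior.coords)[:3]
        try:
            tri = [coord_to_id[(float(x), float(y))] for x, y in xy]
        except KeyError:
            return None  # triangulator introduced a point; fall back
        # orient consistently (+normal of the projection plane)
        ax, ay = xy[0]
        bx, by = xy[1]
        cx, cy = xy[2]
        if (bx - ax) * (cy - ay) - (by - ay) * (cx - ax) < 0:
            tri = [tri[0], tri[2], tri[1]]
        faces.append(tri)
    return faces


def _zipper(outer, inner, vertices):
    """Ribbon triangulation between two correspondingly oriented loops.

    Both loops must already share the traversal sense (guaranteed by
    :func:`extract_fracture_contours`); only the start is aligned here.
    """
    vo = vertices[outer]
    vi = vertices[inner]
    j0 = int(np.argmin(np.linalg.norm(vi - vo[0], axis=1)))
    inner = inner[j0:] + inner[:j0]
    vi = vertices[inner]
    n, m = len(outer), len(inner)
    faces = []
    i = j = 0
    while i < n or j < m:
        adv_outer = False
        if i < n and j < m:
            d_o = np.linalg.norm(vo[(i + 1) % n] - vi[j % m])
            d_i = np.linalg.norm(vo[i % n] - vi[(j + 1) % m])
            adv_outer = d_o <= d_i
        elif i < n:
            adv_outer = True
        if adv_outer:
            faces.append([outer[i % n], outer[(i + 1) % n], inner[j % m]])
            i += 1
        else:
            faces.append([outer[i % n], inner[(j + 1) % m], inner[j % m]])
            j += 1
    return faces


# ---------------------------------------------------------------------------
# Perturbation
# ---------------------------------------------------------------------------

def _interface_rng(config: PerturbationConfig, line_id: int, salt: int):
    # documented seed-splitting rule: fragment/interface order cannot
    # change the draws
    return np.random.default_rng([config.seed, salt, line_id])


def _draw(rng, size, config: PerturbationConfig):
    u = rng.uniform(0.0, 1.0, size) if config.one_sided else rng.uniform(-1.0, 1.0, size)
    return config.tau * u


def perturb_contours(
    mesh: TriangleMesh, contours: FractureContours,
    config: PerturbationConfig,
) -> None:
    """Method A: displace contour vertices along shell-vertex normals.

    Normals are the angle-weighted average of the incident outer/inner
    shell faces.  A displacement that would invert an incident shell face
    is retried at half amplitude up to 5 times, then raises
    :class:`PerturbationError`.  Mutates ``mesh.vertices`` in place —
    call before triangulating the fracture zone.
    """
    if config.tau == 0:
        return
    loop_ids = list(dict.fromkeys(contours.outer + contours.inner))
    normals = _vertex_normals(mesh, loop_ids)
    rng = _interface_rng(config, contours.line_id, 11)
    disp = _draw(rng, len(loop_ids), config)
    incident = _incident_shell_faces(mesh, loop_ids)
    for k, vid in enumerate(loop_ids):
        d = disp[k]
        for attempt in range(6):
            new_pos = mesh.vertices[vid] + d * normals[k]
            if _no_flip(mesh, incident[vid], vid, new_pos):
                mesh.vertices[vid] = new_pos
                break
            if attempt == 5:
                raise PerturbationError(
                    f"vertex {vid}: displacement causes shell "
                    "self-intersection even after 5 halvings"
                )
            d *= 0.5


def _vertex_normals(mesh: TriangleMesh, vertex_ids) -> np.ndarray:
    """Angle-weighted vertex normals from shell (non-fracture) faces."""
    want = set(int(v) for v in vertex_ids)
    acc = {v: np.zeros(3) for v in want}
    labels = mesh.face_labels
    fn = mesh.face_normals()
    for fi, f in enumerate(mesh.faces):
        if labels is not None and labels[fi] == LABEL_FRACTURE:
            continue
        hits = [k for k in range(3) if int(f[k]) in want]
        if not hits:
            continue
        v = mesh.vertices
        for k in hits:
            p = v[f[k]]
            u1 = v[f[(k + 1) % 3]] - p
            u2 = v[f[(k + 2) % 3]] - p
            n1, n2 = np.linalg.norm(u1), np.linalg.norm(u2)
            if n1 == 0 or n2 == 0:
                continue
            ang = np.arccos(np.clip(u1 @ u2 / (n1 * n2), -1, 1))
            acc[int(f[k])] += ang * fn[fi]
    out = np.zeros((len(vertex_ids), 3))
    for k, vid in enumerate(vertex_ids):
        n = acc[int(vid)]
        norm = np.linalg.norm(n)
        out[k] = n / norm if norm > 0 else n
    return out


def _incident_shell_faces(mesh: TriangleMesh, vertex_ids) -> dict:
    want = set(int(v) for v in vertex_ids)
    out: dict = {v: [] for v in want}
    for fi, f in enumerate(mesh.faces):
        for k in range(3):
            if int(f[k]) in want:
                out[int(f[k])].append(fi)
    return out


#: Shell faces with area below this (mm^2) are exempt from the
#: inversion check: slivers left by near-endpoint subdivision cannot
#: produce self-intersection beyond tolerance.
_FLIP_AREA_TOL = 0.05


def _no_flip(mesh, face_ids, vid, new_pos) -> bool:
    v = mesh.vertices
    for fi in face_ids:
        f = mesh.faces[fi]
        old = [v[x] for x in f]
        n_old = np.cross(old[1] - old[0], old[2] - old[0])
        if 0.5 * np.linalg.norm(n_old) < _FLIP_AREA_TOL:
            continue
        p = [new_pos if int(x) == vid else v[x] for x in f]
        n_new = np.cross(p[1] - p[0], p[2] - p[0])
        if n_new @ n_old <= 0:
            return False
    return True


def perturb_surface(
    vertices: np.ndarray, surface_faces: np.ndarray,
    config: PerturbationConfig, line_id: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Method B: centroid-fan refinement with normal displacement.

    Each surface triangle gains an auxiliary point at its centroid,
    displaced along the face normal by a seeded uniform draw; the triangle
    is replaced by the 3-fan around it.  Triangle count triples exactly
    and boundary loops are untouched.  Returns (new vertex array, new
    surface faces); ``vertices`` is extended, not modified.
    """
    faces = np.asarray(surface_faces)
    a = vertices[faces[:, 0]]
    b = vertices[faces[:, 1]]
    c = vertices[faces[:, 2]]
    centroids = (a + b + c) / 3.0
    n = np.cross(b - a, c - a)
    norms = np.linalg.norm(n, axis=1)
    ok = norms > 0
    n[ok] /= norms[ok, None]
    rng = _interface_rng(config, line_id, 13)
    disp = _draw(rng, len(faces), config)
    centroids = centroids + disp[:, None] * n

    base = len(vertices)
    new_vertices = np.concatenate([vertices, centroids])
    cid = base + np.arange(len(faces))
    fan = np.concatenate([
        np.stack([faces[:, 0], faces[:, 1], cid], axis=1),
        np.stack([faces[:, 1], faces[:, 2], cid], axis=1),
        np.stack([faces[:, 2], faces[:, 0], cid], axis=1),
    ])
    return new_vertices, fan


# ---------------------------------------------------------------------------
# Fragment assembly
# ---------------------------------------------------------------------------

@dataclass
class Fragment:
    """One watertight bone fragment (shell patches + fracture surfaces)."""

    fragment_id: int
    mesh: TriangleMesh
    volume: float

    def compact(self) -> TriangleMesh:
        return self.mesh.submesh(np.ones(self.mesh.n_faces, dtype=bool))


def assemble_fragment(
    vertices: np.ndarray,
    shell_faces: np.ndarray,
    shell_labels: np.ndarray,
    surfaces: list,
    fragment_id: int = 0,
) -> Fragment:
    """Weld shell faces with fracture surfaces into a watertight solid.

    Each entry of ``surfaces`` is a (k, 3) face array sharing the vertex
    pool; its orientation is fixed by directed-edge matching against the
    shell (mating fragments receive the same surface flipped).  Raises
    :class:`WeldError` if boundaries do not match or the result is not
    watertight.
    """
    directed = set()
    for f in shell_faces:
        directed.update(
            ((int(f[0]), int(f[1])), (int(f[1]), int(f[2])), (int(f[2]), int(f[0])))
        )
    all_faces = [shell_faces]
    all_labels = [shell_labels]
    for surf in surfaces:
        surf = np.asarray(surf, dtype=np.int64)
        flip = None
        for f in surf:
            for e in ((int(f[0]), int(f[1])), (int(f[1]), int(f[2])),
                      (int(f[2]), int(f[0]))):
                if e in directed:
                    flip = True
                    break
                if (e[1], e[0]) in directed:
                    flip = False
                    break
            if flip is not None:
                break
        if flip is None:
            raise WeldError(
                "fracture surface shares no boundary edge with the shell"
            )
        if flip:
            surf = surf[:, [0, 2, 1]]
        all_faces.append(surf)
        all_labels.append(np.full(len(surf), LABEL_FRACTURE, dtype=np.int64))

    mesh = TriangleMesh(
        vertices,
        np.concatenate(all_faces),
        np.concatenate(all_labels),
    )
    report = validate_mesh(mesh)
    if not report.watertight or not report.orientable:
        raise WeldError(
            f"assembled fragment {fragment_id} is not watertight "
            f"(boundary edges: {report.n_boundary_edges}, "
            f"non-manifold: {report.n_nonmanifold_edges})"
        )
    return Fragment(
        fragment_id=fragment_id, mesh=mesh, volume=mesh.signed_volume()
    )


def split_into_fragments(
    embedded: EmbeddedMesh,
    cylinder: ProjectionCylinder,
    placed_pattern,
    perturbation: PerturbationConfig = PerturbationConfig(),
) -> list:
    """Full closure stage: contours -> perturbation -> surfaces -> solids.

    Shell components are glued across each fracture interface by side
    classification in the unwrapped frame (above/below for winding loops,
    inside/outside for detached-fragment loops), each interface's surface
    is generated once, and every resulting solid is welded watertight.
    Returns the fragments sorted by id (descending volume).
    """
    mesh = embedded.mesh
    axis = cylinder.axis
    labeling = identify_fragments(mesh, embedded.fracture_edges)

    line_ids = sorted({lid for lid, _ in embedded.contours})

    # Method A must move contour vertices before any triangulation; side
    # classification below uses the unperturbed coordinates, so roughness
    # cannot flip a sliver face across the contour
    contour_objs = {}
    for lid in line_ids:
        contour_objs[lid] = extract_fracture_contours(
            embedded, lid, axis, cylinder
        )
    unperturbed = mesh.vertices.copy()
    if perturbation.method == "pre_triangulation":
        for lid in line_ids:
            perturb_contours(mesh, contour_objs[lid], perturbation)

    vertices = mesh.vertices
    mesh_edge_set = set(
        map(tuple, np.sort(mesh.edges(), axis=1).tolist())
    )
    surfaces = {}
    for lid in line_ids:
        loop_edges = set()
        for loop in (contour_objs[lid].outer, contour_objs[lid].inner):
            for a, b in zip(loop, loop[1:] + loop[:1]):
                loop_edges.add((min(a, b), max(a, b)))
        forbidden = mesh_edge_set - loop_edges
        surf = triangulate_fracture_zone(
            contour_objs[lid], vertices, forbidden_edges=forbidden
        )
        if perturbation.method == "post_triangulation":
            vertices, surf = perturb_surface(
                vertices, surf, perturbation, line_id=lid
            )
        surfaces[lid] = surf

    # unwrapped coordinates for side classification (pre-perturbation)
    e1, e2 = _axis_frame(axis.direction)
    p = unperturbed - axis.origin
    h = p @ axis.direction
    theta = np.arctan2(p @ e2, p @ e1) % (2 * np.pi)
    x = theta * cylinder.radius
    C = cylinder.circumference

    edge_to_faces: dict = {}
    for fi, f in enumerate(mesh.faces):
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            edge_to_faces.setdefault((min(a, b), max(a, b)), []).append(fi)

    # union-find over shell regions
    parent = list(range(labeling.n_fragments))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    # per interface, per side: which shell regions touch it.  The side of
    # each adjacent face is decided locally against the DIRECTED contour
    # edge (left/right in the unwrapped frame); the loops' consistent
    # orientation makes "left" agree across layers and across the seam.
    loop_dirs: dict = {}
    for lid in line_ids:
        for layer, loop in ((LABEL_OUTER, contour_objs[lid].outer),
                            (LABEL_INNER, contour_objs[lid].inner)):
            dirs = {}
            n = len(loop)
            for i in range(n):
                a, b = loop[i], loop[(i + 1) % n]
                dirs[(min(a, b), max(a, b))] = (a, b)
            loop_dirs[(lid, layer)] = dirs

    votes: dict = {}  # (lid, region) -> net side vote
    for (e, tags) in embedded.fracture_edges.items():
        for (lid, layer) in tags:
            dirs = loop_dirs[(lid, layer)]
            if e not in dirs:
                continue
            a, b = dirs[e]
            for fi in edge_to_faces.get(e, []):
                region = int(labeling.face_labels[fi])
                f = mesh.faces[fi]
                c = int(next(v for v in f if v != a and v != b))
                side = _edge_side(a, b, c, x, h, C)
                votes[(lid, region)] = votes.get((lid, region), 0) + side
    # each region sits on the side where most of its contour-adjacent
    # faces lie; slivers may cast a few stray votes, majority rules
    interface_sides: dict = {}
    for (lid, region), net in votes.items():
        side = 1 if net > 0 else -1
        interface_sides.setdefault((lid, side), set()).add(region)

    for (lid, side), regions in interface_sides.items():
        regions = sorted(regions)
        for r in regions[1:]:
            ra, rb = find(regions[0]), find(r)
            if ra != rb:
                parent[rb] = ra

    solids: dict = {}
    for region in range(labeling.n_fragments):
        solids.setdefault(find(region), set()).add(region)

    # which solids flank each interface
    fragments = []
    solid_keys = sorted(solids)
    for k, root in enumerate(solid_keys):
        regions = solids[root]
        face_mask = np.isin(labeling.face_labels, list(regions))
        shell_faces = mesh.faces[face_mask]
        shell_labels = (mesh.face_labels[face_mask]
                        if mesh.face_labels is not None
                        else np.zeros(face_mask.sum(), dtype=np.int64))
        my_surfaces = []
        for (lid, side), regs in interface_sides.items():
            if regs & regions:
                my_surfaces.append(surfaces[lid])
        fragments.append(assemble_fragment(
            vertices, shell_faces, shell_labels, my_surfaces, fragment_id=k
        ))
    fragments.sort(key=lambda fr: -fr.volume)
    for k, fr in enumerate(fragments):
        fr.fragment_id = k
    return fragments


def _edge_side(a, b, c, x, h, C) -> int:
    """Is vertex c left (+1) or right (-1) of directed edge a->b in the
    locally unwrapped frame?  The three x coordinates are seam-adjusted
    together, so the test is wrap-safe."""
    xs = np.array([x[a], x[b], x[c]])
    if xs.max() - xs.min() > C / 2:
        xs = np.where(xs < C / 2, xs + C, xs)
    ys = np.array([h[a], h[b], h[c]])
    cross = (xs[1] - xs[0]) * (ys[2] - ys[0]) - (ys[1] - ys[0]) * (xs[2] - xs[0])
    return 1 if cross > 0 else -1
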