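"""Triangle-mesh data model, I/O and geometric primitives.

All coordinates are millimetres by convention: STL/OBJ/PLY carry no unit
metadata, so the package asserts mm throughout and documents it here once.

The central container is :class:`TriangleMesh`, a plain indexed triangle
mesh with an optional per-face ``layer`` label distinguishing the outer
cortical surface, the inner cortical surface (the wall of the medullary
canal) and generated fracture surfaces.  A :class:`CorticalBoneModel`
couples such a mesh with the bone's long axis, from which axial ("height")
coordinates and generalized radii are measured.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import (
    DegeneracyError,
    EmptyBandError,
    EmptyInputError,
    FormatError,
)

logger = logging.getLogger("osteofract")

#: Per-face layer labels.
LABEL_OUTER = 0
LABEL_INNER = 1
LABEL_FRACTURE = 2

#: Faces with area below this (mm^2) are reported as degenerate.
DEGENERATE_AREA_TOL = 1e-10

#: Minimum ratio of the two largest principal extents for a well-defined
#: long axis.
AXIS_SPREAD_RATIO = 1.2


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------

@dataclass
class TriangleMesh:
    """Indexed triangle mesh in mm.

    Parameters
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array
        Vertex indices, counter-clockwise when viewed from outside.
    face_labels : (m,) int array, optional
        ``LABEL_OUTER`` / ``LABEL_INNER`` / ``LABEL_FRACTURE`` per face.
    """

    vertices: np.ndarray
    faces: np.ndarray
    face_labels: Optional[np.ndarray] = None

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise ValueError("face index out of range")
            f = self.faces
            if (
                (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
            ).any():
                raise ValueError("a face repeats a vertex")
        if self.face_labels is not None:
            self.face_labels = np.ascontiguousarray(self.face_labels, dtype=np.int64)
            if self.face_labels.shape != (len(self.faces),):
                raise ValueError("face_labels must be (m,)")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(
            self.vertices.copy(),
            self.faces.copy(),
            None if self.face_labels is None else self.face_labels.copy(),
        )

    # -- derived geometry ---------------------------------------------------

    def face_corners(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        v = self.vertices
        return v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]

    def face_areas(self) -> np.ndarray:
        a, b, c = self.face_corners()
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def face_normals(self) -> np.ndarray:
        """Unit face normals; zero vector for degenerate faces."""
        a, b, c = self.face_corners()
        n = np.cross(b - a, c - a)
        norm = np.linalg.norm(n, axis=1)
        ok = norm > 0
        n[ok] /= norm[ok, None]
        return n

    def signed_volume(self) -> float:
        """Signed enclosed volume (mm^3) by the divergence theorem.

        Meaningful only for closed, consistently oriented meshes; used as
        the exact conservation oracle for fragment assembly (a face and its
        orientation-reversed copy contribute exactly opposite amounts).
        """
        a, b, c = self.face_corners()
        return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)

    def edges(self) -> np.ndarray:
        """All face edges as (3m, 2) directed index pairs."""
        f = self.faces
        return np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])

    def unique_edges(self) -> tuple[np.ndarray, np.ndarray]:
        """Undirected unique edges and their face-degree counts."""
        e = np.sort(self.edges(), axis=1)
        return np.unique(e, axis=0, return_counts=True)

    def submesh(self, face_mask: np.ndarray) -> "TriangleMesh":
        """Extract the faces selected by ``face_mask``, compacting vertices."""
        faces = self.faces[face_mask]
        used, inverse = np.unique(faces, return_inverse=True)
        labels = None if self.face_labels is None else self.face_labels[face_mask]
        return TriangleMesh(self.vertices[used], inverse.reshape(-1, 3), labels)


@dataclass
class Axis:
    """Oriented line: unit direction plus origin point (mm)."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=np.float64)
        d = np.asarray(self.direction, dtype=np.float64)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("axis direction must be non-zero")
        self.direction = d / n

    def axial_coord(self, points: np.ndarray) -> np.ndarray:
        """Scalar projection of points onto the axis ("height", mm)."""
        return (np.atleast_2d(points) - self.origin) @ self.direction

    def radial_distance(self, points: np.ndarray) -> np.ndarray:
        """Perpendicular distance of points from the axis line (mm)."""
        p = np.atleast_2d(points) - self.origin
        t = p @ self.direction
        return np.linalg.norm(p - t[:, None] * self.direction, axis=1)


@dataclass
class CorticalBoneModel:
    """Two-layer cortical shell with its long axis.

    The mesh's ``face_labels`` separate the outer cortical surface from the
    inner (medullary-canal) surface; annular end caps carry the outer label.
    """

    mesh: TriangleMesh
    axis: Axis
    length: float

    def outer_vertex_mask(self) -> np.ndarray:
        """Vertices referenced by at least one outer-labelled face."""
        mask = np.zeros(self.mesh.n_vertices, dtype=bool)
        if self.mesh.face_labels is None:
            mask[:] = True
        else:
            outer = self.mesh.faces[self.mesh.face_labels == LABEL_OUTER]
            mask[np.unique(outer)] = True
        return mask


@dataclass
class MeshQualityReport:
    watertight: bool
    orientable: bool
    n_degenerate: int
    n_nonmanifold_edges: int
    n_boundary_edges: int = 0


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def validate_mesh(mesh: TriangleMesh) -> MeshQualityReport:
    """Diagnose watertightness, orientability and degeneracy.

    A mesh is watertight iff every undirected edge bounds exactly two
    faces; orientable iff no directed edge is repeated (two faces sharing
    an edge traverse it in opposite directions).
    """
    if mesh.n_faces == 0:
        raise EmptyInputError("cannot validate an empty mesh")
    _, counts = mesh.unique_edges()
    watertight = bool((counts == 2).all())
    n_nonmanifold = int((counts > 2).sum())
    n_boundary = int((counts == 1).sum())
    directed = mesh.edges()
    _, dcounts = np.unique(directed, axis=0, return_counts=True)
    orientable = bool((dcounts == 1).all())
    n_degenerate = int((mesh.face_areas() < DEGENERATE_AREA_TOL).sum())
    return MeshQualityReport(
        watertight=watertight,
        orientable=orientable,
        n_degenerate=n_degenerate,
        n_nonmanifold_edges=n_nonmanifold,
        n_boundary_edges=n_boundary,
    )


# ---------------------------------------------------------------------------
# Long axis and generalized radius
# ---------------------------------------------------------------------------

def compute_long_axis(mesh: TriangleMesh) -> Axis:
    """Principal direction of the vertex cloud, anchored at its centroid.

    The long axis of a diaphysis is taken as the first principal component
    of the vertices.  The sign is fixed so the direction has a non-negative
    +Z component (ties broken toward +Y, then +X).

    Raises
    ------
    DegeneracyError
        If the spread ratio of the two largest principal extents is below
        ``AXIS_SPREAD_RATIO`` (isotropic cloud: no well-defined axis).
    """
    v = mesh.vertices
    if len(v) < 4:
        raise DegeneracyError("need at least 4 vertices for an axis")
    centroid = v.mean(axis=0)
    cov = np.cov((v - centroid).T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    extents = np.sqrt(np.clip(evals[order], 0, None))
    if extents[1] <= 0 or extents[0] / extents[1] < AXIS_SPREAD_RATIO:
        raise DegeneracyError(
            f"vertex cloud is too isotropic for a long axis "
            f"(spread ratio {extents[0] / max(extents[1], 1e-300):.3f} < "
            f"{AXIS_SPREAD_RATIO})"
        )
    d = evecs[:, order[0]]
    for comp in (2, 1, 0):
        if abs(d[comp]) > 1e-12:
            if d[comp] < 0:
                d = -d
            break
    return Axis(origin=centroid, direction=d)


def generalized_radius(
    model: CorticalBoneModel, height: float, band: float
) -> float:
    """Band-averaged outer-cortical radius at an axial height.

    Mean perpendicular distance to the axis of the outer-layer vertices
    whose axial coordinate lies in ``[height - band, height + band]``.
    This is the package's stand-in for the local bone thickness used to
    size the projection cylinder and to scale height-map statistics.
    """
    if band <= 0:
        raise ValueError("band half-width must be > 0")
    mask = model.outer_vertex_mask()
    pts = model.mesh.vertices[mask]
    h = model.axis.axial_coord(pts)
    lo, hi = height - band, height + band
    if hi < h.min() or lo > h.max():
        raise EmptyBandError(
            f"band [{lo:g}, {hi:g}] mm lies outside the axial extent "
            f"[{h.min():g}, {h.max():g}] mm"
        )
    in_band = (h >= lo) & (h <= hi)
    if not in_band.any():
        raise EmptyBandError(f"no outer vertices in band [{lo:g}, {hi:g}] mm")
    return float(model.axis.radial_distance(pts[in_band]).mean())


# ---------------------------------------------------------------------------
# I/O: STL (ascii + binary), OBJ, PLY (ascii + binary little-endian)
# ---------------------------------------------------------------------------

_FORMATS = ("stl", "ply", "obj")


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    f = (fmt or path.suffix.lstrip(".")).lower()
    if f not in _FORMATS:
        raise FormatError(f"unsupported mesh format {f!r} (use stl/ply/obj)")
    return f


def read_mesh(path, fmt: Optional[str] = None) -> TriangleMesh:
    """Read a triangle mesh from STL, PLY or OBJ (mm assumed).

    STL stores no vertex indexing: vertices are re-indexed by first
    appearance, merging exactly coincident coordinates, so topology — but
    not the original vertex order — survives an STL round trip.  PLY may
    carry the per-face ``layer`` property written by :func:`write_mesh`.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    f = _infer_format(path, fmt)
    try:
        if f == "stl":
            mesh = _read_stl(path)
        elif f == "obj":
            mesh = _read_obj(path)
        else:
            mesh = _read_ply(path)
    except FormatError:
        raise
    except Exception as exc:  # noqa: BLE001 - wrap parser failures
        raise FormatError(f"could not parse {path} as {f}: {exc}") from exc
    if mesh.n_faces == 0:
        raise EmptyInputError(f"{path} contains no triangles")
    return mesh


def write_mesh(mesh: TriangleMesh, path, fmt: Optional[str] = None, binary: bool = False) -> None:
    """Write a mesh to STL, PLY or OBJ.

    Face labels persist only in PLY (integer face property ``layer``);
    on STL/OBJ export they are dropped with a logged warning.
    """
    path = Path(path)
    f = _infer_format(path, fmt)
    if f != "ply" and mesh.face_labels is not None:
        logger.warning("face labels are dropped on %s export (%s)", f.upper(), path)
    if f == "stl":
        _write_stl(mesh, path, binary=binary)
    elif f == "obj":
        _write_obj(mesh, path)
    else:
        _write_ply(mesh, path, binary=binary)


# -- STL --------------------------------------------------------------------

def _reindex_soup(tri_pts: np.ndarray) -> TriangleMesh:
    """Triangle soup (m, 3, 3) -> indexed mesh, merging identical coords."""
    flat = tri_pts.reshape(-1, 3)
    uniq, first, inverse = np.unique(
        flat, axis=0, return_index=True, return_inverse=True
    )
    # preserve first-appearance order rather than lexicographic order
    order = np.argsort(first)
    rank = np.empty(len(order), dtype=np.int64)
    rank[order] = np.arange(len(order))
    return TriangleMesh(uniq[order], rank[inverse].reshape(-1, 3))


def _read_stl(path: Path) -> TriangleMesh:
    raw = path.read_bytes()
    is_ascii = raw[:5] == b"solid" and b"facet" in raw[:1000]
    if is_ascii:
        pts = []
        for line in raw.decode("utf-8", "replace").splitlines():
            parts = line.split()
            if parts[:1] == ["vertex"]:
                pts.append([float(x) for x in parts[1:4]])
        tri = np.asarray(pts, dtype=np.float64)
        if len(tri) % 3:
            raise FormatError("ASCII STL vertex count not a multiple of 3")
        return _reindex_soup(tri.reshape(-1, 3, 3))
    if len(raw) < 84:
        raise FormatError("binary STL too short")
    (n,) = struct.unpack("<I", raw[80:84])
    rec = np.frombuffer(raw, dtype=np.uint8, count=n * 50, offset=84)
    rec = rec.reshape(n, 50)
    tri = rec[:, 12:48].copy().view("<f4").reshape(n, 3, 3).astype(np.float64)
    return _reindex_soup(tri)


def _write_stl(mesh: TriangleMesh, path: Path, binary: bool) -> None:
    a, b, c = mesh.face_corners()
    n = np.cross(b - a, c - a)
    norm = np.linalg.norm(n, axis=1)
    ok = norm > 0
    n[ok] /= norm[ok, None]
    if binary:
        buf = bytearray(b"\0" * 80)
        buf += struct.pack("<I", mesh.n_faces)
        rec = np.zeros((mesh.n_faces, 50), dtype=np.uint8)
        data = np.concatenate(
            [n, a, b, c], axis=1
        ).astype("<f4").view(np.uint8).reshape(mesh.n_faces, 48)
        rec[:, :48] = data
        buf += rec.tobytes()
        path.write_bytes(bytes(buf))
        return
    with path.open("w") as fh:
        fh.write("solid osteofract\n")
        for i in range(mesh.n_faces):
            fh.write(f"  facet normal {n[i,0]:.17g} {n[i,1]:.17g} {n[i,2]:.17g}\n")
            fh.write("    outer loop\n")
            for p in (a[i], b[i], c[i]):
                fh.write(f"      vertex {p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
            fh.write("    endloop\n  endfacet\n")
        fh.write("endsolid osteofract\n")


# -- OBJ --------------------------------------------------------------------

def _read_obj(path: Path) -> TriangleMesh:
    verts, faces = [], []
    for line in path.read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "v":
            verts.append([float(x) for x in parts[1:4]])
        elif parts[0] == "f":
            idx = [int(tok.split("/")[0]) for tok in parts[1:]]
            idx = [i - 1 if i > 0 else len(verts) + i for i in idx]
            for k in range(1, len(idx) - 1):  # fan-triangulate polygons
                faces.append([idx[0], idx[k], idx[k + 1]])
    if not verts:
        raise FormatError("OBJ contains no vertices")
    return TriangleMesh(np.asarray(verts), np.asarray(faces, dtype=np.int64))


def _write_obj(mesh: TriangleMesh, path: Path) -> None:
    with path.open("w") as fh:
        fh.write("# osteofract OBJ (mm)\n")
        for p in mesh.vertices:
            fh.write(f"v {p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
        for f in mesh.faces + 1:
            fh.write(f"f {f[0]} {f[1]} {f[2]}\n")


# -- PLY --------------------------------------------------------------------

_PLY_DTYPES = {
    "char": "i1", "int8": "i1", "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2", "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4", "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4", "double": "f8", "float64": "f8",
}


def _write_ply(mesh: TriangleMesh, path: Path, binary: bool) -> None:
    has_labels = mesh.face_labels is not None
    fmt = "binary_little_endian" if binary else "ascii"
    header = [
        "ply",
        f"format {fmt} 1.0",
        "comment osteofract (units: mm)",
        f"element vertex {mesh.n_vertices}",
        "property double x",
        "property double y",
        "property double z",
        f"element face {mesh.n_faces}",
        "property list uchar int vertex_indices",
    ]
    if has_labels:
        header.append("property int layer")
    header.append("end_header")
    if binary:
        with path.open("wb") as fh:
            fh.write(("\n".join(header) + "\n").encode())
            fh.write(mesh.vertices.astype("<f8").tobytes())
            fdt = [("n", "u1"), ("idx", "<i4", 3)]
            if has_labels:
                fdt.append(("layer", "<i4"))
            rec = np.zeros(mesh.n_faces, dtype=fdt)
            rec["n"] = 3
            rec["idx"] = mesh.faces
            if has_labels:
                rec["layer"] = mesh.face_labels
            fh.write(rec.tobytes())
        return
    with path.open("w") as fh:
        fh.write("\n".join(header) + "\n")
        for p in mesh.vertices:
            fh.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
        for i, f in enumerate(mesh.faces):
            row = f"3 {f[0]} {f[1]} {f[2]}"
            if has_labels:
                row += f" {mesh.face_labels[i]}"
            fh.write(row + "\n")


def _read_ply(path: Path) -> TriangleMesh:
    raw = path.read_bytes()
    end = raw.find(b"end_header")
    if end < 0:
        raise FormatError("PLY missing end_header")
    header = raw[:end].decode("ascii", "replace").splitlines()
    body = raw[end:]
    body = body[body.find(b"\n") + 1:]

    fmt = None
    elements: list[tuple[str, int, list]] = []  # (name, count, [props])
    for line in header:
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "format":
            fmt = parts[1]
        elif parts[0] == "element":
            elements.append((parts[1], int(parts[2]), []))
        elif parts[0] == "property":
            if not elements:
                raise FormatError("PLY property before element")
            if parts[1] == "list":
                elements[-1][2].append(("list", parts[2], parts[3], parts[4]))
            else:
                elements[-1][2].append(("scalar", parts[1], parts[2]))
    if fmt not in ("ascii", "binary_little_endian"):
        raise FormatError(f"unsupported PLY format {fmt!r}")

    vertices = faces = labels = None
    if fmt == "ascii":
        tokens = body.decode("ascii").split("\n")
        row = 0
        for name, count, props in elements:
            rows = [tokens[row + i].split() for i in range(count)]
            row += count
            if name == "vertex":
                names = [p[2] for p in props if p[0] == "scalar"]
                arr = np.asarray(rows, dtype=np.float64)
                cols = [names.index(c) for c in ("x", "y", "z")]
                vertices = arr[:, cols]
            elif name == "face":
                faces = np.empty((count, 3), dtype=np.int64)
                want_layer = any(
                    p[0] == "scalar" and p[2] == "layer" for p in props
                )
                if want_layer:
                    labels = np.empty(count, dtype=np.int64)
                for i, toks in enumerate(rows):
                    n = int(toks[0])
                    if n != 3:
                        raise FormatError("only triangle PLY faces supported")
                    faces[i] = [int(t) for t in toks[1:4]]
                    if want_layer:
                        labels[i] = int(toks[4])
    else:
        offset = 0
        for name, count, props in elements:
            if name == "vertex":
                dt = np.dtype(
                    [(p[2], "<" + _PLY_DTYPES[p[1]]) for p in props if p[0] == "scalar"]
                )
                rec = np.frombuffer(body, dtype=dt, count=count, offset=offset)
                offset += dt.itemsize * count
                vertices = np.stack(
                    [rec["x"], rec["y"], rec["z"]], axis=1
                ).astype(np.float64)
            elif name == "face":
                lst = next(p for p in props if p[0] == "list")
                cnt_dt = np.dtype("<" + _PLY_DTYPES[lst[1]])
                idx_dt = np.dtype("<" + _PLY_DTYPES[lst[2]])
                extras = [p for p in props if p[0] == "scalar"]
                ex_dt = np.dtype([(p[2], "<" + _PLY_DTYPES[p[1]]) for p in extras]) if extras else None
                faces = np.empty((count, 3), dtype=np.int64)
                if ex_dt is not None and "layer" in ex_dt.names:
                    labels = np.empty(count, dtype=np.int64)
                for i in range(count):
                    n = int(np.frombuffer(body, cnt_dt, 1, offset)[0])
                    offset += cnt_dt.itemsize
                    if n != 3:
                        raise FormatError("only triangle PLY faces supported")
                    faces[i] = np.frombuffer(body, idx_dt, 3, offset)
                    offset += idx_dt.itemsize * 3
                    if ex_dt is not None:
                        rec = np.frombuffer(body, ex_dt, 1, offset)
                        offset += ex_dt.itemsize
                        if labels is not None:
                            labels[i] = int(rec["layer"][0])
            else:
                raise FormatError(f"unsupported PLY element {name!r}")
    if vertices is None or faces is None:
        raise FormatError("PLY lacks vertex or face element")
    return TriangleMesh(vertices, faces, labels)
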