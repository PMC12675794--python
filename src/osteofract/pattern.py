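"""2D fracture patterns: representation, parametric generation, forensic
validation and JSON persistence.

A pattern is the trace of a fracture on the unwrapped bone surface, one
polyline set per cortical layer.  Coordinates are ``(u, v)`` with ``u`` the
normalized circumferential position in ``[0, 1)`` (the seam ``u = 0`` is an
arbitrary but persisted reference meridian; all wrap arithmetic is modulo 1)
and ``v`` the longitudinal position in mm.  Normalizing ``u`` makes the
transverse rescaling applied at projection time explicit and
bone-independent; ``v`` stays metric because fracture extents are
anatomical lengths.

Covered AO/OTA-style types: transverse, oblique, spiral, wedge,
comminuted.  Oblique and spiral lines are constant-slope helices closed by
a vertical connector at the seam; a wedge adds a detached triangular loop
above a transverse line (two lines, three regions); a comminuted pattern
stacks three or more wavy winding loops.

The inner-layer line set is derived from the outer set by a deterministic
longitudinal offset plus seeded bounded smooth noise, emulating the change
of the fracture line as it propagates through the cortical wall.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import scipy.ndimage

from .errors import FormatError, ParameterError

logger = logging.getLogger("osteofract")

FRACTURE_TYPES = ("transverse", "oblique", "spiral", "wedge", "comminuted")
PATTERN_SOURCES = ("drawn", "parametric", "extracted")


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------

@dataclass
class Polyline:
    """Ordered (u, v) points; ``closed`` joins last back to first.

    Points store ``u`` modulo 1.  Consecutive u-steps are interpreted
    minimally (a jump of more than 0.5 is read as a wrap), so a winding
    loop can be stored with wrapped coordinates and recovered exactly.
    """

    points: np.ndarray
    closed: bool = False

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("polyline points must be (n, 2)")
        if len(self.points) < 2:
            raise ValueError("polyline needs at least 2 points")
        u = self.points[:, 0]
        if (u < 0).any() or (u >= 1).any():
            raise ValueError("u coordinates must lie in [0, 1)")

    def unwrapped_u(self) -> np.ndarray:
        """Continuous u coordinates (minimal-step unwrap)."""
        u = self.points[:, 0]
        du = np.diff(u)
        du -= np.round(du)
        return u[0] + np.concatenate([[0.0], np.cumsum(du)])

    def winding(self) -> int:
        """Net number of wraps around the circumference (closed lines)."""
        if not self.closed:
            return 0
        uu = self.unwrapped_u()
        du_close = self.points[0, 0] - self.points[-1, 0]
        du_close -= np.round(du_close)
        return int(np.round(uu[-1] + du_close - uu[0]))

    def length(self, circumference: float) -> float:
        """Arc length in mm for a given circumference (mm)."""
        uu = self.unwrapped_u()
        v = self.points[:, 1]
        du = np.diff(uu) * circumference
        dv = np.diff(v)
        total = float(np.sqrt(du**2 + dv**2).sum())
        if self.closed:
            duc = self.points[0, 0] - self.points[-1, 0]
            duc -= np.round(duc)
            total += float(np.hypot(duc * circumference, v[0] - v[-1]))
        return total

    def segments(self) -> np.ndarray:
        """(s, 2, 2) array of segments in continuous (u, v) coordinates."""
        uu = self.unwrapped_u()
        pts = np.stack([uu, self.points[:, 1]], axis=1)
        segs = np.stack([pts[:-1], pts[1:]], axis=1)
        if self.closed:
            duc = self.points[0, 0] - self.points[-1, 0]
            duc -= np.round(duc)
            closing = np.array([[pts[-1], [uu[-1] + duc, self.points[0, 1]]]])
            segs = np.concatenate([segs, closing])
        return segs


@dataclass
class FracturePattern2D:
    """Dual-layer 2D fracture pattern (the planning object ``P``)."""

    lines_outer: list
    lines_inner: list
    fracture_type: str = "transverse"
    source: str = "parametric"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.fracture_type not in FRACTURE_TYPES:
            raise ValueError(f"unknown fracture type {self.fracture_type!r}")
        if self.source not in PATTERN_SOURCES:
            raise ValueError(f"unknown pattern source {self.source!r}")

    def v_extent(self) -> tuple[float, float]:
        vs = np.concatenate(
            [ln.points[:, 1] for ln in self.lines_outer + self.lines_inner]
        )
        return float(vs.min()), float(vs.max())


# ---------------------------------------------------------------------------
# Parametric generation
# ---------------------------------------------------------------------------

_PARAM_RANGES = {
    "transverse": {"v0": (-500, 500), "waviness": (0.0, 5.0),
                   "n_waves": (1, 8), "n_points": (32, 2048), "u0": (0.0, 1.0)},
    "oblique": {"v0": (-500, 500), "angle_deg": (5.0, 60.0),
                "circumference": (1.0, 1000.0), "n_points": (32, 2048),
                "u0": (0.0, 1.0)},
    "spiral": {"v0": (-500, 500), "angle_deg": (20.0, 75.0),
               "turns": (1.0, 1.0), "circumference": (1.0, 1000.0),
               "n_points": (32, 4096), "u0": (0.0, 1.0)},
    "wedge": {"v0": (-500, 500), "width_u": (0.1, 0.5),
              "height": (2.0, 40.0), "clearance": (1.0, 20.0),
              "waviness": (0.0, 5.0), "n_points": (32, 2048), "u0": (0.0, 1.0)},
    "comminuted": {"v0": (-500, 500), "n_lines": (3, 6),
                   "spacing": (4.0, 40.0), "waviness": (0.0, 4.0),
                   "n_points": (32, 2048), "u0": (0.0, 1.0)},
}

_PARAM_DEFAULTS = {
    "transverse": {"v0": 0.0, "waviness": 0.0, "n_waves": 3, "n_points": 128,
                   "u0": 0.037},
    "oblique": {"v0": 0.0, "angle_deg": 30.0, "circumference": 62.832,
                "n_points": 192, "u0": 0.037},
    "spiral": {"v0": 0.0, "angle_deg": 45.0, "turns": 1.0,
               "circumference": 62.832, "n_points": 256, "u0": 0.037},
    "wedge": {"v0": 0.0, "width_u": 0.3, "height": 12.0, "clearance": 3.0,
              "waviness": 0.0, "n_points": 128, "u0": 0.037},
    "comminuted": {"v0": 0.0, "n_lines": 3, "spacing": 12.0, "waviness": 1.0,
                   "n_points": 128, "u0": 0.037},
}


def _check_params(fracture_type: str, params: dict) -> dict:
    if fracture_type not in FRACTURE_TYPES:
        raise ParameterError(f"unknown fracture type {fracture_type!r}")
    out = dict(_PARAM_DEFAULTS[fracture_type])
    ranges = _PARAM_RANGES[fracture_type]
    for key, val in (params or {}).items():
        if key not in ranges:
            raise ParameterError(f"unknown parameter {key!r} for {fracture_type}")
        lo, hi = ranges[key]
        if not (lo <= val <= hi):
            raise ParameterError(
                f"{fracture_type} parameter {key}={val} outside [{lo}, {hi}]"
            )
        out[key] = val
    return out


def _wavy_loop(v0, waviness, n_waves, n_points, u0, phase) -> Polyline:
    """Closed winding loop at height v0 with sinusoidal waviness."""
    u = (u0 + np.arange(n_points) / n_points) % 1.0
    s = np.arange(n_points) / n_points
    v = v0 + waviness * np.sin(2 * np.pi * n_waves * s + phase)
    return Polyline(np.stack([u, v], axis=1), closed=True)


def _helix_loop(v0, rise, n_points, u0) -> Polyline:
    """One-turn constant-slope loop closed by a vertical seam connector.

    Points run from (u0, v0 - rise/2) around the full circumference to
    (u0, v0 + rise/2); the closing segment drops vertically at the seam.
    """
    i = np.arange(n_points + 1)
    u = (u0 + i / n_points) % 1.0
    u[-1] = u[0]  # exact seam closure
    v = v0 - rise / 2.0 + rise * i / n_points
    return Polyline(np.stack([u, v], axis=1), closed=True)


def generate_parametric_pattern(
    fracture_type: str,
    params: Optional[dict] = None,
    inner_offset: float = 0.0,
    inner_noise: float = 0.0,
    seed: int = 0,
) -> FracturePattern2D:
    """Generate a dual-layer pattern for one AO/OTA-style fracture type.

    ``inner_offset`` shifts the inner-layer lines along v (mm);
    ``inner_noise`` adds seeded smooth periodic noise bounded by that
    amplitude, so inner and outer cut points differ the way a real crack
    front shifts while traversing the cortical wall.  With both zero the
    inner lines equal the outer lines exactly.
    """
    p = _check_params(fracture_type, params)
    rng = np.random.default_rng(seed)
    lines: list[Polyline] = []

    if fracture_type == "transverse":
        lines.append(_wavy_loop(p["v0"], p["waviness"], int(p["n_waves"]),
                                int(p["n_points"]), p["u0"],
                                rng.uniform(0, 2 * np.pi)))
    elif fracture_type in ("oblique", "spiral"):
        rise = p["circumference"] * np.tan(np.radians(p["angle_deg"]))
        if fracture_type == "spiral":
            rise *= p["turns"]
        lines.append(_helix_loop(p["v0"], rise, int(p["n_points"]), p["u0"]))
    elif fracture_type == "wedge":
        lines.append(_wavy_loop(p["v0"], p["waviness"], 3,
                                int(p["n_points"]), p["u0"],
                                rng.uniform(0, 2 * np.pi)))
        # detached region: a truncated triangle (the top edge keeps the
        # narrowest part of the wedge wider than a mesh cell, which a
        # sharp apex cannot guarantee at any mesh resolution)
        base_v = p["v0"] + p["clearance"]
        u1 = p["u0"] + 0.25
        u2 = u1 + p["width_u"]
        shrink = 0.30 * p["width_u"]
        quad = np.array([
            [u1, base_v],
            [u2, base_v],
            [u2 - shrink, base_v + p["height"]],
            [u1 + shrink, base_v + p["height"]],
        ])
        # sample each side so segments stay short relative to mesh cells
        dense = []
        nseg = max(int(p["n_points"]) // 8, 8)
        for a in range(4):
            b = (a + 1) % 4
            t = np.arange(nseg) / nseg
            ua, ub = quad[a, 0], quad[b, 0]
            du = (ub - ua) - np.round(ub - ua)
            dense.append(np.stack([
                (ua + du * t) % 1.0,
                quad[a, 1] + (quad[b, 1] - quad[a, 1]) * t,
            ], axis=1))
        lines.append(Polyline(np.concatenate(dense), closed=True))
    else:  # comminuted
        n_lines = int(p["n_lines"])
        for j in range(n_lines):
            v0 = p["v0"] + (j - (n_lines - 1) / 2.0) * p["spacing"]
            lines.append(_wavy_loop(v0, p["waviness"], 2 + (j % 3),
                                    int(p["n_points"]), p["u0"],
                                    rng.uniform(0, 2 * np.pi)))

    inner = _derive_inner(lines, inner_offset, inner_noise, rng)
    meta = {"params": {k: float(v) for k, v in p.items()},
            "inner_offset": float(inner_offset),
            "inner_noise": float(inner_noise), "seed": int(seed)}
    if "circumference" in p:
        meta["source_circumference"] = float(p["circumference"])
    return FracturePattern2D(
        lines_outer=lines, lines_inner=inner,
        fracture_type=fracture_type, source="parametric", meta=meta,
    )


def _derive_inner(lines, inner_offset, inner_noise, rng) -> list:
    """Inner-layer lines: v-offset plus bounded periodic smooth noise."""
    out = []
    for ln in lines:
        pts = ln.points.copy()
        pts[:, 1] += inner_offset
        if inner_noise > 0:
            n = len(pts)
            s = np.arange(n) / n
            noise = np.zeros(n)
            for k in (1, 2, 3):
                noise += rng.uniform(0.4, 1.0) * np.sin(
                    2 * np.pi * k * s + rng.uniform(0, 2 * np.pi)
                )
            noise *= inner_noise / np.abs(noise).max()
            pts[:, 1] += noise
        out.append(Polyline(pts, closed=ln.closed))
    return out


# ---------------------------------------------------------------------------
# Region counting (rasterized band arrangement)
# ---------------------------------------------------------------------------

def count_regions(
    lines, v_pad: float = 5.0, grid: tuple[int, int] = (512, 256)
) -> int:
    """Number of regions the lines cut the cylindrical band into.

    The band is rasterized on a (u, v) grid that wraps in u; cells touched
    by any line are blocked and the free cells are flood-filled with
    wrap-aware 4-connectivity.  Grid resolution bounds the smallest
    resolvable region at about one cell.
    """
    vs = np.concatenate([ln.points[:, 1] for ln in lines])
    vmin, vmax = vs.min() - v_pad, vs.max() + v_pad
    nu, nv = grid
    blocked = np.zeros((nu, nv), dtype=bool)
    dv = (vmax - vmin) / nv
    for ln in lines:
        for (a, b) in ln.segments():
            length = np.hypot((b[0] - a[0]) * nu, (b[1] - a[1]) / dv)
            n = max(int(np.ceil(length * 2)), 2)
            t = np.linspace(0, 1, n)
            uu = (a[0] + (b[0] - a[0]) * t) % 1.0
            vv = a[1] + (b[1] - a[1]) * t
            iu = np.clip((uu * nu).astype(int), 0, nu - 1)
            iv = np.clip(((vv - vmin) / dv).astype(int), 0, nv - 1)
            blocked[iu, iv] = True
    free = ~blocked
    labels, n_lab = scipy.ndimage.label(
        free, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    )
    # merge labels across the u seam
    parent = list(range(n_lab + 1))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for j in range(nv):
        a, b = labels[0, j], labels[-1, j]
        if a and b:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra
    roots = {find(l) for l in range(1, n_lab + 1)}
    return len(roots)


# ---------------------------------------------------------------------------
# Forensic validation
# ---------------------------------------------------------------------------

@dataclass
class ForensicCriteria:
    """Configurable acceptance thresholds for generated patterns.

    The published forensic threshold tables are not reproduced here; these
    are editable defaults chosen per fracture type, persisted as JSON so a
    forensic expert can tighten them.  Lengths are measured as multiples
    of the reference circumference.
    """

    n_lines: tuple[int, int] = (1, 8)
    total_length: tuple[float, float] = (0.5, 12.0)
    n_fragments: tuple[int, int] = (2, 9)
    max_v_extent: float = 80.0
    reference_circumference: float = 62.832

    def __post_init__(self):
        for lo, hi in (self.n_lines, self.total_length, self.n_fragments):
            if lo > hi:
                raise ValueError("criteria minimum exceeds maximum")

    def to_dict(self) -> dict:
        return {
            "n_lines": list(self.n_lines),
            "total_length": list(self.total_length),
            "n_fragments": list(self.n_fragments),
            "max_v_extent": self.max_v_extent,
            "reference_circumference": self.reference_circumference,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ForensicCriteria":
        return cls(
            n_lines=tuple(d["n_lines"]),
            total_length=tuple(d["total_length"]),
            n_fragments=tuple(d["n_fragments"]),
            max_v_extent=d["max_v_extent"],
            reference_circumference=d["reference_circumference"],
        )


_DEFAULT_CRITERIA = {
    "transverse": ForensicCriteria((1, 1), (0.8, 1.6), (2, 2), 20.0),
    "oblique": ForensicCriteria((1, 1), (1.0, 3.5), (2, 2), 60.0),
    "spiral": ForensicCriteria((1, 1), (1.5, 5.0), (2, 2), 80.0),
    "wedge": ForensicCriteria((2, 2), (1.0, 3.0), (3, 3), 60.0),
    "comminuted": ForensicCriteria((3, 8), (2.5, 12.0), (3, 9), 80.0),
}


def default_criteria(fracture_type: str) -> ForensicCriteria:
    if fracture_type not in _DEFAULT_CRITERIA:
        raise ParameterError(f"unknown fracture type {fracture_type!r}")
    c = _DEFAULT_CRITERIA[fracture_type]
    return ForensicCriteria(c.n_lines, c.total_length, c.n_fragments,
                            c.max_v_extent, c.reference_circumference)


@dataclass
class CriterionResult:
    name: str
    passed: bool
    measured: float
    bounds: tuple


@dataclass
class PatternValidationResult:
    valid: bool
    criteria: list

    def failures(self) -> list:
        return [c for c in self.criteria if not c.passed]


def validate_pattern(
    pattern: FracturePattern2D, criteria: ForensicCriteria
) -> PatternValidationResult:
    """Check a pattern against forensic criteria.

    Three aspects are measured per the forensic-analysis protocol: the
    number of fracture lines, their total length, and the fragments they
    delimit (count plus longitudinal distribution).  An invalid pattern is
    returned with per-criterion reasons, never raised.
    """
    results = []
    C = criteria.reference_circumference

    n_out = len(pattern.lines_outer)
    lo, hi = criteria.n_lines
    results.append(CriterionResult(
        "line count", lo <= n_out <= hi, n_out, (lo, hi)))

    if n_out:
        total = sum(ln.length(C) for ln in pattern.lines_outer) / C
        lo, hi = criteria.total_length
        results.append(CriterionResult(
            "total length (x circumference)", lo <= total <= hi, total, (lo, hi)))

        n_reg = count_regions(pattern.lines_outer)
        lo, hi = criteria.n_fragments
        results.append(CriterionResult(
            "fragment count", lo <= n_reg <= hi, n_reg, (lo, hi)))

        vmin, vmax = pattern.v_extent()
        results.append(CriterionResult(
            "longitudinal extent (mm)", (vmax - vmin) <= criteria.max_v_extent,
            vmax - vmin, (0.0, criteria.max_v_extent)))
    else:
        results.append(CriterionResult(
            "total length (x circumference)", False, 0.0, criteria.total_length))

    return PatternValidationResult(
        valid=all(c.passed for c in results), criteria=results
    )


# ---------------------------------------------------------------------------
# Persistence (JSON, schema 1)
# ---------------------------------------------------------------------------

def write_pattern(pattern: FracturePattern2D, path) -> None:
    doc = {
        "schema": 1,
        "type": pattern.fracture_type,
        "source": pattern.source,
        "lines_outer": [
            {"points": ln.points.tolist(), "closed": ln.closed}
            for ln in pattern.lines_outer
        ],
        "lines_inner": [
            {"points": ln.points.tolist(), "closed": ln.closed}
            for ln in pattern.lines_inner
        ],
        "meta": pattern.meta,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def _parse_lines(doc, key) -> list:
    lines = []
    for i, entry in enumerate(doc.get(key, [])):
        pts = np.asarray(entry.get("points", []), dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
            raise FormatError(f"/{key}/{i}/points: need >= 2 [u, v] pairs")
        bad = np.where((pts[:, 0] < 0) | (pts[:, 0] >= 1))[0]
        if len(bad):
            j = int(bad[0])
            raise FormatError(
                f"/{key}/{i}/points/{j}/0: u = {pts[j, 0]} outside [0, 1)"
            )
        lines.append(Polyline(pts, closed=bool(entry.get("closed", False))))
    return lines


def read_pattern(path) -> FracturePattern2D:
    """Read a schema-1 pattern file; errors name the offending field.

    A file carrying only outer lines is accepted: the inner set is filled
    with a zero-offset copy and a warning is logged.
    """
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON ({exc})") from exc
    if doc.get("schema") != 1:
        raise FormatError(f"/schema: expected 1, got {doc.get('schema')!r}")
    ftype = doc.get("type")
    if ftype not in FRACTURE_TYPES:
        raise FormatError(f"/type: unknown fracture type {ftype!r}")
    source = doc.get("source", "drawn")
    if source not in PATTERN_SOURCES:
        raise FormatError(f"/source: unknown source {source!r}")
    outer = _parse_lines(doc, "lines_outer")
    if not outer:
        raise FormatError("/lines_outer: pattern has no outer lines")
    inner = _parse_lines(doc, "lines_inner")
    if not inner:
        logger.warning(
            "%s: no inner lines; copying outer lines with zero offset", path
        )
        inner = [Polyline(ln.points.copy(), ln.closed) for ln in outer]
    return FracturePattern2D(
        lines_outer=outer, lines_inner=inner,
        fracture_type=ftype, source=source, meta=doc.get("meta", {}),
    )
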