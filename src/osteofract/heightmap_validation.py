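"""Height maps of fracture zones and MMAR/MMAS comparison reports.

A reference plane is placed perpendicular to the bone axis a fixed margin
above the highest point of the fracture zone; the height map is the set
of perpendicular distances from that plane to every fracture-surface
point.  Its arithmetic mean is the "mean map" statistic — MMAR when the
surface comes from a real (reference) fracture, MMAS when it comes from a
simulated one.  To compare bones of different calibre, MMAS is rescaled
by the thickness ratio ``T_original / T_new`` (thickness measured as the
generalized outer radius at the fracture height), and the comparison
reports the distance ``MMAS_scaled - MMAR`` and the percentage variation
``(MMAR - MMAS_scaled) / MMAR * 100``.

Means are margin-sensitive, so every map records its margin and
comparisons require equal margins.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .errors import ConfigError, EmptyInputError
from .mesh_core import Axis, LABEL_FRACTURE, TriangleMesh

logger = logging.getLogger("osteofract")


@dataclass
class HeightMap:
    """Per-point heights (mm) below a reference plane above the zone."""

    heights: np.ndarray
    mask: np.ndarray
    margin: float
    plane_offset: float = 0.0   # axial coordinate of the plane
    meta: dict = field(default_factory=dict)

    def valid(self) -> np.ndarray:
        return self.heights[self.mask]


def build_height_map(
    surface: Union[TriangleMesh, np.ndarray],
    axis: Axis,
    margin: float = 1.0,
) -> HeightMap:
    """Height map of a fracture surface from a plane above it.

    ``surface`` is either a labelled mesh (only ``LABEL_FRACTURE``
    vertices are sampled; an unlabelled mesh uses all vertices) or a bare
    (n, 3) point array.  The plane is perpendicular to ``axis``, placed
    ``margin`` mm above the highest surface point along the axis, so all
    heights are >= margin.
    """
    if isinstance(surface, TriangleMesh):
        if surface.face_labels is not None:
            faces = surface.faces[surface.face_labels == LABEL_FRACTURE]
            if len(faces) == 0:
                raise EmptyInputError("mesh has no fracture-surface faces")
            pts = surface.vertices[np.unique(faces)]
        else:
            pts = surface.vertices
    else:
        pts = np.atleast_2d(np.asarray(surface, dtype=np.float64))
    if len(pts) == 0:
        raise EmptyInputError("fracture surface is empty")
    h = axis.axial_coord(pts)
    plane = h.max() + margin
    heights = plane - h
    return HeightMap(
        heights=heights,
        mask=np.ones(len(heights), dtype=bool),
        margin=margin,
        plane_offset=float(plane),
    )


def mma(hmap: HeightMap) -> float:
    """Mean height over valid samples (the MMAR/MMAS statistic, mm)."""
    v = hmap.valid()
    if len(v) == 0:
        raise EmptyInputError("height map has no valid samples")
    return float(v.mean())


def height_range(hmap: HeightMap) -> float:
    """max - min height over valid samples (mm)."""
    v = hmap.valid()
    if len(v) == 0:
        raise EmptyInputError("height map has no valid samples")
    return float(v.max() - v.min())


@dataclass
class ComparisonReport:
    """Table-style comparison of a real and a simulated fracture zone.

    Invariants (asserted at construction):
    ``mmas_scaled = mmas * t_original / t_new``,
    ``distance = mmas_scaled - mmar``,
    ``percent_variation = (mmar - mmas_scaled) / mmar * 100``.
    """

    mmar: float
    mmas: float
    t_original: float
    t_new: float
    mmas_scaled: float
    range_real: float
    range_sim: float
    distance: float
    percent_variation: Optional[float]
    margin: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        assert np.isclose(self.mmas_scaled,
                          self.mmas * self.t_original / self.t_new,
                          rtol=1e-12)
        assert np.isclose(self.distance, self.mmas_scaled - self.mmar,
                          rtol=0, atol=1e-12)
        if self.percent_variation is not None:
            assert np.isclose(
                self.percent_variation,
                (self.mmar - self.mmas_scaled) / self.mmar * 100.0,
                rtol=1e-9, atol=1e-12,
            )

    def to_dict(self) -> dict:
        return {
            "mmar": self.mmar, "mmas": self.mmas,
            "t_original": self.t_original, "t_new": self.t_new,
            "mmas_scaled": self.mmas_scaled,
            "range_real": self.range_real, "range_sim": self.range_sim,
            "distance": self.distance,
            "percent_variation": self.percent_variation,
            "margin": self.margin, "meta": self.meta,
        }

    def write_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    def csv_row(self) -> str:
        pv = "" if self.percent_variation is None else f"{self.percent_variation:.2f}"
        return (f"{self.t_original:.2f},{self.range_real:.2f},{self.mmar:.2f},"
                f"{self.t_new:.2f},{self.range_sim:.2f},{self.mmas:.2f},"
                f"{self.mmas_scaled:.2f},{self.distance:.2f},{pv}")


def compare(
    real_map: HeightMap,
    sim_map: HeightMap,
    t_original: float,
    t_new: float,
    meta: Optional[dict] = None,
) -> ComparisonReport:
    """Build the comparison report between real and simulated maps.

    No point correspondence is required: the statistics are means and
    ranges.  ``t_original`` / ``t_new`` are the generalized radii of the
    reference and simulated bones at the fracture height.
    """
    if t_new == 0:
        raise ZeroDivisionError("t_new must be non-zero for scaling")
    if real_map.margin != sim_map.margin:
        raise ConfigError(
            f"height maps use different margins "
            f"({real_map.margin} vs {sim_map.margin} mm); means would not "
            "be comparable"
        )
    mmar = mma(real_map)
    mmas = mma(sim_map)
    mmas_scaled = mmas * t_original / t_new
    if mmar == 0:
        logger.warning("MMAR is zero; percentage variation undefined")
        pct = None
    else:
        pct = (mmar - mmas_scaled) / mmar * 100.0
    return ComparisonReport(
        mmar=mmar, mmas=mmas, t_original=t_original, t_new=t_new,
        mmas_scaled=mmas_scaled,
        range_real=height_range(real_map), range_sim=height_range(sim_map),
        distance=mmas_scaled - mmar, percent_variation=pct,
        margin=real_map.margin, meta=meta or {},
    )


def compare_scalar(
    mmar: float, mmas: float, t_original: float, t_new: float,
    range_real: float = 0.0, range_sim: float = 0.0,
) -> ComparisonReport:
    """Comparison arithmetic from already-computed statistics.

    Used to reproduce published comparison tables whose height maps are
    not available: only the printed MMAR/MMAS/radius numbers enter.
    """
    if t_new == 0:
        raise ZeroDivisionError("t_new must be non-zero for scaling")
    mmas_scaled = mmas * t_original / t_new
    pct = None if mmar == 0 else (mmar - mmas_scaled) / mmar * 100.0
    return ComparisonReport(
        mmar=mmar, mmas=mmas, t_original=t_original, t_new=t_new,
        mmas_scaled=mmas_scaled, range_real=range_real, range_sim=range_sim,
        distance=mmas_scaled - mmar, percent_variation=pct,
    )


def distance_from_scaled(mmar: float, mmas_scaled: float) -> float:
    """distance = MMAS_scaled - MMAR (the published tables' convention)."""
    return mmas_scaled - mmar
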