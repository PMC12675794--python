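"""End-to-end orchestration: configuration, the fracture pipeline, and
the six-step validation loop.

``run_fracture`` executes project -> embed -> identify -> close ->
perturb -> export on one bone and one pattern.  ``run_validation`` runs
the reverse loop: detect the fracture zone on a fragment, extract its 2D
pattern, re-apply it to an intact bone, and compare the real and
simulated fracture zones through height-map statistics.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import AmbiguityError, ConfigError
from .fracture_surface import (
    Fragment,
    PerturbationConfig,
    split_into_fragments,
)
from .fragmentation import CutStrategy, embed_cuts, identify_fragments, mesh_quality
from .heightmap_validation import (
    ComparisonReport,
    build_height_map,
    compare,
)
from .mesh_core import (
    CorticalBoneModel,
    LABEL_FRACTURE,
    LABEL_INNER,
    LABEL_OUTER,
    TriangleMesh,
    compute_long_axis,
    read_mesh,
    write_mesh,
)
from .pattern import (
    FracturePattern2D,
    generate_parametric_pattern,
    read_pattern,
)
from .pattern_extraction import detect_fracture_zone, extract_pattern
from .projection import (
    ProjectionCylinder,
    compute_cut_points,
    fit_projection_cylinder,
    place_pattern,
    unwrap_band,
)
from .synthetic_bone import BoneSpec, generate_long_bone

logger = logging.getLogger("osteofract")


@dataclass
class RunConfig:
    """Parameters of one fracture-simulation run.

    Length-like fields are mm.  ``strategy_threshold`` is the hybrid
    approximation threshold (fraction of edge length, default 0.10);
    ``tau`` the perturbation amplitude (0-1 mm).
    """

    input_mesh: Optional[str] = None
    bone: BoneSpec = field(default_factory=BoneSpec)
    pattern_file: Optional[str] = None
    fracture_type: str = "transverse"
    pattern_params: dict = field(default_factory=dict)
    inner_offset: float = 0.5
    inner_noise: float = 0.2
    fracture_height: float = 0.7
    band_halfwidth: float = 40.0
    aspect_limit: float = 2.0
    strategy_mode: str = "hybrid"
    strategy_threshold: float = 0.10
    perturb_method: str = "none"
    tau: float = 0.3
    seed: int = 0
    margin: float = 1.0
    out_dir: Optional[str] = None

    def validate(self) -> None:
        if not (0.0 <= self.strategy_threshold <= 0.5):
            raise ConfigError("strategy threshold must lie in [0, 0.5]")
        if not (0.0 <= self.tau <= 1.0):
            raise ConfigError("tau must lie in [0, 1] mm")
        if self.band_halfwidth <= 0:
            raise ConfigError("band halfwidth must be > 0")
        if self.input_mesh and not Path(self.input_mesh).exists():
            raise ConfigError(f"input mesh not found: {self.input_mesh}")
        if self.pattern_file and not Path(self.pattern_file).exists():
            raise ConfigError(f"pattern file not found: {self.pattern_file}")

    def strategy(self) -> CutStrategy:
        return CutStrategy(self.strategy_mode, self.strategy_threshold)

    def perturbation(self) -> PerturbationConfig:
        return PerturbationConfig(
            method=self.perturb_method, tau=self.tau, seed=self.seed
        )


@dataclass
class FractureResult:
    fragments: list
    manifest: dict
    cylinder: ProjectionCylinder
    embedded: object
    pattern: FracturePattern2D


def _load_bone(config: RunConfig) -> CorticalBoneModel:
    if config.input_mesh:
        mesh = read_mesh(config.input_mesh)
        axis = compute_long_axis(mesh)
        h = axis.axial_coord(mesh.vertices)
        return CorticalBoneModel(mesh=mesh, axis=axis,
                                 length=float(h.max() - h.min()))
    return generate_long_bone(config.bone)


def _load_pattern(config: RunConfig) -> FracturePattern2D:
    if config.pattern_file:
        return read_pattern(config.pattern_file)
    return generate_parametric_pattern(
        config.fracture_type, config.pattern_params,
        inner_offset=config.inner_offset, inner_noise=config.inner_noise,
        seed=config.seed,
    )


def fracture_model(
    model: CorticalBoneModel,
    pattern: FracturePattern2D,
    config: RunConfig,
) -> FractureResult:
    """Apply a pattern to a bone model and return watertight fragments."""
    t0 = time.perf_counter()
    cyl = fit_projection_cylinder(
        model, config.fracture_height, config.band_halfwidth
    )
    placed = place_pattern(
        pattern, cyl, config.fracture_height, aspect_limit=config.aspect_limit
    )
    chains = []
    for layer, lines in ((LABEL_OUTER, placed.outer), (LABEL_INNER, placed.inner)):
        uw = unwrap_band(model, cyl, layer)
        chains.extend(compute_cut_points(uw, lines))
    logger.info("projection: %d cut chains, %d cut points",
                len(chains), sum(len(c.points) for c in chains))

    embedded = embed_cuts(model.mesh, chains, config.strategy())
    logger.info("embedding: %d snapped, %d subdivided, %d fracture edges",
                embedded.n_snapped, embedded.n_subdivided,
                len(embedded.fracture_edges))

    fragments = split_into_fragments(
        embedded, cyl, placed, config.perturbation()
    )
    logger.info("assembly: %d watertight fragments", len(fragments))

    q = mesh_quality(embedded.mesh)
    manifest = {
        "n_fragments": len(fragments),
        "fragment_volumes_mm3": [round(f.volume, 9) for f in fragments],
        "intact_volume_mm3": round(embedded.mesh.signed_volume(), 9),
        "quality_mean_q": round(float(np.mean(q[np.isfinite(q)])), 9),
        "quality_max_q": round(float(np.max(q[np.isfinite(q)])), 9),
        "n_snapped": embedded.n_snapped,
        "n_subdivided": embedded.n_subdivided,
        "strategy": {"mode": config.strategy_mode,
                     "threshold": config.strategy_threshold},
        "perturbation": {"method": config.perturb_method, "tau": config.tau},
        "seed": config.seed,
        "fracture_type": pattern.fracture_type,
        "timing_s": round(time.perf_counter() - t0, 3),
    }
    return FractureResult(
        fragments=fragments, manifest=manifest, cylinder=cyl,
        embedded=embedded, pattern=pattern,
    )


def run_fracture(config: RunConfig) -> FractureResult:
    """Full pipeline from a :class:`RunConfig`, optionally writing
    per-fragment PLY files and a JSON manifest to ``config.out_dir``."""
    config.validate()
    model = _load_bone(config)
    pattern = _load_pattern(config)
    result = fracture_model(model, pattern, config)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        files = []
        for fr in result.fragments:
            path = out / f"fragment_frag{fr.fragment_id}.ply"
            write_mesh(fr.compact(), path)
            files.append(path.name)
        result.manifest["fragment_files"] = files
        (out / "manifest.json").write_text(
            json.dumps(result.manifest, indent=1)
        )
    return result


def run_validation(
    real_fragment: TriangleMesh,
    intact_model: CorticalBoneModel,
    config: RunConfig,
) -> ComparisonReport:
    """Validation steps 2-6: zone detection through height-map comparison.

    The fragment's fracture zone is detected geometrically, converted to
    a 2D pattern in the fragment's own cylinder frame, re-applied to the
    intact model at the configured height, and the two fracture zones are
    compared via MMAR/MMAS with radius-ratio scaling.
    """
    config.validate()
    zone = detect_fracture_zone(real_fragment)
    if zone.empty:
        raise AmbiguityError("no fracture zone detected on the fragment")

    real_axis = compute_long_axis(real_fragment)
    outer_pts = zone.points[zone.layers == 0]
    r_real = float(real_axis.radial_distance(outer_pts).mean())
    h_zone = real_axis.axial_coord(zone.points)
    real_cyl = ProjectionCylinder(
        axis=real_axis, radius=r_real,
        band=(float(h_zone.min()) - 1.0, float(h_zone.max()) + 1.0),
    )

    # an extracted line is jagged at the source mesh's scale; if the
    # target mesh cannot host that detail, re-extract with stronger
    # simplification instead of failing outright
    from .errors import (
        ContourError,
        RefinementRequestError,
        TopologyError,
        WeldError,
    )
    retryable = (RefinementRequestError, TopologyError, ContourError, WeldError)
    sim = None
    last_exc = None
    for simplify in (None, 1.0, 2.0, 4.0):
        pattern = extract_pattern(zone, real_cyl, simplify=simplify)
        pattern.fracture_type = config.fracture_type
        try:
            sim = fracture_model(intact_model, pattern, config)
            break
        except retryable as exc:
            last_exc = exc
            logger.info("re-extracting with simplification %s mm: %s",
                        simplify, exc)
    if sim is None:
        raise last_exc

    real_map = build_height_map(zone.points, real_axis, margin=config.margin)
    surf_mask = sim.embedded.mesh.face_labels is not None
    frag0 = sim.fragments[0].mesh
    sim_pts = frag0.vertices[
        np.unique(frag0.faces[frag0.face_labels == LABEL_FRACTURE])
    ]
    sim_map = build_height_map(sim_pts, sim.cylinder.axis, margin=config.margin)

    return compare(
        real_map, sim_map,
        t_original=r_real, t_new=sim.cylinder.radius,
        meta={"n_zone_points": int(len(zone.points)),
              "n_sim_surface_points": int(len(sim_pts))},
    )
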