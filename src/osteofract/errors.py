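"""Exception hierarchy.

Every error raised by this package derives from :class:`OsteofractError`,
so callers (and the CLI) can separate geometric failures from bad input.
"""


class OsteofractError(Exception):
    """Base class for all package errors."""


class ConfigError(OsteofractError):
    """Invalid run configuration or out-of-range parameter."""


class FormatError(OsteofractError):
    """A file could not be parsed as the expected format/schema."""


class EmptyInputError(OsteofractError):
    """An operation received an empty mesh, map, or point set."""


class DegeneracyError(OsteofractError):
    """Geometric degeneracy: collinear triangle, isotropic point cloud, ..."""


class EmptyBandError(OsteofractError):
    """An axial band contains no vertices / lies outside the bone."""


class ParameterError(ConfigError):
    """Pattern-generation parameter outside its documented range."""


class ScaleInfeasibleError(OsteofractError):
    """Pattern placement would exceed the allowed aspect-ratio distortion."""


class BandError(OsteofractError):
    """Placed pattern extends beyond the projection band."""


class OpenLineError(OsteofractError):
    """A non-closed fracture line terminates strictly inside the band."""


class GeometryError(OsteofractError):
    """Robustness failure: seam-spanning face, self-intersecting loops, ..."""


class TopologyError(OsteofractError):
    """Cut embedding collapsed or disconnected the fracture path."""


class RefinementRequestError(OsteofractError):
    """More than two cut points fell on one face; refine mesh or simplify
    the pattern."""


class ContourError(OsteofractError):
    """Fracture edges do not chain into the expected closed loop(s)."""


class LayerError(OsteofractError):
    """A cortical layer is missing required fracture edges."""


class PerturbationError(OsteofractError):
    """Perturbation could not be applied without shell self-intersection."""


class WeldError(OsteofractError):
    """Fracture-surface boundary does not match the shell contour."""


class AmbiguityError(OsteofractError):
    """Point chaining hit an unresolvable branch."""
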