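"""Exception hierarchy shared by all pipeline stages.

Validation failures map to CLI exit code 2, geometric degeneracy and
infeasible configurations to exit code 3.
"""


class JointRomError(Exception):
    """Base class for all package errors."""


class ValidationError(JointRomError):
    """Malformed or out-of-contract input (exit code 2)."""


class InvalidAngleError(ValidationError):
    """Non-finite Euler angle."""


class InvalidRotationError(ValidationError):
    """Matrix is not a proper rotation within tolerance."""


class InvalidTransformError(ValidationError):
    """Rigid transform with an invalid rotation part."""


class FormatError(ValidationError):
    """File does not match a declared header/layout."""


class MissingLabelError(ValidationError):
    """Trial lacks the sweep-sequence / planar label needed by a rule."""


class MissingReferenceError(ValidationError):
    """Axis-sign disambiguation requested but no reference point given."""


class IncompatibleDataError(ValidationError):
    """Mixing joints/sides/conventions that cannot be pooled."""


class EmptyInputError(ValidationError):
    """Operation requires at least one element."""


class GeometryError(JointRomError):
    """Degenerate or infeasible geometry (exit code 3)."""


class DegenerateGeometryError(GeometryError):
    """Point cloud cannot support the requested primitive fit."""


class InsufficientMarkersError(GeometryError):
    """Fewer than three visible, non-collinear markers in a frame."""


class RegionTooLargeError(GeometryError):
    """Axis-tip cloud does not fit in an open hemisphere."""


class InvalidModelError(GeometryError):
    """Joint-limit model is self-inconsistent."""


class InfeasibleStrideError(GeometryError):
    """Stride envelope exits the (shrunken) feasible set."""
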