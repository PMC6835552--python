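"""Typed exceptions raised by the geometry and pipeline layers."""


class GeometryError(ValueError):
    """Base class for degenerate geometric configurations."""


class DegeneratePitchError(GeometryError):
    """Eye pitch at or beyond ±90°, where the yaw/pitch parameterization folds."""


class GimbalLockError(GeometryError):
    """Optical axis within numerical tolerance of the device column axis (0, ±1, 0)."""


class CoincidentPointsError(GeometryError):
    """Pupil center and cornea-curvature center coincide; no optical axis."""


class DegenerateFrameError(GeometryError):
    """Eye-coordinate-system frame undefined: optical axis parallel to y_device."""


class NoIntersectionError(GeometryError):
    """Visual axis does not point toward the display plane."""


class ConvergenceError(RuntimeError):
    """Iterative solver failed to converge within its iteration budget."""


class SessionSchemaError(ValueError):
    """Session file violates the per-frame CSV schema."""


class InsufficientTargetsError(ValueError):
    """Too few distinct fixation targets for the requested estimation."""
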