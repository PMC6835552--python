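"""Oculomotor geometry in the device coordinate system (DCS).

The model underlying the whole package: the optical axis of the eye is the
line through the center of corneal curvature ``c`` and the pupil center
``p``; the visual axis (the line of sight, through the fovea) is offset from
it by fixed subject-specific angles ``alpha`` (horizontal) and ``beta``
(vertical), together often called the kappa angle.  Because those offsets are
constant only in a frame rigid to the eye, we build an eye coordinate system
(ECS) whose z-axis is the optical axis, express the visual axis there, and
rotate it back into the DCS.  The relative roll angle ``lam`` between eye and
device — the R-Roll, which changes freely when a phone is held in the hand —
enters as a rotation of the ECS basis about the optical axis.

Conventions
-----------
* DCS: right-handed, origin at the display center, x along display rows,
  y along columns (toward the front camera), z out of the display toward the
  subject.  The display plane is z = 0.  Positions are millimetres.
* All angles at the public boundary are degrees; radians are internal.
* The ECS basis written as matrix columns ``[x_eye y_eye z_eye]`` has
  determinant −1 in the frontal pose (x=(1,0,0), y=(0,1,0), z=(0,0,−1));
  this is the normative convention fixed by the roll rotation matrix
  ``[[cos λ, −sin λ, 0], [sin λ, cos λ, 0], [0, 0, −1]]``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    CoincidentPointsError,
    DegenerateFrameError,
    DegeneratePitchError,
    GimbalLockError,
    NoIntersectionError,
)

__all__ = [
    "Y_DEVICE",
    "EyeAngles",
    "SubjectEyeParams",
    "Screen",
    "ECSFrame",
    "PoG",
    "unit",
    "optical_axis_from_angles",
    "angles_from_direction",
    "optical_axis_from_pc",
    "visual_axis_in_ecs",
    "ecs_frame",
    "visual_axis_in_dcs",
    "visual_axis_euler",
    "pog_on_screen",
]

#: Unit vector along the device column axis (y of the DCS).
Y_DEVICE = np.array([0.0, 1.0, 0.0])

_PARALLEL_TOL = 1e-9


def _as_point(v, name: str = "point") -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} has non-finite components: {arr}")
    return arr


def unit(v, name: str = "vector") -> np.ndarray:
    """Return ``v`` normalized to unit length (tolerance 1e-12)."""
    arr = _as_point(v, name)
    n = float(np.linalg.norm(arr))
    if n < 1e-12:
        raise ValueError(f"{name} has near-zero norm, cannot normalize")
    return arr / n


@dataclass(frozen=True)
class EyeAngles:
    """Horizontal (yaw) and vertical (pitch) angles of the eye, degrees."""

    theta_deg: float
    phi_deg: float

    def __post_init__(self) -> None:
        if not abs(self.phi_deg) < 90.0:
            raise DegeneratePitchError(
                f"pitch {self.phi_deg}° is degenerate (|phi| must be < 90°)"
            )


@dataclass(frozen=True)
class SubjectEyeParams:
    """Angular offsets between the optical and visual axes (degrees).

    ``alpha_deg`` is the horizontal offset, ``beta_deg`` the vertical one.
    Adult values are a few degrees; anything beyond ±10° is rejected as a
    unit mix-up rather than an eye.
    """

    alpha_deg: float
    beta_deg: float

    def __post_init__(self) -> None:
        for name, v in (("alpha_deg", self.alpha_deg), ("beta_deg", self.beta_deg)):
            if not np.isfinite(v) or abs(v) > 10.0:
                raise ValueError(f"{name}={v} outside the plausible range ±10°")

    @property
    def offset_magnitude_deg(self) -> float:
        """sqrt(alpha² + beta²), the overall optical/visual-axis separation."""
        return math.hypot(self.alpha_deg, self.beta_deg)


@dataclass(frozen=True)
class Screen:
    """Display geometry: the z = 0 plane of the DCS, origin at its center."""

    width_mm: float = 110.0
    height_mm: float = 62.0

    def __post_init__(self) -> None:
        if not (self.width_mm > 0 and self.height_mm > 0):
            raise ValueError("screen dimensions must be positive")

    @property
    def diagonal_mm(self) -> float:
        return math.hypot(self.width_mm, self.height_mm)

    def contains(self, x_mm: float, y_mm: float) -> bool:
        return abs(x_mm) <= self.width_mm / 2 and abs(y_mm) <= self.height_mm / 2


@dataclass(frozen=True)
class ECSFrame:
    """Eye-coordinate-system basis vectors expressed in the DCS.

    ``z_eye`` is the optical axis; ``x_eye``/``y_eye`` span the plane normal
    to it, rolled by the R-Roll angle.  ``rotation`` stacks them as columns,
    giving the matrix that maps ECS vectors into the DCS.
    """

    x_eye: np.ndarray
    y_eye: np.ndarray
    z_eye: np.ndarray

    @property
    def rotation(self) -> np.ndarray:
        return np.column_stack([self.x_eye, self.y_eye, self.z_eye])


@dataclass(frozen=True)
class PoG:
    """A point-of-gaze estimate on the display plane (mm)."""

    x_mm: float
    y_mm: float
    on_screen: bool = True

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x_mm, self.y_mm])


def optical_axis_from_angles(angles: EyeAngles) -> np.ndarray:
    """Optical-axis direction from yaw/pitch.

    Returns ``(sin θ cos φ, sin φ, −cos θ cos φ)``: the frontal pose
    (θ=φ=0) looks along −z, straight into the display.
    """
    th = math.radians(angles.theta_deg)
    ph = math.radians(angles.phi_deg)
    return np.array(
        [math.sin(th) * math.cos(ph), math.sin(ph), -math.cos(th) * math.cos(ph)]
    )


def angles_from_direction(omega) -> EyeAngles:
    """Invert :func:`optical_axis_from_angles` (degrees; gimbal at ±y)."""
    w = unit(omega, "omega")
    if 1.0 - abs(w[1]) < _PARALLEL_TOL:
        raise GimbalLockError("optical axis along ±y_device: yaw undefined")
    theta = math.degrees(math.atan2(w[0], -w[2]))
    phi = math.degrees(math.asin(np.clip(w[1], -1.0, 1.0)))
    return EyeAngles(theta_deg=theta, phi_deg=phi)


def optical_axis_from_pc(p, c) -> np.ndarray:
    """Unit direction of the optical axis, from cornea center toward pupil."""
    pv = _as_point(p, "p")
    cv = _as_point(c, "c")
    d = pv - cv
    n = float(np.linalg.norm(d))
    if n < 1e-9:
        raise CoincidentPointsError("pupil center coincides with cornea center")
    return d / n


def visual_axis_in_ecs(params: SubjectEyeParams) -> np.ndarray:
    """Visual-axis direction in the eye frame: (sin α cos β, sin β, cos α cos β)."""
    a = math.radians(params.alpha_deg)
    b = math.radians(params.beta_deg)
    return np.array(
        [math.sin(a) * math.cos(b), math.sin(b), math.cos(a) * math.cos(b)]
    )


def ecs_frame(omega, lam_deg: float) -> ECSFrame:
    """Construct the ECS basis in the DCS for optical axis ``omega``, rolled by ``lam_deg``.

    The zero-roll x axis is ``normalize(ω × y_device)`` and the y axis
    ``x × z``; rolling mixes x and y about the optical axis:
    ``x_λ = cos λ · x₀ + sin λ · y₀``, ``y_λ = −sin λ · x₀ + cos λ · y₀``.
    Undefined when the optical axis is parallel to the device column axis.
    An already-unit ``omega`` is used bit-exactly as ``z_eye``.
    """
    w = _as_point(omega, "omega")
    n = float(np.linalg.norm(w))
    if abs(n - 1.0) > 1e-9:
        w = unit(w, "omega")
    x0 = np.cross(w, Y_DEVICE)
    n = float(np.linalg.norm(x0))
    if n < _PARALLEL_TOL:
        raise DegenerateFrameError(
            "optical axis parallel to y_device: ECS roll reference undefined"
        )
    x0 /= n
    y0 = np.cross(x0, w)
    lam = math.radians(lam_deg)
    cl, sl = math.cos(lam), math.sin(lam)
    return ECSFrame(x_eye=cl * x0 + sl * y0, y_eye=-sl * x0 + cl * y0, z_eye=w)


def visual_axis_in_dcs(omega, params: SubjectEyeParams, lam_deg: float) -> np.ndarray:
    """Visual-axis direction in the DCS for a given optical axis and R-Roll."""
    frame = ecs_frame(omega, lam_deg)
    return frame.rotation @ visual_axis_in_ecs(params)


def visual_axis_euler(angles: EyeAngles, params: SubjectEyeParams) -> np.ndarray:
    """Visual axis via added Euler offsets: the fixed-frame parameterization.

    ``(sin(θ+α) cos(φ+β), sin(φ+β), −cos(θ+α) cos(φ+β))``.  Agrees exactly
    with the ECS route at φ = 0 and to second order elsewhere; kept as an
    independent cross-check of the frame construction.
    """
    th = math.radians(angles.theta_deg + params.alpha_deg)
    ph = math.radians(angles.phi_deg + params.beta_deg)
    if not abs(angles.phi_deg + params.beta_deg) < 90.0:
        raise DegeneratePitchError("phi + beta at or beyond ±90°")
    return np.array(
        [math.sin(th) * math.cos(ph), math.sin(ph), -math.cos(th) * math.cos(ph)]
    )


def pog_on_screen(c, nu, screen: Screen | None = None) -> PoG:
    """Intersect the visual-axis ray from ``c`` with the display plane z = 0.

    The ray is ``c + t·ν`` with t > 0; requires the eye in front of the
    display (c.z > 0) and the axis directed toward it (ν.z < 0).  When a
    :class:`Screen` is supplied, off-panel intersections are flagged via
    ``on_screen`` rather than raised or clamped.
    """
    cv = _as_point(c, "c")
    n = unit(nu, "nu")
    if cv[2] <= 0:
        raise NoIntersectionError(f"eye position must have c.z > 0, got {cv[2]}")
    if n[2] >= -1e-9:
        raise NoIntersectionError("visual axis does not point toward the display")
    t = -cv[2] / n[2]
    x = cv[0] + t * n[0]
    y = cv[1] + t * n[1]
    on = screen.contains(x, y) if screen is not None else True
    return PoG(x_mm=float(x), y_mm=float(y), on_screen=on)


def pog_batch(
    P: np.ndarray,
    C: np.ndarray,
    alpha_deg: float,
    beta_deg: float,
    lam_deg: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized pupil/cornea → PoG for n frames.

    Parameters are arrays of shape (n, 3), (n, 3) and (n,); returns
    ``(pog, valid)`` with ``pog`` of shape (n, 2) (NaN where invalid) and a
    boolean validity mask.  Frames with a degenerate optical axis, a frame
    parallel to y_device, an eye behind the display or a visual axis that
    misses the display plane are marked invalid instead of raising — this is
    the per-frame contract of the evaluation pipeline.
    """
    P = np.asarray(P, float)
    C = np.asarray(C, float)
    lam = np.deg2rad(np.asarray(lam_deg, float))
    d = P - C
    dn = np.linalg.norm(d, axis=1)
    valid = dn > 1e-9
    dn_safe = np.where(valid, dn, 1.0)
    omega = d / dn_safe[:, None]

    x0 = np.cross(omega, Y_DEVICE)
    x0n = np.linalg.norm(x0, axis=1)
    valid &= x0n > _PARALLEL_TOL
    x0 = x0 / np.where(valid, x0n, 1.0)[:, None]
    y0 = np.cross(x0, omega)

    cl = np.cos(lam)[:, None]
    sl = np.sin(lam)[:, None]
    xe = cl * x0 + sl * y0
    ye = -sl * x0 + cl * y0

    a = math.radians(alpha_deg)
    b = math.radians(beta_deg)
    sx = math.sin(a) * math.cos(b)
    sy = math.sin(b)
    cz = math.cos(a) * math.cos(b)
    nu = sx * xe + sy * ye + cz * omega

    valid &= (C[:, 2] > 0) & (nu[:, 2] < -1e-9)
    t = -C[:, 2] / np.where(nu[:, 2] < -1e-9, nu[:, 2], -1.0)
    pog = C[:, :2] + t[:, None] * nu[:, :2]
    pog = np.where(valid[:, None], pog, np.nan)
    return pog, valid
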