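"""Subject calibration: estimating the optical/visual-axis offsets (α, β).

The tracker's geometry needs two subject-specific numbers — the horizontal
and vertical kappa offsets between the optical and visual axes.  They are
recovered from a calibration session in which the subject fixates known
targets at a known (usually zero) R-Roll: for candidate (α, β), every
frame's optical axis is rotated into a visual axis and intersected with the
display, and the squared on-screen distances to the fixated targets are
minimized by bounded nonlinear least squares.

The loss is in screen millimetres, matching how fixation accuracy is
reported; frames whose initial PoG lands more than three screen diagonals
from their target are discarded as degenerate feature-noise draws before
fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import InsufficientTargetsError
from .geometry import SubjectEyeParams, pog_batch
from .session import Session, apply_subject  # noqa: F401  (re-export)

__all__ = ["CalibrationResult", "estimate_alpha_beta", "apply_subject"]

logger = logging.getLogger(__name__)

_OUTLIER_DIAGONALS = 3.0


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of an α/β calibration fit."""

    params: SubjectEyeParams
    rms_residual_mm: float
    n_samples_used: int
    n_outliers_dropped: int
    converged: bool


def estimate_alpha_beta(
    session: Session,
    lam_cal_deg: float = 0.0,
    bound_deg: float = 10.0,
    tol: float = 1e-10,
) -> CalibrationResult:
    """Fit the subject's (α, β) to a known-target calibration session.

    ``lam_cal_deg`` is the R-Roll assumed during calibration (0 for the
    standard protocol, where calibration defines the roll reference).
    Requires at least two distinct fixation targets — one target cannot
    separate the two offsets from the eye orientation.
    """
    f = session.frames
    if f["target_id"].nunique() < 2:
        raise InsufficientTargetsError(
            "calibration needs ≥ 2 distinct fixation targets for 2 unknowns"
        )
    P = f[["p_x", "p_y", "p_z"]].to_numpy()
    C = f[["c_x", "c_y", "c_z"]].to_numpy()
    T = f[["target_x_mm", "target_y_mm"]].to_numpy()
    lam = np.full(len(f), float(lam_cal_deg))

    # outlier screen: PoG at the initial guess further than 3 diagonals
    pog0, valid0 = pog_batch(P, C, 0.0, 0.0, lam)
    dist0 = np.hypot(*(pog0 - T).T)
    keep = valid0 & (dist0 < _OUTLIER_DIAGONALS * session.screen.diagonal_mm)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("calibration dropped %d outlier/invalid frame(s)", n_dropped)
    if not keep.any():
        raise InsufficientTargetsError("no usable calibration frames after outlier screen")
    P, C, T, lam = P[keep], C[keep], T[keep], lam[keep]

    def residuals(x: np.ndarray) -> np.ndarray:
        pog, valid = pog_batch(P, C, x[0], x[1], lam)
        r = pog - T
        r[~valid] = 0.0
        return r.ravel()

    fit = least_squares(
        residuals,
        x0=np.zeros(2),
        bounds=(-bound_deg, bound_deg),
        xtol=tol,
        ftol=tol,
        gtol=tol,
        method="trf",
    )
    if not fit.success:
        logger.warning("calibration did not converge: %s", fit.message)
    # RMS of the 2-D residual distances
    res = fit.fun.reshape(-1, 2)
    rms = float(np.sqrt(np.mean(np.sum(res**2, axis=1))))
    return CalibrationResult(
        params=SubjectEyeParams(alpha_deg=float(fit.x[0]), beta_deg=float(fit.x[1])),
        rms_residual_mm=rms,
        n_samples_used=len(P),
        n_outliers_dropped=n_dropped,
        converged=bool(fit.success),
    )
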