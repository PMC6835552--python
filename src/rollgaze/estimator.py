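"""Scikit-learn-style front end: calibrate once, predict PoG per frame.

``PoGEstimator`` wraps the calibration + geometry pipeline in the familiar
fit/predict shape: ``fit`` runs the α/β least-squares calibration on a
known-target session, ``predict`` maps frames to on-screen gaze coordinates
using either roll policy.  It subclasses :class:`sklearn.base.BaseEstimator`,
so ``get_params``/``set_params``/``clone`` and pipeline composition work as
usual.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .calibration import estimate_alpha_beta
from .geometry import SubjectEyeParams, pog_batch
from .metrics import estimate_session, error_report
from .session import Session

__all__ = ["PoGEstimator"]


class PoGEstimator(BaseEstimator):
    """Point-of-gaze estimator with optional relative-roll compensation.

    Parameters
    ----------
    method : {1, 2}
        1 assumes the device roll is always 0 (the desktop assumption);
        2 compensates with the per-frame measured R-Roll.
    lam_cal_deg : float
        R-Roll assumed during the calibration session.
    bound_deg : float
        Box bound on the fitted kappa offsets |α|, |β|.
    tol : float
        Least-squares convergence tolerance (xtol/ftol/gtol).

    Attributes
    ----------
    alpha_deg_, beta_deg_ : float
        Calibrated optical/visual-axis offsets.
    rms_residual_mm_ : float
        RMS on-screen calibration residual.
    n_samples_used_ : int
        Calibration frames kept after the outlier screen.
    converged_ : bool
        Whether the least-squares fit reported convergence.
    """

    def __init__(
        self,
        method: int = 2,
        lam_cal_deg: float = 0.0,
        bound_deg: float = 10.0,
        tol: float = 1e-10,
    ):
        self.method = method
        self.lam_cal_deg = lam_cal_deg
        self.bound_deg = bound_deg
        self.tol = tol

    def fit(self, X: Session, y=None) -> "PoGEstimator":
        """Calibrate α, β on a session whose frames carry their fixated targets."""
        if self.method not in (1, 2):
            raise ValueError(f"method must be 1 or 2, got {self.method!r}")
        result = estimate_alpha_beta(
            X, lam_cal_deg=self.lam_cal_deg, bound_deg=self.bound_deg, tol=self.tol
        )
        self.alpha_deg_ = result.params.alpha_deg
        self.beta_deg_ = result.params.beta_deg
        self.rms_residual_mm_ = result.rms_residual_mm
        self.n_samples_used_ = result.n_samples_used
        self.converged_ = result.converged
        return self

    @property
    def subject_params_(self) -> SubjectEyeParams:
        check_is_fitted(self, "alpha_deg_")
        return SubjectEyeParams(alpha_deg=self.alpha_deg_, beta_deg=self.beta_deg_)

    def predict(self, X: Session | pd.DataFrame) -> np.ndarray:
        """Per-frame PoG estimates, shape (n_frames, 2) in mm (NaN if invalid)."""
        check_is_fitted(self, "alpha_deg_")
        frames = X.frames if isinstance(X, Session) else X
        P = frames[["p_x", "p_y", "p_z"]].to_numpy()
        C = frames[["c_x", "c_y", "c_z"]].to_numpy()
        lam = (
            np.zeros(len(frames))
            if self.method == 1
            else frames["lam_measured_deg"].to_numpy(dtype=float)
        )
        pog, _ = pog_batch(P, C, self.alpha_deg_, self.beta_deg_, lam)
        return pog

    def estimate(self, X: Session) -> pd.DataFrame:
        """Estimation table with validity flags (see :func:`metrics.estimate_session`)."""
        return estimate_session(X, self.subject_params_, self.method)

    def score(self, X: Session, y=None) -> float:
        """Negative mean absolute on-screen error (mm): higher is better."""
        return -error_report(X, self.subject_params_, self.method).overall_err_mm
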