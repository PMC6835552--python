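"""Fixation-session container and its CSV serialization.

A :class:`Session` is the unit of data flowing through the pipeline: one row
per camera frame holding the estimated pupil center ``p`` and cornea-curvature
center ``c`` (mm, device coordinates), the true and head-tracker-measured
R-Roll angles, and the fixation target shown on that frame.  Protocol
metadata (screen, viewing distance, target layout, and — for synthetic
sessions — the generating eye parameters) travels in commented header lines
so a session round-trips through a single plain-text file.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SessionSchemaError
from .geometry import Screen, SubjectEyeParams

__all__ = ["FRAME_COLUMNS", "Session", "read_session", "write_session", "apply_subject"]

logger = logging.getLogger(__name__)

_FORMAT_TAG = "rollgaze-session.v1"

FRAME_COLUMNS = [
    "frame",
    "target_id",
    "target_x_mm",
    "target_y_mm",
    "p_x",
    "p_y",
    "p_z",
    "c_x",
    "c_y",
    "c_z",
    "lam_true_deg",
    "lam_measured_deg",
]

_NUMERIC_COLUMNS = [c for c in FRAME_COLUMNS if c not in ("frame", "target_id")]


@dataclass
class Session:
    """Per-frame gaze samples plus the protocol they were recorded under."""

    frames: pd.DataFrame
    targets: list[tuple[str, float, float]]
    screen: Screen
    viewing_distance_mm: float
    subject_truth: SubjectEyeParams | None = None
    subject_calibrated: SubjectEyeParams | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in FRAME_COLUMNS if c not in self.frames.columns]
        if missing:
            raise SessionSchemaError(f"session frames missing column(s): {missing}")
        known = {tid for tid, _, _ in self.targets}
        present = set(self.frames["target_id"].astype(str))
        unknown = present - known
        if unknown:
            raise SessionSchemaError(
                f"frames reference target_id(s) not in the target list: {sorted(unknown)}"
            )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def target_map(self) -> dict[str, tuple[float, float]]:
        return {tid: (x, y) for tid, x, y in self.targets}

    @property
    def rolls_deg(self) -> list[float]:
        """Distinct true R-Roll angles present, in order of appearance."""
        seen = self.frames["lam_true_deg"].round(9)
        return list(dict.fromkeys(seen))


def apply_subject(params: SubjectEyeParams, session: Session) -> Session:
    """Return a copy of ``session`` carrying calibrated eye parameters."""
    if len(session) == 0:
        raise ValueError("cannot attach subject parameters to an empty session")
    if session.subject_calibrated is not None:
        logger.info(
            "overwriting calibrated parameters (%.3f°, %.3f°) with (%.3f°, %.3f°)",
            session.subject_calibrated.alpha_deg,
            session.subject_calibrated.beta_deg,
            params.alpha_deg,
            params.beta_deg,
        )
    return dataclasses.replace(session, subject_calibrated=params)


def _meta_dict(session: Session) -> dict:
    d = {
        "screen": {"width_mm": session.screen.width_mm, "height_mm": session.screen.height_mm},
        "viewing_distance_mm": session.viewing_distance_mm,
        "targets": [[tid, x, y] for tid, x, y in session.targets],
    }
    if session.subject_truth is not None:
        d["subject_truth"] = {
            "alpha_deg": session.subject_truth.alpha_deg,
            "beta_deg": session.subject_truth.beta_deg,
        }
    if session.subject_calibrated is not None:
        d["subject_calibrated"] = {
            "alpha_deg": session.subject_calibrated.alpha_deg,
            "beta_deg": session.subject_calibrated.beta_deg,
        }
    if session.meta:
        d["extra"] = session.meta
    return d


def write_session(session: Session, path: str | Path) -> None:
    """Write a session to CSV with its metadata in ``#``-comment header lines."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(f"# {_FORMAT_TAG}\n")
        fh.write(f"# meta: {json.dumps(_meta_dict(session), sort_keys=True)}\n")
        session.frames.to_csv(fh, index=False, columns=FRAME_COLUMNS, float_format="%.12g")


def read_session(path: str | Path) -> Session:
    """Read a session CSV, validating the schema with line-numbered errors."""
    path = Path(path)
    meta: dict | None = None
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            body = line[1:].strip()
            if body.startswith("meta:"):
                try:
                    meta = json.loads(body[len("meta:"):])
                except json.JSONDecodeError as exc:
                    raise SessionSchemaError(
                        f"{path}:{header_lines}: malformed meta JSON ({exc})"
                    ) from exc
    if meta is None:
        raise SessionSchemaError(f"{path}: missing '# meta:' header line")

    try:
        frames = pd.read_csv(path, comment="#", dtype={"target_id": str})
    except pd.errors.EmptyDataError as exc:
        raise SessionSchemaError(f"{path}: empty session file") from exc
    missing = [c for c in FRAME_COLUMNS if c not in frames.columns]
    if missing:
        raise SessionSchemaError(f"{path}: missing column(s): {missing}")
    if len(frames) == 0:
        raise SessionSchemaError(f"{path}: session contains no frames")

    # header + column line precede the first data row
    data_offset = header_lines + 2
    for col in _NUMERIC_COLUMNS:
        vals = pd.to_numeric(frames[col], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(vals.to_numpy()))
        if bad.size:
            raise SessionSchemaError(
                f"{path}:{data_offset + int(bad[0])}: non-numeric or non-finite "
                f"value in column '{col}'"
            )
        frames[col] = vals

    truth = meta.get("subject_truth")
    calib = meta.get("subject_calibrated")
    return Session(
        frames=frames,
        targets=[(str(t[0]), float(t[1]), float(t[2])) for t in meta["targets"]],
        screen=Screen(**meta["screen"]),
        viewing_distance_mm=float(meta["viewing_distance_mm"]),
        subject_truth=SubjectEyeParams(**truth) if truth else None,
        subject_calibrated=SubjectEyeParams(**calib) if calib else None,
        meta=meta.get("extra", {}),
    )
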