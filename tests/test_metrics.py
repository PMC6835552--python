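"""Error metrics, report aggregation, and session CSV round trips."""

import math

import numpy as np
import pandas as pd
import pytest

from rollgaze import (
    NoiseConfig,
    Screen,
    SubjectEyeParams,
    distinct_targets,
    error_report,
    estimate_pog,
    estimate_session,
    mm_to_degrees,
    per_target_error,
    radius_95,
    read_session,
    simulate_session,
    write_session,
)
from rollgaze.errors import SessionSchemaError


def _est_frame(points, valid=None):
    pts = np.asarray(points, float)
    return pd.DataFrame(
        {
            "x_mm": pts[:, 0],
            "y_mm": pts[:, 1],
            "valid": valid if valid is not None else [True] * len(pts),
        }
    )


def test_mm_to_degrees():
    assert mm_to_degrees(5.07, 300.0) == pytest.approx(0.97, abs=0.01)
    assert mm_to_degrees(0.0, 123.0) == 0.0
    assert mm_to_degrees(300.0, 300.0) == pytest.approx(45.0)
    with pytest.raises(ValueError):
        mm_to_degrees(1.0, 0.0)


def test_per_target_error():
    assert per_target_error(_est_frame([(10, 20), (10, 20)]), (10, 20)) == 0.0
    est = _est_frame([(13, 24), (7, 16)])
    assert per_target_error(est, (10, 20)) == pytest.approx(5.0)  # 3-4-5 pairs
    mixed = _est_frame([(13, 24), (999, 999)], valid=[True, False])
    assert per_target_error(mixed, (10, 20)) == pytest.approx(5.0)
    with pytest.raises(ValueError):
        per_target_error(_est_frame([(0, 0)], valid=[False]), (0, 0))


def test_radius_95_interpolated_percentile():
    pts = [(float(d), 0.0) for d in range(1, 101)]
    assert radius_95(_est_frame(pts), (0.0, 0.0)) == pytest.approx(95.05)
    with pytest.raises(ValueError, match="20"):
        radius_95(_est_frame(pts[:10]), (0.0, 0.0))


def test_radius_95_rotation_invariant():
    rng = np.random.default_rng(0)
    pts = rng.normal(0, 3.0, (200, 2))
    r0 = radius_95(_est_frame(pts + [5.0, -2.0]), (5.0, -2.0))
    ang = 0.7
    rot = np.array([[math.cos(ang), -math.sin(ang)], [math.sin(ang), math.cos(ang)]])
    r1 = radius_95(_est_frame(pts @ rot.T + [5.0, -2.0]), (5.0, -2.0))
    assert r1 == pytest.approx(r0, abs=1e-9)


def test_distinct_targets_packing():
    screen = Screen(110.0, 62.0)
    assert distinct_targets(12.0, screen) == 45  # 9 x 5 grid
    assert distinct_targets(28.0, screen) == 6  # 3 x 2 grid
    assert distinct_targets(70.0, screen) == 0  # radius taller than the panel
    assert distinct_targets(24.0, screen) <= distinct_targets(12.0, screen)


def test_estimate_pog_scalar_paths(average_eye):
    sample = pd.Series(
        {
            "frame": 0, "target_id": "c",
            "p_x": 0.0, "p_y": 0.0, "p_z": 296.0,
            "c_x": 0.0, "c_y": 0.0, "c_z": 300.0,
            "lam_measured_deg": 0.0,
        }
    )
    est = estimate_pog(sample, SubjectEyeParams(0, 0), method=2)
    assert est.valid
    assert (est.x_mm, est.y_mm) == pytest.approx((0.0, 0.0), abs=1e-9)
    # optical axis pointing away from the display -> flagged invalid, not raised
    away = sample.copy()
    away["p_z"] = 304.0
    est_bad = estimate_pog(away, SubjectEyeParams(0, 0), method=2)
    assert not est_bad.valid
    with pytest.raises(ValueError):
        estimate_pog(sample, average_eye, method=3)


def test_estimate_session_matches_scalar_path(clean_session, average_eye):
    table = estimate_session(clean_session, average_eye, method=2)
    row = clean_session.frames.iloc[37]
    scalar = estimate_pog(row, average_eye, method=2)
    vec = table.iloc[37]
    assert (vec["x_mm"], vec["y_mm"]) == pytest.approx((scalar.x_mm, scalar.y_mm), abs=1e-9)


def test_method2_error_invariant_across_rolls(clean_session, average_eye):
    """Roll compensation makes accuracy roll-independent on exact data."""
    rep = error_report(clean_session, average_eye, method=2)
    assert rep.per_roll["err_mm"].max() < 1e-9


def test_report_aggregation_is_unweighted_mean(clean_session, average_eye):
    rep = error_report(clean_session, average_eye, method=1)
    for _, row in rep.per_roll.iterrows():
        cells = rep.per_target.query("roll_deg == @row.roll_deg")["err_mm"]
        assert row["err_mm"] == pytest.approx(cells.mean(), abs=1e-12)
    assert rep.overall_err_mm == pytest.approx(rep.per_roll["err_mm"].mean(), abs=1e-12)


def test_session_csv_round_trip(average_eye, tmp_path):
    session = simulate_session(
        average_eye, frames_per_target=3, noise=NoiseConfig(seed=9)
    )
    path = tmp_path / "session.csv"
    write_session(session, path)
    back = read_session(path)
    pd.testing.assert_frame_equal(back.frames, session.frames, check_dtype=False)
    assert back.targets == session.targets
    assert back.screen == session.screen
    assert back.viewing_distance_mm == session.viewing_distance_mm
    assert back.subject_truth == session.subject_truth


def test_read_session_missing_column(average_eye, tmp_path):
    session = simulate_session(average_eye, frames_per_target=2, noise=NoiseConfig(seed=0))
    path = tmp_path / "bad.csv"
    write_session(session, path)
    text = path.read_text().replace("lam_measured_deg", "lam_other")
    path.write_text(text)
    with pytest.raises(SessionSchemaError, match="lam_measured_deg"):
        read_session(path)


def test_read_session_reports_bad_row_line(average_eye, tmp_path):
    session = simulate_session(average_eye, frames_per_target=2, noise=NoiseConfig(seed=0))
    path = tmp_path / "bad.csv"
    write_session(session, path)
    lines = path.read_text().splitlines()
    parts = lines[4].split(",")
    parts[4] = "not-a-number"
    lines[4] = ",".join(parts)
    path.write_text("\n".join(lines) + "\n")
    with pytest.raises(SessionSchemaError, match=r":5:"):
        read_session(path)


def test_read_empty_file_errors(tmp_path):
    path = tmp_path / "empty.csv"
    path.write_text("")
    with pytest.raises(SessionSchemaError):
        read_session(path)
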