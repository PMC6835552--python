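"""Axis construction, eye-frame orthonormality, and ray-screen intersection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rollgaze import (
    EyeAngles,
    Screen,
    SubjectEyeParams,
    angles_from_direction,
    ecs_frame,
    optical_axis_from_angles,
    optical_axis_from_pc,
    pog_on_screen,
    visual_axis_euler,
    visual_axis_in_dcs,
    visual_axis_in_ecs,
)
from rollgaze.errors import (
    CoincidentPointsError,
    DegenerateFrameError,
    DegeneratePitchError,
    GimbalLockError,
    NoIntersectionError,
)

prop = settings(derandomize=True, max_examples=60, deadline=None)

angles_st = st.floats(-80.0, 80.0)
small_st = st.floats(-5.0, 5.0)


@pytest.mark.parametrize(
    "theta, phi, expected",
    [
        (0.0, 0.0, (0.0, 0.0, -1.0)),
        (90.0, 0.0, (1.0, 0.0, 0.0)),
        (30.0, 0.0, (0.5, 0.0, -0.86603)),
    ],
)
def test_optical_axis_from_angles(theta, phi, expected):
    omega = optical_axis_from_angles(EyeAngles(theta, phi))
    assert omega == pytest.approx(expected, abs=1e-5)
    assert np.linalg.norm(omega) == pytest.approx(1.0, abs=1e-12)


def test_pitch_at_90_is_degenerate():
    with pytest.raises(DegeneratePitchError):
        EyeAngles(0.0, 90.0)


@pytest.mark.parametrize(
    "omega, expected",
    [((0, 0, -1.0), (0.0, 0.0)), ((1.0, 0, 0), (90.0, 0.0)), ((0.5, 0, -0.86603), (30.0, 0.0))],
)
def test_angles_from_direction(omega, expected):
    ang = angles_from_direction(np.array(omega, float))
    assert (ang.theta_deg, ang.phi_deg) == pytest.approx(expected, abs=1e-3)


@prop
@given(theta=angles_st, phi=angles_st)
def test_angle_direction_round_trip(theta, phi):
    ang = EyeAngles(theta, phi)
    back = angles_from_direction(optical_axis_from_angles(ang))
    assert back.theta_deg == pytest.approx(theta, abs=1e-9)
    assert back.phi_deg == pytest.approx(phi, abs=1e-9)


def test_gimbal_lock_at_vertical_axis():
    with pytest.raises(GimbalLockError):
        angles_from_direction(np.array([0.0, 1.0, 0.0]))


def test_optical_axis_from_pc():
    omega = optical_axis_from_pc([0, 0, 296.0], [0, 0, 300.0])
    assert omega == pytest.approx((0, 0, -1.0), abs=1e-12)
    omega = optical_axis_from_pc([2, 0, 298.0], [0, 0, 300.0])
    assert omega == pytest.approx((0.70711, 0, -0.70711), abs=1e-5)
    with pytest.raises(CoincidentPointsError):
        optical_axis_from_pc([1, 2, 3.0], [1, 2, 3.0])


def test_visual_axis_in_ecs_examples():
    assert visual_axis_in_ecs(SubjectEyeParams(0, 0)) == pytest.approx((0, 0, 1.0))
    nu = visual_axis_in_ecs(SubjectEyeParams(3.0, 1.5))
    assert nu == pytest.approx((0.05232, 0.02618, 0.99829), abs=1e-5)
    mirrored = visual_axis_in_ecs(SubjectEyeParams(-3.0, 1.5))
    assert mirrored == pytest.approx((-nu[0], nu[1], nu[2]), abs=1e-15)


def test_subject_params_reject_implausible_offsets():
    with pytest.raises(ValueError):
        SubjectEyeParams(alpha_deg=45.0, beta_deg=0.0)


def test_ecs_frame_frontal_matches_roll_matrices():
    frontal = np.array([0.0, 0.0, -1.0])
    f0 = ecs_frame(frontal, 0.0)
    assert f0.rotation == pytest.approx(
        np.array([[1, 0, 0], [0, 1, 0], [0, 0, -1.0]]), abs=1e-12
    )
    f90 = ecs_frame(frontal, 90.0)
    assert f90.x_eye == pytest.approx((0, 1, 0.0), abs=1e-12)
    assert f90.y_eye == pytest.approx((-1, 0, 0.0), abs=1e-12)
    assert f90.z_eye == pytest.approx((0, 0, -1.0), abs=1e-12)


def test_ecs_frame_degenerate_along_column_axis():
    with pytest.raises(DegenerateFrameError):
        ecs_frame(np.array([0.0, 1.0, 0.0]), 0.0)


@prop
@given(theta=angles_st, phi=st.floats(-60.0, 60.0), lam=st.floats(-180.0, 180.0))
def test_ecs_frame_orthonormal(theta, phi, lam):
    omega = optical_axis_from_angles(EyeAngles(theta, phi))
    f = ecs_frame(omega, lam)
    for v in (f.x_eye, f.y_eye, f.z_eye):
        assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-9)
    assert abs(f.x_eye @ f.y_eye) < 1e-9
    assert abs(f.x_eye @ f.z_eye) < 1e-9
    assert abs(f.y_eye @ f.z_eye) < 1e-9
    assert np.array_equal(f.z_eye, omega)
    assert np.cross(f.x_eye, f.z_eye) == pytest.approx(f.y_eye, abs=1e-12)


@prop
@given(theta=angles_st, phi=st.floats(-60.0, 60.0), lam1=st.floats(-90, 90), lam2=st.floats(-90, 90))
def test_roll_composition(theta, phi, lam1, lam2):
    """Rolling by lam1 then lam2 equals rolling once by lam1 + lam2."""
    omega = optical_axis_from_angles(EyeAngles(theta, phi))
    once = ecs_frame(omega, lam1 + lam2)
    f1 = ecs_frame(omega, lam1)
    c, s = math.cos(math.radians(lam2)), math.sin(math.radians(lam2))
    x12 = c * f1.x_eye + s * f1.y_eye
    y12 = -s * f1.x_eye + c * f1.y_eye
    assert x12 == pytest.approx(once.x_eye, abs=1e-9)
    assert y12 == pytest.approx(once.y_eye, abs=1e-9)


def test_visual_axis_in_dcs_frontal():
    frontal = np.array([0.0, 0.0, -1.0])
    p = SubjectEyeParams(3.0, 1.5)
    nu0 = visual_axis_in_dcs(frontal, p, 0.0)
    assert nu0 == pytest.approx((0.05232, 0.02618, -0.99829), abs=1e-5)
    nu90 = visual_axis_in_dcs(frontal, p, 90.0)
    assert nu90 == pytest.approx((-0.02618, 0.05232, -0.99829), abs=1e-5)
    angle = math.degrees(math.acos(np.clip(nu0 @ nu90, -1, 1)))
    assert angle == pytest.approx(4.7, abs=0.05)


@prop
@given(theta=angles_st, alpha=small_st, beta=st.floats(-3.0, 3.0))
def test_euler_route_exact_at_zero_pitch(theta, alpha, beta):
    """At phi = 0 the rolled-frame and added-offset parameterizations coincide."""
    omega = optical_axis_from_angles(EyeAngles(theta, 0.0))
    p = SubjectEyeParams(alpha, beta)
    nu_frame = visual_axis_in_dcs(omega, p, 0.0)
    nu_euler = visual_axis_euler(EyeAngles(theta, 0.0), p)
    assert nu_frame == pytest.approx(nu_euler, abs=1e-12)


@prop
@given(
    theta=st.floats(-10.0, 10.0),
    phi=st.floats(-10.0, 10.0),
    alpha=small_st,
    beta=st.floats(-3.0, 3.0),
)
def test_euler_route_second_order_off_axis(theta, phi, alpha, beta):
    """Off the phi = 0 plane the two parameterizations differ below 0.05 deg."""
    omega = optical_axis_from_angles(EyeAngles(theta, phi))
    p = SubjectEyeParams(alpha, beta)
    nu_frame = visual_axis_in_dcs(omega, p, 0.0)
    nu_euler = visual_axis_euler(EyeAngles(theta, phi), p)
    angle = math.degrees(math.acos(np.clip(nu_frame @ nu_euler, -1, 1)))
    assert angle < 0.05


def test_pog_on_screen_examples():
    c = np.array([0.0, 0.0, 300.0])
    assert pog_on_screen(c, [0, 0, -1.0]).xy == pytest.approx((0, 0))
    pog = pog_on_screen(c, [0.05232, 0.02618, -0.99829])
    assert (pog.x_mm, pog.y_mm) == pytest.approx((15.72, 7.87), abs=0.01)
    with pytest.raises(NoIntersectionError):
        pog_on_screen(c, [0, 0, 1.0])
    with pytest.raises(NoIntersectionError):
        pog_on_screen([0, 0, -5.0], [0, 0, -1.0])


def test_pog_off_screen_flagged_not_clamped():
    pog = pog_on_screen([0, 0, 300.0], [0.3, 0, -0.9], Screen(110, 62))
    assert not pog.on_screen
    assert pog.x_mm > 55  # untouched coordinate


@prop
@given(theta=st.floats(-8.0, 8.0), phi=st.floats(-5.0, 5.0), lam=st.floats(-180, 180))
def test_pog_ray_consistency(theta, phi, lam):
    """Re-deriving the direction eye -> PoG recovers the visual axis."""
    c = np.array([3.0, -2.0, 300.0])
    omega = optical_axis_from_angles(EyeAngles(theta, phi))
    nu = visual_axis_in_dcs(omega, SubjectEyeParams(3.0, 1.5), lam)
    pog = pog_on_screen(c, nu)
    back = np.array([pog.x_mm, pog.y_mm, 0.0]) - c
    back /= np.linalg.norm(back)
    assert back == pytest.approx(nu, abs=1e-9)
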