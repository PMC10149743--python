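"""Superposition, axes, planes, angles and gravity centers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cubeshell.assembly_builder import make_subunit
from cubeshell.rigid_geometry import (DegenerateGeometryError, angle_deg,
                                      center_distance, fit_plane,
                                      gravity_center, principal_long_axis,
                                      subunit_tilt_deg, superpose_points)


def rotation_about(axis, angle_deg_):
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    a = np.radians(angle_deg_)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)


def quaternion_superpose(moving, fixed):
    """Independent oracle: Horn's closed-form quaternion superposition."""
    cm, cf = moving.mean(axis=0), fixed.mean(axis=0)
    M = (moving - cm).T @ (fixed - cf)
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    N = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz]])
    w, v = np.linalg.eigh(N)
    q = v[:, -1]                   # w x y z
    w0, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w0 * z), 2 * (x * z + w0 * y)],
        [2 * (x * y + w0 * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w0 * x)],
        [2 * (x * z - w0 * y), 2 * (y * z + w0 * x), 1 - 2 * (x * x + y * y)]])
    t = cf - R @ cm
    rmsd = np.sqrt(((moving @ R.T + t - fixed) ** 2).sum(axis=1).mean())
    return R, t, rmsd


def test_superpose_identity():
    pts = np.random.default_rng(0).normal(0, 10, (50, 3))
    tf, rmsd = superpose_points(pts, pts)
    np.testing.assert_allclose(tf.rotation, np.eye(3), atol=1e-12)
    np.testing.assert_allclose(tf.translation, 0, atol=1e-12)
    assert rmsd < 1e-12


def test_superpose_recovers_known_transform():
    """A planted 30 degree rotation + (5, -3, 2) A translation is recovered."""
    rng = np.random.default_rng(1)
    pts = rng.normal(0, 15, (80, 3))
    R = rotation_about([1, 2, 0.5], 30.0)
    t = np.array([5.0, -3.0, 2.0])
    moved = pts @ R.T + t
    tf, rmsd = superpose_points(pts, moved)
    np.testing.assert_allclose(tf.rotation, R, atol=1e-6)
    np.testing.assert_allclose(tf.translation, t, atol=1e-6)
    assert rmsd < 1e-9


def test_superpose_matches_quaternion_oracle():
    """Kabsch agrees with the closed-form quaternion method on 200 instances."""
    rng = np.random.default_rng(42)
    for _ in range(200):
        n = int(rng.integers(4, 40))
        moving = rng.normal(0, rng.uniform(1, 20), (n, 3))
        fixed = rng.normal(0, rng.uniform(1, 20), (n, 3))
        tf, rmsd = superpose_points(moving, fixed)
        R_q, t_q, rmsd_q = quaternion_superpose(moving, fixed)
        assert rmsd == pytest.approx(rmsd_q, abs=1e-8)
        np.testing.assert_allclose(tf.rotation, R_q, atol=1e-6)


def test_superpose_rmsd_invariant_to_premotion():
    rng = np.random.default_rng(3)
    moving = rng.normal(0, 10, (30, 3))
    fixed = rng.normal(0, 10, (30, 3))
    _, rmsd0 = superpose_points(moving, fixed)
    R = rotation_about([0.3, -1, 2], 117.0)
    _, rmsd1 = superpose_points(moving @ R.T + np.array([9, 9, -4.0]), fixed)
    assert rmsd1 == pytest.approx(rmsd0, abs=1e-9)


def test_superpose_degenerate_inputs_raise():
    line = np.outer(np.linspace(0, 1, 10), [1.0, 2.0, 3.0])
    with pytest.raises(DegenerateGeometryError):
        superpose_points(line, line + 1.0)
    with pytest.raises(DegenerateGeometryError):
        superpose_points(np.zeros((2, 3)), np.zeros((2, 3)))


def test_principal_long_axis_of_cuboid():
    """The long axis of a 60 x 40 x 70 A cuboid cloud is the 70 A edge."""
    sub = make_subunit()
    ax = principal_long_axis(sub.points)
    assert not ax.degenerate
    assert abs(ax.direction @ [0, 0, 1]) > 1 - 1e-12


def test_principal_long_axis_equivariance():
    sub = make_subunit(seed=5)
    R = rotation_about([1, -1, 0.25], 37.0)
    ax0 = principal_long_axis(sub.points)
    ax1 = principal_long_axis(sub.points @ R.T)
    assert angle_deg(R @ ax0.direction, ax1.direction) < 1e-9


def test_principal_long_axis_degeneracy_flag():
    """An isotropic cloud (equal top inertia eigenvalues) raises the flag."""
    g = np.linspace(-1, 1, 5)
    cubic = np.array([[x, y, z] for x in g for y in g for z in g])
    assert principal_long_axis(cubic).degenerate
    assert not principal_long_axis(make_subunit().points).degenerate


def test_fit_plane_exact_and_noisy():
    rng = np.random.default_rng(8)
    uv = rng.uniform(-30, 30, (100, 2))
    flat = np.column_stack([uv, np.zeros(100)])
    R = rotation_about([1, 0.2, 0], 25.0)
    plane = fit_plane(flat @ R.T)
    assert plane.residual < 1e-9
    assert angle_deg(plane.normal, R @ np.array([0, 0, 1.0])) < 1e-9
    # Gaussian noise sigma = 0.5 A leaves the normal within 1 degree
    noisy = flat @ R.T + rng.normal(0, 0.5, (100, 3))
    assert angle_deg(fit_plane(noisy).normal, R @ np.array([0, 0, 1.0])) < 1.0


def test_fit_plane_normal_orthogonal_to_principal_directions():
    rng = np.random.default_rng(9)
    pts = rng.normal(0, 1, (200, 3)) * np.array([20.0, 10.0, 0.5])
    plane = fit_plane(pts)
    c = pts - pts.mean(axis=0)
    _, _, Vt = np.linalg.svd(c)
    assert abs(plane.normal @ Vt[0]) < 1e-9
    assert abs(plane.normal @ Vt[1]) < 1e-9


def test_fit_plane_collinear_raises():
    with pytest.raises(DegenerateGeometryError):
        fit_plane(np.outer(np.arange(5.0), [1, 1, 0]))


@given(st.integers(0, 359), st.integers(0, 359))
@settings(max_examples=60, deadline=None)
def test_angle_deg_symmetric_and_bounded(a, b):
    u = np.array([np.cos(np.radians(a)), np.sin(np.radians(a)), 0.3])
    v = np.array([np.cos(np.radians(b)), 0.1, np.sin(np.radians(b))])
    ang = angle_deg(u, v)
    assert 0.0 <= ang <= 90.0
    assert ang == pytest.approx(angle_deg(v, u), abs=1e-12)


def test_angle_deg_special_cases():
    assert angle_deg([1, 0, 0], [2, 0, 0]) == pytest.approx(0.0, abs=1e-9)
    assert angle_deg([1, 0, 0], [-1, 0, 0]) == pytest.approx(0.0, abs=1e-9)
    assert angle_deg([1, 0, 0], [0, 1, 0]) == pytest.approx(90.0)


def test_gravity_center_and_distance():
    corners = np.array(list(np.ndindex(2, 2, 2)), dtype=float)
    np.testing.assert_allclose(gravity_center(corners), [0.5, 0.5, 0.5])
    assert center_distance(corners, corners) == 0.0
    assert center_distance(corners, corners + [3.0, 0, 4.0]) == pytest.approx(5.0)
    with pytest.raises(ValueError):
        gravity_center(np.empty((0, 3)))


def test_subunit_tilt_cases():
    """Tilt about a perpendicular axis reads exactly; spin about the long
    axis reads zero (documented convention)."""
    sub = make_subunit()
    assert subunit_tilt_deg(sub, sub) == pytest.approx(0.0, abs=1e-9)
    perp = sub.transformed(rotation_about([1, 0, 0], 17.0), np.zeros(3))
    assert subunit_tilt_deg(perp, sub) == pytest.approx(17.0, abs=1e-6)
    spin = sub.transformed(rotation_about([0, 0, 1], 10.0), np.zeros(3))
    assert subunit_tilt_deg(spin, sub) == pytest.approx(0.0, abs=1e-9)
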