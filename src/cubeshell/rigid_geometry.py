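"""Rigid-body geometric primitives.

Least-squares superposition (Kabsch, SVD-based), principal long axes from
the second-moment tensor, total-least-squares plane fits, angles between
planes/axes (acute convention, degrees), and centroid ("gravity center")
utilities.  All coordinates are Angstrom in a right-handed frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import SubunitModel

#: relative eigenvalue gap below which the long axis is flagged degenerate
DEGENERACY_REL_GAP = 1e-3


class DegenerateGeometryError(ValueError):
    """Raised for inputs without a well-defined fit (collinear, too few points)."""


@dataclass
class Transform:
    """Proper rigid motion ``x -> R x + t``."""

    rotation: np.ndarray      # (3, 3), orthogonal, det +1
    translation: np.ndarray   # (3,), Angstrom

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "Transform") -> "Transform":
        """Return the transform equivalent to applying ``other`` then ``self``."""
        return Transform(self.rotation @ other.rotation,
                         self.rotation @ other.translation + self.translation)

    def inverse(self) -> "Transform":
        return Transform(self.rotation.T, -self.rotation.T @ self.translation)

    @classmethod
    def identity(cls) -> "Transform":
        return cls(np.eye(3), np.zeros(3))

    @property
    def rotation_angle_deg(self) -> float:
        tr = np.clip((np.trace(self.rotation) - 1.0) / 2.0, -1.0, 1.0)
        return float(np.degrees(np.arccos(tr)))


@dataclass
class Plane:
    """A plane as unit normal + point, with the rms fit residual in Angstrom."""

    normal: np.ndarray
    point: np.ndarray
    residual: float = 0.0

    def __post_init__(self):
        self.normal = np.asarray(self.normal, dtype=float)
        n = np.linalg.norm(self.normal)
        if n == 0:
            raise ValueError("plane normal must be non-zero")
        self.normal = self.normal / n
        self.point = np.asarray(self.point, dtype=float)

    def distance(self, points: np.ndarray) -> np.ndarray:
        """Signed point-plane distances."""
        return (np.asarray(points) - self.point) @ self.normal


@dataclass
class AxisLine:
    """A line as unit direction + point; ``degenerate`` flags an ill-defined fit."""

    direction: np.ndarray
    point: np.ndarray
    degenerate: bool = False

    def __post_init__(self):
        self.direction = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(self.direction)
        if n == 0:
            raise ValueError("axis direction must be non-zero")
        self.direction = self.direction / n
        self.point = np.asarray(self.point, dtype=float)


def _check_noncollinear(points: np.ndarray, what: str) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"{what}: expected an (n, 3) array")
    if len(pts) < 3:
        raise DegenerateGeometryError(f"{what}: need at least 3 points")
    c = pts - pts.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise DegenerateGeometryError(f"{what}: points are collinear or coincident")
    return pts


def superpose_points(moving: np.ndarray, fixed: np.ndarray,
                     pairing: np.ndarray | None = None) -> tuple[Transform, float]:
    """Least-squares rigid superposition of paired points (Kabsch).

    ``pairing`` is an optional (k, 2) index array pairing ``moving[i0]`` with
    ``fixed[i1]``; by default points pair positionally.  Returns the
    transform minimizing the paired RMSD and the RMSD after applying it.
    """
    mv = np.asarray(moving, dtype=float)
    fx = np.asarray(fixed, dtype=float)
    if pairing is not None:
        pairing = np.asarray(pairing, dtype=int)
        mv = mv[pairing[:, 0]]
        fx = fx[pairing[:, 1]]
    if len(mv) != len(fx):
        raise ValueError("moving and fixed must pair one-to-one")
    mv = _check_noncollinear(mv, "superpose_points(moving)")
    fx = _check_noncollinear(fx, "superpose_points(fixed)")
    cm, cf = mv.mean(axis=0), fx.mean(axis=0)
    H = (mv - cm).T @ (fx - cf)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cf - R @ cm
    tf = Transform(R, t)
    rmsd = float(np.sqrt(((tf.apply(mv) - fx) ** 2).sum(axis=1).mean()))
    return tf, rmsd


def principal_long_axis(points: np.ndarray,
                        reference_direction: np.ndarray | None = None) -> AxisLine:
    """Long axis of a point cloud from the centered second-moment tensor.

    The direction is the eigenvector with the largest eigenvalue.  The sign
    is fixed by ``reference_direction`` when given (positive dot product; in
    assembly context callers pass the vector from the assembly center to the
    subunit centroid), otherwise by the +z hemisphere (then +y, then +x on
    exact ties).  A relative gap below ``DEGENERACY_REL_GAP`` between the two
    largest eigenvalues sets the ``degenerate`` flag.
    """
    pts = _check_noncollinear(points, "principal_long_axis")
    c = pts.mean(axis=0)
    cov = np.cov((pts - c).T)
    evals, evecs = np.linalg.eigh(cov)        # ascending
    direction = evecs[:, -1]
    gap = (evals[-1] - evals[-2]) / max(evals[-1], 1e-300)
    degenerate = bool(gap < DEGENERACY_REL_GAP)
    if reference_direction is not None:
        ref = np.asarray(reference_direction, dtype=float)
    else:
        ref = np.array([0.0, 0.0, 1.0])
    dot = float(direction @ ref)
    if dot == 0.0:
        for fallback in (np.array([0.0, 1.0, 0.0]), np.array([1.0, 0.0, 0.0])):
            dot = float(direction @ fallback)
            if dot != 0.0:
                break
    if dot < 0:
        direction = -direction
    return AxisLine(direction, c, degenerate=degenerate)


def fit_plane(points: np.ndarray) -> Plane:
    """Total-least-squares plane: normal = smallest-variance direction.

    The residual is the rms point-plane distance.  Collinear input raises
    :class:`DegenerateGeometryError`.
    """
    pts = _check_noncollinear(points, "fit_plane")
    c = pts.mean(axis=0)
    _, s, Vt = np.linalg.svd(pts - c)
    normal = Vt[-1]
    residual = float(s[-1] / np.sqrt(len(pts)))
    return Plane(normal, c, residual)


def angle_deg(a: Plane | AxisLine | np.ndarray, b: Plane | AxisLine | np.ndarray) -> float:
    """Acute angle in degrees between two planes, axes, or direction vectors.

    Plane-plane uses the normals, axis-axis the directions; the result is
    folded into [0, 90] (line orientations are sign-free).
    """

    def _vec(x):
        if isinstance(x, Plane):
            return x.normal
        if isinstance(x, AxisLine):
            return x.direction
        v = np.asarray(x, dtype=float)
        return v / np.linalg.norm(v)

    cosang = abs(float(_vec(a) @ _vec(b)))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def gravity_center(points: np.ndarray) -> np.ndarray:
    """Unweighted centroid of a non-empty point set."""
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValueError("gravity_center: empty point set")
    return pts.reshape(-1, 3).mean(axis=0)


def center_distance(set_a: np.ndarray, set_b: np.ndarray) -> float:
    """Euclidean distance between the gravity centers of two point sets."""
    return float(np.linalg.norm(gravity_center(set_a) - gravity_center(set_b)))


def subunit_tilt_deg(observed: SubunitModel, reference: SubunitModel,
                     center: np.ndarray | None = None) -> float:
    """Angle between the long axes of two paired subunits, in [0, 90] degrees.

    Both subunits must already sit in the same global frame.  ``center`` is
    the assembly center used for the axis sign convention.  A rotation purely
    about the long axis reads as 0 by construction (documented limitation:
    spin about the long axis is invisible to this measure).
    """
    ref_dir_o = ref_dir_r = None
    if center is not None:
        center = np.asarray(center, dtype=float)
        ref_dir_o = observed.centroid - center
        ref_dir_r = reference.centroid - center
    ax_o = principal_long_axis(observed.points, ref_dir_o)
    ax_r = principal_long_axis(reference.points, ref_dir_r)
    if ax_o.degenerate or ax_r.degenerate:
        raise DegenerateGeometryError("subunit long axis is degenerate")
    return angle_deg(ax_o, ax_r)
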