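"""Finite rotation groups and symmetry expansion of asymmetric units.

Supports the proper point groups C1, Cn, Dn, T and O.  The octahedral group O
is enumerated with its three 4-fold axes along the coordinate axes, so cube
faces are perpendicular to x, y and z and face labels {+x, -x, +y, -y, +z,
-z} are canonical.  Matrices act on column coordinate vectors (Angstrom,
right-handed frame).
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .model import Assembly, SubunitModel


class UnsupportedGroupError(ValueError):
    """Raised for point-group symbols this module does not implement."""


@dataclass
class RotationSet:
    """A finite group of proper rotations.

    ``rotations`` is an ordered (deterministically enumerated) list of 3x3
    proper rotation matrices; the first element is always the identity.
    ``axes`` names the principal symmetry axes as ``name -> unit vector``.
    """

    label: str
    rotations: np.ndarray               # (m, 3, 3)
    axes: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def order(self) -> int:
        return len(self.rotations)

    def __iter__(self):
        return iter(self.rotations)

    def validate(self, tol: float = 1e-9) -> None:
        """Assert orthogonality, det +1, identity membership and closure."""
        rots = self.rotations
        eye = np.eye(3)
        for R in rots:
            if not np.allclose(R.T @ R, eye, atol=tol):
                raise ValueError("rotation matrix is not orthogonal")
            if abs(np.linalg.det(R) - 1.0) > 1e-6:
                raise ValueError("rotation matrix does not have det +1")
        if not any(np.allclose(R, eye, atol=tol) for R in rots):
            raise ValueError("group does not contain the identity")
        for A, B in itertools.product(rots, repeat=2):
            C = A @ B
            if not any(np.allclose(C, R, atol=1e-8) for R in rots):
                raise ValueError("group is not closed under composition")


def _axis_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix about ``axis`` by ``angle`` radians (Rodrigues)."""
    u = np.asarray(axis, dtype=float)
    u = u / np.linalg.norm(u)
    K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _signed_permutation_matrices():
    """All 48 signed permutation matrices, lexicographic in flattened form."""
    mats = []
    for perm in itertools.permutations(range(3)):
        for signs in itertools.product((1, -1), repeat=3):
            M = np.zeros((3, 3))
            for i, (p, s) in enumerate(zip(perm, signs)):
                M[i, p] = s
            mats.append(M)
    mats.sort(key=lambda M: tuple(-M.ravel()))
    return mats


def _octahedral_rotations() -> np.ndarray:
    """The 24 proper rotations of the cube, 4-folds along x, y, z.

    Enumerated as the signed permutation matrices with determinant +1 in a
    fixed lexicographic order, identity moved to the front.
    """
    rots = [M for M in _signed_permutation_matrices() if np.linalg.det(M) > 0.5]
    eye = np.eye(3)
    rots.sort(key=lambda M: (not np.allclose(M, eye), tuple(-M.ravel())))
    return np.array(rots)


def _tetrahedral_rotations() -> np.ndarray:
    """The 12 rotations of the tetrahedron inscribed in the canonical cube.

    These are the orientation-preserving signed permutations whose
    permutation part is even (identity, the three axial 2-folds, and the
    eight 3-folds about the body diagonals).
    """

    def perm_of(M):
        return tuple(int(np.argmax(np.abs(M[i]))) for i in range(3))

    def parity(p):
        inv = sum(1 for i in range(3) for j in range(i + 1, 3) if p[i] > p[j])
        return inv % 2

    return np.array([M for M in _octahedral_rotations() if parity(perm_of(M)) == 0])


_SYMBOL_RE = re.compile(r"^([CD])(\d+)$")


def make_point_group(label: str) -> RotationSet:
    """Build a :class:`RotationSet` for a point-group symbol.

    Supported symbols: ``C1``, ``Cn``, ``Dn`` (n >= 1), ``T``, ``O``.
    Enumeration order is deterministic: Cn lists rotations about +z by
    k*360/n degrees for k = 0..n-1; Dn appends the n in-plane 2-folds at
    angles k*180/n from +x; T and O use a fixed lexicographic enumeration of
    signed permutation matrices with the identity first.
    """
    label = label.strip()
    z = np.array([0.0, 0.0, 1.0])
    if label == "O":
        axes = {
            "4-fold-x": np.array([1.0, 0.0, 0.0]),
            "4-fold-y": np.array([0.0, 1.0, 0.0]),
            "4-fold-z": z,
        }
        for i, d in enumerate(itertools.product((1, -1), repeat=2)):
            axes[f"3-fold-{i}"] = np.array([d[0], d[1], 1.0]) / np.sqrt(3)
        return RotationSet("O", _octahedral_rotations(), axes)
    if label == "T":
        axes = {"2-fold-x": np.array([1.0, 0.0, 0.0]),
                "2-fold-y": np.array([0.0, 1.0, 0.0]),
                "2-fold-z": z}
        for i, d in enumerate(itertools.product((1, -1), repeat=2)):
            axes[f"3-fold-{i}"] = np.array([d[0], d[1], 1.0]) / np.sqrt(3)
        return RotationSet("T", _tetrahedral_rotations(), axes)
    m = _SYMBOL_RE.match(label)
    if m is None:
        raise UnsupportedGroupError(f"unsupported point-group symbol: {label!r}")
    kind, n = m.group(1), int(m.group(2))
    if n < 1:
        raise UnsupportedGroupError(f"point-group order must be >= 1: {label!r}")
    cyc = [_axis_rotation(z, 2 * np.pi * k / n) for k in range(n)]
    if kind == "C":
        return RotationSet(label, np.array(cyc), {f"{n}-fold-z": z})
    dih = [_axis_rotation([np.cos(np.pi * k / n), np.sin(np.pi * k / n), 0.0], np.pi)
           for k in range(n)]
    axes = {f"{n}-fold-z": z, "2-fold-x": np.array([1.0, 0.0, 0.0])}
    return RotationSet(label, np.array(cyc + dih), axes)


def expand_asymmetric_unit(subunit: SubunitModel, group: RotationSet) -> Assembly:
    """Apply every group rotation (about the origin) to one subunit.

    Copy *i* is the subunit rotated by ``group.rotations[i]``; its label
    records the generating element as ``<label>@<group>_<i>``.
    """
    if not np.all(np.isfinite(subunit.points)):
        raise ValueError("subunit coordinates must be finite")
    subs = []
    for i, R in enumerate(group.rotations):
        s = subunit.transformed(R, np.zeros(3))
        s.label = f"{subunit.label}@{group.label}_{i:02d}"
        subs.append(s)
    return Assembly(subs, provenance="ideal", symmetry=group.label)


def match_equivalent_subunits(observed: Assembly, reference: Assembly) -> np.ndarray:
    """Pair observed subunits with reference subunits by centroid proximity.

    Returns an integer array ``pairing`` with ``pairing[i] = j`` meaning
    observed subunit *i* corresponds to reference subunit *j*.  The pairing
    is the global minimum of total squared centroid distance over all
    bijections (Hungarian assignment); ties resolve to the lowest subunit
    index by the solver's deterministic ordering.
    """
    if observed.n_subunits != reference.n_subunits:
        raise ValueError(
            f"subunit count mismatch: {observed.n_subunits} vs {reference.n_subunits}")
    co = observed.centroids()
    cr = reference.centroids()
    cost = ((co[:, None, :] - cr[None, :, :]) ** 2).sum(axis=2)
    rows, cols = linear_sum_assignment(cost)
    pairing = np.empty(observed.n_subunits, dtype=int)
    pairing[rows] = cols
    return pairing
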