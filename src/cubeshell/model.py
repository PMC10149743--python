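"""Shared in-memory containers for subunits and multi-subunit assemblies.

A :class:`SubunitModel` is a labelled pseudo-atomic point cloud (coordinates
in Angstrom, unit weights).  An :class:`Assembly` is an ordered collection of
subunits plus the combinatorial annotations the deviation analysis needs:
which four subunits form each flat head-to-tail face tetramer, and which four
span each cube edge as a concave tetramer with roles A, B, A', B'.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: canonical face order used for face ids and edge ids
FACE_ORDER = ("+x", "-x", "+y", "-y", "+z", "-z")

FACE_NORMALS = {
    "+x": np.array([1.0, 0.0, 0.0]),
    "-x": np.array([-1.0, 0.0, 0.0]),
    "+y": np.array([0.0, 1.0, 0.0]),
    "-y": np.array([0.0, -1.0, 0.0]),
    "+z": np.array([0.0, 0.0, 1.0]),
    "-z": np.array([0.0, 0.0, -1.0]),
}


@dataclass
class SubunitModel:
    """One subunit as a point cloud with unit point weights."""

    points: np.ndarray            # (n, 3) float64, Angstrom
    label: str = "A"
    face_id: str | None = None    # one of FACE_ORDER or None
    role: str | None = None       # A / B / A' / B' for standalone tetramers
    dims: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("subunit points must be an (n, 3) array")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("subunit points must be finite")

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "SubunitModel":
        """Return a copy with ``x -> R x + t`` applied to every point."""
        pts = self.points @ np.asarray(rotation, dtype=float).T + np.asarray(translation, dtype=float)
        return replace(self, points=pts)

    def copy(self) -> "SubunitModel":
        return replace(self, points=self.points.copy())


@dataclass
class EdgeRecord:
    """Concave tetramer bookkeeping for one cube edge.

    ``roles`` maps each of "A", "B", "A'", "B'" to a subunit index.  The two
    2-fold related pairs are (A, B') on ``faces[0]`` and (A', B) on
    ``faces[1]``.
    """

    edge_id: str
    faces: tuple[str, str]
    roles: dict[str, int]
    # hinge line of the ideal geometry (edge direction and a point on it);
    # carried so perturbations and bending measurements share one definition
    hinge_point: np.ndarray | None = None
    hinge_direction: np.ndarray | None = None

    def pair_indices(self) -> tuple[tuple[int, int], tuple[int, int]]:
        """Subunit indices of the (A, B') and (A', B) pairs."""
        r = self.roles
        return (r["A"], r["B'"]), (r["A'"], r["B"])


@dataclass
class Assembly:
    """An ordered multi-subunit assembly with face/edge annotations."""

    subunits: list[SubunitModel]
    provenance: str = "ideal"            # ideal | perturbed | external
    symmetry: str = "C1"
    faces: dict[str, list[int]] = field(default_factory=dict)
    edges: list[EdgeRecord] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def n_subunits(self) -> int:
        return len(self.subunits)

    def centroids(self) -> np.ndarray:
        return np.array([s.centroid for s in self.subunits])

    @property
    def center(self) -> np.ndarray:
        """Unweighted mean of all points of all subunits."""
        return np.concatenate([s.points for s in self.subunits]).mean(axis=0)

    def all_points(self) -> np.ndarray:
        return np.concatenate([s.points for s in self.subunits])

    def bounding_box(self) -> np.ndarray:
        """(2, 3) array of [min, max] over all points."""
        pts = self.all_points()
        return np.array([pts.min(axis=0), pts.max(axis=0)])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Assembly":
        """Rigidly move the whole assembly, keeping all annotations.

        Hinge lines stored on edge records are moved along with the points.
        """
        subs = [s.transformed(rotation, translation) for s in self.subunits]
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        edges = []
        for e in self.edges:
            hp = None if e.hinge_point is None else R @ e.hinge_point + t
            hd = None if e.hinge_direction is None else R @ e.hinge_direction
            edges.append(EdgeRecord(e.edge_id, e.faces, dict(e.roles), hp, hd))
        return Assembly(subs, self.provenance, self.symmetry,
                        {k: list(v) for k, v in self.faces.items()}, edges,
                        dict(self.metadata))

    def copy(self) -> "Assembly":
        return self.transformed(np.eye(3), np.zeros(3))

    def validate_cube_topology(self) -> None:
        """Check the 24 / 6 / 12 census and the 1-face / 2-edge membership."""
        if self.n_subunits != 24:
            raise ValueError(f"cube assembly must have 24 subunits, got {self.n_subunits}")
        if len(self.faces) != 6:
            raise ValueError(f"cube assembly must have 6 faces, got {len(self.faces)}")
        if len(self.edges) != 12:
            raise ValueError(f"cube assembly must have 12 edges, got {len(self.edges)}")
        face_count = np.zeros(24, dtype=int)
        for members in self.faces.values():
            if len(members) != 4:
                raise ValueError("each face tetramer must have 4 subunits")
            face_count[members] += 1
        edge_count = np.zeros(24, dtype=int)
        for e in self.edges:
            idx = list(e.roles.values())
            if sorted(e.roles) != ["A", "A'", "B", "B'"]:
                raise ValueError(f"edge {e.edge_id} must carry roles A, B, A', B'")
            edge_count[idx] += 1
        if not np.all(face_count == 1):
            raise ValueError("every subunit must belong to exactly one face")
        if not np.all(edge_count == 2):
            raise ValueError("every subunit must belong to exactly two concave tetramers")
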