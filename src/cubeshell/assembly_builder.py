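"""Parametric generation of shell subunits, tetramers, cubes and sheets.

The generator emulates the geometry of the nucleus-like-shell protein
assemblies this package analyses: a subunit is a cuboid of roughly
60 x 40 x 70 Angstrom standing with its 70 A long axis along the local shell
normal; four subunits form a flat C4 head-to-tail tetramer with a ~100 x
100 A footprint (a pinwheel of 60 x 40 rectangles around a 20 x 20 center
pore); six such tetramers form a 220 A octahedral cube of 24 subunits whose
twelve edges each host a 2-fold-symmetric concave tetramer (roles A, B, A',
B'); tetramers tile P4 sheet lattices; and two cubes fuse into an elongated
merged particle.  Controlled perturbations plant known per-subunit tilts,
per-edge bending-angle changes and coordinate noise, so the deviation
pipeline can be validated against ground truth.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np

from .model import FACE_NORMALS, FACE_ORDER, Assembly, EdgeRecord, SubunitModel
from .point_symmetry import _axis_rotation, make_point_group
from .rigid_geometry import principal_long_axis

#: subunit cuboid edge lengths (a, b, c) in Angstrom; c is the long axis
DEFAULT_DIMS = (60.0, 40.0, 70.0)
#: pseudo-atoms per subunit (stable inertia and plane estimates)
DEFAULT_N_POINTS = 400
#: target cube bounding-box edge, Angstrom
CUBE_EDGE = 220.0
#: face-tetramer in-plane footprint = a + b with default dims, Angstrom
FOOTPRINT = DEFAULT_DIMS[0] + DEFAULT_DIMS[1]
#: face center distance from the cube center: (edge - c) / 2 puts the outer
#: subunit surface exactly on the 220 A bounding box
DEFAULT_FACE_OFFSET = (CUBE_EDGE - DEFAULT_DIMS[2]) / 2.0
#: default inter-tetramer gap in sheets; sets the auxiliary pore near 30 A
DEFAULT_SHEET_GAP = 21.0
#: default center separation of the two fused cubes; long axis = edge +
#: offset = 320 A, i.e. ~1.5 cube edges
DEFAULT_FUSION_OFFSET = 100.0
#: default seed of the subunit point cloud
DEFAULT_SEED = 7


def make_subunit(dims: tuple[float, float, float] = DEFAULT_DIMS,
                 n_points: int = DEFAULT_N_POINTS,
                 seed: int = DEFAULT_SEED) -> SubunitModel:
    """A cuboid subunit centered at the origin, long axis along +z.

    Quasi-uniform interior points plus the 8 corners (so the bounding box is
    exact) and a deterministic marker column just inside the +z "head" face
    that breaks head/tail symmetry.  The random fill is symmetrized under
    the cuboid's D2 rotations and the marker sits on the long axis, so the
    cloud's centroid is exactly the cuboid center and its inertia axes are
    exactly the cuboid axes — planted rotations are then recovered without
    sampling bias.  Bit-reproducible for a given seed.
    """
    a, b, c = dims
    if min(dims) <= 0:
        raise ValueError("subunit dimensions must be positive")
    if n_points < 20:
        raise ValueError("need at least 20 points per subunit")
    half = np.array([a, b, c]) / 2.0
    corners = np.array(list(np.ndindex(2, 2, 2)), dtype=float) * 2 - 1
    corners *= half
    # head marker: on-axis points toward +z (no off-diagonal inertia terms)
    marker = np.array([[0.0, 0.0, c / 2 - 1.5 * j] for j in range(6)])
    n_rest = n_points - len(corners) - len(marker)
    n_quad, n_extra = divmod(n_rest, 4)
    rng = np.random.default_rng(seed)
    base = rng.uniform(-half, half, size=(n_quad, 3))
    x, y, z = base.T
    fill = np.concatenate([
        np.stack([x, y, z], axis=1), np.stack([x, -y, -z], axis=1),
        np.stack([-x, y, -z], axis=1), np.stack([-x, -y, z], axis=1)])
    extra = np.array([[0.0, 0.0, (j - (n_extra - 1) / 2.0) * 2.0]
                      for j in range(n_extra)])
    pts = np.vstack([corners, marker, fill, extra])
    return SubunitModel(pts, label="S", dims=tuple(dims))


def _pinwheel_offsets(dims: tuple[float, float, float]) -> np.ndarray:
    """In-plane centers of the four pinwheel positions (C4 about +z).

    Position 0 puts the subunit's a-edge along x in the lower-left of the
    footprint square; positions 1-3 are its images under 90, 180, 270 degree
    rotations about +z.  With dims (60, 40, 70) the footprint is exactly
    100 x 100 A with a 20 x 20 A center pore.
    """
    a, b, _ = dims
    f = a + b
    c0 = np.array([-f / 2 + a / 2, -f / 2 + b / 2, 0.0])
    rz = _axis_rotation([0, 0, 1], np.pi / 2)
    return np.array([np.linalg.matrix_power(rz, k) @ c0 for k in range(4)])


def make_face_tetramer(subunit: SubunitModel | None = None) -> Assembly:
    """One flat head-to-tail tetramer in the z = 0 plane (C4 about +z)."""
    if subunit is None:
        subunit = make_subunit()
    dims = subunit.dims or DEFAULT_DIMS
    offsets = _pinwheel_offsets(dims)
    rz = _axis_rotation([0, 0, 1], np.pi / 2)
    subs = []
    for k in range(4):
        R = np.linalg.matrix_power(rz, k)
        s = subunit.transformed(R, offsets[k])
        s.label = f"T{k}"
        s.face_id = "+z"
        subs.append(s)
    return Assembly(subs, provenance="ideal", symmetry="C4",
                    faces={"+z": [0, 1, 2, 3]},
                    metadata={"footprint": dims[0] + dims[1]})


def _face_of(centroid: np.ndarray) -> str:
    ax = int(np.argmax(np.abs(centroid)))
    sign = "+" if centroid[ax] >= 0 else "-"
    return sign + "xyz"[ax]


def _annotate_cube(assembly: Assembly, face_offset: float) -> None:
    """Populate face and concave-tetramer (edge) membership tables.

    For the edge between adjacent faces f1 < f2 (canonical face order) the
    members are the two subunits of each face nearest the edge; the in-plane
    pair on f1 carries roles (A, B') and the pair on f2 carries (A', B),
    where the edge 2-fold maps A <-> A' and B <-> B'.
    """
    cents = assembly.centroids()
    faces: dict[str, list[int]] = {f: [] for f in FACE_ORDER}
    for i, c in enumerate(cents):
        faces[_face_of(c)].append(i)
    assembly.faces = {f: sorted(m) for f, m in faces.items() if m}

    edges: list[EdgeRecord] = []
    for i1, f1 in enumerate(FACE_ORDER):
        n1 = FACE_NORMALS[f1]
        for f2 in FACE_ORDER[i1 + 1:]:
            n2 = FACE_NORMALS[f2]
            if abs(n1 @ n2) > 0.5:      # same or opposite face: no edge
                continue
            members1 = sorted(assembly.faces[f1], key=lambda i: -(cents[i] @ n2))[:2]
            members2 = sorted(assembly.faces[f2], key=lambda i: -(cents[i] @ n1))[:2]
            axis2 = (n1 + n2) / np.linalg.norm(n1 + n2)
            R2 = _axis_rotation(axis2, np.pi)
            A = min(members1)
            Bp = max(members1)
            imgA = R2 @ cents[A]
            d = [np.linalg.norm(cents[j] - imgA) for j in members2]
            Ap = members2[int(np.argmin(d))]
            B = members2[1 - int(np.argmin(d))]
            hinge_point = face_offset * (n1 + n2)
            hinge_dir = np.cross(n1, n2)
            hinge_dir = hinge_dir / np.linalg.norm(hinge_dir)
            edges.append(EdgeRecord(
                edge_id=f"{f1}|{f2}", faces=(f1, f2),
                roles={"A": A, "B'": Bp, "A'": Ap, "B": B},
                hinge_point=hinge_point, hinge_direction=hinge_dir))
    assembly.edges = edges


def make_cube(subunit: SubunitModel | None = None,
              face_offset: float = DEFAULT_FACE_OFFSET) -> Assembly:
    """The ideal 24-subunit octahedral cube assembly.

    Built as the orbit of one face subunit under the octahedral rotation
    group (4-folds along x, y, z), so the assembly is exactly O-symmetric:
    six pinwheel face tetramers on +-x, +-y, +-z and twelve concave edge
    tetramers.  With default dims and offset the bounding box edge is
    exactly 220 A.
    """
    if subunit is None:
        subunit = make_subunit()
    dims = subunit.dims or DEFAULT_DIMS
    c0 = _pinwheel_offsets(dims)[0] + np.array([0.0, 0.0, face_offset])
    seed_sub = subunit.transformed(np.eye(3), c0)
    group = make_point_group("O")
    subs = []
    for i, R in enumerate(group.rotations):
        s = seed_sub.transformed(R, np.zeros(3))
        s.label = f"S{i:02d}"
        subs.append(s)
    assembly = Assembly(subs, provenance="ideal", symmetry="O",
                        metadata={"face_offset": face_offset, "dims": tuple(dims)})
    for i, s in enumerate(assembly.subunits):
        s.face_id = _face_of(s.centroid)
    _annotate_cube(assembly, face_offset)
    assembly.validate_cube_topology()
    return assembly


def make_sheet(rows: int, cols: int, gap: float = DEFAULT_SHEET_GAP,
               curvature: float = 0.0,
               subunit: SubunitModel | None = None) -> Assembly:
    """A P4-like sheet of head-to-tail tetramers.

    Tetramers sit on a square lattice with pitch = footprint + gap, in the
    z = 0 plane for curvature 0; a positive curvature (1/Angstrom) bends the
    lattice cylindrically about the y axis (each tetramer stays rigid and is
    rotated to the local tangent).
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    if gap < 0:
        raise ValueError("gap must be >= 0")
    template = make_face_tetramer(subunit)
    pitch = template.metadata["footprint"] + gap
    subs: list[SubunitModel] = []
    faces: dict[str, list[int]] = {}
    centers = []
    for i in range(cols):
        x = (i - (cols - 1) / 2.0) * pitch
        for j in range(rows):
            y = (j - (rows - 1) / 2.0) * pitch
            if curvature > 0:
                Rcyl = 1.0 / curvature
                theta = x * curvature
                R = _axis_rotation([0, 1, 0], -theta)
                t = np.array([Rcyl * np.sin(theta), y, Rcyl * (1 - np.cos(theta))])
            else:
                R = np.eye(3)
                t = np.array([x, y, 0.0])
            key = f"t{i}_{j}"
            idx0 = len(subs)
            for k, s in enumerate(template.subunits):
                sn = s.transformed(R, t)
                sn.label = f"{key}.{k}"
                sn.face_id = None
                subs.append(sn)
            faces[key] = list(range(idx0, idx0 + 4))
            centers.append(t)
    return Assembly(subs, provenance="ideal", symmetry="P4-sheet", faces=faces,
                    metadata={"rows": rows, "cols": cols, "gap": gap,
                              "pitch": pitch, "curvature": curvature,
                              "tetramer_centers": np.array(centers)})


def make_merged_particle(subunit: SubunitModel | None = None,
                         fusion_offset: float = DEFAULT_FUSION_OFFSET) -> Assembly:
    """Two cubes fused along a shared 4-fold (z) axis.

    ``fusion_offset`` is the center-to-center distance of the two cubes.
    Below one cube edge the facing faces are removed and replaced by a single
    shared tetramer at the midplane; the default offset of 100 A gives a long
    axis of 320 A, ~1.5 cube edges.  At ``fusion_offset >= edge`` the
    limiting case of two complete, disjoint cubes is produced.
    """
    if subunit is None:
        subunit = make_subunit()
    cube = make_cube(subunit)
    edge = cube.bounding_box()[1][0] - cube.bounding_box()[0][0]
    half = fusion_offset / 2.0
    subs: list[SubunitModel] = []
    if fusion_offset >= edge:
        for dz in (-half, half):
            for s in cube.subunits:
                subs.append(s.transformed(np.eye(3), np.array([0, 0, dz])))
    else:
        lower = cube.transformed(np.eye(3), np.array([0, 0, -half]))
        upper = cube.transformed(np.eye(3), np.array([0, 0, half]))
        for asm, drop in ((lower, "+z"), (upper, "-z")):
            keep = [i for i in range(asm.n_subunits)
                    if i not in asm.faces[drop]]
            subs.extend(asm.subunits[i].copy() for i in keep)
        shared = make_face_tetramer(subunit)
        subs.extend(s.copy() for s in shared.subunits)
    for i, s in enumerate(subs):
        s.label = f"M{i:02d}"
        s.face_id = None
    return Assembly(subs, provenance="ideal", symmetry="C4",
                    metadata={"fusion_offset": fusion_offset, "cube_edge": edge})


# ---------------------------------------------------------------------------
# controlled perturbations


@dataclass
class TiltSpec:
    """Planted rotation of one subunit.

    ``axis`` is either the string ``"outward"`` (hinge through the subunit's
    assembly-facing end, perpendicular to both the outward radial direction
    and the long axis, so a positive angle tips the subunit outward) or an
    explicit ``(direction, point)`` pair.
    """

    angle_deg: float
    axis: str | tuple[np.ndarray, np.ndarray] = "outward"


@dataclass
class PerturbationSpec:
    """Planted deviations applied to an ideal assembly.

    A subunit may carry a single :class:`TiltSpec` or a sequence of them
    (successive hinge rotations, applied in order).
    """

    tilts: dict[int, TiltSpec | list[TiltSpec]] = field(default_factory=dict)
    bends: dict[str, float] = field(default_factory=dict)     # edge_id -> delta deg
    sigma: float = 0.0                                        # coordinate noise, A
    dropout: list[int] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        for idx, entry in self.tilts.items():
            for t in (entry if isinstance(entry, (list, tuple)) else (entry,)):
                if not (0.0 <= abs(t.angle_deg) < 90.0):
                    raise ValueError(
                        f"tilt magnitude for subunit {idx} must be in [0, 90)")
        if self.sigma < 0:
            raise ValueError("noise sigma must be >= 0")


def _rotate_about_line(points: np.ndarray, direction: np.ndarray,
                       point: np.ndarray, angle_rad: float) -> np.ndarray:
    R = _axis_rotation(direction, angle_rad)
    return (points - point) @ R.T + point


def _outward_hinge(subunit: SubunitModel, center: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    c = subunit.centroid
    radial = c - center
    axis_line = principal_long_axis(subunit.points, radial)
    u = axis_line.direction
    v = radial - (radial @ u) * u
    nv = np.linalg.norm(v)
    if nv < 1e-9:
        # subunit centroid on the radial axis: fall back to any perpendicular
        v = np.cross(u, [0.0, 0.0, 1.0])
        if np.linalg.norm(v) < 1e-9:
            v = np.cross(u, [1.0, 0.0, 0.0])
        nv = np.linalg.norm(v)
    v = v / nv
    hinge_dir = np.cross(u, v)
    half_len = (subunit.dims[2] if subunit.dims else
                np.ptp(subunit.points @ u)) / 2.0
    hinge_point = c - half_len * u
    return hinge_dir, hinge_point


def perturb(assembly: Assembly, spec: PerturbationSpec) -> Assembly:
    """Apply planted tilts, edge bending changes and noise to an assembly.

    Subunit tilts are applied first, then per-edge bending (both concave-
    tetramer pairs rotate symmetrically about the ideal hinge line; a delta
    of -9 degrees takes the bending angle from 90 to 81), then Gaussian
    coordinate noise with per-subunit streams derived from ``spec.seed``.
    """
    out = assembly.copy()
    out.provenance = "perturbed"
    center = assembly.center
    n = out.n_subunits
    # rotations about different hinge lines do not commute; apply in a
    # canonical (sorted) order so the result depends only on the spec content
    for idx in sorted(spec.tilts):
        entry = spec.tilts[idx]
        if not (0 <= idx < n):
            raise ValueError(f"tilt refers to unknown subunit {idx}")
        s = out.subunits[idx]
        for tilt in (entry if isinstance(entry, (list, tuple)) else (entry,)):
            if tilt.axis == "outward":
                hinge_dir, hinge_point = _outward_hinge(assembly.subunits[idx], center)
            else:
                hinge_dir, hinge_point = (np.asarray(tilt.axis[0], dtype=float),
                                          np.asarray(tilt.axis[1], dtype=float))
            s.points = _rotate_about_line(s.points, hinge_dir, hinge_point,
                                          np.radians(tilt.angle_deg))
    edge_by_id = {e.edge_id: e for e in out.edges}
    for edge_id in sorted(spec.bends):
        delta = spec.bends[edge_id]
        if edge_id not in edge_by_id:
            raise ValueError(f"bend refers to unknown edge {edge_id!r}")
        e = edge_by_id[edge_id]
        if e.hinge_point is None or e.hinge_direction is None:
            raise ValueError(f"edge {edge_id!r} carries no hinge line")
        u_bis = sum(FACE_NORMALS[f] for f in e.faces)
        u_bis = u_bis / np.linalg.norm(u_bis)
        pair1, pair2 = e.pair_indices()
        for pair, face in ((pair1, e.faces[0]), (pair2, e.faces[1])):
            nrm = FACE_NORMALS[face]
            toward = np.sign(np.cross(e.hinge_direction, nrm) @ u_bis) or 1.0
            ang = np.radians(-delta / 2.0) * toward
            for idx in pair:
                s = out.subunits[idx]
                s.points = _rotate_about_line(s.points, e.hinge_direction,
                                              e.hinge_point, ang)
    if spec.sigma > 0:
        for idx, s in enumerate(out.subunits):
            rng = np.random.default_rng(np.random.SeedSequence((spec.seed, idx)))
            s.points = s.points + rng.normal(0.0, spec.sigma, size=s.points.shape)
    if spec.dropout:
        keep = [i for i in range(n) if i not in set(spec.dropout)]
        remap = {old: new for new, old in enumerate(keep)}
        out.subunits = [out.subunits[i] for i in keep]
        out.faces = {f: [remap[i] for i in m if i in remap]
                     for f, m in out.faces.items()}
        out.edges = [EdgeRecord(e.edge_id, e.faces,
                                {r: remap[i] for r, i in e.roles.items()},
                                e.hinge_point, e.hinge_direction)
                     for e in out.edges
                     if all(i in remap for i in e.roles.values())]
    out.metadata = dict(out.metadata)
    out.metadata["perturbation"] = {
        "tilts": {i: [(t.angle_deg, "outward" if t.axis == "outward" else "explicit")
                      for t in (e if isinstance(e, (list, tuple)) else (e,))]
                  for i, e in spec.tilts.items()},
        "bends": dict(spec.bends), "sigma": spec.sigma,
        "dropout": list(spec.dropout), "seed": spec.seed}
    return out


# ---------------------------------------------------------------------------
# the shipped deviation fixture


def _fixture_path():
    return importlib.resources.files("cubeshell.data") / "deviation_fixture.tsv"


def load_fixture_spec(path=None) -> PerturbationSpec:
    """Parse the plain-text deviation schedule shipped with the package."""
    res = _fixture_path() if path is None else path
    try:
        text = res.read_text() if hasattr(res, "read_text") else open(res).read()
    except (FileNotFoundError, OSError) as exc:
        raise FileNotFoundError(f"deviation fixture file not found: {res}") from exc
    tilts: dict[int, TiltSpec] = {}
    bends: dict[str, float] = {}
    sigma, seed = 0.0, 0
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        kind = parts[0]
        if kind == "meta":
            if parts[1] == "sigma":
                sigma = float(parts[2])
            elif parts[1] == "noise_seed":
                seed = int(parts[2])
        elif kind == "tilt":
            idx = int(parts[1])
            angle = float(parts[2])
            axis = np.array([float(x) for x in parts[3].split()])
            point = np.array([float(x) for x in parts[4].split()])
            tilts.setdefault(idx, []).append(TiltSpec(angle, (axis, point)))
        elif kind == "bend":
            bends[parts[1]] = float(parts[2])
        else:
            raise ValueError(f"unknown fixture row kind {kind!r}")
    return PerturbationSpec(tilts=tilts, bends=bends, sigma=sigma, seed=seed)


def make_deviation_fixture(subunit: SubunitModel | None = None
                           ) -> tuple[Assembly, Assembly]:
    """The packaged deterministic (reference, observed) deviation pair.

    The reference is the ideal cube; the observed assembly is the cube
    perturbed by the schedule shipped in ``data/deviation_fixture.tsv``
    (per-face rigid tilts, extra cap-subunit tilts near two opposite 3-fold
    corners, and per-edge bending changes, calibrated once so the measured
    statistics are a 9 degree mean face tilt, a 17 degree maximum subunit
    tilt and bending angles spanning 81-89 degrees).
    """
    reference = make_cube(subunit)
    spec = load_fixture_spec()
    observed = perturb(reference, spec)
    return reference, observed
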