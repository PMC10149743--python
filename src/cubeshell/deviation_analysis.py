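"""The symmetry-deviation pipeline.

Given a symmetry-ideal reference assembly and an observed assembly, the
pipeline aligns them globally, computes a masked per-subunit map correlation
coefficient, per-subunit long-axis tilts, per-face plane tilts, the bending
angle and gravity-center distance of every concave tetramer, classifies each
concave tetramer as 2-fold-maintained or 2-fold-broken, and summarizes.

Conventions.  Face tilt is plane-based (total-least-squares plane of the
four face subunits); subunit tilt is long-axis-based; the two are reported
separately and never mixed.  The plane of a concave-tetramer pair (A, B') is
the plane through the pair centroid whose normal is the normalized mean of
the two subunits' outward-signed long axes: for slab-shaped subunits
standing along the local shell normal this is the local shell tangent plane,
it gives exactly 90 degrees between the pairs of an ideal cube edge and 0
degrees when a hinge is flattened into a lattice.  The bending angle uses
the acute convention (cube 90, flat 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .density_maps import (DensityMap, align_maps, correlation, default_width,
                           make_grid, rasterize, subunit_mask)
from .model import Assembly
from .point_symmetry import match_equivalent_subunits
from .rigid_geometry import (Plane, Transform, angle_deg, center_distance,
                             fit_plane, principal_long_axis, subunit_tilt_deg,
                             superpose_points)

#: default dilation radius of the per-subunit correlation mask, Angstrom
DEFAULT_MASK_RADIUS = 4.0
#: default |tilt(A) - tilt(A')| threshold separating the two concave-tetramer
#: groups, degrees
DEFAULT_CLASSIFY_THRESHOLD = 3.0


@dataclass
class PipelineConfig:
    """Tunable parameters of the deviation pipeline."""

    voxel: float = 2.0                    # A
    width: float | None = None            # gaussian sigma, A (None: 0.425 * 8)
    mask_radius: float = DEFAULT_MASK_RADIUS
    classify_threshold_deg: float = DEFAULT_CLASSIFY_THRESHOLD
    compute_cc: bool = True
    pore_pixel: float = 1.0               # A
    pore_dilate: float = 2.5              # A
    seed: int = 0                         # echoed into the report

    def resolved_width(self) -> float:
        return default_width() if self.width is None else self.width


@dataclass
class TetramerGeometry:
    """Bending geometry of one concave tetramer."""

    edge_id: str
    roles: dict[str, int]
    bending_angle_deg: float      # acute: ideal cube 90, coplanar 0
    center_distance: float        # A, between pair gravity centers
    pair_residuals: tuple[float, float]
    classification: str = ""      # twofold-maintained | twofold-broken


@dataclass
class PoreMeasurement:
    """An opening in a sheet lattice."""

    pore_class: str               # center | auxiliary
    diameter: float               # A; 2 x largest inscribed circle radius
    location: np.ndarray          # in-plane coordinates, A
    enclosed: bool = True         # False when no empty region was found


@dataclass
class DeviationReport:
    """Full output of :func:`run_pipeline`."""

    transform: Transform
    global_cc: float | None
    subunits: pd.DataFrame        # ref_id, obs_id, cc, tilt_deg, outwardness
    faces: pd.DataFrame           # face_id, tilt_deg
    edges: pd.DataFrame           # edge_id, bending/deg, d/A, classification
    tetramers: list[TetramerGeometry]
    summary: dict
    pores: list[PoreMeasurement] = field(default_factory=list)
    config: PipelineConfig = field(default_factory=PipelineConfig)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def global_align(observed: Assembly | DensityMap,
                 reference: Assembly | DensityMap) -> Transform:
    """Transform superposing the observed input onto the reference.

    Model inputs use trimmed least-squares superposition of
    assignment-matched subunit centroids: after a full fit, the quarter of
    subunits with the largest centroid residuals is excluded and the fit
    repeated, so sparse internal deviations (a few displaced subunits) do
    not drag the global frame with them.  Map inputs use
    correlation-maximizing map alignment.
    """
    if isinstance(observed, DensityMap) and isinstance(reference, DensityMap):
        transform, _, _ = align_maps(observed, reference)
        return transform
    if isinstance(observed, Assembly) and isinstance(reference, Assembly):
        pairing = match_equivalent_subunits(observed, reference)
        co = observed.centroids()
        cr = reference.centroids()[pairing]
        transform, _ = superpose_points(co, cr)
        n_keep = max(3, int(np.ceil(0.75 * len(co))))
        for _ in range(2):
            residuals = np.linalg.norm(transform.apply(co) - cr, axis=1)
            keep = np.argsort(residuals, kind="stable")[:n_keep]
            if len(keep) == len(co):
                break
            transform, _ = superpose_points(co[keep], cr[keep])
        return transform
    raise TypeError("global_align needs two assemblies or two maps")


def _shared_grid(observed: Assembly, reference: Assembly, config: PipelineConfig):
    pts = np.vstack([observed.all_points(), reference.all_points()])
    return make_grid(pts, config.voxel, 3.0 * config.resolved_width()
                     + config.mask_radius)


def per_subunit_cc(observed: Assembly, reference: Assembly,
                   radius: float = DEFAULT_MASK_RADIUS,
                   pairing: np.ndarray | None = None,
                   config: PipelineConfig | None = None) -> pd.DataFrame:
    """Masked map CC per symmetry position (observed already aligned).

    Both assemblies are rasterized on one shared grid; the mask of reference
    subunit *j* is its point cloud dilated by ``radius``.  Rows are ordered
    by reference subunit id.
    """
    config = config or PipelineConfig(mask_radius=radius)
    if pairing is None:
        pairing = match_equivalent_subunits(observed, reference)
    grid = _shared_grid(observed, reference, config)
    width = config.resolved_width()
    map_obs = rasterize(observed, config.voxel, width, grid=grid)
    map_ref = rasterize(reference, config.voxel, width, grid=grid)
    inverse = np.empty_like(pairing)
    inverse[pairing] = np.arange(len(pairing))
    rows = []
    for j, ref_sub in enumerate(reference.subunits):
        mask = subunit_mask(map_ref, ref_sub, radius)
        cc = correlation(map_obs, map_ref, mask)
        rows.append({"ref_id": j, "obs_id": int(inverse[j]), "cc": cc})
    return pd.DataFrame(rows)


def subunit_tilts(observed: Assembly, reference: Assembly,
                  pairing: np.ndarray | None = None) -> pd.DataFrame:
    """Long-axis tilt (degrees, [0, 90]) and outwardness sign per subunit."""
    if pairing is None:
        pairing = match_equivalent_subunits(observed, reference)
    center_r = reference.center
    center_o = observed.center
    rows = []
    for i, j in enumerate(pairing):
        sub_o = observed.subunits[i]
        sub_r = reference.subunits[j]
        tilt = subunit_tilt_deg(sub_o, sub_r, center=center_r)
        u_r = principal_long_axis(sub_r.points, sub_r.centroid - center_r).direction
        u_o = principal_long_axis(sub_o.points, sub_o.centroid - center_o).direction
        radial = sub_r.centroid - center_r
        v = radial - (radial @ u_r) * u_r
        nv = np.linalg.norm(v)
        outward = 0.0
        if nv > 1e-9 and tilt > 1e-9:
            outward = float(np.sign((u_o - u_r) @ (v / nv)))
        rows.append({"ref_id": int(j), "obs_id": i, "tilt_deg": tilt,
                     "outwardness": outward})
    return pd.DataFrame(rows).sort_values("ref_id", ignore_index=True)


def face_tilts(observed: Assembly, reference: Assembly,
               pairing: np.ndarray | None = None) -> pd.DataFrame:
    """Angle between observed and reference face-tetramer planes, per face."""
    if pairing is None:
        pairing = match_equivalent_subunits(observed, reference)
    inverse = np.empty_like(pairing)
    inverse[pairing] = np.arange(len(pairing))
    rows = []
    for face_id, ref_members in reference.faces.items():
        try:
            plane_r = fit_plane(np.vstack([reference.subunits[j].points
                                           for j in ref_members]))
            obs_members = [int(inverse[j]) for j in ref_members]
            plane_o = fit_plane(np.vstack([observed.subunits[i].points
                                           for i in obs_members]))
        except Exception as exc:
            raise PipelineStageError(f"face_tilts[{face_id}]: {exc}") from exc
        rows.append({"face_id": face_id, "tilt_deg": angle_deg(plane_o, plane_r)})
    return pd.DataFrame(rows)


def _pair_plane(assembly: Assembly, pair: tuple[int, int],
                center: np.ndarray) -> Plane:
    """Shell-tangent plane of a concave-tetramer pair.

    Normal = normalized mean of the two outward-signed subunit long axes;
    point = pair gravity center; residual = rms point-plane distance.
    """
    axes = []
    pts = []
    for idx in pair:
        s = assembly.subunits[idx]
        axes.append(principal_long_axis(s.points, s.centroid - center).direction)
        pts.append(s.points)
    normal = axes[0] + axes[1]
    pts = np.vstack(pts)
    plane = Plane(normal, pts.mean(axis=0))
    plane.residual = float(np.sqrt((plane.distance(pts) ** 2).mean()))
    return plane


def bending_geometry(assembly: Assembly) -> list[TetramerGeometry]:
    """Bending angle and gravity-center distance for every concave tetramer."""
    if not assembly.edges:
        raise ValueError("assembly carries no concave-tetramer (edge) records")
    center = assembly.center
    out = []
    for e in assembly.edges:
        pair1, pair2 = e.pair_indices()
        p1 = _pair_plane(assembly, pair1, center)
        p2 = _pair_plane(assembly, pair2, center)
        theta = angle_deg(p1, p2)
        d = center_distance(np.vstack([assembly.subunits[i].points for i in pair1]),
                            np.vstack([assembly.subunits[i].points for i in pair2]))
        out.append(TetramerGeometry(e.edge_id, dict(e.roles), theta, d,
                                    (p1.residual, p2.residual)))
    return out


def classify_tetramers(geometries: list[TetramerGeometry],
                       tilts: pd.DataFrame,
                       threshold_deg: float = DEFAULT_CLASSIFY_THRESHOLD
                       ) -> list[TetramerGeometry]:
    """Two-group classification of the concave tetramers.

    An edge is 2-fold-broken when the tilt deviations of either pair of
    2-fold-related subunits (A vs A', B vs B') differ by more than
    ``threshold_deg``; a symmetric deformation (both pairs moved equally)
    keeps the 2-fold and stays "maintained" even at a reduced bending angle.
    """
    tilt_by_ref = dict(zip(tilts["ref_id"], tilts["tilt_deg"]))
    for g in geometries:
        dA = abs(tilt_by_ref[g.roles["A"]] - tilt_by_ref[g.roles["A'"]])
        dB = abs(tilt_by_ref[g.roles["B"]] - tilt_by_ref[g.roles["B'"]])
        g.classification = ("twofold-broken" if max(dA, dB) > threshold_deg
                            else "twofold-maintained")
    return geometries


# ---------------------------------------------------------------------------
# sheet pores


def measure_pores(sheet: Assembly, pixel: float = 1.0,
                  dilate: float = 2.5) -> list[PoreMeasurement]:
    """Center and auxiliary pore diameters of a sheet lattice.

    Points are projected onto the lattice plane and rasterized into an
    occupancy image (pixels within ``dilate`` of a projected point are
    occupied).  The center pore of each tetramer sits at its 4-fold center;
    auxiliary pores sit at the interior 4-fold junctions between tetramers.
    The diameter is twice the maximum of the Euclidean distance transform
    over empty pixels within a quarter-pitch window of the expected
    location.
    """
    centers = sheet.metadata.get("tetramer_centers")
    pitch = sheet.metadata.get("pitch")
    rows = sheet.metadata.get("rows")
    cols = sheet.metadata.get("cols")
    if centers is None or pitch is None:
        raise ValueError("measure_pores needs a generated sheet assembly")
    if rows * cols < 4:
        raise ValueError("measure_pores needs at least a 2 x 2 sheet")
    plane = fit_plane(np.asarray(centers).reshape(-1, 3)) if len(centers) >= 3 \
        else Plane(np.array([0.0, 0.0, 1.0]), np.zeros(3))
    n = plane.normal
    e1 = np.array([1.0, 0.0, 0.0])
    if abs(n @ e1) > 0.9:
        e1 = np.array([0.0, 1.0, 0.0])
    e1 = e1 - (e1 @ n) * n
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)

    pts = sheet.all_points() - plane.point
    uv = np.stack([pts @ e1, pts @ e2], axis=1)
    lo = uv.min(axis=0) - 2 * dilate
    hi = uv.max(axis=0) + 2 * dilate
    shape = tuple(int(np.ceil((hi[k] - lo[k]) / pixel)) + 1 for k in range(2))
    point_mask = np.zeros(shape, dtype=bool)
    idx = np.clip(np.rint((uv - lo) / pixel).astype(int), 0,
                  np.array(shape) - 1)
    point_mask[idx[:, 0], idx[:, 1]] = True
    occupied = ndimage.distance_transform_edt(~point_mask) * pixel <= dilate
    empty_dist = ndimage.distance_transform_edt(~occupied) * pixel

    def measure_at(loc_uv: np.ndarray, pore_class: str) -> PoreMeasurement:
        window = pitch / 4.0
        i0 = np.maximum(np.floor((loc_uv - window - lo) / pixel), 0).astype(int)
        i1 = np.minimum(np.ceil((loc_uv + window - lo) / pixel),
                        np.array(shape) - 1).astype(int)
        region = empty_dist[i0[0]:i1[0] + 1, i0[1]:i1[1] + 1]
        best = float(region.max()) if region.size else 0.0
        return PoreMeasurement(pore_class, 2.0 * best, loc_uv.copy(),
                               enclosed=best > 0)

    out = []
    centers3 = np.asarray(centers).reshape(-1, 3) - plane.point
    centers_uv = np.stack([centers3 @ e1, centers3 @ e2], axis=1)
    for c_uv in centers_uv:
        out.append(measure_at(c_uv, "center"))
    # interior junctions: average of the four surrounding tetramer centers
    grid_uv = centers_uv.reshape(cols, rows, 2)
    for i in range(cols - 1):
        for j in range(rows - 1):
            junction = 0.25 * (grid_uv[i, j] + grid_uv[i + 1, j]
                               + grid_uv[i, j + 1] + grid_uv[i + 1, j + 1])
            out.append(measure_at(junction, "auxiliary"))
    return out


# ---------------------------------------------------------------------------
# the end-to-end pipeline


def run_pipeline(reference: Assembly, observed: Assembly,
                 config: PipelineConfig | None = None) -> DeviationReport:
    """Full deviation analysis of an observed assembly against a reference.

    Stages: global alignment -> per-subunit masked CC -> per-subunit
    long-axis tilts -> per-face plane tilts -> concave-tetramer bending
    geometry -> two-group classification -> summary.  Deterministic given
    the inputs and configuration.  Any stage failure raises
    :class:`PipelineStageError` naming the stage; no partial report is
    returned.
    """
    config = config or PipelineConfig()

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError(f"{name}: {exc}") from exc

    transform = stage("global_align", global_align, observed, reference)
    aligned = observed.transformed(transform.rotation, transform.translation)
    pairing = stage("match_subunits", match_equivalent_subunits, aligned, reference)

    global_cc = None
    cc_table = None
    if config.compute_cc:
        grid = _shared_grid(aligned, reference, config)
        width = config.resolved_width()
        map_obs = stage("rasterize", rasterize, aligned, config.voxel, width, grid=grid)
        map_ref = stage("rasterize", rasterize, reference, config.voxel, width, grid=grid)
        global_cc = stage("global_cc", correlation, map_obs, map_ref)
        cc_table = stage("per_subunit_cc", per_subunit_cc, aligned, reference,
                         config.mask_radius, pairing, config)

    tilt_table = stage("subunit_tilts", subunit_tilts, aligned, reference, pairing)
    if cc_table is not None:
        tilt_table = tilt_table.merge(cc_table[["ref_id", "cc"]], on="ref_id")
    else:
        tilt_table["cc"] = np.nan
    face_table = stage("face_tilts", face_tilts, aligned, reference, pairing)

    tetramers: list[TetramerGeometry] = []
    edges_df = pd.DataFrame()
    if aligned.edges:
        tetramers = stage("bending_geometry", bending_geometry, aligned)
        tetramers = stage("classify_tetramers", classify_tetramers, tetramers,
                          tilt_table, config.classify_threshold_deg)
        edges_df = pd.DataFrame([{
            "edge_id": g.edge_id, "bending_angle_deg": g.bending_angle_deg,
            "center_distance_A": g.center_distance,
            "residual_AB'": g.pair_residuals[0],
            "residual_A'B": g.pair_residuals[1],
            "classification": g.classification,
            **{f"role_{r}": i for r, i in g.roles.items()},
        } for g in tetramers])

    summary = {
        "n_subunits": reference.n_subunits,
        "n_faces": len(reference.faces),
        "n_edges": len(reference.edges),
        "global_cc": global_cc,
        "mean_face_tilt_deg": float(face_table["tilt_deg"].mean()) if len(face_table) else np.nan,
        "max_subunit_tilt_deg": float(tilt_table["tilt_deg"].max()),
        "mean_subunit_tilt_deg": float(tilt_table["tilt_deg"].mean()),
        "bending_angle_min_deg": float(edges_df["bending_angle_deg"].min()) if len(edges_df) else np.nan,
        "bending_angle_max_deg": float(edges_df["bending_angle_deg"].max()) if len(edges_df) else np.nan,
        "n_twofold_broken": int((edges_df["classification"] == "twofold-broken").sum()) if len(edges_df) else 0,
        "global_rotation_deg": transform.rotation_angle_deg,
        "global_translation_A": float(np.linalg.norm(transform.translation)),
        "seed": config.seed,
    }
    cols = ["ref_id", "obs_id", "cc", "tilt_deg", "outwardness"]
    return DeviationReport(
        transform=transform, global_cc=global_cc,
        subunits=tilt_table[cols], faces=face_table, edges=edges_df,
        tetramers=tetramers, summary=summary, config=config)
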