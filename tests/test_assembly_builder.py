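"""Generators: subunit, tetramer, cube, sheet, merged particle, perturbations."""

import numpy as np
import pytest

from cubeshell.assembly_builder import (CUBE_EDGE, PerturbationSpec, TiltSpec,
                                        load_fixture_spec, make_cube,
                                        make_deviation_fixture,
                                        make_face_tetramer,
                                        make_merged_particle, make_sheet,
                                        make_subunit, perturb)
from cubeshell.deviation_analysis import bending_geometry, subunit_tilts
from cubeshell.point_symmetry import make_point_group, match_equivalent_subunits
from cubeshell.rigid_geometry import fit_plane, principal_long_axis
from tests.test_rigid_geometry import rotation_about


# ---------------------------------------------------------------------- subunit

def test_subunit_bounding_box_and_axis():
    sub = make_subunit()
    box = sub.points.max(axis=0) - sub.points.min(axis=0)
    np.testing.assert_allclose(box, [60.0, 40.0, 70.0], atol=1.0)
    ax = principal_long_axis(sub.points)
    assert abs(ax.direction @ [0, 0, 1]) > 1 - 1e-12


def test_subunit_reproducible_and_seed_sensitive():
    a = make_subunit(seed=123)
    b = make_subunit(seed=123)
    c = make_subunit(seed=124)
    np.testing.assert_array_equal(a.points, b.points)
    assert not np.array_equal(a.points, c.points)


def test_subunit_head_tail_asymmetry():
    """A 180 degree flip about x does not map the cloud onto itself."""
    sub = make_subunit()
    flipped = sub.points @ rotation_about([1, 0, 0], 180.0).T
    from scipy.spatial import cKDTree
    d, _ = cKDTree(sub.points).query(flipped)
    assert d.max() > 2.0          # the head marker singles out one end


def test_subunit_validation():
    with pytest.raises(ValueError):
        make_subunit(dims=(0, 40, 70))
    with pytest.raises(ValueError):
        make_subunit(n_points=10)


# ------------------------------------------------------------------- tetramer

def test_face_tetramer_c4_and_footprint():
    tet = make_face_tetramer()
    box = tet.bounding_box()
    np.testing.assert_allclose((box[1] - box[0])[:2], [100.0, 100.0], atol=5.0)
    assert [s.face_id for s in tet.subunits] == ["+z"] * 4
    # a 90 degree rotation about the face normal permutes the four subunits
    moved = tet.transformed(rotation_about([0, 0, 1], 90.0), np.zeros(3))
    pairing = match_equivalent_subunits(moved, tet)
    assert sorted(pairing) == [0, 1, 2, 3] and list(pairing) != [0, 1, 2, 3]
    for i, j in enumerate(pairing):
        np.testing.assert_allclose(moved.subunits[i].points,
                                   tet.subunits[j].points, atol=1e-9)


def test_face_tetramer_neighbors_perpendicular_in_plane():
    """Adjacent molecules of the head-to-tail tetramer are rotated 90 deg."""
    tet = make_face_tetramer()
    # in-plane long direction of each subunit (the 60 A edge)
    dirs = []
    for s in tet.subunits:
        c = s.points - s.points.mean(axis=0)
        cov = np.cov(c[:, :2].T)
        w, v = np.linalg.eigh(cov)
        dirs.append(v[:, -1])
    for k in range(4):
        dot = abs(dirs[k] @ dirs[(k + 1) % 4])
        assert dot < 1e-6          # perpendicular neighbors


# ----------------------------------------------------------------------- cube

def test_cube_census():
    cube = make_cube()
    assert cube.n_subunits == 24
    assert len(cube.faces) == 6
    assert len(cube.edges) == 12
    cube.validate_cube_topology()   # 1 face and 2 edges per subunit


def test_cube_bounding_box_edge():
    box = make_cube().bounding_box()
    np.testing.assert_allclose(box[1] - box[0], CUBE_EDGE, atol=5.0)


def test_cube_is_octahedrally_symmetric():
    """All 24 octahedral rotations map the assembly onto itself."""
    cube = make_cube()
    for R in make_point_group("O").rotations:
        moved = cube.transformed(R, np.zeros(3))
        pairing = match_equivalent_subunits(moved, cube)
        for i, j in enumerate(pairing):
            err = np.abs(moved.subunits[i].points - cube.subunits[j].points).max()
            assert err < 1e-6


def test_cube_concave_tetramer_roles():
    """Each edge carries roles A, B, A', B'; pairs sit on the two faces."""
    cube = make_cube()
    for e in cube.edges:
        assert sorted(e.roles) == ["A", "A'", "B", "B'"]
        (a, bp), (ap, b) = e.pair_indices()
        f1, f2 = e.faces
        assert {a, bp} <= set(cube.faces[f1])
        assert {ap, b} <= set(cube.faces[f2])


# ---------------------------------------------------------------------- sheet

def test_sheet_flat_and_pitch():
    sheet = make_sheet(3, 3, gap=21.0)
    centers = sheet.metadata["tetramer_centers"]
    assert fit_plane(centers).residual < 1e-9
    pitch = sheet.metadata["pitch"]
    d = np.linalg.norm(centers[0] - centers[1])
    assert d == pytest.approx(pitch, abs=1e-9)


def test_sheet_lattice_translation_symmetry():
    sheet = make_sheet(2, 2, gap=10.0)
    pitch = sheet.metadata["pitch"]
    # translating by one pitch maps the first tetramer onto its neighbor
    t0 = np.vstack([sheet.subunits[i].points for i in sheet.faces["t0_0"]])
    t1 = np.vstack([sheet.subunits[i].points for i in sheet.faces["t0_1"]])
    np.testing.assert_allclose(t0 + [0, pitch, 0], t1, atol=1e-9)


def test_sheet_curvature_bends_cylindrically():
    sheet = make_sheet(2, 3, gap=10.0, curvature=1.0 / 500.0)
    centers = sheet.metadata["tetramer_centers"]
    radii = np.linalg.norm(centers[:, [0, 2]] - [0.0, 500.0], axis=1)
    np.testing.assert_allclose(radii, 500.0, atol=1e-6)


# ------------------------------------------------------------ merged particle

def test_merged_particle_long_axis_and_ratio():
    cube = make_cube()
    edge = float((cube.bounding_box()[1] - cube.bounding_box()[0])[0])
    merged = make_merged_particle()
    box = merged.bounding_box()
    long_axis = float((box[1] - box[0])[2])
    assert long_axis == pytest.approx(320.0, abs=5.0)
    assert long_axis / edge == pytest.approx(1.5, abs=0.1)


def test_merged_particle_limiting_case_disjoint():
    merged = make_merged_particle(fusion_offset=250.0)
    assert merged.n_subunits == 48
    box = merged.bounding_box()
    assert float((box[1] - box[0])[2]) == pytest.approx(220.0 + 250.0, abs=1e-6)


def test_merged_particle_symmetry_is_c4_not_o():
    merged = make_merged_particle()

    def self_maps(R):
        moved = merged.transformed(R, np.zeros(3))
        pairing = match_equivalent_subunits(moved, merged)
        err = max(np.abs(moved.subunits[i].points
                         - merged.subunits[j].points).max()
                  for i, j in enumerate(pairing))
        return err < 1e-6

    assert self_maps(rotation_about([0, 0, 1], 90.0))        # the shared 4-fold
    assert not self_maps(rotation_about([1, 0, 0], 90.0))    # no other 4-fold
    assert not self_maps(rotation_about([0, 1, 0], 90.0))


# --------------------------------------------------------------- perturbation

def test_perturb_empty_spec_is_identity():
    cube = make_cube()
    out = perturb(cube, PerturbationSpec())
    for a, b in zip(out.subunits, cube.subunits):
        np.testing.assert_array_equal(a.points, b.points)


def test_perturb_single_tilt_recovered():
    cube = make_cube()
    obs = perturb(cube, PerturbationSpec(tilts={5: TiltSpec(17.0)}))
    tilts = subunit_tilts(obs, cube)
    row = tilts[tilts.ref_id == 5]
    assert float(row.tilt_deg.iloc[0]) == pytest.approx(17.0, abs=1e-6)
    assert float(row.outwardness.iloc[0]) == 1.0
    assert tilts[tilts.ref_id != 5].tilt_deg.max() < 1e-9


def test_perturb_single_bend_recovered():
    cube = make_cube()
    eid = cube.edges[3].edge_id
    obs = perturb(cube, PerturbationSpec(bends={eid: -9.0}))
    for g in bending_geometry(obs):
        expected = 81.0 if g.edge_id == eid else 90.0
        assert g.bending_angle_deg == pytest.approx(expected, abs=1e-6)


def test_perturb_unknown_ids_raise():
    cube = make_cube()
    with pytest.raises(ValueError, match="unknown subunit"):
        perturb(cube, PerturbationSpec(tilts={99: TiltSpec(5.0)}))
    with pytest.raises(ValueError, match="unknown edge"):
        perturb(cube, PerturbationSpec(bends={"nope": -5.0}))


def test_perturb_noise_reproducible():
    cube = make_cube()
    spec = PerturbationSpec(sigma=0.5, seed=77)
    a = perturb(cube, spec)
    b = perturb(cube, spec)
    for sa, sb in zip(a.subunits, b.subunits):
        np.testing.assert_array_equal(sa.points, sb.points)


def test_bending_distance_monotone_with_angle():
    """Gravity-center distance increases strictly as the hinge flattens."""
    cube = make_cube()
    eid = cube.edges[0].edge_id
    thetas, dists = [], []
    for delta in np.arange(-5.0, -90.1, -5.0):
        obs = perturb(cube, PerturbationSpec(bends={eid: float(delta)}))
        g = next(g for g in bending_geometry(obs) if g.edge_id == eid)
        thetas.append(g.bending_angle_deg)
        dists.append(g.center_distance)
    assert all(a > b for a, b in zip(thetas, thetas[1:]))
    assert all(a < b for a, b in zip(dists, dists[1:]))


# -------------------------------------------------------------------- fixture

def test_fixture_loads_and_is_deterministic():
    spec = load_fixture_spec()
    assert spec.sigma > 0 and spec.bends and spec.tilts
    ref1, obs1 = make_deviation_fixture()
    ref2, obs2 = make_deviation_fixture()
    for a, b in zip(obs1.subunits, obs2.subunits):
        np.testing.assert_array_equal(a.points, b.points)
    assert ref1.provenance == "ideal" and obs1.provenance == "perturbed"
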