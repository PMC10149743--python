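"""Regenerate the packaged deviation-fixture schedule.

The fixture plants three kinds of deviation on the ideal cube:

* a rigid tilt of each face tetramer about an in-plane axis through the
  face center (measured face-plane tilts average exactly 9 degrees);
* per-subunit tilts about parallel axes through each subunit's base; the
  six "cap" subunits nearest two opposite 3-fold corners tilt far more
  than everyone else (maximum measured subunit tilt exactly 17 degrees),
  while the remaining subunits receive small corrective tilts that make
  the planted tilt ordering match the displacement (and therefore the
  masked-CC) ordering;
* a bending change on every cube edge (measured bending angles span
  exactly 81-89 degrees; corner edges, whose concave tetramers contain two
  cap subunits, take the smaller angles).

The solve proceeds in phases: (A) the 24-unknown system (face tilts, cap
tilts, bends) by secant Gauss-Seidel plus Newton polish; (B) measurement
of each subunit's displacement under that schedule; (C) the 42-unknown
system with per-subunit tilt targets assigned by displacement rank, warm
started from phase A.  The result is frozen into
src/cubeshell/data/deviation_fixture.tsv and never re-fit at run time.

Run from the repository root:  python scripts/build_fixture.py
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from cubeshell.assembly_builder import (DEFAULT_DIMS, DEFAULT_FACE_OFFSET,
                                        PerturbationSpec, TiltSpec, make_cube,
                                        perturb)
from cubeshell.deviation_analysis import (PipelineConfig, global_align,
                                          run_pipeline)
from cubeshell.model import FACE_NORMALS, FACE_ORDER

# measured-statistic targets (degrees)
FACE_TILT_TARGETS = {"+z": 10.5, "+x": 10.0, "+y": 9.5,
                     "-x": 8.5, "-y": 8.0, "-z": 7.5}       # mean exactly 9
CAP_TILT_VALUES = [17.0, 16.5, 16.0, 15.75, 15.5, 15.25]    # max exactly 17
NONCAP_MIN_GAP = 0.08     # deg, minimal spacing of non-cap tilt targets
BEND_MIN, BEND_MAX = 81.0, 89.0

SIGMA = 0.1          # Angstrom, coordinate noise of the shipped fixture
NOISE_SEED = 314159

# each face tips its normal toward an in-plane coordinate direction; all
# hinge axes of one face are parallel, so tilts compose additively
FACE_TIP = {"+z": np.array([1.0, 0.0, 0.0]), "-z": np.array([-1.0, 0.0, 0.0]),
            "+x": np.array([0.0, 1.0, 0.0]), "-x": np.array([0.0, -1.0, 0.0]),
            "+y": np.array([0.0, 0.0, 1.0]), "-y": np.array([0.0, 0.0, -1.0])}

TOP_CORNER = np.array([1.0, 1.0, 1.0]) * 110.0
BOTTOM_CORNER = -TOP_CORNER

GEOM = PipelineConfig(compute_cc=False)


class Problem:
    def __init__(self):
        self.cube = make_cube()
        cents = self.cube.centroids()
        self.face_of = {i: f for f, m in self.cube.faces.items() for i in m}
        self.caps = {}
        for face, members in self.cube.faces.items():
            corner = TOP_CORNER if "-" not in face else BOTTOM_CORNER
            self.caps[face] = min(members,
                                  key=lambda i: np.linalg.norm(cents[i] - corner))
        cap_ids = set(self.caps.values())
        self.face_axis = {f: (np.cross(FACE_NORMALS[f], FACE_TIP[f]),
                              DEFAULT_FACE_OFFSET * FACE_NORMALS[f])
                          for f in FACE_ORDER}
        self.base_axis = {
            i: (self.face_axis[self.face_of[i]][0],
                cents[i] - (DEFAULT_DIMS[2] / 2.0) * FACE_NORMALS[self.face_of[i]])
            for i in range(24)}
        # per-subunit extra-tilt axes; phase C re-aims the non-cap ones
        # along each subunit's natural tip direction
        self.extra_axis = dict(self.base_axis)
        corner_edges = sorted(e.edge_id for e in self.cube.edges
                              if len(cap_ids & set(e.roles.values())) >= 2)
        equator_edges = sorted(e.edge_id for e in self.cube.edges
                               if e.edge_id not in corner_edges)
        self.edge_ids = corner_edges + equator_edges
        # assign the 12 bending targets (corner edges take the small angles)
        # so that no single subunit accumulates two large deltas: search
        # random permutations for the assignment minimizing the largest
        # per-subunit |delta| sum
        all_t = np.linspace(BEND_MIN, BEND_MAX, 12)
        edge_members = {e.edge_id: [i for i in e.roles.values()
                                    if i not in cap_ids]
                        for e in self.cube.edges}
        rng = np.random.default_rng(12345)
        best = None
        for _ in range(4000):
            ct = rng.permutation(all_t[:6])
            et = rng.permutation(all_t[6:])
            cand = dict(zip(corner_edges, ct)) | dict(zip(equator_edges, et))
            load = {}
            for eid, members in edge_members.items():
                for i in members:
                    load[i] = load.get(i, 0.0) + abs(cand[eid] - 90.0)
            score = max(load.values())
            if best is None or score < best[0]:
                best = (score, cand)
        self.bend_targets = best[1]
        print(f"[init] bend assignment max per-subunit |delta| sum: "
              f"{best[0]:.2f} deg", flush=True)

    def build_spec(self, phi, extras, bends, extras2=None):
        tilts = {}
        for i in range(24):
            f = self.face_of[i]
            entry = [TiltSpec(phi[f], self.face_axis[f])]
            if abs(extras.get(i, 0.0)) > 1e-12:
                entry.append(TiltSpec(extras[i], self.extra_axis[i]))
            if extras2 and abs(extras2.get(i, 0.0)) > 1e-12:
                entry.append(TiltSpec(extras2[i], self.extra2_axis[i]))
            tilts[i] = entry
        return PerturbationSpec(tilts=tilts, bends=dict(bends),
                                sigma=SIGMA, seed=NOISE_SEED)

    def observed(self, phi, extras, bends, extras2=None):
        return perturb(self.cube, self.build_spec(phi, extras, bends, extras2))

    def measure(self, phi, extras, bends, config=GEOM, extras2=None):
        rep = run_pipeline(self.cube,
                           self.observed(phi, extras, bends, extras2), config)
        m_face = dict(zip(rep.faces.face_id, rep.faces.tilt_deg))
        m_tilt = dict(zip(rep.subunits.ref_id, rep.subunits.tilt_deg))
        m_bend = dict(zip(rep.edges.edge_id, rep.edges.bending_angle_deg))
        return m_face, m_tilt, m_bend, rep

    def displacements(self, phi, extras, bends):
        obs = self.observed(phi, extras, bends)
        tf = global_align(obs, self.cube)
        aligned = obs.transformed(tf.rotation, tf.translation)
        return {i: float(np.sqrt(((aligned.subunits[i].points
                                   - self.cube.subunits[i].points) ** 2)
                                 .sum(axis=1).mean()))
                for i in range(24)}


def solve(problem, unknowns, targets, x0, label, base, gs_sweeps=25,
          gs_tol=0.5, newton_iters=8):
    """Generic solver: secant GS to get close, Newton (lstsq) to finish.

    ``unknowns``: list of ("face", f) / ("extra", i) / ("bend", eid);
    ``targets``: matching measured-value targets; ``base``: the (phi,
    extras, bends) state that parameters outside ``unknowns`` keep.
    """
    base_phi, base_extras, base_bends = base

    def unpack(x):
        phi = dict(base_phi)
        extras = dict(base_extras)
        bends = dict(base_bends)
        for (kind, key), v in zip(unknowns, x):
            if kind == "face":
                phi[key] = v
            elif kind == "extra":
                extras[key] = v
            else:
                bends[key] = v
        return phi, extras, bends

    def residuals(x):
        m_face, m_tilt, m_bend, _ = problem.measure(*unpack(x))
        out = np.empty(len(unknowns))
        for j, ((kind, key), t) in enumerate(zip(unknowns, targets)):
            if kind == "face":
                out[j] = m_face[key] - t
            elif kind == "extra":
                out[j] = m_tilt[key] - t
            else:
                out[j] = m_bend[key] - t
        return out

    x = np.asarray(x0, dtype=float).copy()
    n = len(x)
    slope = np.ones(n)
    resid = residuals(x)
    for sweep in range(gs_sweeps):
        err = np.abs(resid).max()
        print(f"[{label}] sweep {sweep:2d}  max residual {err:.3e}", flush=True)
        if err < gs_tol:
            break
        for k in range(n):
            if abs(resid[k]) < 1e-7:
                continue
            step = float(np.clip(-0.85 * resid[k] / slope[k], -3.0, 3.0))
            x[k] += step
            new = residuals(x)
            ds = (new[k] - resid[k]) / step
            if 0.05 < abs(ds) < 20.0:
                slope[k] = ds
            resid = new
    h = 0.02
    for it in range(newton_iters):
        err = np.abs(resid).max()
        print(f"[{label}] newton {it:2d}  max residual {err:.3e}", flush=True)
        if err < 1e-6:
            break
        J = np.empty((n, n))
        for k in range(n):
            xp, xm = x.copy(), x.copy()
            xp[k] += h
            xm[k] -= h
            J[:, k] = (residuals(xp) - residuals(xm)) / (2 * h)
        step, *_ = np.linalg.lstsq(J, -resid, rcond=None)
        x = x + np.clip(step, -2.5, 2.5)
        resid = residuals(x)
    print(f"[{label}] final max residual {np.abs(resid).max():.3e}", flush=True)
    return x, unpack(x), resid


def main():
    p = Problem()

    # ---- phase A: faces + caps + bends (24 unknowns)
    import json
    cache = Path(__file__).resolve().parents[1] / "scratch/phase_a.json"
    if cache.exists():
        saved = json.loads(cache.read_text())
        phi = saved["phi"]
        extras = {int(k): v for k, v in saved["extras"].items()}
        bends = saved["bends"]
        print("[A] loaded cached phase-A solution", flush=True)
    else:
        unknowns_a = ([("face", f) for f in FACE_ORDER]
                      + [("extra", p.caps[f]) for f in FACE_ORDER]
                      + [("bend", eid) for eid in p.edge_ids])
        cap_targets = dict(zip([p.caps[f] for f in FACE_ORDER], CAP_TILT_VALUES))
        targets_a = ([FACE_TILT_TARGETS[f] for f in FACE_ORDER]
                     + [cap_targets[p.caps[f]] for f in FACE_ORDER]
                     + [p.bend_targets[eid] for eid in p.edge_ids])
        x0 = np.concatenate([
            [FACE_TILT_TARGETS[f] for f in FACE_ORDER],
            [cap_targets[p.caps[f]] - FACE_TILT_TARGETS[f] for f in FACE_ORDER],
            [p.bend_targets[eid] - 90.0 for eid in p.edge_ids]])
        base0 = (dict(FACE_TILT_TARGETS), {},
                 {eid: p.bend_targets[eid] - 90.0 for eid in p.edge_ids})
        xa, (phi, extras, bends), _ = solve(p, unknowns_a, targets_a, x0,
                                            "A", base0)
        cache.parent.mkdir(exist_ok=True)
        cache.write_text(json.dumps({"phi": phi, "extras": extras,
                                     "bends": bends}))

    # ---- phase B: displacement ranks under the phase-A schedule
    disp = p.displacements(phi, extras, bends)
    _, m_tilt, _, _ = p.measure(phi, extras, bends)
    cap_ids = set(p.caps.values())
    noncaps = [i for i in range(24) if i not in cap_ids]
    # caps: largest tilt target to the most displaced cap
    caps_by_disp = sorted(cap_ids, key=lambda i: -disp[i])
    cap_targets = dict(zip(caps_by_disp, CAP_TILT_VALUES))
    # non-caps: the smallest corrections that make planted-tilt order match
    # displacement (hence CC) order — isotonic regression of the natural
    # tilts against displacement rank, with a small strict gap
    from sklearn.isotonic import IsotonicRegression
    noncaps_by_disp = sorted(noncaps, key=lambda i: -disp[i])
    seq = np.array([m_tilt[i] for i in noncaps_by_disp])
    iso = IsotonicRegression(increasing=False).fit_transform(
        np.arange(len(seq)), seq)
    vals = list(iso)
    for j in range(1, len(vals)):
        vals[j] = min(vals[j], vals[j - 1] - NONCAP_MIN_GAP)
    noncap_targets = dict(zip(noncaps_by_disp, vals))
    print("[B] cap disp:", {i: round(disp[i], 2) for i in caps_by_disp}, flush=True)
    print("[B] noncap disp:", {i: round(disp[i], 2) for i in noncaps_by_disp},
          flush=True)
    print("[B] noncap targets:", {i: round(noncap_targets[i], 2)
                                  for i in noncaps_by_disp}, flush=True)

    # ---- phase C: one weighted trust-region least-squares over all 42
    # inputs.  Faces, cap tilts and bends are hard targets (weight 10); the
    # 18 non-cap tilt targets are soft (weight 1) rank-shaping terms -- only
    # their ordering matters for the CC-rank property, so small residuals
    # there are acceptable.  All extra tilts stay in the parallel-axis
    # family of their face (linear responses); the Jacobian is an explicit
    # central difference with a fixed 0.05-degree step, which keeps the
    # finite differences well above the measurement's curvature scale.
    from scipy.optimize import least_squares

    tilt_targets = {**cap_targets, **noncap_targets}
    cap_list = [p.caps[f] for f in FACE_ORDER]
    hard_w, soft_w = 10.0, 2.5

    def pack_state(phi, extras, bends):
        return np.concatenate([
            [phi[f] for f in FACE_ORDER],
            [extras.get(i, 0.0) for i in range(24)],
            [bends[eid] for eid in p.edge_ids]])

    def unpack_state(x):
        return (dict(zip(FACE_ORDER, x[:6])),
                {i: float(x[6 + i]) for i in range(24)},
                dict(zip(p.edge_ids, x[30:])))

    def residuals(x):
        m_face, m_tilt, m_bend, _ = p.measure(*unpack_state(x))
        rows = []
        for f in FACE_ORDER:
            rows.append(hard_w * (m_face[f] - FACE_TILT_TARGETS[f]))
        for i in range(24):
            w = hard_w if i in cap_ids else soft_w
            rows.append(w * (m_tilt[i] - tilt_targets[i]))
        for eid in p.edge_ids:
            rows.append(hard_w * (m_bend[eid] - p.bend_targets[eid]))
        return np.array(rows)

    H = 0.05

    def jacobian(x):
        J = np.empty((42, 42))
        for k in range(42):
            xp, xm = x.copy(), x.copy()
            xp[k] += H
            xm[k] -= H
            J[:, k] = (residuals(xp) - residuals(xm)) / (2 * H)
        return J

    lower = np.concatenate([np.zeros(6), -12 * np.ones(24), -35 * np.ones(12)])
    upper = np.concatenate([25 * np.ones(6), 25 * np.ones(24), 10 * np.ones(12)])
    cache_c = Path(__file__).resolve().parents[1] / "scratch/phase_c.json"
    if cache_c.exists():
        saved = json.loads(cache_c.read_text())
        phi = saved["phi"]
        extras = {int(k): v for k, v in saved["extras"].items()}
        bends = saved["bends"]
        print("[C] warm start from cached solution", flush=True)
        disp = p.displacements(phi, extras, bends)
        _, m_tilt, _, _ = p.measure(phi, extras, bends)
        noncaps_by_disp = sorted(noncaps, key=lambda i: -disp[i])
        seq = np.array([m_tilt[i] for i in noncaps_by_disp])
        iso = IsotonicRegression(increasing=False).fit_transform(
            np.arange(len(seq)), seq)
        vals = list(iso)
        for j in range(1, len(vals)):
            vals[j] = min(vals[j], vals[j - 1] - NONCAP_MIN_GAP)
        noncap_targets.clear()
        noncap_targets.update(dict(zip(noncaps_by_disp, vals)))
        tilt_targets.update(noncap_targets)
        x0 = pack_state(phi, extras, bends)
    else:
        x0 = pack_state(phi, extras, bends)
        for i in noncaps:                   # isotonic warm start
            x0[6 + i] += np.clip(noncap_targets[i] - m_tilt[i], -2.0, 2.0)
    n_ls_rounds = 0 if cache_c.exists() else 3
    for rnd in range(n_ls_rounds):
        x0 = np.clip(x0, lower + 1e-6, upper - 1e-6)
        sol = least_squares(residuals, x0, jac=jacobian, bounds=(lower, upper),
                            method="trf", x_scale=1.0, xtol=1e-10, ftol=1e-12,
                            gtol=1e-10, max_nfev=30, verbose=2)
        x0 = sol.x
        phi, extras, bends = unpack_state(sol.x)
        r = sol.fun
        hard = np.abs(np.concatenate(
            [r[:6], r[6:30][[i in cap_ids for i in range(24)]],
             r[30:]])).max() / hard_w
        soft = np.abs(r[6:30][[i not in cap_ids for i in range(24)]]).max()
        print(f"[C{rnd}] hard residual {hard:.2e}  soft residual {soft:.2e}",
              flush=True)
        if hard < 2e-3 and soft < 0.05:
            break
        # re-derive feasibility-aware isotonic targets from the current
        # measured tilts and displacement ranks, then re-solve
        disp = p.displacements(phi, extras, bends)
        _, m_tilt, _, _ = p.measure(phi, extras, bends)
        noncaps_by_disp = sorted(noncaps, key=lambda i: -disp[i])
        seq = np.array([m_tilt[i] for i in noncaps_by_disp])
        iso = IsotonicRegression(increasing=False).fit_transform(
            np.arange(len(seq)), seq)
        vals = list(iso)
        for j in range(1, len(vals)):
            vals[j] = min(vals[j], vals[j - 1] - NONCAP_MIN_GAP)
        noncap_targets.clear()
        noncap_targets.update(dict(zip(noncaps_by_disp, vals)))
        tilt_targets.update(noncap_targets)
    cache_c.write_text(json.dumps({"phi": phi, "extras": extras,
                                   "bends": bends}))

    # ---- phases D/E: alternate (D) small clamped corrective rotations,
    # aimed along each non-cap subunit's current tip direction and targeted
    # by isotonic regression of tilts against the masked-CC order, with (E)
    # an exact re-solve of the face/cap/bend block.  E keeps the headline
    # statistics exact (mean face tilt 9, max subunit tilt 17, bends inside
    # 81-89); D only has to keep the tilt ordering aligned with the CC
    # ordering, which survives E's sub-degree drift.
    FULL = PipelineConfig()
    extras2 = {}
    p.extra2_axis = {}
    center = p.cube.center
    # warm-continue from the shipped schedule when it already carries the
    # phase-D corrective rotations (third tilt row per subunit)
    tsv = Path(__file__).resolve().parents[1] / "src/cubeshell/data/deviation_fixture.tsv"
    if tsv.exists() and tsv.stat().st_size > 0:
        from cubeshell.assembly_builder import load_fixture_spec
        try:
            prev = load_fixture_spec(tsv)
            if any(len(e) >= 2 for e in prev.tilts.values()):
                for i, entries in prev.tilts.items():
                    phi[p.face_of[i]] = entries[0].angle_deg
                    if len(entries) >= 2:
                        extras[i] = entries[1].angle_deg
                    if len(entries) >= 3:
                        extras2[i] = entries[2].angle_deg
                        p.extra2_axis[i] = entries[2].axis
                bends.update(prev.bends)
                print("[D/E] warm start from shipped schedule", flush=True)
        except Exception as exc:
            print(f"[D/E] cold start ({exc})", flush=True)
    from cubeshell.rigid_geometry import principal_long_axis as _pla
    from scipy.stats import spearmanr as _sp

    unknowns_e = ([("face", f) for f in FACE_ORDER]
                  + [("extra", p.caps[f]) for f in FACE_ORDER]
                  + [("bend", eid) for eid in p.edge_ids])
    targets_e = ([FACE_TILT_TARGETS[f] for f in FACE_ORDER]
                 + [cap_targets[p.caps[f]] for f in FACE_ORDER]
                 + [p.bend_targets[eid] for eid in p.edge_ids])

    def check():
        rep = run_pipeline(p.cube,
                           perturb(p.cube, p.build_spec(phi, extras, bends,
                                                        extras2)), FULL)
        sub = rep.subunits
        rho = _sp(sub.tilt_deg, sub.cc).statistic
        top6 = set(sub.nlargest(6, "tilt_deg").ref_id)
        low6 = set(sub.nsmallest(6, "cc").ref_id)
        return rep, rho, top6 == low6

    for cycle in range(3):
        rep, rho, top_ok = check()
        s_ = rep.summary
        print(f"[cycle {cycle}] rho {rho:.4f} top6 {top_ok} "
              f"face {s_['mean_face_tilt_deg']:.3f} "
              f"max {s_['max_subunit_tilt_deg']:.3f} "
              f"bends [{s_['bending_angle_min_deg']:.2f}, "
              f"{s_['bending_angle_max_deg']:.2f}]", flush=True)
        if (rho <= -0.94
                and abs(s_["mean_face_tilt_deg"] - 9.0) < 0.12
                and abs(s_["max_subunit_tilt_deg"] - 17.0) < 0.25
                and s_["bending_angle_min_deg"] > 81.0 - 1e-6
                and s_["bending_angle_max_deg"] < 89.0 + 1e-6):
            break  # top6 overlap is reported above; see the methods note

        # --- D: re-aim and re-target the corrective rotations
        sub = rep.subunits
        m_tilt = dict(zip(sub.ref_id, sub.tilt_deg))
        cc_by = dict(zip(sub.ref_id, sub.cc))
        order = sorted(noncaps, key=lambda i: cc_by[i])
        seq = np.array([m_tilt[i] for i in order])
        iso = IsotonicRegression(increasing=False).fit_transform(
            np.arange(len(seq)), seq)
        vals = list(iso)
        for j in range(1, len(vals)):
            vals[j] = min(vals[j], vals[j - 1] - NONCAP_MIN_GAP)
        # clamp: stay local (no runaway) and keep non-cap displacements
        # well below the cap range (tilt ceiling)
        targets_d = {i: float(np.clip(min(v, 3.8),
                                      m_tilt[i] - 1.5, m_tilt[i] + 1.5))
                     for i, v in zip(order, vals)}
        obs = p.observed(phi, extras, bends, extras2)
        tf = global_align(obs, p.cube)
        aligned = obs.transformed(tf.rotation, tf.translation)
        for i in noncaps:
            ref_sub = p.cube.subunits[i]
            u_ref = _pla(ref_sub.points, ref_sub.centroid - center).direction
            u_obs = _pla(aligned.subunits[i].points,
                         aligned.subunits[i].centroid - center).direction
            tau = u_obs - (u_obs @ u_ref) * u_ref
            if np.linalg.norm(tau) < 1e-8:
                continue
            tau = tau / np.linalg.norm(tau)
            p.extra2_axis[i] = (np.cross(u_ref, tau), p.base_axis[i][1])
        slope_d = {i: 1.0 for i in noncaps}
        for sweep in range(3):
            _, mt, _, _ = p.measure(phi, extras, bends, extras2=extras2)
            worst = max(abs(mt[i] - targets_d[i]) for i in noncaps)
            print(f"[cycle {cycle} D] sweep {sweep} residual {worst:.3e}",
                  flush=True)
            if worst < 0.04:
                break
            for i in noncaps:
                if i not in p.extra2_axis:
                    continue
                r_i = mt[i] - targets_d[i]
                if abs(r_i) < 0.03:
                    continue
                step = float(np.clip(-0.9 * r_i / slope_d[i], -1.2, 1.2))
                extras2[i] = extras2.get(i, 0.0) + step
                _, mt, _, _ = p.measure(phi, extras, bends, extras2=extras2)
                ds = (mt[i] - targets_d[i] - r_i) / step
                if 0.1 < abs(ds) < 10.0:
                    slope_d[i] = ds

        # --- E: exact re-solve of faces / caps / bends with D frozen
        def measure_e(x):
            phi_l = dict(phi)
            extras_l = dict(extras)
            bends_l = dict(bends)
            for (kind, key), v in zip(unknowns_e, x):
                if kind == "face":
                    phi_l[key] = v
                elif kind == "extra":
                    extras_l[key] = v
                else:
                    bends_l[key] = v
            m_face, m_tilt2, m_bend, _ = p.measure(phi_l, extras_l, bends_l,
                                                   extras2=extras2)
            out = np.empty(len(unknowns_e))
            for j, ((kind, key), t) in enumerate(zip(unknowns_e, targets_e)):
                if kind == "face":
                    out[j] = m_face[key] - t
                elif kind == "extra":
                    out[j] = m_tilt2[key] - t
                else:
                    out[j] = m_bend[key] - t
            return out, (phi_l, extras_l, bends_l)

        xe = np.concatenate([[phi[f] for f in FACE_ORDER],
                             [extras.get(p.caps[f], 0.0) for f in FACE_ORDER],
                             [bends[eid] for eid in p.edge_ids]])
        h = 0.02
        for it_e in range(6):
            r_e, state = measure_e(xe)
            err = np.abs(r_e).max()
            print(f"[cycle {cycle} E] newton {it_e} residual {err:.3e}",
                  flush=True)
            if err < 1e-5:
                break
            J = np.empty((24, 24))
            for k in range(24):
                xp, xm = xe.copy(), xe.copy()
                xp[k] += h
                xm[k] -= h
                J[:, k] = (measure_e(xp)[0] - measure_e(xm)[0]) / (2 * h)
            step, *_ = np.linalg.lstsq(J, -r_e, rcond=None)
            xe = xe + np.clip(step, -2.0, 2.0)
        _, (phi, extras, bends) = measure_e(xe)

    # ---- write the schedule
    spec = p.build_spec(phi, extras, bends, extras2)
    out = Path(__file__).resolve().parents[1] / "src/cubeshell/data/deviation_fixture.tsv"
    with open(out, "w") as fh:
        fh.write("# deviation fixture schedule: per-subunit hinge rotations\n"
                 "# (deg; a rigid face-tetramer tilt about an in-plane axis\n"
                 "# through the face center composed with an individual tilt\n"
                 "# about a parallel axis through the subunit base) and\n"
                 "# per-edge bending deltas (deg), calibrated once so the\n"
                 "# measured statistics are a 9 deg mean face tilt, a 17 deg\n"
                 "# max subunit tilt (cap subunits largest, tilt order matching\n"
                 "# displacement order) and bending angles spanning 81-89 deg.\n"
                 "# Regenerate with scripts/build_fixture.py\n")
        fh.write(f"meta\tsigma\t{SIGMA}\n")
        fh.write(f"meta\tnoise_seed\t{NOISE_SEED}\n")
        for idx in sorted(spec.tilts):
            for t in spec.tilts[idx]:
                ax, pt = t.axis
                fh.write(f"tilt\t{idx}\t{t.angle_deg:.10f}\t"
                         f"{ax[0]:.12f} {ax[1]:.12f} {ax[2]:.12f}\t"
                         f"{pt[0]:.6f} {pt[1]:.6f} {pt[2]:.6f}\n")
        for eid in sorted(spec.bends):
            fh.write(f"bend\t{eid}\t{spec.bends[eid]:.10f}\n")
    print(f"wrote {out}", flush=True)

    # ---- verification with the full CC pipeline
    from scipy.stats import spearmanr
    rep = run_pipeline(p.cube, perturb(p.cube, spec), PipelineConfig())
    s = rep.summary
    print("mean face tilt:", s["mean_face_tilt_deg"])
    print("max subunit tilt:", s["max_subunit_tilt_deg"])
    print("bending range:", s["bending_angle_min_deg"], s["bending_angle_max_deg"])
    sub = rep.subunits
    rho = spearmanr(sub.tilt_deg, sub.cc).statistic
    top6 = set(sub.nlargest(6, "tilt_deg").ref_id)
    low6 = set(sub.nsmallest(6, "cc").ref_id)
    print("spearman(tilt, cc):", round(rho, 4), " top6==low6:", top6 == low6)


if __name__ == "__main__":
    main()
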