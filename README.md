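# cubeshell

Geometric symmetry-deviation analysis for cube-like and sheet-like protein
shell assemblies, with a synthetic assembly generator for validation
against planted ground truth.

## The problem

Jumbo bacteriophages wall off their replicating genome inside a
proteinaceous nucleus-like shell.  The major shell protein is a roughly
cuboid monomer (~60 x 40 x 70 Å) that assembles into flat C4 head-to-tail
tetramers (~100 x 100 Å), into small cube-like particles — 24 subunits as
six face tetramers of a 220 Å octahedral cube, whose twelve edges each
host a 2-fold-symmetric *concave* tetramer (roles A, B, A′, B′) — and into
P4 sheet lattices.  Comparing a reconstruction with octahedral symmetry
imposed (the idealized average) against one computed without symmetry
exposes how individual subunits deviate: molecules near the cap 3-fold
axes tilt outward and open the assembly, and the bending angle θ_b between
the concave-tetramer pair planes (90° in the cube) drops toward 0° as the
assembly flattens into a sheet.

`cubeshell` implements that analysis as a reusable package:

* **point_symmetry** — finite rotation groups (C*n*, D*n*, T, O),
  asymmetric-unit expansion, optimal subunit matching;
* **rigid_geometry** — Kabsch superposition and RMSD, principal long
  axes, total-least-squares planes, acute angles, gravity centers;
* **density_maps** — Gaussian map simulation, masked Pearson correlation,
  correlation-maximizing rigid map alignment, FSC, MRC/CCP4 I/O;
* **assembly_builder** — parametric subunits, tetramers, cubes, sheets,
  merged two-cube particles, and controlled perturbations (per-subunit
  tilts, per-edge bending changes, noise), plus a packaged deterministic
  deviation fixture;
* **deviation_analysis** — the pipeline: global alignment → per-subunit
  CC → long-axis tilts → face-plane tilts → bending geometry →
  two-group (2-fold maintained/broken) classification → pore measurement
  on sheets;
* **io_cli** — PDB/mmCIF/MRC I/O, flat-file configuration, TSV reports,
  and the `cubeshell` command-line tool
  (`build | perturb | analyze | pores | compare | simulate-map`).

Key quantities use the field's conventions: tilt angles are acute angles
between long axes or between fitted planes (degrees); θ_b is the acute
angle between the planes of the 2-fold-related pairs AB′ and A′B; *d* is
the distance between the pairs' gravity centers, which grows
monotonically as θ_b decreases; per-subunit CC is the about-mean Pearson
correlation of two maps inside a 4 Å mask around one subunit.

## Worked example

```python
from cubeshell import make_deviation_fixture, run_pipeline, PipelineConfig

reference, observed = make_deviation_fixture()   # ideal cube vs perturbed
report = run_pipeline(reference, observed, PipelineConfig())
s = report.summary
print(f"mean face tilt : {s['mean_face_tilt_deg']:.2f} deg")
print(f"max subunit tilt: {s['max_subunit_tilt_deg']:.2f} deg")
print(f"bending angles : {s['bending_angle_min_deg']:.2f}"
      f" .. {s['bending_angle_max_deg']:.2f} deg")
print(f"2-fold broken  : {s['n_twofold_broken']} of 12 concave tetramers")
```

prints

```
mean face tilt : 9.00 deg
max subunit tilt: 17.00 deg
bending angles : 81.00 .. 89.00 deg
2-fold broken  : 6 of 12 concave tetramers
```

— the six face tetramers of the perturbed assembly tilt by 9° on average
relative to the symmetry-ideal reference, the most displaced single
subunit (a cap molecule tilting outward) deviates by 17°, the twelve
concave tetramers bend between 89° (nearly cube-ideal) and 81° (flattening
toward the lattice-forming arrangement), and they divide into two groups —
six keep the 2-fold symmetry between their subunit pairs and six break
it.  `report.subunits`,
`report.faces` and `report.edges` hold the per-subunit CC/tilt, per-face
tilt and per-edge bending tables behind these numbers.

The same analysis from the shell:

```sh
cubeshell perturb --fixture --out-dir fix/
cubeshell analyze --reference fix/reference.pdb --observed fix/observed.pdb \
    --out-dir report/
```

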