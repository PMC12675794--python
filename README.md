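# osteofract

Simulation of long-bone fractures on two-layer cortical shell meshes, and
quantitative validation of simulated fractures against reference ones.

Surgeons, biomechanical engineers and forensic researchers need fractured
bone models — for surgical planning, implant design, training simulators —
but CT scans of real fractures are scarce and never cover the exact bone
and fracture type a study needs. `osteofract` generates them: it takes an
intact bone model (a CT-derived triangle mesh, or the built-in synthetic
two-layer generator), a 2D fracture pattern in the AO/OTA families
(transverse, oblique, spiral, wedge, comminuted), and produces watertight
fragment meshes with anatomically plausible fracture surfaces.

## Method

A long bone's diaphysis is approximated by an enclosing cylinder whose
radius is the *generalized radius* — the band-averaged distance of
outer-cortical vertices from the bone's principal axis at the intended
fracture height. Both cortical layers (outer wall and medullary-canal
wall) are unwrapped in this cylinder frame, `x = θR`, `y` = axial
position. A fracture pattern `P`, a set of polylines in normalized
circumferential/longitudinal coordinates `(u, v)`, is scaled and placed
there (`P′ = T(P)`, with an aspect-ratio guard against transplanting a
pattern onto a bone of incompatible calibre), and every crossing of a
pattern segment with a mesh edge becomes a *cut point*.

Cut points are embedded by one of three strategies: **approximation**
(snap to the nearest vertex; topology preserved), **subdivision** (insert
each cut point as a new vertex; geometry exact), or **hybrid** (snap only
within an approximation threshold — default 10% of the edge length — and
subdivide the rest). Where faces are split, the re-triangulation with the
best mean radius-ratio quality

```
q = R / (2r),   r = inradius, R = circumradius,   q ≥ 1,  q = 1 ⇔ equilateral
```

is chosen. Fragments are found by region growing over face adjacency,
never crossing an embedded fracture edge. Each fracture interface is then
closed across the cortical wall by a constrained Delaunay triangulation
of the annulus between the outer and inner fracture loops — the medullary
canal is kept as a hole — and roughened by one of two perturbation
methods: displacement of contour vertices along their normals before
triangulation, or centroid-fan refinement of each surface triangle after
it (uniform draws in `[−τ, +τ]`, τ = 0.1–1.0 mm). The surface is computed
once per interface and shared (orientation-reversed) by the mating
fragments, so the fragment volumes sum to the intact shell volume exactly
up to floating-point rounding.

Validation runs the loop backwards: the fracture zone of a (real or
simulated) fragment is detected by dihedral-crease analysis under an
oriented-bounding-box grid sweep, classified into cortical layers,
converted back to a 2D pattern, re-applied to an intact bone, and the two
fracture zones are compared through height maps — perpendicular distances
from a reference plane above the zone. The mean heights (**MMAR** for the
reference model, **MMAS** for the simulated one) are compared after
scaling MMAS by the thickness ratio `T_original / T_new`; the report
carries `MMAS_scaled − MMAR` and the percentage variation.

## Worked example

```python
import osteofract as of

spec = of.BoneSpec(length=100.0, outer_radius_profile=10.0,
                   cortical_thickness_profile=3.0, n_theta=64, n_z=50)
config = of.RunConfig(fracture_type="wedge", strategy_mode="hybrid",
                      strategy_threshold=0.10,
                      perturb_method="post_triangulation", tau=0.3, seed=42)
config.bone = spec
result = of.run_fracture(config)
m = result.manifest
print(f"fragments: {m['n_fragments']}")
print(f"volumes (mm^3): {[round(v, 1) for v in m['fragment_volumes_mm3']]}")
print(f"intact shell volume (mm^3): {round(m['intact_volume_mm3'], 1)}")
print(f"mean triangle quality q: {round(m['quality_mean_q'], 3)}")
print(f"cut points snapped/subdivided: {m['n_snapped']}/{m['n_subdivided']}")
```

prints

```
fragments: 3
volumes (mm^3): [8695.0, 6903.9, 397.5]
intact shell volume (mm^3): 15996.4
mean triangle quality q: 1.696
cut points snapped/subdivided: 76/358
```

A wedge fracture of a 100 mm synthetic bone (outer radius 10 mm, 3 mm
cortical wall) yields three watertight fragments — the two main shaft
pieces and a 397.5 mm³ detached wedge — whose volumes sum to the intact
shell volume (8695.0 + 6903.9 + 397.5 = 15996.4 mm³): the fracture
surfaces are shared between mating fragments, so no material is created
or lost. The same pipeline is available from the shell:

```bash
osteofract synth-bone --out bone.ply
osteofract gen-pattern --type oblique --param angle_deg=30 --out pat.json
osteofract validate-pattern pat.json
osteofract fracture --mesh bone.ply --pattern pat.json --perturb post --tau 0.3 --out frags/
```

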