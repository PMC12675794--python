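# Methods

This note records the models, conventions, numerical choices and known
limitations behind `osteofract`, in the order the pipeline runs.

## Coordinates, units, axis convention

All coordinates are millimetres; STL/OBJ/PLY carry no unit metadata, so
mm is asserted by convention. The bone's long axis is the first principal
component of the mesh vertex cloud, anchored at the vertex centroid; the
axial coordinate ("height") is the scalar projection onto it, so
mid-shaft is height 0 and the synthetic bone ends sit near ±length/2. The
axis sign is fixed toward +Z (ties toward +Y, then +X). An isotropic
vertex cloud (spread ratio of the top two principal extents below 1.2)
has no meaningful long axis and is rejected.

The *generalized radius* at a height is the mean perpendicular distance
from the axis of the outer-cortical vertices within a band around that
height. It stands in for the local bone thickness everywhere a thickness
is needed: the projection-cylinder radius and the height-map scaling
ratio. Only outer-layer vertices enter, because the enclosing cylinder
must contain the bone.

## Synthetic bone generator

The generator emulates what a CT segmentation of a long-bone diaphysis
provides: two concentric tubular surfaces — outer cortical wall and the
wall of the medullary canal — with piecewise-linear radius and thickness
profiles, optional bow (a sinusoidal centreline offset), closed by
annular caps at both ends. Faces carry layer labels; the caps are
labelled "outer" and excluded from fracture logic, because diaphyseal
fractures never reach the bone ends. Defaults (length 100 mm, outer
radius 10 mm, cortical thickness 3 mm, 64 × 50 grid) are in the range of
an adult human femoral/tibial diaphysis.

Surface noise is a low-order sinusoidal mixture in (θ, z) with seeded
random phases, normalized so the maximum displacement equals the
requested amplitude. Smooth noise mimics anatomical undulation without
creating degenerate triangles; white noise would. The inner layer is
clamped so the local wall thickness never drops below 10% of nominal.

What the generator does **not** emulate: epiphyses/condyles, trabecular
interior, cortical porosity, anisotropic surface texture. Tests passing
on these fixtures therefore demonstrate the geometry pipeline, not
anatomical fidelity of any particular bone.

## Patterns

A pattern stores polylines in `(u, v)`: `u` ∈ [0, 1) is the normalized
circumferential position (the seam u = 0 is an arbitrary but persisted
reference meridian; wrap arithmetic is modulo 1) and `v` is longitudinal
in mm. Normalizing `u` makes the transverse scaling at projection time
explicit and bone-independent; `v` stays metric because fracture extents
are anatomical lengths. Consecutive u-steps are read minimally (a jump
above 0.5 wraps), so winding loops round-trip through JSON losslessly.

Parametric generators per AO/OTA-style family:

- **transverse** — one closed winding loop at constant `v`, optionally
  with low-amplitude sinusoidal waviness;
- **oblique / spiral** — a constant-slope line rising `C·tan α` per wrap
  (C the nominal circumference, passed as a parameter and persisted as
  `source_circumference`), closed by a vertical connector at the seam.
  Spiral is the steeper variant and is limited to one full turn: with
  more turns the seam connector necessarily crosses the helix's earlier
  passes, which no simple closed loop can represent;
- **wedge** — a transverse loop plus a detached closed quadrilateral
  (truncated triangle) above it, three regions in total. The truncation
  is deliberate: a sharp apex always narrows below one mesh cell near the
  tip, which no embedding resolution can represent;
- **comminuted** — three or more stacked wavy winding loops, one region
  more than there are loops.

Inner-layer lines derive from outer lines by a longitudinal offset plus
seeded bounded periodic noise, emulating how a crack front shifts while
traversing the cortical wall; with offset and noise zero the two layers
are identical.

Forensic validation measures line count, total length (as a multiple of
the reference circumference), region count (fragments) and longitudinal
extent against per-type criteria. The published forensic threshold tables
are not reproduced in the literature this pipeline draws on, so the
criteria ship as editable defaults (e.g. transverse: exactly 1 line, 2
fragments). Region counting rasterizes the band on a wrap-aware grid and
flood-fills; the grid (512 × 256) bounds the smallest resolvable region.

## Projection and cut points

The unwrap is angular (`x = θR`), not conformal: the cylinder
approximation of a diaphysis justifies radial projection, and both
cortical layers share the same (outer-radius) frame so their patterns
stay aligned; cut points are still computed per layer independently.
Seam-crossing faces are unwrapped locally (coordinates shifted by one
circumference), so no 2D face straddles the seam. Placement rescales `u`
by the circumference and centres the pattern's `v` at the fracture
height; if the pattern records its source circumference, the implied
transverse/longitudinal distortion is checked against an aspect limit
(default 2.0) — transplanting a fibula-scale pattern onto a much thinner
bone fails here, mirroring the infeasibility of such transfers in
practice.

Intersection tests use sign-of-orientation predicates with an exact
rational (Fraction) fallback inside a conservative float error bound, so
near-vertex and seam-adjacent crossings are classified exactly. One cut
point is produced per genuine edge crossing: duplicates from the two
faces sharing an edge and from seam copies are collapsed by an
(edge, parameter) key, which still distinguishes two genuine crossings of
the same edge by a wiggly line. Hits within the snap tolerance of an
endpoint are only *flagged* on-vertex here; actual snapping is the
embedding stage's decision, so the strategy choice lives in one place.
A non-closed line ending strictly inside the band is rejected: it cannot
separate fragments.

## Embedding and fragmentation

The snapping band is expressed as a fraction of the cut edge's length —
the only scale-invariant base for a percentage threshold like the 10%
default.
Snapping uses `min(t, 1−t) ≤ threshold`, so hybrid(0) reproduces
subdivision and hybrid(0.5) reproduces approximation face-for-face — an
identity the tests check exhaustively. A snap that would merge two
distinct cut points on one edge falls back to subdivision.

A crossed face is rebuilt as a convex polygon (its corners plus inserted
edge points) triangulated with the fracture segments forced as diagonals;
the remaining freedom is resolved by choosing the fan whose mean
`q = R/(2r)` is closest to 1. Note the convention: q = 1 is the
equilateral optimum and *larger is worse*, with values up to about 1.3
considered well shaped; the quality-guided choice therefore minimizes
mean q, and snapping near-endpoint cuts (hybrid) improves — lowers —
mean q relative to pure subdivision, which the suite verifies across
seeds. Several fracture segments per face embed fine as long as they do
not cross (segments of a simple line never do); past six segments per
face the pattern is declared finer than the mesh.

Fragment identification is seeded region growing over face adjacency
blocked by fracture edges; the partition is seed-independent because
adjacency is symmetric. On the full two-layer shell, a detached-fragment
loop (wedge) leaves its outer and inner wall patches as separate
components; the assembly stage glues components across each interface by
classifying every contour-adjacent face as left/right of the *directed*
contour edge in the unwrapped frame (a local, wrap-safe test, decided per
region by majority vote so slivers cannot flip it), which yields the
expected solid counts: transverse/oblique/spiral 2, wedge 3, comminuted
k+1.

## Fracture-zone geometry

Per interface, the fracture edges of each layer are chained into a closed
loop (snapping can fold the path into zero-width spikes; these are
removed from the ordered chain). Loops are oriented consistently —
counter-clockwise viewed along the axis, or in the unwrapped frame for
wall loops whose plan-view area vanishes.

The cross-section between the loops is triangulated by a constrained
Delaunay triangulation on the loops' total-least-squares best-fit plane,
the inner loop marked as a hole so the medullary canal stays open; the
triangulation adds no vertices, making the surface boundary exactly the
two input loops (welding is then exact). When the planar projection
degenerates or self-intersects — spiral fractures, wedge side walls,
whose loops nearly coincide in projection — or when a Delaunay chord
would coincide with an existing shell edge, a ribbon ("zipper")
triangulation marching along corresponding loop points is used instead.

Perturbation: method A displaces contour vertices along angle-weighted
shell-vertex normals *before* triangulation (only contour vertices exist
at that point); method B adds an auxiliary centroid per surface triangle
displaced along the face normal *after* it, exactly tripling the
triangle count and leaving boundaries untouched. Draws are uniform on
[−τ, +τ] (a one-sided [0, τ] switch exists); τ defaults to 0.3 mm within
the anatomically sensible 0.1–1.0 mm range. A displacement that would
invert an incident shell face retries at half amplitude up to five
times; faces below a small area floor are exempt from the inversion
check, since slivers left by near-endpoint subdivision cannot produce
self-intersection beyond tolerance. RNG streams are derived from the
root seed and the interface id, so fragment order cannot change results.

Because every interface's surface is built once and attached to both
mating fragments with opposite orientation, the signed-volume
contributions of shared surfaces cancel exactly and
Σ fragment volumes = intact shell volume to float rounding — the
pipeline's strongest invariant, checked across the full pattern ×
strategy × perturbation matrix.

## Fracture-zone detection and pattern recovery

Detection is a simplified oriented-bounding-box / grid-sweep scheme: the
principal-axis box supplies the sweep axis (its long edge, the only
defensible reading of an unspecified "sweep vector"); the cross-section
is discretized into columns of width long-edge/100, and isolated
single-candidate columns are dropped as noise. Candidates are vertices of
crease edges (dihedral above 35°) between a "wall-like" face (normal
within 40° of the local radial direction) and a "fracture-like" face
(more than 50° off radial); the wall face's signed radial alignment also
classifies the layer (outward = outer cortical, inward = canal wall), a
test insensitive to the axis tilt an asymmetric fragment induces,
unlike radial-distance thresholds. Vertices with fewer than two incident
crease edges are dropped: the contour passes *through* its vertices.

Flat, axis-normal, coplanar patches ("machined ends") are excluded. This
is deliberate and has a consequence: a perfectly flat transverse fracture
surface is geometrically indistinguishable from a machined bone end (the
synthetic generator's annular caps), so detection requires either an
inclined fracture or non-zero surface roughness. The round-trip fixtures
therefore use a wavy transverse pattern with τ = 0.3 roughness.

Recovery orders the detected points into polylines: connected components
of the link graph (link scale = the sparsest point's nearest-neighbour
distance), each ordered by the shorter of a 2-opt-refined
nearest-neighbour cycle and a plain circumferential sort, open chains
re-joined at their closest endpoints, winding chains collapsed to a
median height per circumferential bin (a graph over the circumference is
simple by construction), and finally Douglas–Peucker simplification with
the tolerance escalated until the wrap-closed ring is free of
self-intersection — a self-crossing line cannot be re-embedded. Only
closed chains are usable (a fracture must separate fragments); a missing
or unusable inner layer falls back to a copy of the outer line with a
logged warning. When an extracted line is still too detailed for the
target mesh, the validation driver re-extracts with stronger
simplification before giving up.

## Height maps and comparison

The reference plane is perpendicular to the axis, a margin (default
1.0 mm) above the highest fracture-surface point, so all heights are
≥ margin. Means are margin-sensitive; maps record their margin and
comparisons require equal margins. The comparison report satisfies, by
construction and by assertion:

```
MMAS_scaled = MMAS · T_original / T_new
distance    = MMAS_scaled − MMAR
percent     = (MMAR − MMAS_scaled) / MMAR · 100
```

with T the generalized radius at the fracture height. The sign
conventions are fixed by the published comparison tables' arithmetic,
which the suite reproduces exactly from the printed inputs. The
operational content of the scaling step is the identity the tests check:
simulating the same seeded fracture on a uniformly scaled bone and
rescaling by the measured radius ratio reproduces the original mean
height to ~1e-15 relative.

## Problem sizes and defaults

The test suite and acceptance script run on tubes of 64 or 128
circumferential segments (about 13k–26k faces), a 27-run conservation
matrix, 100 seeded strategy-equivalence fixtures and single end-to-end
validation loops — sizes chosen so the full suite completes in about a
minute while every code path (all five pattern families, all three
strategies, both perturbation methods, CDT and zipper surfaces) is
exercised at full fidelity.

## Known limitations

- Detection cannot see a perfectly flat transverse fracture on a
  capped synthetic tube (see above); real bone ends are not flat annuli,
  so this is a fixture artifact, not a clinical one.
- Extraction of oblique/spiral patterns recovers the helix well but the
  vertical seam connector only approximately (its crease is sparsely
  sampled), so round-trip fidelity is quantified on transverse fixtures.
- Spiral patterns are limited to one full turn (see Patterns).
- Strongly curved bones would need piecewise cylinders; the single
  enclosing cylinder assumes a roughly straight diaphysis (the bow
  amplitude of the generator is fine; a 90° curve is not).
- Localized impact defects and trabecular interior are out of scope.
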