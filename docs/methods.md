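# Methods

`pigairway` reproduces the morphometry of the domestic-pig bronchial tree
from synthetic data: a parametric generator grows trees with the measured
pig geometry, a rasterizer turns them into CT-like binary lumen masks, an
extraction stage recovers a measured tree from the mask, and the
morphometry module applies the measurement procedures (generation
assignment, bifurcation geometry, planarity classification, piecewise
log-linear diameter regression). This note documents the model, its
parameters, the numerical choices, and what the validation does and does
not show.

## The morphology model

Pig airways differ from human airways in three load-bearing ways, all
encoded in the generator:

1. **Tracheal bronchus.** A pre-carinal branch leaves the trachea and feeds
   the right upper lobe. The trachea is modeled as two stacked segments,
   both generation 0, so every branching event remains a strict bifurcation:
   proximal trachea → {tracheal bronchus, distal trachea} → {right mainstem,
   left mainstem}. The distal trachea continues at the parent diameter with
   zero deflection (the trachea is one straight anatomical structure); the
   tracheal bronchus leaves at a configurable take-off angle, default 95°
   from the trachea axis, i.e. slightly cranial of perpendicular, so its
   subtree occupies the upper right territory instead of running down into
   the right mainstem's.

2. **Monopodial branching.** At each bifurcation the major daughter
   continues close to the parent direction (angle 1; mean 14.34° for
   in-plane bifurcations, 0° for out-of-plane, SD 5°) while the minor
   daughter leaves laterally at angle 2 (means 41.44°/41.37° in/out of
   plane, SD 7°). The side of the major daughter's small deflection
   alternates at successive in-plane bifurcations: a fixed side would make
   the pathway drift steadily (≈14° per schedule cycle) into neighbouring
   lung territory, whereas real mainstem pathways continue in one general
   direction. Diameter ratios are class-conditional: d1/D 0.88 (in-plane)
   / 0.86 (out-of-plane) with SD 0.03, and d2/D 0.57 / 0.35 with SD 0.05 —
   the bimodal minor-daughter ratio that distinguishes the pig's monopodial
   tree from the human dichotomous one. Draws are truncated normals
   (rejection sampling; ratios in (0,1), angles in [0°, 90°], d1 ≥ d2), one
   seeded stream per tree with a documented draw order (d1/D, d2/D, angle 1,
   angle 2, same-generation event, then per daughter: length, lumen shape).

3. **Bifurcating-plane schedule.** Along every monopodial pathway the minor
   daughters' bifurcating plane follows the repeating pattern 0, +90, −90
   degrees relative to the reference plane (the plane of the trachea and
   mainstem bronchi, initialized to the x–z plane; trachea along −z). Each
   minor daughter starts a new pathway with the schedule reset. Classifying
   a bifurcation as in-plane vs out-of-plane uses a 45° threshold on the
   plane rotation; the threshold is uncritical because rotations cluster
   tightly at 0 and ±90.

   One subtlety: the schedule is applied in the local pathway frame, but a
   sub-pathway that itself leaves the reference plane at ~41° cannot host a
   bifurcation plane with dihedral 0 — any plane containing its axis is at
   least 41° from the reference plane. So the generator conditions each
   bifurcation's ratio/angle draws on the class the *measurement* rule
   assigns (the dihedral of the plane actually constructed, thresholded at
   45°), keeping generated ground truth and downstream classification
   consistent by construction. Mainstem pathways still produce the exact
   0/+90/−90 series.

   The sign convention: the rotation magnitude is the dihedral angle folded
   to [0°, 90°]; the sign is the side of the reference plane the minor
   daughter grows toward. At exactly ±90° the dihedral's own sign is
   numerically degenerate (any epsilon flips it), while the daughter side is
   well defined and matches the anatomical description of two consecutive
   out-of-plane bifurcations growing in opposite directions.

**Other structure.** Branch lengths: generations 1–4 decrease linearly from
40 to 15 mm with a short generation 2 (12 mm, the pre-branching right
mainstem); generations ≥ 5 are uniform on [5, 12] mm. The trachea is 120 mm
(an engineering default — no trachea length is printed anywhere;
configurable), split 75/25 around the tracheal-bronchus take-off. All
branches are straight except the left mainstem, a circular arc with 45 mm
radius of curvature bending back toward the caudal direction. Growth stops
at generation 24 or when a branch falls below 1 mm diameter; every expanding
parent creates exactly two daughters (daughters below the diameter floor
become leaves rather than being rejected, which lets major pathways reach
generation ≈ 23 before termination). Occasionally (probability 0.02, parent
generations 5–25) the major daughter is drawn indistinguishable from its
parent (within the 0.3 mm grouping tolerance) and keeps the parent's
generation label.

**Lumen cross-section.** The distal 15–40 % of every internal branch is a
transition zone: the cross-section widens in the bifurcating-plane direction
from a near-circular shape (aspect ratio D_min/D_max drawn in [0.9, 0.98])
toward 0.6 at the flow divider, with a square-root ramp so the zone is
noncircular essentially from its entry. The nominal branch diameter is the
*minor* (plane-normal) axis, so inscribed-sphere (distance-transform)
measurements estimate it without an aspect-dependent bias. Flow dividers
are realised as spherical junction blends (radius = larger daughter radius);
the 0.5–1.5 mm divider edge radius is carried as ground-truth metadata —
a true fillet at that scale is at or below the default voxel size and no
measured quantity here depends on it.

**CI half-widths are not SDs.** The published means carry 95 % CIs without
sample sizes, so the half-widths cannot be converted to population SDs;
the SDs above are free parameters of the model with the stated defaults.

## Rasterization

A voxel is foreground iff its center lies inside the lumen solid (union of
elliptical tube segments along 1 mm-resampled centerlines, wedge-filler
ellipsoids at bending polyline joints, and junction blend spheres). No
partial-volume model — the mask is binary, like the segmentation output it
emulates. Defaults: 0.8 mm in-plane, 1 mm axial. World coordinates are
`origin + index · spacing` at voxel centers, x fastest; NIfTI output carries
spacing and origin in the affine. Tube phantoms offset their grid a quarter
voxel from the cylinder axis: a perfectly symmetric even-extent footprint is
a degenerate input for parallel thinning (both sides erode in the same
pass), and no physical scan is grid-aligned to sub-voxel perfection anyway.

The surface mesh is the zero level set (marching cubes) of an approximate
signed-distance field of the same solid, with interior segment seams
overlapped so no internal zero sheet appears; the export refuses to emit a
non-watertight mesh.

## Extraction

The mask is thinned to a one-voxel 26-connected skeleton
(`skimage.morphology.skeletonize`), reduced to a branch graph, and measured.
Three thinning artifacts are handled explicitly, each with its scale set by
the local inscribed radius (the Euclidean distance transform, EDT), because
all of them grow with lumen caliber rather than any fixed length:

* **Spurs** — terminal chains are pruned when shorter than 2 mm, or when
  shorter than 1.5 local radii *and* ending within 1.2 junction radii of
  their junction: a spur lives inside the parent lumen, while a genuine
  short thick branch reaches beyond the junction ball.
* **Split junctions** — one anatomical bifurcation can thin into two
  junction clusters a few voxels apart; clusters joined by a chain shorter
  than the local radius are merged (their true separation must exceed the
  caliber for the junction to be resolvable at all).
* **Fused branches** — voxel-scale touching of adjacent lumens creates
  loops. Policy is configurable: `on_cycles="error"` (default) raises
  listing the loop; `"break"` removes the thinnest fused chain per loop and
  proceeds. Junctions left with two chains after cleanup are spliced away.

Per-branch measurements: diameter = 2 × EDT sampled along the middle 60 %
of the centerline (median), where each sample takes the maximum EDT over
its 3×3×3 voxel neighbourhood — the EDT is maximal on the medial axis, and
the thinned skeleton can sit up to a voxel off it; length = arc length of
the moving-average-smoothed (window 3) polyline; directions = line fits
after trimming one parent diameter of junction region (the medial axis
bends across roughly one parent diameter while crossing from the parent
axis into a daughter lumen — calibrated on analytic Y-junction phantoms,
which come back within ~1.3° once branch length exceeds ~1.5× caliber).
Since airway branches are predominantly straight, the fit uses the whole
trimmed centerline; a branch whose points deviate from their chord by more
than 1.5 mm (the curved left mainstem) falls back to the end-30 % fit.

Cross-section profiles probe the mask along rays in the plane normal to the
local tangent (36 directions per half-turn), locate the boundary at
sub-voxel precision by interpolating the occupancy across 0.5, and smooth
the width-vs-angle function with a circular 3-tap average before taking
min/max calipers (extreme statistics over raw noisy widths would bias the
minimum low and the maximum high).

## Morphometric procedures

* **Generation assignment:** trachea = 0; all other branches sorted by
  diameter descending; greedy grouping — a new group starts at the largest
  ungrouped branch and every branch within 0.3 mm (the diameter-measurement
  uncertainty) of that group leader joins it; groups numbered 1, 2, …; each
  branch finally clamped to ≥ its parent's generation. Deterministic and
  invariant to input order (ties broken by branch id).
* **Bifurcation geometry:** major daughter = larger diameter (ties toward
  the smaller id); angle 1/angle 2 between the parent's distal direction
  and each daughter's proximal direction; plane rotation and planarity as
  above. Trees measured from masks can contain non-binary junctions
  (fused branches); `strict=False` skips them with a warning.
* **Piecewise regression:** independent per-segment OLS of log10(diameter)
  on generation, segments [0, 11], [12, 20], [21, ∞) — "up to generation
  11" read as inclusive; no continuity constraint because the three printed
  equations are mutually inconsistent at the breakpoints. 95 % CIs use
  Student-t with n−2 df (no CI method is stated for the published values; t is
  the standard choice at these sample sizes). Segments the series never
  reaches are skipped; a non-empty segment with one point is an error; two
  points fit without a CI, flagged.
* **Summaries:** class-stratified means with 95 % t CIs (out-of-plane pools
  both rotation signs), pooled d1/D, per-generation length/diameter tables.
* **Transition zone:** fraction of branch arc length, contiguous from the
  distal end, with aspect ratio below 0.9.

## Validation design and problem sizes

* **Regression recovery** refits noise-free series generated from the three
  printed equations (3 points per generation) and must return the printed
  coefficients to ≤ 1e-6.
* **Morphology statistics** pool ~5 000 bifurcations from six
  default-parameter trees (one per animal). Comparisons use
  max(3 × ensemble SE, the published 95 % CI half-width for that quantity) —
  with thousands of pooled bifurcations, 3 SE (≈0.002 on d1/D) is far below
  the two-decimal precision of the printed values, and a comparison should
  never be tighter than the precision the reference value carries. Note the
  realized ensemble means include the special trachea records (d1/D = 1,
  angle 1 = 0 at the tracheal-bronchus event) and same-generation events,
  exactly as a measured dataset would.
* **Phantom validation** voxelizes 20/12/7/3 mm tubes at 0.4 mm and
  requires a maximum diameter error ≤ 0.3 mm after extraction.
* **Pipeline recovery** uses six reduced trees — max generation 4, diameter
  floor 3 mm, trachea 80 mm, generation-2 override 24 mm — at 0.4 mm
  voxels. The reduction is a validity requirement, not merely a size
  choice: a branch shorter than its own caliber (the default generation-2
  override of 12 mm against a ~15.8 mm diameter) has junction regions that
  overlap, and no medial-axis method can separate them at any resolution.
  Per-branch assertions additionally exclude (a) branches whose lumens
  genuinely touch a non-adjacent branch (`find_collisions`; the generator
  has no space-filling constraint, so sibling subtrees occasionally
  intersect, and a mask rasterized there contains one fused lumen that no
  segmentation could split) and (b) measured branches whose boundaries were
  moved by fused or split junctions (`pair_is_consistent`). Those are
  topology errors, scored separately by branch-count checks; the diameter
  and angle bounds (≤ 0.3 mm for ≥ 4 mm branches; class means within 3°
  and 0.03) measure measurement fidelity on correctly recovered anatomy.
* **Exact branch counting** is demonstrated on coarse circular-lumen trees:
  a flattened transition zone has a medial *sheet* rather than a curve, and
  thinning a sheet necessarily emits extra stub branches near wide
  bifurcations, so exact counting is only well-posed for tubular lumens.

## What the synthetic data does not emulate

Binary masks only — no Hounsfield intensities, noise, beam hardening or
partial volume, so nothing here validates intensity-based segmentation
itself (the original active-contour step is out of scope; its output is
this pipeline's input). The generator has no space-filling/territory model, no
lobar anatomy beyond role tags, no airway walls, no respiratory-phase
deformation, and no terminal bronchioles. Branch-diameter multisets are
multiplicative cascades: they form a near-continuum at depth rather than
the discrete per-generation clusters a small measured sample shows. One
consequence is documented and accepted: raising the generation-grouping
tolerance from 0.3 to 0.4 mm shifts the maximum generation by 3–7 here
(and by 3 even on the noise-free printed diameter model), not the published 1–2 observed on the original empirical multiset — beyond generation ~11 the
printed model spaces consecutive generation diameters by less than the
tolerance, so the group count in that regime scales like span/tolerance.
The corresponding robustness check is therefore expected to fail and is
kept failing rather than loosened; tolerance monotonicity (raising the
tolerance never increases the generation count) does hold and is tested.

## Known limitations

* Extraction accuracy degrades for branches thinner than ~5 voxels and for
  branch lengths below ~1.5× caliber; out-of-plane angle-1 means carry a
  small positive bias (≈ +1°) because an unsigned near-zero angle measured
  with noise has a folded-normal mean.
* The EDT diameter estimator carries boundary-sampling phase error of up to
  ~0.6 voxel (both signs); no constant correction is applied because the
  bias direction depends on the diameter/voxel phase.
* `on_cycles="break"` chooses the thinnest chain in a loop, which can cut a
  true thin branch instead of a fusion when the fusion is thicker.
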