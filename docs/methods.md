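# Methods

This note records the models, parameters and numerical choices behind
`elbowrecon`, and what the phantom-based validation does and does not show.

## Scene model and recognition rules

The pipeline assumes a standard unilateral elbow CT: after thresholding,
the four largest connected components are the scanner bed, humerus, ulna
and radius.  Three geometric facts drive identification, all computed in
millimetres (voxel centers scaled by pixel spacing in-plane and slice
distance axially):

* every articular gap (humeroulnar, humeroradial, proximal radioulnar) is
  a few millimetres, while the bed lies centimetres from the arm — so the
  bed maximizes the row sum of the 4×4 minimum-distance matrix;
* the ulna and radius run parallel at roughly constant separation, while
  the humerus extends away from both — so the humerus maximizes the row
  sum of the 3×3 relative-distance matrix;
* the olecranon reaches farther proximally along the forearm axis than the
  radial head — so the ulna has the larger maximum projection onto the
  proximally-oriented axis `n_f`.

Decisions taken where the rules leave freedom:

* **Threshold** defaults to 250 HU, configurable.  It must sit above
  marrow/soft tissue and below blurred cortical bone; if fewer than four
  components appear (adhesion suspected) the stage optionally retries in
  +50 HU steps up to 500 HU.
* **Connectivity** is 26-neighborhood (6 available).  Component order is
  size-descending with ties broken by smallest raster index, making
  labeling deterministic.
* **Relative distances** sample 100 points per component by uniform stride
  over the raster-ordered voxel list — deterministic, no RNG — and the
  matrix is symmetrized as `(M + Mᵀ)/2`, since one-directional
  mean-of-nearest distances are asymmetric.
* **`A` ("distal point of the humerus")** is operationalized as the
  humerus point nearest the union of the two forearm components; the
  joint-facing end is the distal end in every admissible posture.
* **Orientation of `n_f`**: the projection rule labels the *largest*
  projection proximal (olecranon), which forces `n_f = (A − B)/‖A − B‖`
  with `B` the far (distal) forearm point.  The axis points proximally.
* **Ties** within 1e-9 in any argmax raise an error instead of guessing:
  a tie means the anatomical assumption backing the rule does not hold in
  that scene, and any silent choice would be arbitrary.

## Prompt boxes

Narrow boxes are exact per-slice bounding rectangles of the recognized
component (one box even when a bone appears as several in-slice regions).
Expansion is 20 px at bone ends and 10 px at shafts; since no rule for
classifying a slice as end or shaft accompanies those values, a slice is
an "end" when it lies within 20 % (configurable) of either extreme of the
bone's slice span.  Boxes are inclusive pixel indices; adapters convert to
whatever convention a backend needs.  Training-sample jitter expands each
of the four sides independently by an integer uniform on [0, 30] px
(a single per-box amount was the plausible alternative; independent sides
give the trained model strictly more box variability).

## Segmentation backend

The deep promptable segmenter is deliberately outside the package: the
`SegmenterBackend` protocol (deterministic `segment(slice, box)`, mask
empty outside the box — asserted on every call) isolates it.  The shipped
reference backend thresholds at 150 HU inside the box (below the
recognition threshold, so low-density bone ends and marrow are captured),
applies morphological closing (disk radius 2 px, edge-padded so the box
border is not eroded) and drops components under 5 px.  The adapter
contract for an external checkpoint normalizes slices from a configurable
HU window (default [−500, 1500]) to [0, 1] and hands boxes over as corner
points; the window is configurable precisely because no canonical choice
exists.  No loss function or training loop is included — the package's
scope is the pipeline around a segmenter, not the segmenter.

## Mask refinement

Reclassification runs **before** hole filling: removing a foreign bone's
pixels can expose a cavity that is genuinely background, and filling first
would bake it in as bone.  Hole filling is per-slice 2D (marrow-cavity
holes are in-slice artifacts; 3D filling exists behind a flag, off by
default because it would also fill through-going channels).  The
intersection criterion is literal: one shared pixel keeps a component.
Voxels still claimed by two bones afterwards — typically a merged
joint-region component kept by both — are assigned to the bone whose
recognized voxels are nearer (ties to the lower label), and the count is
reported.

## Reconstruction

Marching cubes runs at isovalue 0.5 on the binary mask padded by one
background voxel, so bones touching the volume edge still produce closed
surfaces.  Vertices map to patient space through the scan affine built
from the image orientation, pixel spacing, slice distance and origin, with
the slice normal taken right-handed (column × row direction).  Laplacian
smoothing replaces every vertex *simultaneously* by the arithmetic mean of
its adjacent vertices (Jacobi-style umbrella operator; isolated vertices
stay put), default 10 iterations — enough to remove voxel staircase noise
while keeping shrinkage of a 4 mm-radius shaft well under half a voxel.
Smoothing runs **after** the transform to millimetres: under anisotropic
voxels, neighbor averaging in index space would smooth anisotropically.

## Metrics

IoU is `|A∩B|/|A∪B|`; two empty masks score 1.0 with a warning (a slice
where neither prediction nor truth contains bone is not an error).
Surface error is the one-directional distance from each predicted-mesh
vertex to the reference surface (exact point-to-triangle distance, with
candidate triangles from a centroid KD-tree; a symmetric variant is behind
a flag).  Quantiles use linear interpolation (type 7).  The error is
reported as max/mean/quartiles per bone; the per-case maximum is the
conservative headline figure.

## The phantom generator

Each phantom is one static scene built from analytic capsules and spheres
in a fixed layout: humeral shaft (radius 7 mm) joined through a tilted
neck to a 9 mm trochlea sphere; ulnar shaft (radius 5 mm) whose olecranon
is a capsule chain on a circle of radius `r_trochlea + joint_gap +
r_olecranon` around the trochlea center — making the humeroulnar minimum
gap equal `joint_gap` (default 2.5 mm) by construction; a radius with a
5 mm spherical head placed so the humeroradial gap is `joint_gap + 1` and
the olecranon out-reaches every radius point by `olecranon_overhang`
(default 8 mm) along the forearm axis, at every flexion angle.  The
forearm rotates in the x–z plane by the flexion angle (82°–170°); the bed
slab sits `bed_offset` (default 25 mm) from the nearest bone.  The humeral
neck is tilted 50° out of the flexion plane: a humerus kept convex inside
that plane would intersect the wrapped olecranon at some admissible
flexion (real anatomy resolves this with the concave olecranon fossa,
which convex primitives cannot express); the tilt preserves every distance
ordering the recognition rules test.

Tissue model: cortical shell 2 mm at 1100 HU, marrow 150 HU, soft tissue
40 HU, bed 300 HU — plausible CT values with no claim of clinical realism.
Partial volume is emulated by a Gaussian blur of 0.4 voxel
(σ ≈ FWHM/3 of a typical CT point-spread function), then Gaussian noise of
15 HU is added (seeded).  The blur choice matters quantitatively: the
reference backend's 150 HU threshold crosses the blurred 40→1100 HU edge
about 1.26 σ outside the true boundary, a systematic dilation of
~0.2 voxel at these settings; much larger blur would push thin-bone IoU
down mechanically rather than reveal anything about the method.  Ground
truth is the solid interior (shell + marrow).  Analytic surfaces are
sampled at 0.35 mm from the primitive boundaries (points inside a sibling
primitive discarded), giving exact references for mesh error.

The generator validates its own assumptions numerically before
voxelizing: inter-bone gaps at least 1 mm and all smaller than the bed
offset, overhang realizable by the arc, flexion in range — violations
raise errors naming the broken assumption.

**What phantom results do and do not show.**  Phantoms exercise the full
decision structure of recognition (all distance orderings, both forearm
identities, the flexion range, clinical voxel spacings), the geometric
correctness of boxes/refinement/reconstruction, and the pipeline's
determinism.  They do not exhibit trabecular texture, osteophytes,
fractures, metal, or truly low-contrast bone ends; passing here therefore
validates the *logic and geometry* of the method, not segmentation
accuracy on clinical images — which depends on the promptable model a
user plugs in.

## Problem sizes and runtime

Default phantoms are ~6.6 M voxels (0.43 mm in-plane, 0.8 mm slices, a
96 × 88 × 120 mm field of view); the full pipeline runs in ~2 s and the
25-phantom recognition suite in well under a minute on one CPU.  These
sizes were chosen to match the clinical voxel geometry while keeping the
whole validation suite fast enough to run on every change.

## Known limitations

* Bilateral scans, implants/hardware and pediatric ossification centers
  are out of scope; the four-component assumption fails there.
* The reference backend is intensity-based; its accuracy on real CT would
  be limited at genuinely low-contrast bone ends.  It exists to make the
  pipeline testable and to define the backend contract.
* Recognition assumes the bed is present; a cropped volume without a bed
  would make the 4-component rule mislabel a noise blob as "bed" (it would
  still be the most distant component, so bones are typically unaffected).
* Meshes are not decimated or remeshed; vertex counts follow voxel
  resolution.
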