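# Methods

`nasalmorph` builds a standardized ("average") nasal-cavity geometry from a
cohort of segmented airway scans by deformable-template registration of 2-D
coronal cross-sections.  This note describes the model, the numerical
choices, the synthetic data the package is validated on, and the known
limitations.

## Coordinate frame and alignment

All geometry lives in an anatomical frame: x lateral (+x = subject's left),
y posterior, z superior, millimetres throughout.  Two bone landmarks define
the frame: the tip of the anterior maxillary spine (AMS) and the choana (the
point where the two nasal passages meet the nasopharynx).  A seven-parameter
similarity transform (3 translations, 3 rotations, 1 scale) places the AMS
at the origin and the choana on the +y axis at 60 mm — a typical AMS–choana
distance, used here as the size normalisation.  The remaining degree of
freedom, roll about the AMS–choana axis, does not affect the downstream 2-D
analysis; it is fixed canonically by projecting the scan's +z direction off
the axis (falling back to +x when the axis is vertical), which makes the
transform deterministic.

Exterior air in front of the face is removed by a morphological opening with
a spherical structuring element of radius r = 10 mm: the ball fits in the
exterior volume but not in the passages (wall-to-wall < 2r), so the opening
keeps exactly the exterior component, which is then grown by a capture
radius r_eps and subtracted.  r_eps (default 2 mm, a configurable choice —
no canonical value exists) picks up slivers the ball cannot enter, such as
the channel between nose and upper lip.  Erosion and dilation by a ball are
computed exactly through Euclidean distance transforms, so anisotropic voxel
spacing is handled without discretising a structuring element.  The
operation is anti-extensive and idempotent.

Coronal sections are cut every 1 mm from y = 0 to 60 by default (the display
figures of such studies use ~1 cm spacing; the analysis spacing is free and
this default is simply dense).  Mesh sections are the even–odd rasterization
of the plane–mesh intersection (contours chained from the intersection
segments; gaps up to 2 px are closed with a warning, larger gaps are
errors); volume sections are nearest-voxel resamplings.  The default pixel
spacing, 0.43 mm, matches the planar resolution of the CT protocol the
method targets.

## Skeletonization

The medial axis of each section is computed by Zhang–Suen thinning: two
parallel subiterations per pass, deleting pixels with neighbour count
2 ≤ B(p) ≤ 6, crossing number A(p) = 1 and vanishing directional products,
until convergence.  Thinning alone leaves staircase artifacts (diagonal
chains with shortcut adjacencies), so a regularization pass removes, in
raster order, every non-endpoint pixel whose foreground neighbours remain
mutually 8-connected without it.  After regularization edge pixels have
exactly two neighbours and bifurcation pixels three (rare pixel-perfect
crossings keep degree four and are reported as such; branch rules use the
three longest incident branches).

The skeleton decomposes into a graph: degree-1 pixels are endpoints,
degree-≥3 pixels junctions, degree-2 chains edges; isolated loops become
closed edges anchored at their lexicographically smallest pixel.  Edge
tracing visits neighbours clockwise from north, making the graph
deterministic.  Spurs — leaf edges shorter than 1.5 mm (configurable)
attached to a junction — are pruned iteratively; isolated short segments are
never deleted, so pruning preserves connectivity.  Thinning is known to
erase a compact blob that shrinks to an isolated 2×2 block; airway sections
(elongated passages ≥ ~3 px wide) never hit this case, and the topology
tests run on such shapes.

## Template and control points

A template is built from any aligned reference geometry — per slice: the
skeleton graph, part tags from the branch rules below, and control points
{X_ij} obtained by Ramer–Douglas–Peucker simplification of each edge
polyline at ε = 1 mm (the base value; larger ε gives fewer control points).
RDP keeps first and last points, splits at the farthest point when its
perpendicular distance to the chord exceeds ε (lower index wins ties), and
guarantees every input point lies within ε of the simplified polyline.
Closed loops are cut at the point farthest from their centroid and
simplified open.  Only an approximate reference skeleton is needed: the
template's own control-point coordinates are discarded after registration in
favour of the population's.  The package ships no anatomical template; any
user mask stack can be promoted to one, and the synthetic generator provides
a labelled stand-in for testing.

## Thin-plate-spline registration

The deformation model is the 2-D thin-plate spline: the minimizer of the
squared control-point residual plus λ times the integrated squared second
derivatives.  It decomposes into an affine part plus radial-basis weights
with kernel U(r) = r² log r², subject to Σw = 0, Σw xᵀ = 0.  λ is made
dimensionless by scaling the regulariser with n and the squared mean
inter-point distance of the source points, so one λ value means the same
stiffness at every slice.  Systems are solved in centred, unit-RMS-scaled
coordinates for conditioning; the similarity transforms back exactly (the
kernel's log-scale term is constant under the boundedness constraints and
folds into the offset).

Registration of the template skeleton onto a target skeleton uses
deformable robust point matching (TPS-RPM) under deterministic annealing:
soft correspondences m_ab ∝ exp(−‖t_b − f(r_a)‖²/2T) with a constant-weight
outlier row/column and a few Sinkhorn normalisations, alternated with a
weighted TPS refit whose basis is anchored at the (small) control-point set.
T starts at (half the target bounding-box diagonal)² and decays by 0.93 per
outer iteration down to one pixel squared; λ is annealed down with T to the
user's final value.  Initialization aligns the two centroids; nothing is
random, so results are bit-for-bit reproducible.  Two guards matter in
practice:

* **Orientation.**  Nasal sections are nearly mirror symmetric, and the
  annealing can lock onto a reflected match (affine determinant < 0).
  Anatomical deformations are orientation-preserving, so when a fit comes
  back reflected the affine block is pulled toward the identity until the
  determinant is positive again.  The guard never triggers when the
  unconstrained optimum is already orientation-preserving, so normal fits
  and rotation/translation equivariance are unaffected; the warp-recovery
  test exercises the cases it protects against.
* **Stiffness default.**  λ = 0.1 (dimensionless).  Sweep studies fix
  ε = 1 mm and vary λ; the default here was calibrated on the synthetic
  generator as the largest stiffness that does not visibly bias the
  recovered control points.

## Averaging

Per slice j, registration gives each scan k the deformed control points
Y_ikj; their coordinate-wise mean Ȳ_ij defines the average geometry's
control positions.  Each scan's *image* (not skeleton) is then deformed so
its control points land on Ȳ: since a TPS has no closed-form inverse, the
reverse-direction spline (source Ȳ, target Y_k) is fitted and each output
pixel pulled back with nearest-neighbour sampling (backward mapping;
forward splatting was rejected for hole artifacts).  Fold-over is detected
by sampling the Jacobian sign and logged, never fatal.  The warped stack is
averaged pixelwise, filtered with a Gaussian of σ = 0.5 mm, and thresholded
at 0.5 with a strict ">" — an exact split vote is background.  With σ = 0
this is exactly the pixelwise majority.  Optionally the median masks are
promoted to a new template and the whole procedure repeats once.

Scans that fail to register on a slice are excluded from that slice's
average and logged; a slice with fewer than 3 contributors is flagged
unreliable.

## Per-passage labeling and CSA

Each side of a section (sides split by connected components, or at the
skeleton curve nearest the midline when a deviated septum does not separate
them) is labelled from its skeleton.  The main branch point — where the
middle turbinate leaves the main passage — is found by scanning junctions
bottom-up and accepting the first whose three longest branches give
non-conflicting assignments under the direction rules: with the first
r = 3 mm of each branch excluded (to remove ambiguity near the junction),
the branch reaching the most negative z is *inferior* and the branch
reaching the most negative x is *middle* (right passage; the sign flips on
the left); the remaining branch is *superior*.  A side with no junction
(posterior slices may lack a superior meatus) is labelled *main* entirely.
A supreme meatus is folded into *superior* by default; a config flag splits
it out at the topmost junction of the superior subgraph.

Remaining curves inherit labels greedily: the unlabeled curve with an
endpoint closest to any labeled curve takes that curve's label, repeatedly —
this tolerates broken skeletons and extraneous branches.  Mask pixels are
then labelled by greedy growth: the unlabeled pixel closest to the labeled
set takes the label of its nearest labeled pixel, one pixel at a time, so a
thick passage cannot annex a thin neighbour's territory (which a naive
nearest-curve assignment would).  Candidate ties break lexicographically;
among equidistant anchors the one that first attained that distance wins —
a purely lexicographic anchor rule would let a label front creep along a
channel wall into the adjacent passage on an integer grid, where exact ties
are everywhere.  The implementation uses incremental nearest-anchor updates
but is exactly equivalent to the literal one-at-a-time procedure (verified
against a brute-force oracle).  One intrinsic property of the greedy order
is worth knowing: a row at distance d from its own skeleton can be reached
by a same-label chain racing along that row at unit steps, so label
boundaries far from any skeleton curve are order-determined rather than
equidistant; boundaries near the skeleton split at the midline as expected.

Labels partition the mask exactly, so per-label pixel counts times the pixel
area give per-passage cross-sectional areas whose sum equals the total CSA
identically.  Profiles are reported per slice, side and label as CSV.

## Quality metric

The overlap of N deformed images S_i of one slice is summarised by
Similarity = |∩S_i| / |∪S_i| — the multi-image Jaccard coefficient, in
[0, 1], order-invariant, undefined (an error) for an empty union.  The λ
sweep registers and warps the whole cohort at each stiffness and reports
this statistic along the airway; figure-read similarity values from the
literature are not reproduction targets, only the qualitative ordering
(very stiff is generally suboptimal) is asserted.

## Synthetic data

No airway imaging data is redistributable here, so every stage is validated
against a parametric generator (`nasalmorph.synthetic`) whose sections
emulate the documented variation catalogue: two passages separated by a
septum with configurable sinusoidal deviation (default amplitude 2 mm), a
near-vertical main channel with an inferior hook, a middle meatus curving
laterally, a superior meatus curving up, optionally a supreme meatus (3 or 4
meatuses per side), part-specific half-width profiles that rise, peak and
fall along the airway, and congestion events that close arbitrary arc
intervals of a passage (possibly splitting its boundary into several closed
curves).  Sections are 112×112 px at 0.43 mm; ground truth carries the
centerline polylines, branch points, a part-label image, and — for cohort
scans — the exact warp applied.

A population is one base anatomy plus K scans (default K = 26, the cohort
size the method targets), each the *image-warp* of the base by a random TPS
whose 4×4-grid control displacements are truncated Gaussians (σ = 1 mm,
bound 2 mm), rescaled if necessary to keep the warp injective (positive
sampled Jacobian).  Warps are antithetically paired — scan 2p+1 applies the
negated displacements of scan 2p — so an even cohort's sample-mean
displacement field is exactly zero and the population mean shape *is* the
base shape, making "does the average recover the base?" well-posed rather
than limited by √K sampling noise.  Default analysis slices for cohort
studies are six positions spanning the turbinate region (y = 18…48 mm);
this problem size keeps a full recovery study (26 scans × 6 slices,
registration + warping + median) under three minutes on one CPU.

What the generator does not emulate: CT intensities and segmentation error,
3-D sinus structures, mucosal texture, and anatomies whose topology changes
between neighbouring slices.  Passing tests therefore demonstrate the
correctness and robustness of the algorithmic chain under realistic shape
variation, not segmentation robustness on clinical data.

## Numerical choices and degenerate inputs

* TPS data term is squared (the standard form; the unsquared norm sometimes
  printed in the literature does not yield the radial-basis solution).
* Duplicate or collinear control points are errors, not silent fixes.
* Nearest-neighbour resampling everywhere (binary data); voxel-count change
  under rigid motion is bounded by ~2% for features ≥ 5 voxels.
* Empty sections/masks: empty skeletons and empty template slices are legal
  and skipped downstream; an empty union makes similarity undefined.
* Strict ">" at the median threshold; even-K split votes are background.
* All tie-breaks (edge tracing order, RDP farthest point, propagation
  anchors) are fixed and documented so every pipeline stage is
  deterministic.

## Known limitations

* The per-slice deformation model ignores through-plane (y) continuity;
  neighbouring median slices are averaged independently.
* Classic Zhang–Suen deletes isolated 2×2 blocks; irrelevant for airway
  sections but a caveat for arbitrary masks.
* The greedy pixel labeling is order-dependent on exact-tie grids (see
  above); boundaries distant from every skeleton curve are reproducible but
  not geometrically "fair".
* Registration quality degrades when a slice's skeleton topology differs
  grossly from the template's (e.g. fully congested passages); such scans
  are outliers to the RPM correspondence and mostly absorbed by the outlier
  bin, but their control images are then extrapolations.
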