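# Methods

## Problem and pipeline

The package quantifies the 3D geometry of the bronchial path from the top
of the trachea to a target lesion, the geometry that decides whether a
radial ultrasound probe can be navigated to that lesion.  The pipeline is

1. **Segmentation** (optional): seeded region growing on a CT-like volume —
   the connected component, under 6- or 26-connectivity, of an intensity
   band containing the seed.  Default connectivity is 26, because thin
   obliquely-oriented peripheral airways fragment under 6-connectivity.  No
   leak detection is attempted; on real CT the quality of everything
   downstream is bounded by the quality of this mask (see Limitations).
2. **Surface**: marching cubes on the zero-padded mask, vertex clustering to
   remove the sliver triangles marching cubes produces (the cluster size
   grows until the max/min edge-length ratio is ≤ 4), then shrink-free
   Taubin smoothing (30 passes by default) to suppress the voxel staircase.
   On the reference cylinder phantom the mesh area is within ~4% of the
   analytic value at 0.5 mm spacing.
3. **Root and termini**: 3D thinning skeleton; the root is the topmost
   skeleton voxel (z points superior, so this is the top of the trachea) and
   the airway termini are local maxima of geodesic distance from the root
   along the skeleton.  The local-maximum definition is deliberately more
   robust than "skeleton voxel with exactly one neighbor", which fails when
   a digitized tip thickens or forms a 2-voxel loop.  Termini within
   `min_branch_length` (3 mm) of a kept terminus along the skeleton are
   pruned.
4. **Centerlines**: one medial polyline per terminus.  The provider is a
   clearance-weighted shortest path: on the 26-connected interior voxel
   graph an edge of length `ds` costs `ds / clearance^p` (p = 2), where
   clearance is the Euclidean distance to the wall; minimizing the cost
   pulls the path onto the locus of maximal inscribed spheres, the same
   contract a Voronoi-edge centerline satisfies.  Each voxel path is then
   Gaussian-smoothed (1 mm), resampled at `h = 0.5 mm`, re-centered on the
   interpolated clearance ridge in its normal plane (a coarse-to-fine
   search; ties on clearance plateaus resolve to the nearest candidate),
   smoothed again at a grid-scaled sigma, and extended straight along its
   end tangents to the lumen caps (the skeleton stops about one tube radius
   short of them).  The per-point radius is the distance to the extracted
   surface.  The re-centering step is what makes the curvature error decay
   monotonically with voxel size (22% / 2% / 0.1% at 1.0 / 0.5 / 0.25 mm on
   a 20 mm-radius torus); without it, sub-voxel zig-zag from the discrete
   neighborhood dominates at fine spacing.
5. **Frenet estimates**: on the uniformly resampled curve, coordinates are
   smoothed with a 1 mm Gaussian and differentiated by central differences;
   `kappa = |r' x r''|/|r'|^3`, `tau = |(r' x r'').r'''|/|r' x r''|^2`.
   Torsion is reported as a magnitude: its sign encodes chirality, which is
   irrelevant to navigability.  Within ~6 mm of a polyline end the
   estimates are damped by the smoothing window; consumers that need
   unbiased values (the convergence study) use an 8 mm interior margin.
6. **Tree assembly**: polylines that share the root are merged where they
   coincide; the shared prefix is recovered exactly from the Dijkstra
   predecessor tree when available, otherwise by a `merge_tol` (0.5 mm)
   distance scan.  Divergence points become bifurcation nodes (coincident
   detections within the junction slack merge into one node); sections are
   the pieces between nodes.
7. **Features**: per section, cross-sections are cut at every resampled
   centerline point except within one (median) tube radius of the section
   ends, where a plane would straddle the bifurcation or the lumen cap.
   A cut is the intersection of the smoothed surface with the plane normal
   to the local tangent; among the intersection polygons, the one enclosing
   the centerline point is the lumen contour.  Contouring the mesh rather
   than a resampled binary (or distance) image avoids the systematic
   shrink of iso-contouring voxelized convex shapes (measured −3 to −7% in
   area on a 3 mm-radius tube; the mesh route is within 0.5%).  Area is the
   shoelace polygon area, diameters are min/max Feret via rotating
   calipers on the convex hull, circularity is `4*pi*A/P^2` (1 for a
   circle), and the per-section statistics are min/max/mean/sample SD
   (ddof = 1).  Branch 0 is the section whose centerline comes closest to
   the lesion (ties to the lower section id; lesions farther than 50 mm
   from every centerline point have no leading bronchus and raise).

## Bifurcation angles

The entry angle of a child section is the angle between the parent and
child axis directions around the node — consistent with cohort values of
~23–35 degrees, which describe parent-versus-child deviation rather than the
child-versus-child opening angle.  Both directions are chords over
`tangent_window_w` (6 mm) windows offset from the node by the junction
pocket size (the local tube radius + 1 mm).  The offset exists because the
medial paths of both children follow a shared corridor inside the junction
pocket; the window length was chosen on a 20/35/50-degree Y-phantom sweep,
where shallow 20-degree siblings share a merged lumen for
`~2r/sin(angle)` mm past the geometric junction and short windows read the
S-shaped transition instead of the child axis.  Recovery errors on that
sweep are +3.8/+0.2/−0.5 degrees; repeatability under rigid rotation of a
three-generation phantom is within ~2–3 degrees.  For strongly curved
children the "entry angle" necessarily reflects the child's direction a few
mm past the junction.

The root section has no entry angle; it is recorded as missing and excluded
from path statistics, never imputed as zero.

## Phantoms as oracles

The phantom module generates trees of straight tubes, torus arcs and
circular helices, rasterized by the rule *voxel center within one tube
radius of the centerline curve*, clipped at the segment end planes (so a
lone tube is a flat-capped cylinder of volume `pi r^2 L`), with junctions
filled by the plain union of parent and child tubes.  Ground truth is
closed-form: `kappa = 0 | 1/R | R/(R^2+c^2)` and `tau = 0 | 0 | c/(R^2+c^2)`
for straight/torus/helix, declared bifurcation angles are axis-to-axis by
construction, and a rigid-rotation helper re-poses a finished tree without
changing it.  Rasterization requires at least 4 voxels across the tube
diameter and refuses less.

The synthetic cohort generator draws each of the 16 discriminative
geometric features independently from per-class Gaussians whose means and
SDs are the reference values for navigation success/failure cohorts
(n = 27 + 27 after matching); e.g. Branch 0 average MinDiameter
3.547 (0.753) mm in success vs 2.782 (0.525) mm in failure.  What the
generator deliberately does not emulate: inter-feature correlation (the
real statistics of, say, MinDiameter-average and MinDiameter-minimum are
strongly dependent), non-Gaussian tails, and any coupling between geometry
and covariates.  Tests passing on these cohorts therefore validate the
statistical machinery (matching, selection frequencies, hold-out
evaluation) and the direction of effects, not real-data effect sizes or
classifier performance.

## Cohort statistics

Propensity scores come from an unpenalized logistic regression of the
outcome on the covariates; matching is greedy 1:1 nearest-neighbor on the
logit without replacement, caliper 0.25 SD of the logit, balance declared
when all post-match standardized mean differences are < 0.2.  Group
comparisons are two-sample t-tests (continuous) and chi-square tests
(categorical) with raw p-values (an optional Benjamini-Hochberg column is
off by default).  "Bootstrapping with a 0.3 hold-out ratio" is implemented
as repeated stratified random 70/30 splits — training on the training part,
scoring both phases — with standardization fitted on the training split
only.  Models: RBF-kernel SVM with C and gamma chosen per iteration by
internal 3-fold AUC-scored cross-validation; random forest with 512 trees,
unrestricted depth, sqrt(p) features per split; L1-logistic with the
penalty chosen by internal 5-fold cross-validation on a C grid capped at
~3 (larger C is a near-unpenalized fit that selects every feature, which
defeats a selection-frequency analysis).  Scores for AUC are the SVM
decision value, forest class probability, and the linear predictor; the
classification threshold for accuracy/sensitivity/specificity is fixed at
0.5 probability (0 decision value), with failure as the positive class.
All randomness descends from one integer seed through a SeedSequence, so
identical seeds give bit-identical results.

## Problem sizes used in the validation suite

Phantom pipelines run at 0.5 mm isotropic spacing (0.25 mm only in the
convergence study).  The acceptance script evaluates the SVM at the full
1000 hold-out iterations and the random forest and Lasso at 300 (the mean
AUC of a 300-iteration run has a standard error of ~0.005, far below any
band of interest); Lasso sign recovery uses 200 bootstrap resamples per
cohort over 5 (script) or 9 (test suite) independent cohorts.  The null
calibration of the group t-test uses 1000 simulated cohorts and the power
check at the reference effect size uses 400.

## Known limitations

* Everything downstream is conditioned on the mask; the region grower has
  no leak control, which matters on real CT though not on phantoms.
* Curvature/torsion within ~6 mm of path ends are smoothing-damped; section
  curvature averages near bifurcations include the genuine bend of the
  medial path through the junction, which inflates them relative to the
  tube's own axis curvature.
* Entry angles of strongly curved children are direction-at-entry
  estimates, not tangents exactly at the node (see above).
* The feature extractor is validated for tubes at least 4 voxels across;
  real sub-subsegmental airways at clinical CT resolution sit at or below
  that bound.
* Synthetic cohorts carry no inter-feature correlation, so selection
  frequencies among collinear real features will be more unstable than the
  tests suggest.
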