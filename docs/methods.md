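# Methods

This note records the models, conventions and numerical choices behind
`aortashape`, in the order the pipeline runs them, together with what the
synthetic validation does and does not demonstrate.

## Scope and units

The package analyses populations of triangulated ascending-aorta surfaces
(one per subject, cut near the brachiocephalic artery, optionally paired
end-diastole/peak-systole). All lengths are millimetres; mesh files carry
no unit metadata and are assumed mm. Curvature is 1/mm, tortuosity and
strain are dimensionless. Image segmentation, hemodynamic (CFD)
simulation and echocardiography are out of scope; wall shear stress and
flow jet enter only as per-subject scalar covariates.

## Synthetic aorta generator

Because no patient meshes are distributed, a generator provides
populations with exact ground truth. Its defaults emulate the reported
morphology of ascending-aneurysm cohorts and are fixed study conditions,
not tuning knobs:

| parameter | default | rationale |
|---|---|---|
| centerline length | 70 mm | root-to-brachiocephalic span |
| arc angle | 100° | gives tortuosity ≈ 0.12 and curvature ≈ 0.025/mm, the reported magnitudes |
| out-of-plane bow | 6 mm, 1/k² harmonics | real aortas are not planar; the bow pins the arc-plane pose DOF |
| base radius | 18 mm | STJ diameter ≈ 36 mm |
| "ataa" radius profile | sinus bulge +2.5 mm at s=0.08, mid dilatation +4 mm at s=0.5, distal taper −2.5 mm | station diameters ≈ 41 / 38 / 44 mm, narrowing to ≈ 31 mm at the cut; the root-vs-distal asymmetry is what anchors end-to-end registration |
| cross-section ellipticity | 0.10 | aortic sections are mildly oval; a perfectly circular tube leaves the roll angle unobservable to any registration |
| mesh resolution | 60 axial × 24 circumferential | ≈ 2 mm facets |
| rigid perturbation | rotations ≤ 30°, translations ≤ 50 mm | exercises alignment |
| surgery link | logit p = −2.0 + 0.30 w₁ + 0.50 w₂ + 0.60 w₃ (weights in mm) | prevalence ≈ 0.2, matching reported surgical fractions (28%/13% by valve group) |

A deterministic safeguard shrinks the bow if a random harmonic draw would
bend the centerline tighter than the tube radius tolerates.

**Generating shape modes.** Population variation is a weighted sum of
orthogonal deformation fields with per-subject Normal(0, σₖ²) weights.
The default ("radial") basis is uniform wall-normal inflation, a Gaussian
mid-ascending bulge, and a cos 2φ mid-tube ovalization, with σ = 4, 2,
1 mm. Two properties of these fields are deliberate:

* *wall-normal direction with broad envelopes* — closest-point
  correspondence measures the normal component of wall displacement
  faithfully; fields displacing a sloped profile along the
  centerline-radial direction make foot points slide axially and
  manufacture spurious bilinear (w₁·w₂) artifact modes;
* *orthogonality to the six rigid-motion generators* — any rigid residue
  in a field couples per-subject alignment jitter directly into its
  score.

Two variants exist: `basis_kind="bend"` swaps in a one-sided bulge toward
the outer curvature, which shifts cross-section centroids and drives
centerline tortuosity monotonically (used for the tortuosity–mode
correlation study; a lateral bending field would be half-invisible to
normal-displacement capture and largely absorbed as pose);
`basis_kind="extended"` appends three minor nuisance fields (root bulge,
distal bulge, sin 2φ ovalization) so the eigenvalue spectrum has the long
tail real anatomies show — with a bare three-mode spectrum the 90%
variance rule retains only two modes and the surgery-risk comparison
would pit a misspecified shape model against the diameter baseline.

Covariates: surgery labels are Bernoulli draws from the logistic link on
the principal weights; BAV/TAV labels are a seeded 50/50 split; station
diameters and tortuosity are measured from the meshes; orifice area and
STJ wall shear stress are drawn with fixed linear links to the bulge
weight plus noise, producing descriptor–mode correlations of realistic
magnitude (|R| ≈ 0.3–0.6).

## Sampling

Surfaces are resampled by area-weighted uniform random sampling (face
drawn ∝ area, uniform barycentric point), the direct reading of "evenly
sampled"; a blue-noise variant exists behind `method="even"`. The
production default is N = 15,000 points per subject; validation and tests
use 1,000–8,000 for speed, justified by the convergence analysis below.

**Convergence rule.** `mode_convergence_curve` reruns the full
align/correspond/PCA pipeline across increasing N and flags the first
resolution at which the first mode changes by less than 5% between
consecutive resolutions. The tracked scalar is the first-mode
explained-variance fraction — the only summary of "the first shape mode"
that does not depend on the arbitrary eigenvector basis. On the default
synthetic population the flag fires by N = 2,000.

## Rigid alignment

Only translation and rotation are ever applied — size is never
normalized, so overall size remains in the data and dominates Mode 1.

`icp_rigid` is classic point-to-point ICP: k-d-tree closest-point
matching alternated with a Kabsch (SVD) rigid fit, run until the RMSD
change drops below 1e-9 mm — in practice to the exact fixed point where
the discrete matching freezes (typically 40–70 iterations). Because a
smooth curved tube is nearly invariant under an end-to-end flip, ICP
multi-starts from the four proper sign combinations of the principal
axes, evaluates each coarsely and refines the best. The RMSD is
non-increasing by construction and recovers synthetic perturbations
(≤ 30°, ≤ 50 mm) of a fixture cloud to well under 0.1° / 0.01 mm.

ICP has a documented failure mode on this anatomy which motivates the
pipeline's second registration path: for a subject dilated or deflated
relative to the template, the closest-point cost is nearly flat as the
tube slides along the curved channel, so the minimizer wanders by several
degrees and, at ±2 SD size excursions, the flipped basin can genuinely
win. `tube_frame_landmarks`/`tube_frame_pose` therefore register tubes by
*ordered anatomical landmarks*: cross-section centroids at fixed
arc-length offsets from the arc midpoint (offsets, not fractions —
wall dilatation shifts the cut ends axially and would stretch a
fraction grid), plus ellipse-major-axis tips that pin the roll, with
end-to-end orientation decided by the radius-profile signature and
per-station axis signs resolved robustly against the target. On the
synthetic population this holds residual pose scatter to ~1–3° with no
flips. The mesh pipeline uses landmark poses; ICP remains the
registration for generic point clouds and the fallback when landmark
extraction fails (non-tubular input).

**Template.** `build_template` implements the iterated scheme: align all
clouds to an initial reference (the subject whose mid-ascending diameter
is closest to the population mean, ties broken lexicographically),
correspond, average; then re-align to the running mean until its mean
point displacement falls below 1e-3 of the mean bounding-box diagonal
(each new mean is rigidly anchored onto the previous one so the measure
sees shape change, not global drift). In the landmark-posed mesh
pipeline the mean is simply the average of the corresponded rows — with
anatomically fixed poses no iteration is needed.

## Correspondence and the shape data matrix

For point clouds, `correspond` maps each template point to its nearest
subject sample (optionally refined to the foot point of a local plane or
quadric patch). The mesh pipeline goes further: an N-point probe cloud is
sampled from the aligned reference surface, and for every probe point the
*signed normal distance* to each subject's actual mesh surface is
measured (exact point-to-triangle feet; first-hit normal rays in the
strain module). The subject's row in the data matrix is the probe cloud
displaced by those normal distances — still an ordered N×3 configuration,
so every downstream operation is unchanged.

Measuring only the normal displacement is the load-bearing choice. Full
3-D closest-point correspondences slide tangentially when the wall moves
±8–10 mm, and those slides are bilinear in the mode weights: they showed
up as spurious "interaction" modes with 2–3% of total variance each,
exactly adjacent to the smallest true mode, mixing its eigenvector beyond
recovery. Normal-displacement capture eliminates them (trailing
eigenvalues drop five- to ten-fold) and has the side benefit that a probe
offset from the true mean only shifts each point's displacement by a
constant, which PCA's centering removes. Its known cost: displacement
fields with large tangential content (e.g. pure bending) are captured
with roughly half their energy; wall-dilatation modes — the phenomenon of
interest here — are captured fully.

## PCA atlas

Rows are flattened to 3N, column-mean-centred, and decomposed by thin SVD
(identical to eigendecomposition of the 3N×3N covariance, feasible at
N = 15,000). Eigenvalues are singular values squared over (n−1); at most
n−1 modes are non-null; eigenvector signs follow a fixed convention
(non-negative inner product with the template's radial direction, first
nonzero component positive on ties) so repeated fits are bit-identical.
Scores are stored in mm. Reconstruction with all modes reproduces every
training row to <1e-6 mm; a rank-0 population yields an atlas flagged
degenerate rather than an error. The atlas persists as a single HDF5
file; the scree content is exported as CSV.

Validation on the default synthetic population (n = 80, σ = 4:2:1 mm,
rigid perturbations, N = 2,000) recovers variance fractions within ~2–3
percentage points of the population 16:4:1 split and mode scores with
|r| > 0.95 against the generating weights. One caveat belongs in the
open: at n = 80 the *sample* variance of the weights itself fluctuates
with SD ≈ 16%, so an unlucky draw can sit ~8 points from 16:4:1 while the
pipeline still recovers that draw's own split within ~3 points; the test
suite asserts both comparisons.

## Wall strain

The diastolic surface is the baseline. Each diastolic sample point is
projected along its outward facet normal onto the systolic surface
(first-hit ray casting); rays that miss, or overshoot three local radii,
fall back to the unsigned closest-point distance, and the fallback count
is reported. Strain is displacement over the local baseline radius — the
distance to the vessel centerline — a dimensionless Δr/r. Points with
baseline radius under 0.1 mm are flagged invalid. The normalizer choice
(local radius rather than an origin-dependent position magnitude) is a
documented design decision; it reproduces the concentric-sphere oracle
(10→11 mm gives 0.100 within 1e-3 relative) and recovers generated
Gaussian strain profiles (peak 0.15 recovered within 0.001 at the correct
station). No phase alignment is applied by default: CT phases share the
scanner frame.

Centerlines are extracted from tube topology: a harmonic field solved on
the vertex graph between the two boundary rings gives a curvature-robust
axial coordinate; Gaussian-kernel-weighted centroids of its iso-levels
(soft weighting — hard bins slice through vertex rings and pull centroids
off-axis), pinned to the ring centroids at the ends and smoothed with a
cubic spline, give the polyline. Accuracy on generated tubes is ~1% of
the radius (Hausdorff).

## Morphometrics

Station diameters slice the mesh with the plane normal to the centerline
tangent (sinus/STJ/mid-ascending at arc fractions 0.10/0.25/0.50 by
default, configurable) and report the area-equivalent diameter
2√(A/π); max-chord is available behind a flag. A multi-loop slice raises
by default (tube self-overlap); `multi_loop="nearest"` keeps the loop
nearest the centerline for strongly curved vessels whose unbounded slice
plane also clips a distal segment. Near a cut boundary the slice can be
an open curve; the generator's covariate measurement records such
diameters as missing rather than guessing.

Tortuosity is arc length over endpoint chord minus one — the only
convention consistent with reported ascending-aorta values of ~0.13 (the
plain ratio would be ~1.13). Mean curvature is the arc-length-weighted
mean of discrete circumradius curvature over consecutive point triples;
collinear triples contribute zero.

The dilatation-pattern rule (root-dominant N / ascending A / extended E)
is a documented in-package convention, not the published phenotype
scheme, whose exact numeric criteria are not available: E if all three
stations exceed the 40 mm cutoff with relative spread under 10%; N if the
sinus exceeds the mid-ascending diameter; A otherwise. Cutoff and spread
are configurable.

## Statistics

* Pearson correlations with two-sided t-distribution p-values, pairwise
  deletion, zero-variance pairs flagged. Raw p-values at α = 0.05 by
  default; Benjamini–Hochberg available and always labelled in outputs.
* Mann–Whitney: exact null distribution when both groups have ≤ 20
  tie-free observations, tie-corrected normal approximation otherwise.
  Pearson chi-square without Yates correction unless requested.
* The surgery-risk model is unpenalized maximum-likelihood logistic
  regression (L-BFGS on the stable log-likelihood; predictors
  standardized internally and coefficients mapped back). The score
  equations hold to gradient norm < 1e-6, verified against an independent
  implementation. Complete separation triggers a 1e-6 ridge refit,
  reported via `ridge_active`. Predictors are either the mode scores
  retained at 90% cumulative variance or the mid-ascending diameter
  alone.
* ROC curves sweep every distinct threshold plus (0,0) and (1,1); the
  trapezoidal AUC is asserted at run time to equal the rank-sum statistic
  (ties half-counted). Evaluation is in-sample by design — mirroring how
  such models are typically reported in this setting — with k-fold
  evaluation available but off by default.
* Cluster analysis is seeded k-means with 10 restarts on the first two
  mode scores (the Mode 1 × Mode 2 plane), k chosen by silhouette in 2–6
  when "auto".
* The replicated risk study (`shape_risk_study`) draws 50 cohorts of 200
  subjects from the extended basis, labels from the logistic link on the
  three principal weights, and fits both models per cohort. Replicates
  run without rigid perturbation, using mesh vertices as the corresponded
  configurations — alignment robustness is certified by the dedicated
  alignment and mode-recovery checks, and this keeps 50 replicates at
  ~2 minutes. The shape-mode model out-ranks the diameter baseline in
  50/50 replicates (mean AUC ≈ 0.85 vs ≈ 0.82 under the default link).

## Problem sizes and determinism

Validation and the reproduction script run cohorts of 80 subjects at
2,000 points (convergence study up to 8,000) and 50 risk replicates of
200 subjects — sizes chosen so the whole battery completes in minutes on
one CPU while leaving every qualitative conclusion intact. Every
stochastic step takes an explicit seed; child seeds derive from a
`SeedSequence`, and identical (config, seed) pairs reproduce outputs
bit-for-bit, which the test suite checks by hashing pipeline tables.

## What the synthetic validation does not show

The generator produces smooth, noiseless tubes with linear deformation
fields, exact tubular topology, and covariates with known links. Real
CTA-derived surfaces carry segmentation noise, branch stumps, non-tubular
root geometry and nonlinear shape variation; correspondence quality and
pose identifiability will be worse there, and the reported recovery
numbers are upper bounds on real-data performance. The published cohort
statistics (e.g. a shape-model AUC near 0.91 on 106 patients) depend on
those patients' data and cannot be reproduced here; what the synthetic
experiments establish is that each stage recovers known ground truth and
that the qualitative claim — shape modes out-predict the diameter — holds
whenever labels genuinely depend on more than size.
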