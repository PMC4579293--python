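# Methods

## Scope and model of the study

The package reimplements, as a tested pipeline, a probabilistic-tractography
"virtual dissection" of a subcortical visual pathway: superior colliculus
(SC) → dorsolateral pulvinar → over the temporal horn of the lateral
ventricle → lateral amygdala, with the stria terminalis as the adjacent
bundle whose crossing fibers can contaminate the dissection.  Because no
subject-level diffusion data are available, every analysis runs on synthetic
diffusion-weighted phantoms with known fiber geometry; the phantom
generator is a first-class, tested module, and the ground truth it emits is
what all downstream claims are scored against.

## Phantom forward model

Each voxel's diffusion signal follows the ball-and-stick mixture

    S(g, b) = S0 [ (1 − f) e^{−b d} + Σ_j (f / m) e^{−b d (g·v_j)²} ]

with S0 = 100, diffusivity d = 1.7×10⁻³ mm²/s inside bundles (0.9×10⁻³
isotropic background), anisotropic fraction f = 0.7, unit stick
orientations v_j given by the local centerline tangent, and m sticks in a
voxel shared by m bundles (crossing voxels split f equally — the simplest
mixture that produces the adjacency artifact the dissection protocol must
solve).  Void regions (the temporal horn) carry zero signal.  Rician noise
is the magnitude of (S + ε₁, ε₂), ε ~ N(0, S0/SNR); SNR = ∞ gives the
noiseless phantom.  Acquisition schemes mirror the study protocols
(4×b0 + 32 directions at b = 800; 4×b0 + 61 at b = 2000; 11×b0 + 60 at
b = 1000); direction sets are generated by antipodally symmetric
electrostatic repulsion from a seeded random start, since "isotropically
distributed" is their only specified property.

Bundle centerlines are natural cubic splines through control points given
in fractions of the grid extent, re-parametrised by arclength and sampled
every 0.25 mm; occupancy is the set of voxel centers within one bundle
radius of the curve.  The default grid is 40×60×40 at 1 mm isotropic
(the nonhuman-primate protocol's scale); a reduced 24×36×24 variant with
the same fractional geometry serves the fast tests.  World coordinates are
RAS millimetres with voxel centers at `index × voxel_size`; a coronal slice
is a fixed second-axis (y) index throughout.

### Geometry of the crossing phantom

The decoy bundle emerges from the medial-superior amygdala, runs roughly
antiparallel to the pathway, touches it tangentially above the temporal
horn (centerline clearance ≈ 3.3–4.5 mm against summed radii of 4.5 mm),
and then diverges medially toward a frontal-horn waypoint and a BNST
termination region.  This adjacency is deliberate: under a single-stick
model, shared and abutting voxels acquire compromise orientations, and a
measurable fraction of SC-seeded streamlines commits to the decoy branch —
reproducing the crossing-fiber artifact the exclusion protocol exists to
remove.  The tangency depth was chosen so that the contaminated branch
carries more than 10% of the peak visitation count (hence survives the
protocol's own threshold) while the pathway retains an uncontaminated
corridor after exclusion.

## Orientation estimation

Per voxel, a single-stick ball-and-stick model is fitted in two stages:

1. **Point fit.**  S0 is the mean b = 0 signal; the orientation initialiser
   is the principal eigenvector of a log-linear tensor fit (exact for
   noiseless axially symmetric signals); (f, log d) then follow from 30
   damped Gauss–Newton steps with the orientation held fixed, with
   f ∈ [0, 1] and d ∈ [10⁻⁵, 10⁻²] mm²/s.
2. **Posterior sampling.**  A Metropolis random walk over (v, f) under a
   Gaussian likelihood whose noise scale is the point-fit residual RMS
   floored at 1% of S0 (the floor keeps the noiseless posterior proper and
   a few degrees wide).  Burn-in 200, keep every 2nd draw, K = 50 samples
   by default (K is a free parameter; 50 keeps the field ~60 MB at full
   grid).  Proposal scales are set per voxel from the local likelihood
   curvature (1.2 σ/|∂S/∂θ|), which measures ~37% acceptance on the study
   phantoms.  Orientation comparisons are everywhere modulo sign; the
   "mean orientation" is the principal eigenvector of the sample dyadic.

A Gaussian (not Rician) likelihood is used deliberately: it is standard at
the simulated SNRs and its mismatch is part of what the simulation study
measures.  With f ≈ 0 the orientation is unidentified and the sampler's
draws spread over the sphere; the sign-aligned resultant length of such
draws measures ≈ 0.53 (versus > 0.99 for a noiseless stick), which is what
the isotropy test freezes.  All randomness is a counter-based (splitmix64)
stream keyed on (seed, voxel index), so batch and per-voxel fits agree
bit-for-bit in any order.

## Tracking

Streamlines launch from every seed-voxel center (5000 samples per voxel by
default; 500 in the desk-scale studies), propagate in both directions, and
concatenate.  Each step draws one orientation sample from the current
voxel (nearest-voxel lookup — samples are unordered across voxels, so
interpolation would be ill-defined), sign-aligns it with the previous
direction, and advances half the smallest voxel dimension (default step).
Propagation ends when the cosine between successive directions falls below
the curvature threshold (0.2), on leaving the brain mask or grid, on
entering a termination mask (the streamline is kept), or at 2000 steps.
A streamline is discarded if it ever enters an exclusion mask and retained
only if it visits every waypoint; each retained streamline increments a
voxel's count at most once (revisit handling is not specified by the
protocol; once-per-voxel is this package's documented choice).
Per-streamline randomness is keyed on (seed, seed-voxel index, sample
index), making maps reproducible and order-independent.

## Dissection protocol

1. Dissect the stria: amygdala seed, proximal and frontal-horn waypoints,
   BNST termination, **pulvinar as exclusion**.  The pulvinar exclusion is
   this package's protocol choice: amygdala-seeded samples whose second
   (bidirectional) limb strays onto the colliculo-pulvinar pathway would
   otherwise donate the entire pathway's voxels to the stria map — and the
   stria terminalis does not traverse the pulvinar, so the mask encodes
   anatomy, not tuning.  Multiple waypoints along the trajectory serve the
   same purpose for the near-amygdala course.
2. Dissect SC → amygdala (SC seed, optional pulvinar waypoint, amygdala
   waypoint + termination).
3. Repeat the SC → amygdala dissection with the **binarised unthresholded
   stria visitation map** as an exclusion mask, trimmed of the pathway's
   own ROI masks: the stria is seeded inside the amygdala, so its raw map
   necessarily covers that ROI, and an untrimmed mask would contradict the
   amygdala's waypoint role and reject every sample.
4. Threshold every map at 10% of its maximum count, boundary-inclusive
   ("at least 10%").
5. Optionally run the reversed dissection (amygdala seed, SC termination)
   and intersect the binarised maps; the overlap is *continuous* when one
   26-connected component touches both endpoint ROIs (26-connectivity
   chosen because the protocol's "continuous" is otherwise undefined).

Cross-subject composites keep voxels present in at least
⌈min_fraction × n⌉ subject masks (so the 8-of-12 rule is min_fraction
= 8/12, and "at least" is boundary-inclusive via the ceiling).

## Statistics

The center of gravity (CoG) of a tract in a coronal slice is the unweighted
centroid of its binary mask voxels mapped to world mm (count-weighted
centroids are available behind a flag; the binary centroid is the default
because the protocol averages binarised streamlines).  The variability
table reports the across-subject SD (ddof = 1) of x and z per slice and
hemisphere, cross-hemisphere means, and Mean/SD summary rows — in mm, or in
isotropic-voxel units when a voxel size is supplied.  Two streamlines are
compared with a two-factor (streamline × participant) ANOVA on per-slice
CoG values, testing the streamline effect against the
streamline-by-participant interaction — for two streamlines the paired
design with df = (1, n−1), which matches the reported df layout; the exact
observation layout behind the published analysis is ambiguous
(per-slice vs slice-averaged), so the implementation is verified against a
literal sums-of-squares oracle rather than a black-box routine.  Zero
between-streamline variation reports F = 0; zero interaction variation with
a nonzero effect reports F = ∞ with a degenerate-case flag.

The cohort generator for these statistics jitters the true per-slice CoG by
N(0, 1 mm) per subject and hemisphere (12 subjects, 8 slices) and offsets
the second streamline by 5.4 mm medially — jitter at the scale the
variability tables report (SDs of 1–2 mm at 2 mm resolution) and the
reported medial offset used as a realistic effect size.

## Lesion analysis

A lesion interrupts a tract when, in at least one coronal slice, it covers
at least ``coverage_threshold`` (default 1.0 — the full cross-section) of
the tract's voxels.  Published analyses of this kind judged interruption
visually; the coverage criterion is this package's reproducible
operationalisation and is surfaced in every report.  The principal axis
defaults to coronal, matching the slice convention.  On-path lesions are
boxes covering the bundle's mid-course cross-section with a one-voxel
margin; off-path lesions are spheres placed by a deterministic grid scan at
the first position disjoint from the bundle.

## What the phantoms do and do not show

The phantoms reproduce the statistical structure the analysis logic relies
on — oriented compartments, crossing/adjacent bundles, signal voids, Rician
magnitude noise, protocol-matched gradient schemes — with tubes of constant
radius and piecewise-smooth curvature.  They do not emulate eddy currents,
susceptibility distortion, motion, coil inhomogeneity (all corrected in
preprocessing upstream of the reimplemented pipeline), partial-volume
gradients at gray/white boundaries, axonal dispersion, or realistic
bundle cross-sections.  Passing tests therefore validate the *pipeline
logic* — mask-role semantics, threshold and composite algebra, exclusion
soundness, statistical machinery — under a correct forward model, not the
anatomical fidelity of any real-data dissection.  Geometric properties of
the real bundles (lengths, curvatures) are unreported, so phantom geometry
matches topology only.

## Problem sizes and numerical choices

The study phantoms run at 40×60×40 with 500 samples per seed voxel and
K = 50 — sizes chosen so a full simulate→fit→dissect pass takes about two
minutes on a laptop-class core; unit tests use the 24×36×24 variant.  The
visitation threshold comparison uses a relative 10⁻⁹ tolerance below the
exact product so that integer counts sitting exactly on the boundary are
kept ("at least").  Degenerate inputs are errors, not warnings: empty
seeds, empty visitation maps, empty streamline masks, grids that disagree,
waypoints overlapping exclusions, bundles leaving the grid, and ROIs
overlapping voids all raise with a message naming the offender.

## Known limitations

* One stick per voxel: crossing regions get compromise orientations, so
  tracts cannot cross transversally — by design, adjacency artifacts are
  handled by the exclusion protocol (the same limitation motivates it in
  practice).
* Background voxels have diffuse orientation posteriors, so streamlines
  random-walk a few steps beyond bundle boundaries before the curvature
  rule stops them; visitation maps carry a one-to-two-voxel halo that the
  10% threshold largely removes.
* The lesion criterion is slice-based along a fixed axis; a lesion that
  transects a tract obliquely across slices can evade the default
  threshold.
* `propagate_one` exposes single-streamline propagation for inspection,
  but the ensemble tracker is the measurement instrument; the two share
  draw logic, not a bitwise-identical stream layout.
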