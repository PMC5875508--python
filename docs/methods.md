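# Methods

`atlasseg` implements hierarchical multi-atlas segmentation of thoracic and
abdominal CT: a first stage finds each organ's bulk location by warping
several presegmented reference scans (atlases) onto the patient and fusing
the transferred masks probabilistically; a second stage adapts every
structure locally to the patient's intensities with level-set evolution.
This note records the model assumptions, the numeric choices and their
rationale, what the synthetic phantoms do and do not exercise, and known
limitations.

## Registration

Each atlas is aligned to the patient with Mattes mutual information (MI) as
the similarity metric throughout.  MI tolerates the monotone intensity
differences that arise from contrast media and Hounsfield-unit calibration
drift between scanners, which defeat sum-of-squares metrics.

**Affine stage.**  Initialization matches the grey-value centres of mass.
Optimization is a regular-step gradient descent in two phases of 30
iterations each: phase 1 moves only the three translations (couch shifts
and posture offsets dominate the initial misalignment), phase 2 releases
all twelve parameters (rotation, scale, shear, translation).  The metric
uses 20 histogram bins and evaluates on half the voxels; the half-sample
subset is drawn once per run (a re-drawn random subset each iteration makes
the regular-step optimizer misread gradient noise as direction reversals
and collapse its step length).  Parameters are scaled by their physical
boundary shift, each step is trust-region-limited to 10 mm of boundary
motion, and both phases run over a 3-level image pyramid (shrink 4/2/1,
smoothing 2/1/0 voxels) — without the pyramid the rotation component of
the cost is too shallow for 30-iteration convergence.

**Deformable stage.**  A cubic B-spline free-form deformation is refined
over four control-lattice resolutions, 100 → 73 → 40 → 20 mm node spacing
(a near-geometric schedule between the 10 cm and 2 cm endpoints), each
optimized by LBFGS (memory 5, gradient tolerance 1e-7, at most 100
iterations per stage) against Mattes MI with 32 bins at full sampling.
The images are shrunk/smoothed per stage (shrink 2/2/1/1, Gaussian
2/1/1/1 voxels): on the raw noisy images the sampled-MI surface is rough
at the scale of a quasi-Newton line search, which then terminates after a
handful of iterations without recovering any deformation; one voxel of
smoothing restores a consistent descent direction at negligible cost in
alignment accuracy.
Each stage starts a fresh zero-displacement lattice composed under the
frozen earlier stages, so the accumulated field is preserved exactly when a
stage begins.  For metric derivatives the frozen stages are baked into a
dense displacement field sampled on the patient grid (the B-spline
transform exposes no position Jacobian inside a transform chain); the
returned composite keeps the exact B-spline stages.

**Masking.**  The union of the atlas's organ masks, dilated by a true
Euclidean 10 mm margin, restricts the metric in atlas space: a patient-grid
sample contributes only if its mapped point falls inside the dilated mask.
This keeps implants, bowel gas and other structures absent from the atlas
from distorting the match.  The affine stage is unmasked by default
(whole-image alignment is what it is for); this is configurable.

The optimization backend is SimpleITK's registration framework; the
package's own `mattes_mi` (zero-order Parzen window on fixed intensities,
cubic B-spline window on linearly interpolated moving intensities, seeded
sampling) is the reference implementation used for diagnostics and tests.

## STAPLE fusion

The warped per-atlas masks for one organ are treated as raters with latent
sensitivity p and specificity q, conditionally independent given the hidden
true segmentation.  Twenty EM iterations (or convergence of the posterior
to 1e-6) estimate the voxelwise foreground probability; the prior is the
scalar mean foreground fraction over the computation region.  Defaults:
p = q = 0.9 initialization; computation restricted to the bounding box of
the mask union padded by one voxel, with zero probability outside — STAPLE
estimates shift with the amount of surrounding background included, so the
region is explicit and configurable.  The probability map is thresholded
inclusively at 0.7 and the largest 26-connected component becomes the
refinement seed; an empty result marks the organ as needing manual
segmentation rather than aborting the run.

## Per-structure refinement

Three chained steps per organ:

1. **HU interval (multi-level Otsu).**  A 125-bin histogram is split into
   four classes at the thresholds maximizing between-class variance; the
   class holding the most in-seed voxels is taken as the organ tissue, and
   the [min, max] original HU of its in-seed voxels becomes the target
   interval.  Four classes fit abdominal CT's tissue groups (fat/gas, soft
   tissue background, organ parenchyma, bone/contrast).  The histogram is
   estimated over the seed expanded by a 10 mm margin: the non-dominant
   classes must absorb the *adjacent* tissues, and a perfectly clean seed
   would otherwise present a near-unimodal histogram that a four-class
   split can only carve through the organ's own mode — the classic Otsu
   failure on uniform regions.  Class ranking and interval extraction stay
   on in-seed voxels.  The threshold search is an exact float64 dynamic
   program over all contiguous bin partitions (equivalent to enumerating
   every threshold triple); `skimage.filters.threshold_multiotsu` computes
   the same criterion in float32 and serves as a cross-check in the tests.
   If the seed has fewer distinct values than classes, the interval falls
   back to the in-seed [min, max] with a `fallback_threshold` flag, and the
   level-set speed switches to the hard in/out form (the graded ramp is
   meaningless when the extreme values are the only values).

2. **Threshold level set.**  The seed's signed-distance field evolves under
   `phi_t = -alpha*S*|grad phi| + beta*kappa*|grad phi|` with alpha = 1,
   beta = 0.5, up to 500 iterations.  The speed
   `S = clip(min(I-lower, upper-I), -e, e)/e` with `e = (upper-lower)/2` is
   positive inside the interval (expansion) and negative outside
   (contraction), normalized so the weights are scale-free; a binary ±1
   speed is selectable.  Leaks into adjacent tissue of different HU are
   pulled back; the front settles on the organ's intensity envelope.

3. **Geodesic level set.**  A short smoothing/growth pass,
   `phi_t = -alpha*g*|grad phi| + beta*g*kappa*|grad phi| + gamma*grad g . grad phi`
   with alpha = 1, beta = 3, gamma = 1, hard-stopped at 30 iterations or an
   RMS change below 1e-5.  The edge-stopping function is the inverse
   gradient `g = 1/(1 + (|grad(G_sigma * I)|/s)^2)` with sigma = 1.5 mm.
   The scale `s` defaults to twice the median gradient magnitude (the
   noise-gradient floor; 30% of the maximum on noiseless images): flat
   tissue keeps g near 0.8 while organ boundaries, an order of magnitude
   above the noise floor, drop below 0.05.  g deliberately does not vanish
   at edges — the evolution is capped at 30 iterations precisely because a
   soft stopping function leaks if run longer — which is what lets the
   front grow across motion-blurred regions whose HU fell outside the
   interval, up to the next image edge.

**Solver.**  Both PDEs use a dense explicit scheme: Godunov upwinding for
propagation, central differences for mean curvature, upwind advection, a
CFL-bounded time step (advective terms scale with 1/dx, the parabolic
curvature term with 1/dx²; safety factor 0.45).  Updates are confined to a
narrow band around the interface (|phi| < 15 mm): in a full-domain explicit
scheme, distant regions of favourable speed drift through zero and nucleate
spurious components which the next reinitialization would legitimize.  The
field is re-tied to a signed distance (exact Euclidean transform) every 50
iterations and, additionally, whenever the accumulated front motion could
reach the band edge.  Computation is restricted to the seed's bounding box
padded by 25 mm.  All refinement is deterministic.

## Overlap metrics

Dice is `2|A∩B| / (|A|+|B|)` (error if both masks are empty).  Surface
distances extract boundary voxels (foreground with a background
face-neighbour) and use the exact Euclidean distance transform in mm,
honouring anisotropic spacing.  The mean surface distance is symmetrized
(mean of the two directed means); the Hausdorff distance takes the maximum
and flags local spikes that the mean washes out.  One-sided variants are
available.

## Synthetic phantoms

No clinical data ships with the package; the generator emulates the
statistical structure of the intended inputs on a 64³ grid at 2.5 mm
isotropic spacing — the contract is contrast relations and adjacency, not
anatomical realism:

- an elliptical soft-tissue body (10 HU), two lungs (−800 HU), a vertebral
  column (700 HU), a bowel-gas pocket (−600 HU);
- five target organs — liver (75 HU), spleen (62), two kidneys (52), left
  lung — soft-tissue organs of similar intensity, each wrapped in a thin
  (≈2.5 mm) fat capsule (−90 HU);
- fat and background soft tissue carry a smooth random heterogeneity field
  (amplitude 12 HU, 40 mm correlation) the way real tissue does, while
  organ parenchyma stays a tight intensity mode — this is the histogram
  regime the Otsu step assumes: each organ's neighbourhood shows several
  tissue modes of which the organ is the tightest and (in-seed) largest;
- Gaussian noise (sigma 3 HU, a quiet abdominal protocol) everywhere.

Each atlas is the base anatomy warped by a smooth random displacement field
(coarse 55 mm lattice, cubic interpolation, max 8 mm — deliberately a
different lattice family and spacing than the registration's 100–20 mm
schedule, so recovery is not a same-model inverse crime), composed with a
rigid posture change (rotation up to ±6° about the long axis, translation
up to ±7 mm), an intensity remap `a*v + b` (a ∈ [0.92, 1.08], b ∈ [−25, 25]
HU) and independent noise.  The displacement amplitude is kept below the
smallest organ radius so the field is invertible; the patient→atlas map is
recorded exactly and its inverse computed by fixed-point iteration, and
atlas masks are rasterized analytically through that inverse, so
known-transform recovery and warp self-consistency have well-defined ground
truth.  All randomness derives from one seed.

Confounders are inserted into the patient only (as implants and artifacts
would be): a 1500 HU pellet outside all organs, a motion-blurred superior
border layer of a kidney (HU pulled 14 HU toward background over a wide
shallow dome — outside the organ's intensity envelope but without an
internal edge), a 110 HU stomach-like blob attached to the spleen, and a
deleted lung.

What passing tests on these phantoms do **not** show: performance under
real partial-volume profiles, streak/beam-hardening artifacts, contrast
phases, pathology, or anatomies whose in-seed histograms are genuinely
unimodal (the Otsu step's acknowledged failure mode, mitigated but not
removed by the context margin).  Clinical accuracy claims require clinical
validation.

## Pipeline and QA

Per organ, the pipeline never aborts the run: exceptions in fusion or
refinement downgrade the organ to `failed` in the report (to be segmented
manually).  A refined mask whose volume differs from its fused seed by more
than a factor of 3 is also marked failed — the signature of refinement
running away through background tissue, e.g. when the organ is absent from
the patient.  The report records per-atlas agreement with the fused seed,
STAPLE's per-rater sensitivity/specificity, the extracted HU interval, and
per-step volumes.  The clinical deployment the workflow descends from
(DICOM listener, e-mail notification, planning-system insertion) is
replaced by a filesystem watcher with the same shape: volumes dropped in an
inbox are segmented once (content-hash deduplication) and results written
beside them.

Determinism: with a fixed seed and thread count 1 (the default), two runs
of `segment` are bit-identical.

## Problem sizes and defaults

The standard study conditions are the 64³/2.5 mm phantom with three
atlases and five organs.  A full pipeline run registers three atlases
(two-phase affine plus four B-spline stages each) and refines five organs;
the acceptance script runs this once, plus affine recovery experiments and
two confounder refinements.  Unit tests exercise the deformable stage on
reduced lattice schedules; the level-set solvers always run their full 500-
and 30-iteration budgets.

## Known limitations

- The esophagus-class failure mode (small, low-contrast structures with
  negligible weight in the registration cost) is out of scope.
- STAPLE here is binary and per-organ with a scalar prior; multi-label
  fusion, spatially varying priors, and atlas weighting by registration
  quality are not implemented.
- The dense explicit level-set solver is simple and auditable rather than
  fast; a sparse-field implementation would be an optimization, not a
  behaviour change.
- Four Otsu classes are assumed meaningful for the local histogram; when a
  confounding structure adds a fifth mode, the class containing the organ
  can absorb it (the interval then includes the confounder).  The paired
  threshold/geodesic steps and the volume-ratio QA catch most, not all,
  such cases.
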