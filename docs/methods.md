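# Methods

`pmbrainvol` re-implements a semi-automatic volumetry chain for
post-mortem fetal and newborn brain MRI: atlas-prior EM segmentation with
an MRF and prior relaxation, groupwise atlas construction, CSF-threshold
fluid exclusion, and density-based weight estimation, validated with Dice
overlap and Bland–Altman agreement statistics.  This note records the
model, the parameters that matter, and the design choices made where the
design was genuinely open.

## The segmentation model

Brain voxels inside an intracranial mask are classified into four
classes — cerebrum (gray+white matter combined), cerebellum, brainstem and
CSF — with Gaussian class-conditional intensity models.  The E-step
responsibility of class *k* at voxel *i* is proportional to

    π_ik · N(y_i; μ_k, σ_k²) · exp(β · Σ_{j∈N(i)} q_jk)

where `π_ik` is the per-voxel effective prior, the exponential is a
mean-field Potts term over the 6-connected neighbourhood (using the
previous iteration's posteriors `q`), and the M-step re-estimates `μ_k`,
`σ_k²` from responsibilities.  After each iteration the effective prior is
relaxed toward the data:

    π ← (1 − α) · atlas_prior + α · G_σ(q)

with `G_σ` a Gaussian smoother.  Relaxation lets the segmentation depart
from an imperfect atlas while the MRF keeps labels spatially coherent.
With `β = 0, α = 0` the algorithm reduces exactly to textbook EM for a
Gaussian mixture with per-voxel mixing proportions; the test suite checks
the updates against an independently coded oracle at 1e-10 and asserts
the monotone log-likelihood.

Stage 2 merges cerebrum with CSF.  Post mortem, T1 and T2 converge toward
free-water values, so cerebrum and CSF cannot be separated by intensity;
keeping CSF as a separate stage-1 class nevertheless stabilizes the
cerebellum and brainstem boundaries, which are surrounded by fluid.
Merging sums posteriors within groups and re-argmaxes.

Defaults: `mrf_beta = 0.5`, `relaxation_alpha = 0.2`,
`relaxation_sigma = 2` voxels, convergence at relative objective change
< 1e-5 or 100 iterations.  Initialization is deterministic
(prior-weighted intensity moments); when priors are flat this collapses
to a symmetric fixed point, so means are then spread over intensity
quantiles, still deterministically.  Argmax ties break toward the lower
class index in the fixed order (cerebrum, cerebellum, brainstem, CSF).

## Registration

Rigid and affine registrations use SimpleITK's registration framework:
normalized cross-correlation, a 3-level multiresolution pyramid, regular
(deterministic) metric sampling, and a regular-step gradient descent with
physical-shift parameter scaling.  Transforms map fixed (target) space to
moving (source) space — the pull-back convention — so resampling is a
single interpolation; labels are moved nearest-neighbour, intensities and
priors linearly, and resampled priors are renormalized where interpolation
pushes the per-voxel sum above 1.

Two non-rigid models are provided.  The cubic B-spline free-form
deformation (default control-point spacing 8 voxels, coarse-to-fine
lattice matched to the image pyramid) is the classical parameterization.
The default engine, however, is a Gaussian-regularized dense displacement
field estimated by symmetric-forces Demons: on the smooth, same-modality
warps this pipeline needs it recovers a 1.5-voxel-RMS synthetic warp to
about 0.15 voxel mean error in a few seconds, where the B-spline
optimizer needs an order of magnitude longer for about 0.9 voxel.  The
`n` token in registration schedules therefore means the Demons engine;
`b` selects the B-spline FFD.  Folding is detectable from the minimum
Jacobian determinant of the displacement field.

## Groupwise atlas

The cohort template is built by registering all subjects to an evolving
arithmetic-mean image through a schedule of increasing degrees of freedom
(default one rigid, four affine, four non-rigid rounds; configurable
because the rounds needed depend on cohort diversity).  After the final
round, each subject's posterior segmentation (soft posteriors, not hard
labels — averaging posteriors preserves boundary uncertainty) and brain
mask are propagated through its final transform; priors are the voxelwise
mean of propagated posteriors, the atlas mask is a ≥50 % majority vote,
and the mean absolute template change between the last two rounds is
recorded as a convergence diagnostic.

## Bias field

Intensity non-uniformity is modelled as a smooth multiplicative gain
field.  The estimator alternates k-means tissue clustering (4 classes) of
the corrected log-intensities with a least-squares fit of a tensor
polynomial (default total degree 5) to the class-demeaned log-intensities;
without the demeaning step, genuine anatomy leaks into the fitted field.
The field is normalized to unit mean inside the mask so correction
preserves mean brightness — necessary because per-subject CSF thresholds
are chosen on the corrected intensity scale.  On phantoms with a 1.4×
peak-to-trough generating field, the estimate correlates with the truth at
r ≈ 0.97 across seeds.

## Volumetry and weights

The merged cerebrum+CSF region still contains free fluid that leaks out
before autopsy weighing.  A per-subject intensity threshold removes it:
voxels strictly brighter than the threshold are excluded, voxels equal to
it retained.  Volume is voxel count × voxel volume (mm³ → mL); weight is
volume × 1.08 g/mL, a literature brain-density constant that is
configurable since it need not hold for every subject.  An experimental
helper proposes a threshold at the histogram valley between the two
dominant intensity modes of the region.

The packaged cohort tables (17 newborns, 17 fetuses; 15 and 13 with
autopsy weights) drive the agreement layer: differences are
autopsy − MRI, the SD of differences uses the n−1 denominator (the
printed limits of agreement only reproduce with the sample SD), limits
are mean ± 1.96·SD, and aggregates are reported rounded to the nearest
gram (half away from zero).  Two newborn rows (274, 306) carry printed
weights inconsistent with their printed volumes at the 16–35 g level;
both lack autopsy weights, so no aggregate statistic is affected.  The
row-level ±0.02 g round-trip check documents this by failing for exactly
those two rows.  Empty-vs-empty Dice is defined as 1.0 (with a warning)
so degenerate phantom classes cannot poison a suite.

## The phantom generator

Phantoms are nested axis-aligned ellipsoids — fluid shell, cerebrum with
two ventricular pockets, cerebellum, brainstem — chosen as the simplest
family with analytic volumes for oracle checks.  Defaults emulate the
target data: 64³ grid at 0.6 mm isotropic, bright fluid (900), cerebrum
600, additive Gaussian noise (SD 25), smooth multiplicative bias
(peak-to-trough 1.2 by default, 1.4 in recovery tests).  Label priority
at paint time is brainstem > cerebellum > cerebrum, with ventricular
pockets carved as CSF inside the cerebrum.  Cohorts apply independent
smooth random warps (low-frequency displacement fields, RMS 1.5 voxels in
the study conditions, rejection-sampled to keep a positive Jacobian);
warped subjects stay piecewise-constant — class means are applied to the
warped labels — so the generative model remains "class mean + noise"
rather than acquiring partial-volume shells the model does not describe.
Post-mortem contrast collapse is emulated by moving all tissue means
close together (e.g. cerebrum 820, cerebellum 770, brainstem 740, CSF
900 at noise SD 40), which makes the atlas priors, not the intensities,
carry the class information.

What the phantoms do **not** model: cortical folding, Rician noise,
multi-contrast acquisition, lesions/hemorrhage, and true partial-volume
averaging.  Passing phantom tests therefore demonstrates correctness of
the algorithmic chain under its own assumptions, not performance on real
scans.

## Prior-source experiment

The matched-vs-mismatched atlas comparison emulates segmenting
post-mortem images with an in-vivo atlas: the mismatched atlas is built
from a population with inverted fluid contrast (fluid dark), 10 % larger
anatomy, a different deformation distribution and heavier prior
smoothing.  The comparison is asserted on the stage-1 four-class labels,
where the priors act.  On merged stage-2 labels the comparison would be
structurally biased: an atlas that under-segments cerebellum and
brainstem inflates the merged cerebrum+CSF region and thereby *raises*
its Dice, rewarding worse priors.

## Problem sizes

Tests and the acceptance script run the full chain at 64³ voxels with
3–5-subject cohorts and a reduced groupwise schedule (one rigid, one
affine, one non-rigid round); these sizes exercise every code path while
keeping the whole suite desk-scale.  The schedule and grid are
configuration, not code: the defaults reproduce the full 1+4+4 schedule.

## Known limitations

* The EM/MRF/relaxation construction is a declared stand-in for the
  published algorithm's internals, which are specified elsewhere; no
  claim of bit-level replication is made.
* Exact replication of any external registration package's output is a
  non-goal; registration quality is validated by known-transform
  recovery instead.
* Cerebrum/CSF separation is intensity-threshold-based and per-subject
  manual by design; the histogram-valley helper is experimental.
* The density constant 1.08 g/mL is a literature value; true post-mortem
  density varies with maceration and fixation.
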