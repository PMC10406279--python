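# Methods

## Measurement principle

`fetalicv` measures fetal intracranial volume (ICV) from a 3D B-mode
ultrasound volume by atlas-based label propagation.  An *average brain model*
— a template image with a reference ICV mask — is registered to the subject
scan through a staged pipeline of intensity-based registrations.  The inverse
of the subject's accumulated transform carries the model's ICV mask onto the
subject's voxel grid, and

    ICV = (number of mask voxels) x (volume of one subject voxel),

reported in cm³.  The identity is exact by construction: no surface fitting
or partial-volume estimate intervenes.

Key assumptions:

* the subject and model are *monomodal* (both B-mode ultrasound exported to
  NIfTI with mm spacing), so simple intensity metrics (normalized cross
  correlation, sum of squared differences) are appropriate;
* the subject's head is broadly similar in size and age to the model cohort
  (the intensity-based approach degrades when model and subject ICV differ
  markedly — the motivation for per-age-group models and for the
  rotation+scaling escalation described below);
* scans have been sorted into the two mirror-image head orientations
  ("Left"/"Right") and are paired only with the matching-orientation model;
  the pipeline refuses cross-orientation pairs rather than silently
  mirroring.

## Preprocessing

Exported sweeps carry exactly-zero padding outside the conical field of view
(and in acoustic shadows).  The resulting black border is a strong artificial
edge for intensity metrics, so every zero voxel is replaced by the mean
grayscale of the *nonzero* voxels.  Averaging over nonzero voxels only is a
deliberate choice: including the zeros would drag the fill value toward
black and partially recreate the edge the step removes.  The operation is
idempotent and refuses all-zero volumes.

Orientation canonicalization mirrors a scan along the left-right axis
(axis 0) into a requested orientation; it is an involution and preserves the
gray-level histogram exactly.  Orientation labels are supplied per scan by
the user; automatic left/right detection is out of scope.

## Transform model

* **Linear** transforms act as `y = M (x − c) + c + o` about a center `c`
  (the fixed image's world center during registration), with families
  translation / rigid / similarity (s·R) / affine.
* **B-spline free-form deformations** add a displacement field parameterized
  by per-control-point mm displacements interpolated with the cubic B-spline
  basis.  The control grid covers the fixed domain with a two-point margin;
  the default control spacing is 8 voxels (the minc-style variant) or 5
  voxels (the elastix-style variant; see *Pipeline independence*).
* **Chains** apply members in order (fixed-space point → moving-space
  point).  Adjacent linear members compose in closed form.

All resampling uses the pull-back convention: the output voxel at fixed
position `x` takes the moving image's value at `t(x)` (trilinear
interpolation; out-of-domain samples take the moving image's nonzero-mean
background value).  Binary masks are resampled with trilinear interpolation
and thresholded at 0.5, which gives lower discretization noise in volume
estimates than nearest-neighbor sampling.

Linear transforms invert in closed form.  B-spline transforms invert
numerically into a dense displacement field by fixed-point iteration
(`e ← −d(y + e)`) on the domain grid, with a convergence tolerance of
0.05 voxel (configurable) and a 100-iteration cap; the inverse is verified
by the round-trip residual `|t(t⁻¹(x)) − x|` at every voxel center and the
operation fails loudly (reporting the worst residual) if the deformation is
not invertible — which is precisely what happens when a registration has
folded, and is treated downstream as a failed measurement.

## Single-stage registration

Each stage optimizes one transform family over a *smoothing-only*
coarse-to-fine schedule: the images are Gaussian-blurred with decreasing
sigmas (default 4, 2, 1, 0 voxels; the fast preset uses 2, 0) but never
down-sampled.  An optional pre-blur of both images is available as a rescue
preset.

Two optimizer modes mirror the standard/adaptive gradient-descent pair of
mainstream registration toolkits.  Both take steps along the
infinity-norm-normalized gradient with the decaying gain

    a_k = sp_a / (A + k)^alpha ,   alpha = 0.602, A = 50.

Normalizing the gradient makes `sp_a` an initial step length in mm, so one
default works across metrics and intensity scales.  `standard_gd` uses the
configured `sp_a` (default 10 mm, i.e. a first step of ~1 voxel at 2 mm
spacing); `adaptive_gd` calibrates `sp_a` from the first gradient so the
first step moves at most one voxel.  Optimization state is fully determined
by the stage seed; two runs with the same inputs and seed are bit-identical.

Parameters are optimized in a scaled space in which a unit change displaces
a point at the edge of the field of view by roughly 1 mm (rotations and the
log-scale parameter are multiplied by the domain radius), making gradient
components commensurate across translations, rotations and scalings.
Gradients are central finite differences on the (few) linear parameters and
an analytic chain rule through the sparse cubic B-spline basis for the FFD
coefficients.  The intensity loss is evaluated on a seeded random subsample
of fixed-grid voxels: full sampling below 64³ by default (20% above), with
`sample_fraction` exposed per stage — the stock pipeline presets use ~12% at
48³, which changes recovered transforms negligibly while keeping the staged
pipelines fast.

A stage whose loss worsens monotonically for a full level is flagged
not-converged and returns its best-so-far transform; a stage that ends worse
than its starting point falls back to the initial transform.  Reported
metrics are the plain NCC/SSD values (internally the SSD loss is normalized
by the fixed image's variance so loss magnitudes are scale-free).

## The two pipeline variants

Both pipelines follow the average-template scheme: after every stage the
registered model and registered subject are averaged voxelwise (no intensity
normalization), and the average becomes the next stage's target.  The stage
averages combine only the model and the subject, not earlier averages.

* **minc_style** — four "affine" stages followed by three B-spline stages.
  Each affine stage folds a translation + rigid initialization into a full
  affine optimization.  At the first stage the model itself is the target
  (its own registration is the identity), so the subject's first target is
  the model — the model serves both as target and as one of the scans.
* **elastix_style** — a translation stage and a rigid stage, both targeting
  the model, then four B-spline stages under the average-template scheme.
  After the rigid stage an escalation check runs: the overlap similarity of
  the rigid-warped subject against the model, computed on
  *background-suppressed* images (each clipped at its median so image energy
  concentrates in the cranial shell rather than the dominant uniform
  background).  If it falls below the 0.7 floor — in practice, when the
  subject's ICV differs markedly in size from the model's — the rigid result
  is discarded and a similarity stage (rotation + global scaling),
  initialized from the rigid pose, takes its place.  Without this check the
  entire size difference lands on the B-splines, which is exactly when
  deformations fold.

### Pipeline independence

The consensus QC (below) is only informative if the two pipelines fail
independently.  Two variants sharing one code base correlate strongly, so
the variants are deliberately decoupled on three axes:

| axis | minc_style | elastix_style |
|---|---|---|
| optimizer | standard_gd | adaptive_gd |
| B-spline metric | NCC | SSD |
| B-spline stiffness | 8-voxel control grid | 5-voxel control grid, more iterations |

(The linear stages of both variants use NCC, the natural monomodal choice.)
The stiff/floppy split mirrors the character of the two historical tool
families the variants are named after, and empirically restores the
decoupling: a corrupted input (e.g. a mirrored scan) drives the floppy SSD
pipeline into large, often non-invertible deformations while the stiff NCC
pipeline stays near the linear solution, so the two disagree — or one fails
outright — and QC triggers.

## ICV propagation and the counting space

The subject's accumulated chain maps common-grid points into subject space;
the model's chain (identity until the B-spline phase for elastix_style) maps
common-grid points into model space.  The propagated subject mask is

    mask_subject(q) = mask_model( T_model( T_subject⁻¹(q) ) )

evaluated at every subject-grid voxel center `q`.  Voxels are counted on the
**subject grid** and multiplied by the subject's voxel volume; the
counting space is a documented choice (the alternative — counting on the
model grid — makes the result depend on the model's resolution rather than
the subject's).

## Consensus quality control

* **SD gate.**  The two variants' ICVs are summarized by the two-value
  *sample* standard deviation `|a − b| / √2` — the conservative convention,
  √2 larger than the population SD of a pair, so the gate errs toward
  flagging disagreement.  The default rule compares it against 10% of the
  mean ICV; an absolute rule (reference values 10 cm³ for the ~20-week size
  class, 20 cm³ for ~30-week) is also available, and a practical band for
  the fractional rule is 7.5–12% of the mean.
* **Similarity gate.**  For the elastix-style pipeline, the overlap
  similarity

      Similarity = Σ a·b / √(Σ a² · Σ b²)

  between the final warped subject and the last registration average must be
  at least 0.7 (the floor is inclusive: only values *below* 0.7 fail).  On
  nonnegative images the value lies in [0, 1]: 1 for full overlap, 0 for
  disjoint supports.
* **Retry-then-exclude.**  A subject failing a gate is re-measured with
  fallback parameter presets — pre-blurring the affine stages (minc_style);
  switching to standard gradient descent with doubled step scale, then
  forcing the similarity stage (elastix_style) — at most two rounds, after
  which the subject is marked **excluded**.  Exclusion is a recorded verdict
  with a reason, never a silent drop or an error; per-plane mask-contour
  overlays are rendered so a human can attribute the failure.

Masks attached to models are finalized with a 3×3×3 median filter applied
three times ("kernel of three voxels" is read as a 3³ window, the standard
filter parlance); the same smoothing is available for any propagated mask.

## Groupwise model construction

A model is built from N ≥ 2 same-orientation scans: every scan is first
registered (affine, with translation+rigid initialization) to a designated
seed scan and averaged; three further affine rounds and four B-spline rounds
register every scan to the previous round's average and re-average,
sharpening the template each round.  The output template is the final
arithmetic mean.  When per-subject ICV masks are available, a reference
model mask is attached by propagating each mask onto the template grid
through its subject's chain, majority-voting at 0.5, and median-smoothing.
Reference cohort sizes of 10–20 scans per model (13, 11 and 17 in the
validation study this design follows) are typical.

## The phantom generator

Real cohort scans are not distributable, so the package ships a seeded
generator of fetal-head phantoms with *exact* ground truth: the ICV mask is
the set of voxel centers inside the inner cranial surface, so the true ICV
is a voxel count and the pipeline's entire error budget is attributable to
registration and propagation.

A phantom emulates, in order of application: a bright ellipsoidal cranial
shell around textured interior tissue; lateralized internal structures of
mixed contrast (dark ventricle-like and bright choroid-plexus-like
inclusions); an optional one-sided skull-base opening where the bright shell
is absent and tissue darker; a lateral echogenicity gradient of the shell
(angle-dependent skull reflection); multiplicative log-normal speckle
(mean-one, sigma 0.2 — the standard first-order B-mode texture model); an
acoustic-shadow sector zeroed outside the cranial interior; and zero padding
outside a 65°-sweep cone whose apex sits above the grid.  Two size presets
bracket the ~20-week (~100 cm³) and ~30-week (~300 cm³) size classes; they
are size labels, not anatomical models.

The chiral features (asymmetric half-axes, the one-sided opening, the shell
gradient, the lateralized inclusions) exist so that the two head
orientations are *genuinely* different images: a mirrored scan then
mismatches an unmirrored model the way real anatomy would, which is what
the QC failure-injection experiments rely on.  A perfectly symmetric
ellipsoid would make mirroring undetectable — and volumetric label
propagation is intrinsically mirror-robust for symmetric blobs, since
mirroring preserves volume.

What the phantoms do **not** emulate: sulci/gyri and their gestational
development, the cerebellum and skull-base anatomy, depth-dependent
attenuation and focal-zone effects, probe-pressure deformation, fetal
motion, and real inter-subject shape variability beyond isotropic scale and
rigid pose.  Passing the phantom experiments therefore demonstrates the
correctness of the registration/propagation/QC machinery under controlled
conditions, not clinical accuracy on real scans.

## Problem sizes and run times

The shipped experiments use 48³ phantoms at 2 mm spacing (32³ and 24³ for
unit and CLI tests), models built from 6–8 phantoms, and the `fast`
parameter preset (two pyramid levels, ~12% voxel sampling, 20–30 iterations
per level).  These sizes were chosen so the full validation suite runs on a
single CPU in minutes while leaving the method's behavior qualitatively
unchanged; the `full` preset (four levels, full sampling below 64³, 50
iterations) is the default recommendation for real data.

## Numerical choices and degenerate inputs

* Trilinear interpolation everywhere; mask threshold at 0.5 (values exactly
  0.5 are inside).
* NCC is undefined for constant images and fails loudly; the overlap
  similarity fails loudly for all-zero volumes.
* `replace_zero_voxels` fails on all-zero volumes; phantom specs validate
  geometric invariants (shell inside grid with a 2-voxel margin).
* B-spline basis evaluation clamps to the control grid interior; the
  2-control-point margin guarantees domain points never touch the clamp.
* Seeds: every stochastic component (voxel subsampling, phantom speckle,
  cohort draws) derives from explicit integer seeds; reruns are
  bit-identical.

## Known limitations

* The two pipeline variants, while decoupled in optimizer, metric and
  stiffness, still share one resampler and optimizer code base; their errors
  are less independent than two genuinely separate toolkits, and the
  consensus SD is correspondingly less sensitive than the dual-toolkit
  original.  Failures that preserve volume (e.g. a mask of the right size in
  slightly the wrong place) are invisible to a volume-agreement gate by
  construction.
* The global overlap similarity is dominated by the uniform background of
  preprocessed sweeps; it is a coarse gate (hence the background-suppressed
  variant used for the internal escalation check).
* Intensity-based registration assumes model and subject sizes within
  roughly ±10–15%; larger gaps need an age-appropriate model.
* No cohort statistics (growth curves, ICC, sex contrasts) are implemented;
  the package measures individual ICVs and their QC status.
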