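# Methods

This note documents the models and algorithms implemented in chronoatlas,
the parameters that matter, what the synthetic phantoms do and do not
emulate, and the numerical choices made where the design was open.

## Coordinate and transform conventions

Grids are regular and axis-aligned; the physical coordinate of voxel index
`i` is `origin + i * spacing` (mm), and the left–right anatomical axis is
the first array axis. All code is rank-generic (2D and 3D); the test suite
runs mostly in 2D for speed, with 3D covered by targeted cases.

Every transform follows the **pull-back convention**: it maps target-space
coordinates into source space, so source values can be sampled onto the
target grid. A composite transform evaluates literally as

    T(x) = A x + t + D(x),

the affine part applied to the point plus a dense displacement field
interpolated *linearly* at the target coordinate x (cubic B-spline
interpolation is reserved for image intensities). Chains concatenate
pull-back transforms first-link-first, with declared space names checked
for adjacency. Outside a field's domain the affine part alone applies and
the evaluation is flagged.

Resampling rules: intensities use cubic B-spline (`scipy.ndimage`
`map_coordinates`, order 3 with prefilter, so polynomials up to cubic are
reproduced in the interior; the prefilter's boundary transient decays
geometrically inward). Labels use nearest neighbour so no new classes can
appear; an exact .5 fractional index rounds toward the **lower** index — a
deterministic, documented tie rule. Out-of-domain voxels are filled with 0
for both. Tissue probability maps are interpolated linearly and
renormalized to sum to 1.

Displacement inversion is a fixed-point iteration g ← −f(x + g(x)),
accepted when the composition residual max-norm over interior voxels is
below tolerance (default 0.05 voxel); the Jacobian of (identity + f) is
computed by central differences in physical units.

## Registration

**Affine stage.** A similarity transform (translation, rotation, isotropic
log-scale; 4 parameters in 2D, 7 in 3D) is recovered by derivative-free
Powell optimization of the chosen metric over a 4-level pyramid (factor-2
downsampling after Gaussian anti-aliasing, σ = 0.85 voxel), rotation and
scale acting about the grid centre. If no candidate beats the identity the
identity is returned with a non-converged outcome. Powell needs no metric
gradient, which is why it was preferred over a finite-difference gradient
scheme for NMI.

**Deformable stage.** A symmetric stationary-velocity-field (SVF) demons:
one velocity field v lives on the fixed grid (after the affine has been
applied to the moving image once); the forward map is exp(v) and the
inverse exp(−v), computed by scaling-and-squaring with the number of
halvings chosen so each small step moves at most ~0.25 voxel. Forward and
inverse are therefore diffeomorphic mutual inverses by construction —
inverse-consistency error is bounded only by interpolation (≤ 0.1 voxel in
all accepted registrations). Each iteration computes a symmetric-gradient
demons force in both directions (fixed vs warped moving, and moving vs
warped fixed), antisymmetrizes them, smooths the update (fluid-like,
σ = 1 voxel), caps its max norm at the step size (0.25 voxel), adds it to
v and smooths v (diffusion-like, σ = 2 voxels). A level stops when the
relative metric change over a 5-iteration window falls below 1e-5 or the
iteration cap is reached; caps default to 100/100/100/20 from coarsest to
full resolution. If an update produces a non-positive Jacobian it is
rolled back at half step; persistent folding aborts with diagnostics (in
practice the exponential construction keeps Jacobians positive).

**Cross-contrast (NMI) driving.** The reported metric and the convergence
criterion under `metric="nmi"` are Studholme NMI, (H(A)+H(B))/H(A,B) ∈
[1, 2], invariant to any bijective intensity relabeling — the property
needed across the neonatal gray/white contrast inversion. The demons
*force*, which needs an intensity difference, is computed on a
polarity-corrected pair: each image is remapped through a conditional-mean
transfer (128 internal bins, lightly smoothed) estimated from the joint
histogram with the other image, so the forward force compares the fixed
image with the moving image expressed in fixed intensities, and vice
versa. The transfer is estimated once per pyramid level, at level entry.
An adaptive per-iteration refresh was evaluated and rejected: re-estimating
the conditional means on the progressively aligned pair lets the transfer
absorb residual misalignment and destabilizes the optimization.

## Temporal propagation

The chain from a target image to the labeled adult end of an age-template
ladder is `[target→youngest, youngest→next, …, oldest→atlas]`, each link
an affine + deformable registration in pull-back form. Inter-template and
template→atlas links default to NMI; the target-side link uses NCC
(intra-modality). Labels are resampled **exactly once**, through the
composed chain — composing coordinates and sampling once avoids the
cumulative nearest-neighbour erosion that per-rung resampling would cause.
Non-converged links are kept but flagged and named. Per-step quality is
summarized as the NCC between each warped source template and its target
(mean ± SD), the consecutive-time-point accuracy measure.

## Template construction

Given affinely pre-aligned subjects, each of the (default) 4 iterations:
registers every subject to the current template; replaces the template
appearance by the voxelwise mean of the warped subjects (a plain mean — no
Laplacian sharpening); and applies a `shape_step = 0.25` fraction of the
*inverted* voxelwise-mean forward displacement field to the template, so
its shape drifts toward the group mean (the mean field shrinks by roughly
(1 − shape_step) per iteration once registrations are consistent). If no
initial template is given, the voxelwise mean of the subjects is used.
The build is fully deterministic: identical inputs give a bit-identical
template.

Two diagnostics are recorded per iteration: the norm of the voxelwise
*mean* displacement field (the centering signal, which decreases
monotonically and ends ≤ 0.5 voxel in the test conditions) and the mean
per-subject displacement magnitude. The latter is only interpretable from
a sharp initialization: starting from the blurry voxelwise mean, the
first-iteration registrations underestimate displacement against the
blurred target, so that series can rise a few percent before plateauing.
The centering contract is therefore asserted from an off-centre
(single-subject) initialization, where both signals fall.

The symmetric variant runs the same build on the cohort augmented with a
mirrored copy of every subject (flip along the left–right axis), returning
2n transforms ordered originals-then-mirrored. Label maps entering the
symmetric fusion must be flipped **and partner-swapped** — mirroring alone
would put left IDs in right hemispheres; the swap is required for
anatomical consistency.

## Fusion, laterality, volumetry

Majority voting takes the per-voxel most frequent label with ties broken
toward the smallest label ID (deterministic and reproducible). Left–right
pairing is an explicit scheme table (ID → name, hemisphere, partner,
lobar group), never parity arithmetic, because real label schemes break
even/odd conventions around unpaired midline structures; the partner
relation is validated as a symmetric involution with opposite hemispheres.
ROI volume is voxel count × voxel volume (reported in cm³); lobar
proportions divide in-mask group volume by mask volume (unlabeled in-mask
voxels allowed, so percentages sum to ≤ 100). The asymmetry coefficient
S = 2|V_L − V_R|/(V_L + V_R) is scale-invariant, 0 iff the pair is
volumetrically symmetric, 2 when one side is absent, and undefined
(reported missing) when both are empty.

## Validation statistics

Landmark transfer error is the per-landmark Euclidean distance (mm) with
mean/SD summaries. ICC is the two-way mixed-effects, **consistency,
single-measures** form, ICC(3,1) = (MS_t − MS_e)/(MS_t + (k−1) MS_e) from
the two-way ANOVA mean squares — the common reading of "two-way mixed" for
repeated landmark placement; absolute-agreement ICC(2,1) is deliberately
not the default. Dice overlap 2|A∩B|/(|A|+|B|) is undefined when both
masks are empty. An installed independent implementation (pingouin) serves
as the ICC oracle in the tests, and SimpleITK as a resampling oracle;
neither is used by the library code.

## EM tissue segmentation

Per voxel, class posteriors are proportional to a Gaussian intensity
likelihood times a spatial prior probability; the M-step re-estimates
class means and variances from the posteriors. Initialization uses
prior-weighted intensity averages, falling back to intensity quantiles
when the priors are flat (which would otherwise give all classes the same
starting mean). The log-likelihood is non-decreasing across iterations
(asserted); convergence is a 1e-5 relative change, cap 50 iterations;
collapsing variances are floored at (1e-6 × intensity range)² with a
warning. Three classes (CSF/GM/WM) are the default. Deliberately omitted:
Markov-random-field spatial regularization and in-loop bias-field
estimation — bias correction is assumed upstream. Cohort tissue
probability maps are voxelwise means of per-subject posteriors in template
space, renormalized in-mask.

## Synthetic phantoms: what they emulate, and what they don't

The base phantom is a concentric head (background, CSF rim, cortical GM
ribbon, WM core) with four left/right pairs of deep-gray blobs, one
unpaired midline structure, five landmarks at structure extrema, and a
low-amplitude (±0.025) smooth mirror-symmetrized texture sampled in
anatomy coordinates, so it scales with the structures and keeps flat
tissue informative for registration. A laterality factor λ scales the
left blob radius by λ^(1/rank), targeting V_L/V_R ≈ λ; λ = 1 gives exact
voxel-level mirror symmetry by construction.

Cohort subjects are the phantom warped by exp of a random smoothed
velocity field (white noise, Gaussian σ = 4 voxels, scaled to a 3-voxel
maximum displacement by default), times a smooth multiplicative bias field
(±10%) plus Gaussian noise (2% of the intensity range). Because warps are
SVF exponentials, every subject carries an exact inverse warp, true label
map and true landmark positions, so recovery errors isolate pipeline
behaviour. Defaults (8 subjects, 128² grid, 1 mm spacing) are the
desk-scale study conditions used by the acceptance analyses.

Aging sequences shrink the head (default scales 1.0 → 0.8 over 6 stages)
while the WM intensity slides from 0.85 (adult, brighter than GM = 0.5) to
0.35 (neonatal, darker), crossing GM exactly once; each stage also carries
a small random warp (1 voxel). True stage-to-stage transforms are retained
as chains (younger warp ∘ centre scaling ∘ older inverse warp).

Not emulated: MRI physics (no k-space artefacts, no partial-volume mixture
model beyond interpolation), non-diffeomorphic anatomical change,
oblique orientations, and real inter-subject topology differences. Passing
tests therefore demonstrate the correctness and internal consistency of
the algorithms under known smooth deformations and contrast schedules, not
clinical-grade accuracy on real neonatal MRI.

## Scaled-down analysis conditions

`scripts/acceptance.py` recomputes three summary quantities at desk scale,
deriving all randomness from its `--seed` by stable hashing (results are
stable to the seed; the comparisons have generous stochastic slack):

1. **Symmetric-atlas laterality** — 8-subject 2D cohort (128², 3-voxel
   deformations, laterality 1.5 on two pairs), symmetric template over the
   16-image augmented set (4 iterations), flipped-and-swapped majority
   fusion, max S over pairs. The mirror-balanced design drives S well
   below the 0.05 symmetric-atlas bound.
2. **Consecutive-time-point NCC** — 6-stage aging ladder (128²) chained
   with NMI links; mean per-step NCC of warped-source vs target.
3. **Landmark transfer** — 10 subjects from known warps at 1 mm spacing;
   the phantom template is registered to each subject and the 5 landmarks
   mapped through the recovered transforms; mean Euclidean error pooled
   over subjects and landmarks.

Parameter-recovery tests use clean warped phantoms (no noise or bias),
since "known deformation" recovery is only identifiable where intensity
structure exists; endpoint errors are evaluated over the head foreground —
in the textureless background the true field is unobservable to any
intensity-driven method. Problem sizes in the tests (48–128² grids, 2–10
subjects, 1–4 template iterations) were chosen to keep the full suite in
the low minutes while leaving every contract measurable.

## Known limitations

- The demons regularization (fixed σ_update = 1, σ_field = 2 voxels) is a
  global smoothness prior; very sharp true deformations are under-fit.
- The conditional-mean intensity transfer assumes an (approximately)
  functional relation between the two images' tissue intensities; it
  degrades when one image's classes are genuinely unseparable in the
  other's histogram (the near-isointense gray/white stage is the hardest
  link, mirroring the real myelination transition).
- Majority voting ignores local registration confidence (no weighted or
  probabilistic fusion).
- Affine registration optimizes a similarity transform (no shear) —
  adequate for the phantom conditions; full 12-parameter affines would
  need an extended parameterization.
- NIfTI support is restricted to axis-aligned, RAS-like volumes.
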