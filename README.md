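# chronoatlas

Tools for building labeled brain atlases across large developmental gaps —
the kind of problem faced when an adult parcellation must be carried into a
neonatal cohort, where a direct registration fails because brain size,
shape and even gray/white image contrast (which inverts with myelination)
all change between the two endpoints.

The package provides, as a reusable library plus a `chronoatlas` CLI:

- **Chained temporal propagation.** A labeled adult-end atlas is mapped to
  the target space through a ladder of age-ordered intermediate templates.
  Each rung is an affine + symmetric diffeomorphic registration; inter-rung
  links use normalized mutual information, NMI = (H(A)+H(B))/H(A,B), which
  is invariant to contrast remapping, while the intra-modality target-side
  link uses normalized cross-correlation (NCC). All pull-back transforms
  T(x) = T_global(x) + T_local(x) are concatenated and labels are
  transported through the composition in a single nearest-neighbour pass.
- **Groupwise template construction.** An iterative scheme alternating
  (i) per-subject diffeomorphic registration to the current template,
  (ii) appearance update by voxelwise averaging of the warped subjects,
  and (iii) a shape update that applies a step of the inverted mean
  displacement field so the template converges to the group-mean shape.
  A left–right *symmetric* template is built by adding a mirrored copy of
  every subject as an independent subject.
- **Label fusion and laterality.** Majority-vote fusion of propagated label
  maps; mirroring with explicit partner-ID swap; ROI volumetry (cm³); and
  the volumetric asymmetry coefficient
  S = 2·|V_L − V_R| / (V_L + V_R) ∈ [0, 2].
- **Validation tools.** Landmark transfer error, consecutive-time-point NCC
  summaries, Dice overlap, and ICC(3,1) (two-way mixed, consistency,
  single measures).
- **EM tissue segmentation** (CSF/GM/WM) combining Gaussian intensity
  likelihoods with spatial prior maps, and cohort-average tissue
  probability maps.
- **A fully synthetic phantom test bed**: seeded labeled head phantoms,
  cohorts deformed by known diffeomorphisms (with exact inverse warps,
  landmarks and label maps retained as ground truth), and aging template
  ladders with progressive shrinkage and a gray/white contrast crossing —
  so the entire pipeline is exercisable end to end with no external data.

The registration engine is a symmetric stationary-velocity demons: a single
velocity field v is optimized, the forward map is exp(v) and the inverse
exp(−v) by scaling-and-squaring, so forward and inverse are diffeomorphic
mutual inverses by construction.

## Worked example

Build a small asymmetric cohort (the left "thalamus" blob 1.5× the right),
construct a symmetric template from originals plus mirrored copies, fuse the
flipped-and-swapped label maps, and measure the residual laterality:

```python
from chronoatlas import (SyntheticCohortSpec, make_cohort, phantom_scheme,
                         build_symmetric_template, transport_modalities,
                         majority_vote, flip_labels_lr, asymmetry_report)

spec = SyntheticCohortSpec(n_subjects=4, size=96, amplitude=3.0,
                           laterality={"thalamus": 1.5}, seed=42)
(phantom_img, phantom_lab, _), subjects = make_cohort(spec)
scheme = phantom_scheme()

result = build_symmetric_template([s.image for s in subjects], iterations=2)
stack = [s.labels for s in subjects] + \
        [flip_labels_lr(s.labels, scheme) for s in subjects]
fused = majority_vote(transport_modalities(stack, result))
rep = asymmetry_report(fused, scheme)
for r in rep.rows:
    print(f"{r['region']:<12} V_L={r['V_L']:.3f}  V_R={r['V_R']:.3f}  S={r['S']:.3f}")
print(f"max S = {rep.max_s():.3f}")
```

Output:

```
thalamus     V_L=0.079  V_R=0.079  S=0.000
putamen      V_L=0.045  V_R=0.044  S=0.022
caudate      V_L=0.038  V_R=0.039  S=0.026
hippocampus  V_L=0.045  V_R=0.045  S=0.000
max S = 0.026
```

The generating phantom had S = 0.424 for the thalamus pair (volumes 0.100 vs
0.065 cm³); after symmetric-template construction and mirror-balanced fusion
every pair's S collapses below 0.05 — the mirror augmentation removes the
cohort's anatomical laterality from the fused atlas, which is exactly why a
symmetric atlas is the right reference space for asymmetry studies.

The same pipeline is available from the shell:

```
chronoatlas simulate cohort --out-dir work/ --seed 42
chronoatlas symmetrize --subjects work/subject00.nii.gz ... --out template.nii.gz
chronoatlas asymmetry --labels fused.nii.gz --scheme work/scheme.tsv --out S.csv
chronoatlas run --config demo.yaml --out-dir out/     # full end-to-end pipeline
```

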