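# Methods

This note documents the models, the synthetic data they are validated on,
the numerical choices, and the limits of what the tests show.

## Preprocessing

Each modality is clipped at the (0.2, 99.8) percentiles of its **non-zero**
voxels (linear interpolation between order statistics, the NumPy default),
then z-scored with the mean and standard deviation of the clipped values
over the **brain mask** — the two voxel populations are deliberately
distinct: percentiles over non-zero voxels, moments over in-brain voxels.
Outside-brain voxels are set exactly to 0.  The brain mask itself is the
union of non-zero voxels across modalities, since inputs are assumed
skull-stripped and no explicit mask accompanies them.  A constant in-brain
channel (σ = 0) is an error, not a silent pass-through.  Whether clipping
should see in-brain zeros is not decidable from the convention "non-zero
voxels"; we clip over non-zero voxels of the whole volume and document the
choice here.

## Architectures

Both networks run on a small NumPy compute core written for this package
(3D convolution as per-offset channel matmuls, batch/group normalization,
max/average pooling and trilinear resizing as exact per-axis linear maps
with adjoint backward passes, Adam with the AMSGrad correction).  All layer
gradients are verified against central finite differences in the test
suite.  Widths are configuration, not architecture: the paper-scale and
tiny test instances share one code path, and every geometric identity below
holds for any channel count.

**Dual-path multiscale patch CNN.**  A normal-resolution path (receptive
field 25³) and a low-resolution path (receptive field 19³, average-pooled
by factor 3 — kernel 3, stride 3, pad 1 — from a 55³ neighbourhood sharing
the same center).  Each path is 8 valid 3×3×3 convolutions with batch
normalization and ReLU; the normal path adds identity shortcuts over the
layer pairs (3,4), (5,6), (7,8), center-cropped spatially and zero-padded
(or truncated) over channels.  The low-path output (3³) is upsampled ×3 by
trilinear interpolation, concatenated with the normal path, and two 1×1×1
convolutions emit 5-class logits over the central 9³ voxels
(25 − 2·8 = 9; (19 − 2·8)·3 = 9).  Default widths 30/40/50-style widening;
tiny instances use 4 kernels per layer.

**Encoder-decoder CNN.**  Residual encoder blocks (two same-padded 3×3×3
convolutions with group normalization, 4 groups, identity shortcut, ReLU,
dropout 0.3), 2³ max-pooling between levels, trilinear ×2 upsampling with
skip concatenation and two convolution blocks per decoder level, and a
final 1×1×1 convolution at input resolution.  Input sides must be divisible
by 2^(depth−1); whole-volume inference pads to divisibility and strips the
padding.  When a width is not divisible by the group count the
normalization degrades to one group rather than failing, so tiny instances
stay runnable.

**Five-class convention.**  Probability maps always carry classes
[0, 1, 2, 3, 4].  Only {0, 1, 2, 4} are real (background, enhancing tumor,
edema, necrosis & non-enhancing tumor — note label 1 = enhancing here);
class 3 is a legacy channel kept near zero so fusion feature vectors have a
fixed 10-dimensional layout (two 5-class blocks).  Any argmax that lands on
class 3 is remapped to background.

## Training

The patch CNN trains on class-balanced centers — each center is drawn
Bernoulli(0.5) from lesion voxels vs in-brain background (an exact
Bernoulli reading of "approximately 50%") — with flip augmentation (each
axis independently with p = 0.5, applied to all channels and targets) and
Gaussian noise on the image channels only (sd 0.1 in normalized units;
atlas masks and labels are never perturbed), under plain multi-class
cross-entropy.  The encoder-decoder trains on random crops with
hard-negative-mined cross-entropy — all positive voxels plus the K
highest-loss negatives, K = min(#neg, 3·#pos), averaged over the selected
voxels; with no positives K falls back to 1% of the negatives so gradients
never vanish — and no augmentation.  Both use Adam with AMSGrad, initial
rate 10⁻³, L2 weight decay 10⁻⁴.

The decay schedule is `l0 · 0.1^(epoch/epochs)` (one decade over the run).
The literal per-epoch form `l0 · 0.1^epoch` is selectable but underflows to
numerical zero within five epochs of a long run, which cannot be a usable
schedule; it is retained for fidelity only.

## Inference

The patch CNN predicts 9³ windows tiled with step 9 over the brain bounding
box.  240 and 155 (and most test grids) are not multiples of 9, so final
windows are shifted flush to the volume edge and overlapping predictions
are averaged in probability space — averaging is order-independent, and on
small volumes the tiling provably equals dense per-window prediction (an
oracle test).  The encoder-decoder takes the whole padded volume in one
pass.  In both cases voxels outside the brain mask are forced to
background, avoiding intensity/atlas garbage outside the skull-stripped
region.

## Location fusion

The subject-space parcellation atlas is split into one binary mask per
label-table entry in ascending label order and concatenated after the four
modalities — 25 channels for the 21-region subcortical table.  Channels are
emitted for every table label even when absent from a subject's grid, so
the network input arity is fixed by the table, not the data.  Registration
of a template-space atlas is a pluggable affine (4×4 voxel-to-voxel matrix
or a callable returning one) resampled with nearest neighbour — label
interpolation is meaningless — and deformable registration is deliberately
out of scope because a lesion mask, which is the quantity being estimated,
would be required to drive it.  The cohort statistic divides total lesion
volume per (class, parcel) over all subjects by the parcel volume; summing
before dividing means ratios can exceed 1 on large cohorts, which is the
quoted definition and is left as-is.

## Two-level ensemble

Level one is the arithmetic mean of seed-replica probability maps per
architecture.  Level two operates on 10-dimensional per-voxel features
(ensemble-A 5-class block then ensemble-B block) with XGBoost:

* **TLMC** — one multi-class classifier (softmax objective) over the labels
  present in the training table;
* **TLBC** — binary cascade: model_WT (WT vs background) on all sampled
  voxels, model_TC (TC vs WT∖TC) trained on ground-truth WT voxels only,
  model_ET (ET vs TC∖ET) on ground-truth TC voxels only.  At prediction the
  second stage is gated by the *arithmetic-mean* WT mask (as described for
  the original experiments); passing no gate makes the cascade self-gate on
  model_WT.  Cascade labels: ET̂ → enhancing, TĈ∖ET̂ → NCR/NET,
  WT̂∖TĈ → edema;
* **TLFC** — model_WT and model_TC from the cascade plus the multi-class
  model for the NCR/NET class, merged by priority
  NCR/NET > TC > WT > background (a voxel claimed as both WT and TC gets
  the TC outcome, i.e. priority grows with specificity).

Tumor core is ET ∪ NCR/NET (the nested-region definition); a conflicting
phrasing that would make TC include edema contradicts the subset property
the cascade itself requires and is not implemented.

Training voxels for the fusion classifiers are all lesion voxels, a
3-voxel dilated lesion border, and a uniform background subsample capped at
3× the lesion count — full volumes would be millions of rows per subject.
XGBoost hyperparameters default to 300 trees, depth 6, learning rate 0.1,
seeded and recorded in the fitted model's metadata; tests use smaller
instances (40–100 trees, depth 4) of the same configuration surface.

## Metrics

DSC = 2|G∩P|/(|G|+|P|), with the two-empty-masks convention DSC = 1.
HD95 extracts surface voxels (mask voxels with a face-adjacent background
neighbour, 6-connectivity, volume border counts as background), computes
exact Euclidean distance transforms of each surface, and takes the 95th
percentile of the two directed distance sets **pooled** (symmetric by
construction); the max-of-directed-95th-percentiles convention is available
behind a flag since published values do not identify which pooling their
evaluation used.  Both empty → 0; exactly one empty → a sentinel, by
default the physical grid diagonal.  An O(n²) all-pairs oracle validates
both conventions to 1e-9 in the tests.

## Synthetic phantoms

A phantom subject is: an ellipsoidal brain (semi-axes 0.42/0.40/0.38 of the
grid); a Voronoi parcellation of uniformly sampled in-brain seed points
(n_parcels = 21 by default), guaranteeing full brain coverage; and a nested
lesion — three concentric randomly-oriented ellipsoids (edema ⊃ enhancing
shell ⊃ necrotic core) — seeded in a parcel drawn from a per-parcel prior
(uniform by default).  The whole-tumor radius is drawn from 0.16–0.24 of
the smallest grid dimension and capped so the lesion stays strictly inside
the brain; a spec whose smallest requested radius exceeds the deepest brain
voxel fails explicitly rather than clipping.  Default intensities (raw
scale, before normalization): brain 100 in every modality, edema bright on
FLAIR/T2 (155/145), enhancing tumor bright on T1Gd (160), necrosis dark on
T1Gd/T1 (60/70), Gaussian noise sd 10 — contrasts of roughly 2–6 noise
standard deviations, i.e. clearly separable but not noise-free.  In-brain
intensities are floored at 1 so the brain mask is recoverable as the
non-zero support.  Generation is bit-deterministic in (spec, seed).

What the phantoms do **not** emulate: MR physics (bias fields, partial
volume, coil profiles), anisotropic spacing, multifocal or infiltrative
lesion geometry, inter-subject anatomical variability beyond parcel layout,
and real atlas misregistration.  Passing tests therefore demonstrate that
the pipeline's machinery — preprocessing, fusion arity, training dynamics,
tiling, ensembling, metrics — is correct and that the method behaves as
designed on separable data; they do not certify segmentation accuracy on
clinical images.

## Test problem sizes

Tests run tiny instances chosen to keep the full suite at desk scale:
phantoms of 32³–48³ voxels, patch-CNN widths of 3–4 kernels per layer,
encoder-decoder base width 4–8 at depth 3, 2–40 training epochs, XGBoost
with 40–100 trees.  The end-to-end check trains three seed replicas of each
tiny architecture on six 48³ phantoms and requires mean-ensemble whole-
tumor Dice > 0.6 on two held-out phantoms (observed ≈ 0.9 at these sizes).

## Location-information check

The directional claim — location channels help — is tested where it is
information-theoretically guaranteed: phantoms whose lesion occupies
exactly one fixed parcel of a parcellation whose layout is randomized per
subject, with **zero** intensity contrast between lesion and brain tissue.
There the image channels carry no class signal and patch position only
weak priors, so a model without location channels is bounded below by the
entropy of labels given intensity and position, while the fused model can
read the lesion directly off the parcel channel.  Two design points keep
the comparison honest: fresh phantoms are generated every epoch (a
streaming regime in which training loss measures generalizable signal, not
memorized noise — with a fixed small cohort, a network at this scale
demonstrably learns to recognize subjects by their frozen noise patterns),
and both arms share every hyperparameter, including a raised learning rate
(1e-2) that lets tiny models approach their loss floors within the epoch
budget.  The test compares the median number of epochs needed to reach a
training-loss threshold placed between the two floors, over five seeds.
This is a desk-scale analogue of the fusion benefit, not a reproduction of
validation-set improvements on clinical data.

## Known limitations

* CPU-only NumPy compute: paper-scale training (500 epochs, 240³ volumes,
  widths of 30–50) is out of desk-scale reach; all accuracy statements in
  the tests refer to tiny instances on phantoms.
* The unstated per-layer kernel counts of the original figures are
  configuration defaults here, not reproductions.
* Five-fold cross-validation orchestration is a pipeline option, not
  exercised by the default test sizes.
* HD95 pooling convention and the clip-population question above are
  documented choices with the alternative selectable.
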