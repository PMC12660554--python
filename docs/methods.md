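# Methods

## Problem

Different amyloid-beta PET radiotracers are not interchangeable:
[11C]PiB shows a wider cortical SUVr dynamic range (roughly 0–3.0) than
[18F]florbetaben (FBB, roughly 0–2.2), FBB has prominent nonspecific
white-matter binding, and regions such as the choroid plexus differ between
the two. The Centiloid scale harmonizes tracers but reduces a whole image to
one number. This package implements a voxel-wise alternative: a 2D
encoder–decoder network built from deformable-convolution (DCNv3) blocks
that translates PiB SUVr slices (optionally with a coregistered T1 MR
channel) into FBB-like SUVr slices, plus the preprocessing, training,
evaluation and Centiloid chain around it.

## DCNv3 operator

For input feature map `x` with `C` channels split into `G` groups of
`C' = C/G` channels, the operator computes at every location `p`

    y_g(p) = sum_k m_gk(p) * V_g(p + g_k + Δp_gk(p)),      k = 1..K

where `V = W_in x` is a pointwise input projection, `g_k` ranges over the
K = 9 taps of the nominal 3×3 grid, and the per-group offsets `Δp` and
modulation weights `m` (softmax-normalized over the K taps) are predicted
from `x` by a depthwise 3×3 convolution → LayerNorm → GELU → pointwise
linear maps. Sampling at fractional positions is bilinear with a
zero-padding convention (out-of-map reads are 0). Group outputs are
concatenated and passed through an output projection `W_out`.

Choices the operator's published description leaves open, fixed here:

* modulation normalization is softmax over the K taps (per group/location);
* offset and modulation predictors are zero-initialized, so the untrained
  operator is exactly a 3×3 box smoother — a closed form the tests exploit;
* border handling is zero-padded bilinear sampling.

The basic block is pre-norm residual: `x + DCNv3(LN(x))` followed by
`y + FFN(LN(y))` with a 4× hidden-ratio two-layer FFN and GELU.

### Verification

The vectorized operator is checked to machine precision against
`dcnv3_forward_naive`, an explicit loop over locations, groups and taps
built on a scalar `bilinear_sample` (itself checked against
`scipy.ndimage.map_coordinates`). A fused numba kernel (forward and analytic
adjoint, `amytrans.nn._deform`) accelerates the sampling path roughly 2× at
training scale; tests assert the fused, pure-autodiff, and naive routes
agree to ~1e-15 and that autodiff gradients match central finite differences
at 1e-4 (offsets are nudged off the integer grid first, since bilinear
sampling is non-smooth exactly at grid crossings).

## Network

Four hyperparameters `(C1, C', L1, L3)` determine the model through the
stacking rules: stage channels `C_i = 2^(i-1) C1`, groups `G_i = C_i / C'`,
depths `(L1, L1, L3, L1)`. The reference setting `(4, 4, 4, 8)` gives
channels (4, 8, 16, 32), groups (1, 2, 4, 8), depths (4, 4, 8, 4).

* Stem: two 3×3 stride-1 pad-1 convolutions (LN, GELU between) — no
  downsampling, so stage 1 runs at the full slice resolution.
* Between stages: 3×3 stride-2 convolution doubling channels, then LN.
* Stage 4 is the bottleneck.
* Decoder: three upsampling layers — 2×2 stride-2 transposed convolution,
  concatenation with the matching encoder output, 3×3 pad-1 convolution, LN.
* Head: a single 1×1 convolution to one channel.

Total: 132,321 learnable parameters for two input channels — two orders of
magnitude below attention-based U-Nets of the 27M–66M class. The network is
implemented on a small reverse-mode autodiff engine over NumPy
(`amytrans.nn`), channels-last, with im2col+BLAS convolutions.

## Phantom generator

No public paired PiB/FBB cohort ships with the package, so a synthetic
generator provides triplets with a known inter-tracer mapping. Anatomy is a
nested-ellipsoid head (scalp shell, cortical gray ribbon partitioned into
frontal / parietal / temporal / medial-temporal / occipital / cingulate
sectors, white-matter core, ventricle/choroid-plexus, inferior cerebellar
blob), defined in fractional grid coordinates on a default 109×91×91 grid of
2 mm voxels with ±1 % per-subject jitter. Noiseless SUVr per tissue as a
function of latent burden `A ∈ [0, 1]`:

| tissue            | PiB           | FBB           |
|-------------------|---------------|---------------|
| cerebellar gray   | 1.0           | 1.0           |
| cortical gray     | 1.0 + 2.0 A   | 1.0 + 1.2 A   |
| white matter      | 1.3           | 1.6           |
| ventricle / CP    | 0.9 + 0.4 A   | 0.7 + 0.3 A   |
| scalp, background | 0             | 0             |

These values reproduce the qualitative contrasts of real data — the 3.0 vs
2.2 cortical ceilings, FBB's white-matter nonspecific binding, an
inter-tracer discrepancy region — while keeping the mapping invertible for
recovery tests. Volumes are blurred with a 6 mm FWHM Gaussian PSF and
perturbed with additive Gaussian noise (sd 0.05 SUVr, clipped at 0);
MR is a T1-like contrast (WM > GM > CSF) independent of burden. Burdens are
drawn per diagnosis: YHC/FTD [0, 0.15], EHC [0, 0.5], MCI [0.05, 0.9],
AD [0.3, 1.0]; the default cohort is 10/6/9/8/2 = 35 subjects.

What the phantoms do **not** emulate: scanner physics (attenuation,
reconstruction artifacts), kinetic behavior, anatomical variability beyond
jitter, spatially varying tracer kinetics within a tissue class, or
registration error. Passing the phantom-recovery tests therefore
demonstrates that the pipeline and optimization behave correctly on data
with the reported statistical structure, not clinical-grade performance.

## Preprocessing

Head masks are derived from MR by thresholding at a quantile of the
nonzero-voxel intensities (default 0.4, separating clipped background noise
from tissue), 3×3×3 morphological closing (on a padded volume, so the border
is not eroded), per-slice hole filling, and largest-connected-component
selection. PET volumes are masked and converted to SUVr by dividing by the
whole-cerebellum mean. Axial slices 10–75 (0-based, inclusive — 66 slices)
are zero-padded from (109, 91) to (128, 128); the pad split is even with the
extra voxel on the high-index side, i.e. offsets (9, 10, 18, 19), making
padding exactly invertible. Optional augmentation samples one transform set
(flip, shift, scale, rotation, blur, noise sd) and applies it identically to
the input channels and the target.

## Training

Loss: `L = a1·L1 + a2·L2 + a3·(1 − SSIM)` with weights (1, 0, 1). SSIM uses
an 11×11 Gaussian window (σ 1.5), stabilizers `C1 = (0.01 R)²`,
`C2 = (0.03 R)²`, with data range R fixed at 3.0 (the PiB ceiling) rather
than per-batch for stability; the implementation matches
`skimage.metrics.structural_similarity` (Gaussian weights, population
covariance) to ~1e-15 on its valid region.

Cross-validation: subjects are stratified by diagnosis into five folds with
FTD regrouped as EHC (FTD is not an amyloid pathology); within each group
subjects are shuffled and dealt round-robin starting at the least-filled
fold, so fold sizes and per-diagnosis counts differ by at most one (a
35-subject cohort gives folds of exactly 7). Step *k* tests fold *k*,
validates fold *k+1 (mod 5)*, trains on the rest; the best-validation-loss
checkpoint is returned and the test fold never enters a training batch
(asserted by instrumentation in the tests).

Optimization (unspecified in the source design; package defaults): Adam
(β = 0.9/0.999, float64 moments), global gradient-norm clipping at 5,
learning rate 3e-3 with cosine decay to 3e-4, batch size 8. Everything is
seeded; two runs with the same configuration are bit-identical.

Whole-volume prediction runs the network over the kept slices, unpads each
output to (109, 91), stacks (slices outside the range are zero), and applies
the head mask. At the 64×64 fallback resolution (2×2 average pooling after
padding), outputs are bilinearly upsampled back to 128×128 before unpadding.

## Evaluation and Centiloid

RMSE is computed over masked voxels; PSNR = 20 log10(R) − 20 log10(RMSE)
with R the in-mask ground-truth max unless specified; SSIM is computed per
kept axial slice (scikit-image) and averaged. Relative-change maps use a
0.1-SUVr denominator floor against near-skull blow-ups. Bland–Altman limits
are mean ± 1.96 sd of paired differences. The Wilcoxon signed-rank test uses
the exact permutation distribution (rank-polynomial convolution, equivalent
to exhaustive sign-flip enumeration) for n ≤ 25 without ties and a
tie-corrected normal approximation otherwise; the reported statistic is the
signed rank sum T+ − T−, and the pairing unit is the subject (per-slice
pairing would be pseudo-replication).

Centiloid: CL = 100·(SUVr − YC0)/(AD100 − YC0), anchored on the phantom
cohort's own YHC and AD group means in phantom work (with real data the
anchors or coefficients are supplied). A surrogate tracer is calibrated by
an OLS fit of paired (surrogate, PiB) cortical SUVr and composition with the
PiB CL mapping. Amyloid positivity uses the 20-CL cutoff, inclusive.
A published paired-cohort CL table ships with the package
(`amytrans/data/paired_cohort_centiloid.csv`) for concordance arithmetic;
mechanically thresholding its prediction-vs-FBB columns flags exactly one
discordant subject (one false positive, no false negatives).

## Desk-scale phantom recovery study

The end-to-end check trains the PiB+MR model on a 20-subject phantom cohort
(6/4/4/4/2 across diagnoses, seed 0) at the 64×64 fallback resolution, every
6th kept slice, 30 epochs of fold-protocol training at batch size 4 (12
train / 4 validation / 4 held-out test subjects, ~990 optimization steps),
and then asserts the direction of the
control-vs-prediction comparison — masked RMSE(prediction, FBB) below
RMSE(PiB, FBB) and SSIM above — on the held-out subjects, plus a
predicted-vs-true cortical SUVr regression (slope near 1, high R²) on the
noiseless version of the cohort. Predicted volumes are renormalized by their
own cerebellar mean before the regression, the standard SUVr convention.
These problem sizes are the package's desk-scale defaults; the same study at
full resolution and cohort size is a matter of configuration, not code.

## Known limitations

* 2D slice model: no continuity constraint along the axial direction.
* The phantom's tissue-wise linear mapping is far simpler than real
  inter-tracer biology; recovery results bound pipeline correctness, not
  clinical accuracy.
* The autodiff engine is CPU/NumPy only and implements exactly the operator
  set this network needs.
* LayerNorm-heavy stems learn absolute-intensity mappings slowly; at desk
  scale the cortical regression slope is sensitive to the training budget.
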