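# Methods

## Problem

Spectral photon-counting CT (SPCCT) bins detected photons into several
energy windows, giving each voxel a short attenuation spectrum instead of a
single CT number. Materials whose band-integrated attenuation coincides —
low-concentration iodine contrast versus mid-concentration hydroxyapatite
(HA) is the clinically important case — can still differ in spectral
*shape*. `spectraseg` implements voxel-wise material classification from
such multi-energy volumes: each voxel is assigned one of 13 labels
(background, five HA concentrations, three iodine concentrations, three
soft-tissue surrogates, water), with an architecture designed to preserve
and exploit the energy axis, and a synthetic phantom simulator that makes
the whole pipeline testable without scanner data.

## Synthetic phantom simulator

The simulator emulates a cylindrical 100 mm phantom with eight insert
positions (one central, seven on a ring at 0.325x the diameter) holding
10 mm material rods that traverse all axial slices; each scan carries
F = 5 energy-bin images per slice (bins 7–12, 12–15, 15–18, 18–21,
21–120 keV) plus a voxel-exact label map. Five scans with different rod
assignments cover all twelve materials.

**Material table.** No attenuation values are measured; the table is a
constructed set of per-bin signatures in arbitrary units obeying a
water-anchored linear mixing model `mu = mu_water + c * shape`. The HA
shape decreases monotonically with energy (photoelectric-dominated
calcium); the iodine shape is flat at low energy with a rise in the wide
top bin containing the iodine K-edge (33.2 keV). The two unit shapes are
normalized to the same sum, and concentration coefficients are chosen so
that the band-integrated attenuation of I5 equals HA100's and I10 equals
HA200's *exactly*. These engineered confusable pairs encode the hard case
the package exists for: any model that collapses the energy axis cannot
separate them even noiselessly, while their per-bin profiles differ by
well over 5 noise standard deviations in the widest bin at default noise.

**Forward model.** Reconstructed-intensity domain, no projection physics:
voxel intensity in bin f is `mu[f]`, multiplied by a radial cupping field
`1 - A(1 - (r/R)^2)` (A = 0.05 by default, a cheap stand-in for beam
hardening), plus zero-mean Gaussian noise with per-bin standard deviation
`sigma0 * sqrt(w_ref/w_f)` (w_f = bin width; narrow bins are noisier, as
they collect fewer photons). Default `sigma0 = 0.005` keeps the
engineered per-bin separations of the confusable pairs at or above the
5-sigma level. Labels are rasterized by a voxel-center-in-disk test with
no partial-volume mixing; the water-filled phantom bulk renders with
water intensity but is labeled background (water is a class only where a
water rod sits). Rod layouts always include the confusable quartet
{HA100, HA200, I5, I10} so the hard case is present in whichever scan is
held out; the remaining four positions rotate through the other eight
materials, guaranteeing full coverage across five scans. The field of
view is 1.3x the phantom diameter (0.1 mm voxels at a 1300-pixel grid,
scaling to any requested image size); an explicit voxel size can override
this. Everything is a pure function of the seed, and the dataset manifest
(material table, layouts, per-scan seeds, acquisition parameters) allows
bit-identical regeneration.

What the simulator does *not* model: detector charge sharing and pulse
pile-up, reconstruction artifacts beyond smooth cupping, partial-volume
spectra at rod edges, anatomical context, patient motion. Tests passing
on this generator therefore demonstrate correctness of the pipeline and
the spectral-shape-vs-magnitude mechanism, not clinical performance.

## Augmentation

Training-time only (exact identity in eval mode):

- **Grid puzzle** — per sample, g is drawn uniformly from {1..10}; for
  g > 1 the slice is cut into g x g equal tiles (floor-sized, with any
  remainder border left in place) and one random tile permutation is
  applied to all energy bins and the label map. This destroys global
  geometry (rod contours, ring layout) while preserving each voxel's
  spectral-vector/label pairing, pushing the model toward
  energy-dependent attenuation rather than shape priors; large g
  emphasizes small, calcification-scale patterns.
- **Flips / 90-degree rotations** — in-plane only; the energy axis is
  never permuted or reflected.
- **Intensity jitter** — one multiplicative gain per slice drawn from
  U(0.9, 1.1), shared across bins (a per-bin gain would corrupt the
  spectral signature), plus i.i.d. Gaussian noise (sigma 0.01; the
  magnitudes are declared defaults, not measured quantities).

## Network

The backbone is a 3-D U-Net whose third tensor axis is the energy axis:
input `(B, 1, F, H, W)`, double-convolution blocks (3x3x3 kernels,
InstanceNorm3d, LeakyReLU slope 0.01), max-pool downsampling and
transposed-convolution upsampling both with stride 1x2x2 — never along
energy — so every level keeps all F bins. Default widths are 32/64/128
encoder + 256 bottleneck (four resolution levels); skip connections
concatenate at matching resolutions. A fusion head with kernel extent
(F,1,1) and no energy padding collapses the preserved spectral stack into
13 logits per voxel; argmax (ties to the lowest class index) gives labels.

Three spectral modules can follow each double-conv block, inserted in the
order spec-SE, EnergyFiLM, FourierGate:

- **spec-SE**: squeeze = spatial mean only, keeping a (B, C, F)
  descriptor; a two-layer bottleneck (reduction 8, shared across energy
  indices) with sigmoid output gates each (channel, bin) in (0,1).
- **EnergyFiLM**: a sinusoidal encoding of the bin index feeds a small
  per-block perceptron producing per-(channel, bin) affine parameters;
  output is `(1 + dgamma) * u + beta` broadcast over space. The final
  layer is zero-initialized, so the module is exactly the identity at
  initialization — training stability, and ablation deltas stay
  attributable to the module rather than to initialization noise.
- **FourierGate**: the global spectral profile (mean over channels and
  space, per sample) is transformed with a real FFT along the energy
  axis, each of the floor(F/2)+1 coefficients is scaled by a learnable
  nonnegative mask (initialized to ones; clipped at zero when applied),
  and the inverse transform gives a per-bin gate that rescales the
  features. The transform is implemented as fixed cosine/sine matrix
  products, which makes the gradient exact and lets a complex-DFT oracle
  verify it.

Variants: `plain` (no modules), `sp` (SE), `e_sp` (SE+FiLM), `fg_sp`
(SE+FourierGate), `spff` (all three), and `blind_control`, which averages
the *raw* bins before per-scan standardization and runs the same
architecture with F=1. The control's averaging happens before
standardization deliberately: z-scoring bins first would reweight them by
1/sigma_f and leak spectral shape into a model meant to see only
band-integrated intensity. `blind_control` exists to demonstrate that
spectral shape, not magnitude, drives HA–iodine separation.

Initialization is He-style for convolutions, keyed by (seed, layer name),
so architecture variants share identical initial weights for their common
layers. At the default configuration the full model has 5.48 M trainable
parameters.

The network and its gradients are implemented directly in numpy
(reverse-mode, layer by layer) and every backward pass is checked against
central finite differences in float64.

## Objective and metrics

Training minimizes cross-entropy plus one minus a pooled soft foreground
Dice:

    L = CE(p, g) + (1 - Dice_fg(p, g))
    Dice_fg = 2 * sum_fg(p*g) / (sum_fg(p) + sum_fg(g) + 1e-6)
    CE = -(1/N) * sum_i sum_c g_ci log p_ci        N = B*H*W

The Dice term pools sums over the twelve foreground classes before the
ratio (a per-class-averaged alternative exists behind a flag but is
unused by default); cross-entropy runs over all 13 classes.
Probabilities are clipped at 1e-12 before the log.

Evaluation uses one-vs-rest voxel confusion counts per (slice, class):
Dice, sensitivity, specificity, precision, IoU. Missing-value semantics:
when a slice has no ground-truth positives for a class, Dice and
sensitivity are NaN and omitted from means; precision and IoU are NaN
when nothing is predicted either (TP=FP=0) and collapse to 0 when false
positives exist. Macro scores are unweighted means over foreground
classes that occur anywhere in the test ground truth. Slice-wise error
series report e = 1 - Dice per class group (HA: 800/400/200/100; iodine:
15/10/5) with mean and a 1.96 x sample-SD half-width; seed aggregation
uses the sample (n-1) standard deviation.

## Training protocol

Adam (lr 1e-4, no weight decay), ReduceLROnPlateau (factor 0.5, patience
5), early stopping (patience 12, minimum improvement 1e-3), both
monitored on validation macro Dice (maximize; hard-label Dice, since the
monitor is an evaluation quantity), capped at 200 epochs. Splits are at
scan level — one external test scan, remaining scans ~80/20 train/val
(3/1/1 at five scans; scan granularity takes precedence over the exact
ratio) — and a leakage guard refuses to evaluate on any training scan.
The checkpoint kept is the epoch with maximal validation macro Dice.

## Desk-scale study configuration

The canned end-to-end study (`spectraseg.experiments`) runs the full
pipeline on one CPU core in minutes. Problem sizes, chosen once as the
package's desk-scale defaults:

| knob | value | note |
|---|---|---|
| image size | 96 px (1.354 mm voxels) | phantom geometry unchanged |
| slices per scan | 100 | as in the acquisition design |
| backbone | 8 base channels, 3 levels | ~0.34 M parameters |
| training crops | 16 px, foreground-biased (p=0.9) | one crop per slice per epoch |
| batch size | 1 | maximizes Adam steps per unit compute at fixed lr |
| epoch cap | 30 (reduced) | early stopping still active |
| validation slices | 4 per epoch | slices of a scan are statistically exchangeable |

Inference for crop-trained networks is patch-based: slices are predicted
as stitched non-overlapping tiles at the training crop size, the standard
sliding-window practice for patch-trained segmentation networks. This
matters here because instance normalization is content-adaptive: a
network trained on foreground-biased 16-px crops is badly miscalibrated
when fed whole slices (measured macro Dice 0.003 full-slice versus 0.23+
tiled with identical weights, early in training).

Under these conditions the full spectral-preserving model reaches macro
Dice well above 0.6 on the held-out scan while the energy-blind control
collapses on the confusable classes, which is the package's headline
computation (`scripts/acceptance.py` reruns it from scratch).

## Numerical choices and degenerate inputs

- Instance-norm epsilon 1e-5; Adam epsilon 1e-8, betas (0.9, 0.999).
- Scheduler reduces on the (patience+1)-th consecutive epoch whose
  improvement is below 1e-3; early stopping fires on the patience-th.
  An improvement of exactly the threshold counts as improvement.
- Argmax ties break to the lowest class index (numpy argmax semantics),
  so predictions are deterministic.
- `grid_puzzle` rejects g > min(H, W); g = 1 and eval mode are exact
  identities (same array, no copy, in eval mode).
- Empty training partitions, overlapping splits, non-finite losses,
  out-of-phantom rods and non-ascending bin edges all raise immediately
  with a diagnostic rather than propagating bad state.
- The FourierGate mask is stored raw and clipped at zero when applied;
  the subgradient at exactly zero is taken as zero.

## Known limitations

- The simulator's simplifications (listed above) mean desk-scale scores
  do not predict scanner-data performance; the study validates mechanism,
  not clinical accuracy.
- Water rods are spectrally identical to the water-filled phantom bulk
  (labeled background), so the water class is learnable only through
  geometry that the grid puzzle deliberately destroys — water Dice is
  accordingly poor. This mirrors the difficulty of distinguishing a
  water-like insert from background in real phantoms and is kept as an
  honest hard case.
- The numpy implementation is single-threaded compute; wall-clock scales
  linearly with voxels x channels^2. GPU-scale configurations (512-px
  slices, 32 base channels, 200 epochs) are expressible but not practical
  in this implementation.
- Per-block FiLM perceptrons are independent (not shared across blocks);
  spec-SE excitation weights are shared across energy indices. Both are
  design choices where several variants would be defensible.
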