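# Methods

## The problem

In circular-scan photoacoustic tomography (PAT) a ring of ultrasound
transducers records the pressure waves that a laser pulse launches from
optical absorbers. Delay-and-sum (DAS) reconstruction back-projects each
channel at the per-pixel time of flight t_i(Q) = |r_sensor,i − r_Q| / c,
where the sensor position is placed at the assumed scanning radius (SR).
If the assumed radius differs from the true one by ΔR, every point target
smears into an annulus of radius ≈ |ΔR|; across a whole image this produces
blurring, doubled edges and geometric distortion. This package simulates
that failure mode end to end and trains an encoder–decoder network
(SD-ResNet) to map SR-corrupted reconstructions back to the clean
reference.

## Forward model

`srcorrect.wave.simulate_rf` solves the lossless linear wave equation as an
initial-value problem (p(0) = p0, ∂p/∂t(0) = 0) with a first-order coupled
k-space pseudospectral scheme: staggered spectral derivatives, the exact
dispersion correction sinc(c·k·Δt/2), leapfrog time stepping and a
split-field perfectly matched layer (20 cells, quartic profile, absorption
coefficient 2 nepers·c/dx). For a homogeneous medium this scheme is
dispersion-free at all supported wavenumbers, which the arrival-time tests
exploit (leading edges land within two grid cells of the geometric (d−a)/c
prediction). Design points:

- The computational grid auto-expands so the sensor ring sits in the
  interior with an 8-cell margin before the PML; a source overlapping the
  PML is a geometry error.
- The internal time step is Δt = 1/(m·fs) with the smallest integer m
  satisfying the CFL bound 0.3·dx/c, so recorded samples need no
  resampling.
- The source is spectrally smoothed with a Blackman window (as standard for
  pseudospectral PAT solvers) *without* peak restoration — the solver is
  exactly linear in p0, a property the tests check.
- The thermodynamic prefactors (Grüneisen, heat capacity) are folded into
  the arbitrary-unit convention p(t=0) = p0; every later stage is
  scale-invariant under the pairwise normalization.
- Acoustic absorption (0.5 dB/(MHz·cm)) is carried in `Medium` for
  provenance but not modeled in the propagation: its effect at
  centimeter scale is secondary to the SR mismatch being studied, and the
  power-law exponent needed for a faithful implementation is not part of
  the study conditions.
- One k = 0 subtlety: the mean of p0 is a conserved, non-propagating
  offset, so raw channels carry a small DC pedestal. The transducer
  band-pass removes it; tests that look at raw pre-arrival quietness
  subtract the t = 0 channel value first.

Transducers are modeled as a zero-phase Gaussian band-pass whose −6 dB
fractional bandwidth is exact by construction (σ = f0·bw/2 / √(2 ln 2)),
with the DC bin zeroed. White noise is calibrated in amplitude decibels
relative to the *peak* of the clean sinogram (σ = 10^(dB/20)·max|p|);
peak-vs-RMS is a convention choice, documented here because the study
conditions state only "−30 dB".

## Reconstruction

`srcorrect.das.das_reconstruct` is a plain unapodized delay-and-sum with
linear (default) or nearest-neighbor temporal interpolation; delays outside
the recorded window contribute zero, and the reconstruction grid must lie
strictly inside the assumed ring. The vectorized implementation is tested
for exact equality against a triple-loop reference. The biased-radius sweep
`radius_grid` generates the inclusive, integer-indexed grid (23.8–25.8 mm
in 0.2 mm steps at full scale — 11 conditions; the stated ±3.3 % range in
the source material is inconsistent with those millimeter endpoints, and
the explicit grid is taken as authoritative).

## Dataset

Per phantom the RF data are simulated **once**; the noise-free
reconstruction at the true radius is the ground truth, and one degraded
image per sweep radius is reconstructed after adding fresh −30 dB noise
(per-pair seeds derived from the master seed). Pairwise intensity
rescaling maps both members by the GT's 0.5–99.5 percentile interval and
clips to [0, 1]; a constant GT degenerates to two zero images and is
flagged. Splitting is at the phantom level (7:2:1), the only reading
consistent with a test set of (test phantoms) × (radii) images; 480
phantoms split 336/96/48 and 48 × 11 = 528 test images.

Because DAS images are bipolar, the percentile interval places the zero
background near mid-gray (≈ 0.45) rather than at 0 — worth knowing when
interpreting loss values.

The interval can be computed per sampled training patch or per full image
(`norm_scope`). The full-scale preset uses the per-patch convention; the
desk preset uses per-image, because sparse synthetic phantoms frequently
yield nearly-empty patches whose percentile interval is degenerate, which
destabilizes training (dense anatomical slices do not have this problem).

## Synthetic phantoms

Four procedural families emulate the structural variety of anatomical
sources: point/disk/ellipse absorbers (uniform intensity 0.3–1.0),
curvilinear structures (smoothed correlated random walks dilated to 1–4 px),
vascular-like recursive trees with tapering width, and a mixture. Structure
centers are confined to a disk well inside the detection ring so sources
stay inside the reconstruction field of view. Fixed seed ⇒ bit-identical
phantom. What the generator does *not* emulate: tissue-like speckle
backgrounds, smooth intensity gradients, anatomical correlations between
structures, or optical fluence decay with depth — so passing the end-to-end
test demonstrates artifact-correction learning on sparse piecewise-constant
scenes, not clinical-image performance.

## Model

SD-ResNet couples a residual encoder (feature pyramid C2–C5 at strides
4/8/16/32) to a five-stage decoder fed **only by C5**: SR artifacts are
global, spatially correlated distortions, and dropping the C2–C4 skips
keeps the decoder compact. Each decoder stage is a transposed convolution
(kernel 4, stride 2, padding 1 — exact spatial doubling) followed by a 3×3
smoothing convolution with batch norm and ReLU; the smoothing layers
measurably reduce checkerboard (Nyquist) energy in an ablation the tests
run. The head is a linear 3×3 convolution to one channel (the loss operates
on normalized intensities, so no output activation is imposed). Variants:

- `resnet50`: bottleneck blocks [3, 4, 6, 3], C5 width 2048, decoder
  channels 2048→512→256→128→64→32. For a 224×224 3-channel input the
  pyramid is {256×56×56, 512×28×28, 1024×14×14, 2048×7×7} and the decoder
  restores 7→14→28→56→112→224.
- `small`: one basic block per stage, widths 16/32/64/128 (configurable
  base), decoder 128→64→32→16→16→16 — the CPU-scale variant.

Pretrained encoder weights are consumed when a checkpoint path is supplied;
otherwise the model falls back to random (He) initialization with a logged
warning.

All layers are implemented in `srcorrect.nn`, a compact numpy toolkit with
analytic backprop (im2col convolutions; the transposed convolution is the
exact adjoint). Every layer's gradient is verified against central finite
differences in the test suite, and the convolution forward against an
independent library correlation.

## Training

AdamW with decoupled weight decay (default 1e-2); a 5-epoch linear warm-up
from base_lr/warmup to base_lr, then cosine annealing to the final epoch;
an EMA of the weights (decay 0.992, updated per optimizer step) used for
validation inference; encoder batch-norm layers frozen to their running
statistics (small-batch stabilization — gradients still flow to the affine
parameters); gated checkpointing (best raw + EMA weights stored only after
epoch 21, a last-epoch checkpoint always kept); early stop after more than
20 epochs without a relative validation improvement of 1e-4. The loss is
the mean absolute error by default; a mean-squared variant is available
(the source material labels its loss L1 while printing a squared form, so
both are first-class). A NaN loss aborts with a diagnostic.

Unstated hyperparameters were fixed as: base_lr 2e-4, weight decay 1e-2,
batch size 8 for the full-scale preset. The desk preset uses base_lr 2e-3:
with only ~10³ optimizer steps available on one CPU, the conservative rate
leaves the from-scratch network visibly under-converged, while 2e-3 reaches
a clearly better-than-input solution inside the same budget.

## Evaluation protocol

Metrics are PSNR (10·log10(L²/MSE), L = 1), a *global* SSIM computed from
whole-image means/variances/covariance with additive constants C1 = 0.01
and C2 = 0.03 exactly as printed in the source formula (the windowed
scikit-image variant is available behind a flag for comparison, not used in
acceptance), MSE, and the Pearson correlation (constant images are flagged
and scored 0). dB display compresses 20·log10(I/max + 1e-12) into a fixed
[−50, 0] dB window.

Per pair, images are first brought onto the shared GT-percentile scale.
The DAS reconstructions (degraded and GT) are then normalized by their
highest pixel value — the stated display/metric convention for
reconstructed images. The network output already lives on the shared
normalized-intensity scale it was trained to produce, so it is compared
there directly, clipped to [0, 1]: error analysis is only meaningful when
all images of a pair share one scaling, and re-normalizing the output by
its own per-image maximum would let a single under-confident peak rescale
the entire image.

## Problem sizes used by the test suite

The end-to-end study runs at desk scale: 40 phantoms on a 128×128 grid
(0.2 mm pixels), 32 sensors on a 14 mm ring, 2 MHz / 70 % transducers, 512
samples at 25 MHz, the 11-radius sweep scaled proportionally
(ΔR/R = ±1/24.8), reconstruction on 128×128 at 0.14 mm, the small encoder
trained 24 epochs on 64×64 patches (batch 8). These sizes are the package's
chosen CPU-scale study conditions; the full-scale preset (768×768 at 40 µm,
256 sensors at 24.8 mm, 5 MHz, 4500 samples at 50 MHz, ResNet-50, 224×224
patches) is available behind the same interface. Physics checks use their
own geometries: the ring-artifact test uses a 6.5 MHz transducer on an
80 µm grid so the pulse is short relative to the tested ΔR of 0.4–0.8 mm,
and the arrival-time oracle samples at fs = c/dx so its two-sample
tolerance equals two grid cells.

## Known limitations

- The desk-scale network corrects coarse structure and suppresses noise but
  does not restore fine detail: the C5-only bottleneck at 64–128 px inputs
  carries far fewer numbers than pixels (the full-scale architecture does
  not have this deficit — 2048×7×7 exceeds 224² — so the desk results
  understate what the architecture achieves at scale).
- Element directivity, finite aperture, heterogeneous media and
  frequency-dependent absorption are out of scope of the forward model.
- The solver records bilinear-interpolated point samples; real transducers
  integrate over their aperture.
- Reported desk-scale metrics are for sparse synthetic scenes; they are not
  comparable to full-scale results on anatomical data.
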