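# Methods

## Problem and model

The package registers pairs of small grayscale B-mode-like ultrasound images
related by a rigid 2-D motion — three degrees of freedom: a rotation `rot`
(degrees, positive counterclockwise) and translations `dx`, `dy` (pixels).
Instead of iteratively maximizing an image-similarity objective, a compact
CNN regresses the three parameters directly from the two images, and a
bit-accurate fixed-point emulator reproduces what the same network computes
when implemented with integer (Q-format) arithmetic, as on an FPGA.

The fixed image `I_F` and moving image `I_M` (each 32x16x3, intensities
normalized to [0, 1]) are concatenated side by side into a 32x32x3 input,
fixed in columns 0-15, moving in columns 16-31. The network is

    conv 2x2 x 8, stride 1, valid, ReLU   -> (31, 31, 8)    104 parameters
    max-pool 2x2, stride 2                -> (15, 15, 8)
    conv 2x2 x 16, stride 1, valid, ReLU  -> (14, 14, 16)   528 parameters
    max-pool 2x2, stride 2                -> (7, 7, 16)
    flatten                               -> 784
    dropout 0.5 (training only)
    three bias-free linear heads          -> rot, dx, dy    3 x 784 parameters

2984 trainable parameters in total. The per-head parameter count of 784
equals the flatten width, which pins the heads to pure dot products with no
bias; the persistence layer and parameter accounting treat that as
definitional. Convolution means cross-correlation (no kernel flip), the
convention of all mainstream frameworks. Head outputs are raw linear values
on the normalized target scale.

Targets are normalized to [-1, 1] by the generation bounds: the network
regresses `(rot/11, dx/10, dy/10)`. These divisors are the only choice that
maps the draw ranges (below) exactly onto the unit cube, and they are stored
in every weight file so a saved model carries its own denormalization.

## Transform conventions

Transforms are 3x3 homogeneous matrices acting on `(x, y, 1)` column
vectors, `(x, y)` = (column, row), 0-based indices, pixel centers at integer
coordinates. The parameterization is rotate-about-image-center then
translate. Warping uses inverse mapping with bilinear interpolation and
zero fill (black background, the natural choice for B-mode borders).
Bilinear sampling makes integer translations exact and keeps warped values
inside the input's value range.

## Synthetic data generator

The generator stands in for clinical B-mode datasets and emulates their two
dominant statistical features:

- **Anatomy**: a smooth low-frequency field — 3 to 8 random Gaussian blobs
  (mixed bright and dark) over a gentle depth gradient, mimicking
  time-gain-compensated tissue structure.
- **Speckle**: fully developed speckle has a Rayleigh-distributed envelope
  amplitude; the anatomy field is multiplied by unit-mean i.i.d. Rayleigh
  noise, then log-compressed (`log1p(30 x) / log1p(30)`) as display units
  do, and rescaled to [0, 1]. Grayscale is replicated to 3 channels to match
  the network's 3-channel input convention.

Each source phantom (default 96x64) is augmented once with a random
similarity transform — scale uniform in [1.4, 3.2], rotation uniform in
[-25, 25] degrees, translation uniform in [-30, 30] px per axis — and
resized to 32x16 with bilinear anti-aliased resampling (the resampling
kernel is this package's own choice). Each augmented image spawns one
fixed/moving pair, so the full-scale default of 10,230 images yields 10,230
pairs, split 8184/1842/204 into train/val/test. Split counts are train =
round(0.80 n), test = floor(0.02 n), validation = remainder — the rounding
that reproduces both 8184/1842/204 at n = 10,230 and 80/18/2 at n = 100.
Phantom seeds are never shared across splits, so test pairs are unseen
during training.

**Ground truth.** The stored ground truth of a pair is the *registering*
motion (the one that warps moving back onto fixed), drawn uniformly with
`rot` in [-11, 11] degrees and `dx`, `dy` in [-10, 10] px; the moving image
is produced by warping the fixed image with the inverse of that motion.
Drawing the registering motion (rather than the forward motion) keeps every
target inside the stated ranges exactly — the inverse of a
rotation-plus-translation rotates the translation vector, so drawing the
forward motion at the range corners would push the registering translation
to magnitude ~11.7 px, outside the normalization cube.

What the generator does *not* emulate: attenuation and shadowing, speckle
spatial correlation from the point-spread function, probe-dependent fan
geometry, out-of-plane motion, and intensity changes between the two images
of a pair (moving images are resampled versions of fixed, so pairs differ
only by interpolation). Passing tests therefore demonstrate the mechanics
of the method — learnability of the mapping, quantization fidelity, metric
behavior — not clinical registration accuracy.

## Training

Plain numpy throughout: manual backprop mirrored layer-for-layer on the
self-contained forward pass, Adam (beta1 0.9, beta2 0.999, eps 1e-8),
summed per-head MSE loss, batch size 50, Glorot-uniform initialization,
inverted dropout (rate 0.5, one mask on the shared flattened vector).
Per-epoch train and validation losses are recorded per head; with dropout
active the train loss may exceed the val loss, which is expected. One master
seed expands deterministically into independent streams for weight init,
shuffling and dropout, so runs are exactly reproducible.

The reference protocol is 15,000 epochs at learning rate 1e-5. The package's
desk-scale protocol — used by the test suite and the acceptance script — is
2000 training pairs, 500 epochs, learning rate 1e-3. The rationale: Adam's
per-step displacement is approximately the learning rate, so the total
optimization distance scales with lr x steps; 500 epochs x 40 batches at
1e-3 preserves the budget of the reference protocol's ~2.5M steps at 1e-5
within a small factor. `TrainConfig` defaults keep the reference rate
(1e-5); the compact rate is passed explicitly by the desk-scale runs. At
desk scale the trained network reaches R^2 ~ 0.91-0.98 per head against
ground truth on held-out pairs.

## Fixed-point emulation

A Q-format word has `M = I + F` bits, `I` (including sign) above the binary
point; value = two's-complement payload x 2^-F, range
[-2^(I-1), 2^(I-1) - 2^-F]. Defaults: round-to-nearest-even, saturation
(wrap available for hardware-faithfulness experiments, truncation available
to probe worst-case rounding).

**Calibration.** The integer width `I` is chosen per tensor class — input,
each weight/bias tensor, each layer's pre-activation, head weights, outputs
— as the smallest signed width covering the float dynamic range observed on
a calibration batch. The split is shared across word lengths, so a bit-width
sweep varies only the resolution 2^-F. A class whose range cannot fit any
`I < M` raises a configuration error. Rare quantized-path excursions beyond
the calibrated range saturate.

**MAC semantics.** Each convolution / fully connected output element is an
exact integer multiply-accumulate over raw codes in a widened register —
never requantized per term — then a single round + saturate back to the
activation format after bias addition, matching a DSP adder-tree chain.
Exactness at any word length up to 32 bits is implemented by splitting one
operand into 16-bit halves (partial sums provably fit int64 for all layer
sizes here: at most 784 terms of 47-bit products) and recombining in
arbitrary-precision integers for the final requantize. ReLU and max-pooling
act directly on raw codes, where both are exact. The three head outputs are
computed sequentially, mirroring the streaming design's one-at-a-time
output emission; FIFO/handshake machinery is modeled only as this functional
layer order.

If every weight, bias, input and intermediate value is representable in the
word, the quantized pipeline reproduces the float pipeline bit for float
bit — this is tested with a value grid constructed to stay representable
end to end.

**Sweep.** The bit-width study runs the presets fp32 (the float reference),
fxp32, fxp28, fxp20, fxp18, fxp16. All error metrics (MAE/MSE/RMSE/R^2 per
head) compare quantized predictions against the *float model's* predictions,
not ground truth — the emulator's question is "what does the hardware lose",
not "how good is the network". MAE grows close to 4x from the 20-bit to the
18-bit word and ~16x to the 16-bit word (2 and 4 fraction bits dropped),
and is monotone across the sweep. Exact per-format magnitudes depend on the
trained weights and on the unknown rounding/overflow modes of any particular
hardware toolchain, so trends and orders of magnitude, not absolute values,
are the meaningful output.

## Evaluation metrics

MAE, MSE, RMSE and R^2 are the textbook closed forms (R^2 raises on a
zero-variance reference). PSNR = 10 log10(MAX^2 / MSE) dB with MAX = 1 for
the package's normalized floats (MAX = 255 mode available); identical images
report infinity, and mean PSNR over a test set averages the finite values.
SSIM uses the standard parameterization — 11x11 Gaussian window, sigma 1.5,
unit exponents, C1 = (0.01 MAX)^2, C2 = (0.03 MAX)^2 — via scikit-image;
multi-channel images are compared on their channel mean.

The warp-and-compare analysis denormalizes the float and fixed-point
predictions for a pair, warps the moving image with each (I_WS and I_WH),
and reports SSIM, PSNR and the absolute difference map between the two
warped images. A 20-bit prediction difference of ~1e-3 normalized units is
~0.01 px of motion, far below a pixel, so SSIM near 1 and PSNR well above
46 dB are the expected regime.

## Numerical choices and degenerate inputs

- Pooling drops the trailing odd row/column (31 -> 15); pool-gradient ties
  break to the first argmax.
- Angle recovery reports rotations in (-180, 180]; params<->matrix round
  trips are exact to 1e-9 over that range.
- Non-rigid matrices (non-orthonormal upper block, det != +1) are rejected
  by inversion and parameter recovery.
- Quantizing non-finite values, mismatched MAC operand formats, and
  sub-32-px phantom dimensions raise immediately.
- Weight files are zip containers of named float64 tensors plus a JSON
  header recording the parameter count (2984), tensor shapes and
  normalization divisors; loading validates shapes and finiteness.

## Scale of the shipped experiments

The test suite and acceptance script use 2500 pairs (2000/250/250), 500
epochs, and 250-pair evaluation sets; these sizes are the package's
documented desk-scale study conditions and run in minutes on one CPU core.
The full-scale configuration (10,230 pairs, 15,000 epochs) is available
through the same interfaces.

## Known limitations

- The emulator models arithmetic, not timing: no cycle-level FIFO/handshake
  simulation, no resource or latency estimation.
- Quantized activations can saturate if inference inputs exceed the
  calibration batch's dynamic range; calibration batches should be
  representative.
- The synthetic-data caveats above mean absolute regression errors on real
  ultrasound cannot be inferred from these experiments.
- Training is CPU-bound numpy; the full-scale 15,000-epoch protocol is
  supported but slow (hours), which is why the compact protocol exists.
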