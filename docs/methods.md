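# Methods

This note documents the models, numerical choices and validation strategy
behind `ceustic`, and what the synthetic experiments do and do not show
about clinical data.

## Screen geometry and color decoding

A CEUS investigation frame is treated as an 800×525 RGB raster holding the
B-mode panel (x ∈ [0, 400), y ∈ [78, 525)), the contrast panel
(x ∈ [400, 800), same rows) and a 5×70-pixel vertical colorbar at
x ∈ [770, 775), y ∈ [100, 170). All rectangles are half-open `[min, max)`
with x = column, y = row and the origin at the top left; widths are then
exactly `max − min`, and the two panels are congruent, so a lesion mask
drawn in B-mode panel coordinates applies verbatim in contrast panel
coordinates. Coordinates are configurable (YAML or constructor) for other
device layouts. Whether the original acquisition treated the printed
bounds as inclusive or exclusive is unknowable from the values alone; the
half-open convention is a documented choice, not an inference.

The contrast panel encodes scalar enhancement through the device colormap.
The lookup table is always rebuilt from the cropped colorbar of the video
being analysed, never hard-coded: strip rows are averaged to one RGB entry
each, assigned intensities linearly from 255 (top) to 0 (bottom), and
adjacent duplicate colors are collapsed keeping the brighter assignment.
Masked pixels are decoded by nearest LUT color (Euclidean distance in RGB,
ties to the lower index, i.e. the brighter entry). Decoding through the
colorbar rather than converting the colormapped image to grayscale is the
reading that makes the colorbar crop purposeful; with a 70-row bar the
quantisation step is 255/69 ≈ 3.7 intensity units, which bounds the
decoding error of a noiseless round trip.

## TIC extraction

* **Parenchyma reference.** The lesion mask is dilated with an all-true
  10×10 structuring element anchored at (5, 5) — dilation implemented
  directly as the union of mask translates over the active kernel cells,
  clipped at the grid — and the parenchyma ring is `dilated AND NOT mask`.
  Ring and mask partition the dilated mask by construction.
* **Sampling.** One sample per second, taken from the first frame with
  timestamp ≥ that second. A sample is accepted if it is the first, or if
  it differs from the previously *accepted* value by strictly less than
  75% of that value; otherwise later frames within the same second are
  tried and the second is recorded invalid if none qualifies. Anchoring
  the rule to the last accepted value (rather than the last observed one)
  prevents a single dark frame from permanently poisoning the reference.
  A previous value of exactly 0 accepts anything, since no finite change
  can be expressed relative to zero. The parenchyma intensity is taken
  from the same accepted frame as the lesion so the two series stay
  time-aligned. Note the rule is stateful: monotonicity of the accepted
  count in the threshold holds on slowly-varying curves with dropout
  transients (and is tested there) but not for arbitrary series.
* **Smoothing.** Savitzky–Golay, window 51, polynomial order 3, applied to
  both series with invalid gaps linearly interpolated first and re-flagged
  afterwards; boundaries are handled by fitting the filter polynomial to
  the terminal windows, which keeps polynomials of degree ≤ 3 exactly
  invariant. For curves with fewer valid samples than the window, the
  window shrinks to the largest odd number ≤ the valid count (minimum 5).
* **Parameters.** Maximum intensity and TTP are read off the smoothed
  lesion series (earliest sample on ties); AUC is the trapezoidal
  integral over valid samples without baseline subtraction (intensities
  are raw panel means, so the baseline is part of the signal); MTT has no
  single standard definition in this setting, and the first temporal
  moment of the baseline-shifted curve, `Σ t·(I−I_min) / Σ (I−I_min)`, is
  adopted over the alternatives (AUC/peak, FWHM) because it is defined for
  any non-flat sampled curve without model fitting. Flat curves yield NaN
  with a warning. No bolus-model fitting is performed anywhere — the
  parameters are read from the smoothed curve.

## Segmentation backends

Two interchangeable providers satisfy one contract (B-mode panel + frame
index → binary 256×256 mask): stored ground truth, the primary backend for
validating the curve machinery, and a trainable U-Net — 4 levels, base 16
channels, 3×3 convolutions with ReLU, 2×2 max pooling, nearest-neighbour
upsampling with skip concatenation, 1×1 sigmoid head, threshold 0.5.
Panels are resized to 256×256 for inference and masks resized back with
nearest-neighbour interpolation to preserve binarity. Training uses
Dice + binary-cross-entropy loss with Adam at 10⁻³ and batch size 2 (the
batch chosen for single-CPU cache behaviour), optional early stopping on
validation Dice. The network and its backpropagation run on a small
float32 numpy engine (`ceustic/_nn.py`); convolutions are a single GEMM
over an im2col patch matrix. On the easy phantom task (high-contrast
ellipse over smoothed speckle) it converges to held-out Dice ≈ 0.97 in
about 3 epochs; nothing about clinical segmentation difficulty follows
from this — the U-Net here validates the training loop and the backend
interchangeability of the pipeline, not clinical performance.

## Classifier and training protocol

The classifier is a dense network 8→8→6→6→5 over the 8 features (the
first "input layer" is itself trainable, which is what makes the count
72 + 54 + 42 + 35 = 203). Focal cross-entropy uses α = 0.25, γ = 2, with
the true-class probability clipped at 10⁻⁷ before the log. Training:
stratified 70/30 split first, z-score standardisation with training-split
statistics (raw scales differ by orders of magnitude: age in years vs AUC
in intensity-seconds), then oversampling of the training split only —
duplicating random minority-class rows until all classes match the
majority count — then RMSProp (lr 10⁻⁴, ρ = 0.9, ε = 10⁻⁷) for 100 epochs
at batch 50. Splitting before oversampling avoids duplicated rows leaking
into validation. Weights are Glorot-uniform initialised (the default of
the dense layers in mainstream frameworks); biases start at zero.

A property of this exact protocol worth knowing: at n = 1000 with
strongly separated classes it stops mid-convergence. Validation accuracy
at epoch 100 depends on the initial weight draw (observed range roughly
0.55–0.99 across seeds; the same runs reach 1.000 by epoch ~200–300).
The acceptance experiment therefore pins the package default seed; under
it the protocol reaches ≈ 0.95 validation accuracy on the separable table.
On a zero-signal table the balanced (oversampled) training drives the
network toward near-uniform predictions, so validation accuracy lands
near 1/5 — the meaningful null check is that it cannot *exceed* the best
constant guess (the majority-class proportion, 40.67%) beyond binomial
sampling error.

## The phantom generator

The generator emulates the features of a CEUS recording that the pipeline
actually exercises:

* **Perfusion.** Lesion and parenchyma enhancement follow gamma-variate
  bolus curves `I(t) = b + A τ^α e^{α(1−τ)}`, `τ = (t−t₀)/β`, the standard
  parametric bolus-transit model; its closed-form peak (`b + A` at
  `t₀ + β`) gives recovery tests exact truth. Defaults emulate liver
  CEUS: lesion A = 120, t₀ = 15 s, α = 2, β = 30 s, baseline 20, pixel
  noise σ = 4 (≈ 3% of amplitude); parenchyma enhances later and less
  (A = 70, t₀ = 20 s, β = 45 s). These broad kinetics matter: a
  window-51 Savitzky–Golay filter at 1 Hz preserves a β = 30 s peak to
  well under 2% but flattens a hypothetical β = 8 s spike by ~30%, so
  narrow-bolus recovery through the full smoothing chain is not a
  meaningful target.
* **Geometry and motion.** An elliptical lesion (default semi-axes
  45×30 px) drifts slowly and oscillates vertically with breathing
  (3 px, 4 s period); the configuration validates that the ellipse stays
  inside the B-mode panel for the whole recording.
* **Probe lifts.** Configurable intervals during which both panels are
  scaled to 2% brightness (the colorbar, a screen overlay, is unaffected).
  This exercises the 75% rule in both directions — the drop is rejected
  and, provided the lift sits in a slowly-varying part of the curve,
  the recovery is accepted. During steep wash-in, a long lift can
  legitimately lock the rule out, a property of the rule itself.
* **Colormap.** ≥ 8 control colors with monotone channels, interpolated
  to 256 levels, so the rendered ramp never folds back in RGB space and
  nearest-color decoding is well-posed.
* **Patient tables.** Five lesion classes at proportions
  (0.4067, 0.15, 0.15, 0.15, 0.1433) — hepatocellular carcinoma dominant.
  The four TIC features are class-conditional Gaussians whose means are
  pulled apart by a configurable `separation` (in within-class SDs);
  age and cirrhosis prevalence also carry class signal (older, cirrhotic
  patients for HCC; younger for hemangioma), saturating at separation 2
  and vanishing at 0. `separation=0` is an exact no-signal null;
  `separation=6` is the "cleanly separable" acceptance setting.

What the phantoms do **not** model: speckle statistics, attenuation,
shadowing, microbubble acoustics, out-of-plane motion, multi-lesion
frames, or realistic lesion texture. Passing tests therefore demonstrate
the correctness of the extraction and training machinery under known
truth, not clinical accuracy.

## Problem sizes and degenerate inputs

Test and acceptance experiments use: 180-second phantoms at 1–2 fps,
20 phantoms for parameter recovery, 64 training + 12 held-out frames for
the segmentation network, and n = 1000 patient tables. Degenerate inputs
are handled explicitly: empty masks raise a distinct `EmptyMaskError`
(the sampler skips such frames); flat curves give NaN MTT with a warning;
0/0 per-class ratios in macro averages and a zero MCC denominator are
defined as 0 with warnings; a constant colorbar strip is rejected because
no monotone LUT exists.

## Known limitations

* One lesion per video; multi-lesion investigations would need one mask
  provider run per lesion.
* Video containers requiring ffmpeg are not decoded in a minimal install;
  PNG-frame directories (with a JSON sidecar for the frame rate) and
  multi-page TIFF are the supported interchange formats.
* The classifier's reported metrics on synthetic tables say nothing about
  clinical discrimination; they validate the protocol plumbing
  (imbalance handling, loss, optimisation, evaluation) only.
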