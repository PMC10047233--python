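# ceustic

Automated **time-intensity-curve (TIC) extraction and lesion classification
for contrast-enhanced ultrasound (CEUS) liver investigations**.

In CEUS, a microbubble contrast agent is injected intravenously and the
liver is imaged in a dedicated low-mechanical-index panel next to the
conventional B-mode image. The enhancement of a focal lesion over time —
its time-intensity curve — carries diagnostic information: hepatocellular
carcinoma, metastases and benign lesions wash in and out differently.
Extracting TICs by hand is slow and error-prone; this package automates the
whole chain and is aimed at gastroenterology researchers and students who
want either the curves themselves or a five-class lesion prediction.

## The method

Three modules compose the pipeline:

1. **Segmentation** — a per-frame lesion mask for the B-mode panel
   (256×256, strictly binary), either from stored ground truth or from a
   small trainable U-Net (4-level encoder/decoder, base 16 channels).
2. **TIC extraction** — the mask `A` is dilated with an all-true 10×10
   structuring element `K`,

   `A ⊕ K = ⋃_{k∈K} A_k`,

   and the ring `dilated ∖ A` represents the parenchyma surrounding the
   lesion. Both masks are carried to the contrast panel; each masked
   pixel's color is decoded to a scalar 0–255 intensity through a lookup
   table built from the device colorbar strip. Intensities are sampled at
   1 Hz; a sample is valid only if it changed by less than 75% of the
   previously accepted value (which rejects probe-lift dropouts). After
   Savitzky–Golay smoothing (window 51, polynomial order 3) four
   parameters are read off the lesion curve: maximum intensity, time to
   peak (TTP), area under the curve (AUC), and mean transit time (MTT).
3. **Classification** — a feed-forward network (8→8→6→6→5, ReLU hidden
   layers, softmax output, **203 trainable parameters**) over 8 features
   (gender, age, cirrhosis history, hepatitis history + the four TIC
   parameters), trained with focal cross-entropy
   `FCE = −α (1−p_t)^γ log p_t` (α = 0.25, γ = 2), RMSProp (lr 10⁻⁴),
   batch 50, 100 epochs, with a stratified 70/30 split and oversampling of
   minority classes in the training split.

Evaluation uses categorical accuracy, micro/macro F1 and the multiclass
Matthews correlation coefficient
`MCC = (cS − Σᵢ pᵢtᵢ) / √((S² − Σᵢ pᵢ²)(S² − Σᵢ tᵢ²))`.

Clinical CEUS recordings are not redistributable, so the package ships a
**phantom generator**: two-panel frames at the real device geometry, an
elliptical lesion whose enhancement follows a gamma-variate bolus curve
(peak `b + A` at `t₀ + β`, closed form), probe drift + breathing motion,
probe-lift dropouts, and a rendered colorbar — every downstream stage is
validated against this exact ground truth.

## Worked example

```python
from ceustic.frame_io import DEFAULT_REGIONS
from ceustic.segmentation import GroundTruthMaskProvider
from ceustic.synthetic import PhantomConfig, render_phantom
from ceustic.tic import extract_params, sample_tic, smooth_tic

config = PhantomConfig(duration=180.0, frame_rate=1.0, seed=7)
phantom = render_phantom(config)
provider = GroundTruthMaskProvider(phantom.masks, DEFAULT_REGIONS["b_mode"])
params = extract_params(smooth_tic(sample_tic(phantom.frames, provider)))
print(params)
```

prints (see `examples/02_extract_tic.py`):

```
valid seconds: 181/181
maximum intensity:  138.3  (truth 140; deviation is colormap quantisation + filter bias)
time to peak:        46.0 s (truth 45 s)
area under curve:   10208 intensity*s
mean transit time:   65.7 s (first moment of the baseline-shifted curve)
```

The phantom's true peak is 140 intensity units at 45 s; the extracted
maximum (138.3 at 46 s) recovers it to ~1% / 1 s, the residual being
colorbar quantisation plus smoothing bias. The `examples/` directory has
one short script per capability (simulation, TIC extraction, classifier
training, U-Net training, end-to-end prediction); a thin CLI mirrors the
workflows (`ceustic simulate|predict|build-dataset|train|evaluate`).

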