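"""Synthetic CEUS phantoms with known ground truth.

Clinical CEUS recordings are rarely shareable, so every downstream stage of
the pipeline is exercised against phantoms generated here: two-panel video
frames at the real device geometry, an elliptical lesion whose contrast
enhancement follows a gamma-variate bolus curve, slow probe drift plus
periodic breathing motion, optional probe-lift dropouts (near-black
panels), a rendered device colorbar, and class-structured patient feature
tables.

The gamma-variate is the standard parametric model for an intravenous
bolus transit,

    I(t) = b                                          for t <= t0
    I(t) = b + A * tau**alpha * exp(alpha * (1 - tau)) for t >  t0,

with ``tau = (t - t0) / beta``.  Its peak has the closed form location
``t0 + beta`` and height ``b + A``, which gives every recovery test an
exact truth value.  Default kinetics emulate liver CEUS: contrast arrival
~15 s after injection, lesion wash-in peaking ~45 s, wash-out over a few
minutes, with surrounding parenchyma enhancing later and less.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import gaussian_filter

from .frame_io import DEFAULT_REGIONS, FrameSequence, RegionSpec, write_mask_png

__all__ = [
    "PerfusionSpec",
    "PhantomConfig",
    "Phantom",
    "gamma_variate",
    "render_phantom",
    "write_phantom",
    "generate_patient_table",
    "segmentation_training_set",
    "DEFAULT_COLORMAP",
    "DEFAULT_CLASS_PROPORTIONS",
    "FEATURE_COLUMNS",
    "LABEL_COLUMNS",
    "build_colormap",
]

#: Device-style contrast colormap control points, dark to bright.  All three
#: channels are monotone non-decreasing so the rendered color ramp never
#: folds back on itself and nearest-color decoding is well-posed.
DEFAULT_COLORMAP: tuple[tuple[int, int, int], ...] = (
    (0, 0, 0),
    (20, 10, 8),
    (60, 25, 16),
    (110, 45, 24),
    (160, 80, 40),
    (205, 130, 60),
    (235, 185, 90),
    (255, 255, 170),
)

#: Feature columns of the clinical + TIC table, in canonical order.
FEATURE_COLUMNS = (
    "Gender",
    "Age",
    "Cirrhosis History",
    "Hepatitis History",
    "Maximum Intensity",
    "Area Under the Curve",
    "Mean Transit Time",
    "Time to Peak",
)

#: One-hot label columns (three malignant, two benign lesion classes).
LABEL_COLUMNS = (
    "Hepatocarcinoma",
    "Metastasis",
    "Other malignant lesions",
    "Hemangioma",
    "Other benign lesions",
)

#: Default class mix: hepatocellular carcinoma dominates at 40.67%, the
#: remainder spread over the other four classes.
DEFAULT_CLASS_PROPORTIONS = (0.4067, 0.15, 0.15, 0.15, 0.1433)


@dataclass(frozen=True)
class PerfusionSpec:
    """Parameters of one gamma-variate enhancement curve.

    amplitude : peak enhancement above baseline, 0-255 intensity units
    onset     : contrast arrival time t0, seconds
    alpha     : dimensionless shape (> 0); larger = steeper wash-in
    beta      : time scale, seconds (> 0); the peak sits at onset + beta
    baseline  : pre-contrast intensity, >= 0
    sigma     : per-pixel Gaussian noise SD added at render time, >= 0
    """

    amplitude: float
    onset: float
    alpha: float
    beta: float
    baseline: float = 0.0
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError(f"alpha and beta must be positive, got {self.alpha}, {self.beta}")
        if self.baseline < 0 or self.sigma < 0 or self.amplitude < 0:
            raise ValueError("amplitude, baseline and sigma must be non-negative")

    @property
    def peak_time(self) -> float:
        """Closed-form time of the noiseless peak."""
        return self.onset + self.beta

    @property
    def peak_value(self) -> float:
        """Closed-form height of the noiseless peak."""
        return self.baseline + self.amplitude


def gamma_variate(t, spec: PerfusionSpec):
    """Evaluate the noiseless gamma-variate curve at time(s) ``t`` (seconds)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    tau = np.clip((t - spec.onset) / spec.beta, 0.0, None)
    out = spec.baseline + spec.amplitude * tau**spec.alpha * np.exp(spec.alpha * (1.0 - tau))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class PhantomConfig:
    """Everything needed to render one phantom investigation."""

    width: int = 800
    height: int = 525
    frame_rate: float = 2.0
    duration: float = 180.0
    lesion_center: tuple[float, float] = (200.0, 280.0)  # (x, y) full-frame px
    lesion_axes: tuple[float, float] = (45.0, 30.0)      # (semi-x, semi-y) px
    drift: tuple[float, float] = (0.08, 0.04)            # px/s
    breathing_amplitude: float = 3.0                      # px, vertical
    breathing_period: float = 4.0                         # s
    lesion: PerfusionSpec = PerfusionSpec(120.0, 15.0, 2.0, 30.0, 20.0, 4.0)
    parenchyma: PerfusionSpec = PerfusionSpec(70.0, 20.0, 2.0, 45.0, 15.0, 4.0)
    probe_lift: tuple[tuple[float, float], ...] = ()
    colormap: tuple[tuple[int, int, int], ...] = DEFAULT_COLORMAP
    seed: int = 0
    regions: dict = field(default_factory=lambda: dict(DEFAULT_REGIONS))

    def __post_init__(self) -> None:
        if len(self.colormap) < 8:
            raise ValueError("colormap needs at least 8 control colors")
        if self.duration <= 0 or self.frame_rate <= 0:
            raise ValueError("duration and frame_rate must be positive")
        cbar = self.regions["colorbar"]
        if cbar.x_max > self.width or cbar.y_max > self.height:
            raise ValueError("colorbar rectangle outside frame bounds")
        lifts = sorted(self.probe_lift)
        for (s0, e0), (s1, _) in zip(lifts, lifts[1:]):
            if s1 < e0:
                raise ValueError("probe-lift intervals must be disjoint")
        for s, e in lifts:
            if not (0 <= s < e <= self.duration):
                raise ValueError("probe-lift intervals must lie within [0, duration]")
        self._check_lesion_inside()

    def _check_lesion_inside(self) -> None:
        b = self.regions["b_mode"]
        cx, cy = self.lesion_center
        ax, ay = self.lesion_axes
        dx, dy = self.drift
        T = self.duration
        xs = [cx, cx + dx * T]
        ys = [cy, cy + dy * T]
        for x in xs:
            if not (b.x_min + ax <= x <= b.x_max - ax):
                raise ValueError("lesion ellipse leaves the B-mode panel horizontally")
        for y in ys:
            lo = y - self.breathing_amplitude
            hi = y + self.breathing_amplitude
            if not (b.y_min + ay <= lo and hi <= b.y_max - ay):
                raise ValueError("lesion ellipse leaves the B-mode panel vertically")

    def lesion_center_at(self, t: float) -> tuple[float, float]:
        """Lesion center (x, y) in full-frame coordinates at time ``t``."""
        cx, cy = self.lesion_center
        x = cx + self.drift[0] * t
        y = (
            cy
            + self.drift[1] * t
            + self.breathing_amplitude * np.sin(2.0 * np.pi * t / self.breathing_period)
        )
        return (x, y)

    def in_probe_lift(self, t: float) -> bool:
        return any(s <= t <= e for s, e in self.probe_lift)


@dataclass
class Phantom:
    """A rendered phantom: frames, per-frame truth masks, truth curves."""

    frames: FrameSequence
    masks: np.ndarray              # (n, height, width) bool, full-frame coords
    lesion_truth: np.ndarray       # noiseless lesion intensity per frame
    parenchyma_truth: np.ndarray   # noiseless parenchyma intensity per frame
    config: PhantomConfig


def build_colormap(control_colors: Sequence[Sequence[int]], levels: int = 256) -> np.ndarray:
    """Interpolate control colors to a ``levels``-entry uint8 colormap."""
    ctrl = np.asarray(control_colors, dtype=float)
    x = np.linspace(0.0, 1.0, levels)
    xp = np.linspace(0.0, 1.0, len(ctrl))
    cmap = np.stack([np.interp(x, xp, ctrl[:, c]) for c in range(3)], axis=1)
    return np.round(cmap).astype(np.uint8)


def _ellipse_mask(shape: tuple[int, int], center_xy: tuple[float, float],
                  axes_xy: tuple[float, float]) -> np.ndarray:
    rows = np.arange(shape[0])[:, None]
    cols = np.arange(shape[1])[None, :]
    cx, cy = center_xy
    ax, ay = axes_xy
    return ((cols - cx) / ax) ** 2 + ((rows - cy) / ay) ** 2 <= 1.0


def render_phantom(config: PhantomConfig) -> Phantom:
    """Render a phantom investigation frame-by-frame.

    Every frame contains a B-mode panel (smoothed speckle texture with a
    brighter lesion ellipse), a contrast panel whose pixels encode the
    lesion / parenchyma gamma-variate intensities through the colormap, and
    the vertical colorbar strip (bright at the top, dark at the bottom).
    Frames inside probe-lift intervals have both panels scaled to 2% of
    their brightness; the colorbar is a rendered screen overlay and is not
    affected.  Identical configs (same seed) give identical pixel output.
    """
    rng = np.random.default_rng(config.seed)
    n_frames = int(np.floor(config.duration * config.frame_rate)) + 1
    b = config.regions["b_mode"]
    c = config.regions["contrast"]
    cbar = config.regions["colorbar"]
    cmap = build_colormap(config.colormap)

    # Static B-mode speckle texture, smoothed so the lesion is the only
    # sharp structure (the "easy" setting for segmentation training).
    speckle = rng.uniform(25, 105, size=b.shape)
    speckle = gaussian_filter(speckle, sigma=2.0)

    # Colorbar strip: linear intensity ramp, 255 at the top row.
    bar_levels = np.round(np.linspace(255, 0, cbar.height)).astype(int)
    bar = np.repeat(cmap[bar_levels][:, None, :], cbar.width, axis=1)

    frames = np.zeros((n_frames, config.height, config.width, 3), dtype=np.uint8)
    masks = np.zeros((n_frames, config.height, config.width), dtype=bool)
    times = np.arange(n_frames) / config.frame_rate
    lesion_truth = gamma_variate(times, config.lesion)
    par_truth = gamma_variate(times, config.parenchyma)

    for i, t in enumerate(times):
        center = config.lesion_center_at(t)
        full_mask = np.zeros((config.height, config.width), dtype=bool)
        ell = _ellipse_mask(b.shape, (center[0] - b.x_min, center[1] - b.y_min),
                            config.lesion_axes)
        full_mask[b.y_min:b.y_max, b.x_min:b.x_max] = ell
        masks[i] = full_mask

        # B-mode panel: speckle + brighter lesion.
        bpanel = speckle.copy()
        bpanel[ell] += 80.0
        bpanel = np.clip(bpanel, 0, 255)

        # Contrast panel: parenchyma field with the lesion ellipse on top,
        # both intensity-encoded through the colormap.
        field_i = np.full(c.shape, par_truth[i], dtype=float)
        if config.parenchyma.sigma > 0:
            field_i += rng.normal(0.0, config.parenchyma.sigma, size=c.shape)
        lesion_vals = np.full(int(ell.sum()), lesion_truth[i])
        if config.lesion.sigma > 0:
            lesion_vals = lesion_vals + rng.normal(0.0, config.lesion.sigma, size=lesion_vals.shape)
        field_i[ell] = lesion_vals
        idx = np.clip(np.round(field_i), 0, 255).astype(np.intp)

        if config.in_probe_lift(t):
            bpanel *= 0.02
            idx = np.clip(np.round(field_i * 0.02), 0, 255).astype(np.intp)

        frame = np.zeros((config.height, config.width, 3), dtype=np.uint8)
        frame[b.y_min:b.y_max, b.x_min:b.x_max] = bpanel.astype(np.uint8)[..., None]
        frame[c.y_min:c.y_max, c.x_min:c.x_max] = cmap[idx]
        frame[cbar.y_min:cbar.y_max, cbar.x_min:cbar.x_max] = bar
        frames[i] = frame

    return Phantom(
        frames=FrameSequence(frames, config.frame_rate),
        masks=masks,
        lesion_truth=lesion_truth,
        parenchyma_truth=par_truth,
        config=config,
    )


def write_phantom(phantom: Phantom, out_dir: str | Path) -> Path:
    """Write a phantom as numbered PNG frames, truth-mask PNGs and a JSON sidecar."""
    out = Path(out_dir)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    for i in range(len(phantom.frames)):
        iio.imwrite(out / f"frame_{i:04d}.png", phantom.frames[i])
        write_mask_png(phantom.masks[i], out / "masks" / f"mask_{i:04d}.png")
    cfg = phantom.config
    sidecar = {
        "frame_rate": cfg.frame_rate,
        "duration": cfg.duration,
        "seed": cfg.seed,
        "probe_lift": [list(iv) for iv in cfg.probe_lift],
        "lesion": asdict(cfg.lesion),
        "parenchyma": asdict(cfg.parenchyma),
        "lesion_center": list(cfg.lesion_center),
        "lesion_axes": list(cfg.lesion_axes),
    }
    (out / "phantom.json").write_text(json.dumps(sidecar, indent=2))
    return out


# ---------------------------------------------------------------------------
# Patient tables

# Class-conditional mean offsets (rows: classes, cols: the four TIC
# features) in within-class SD units, scaled by the requested separation.
_CLASS_OFFSETS = np.array(
    [
        [-1.0, -1.0, -1.0, -1.0],
        [-1.0, 1.0, 1.0, -1.0],
        [1.0, -1.0, 1.0, -1.0],
        [1.0, 1.0, -1.0, 1.0],
        [0.0, 0.0, 1.0, 1.0],
    ]
)

# Realistic-scale base values and within-class SDs for
# (max intensity, AUC, MTT, TTP).
_TIC_BASE = np.array([120.0, 9000.0, 55.0, 45.0])
_TIC_SCALE = np.array([15.0, 1200.0, 8.0, 6.0])

# Clinical covariates also carry class signal in real cohorts: HCC arises
# predominantly in older, cirrhotic livers while hemangiomas skew younger.
# Age offsets are in years; cirrhosis probabilities are per class.  Both
# effects scale with the separation setting (saturating at separation 2)
# and vanish entirely at separation 0.
_AGE_OFFSET = np.array([8.0, 3.0, 5.0, -12.0, -6.0])
_CIRRHOSIS_P = np.array([0.95, 0.55, 0.7, 0.25, 0.35])


def generate_patient_table(
    n: int,
    class_proportions: Sequence[float] = DEFAULT_CLASS_PROPORTIONS,
    separation: float = 2.0,
    seed: int = 0,
):
    """Generate a class-structured patient feature table.

    Each record carries the 8 canonical features (gender 1=male / 2=female,
    age in years, cirrhosis and hepatitis history as 0/1, and the four TIC
    parameters) plus 5 one-hot lesion-class labels.  The four TIC features
    are drawn from class-conditional Gaussians whose means are pulled apart
    by ``separation`` within-class SDs, so ``separation=0`` is a no-signal
    null and large values give a cleanly separable table.

    Returns a pandas DataFrame with ``FEATURE_COLUMNS + LABEL_COLUMNS``.
    """
    import pandas as pd

    props = np.asarray(class_proportions, dtype=float)
    if props.shape != (5,) or np.any(props < 0) or abs(props.sum() - 1.0) > 1e-8:
        raise ValueError("class_proportions must be 5 non-negative values summing to 1")
    if n < 5:
        raise ValueError("need n >= 5")
    if np.any(props == 1.0):
        warnings.warn(
            "degenerate single-class table; stratified splitting downstream will fail",
            stacklevel=2,
        )

    rng = np.random.default_rng(seed)
    labels = rng.choice(5, size=n, p=props)
    gender = rng.choice([1, 2], size=n, p=[0.63, 0.37])
    effect = min(separation, 2.0) / 2.0
    age = np.clip(
        np.round(rng.normal(66.0 + effect * _AGE_OFFSET[labels], 10.0)), 18, 95
    )
    p_cirr = 0.8 + (_CIRRHOSIS_P[labels] - 0.8) * effect
    cirrhosis = (rng.random(n) < p_cirr).astype(int)
    hepatitis = ((rng.random(n) < 0.2) & (cirrhosis == 0)).astype(int)

    means = _TIC_BASE + separation * _CLASS_OFFSETS[labels] * _TIC_SCALE
    tic = rng.normal(means, _TIC_SCALE)
    tic[:, 0] = np.clip(tic[:, 0], 0, 255)
    tic[:, 1:] = np.clip(tic[:, 1:], 0, None)

    data = {
        "Gender": gender,
        "Age": age.astype(int),
        "Cirrhosis History": cirrhosis,
        "Hepatitis History": hepatitis,
        "Maximum Intensity": tic[:, 0],
        "Area Under the Curve": tic[:, 1],
        "Mean Transit Time": tic[:, 2],
        "Time to Peak": tic[:, 3],
    }
    df = pd.DataFrame(data, columns=list(FEATURE_COLUMNS))
    for k, name in enumerate(LABEL_COLUMNS):
        df[name] = (labels == k).astype(int)
    return df


def segmentation_training_set(
    n_frames: int = 64, seed: int = 0, image_size: int = 256
) -> tuple[np.ndarray, np.ndarray]:
    """Build (images, masks) pairs for desk-scale segmentation training.

    Frames are B-mode panels sampled from several short phantoms with
    varying lesion geometry, resized to ``image_size`` and normalised to
    [0, 1]; masks are the matching ground-truth ellipses.  The lesion is
    high-contrast against the smoothed speckle, i.e. an intentionally easy
    segmentation task used to validate the training loop rather than to
    emulate clinical difficulty.
    """
    from skimage.transform import resize

    rng = np.random.default_rng(seed)
    b = DEFAULT_REGIONS["b_mode"]
    images = np.empty((n_frames, image_size, image_size), dtype=np.float32)
    masks = np.empty((n_frames, image_size, image_size), dtype=bool)
    frames_per_phantom = 8
    i = 0
    while i < n_frames:
        cfg = PhantomConfig(
            duration=float(frames_per_phantom - 1),
            frame_rate=1.0,
            lesion_center=(
                float(rng.uniform(120, 280)),
                float(rng.uniform(200, 380)),
            ),
            lesion_axes=(float(rng.uniform(30, 60)), float(rng.uniform(22, 45))),
            drift=(float(rng.uniform(-0.5, 0.5)), float(rng.uniform(-0.5, 0.5))),
            seed=int(rng.integers(2**31 - 1)),
        )
        ph = render_phantom(cfg)
        take = min(frames_per_phantom, n_frames - i)
        for j in range(take):
            panel = ph.frames[j][b.y_min:b.y_max, b.x_min:b.x_max, 0]
            mask = ph.masks[j][b.y_min:b.y_max, b.x_min:b.x_max]
            images[i] = resize(
                panel.astype(np.float32) / 255.0, (image_size, image_size),
                preserve_range=True, anti_aliasing=True,
            )
            masks[i] = resize(mask, (image_size, image_size), order=0,
                              preserve_range=True, anti_aliasing=False) > 0.5
            i += 1
    return images, masks
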