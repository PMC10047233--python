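"""Time-intensity-curve extraction from masked contrast panels.

Given per-frame lesion masks and the contrast-mode panel, this module
produces the lesion and surrounding-parenchyma intensity series and the
four scalar perfusion parameters used for classification.

The processing chain mirrors the acquisition protocol of the automated
CEUS pipeline:

1. the lesion mask is morphologically dilated with an all-true 10x10
   structuring element (``A ⊕ K = ∪_{k∈K} A_k``, the union of translates);
2. the parenchyma ring is the set difference ``dilated AND NOT mask``;
3. both masks are carried to the contrast panel (same panel-local
   coordinates) and each masked pixel's color is decoded to a scalar
   0-255 intensity through a lookup table built from the device colorbar
   (nearest RGB color, Euclidean metric);
4. intensities are sampled at 1 Hz; a sample is valid only if it changed
   by less than 75% relative to the previously accepted value, which
   rejects probe-lift dropouts — otherwise later frames within the same
   second are tried and the second is marked invalid if none qualifies;
5. the curve is smoothed with a Savitzky-Golay filter (window 51,
   polynomial order 3; window shrinks to the largest odd number <= the
   number of valid samples for short curves, minimum 5);
6. maximum intensity, time to peak (TTP), area under the curve (AUC,
   trapezoidal) and mean transit time (MTT, the first temporal moment of
   the baseline-shifted curve) are read off the smoothed lesion series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .frame_io import DEFAULT_REGIONS, FrameSequence, RegionSpec, crop_region
from .segmentation import MaskProvider, predict_mask, resize_mask

__all__ = [
    "BinaryMask",
    "StructuringElement",
    "ColorLUT",
    "TimeIntensityCurve",
    "TICParams",
    "EmptyMaskError",
    "dilate",
    "parenchyma_ring",
    "build_lut",
    "mean_intensity",
    "accept_sample",
    "sample_tic",
    "smooth_tic",
    "extract_params",
    "write_tic_csv",
    "read_tic_csv",
]

# Coordinate-frame tags for masks.
FRAME_MODEL = "model_256"
FRAME_B_MODE = "b_mode_panel"
FRAME_CONTRAST = "contrast_panel"


class EmptyMaskError(ValueError):
    """Raised when an intensity is requested over a mask with no pixels."""


@dataclass
class BinaryMask:
    """A 2-D boolean grid tagged with the coordinate frame it lives in."""

    data: np.ndarray
    frame: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.dtype != bool:
            uniq = np.unique(self.data)
            if not np.isin(uniq, [0, 1]).all():
                raise ValueError("mask must be strictly binary")
            self.data = self.data.astype(bool)
        if not self.frame:
            raise ValueError("mask frame tag must be set")

    @property
    def area(self) -> int:
        return int(self.data.sum())


@dataclass(frozen=True)
class StructuringElement:
    """Dilation kernel: a boolean grid plus the anchor cell."""

    data: np.ndarray
    anchor: tuple[int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "data", np.asarray(self.data, dtype=bool))
        if self.data.sum() == 0:
            raise ValueError("structuring element must have at least one active cell")

    @classmethod
    def square(cls, size: int = 10) -> "StructuringElement":
        """All-true ``size x size`` kernel anchored at (size//2, size//2)."""
        return cls(np.ones((size, size), dtype=bool), (size // 2, size // 2))


def _shift_or(dst: np.ndarray, src: np.ndarray, dr: int, dc: int) -> None:
    """dst |= src translated by (dr, dc), clipped to the grid."""
    h, w = src.shape
    r0, r1 = max(dr, 0), min(h + dr, h)
    c0, c1 = max(dc, 0), min(w + dc, w)
    if r0 >= r1 or c0 >= c1:
        return
    dst[r0:r1, c0:c1] |= src[r0 - dr:r1 - dr, c0 - dc:c1 - dc]


def dilate(mask: BinaryMask, kernel: StructuringElement | int = 10) -> BinaryMask:
    """Morphological dilation: the union of mask translates over the kernel.

    For every active kernel cell ``k`` the mask is translated by the offset
    of ``k`` from the anchor and the translates are OR-ed together (clipped
    at the grid boundary), so the output always contains the input as long
    as the anchor cell is active.
    """
    if isinstance(kernel, int):
        kernel = StructuringElement.square(kernel)
    src = mask.data
    out = np.zeros_like(src)
    ar, ac = kernel.anchor
    for kr, kc in zip(*np.nonzero(kernel.data)):
        _shift_or(out, src, int(kr) - ar, int(kc) - ac)
    return BinaryMask(out, mask.frame)


def parenchyma_ring(mask: BinaryMask, dilated: BinaryMask) -> BinaryMask:
    """The ring ``dilated AND NOT mask`` representing tissue around the lesion."""
    if mask.frame != dilated.frame:
        raise ValueError(f"frame mismatch: {mask.frame} vs {dilated.frame}")
    if np.any(mask.data & ~dilated.data):
        raise ValueError("dilated mask must be a superset of the lesion mask")
    return BinaryMask(dilated.data & ~mask.data, mask.frame)


@dataclass(frozen=True)
class ColorLUT:
    """Ordered colorbar colors with their scalar intensities (0-255 scale)."""

    colors: np.ndarray      # (m, 3) float
    intensities: np.ndarray  # (m,) float, strictly decreasing top->bottom

    def __post_init__(self) -> None:
        if len(self.colors) < 2:
            raise ValueError("LUT needs at least 2 entries")

    def decode(self, pixels: np.ndarray) -> np.ndarray:
        """Map RGB pixels ``(k, 3)`` to intensities via nearest LUT color."""
        px = np.asarray(pixels, dtype=np.float64)
        d2 = ((px[:, None, :] - self.colors[None, :, :]) ** 2).sum(axis=2)
        return self.intensities[np.argmin(d2, axis=1)]


def build_lut(colorbar_strip: np.ndarray) -> ColorLUT:
    """Build a lookup table from the cropped colorbar strip.

    Each strip row is averaged to a single RGB entry; entries get
    intensities linear from 255 (top row) to 0 (bottom row).  Adjacent rows
    with identical colors are collapsed, keeping the brighter (topmost)
    assignment.
    """
    strip = np.asarray(colorbar_strip)
    if strip.ndim != 3 or strip.shape[0] < 2:
        raise ValueError("colorbar strip must be an RGB raster with >= 2 rows")
    rows = strip.reshape(strip.shape[0], -1, strip.shape[2]).mean(axis=1)[:, :3]
    values = np.linspace(255.0, 0.0, strip.shape[0])
    keep_colors = [rows[0]]
    keep_values = [values[0]]
    for color, value in zip(rows[1:], values[1:]):
        if np.array_equal(np.round(color), np.round(keep_colors[-1])):
            continue
        keep_colors.append(color)
        keep_values.append(value)
    if len(keep_colors) < 2:
        raise ValueError("constant-color colorbar strip: cannot build a monotone LUT")
    return ColorLUT(np.asarray(keep_colors), np.asarray(keep_values))


def mean_intensity(panel: np.ndarray, mask: BinaryMask | np.ndarray, lut: ColorLUT) -> float:
    """Mean LUT-decoded intensity of the masked pixels in a contrast panel."""
    m = mask.data if isinstance(mask, BinaryMask) else np.asarray(mask, bool)
    panel = np.asarray(panel)
    if panel.shape[:2] != m.shape:
        raise ValueError(f"mask shape {m.shape} does not match panel {panel.shape[:2]}")
    if not m.any():
        raise EmptyMaskError("mask selects no pixels")
    return float(lut.decode(panel[m]).mean())


def accept_sample(previous: float | None, candidate: float, reject_fraction: float = 0.75) -> bool:
    """The frame-validity rule.

    The first sample is always accepted.  A later sample is accepted only
    if it differs from the previously *accepted* value by strictly less
    than ``reject_fraction`` of that value; larger jumps (e.g. a probe
    lift, or the recovery from one) are rejected.  A previous value of 0
    accepts anything, since no finite change can be expressed relative to
    zero and the rule would otherwise lock out permanently.
    """
    if previous is None:
        return True
    if previous == 0:
        return True
    return abs(candidate - previous) < reject_fraction * abs(previous)


@dataclass
class TimeIntensityCurve:
    """Per-second lesion/parenchyma intensity records with validity flags."""

    time: np.ndarray          # seconds, strictly increasing at 1 s spacing
    lesion: np.ndarray        # 0-255, NaN where invalid
    parenchyma: np.ndarray    # 0-255, NaN where invalid
    valid: np.ndarray         # bool
    frame_index: np.ndarray   # source frame per record, -1 where invalid

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("lesion", "parenchyma", "valid", "frame_index"):
            if len(getattr(self, name)) != n:
                raise ValueError("curve arrays must have equal length")
        if n >= 2 and not np.allclose(np.diff(self.time), 1.0):
            raise ValueError("curve must be sampled at 1 s spacing")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass(frozen=True)
class TICParams:
    """The four scalar TIC parameters (lesion series by default)."""

    max_intensity: float   # 0-255
    ttp: float             # seconds
    auc: float             # intensity * seconds
    mtt: float             # seconds; NaN for flat curves

    def as_dict(self) -> dict[str, float]:
        return {
            "max_intensity": self.max_intensity,
            "ttp_s": self.ttp,
            "auc": self.auc,
            "mtt_s": self.mtt,
        }


def sample_tic(
    frames: FrameSequence,
    provider: MaskProvider,
    regions: Mapping[str, RegionSpec] | None = None,
    kernel: StructuringElement | int = 10,
    reject_fraction: float = 0.75,
    lut: ColorLUT | None = None,
) -> TimeIntensityCurve:
    """Extract lesion and parenchyma intensities at one sample per second.

    For each second the first frame with timestamp >= that second is
    analysed: the provider's lesion mask (resized to panel space and mapped
    to the contrast panel) gives the lesion intensity, and the ring between
    the 10x10-dilated mask and the mask itself gives the parenchyma
    intensity from the *same* frame, keeping the two series time-aligned.
    A frame failing the 75% validity rule is skipped and the next frame
    within the same second tried; an exhausted second yields an invalid
    record.  The LUT defaults to one built from the first frame's colorbar
    strip.
    """
    if len(frames) < 1:
        raise ValueError("empty frame sequence")
    regions = dict(DEFAULT_REGIONS) if regions is None else regions
    b_spec, c_spec = regions["b_mode"], regions["contrast"]
    if b_spec.shape != c_spec.shape:
        raise ValueError("B-mode and contrast panels must have identical size")
    if lut is None:
        lut = build_lut(crop_region(frames[0], regions["colorbar"]))
    if isinstance(kernel, int):
        kernel = StructuringElement.square(kernel)

    n_seconds = int(np.floor(frames.duration)) + 1
    fps = frames.frame_rate
    time = np.arange(n_seconds, dtype=float)
    lesion = np.full(n_seconds, np.nan)
    parench = np.full(n_seconds, np.nan)
    valid = np.zeros(n_seconds, dtype=bool)
    fidx = np.full(n_seconds, -1, dtype=int)

    previous: float | None = None
    for s in range(n_seconds):
        first = int(np.ceil(s * fps - 1e-9))
        last = min(int(np.ceil((s + 1) * fps - 1e-9)) - 1, len(frames) - 1)
        for i in range(first, last + 1):
            frame = frames[i]
            bpanel = crop_region(frame, b_spec)
            mask256 = predict_mask(provider, bpanel, i)
            panel_mask = BinaryMask(resize_mask(mask256, b_spec.shape), FRAME_CONTRAST)
            if not panel_mask.data.any():
                continue
            cpanel = crop_region(frame, c_spec)
            value = mean_intensity(cpanel, panel_mask, lut)
            if not accept_sample(previous, value, reject_fraction):
                continue
            ring = parenchyma_ring(panel_mask, dilate(panel_mask, kernel))
            lesion[s] = value
            parench[s] = (
                mean_intensity(cpanel, ring, lut) if ring.data.any() else np.nan
            )
            valid[s] = True
            fidx[s] = i
            previous = value
            break

    return TimeIntensityCurve(time, lesion, parench, valid, fidx)


def _interp_invalid(time: np.ndarray, series: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Fill invalid gaps by linear interpolation (edge values extended)."""
    out = np.array(series, dtype=float)
    out[~valid] = np.interp(time[~valid], time[valid], series[valid])
    return out


def smooth_tic(
    curve: TimeIntensityCurve, window: int = 51, polyorder: int = 3
) -> TimeIntensityCurve:
    """Savitzky-Golay smoothing of both intensity series.

    Invalid gaps are linearly interpolated before filtering and re-flagged
    afterwards (their intensities stay NaN).  If the number of valid
    samples is smaller than the window, the window shrinks to the largest
    odd number <= that count, but never below 5.  Boundary samples are
    handled by fitting the filter polynomial to the terminal windows.
    """
    n_valid = curve.n_valid
    if n_valid < polyorder + 2:
        raise ValueError(
            f"need at least {polyorder + 2} valid samples to smooth, have {n_valid}"
        )
    w = min(window, n_valid)
    if w % 2 == 0:
        w -= 1
    w = max(w, 5)

    smoothed = {}
    for name in ("lesion", "parenchyma"):
        series = getattr(curve, name)
        series_valid = curve.valid & np.isfinite(series)
        if series_valid.sum() < polyorder + 2:
            smoothed[name] = np.array(series, dtype=float)
            continue
        filled = _interp_invalid(curve.time, series, series_valid)
        filt = savgol_filter(filled, w, polyorder, mode="interp")
        filt[~series_valid] = np.nan
        smoothed[name] = filt

    return TimeIntensityCurve(
        curve.time.copy(),
        smoothed["lesion"],
        smoothed["parenchyma"],
        curve.valid.copy(),
        curve.frame_index.copy(),
    )


def extract_params(curve: TimeIntensityCurve, series: str = "lesion") -> TICParams:
    """Read the four TIC parameters off a (smoothed) curve.

    * maximum intensity — the largest sample of the series;
    * TTP — the time of that maximum (earliest on ties);
    * AUC — trapezoidal integral over the valid samples, no baseline
      subtraction;
    * MTT — first temporal moment of the baseline-shifted curve,
      ``sum(t * (I - I_min)) / sum(I - I_min)``; undefined (NaN, with a
      warning) for a flat curve.
    """
    values = getattr(curve, series)
    sel = curve.valid & np.isfinite(values)
    if sel.sum() < 3:
        raise ValueError(f"need at least 3 valid samples, have {int(sel.sum())}")
    t = curve.time[sel]
    y = values[sel]
    imax = int(np.argmax(y))
    max_intensity = float(y[imax])
    ttp = float(t[imax])
    auc = float(np.trapezoid(y, t))
    shifted = y - y.min()
    denom = float(shifted.sum())
    if denom <= 0:
        warnings.warn("flat curve: mean transit time is undefined", stacklevel=2)
        mtt = float("nan")
    else:
        mtt = float((t * shifted).sum() / denom)
    return TICParams(max_intensity, ttp, auc, mtt)


def write_tic_csv(
    curve: TimeIntensityCurve, params: TICParams | None, path: str | Path
) -> Path:
    """Write the per-second curve (and a companion params file) as CSV.

    The curve goes to ``path`` with columns ``time_s, lesion_intensity,
    parenchyma_intensity, valid, frame_index`` (invalid rows have empty
    intensity cells); the four parameters go to ``<stem>_params.csv``.
    """
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_s": curve.time,
            "lesion_intensity": curve.lesion,
            "parenchyma_intensity": curve.parenchyma,
            "valid": curve.valid.astype(int),
            "frame_index": curve.frame_index,
        }
    )
    df.to_csv(path, index=False)
    if params is not None:
        params_path = path.with_name(path.stem + "_params.csv")
        pd.DataFrame([params.as_dict()]).to_csv(params_path, index=False)
    return path


def read_tic_csv(path: str | Path) -> tuple[TimeIntensityCurve, TICParams | None]:
    """Read back a curve written by :func:`write_tic_csv`."""
    path = Path(path)
    df = pd.read_csv(path)
    curve = TimeIntensityCurve(
        df["time_s"].to_numpy(float),
        df["lesion_intensity"].to_numpy(float),
        df["parenchyma_intensity"].to_numpy(float),
        df["valid"].to_numpy(bool),
        df["frame_index"].to_numpy(int),
    )
    params = None
    params_path = path.with_name(path.stem + "_params.csv")
    if params_path.exists():
        row = pd.read_csv(params_path).iloc[0]
        params = TICParams(
            float(row["max_intensity"]), float(row["ttp_s"]),
            float(row["auc"]), float(row["mtt_s"]),
        )
    return curve, params
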