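"""Reading CEUS video frames and cropping the named screen regions.

A CEUS investigation frame is a single RGB raster holding two side-by-side
panels (grayscale B-mode on the left, colormapped contrast mode on the
right) plus a narrow vertical colorbar strip that encodes the device's
intensity colormap.  This module reads an ordered frame sequence from disk
and crops those regions using configurable rectangle coordinates.  The
defaults match the Hitachi Arietta layout used throughout the package:

===========  =====  =====  =====  =====
region       x_min  x_max  y_min  y_max
===========  =====  =====  =====  =====
b_mode           0    400     78    525
contrast       400    800     78    525
colorbar       770    775    100    170
===========  =====  =====  =====  =====

Coordinate convention: ``x`` is the column, ``y`` the row, origin at the
top-left corner, and rectangles are half-open ``[min, max)`` on both axes,
so the crop width is exactly ``x_max - x_min``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import imageio.v3 as iio
import numpy as np

__all__ = [
    "RegionSpec",
    "FrameSequence",
    "DEFAULT_REGIONS",
    "read_video",
    "crop_region",
    "map_mask_between_panels",
    "read_mask_png",
    "write_mask_png",
    "regions_from_yaml",
]

_FRAME_EXTENSIONS = (".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp")
_SIDECAR_NAMES = ("phantom.json", "frames.json")


@dataclass(frozen=True)
class RegionSpec:
    """A named rectangle in full-frame coordinates, half-open on both axes."""

    name: str
    x_min: int
    x_max: int
    y_min: int
    y_max: int

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(
                f"region {self.name!r}: require x_min < x_max and y_min < y_max, "
                f"got x [{self.x_min}, {self.x_max}), y [{self.y_min}, {self.y_max})"
            )
        if min(self.x_min, self.y_min) < 0:
            raise ValueError(f"region {self.name!r}: negative coordinates")

    @property
    def width(self) -> int:
        return self.x_max - self.x_min

    @property
    def height(self) -> int:
        return self.y_max - self.y_min

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) of the cropped raster."""
        return (self.height, self.width)


#: Default panel geometry (full frame 800x525).
DEFAULT_REGIONS: Mapping[str, RegionSpec] = {
    "b_mode": RegionSpec("b_mode", 0, 400, 78, 525),
    "contrast": RegionSpec("contrast", 400, 800, 78, 525),
    "colorbar": RegionSpec("colorbar", 770, 775, 100, 170),
}


@dataclass
class FrameSequence:
    """An ordered stack of RGB frames with a known frame rate.

    ``frames`` has shape ``(n, height, width, 3)`` and dtype uint8.
    Timestamps are derived, ``t_i = i / frame_rate``.
    """

    frames: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError(
                f"frames must have shape (n, h, w, 3), got {self.frames.shape}"
            )
        if self.frames.shape[0] == 0:
            raise ValueError("empty frame sequence")
        if not (self.frame_rate > 0):
            raise ValueError(f"frame rate must be positive, got {self.frame_rate}")

    @property
    def timestamps(self) -> np.ndarray:
        return np.arange(len(self)) / self.frame_rate

    @property
    def duration(self) -> float:
        """Timestamp of the last frame, in seconds."""
        return (len(self) - 1) / self.frame_rate

    def __len__(self) -> int:
        return int(self.frames.shape[0])

    def __getitem__(self, i: int) -> np.ndarray:
        return self.frames[i]


def _read_frame_directory(path: Path) -> np.ndarray:
    files = sorted(
        p for p in path.iterdir()
        if p.suffix.lower() in _FRAME_EXTENSIONS and not p.name.startswith("mask")
    )
    if not files:
        raise FileNotFoundError(f"no frame images found in directory {path}")
    frames = []
    for f in files:
        img = iio.imread(f)
        if img.ndim == 2:
            img = np.stack([img] * 3, axis=-1)
        frames.append(img[..., :3])
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"frames of inconsistent size in {path}: {sorted(shapes)}")
    return np.stack(frames).astype(np.uint8)


def _sidecar_frame_rate(path: Path) -> float | None:
    for name in _SIDECAR_NAMES:
        sidecar = path / name
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            if "frame_rate" in meta:
                return float(meta["frame_rate"])
    return None


def read_video(path: str | Path, frame_rate_override: float | None = None) -> FrameSequence:
    """Read an ordered frame sequence from disk.

    Supported inputs: a directory of numbered PNG/TIFF frames (with an
    optional JSON sidecar declaring ``frame_rate``), a multi-page TIFF, or
    any container imageio can decode.  The frame rate comes from the
    sidecar/container metadata, or from ``frame_rate_override``; if neither
    is available an error is raised rather than guessing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    if path.is_dir():
        frames = _read_frame_directory(path)
        rate = frame_rate_override or _sidecar_frame_rate(path)
        if rate is None:
            raise ValueError(
                f"no frame rate metadata found for {path}; pass frame_rate_override"
            )
        return FrameSequence(frames, float(rate))

    if path.suffix.lower() in (".tif", ".tiff"):
        stack = iio.imread(path)
        if stack.ndim == 3 and stack.shape[-1] != 3:
            stack = np.stack([stack] * 3, axis=-1)
        elif stack.ndim == 3:  # single RGB frame
            stack = stack[None]
        if frame_rate_override is None:
            raise ValueError("TIFF stacks carry no frame rate; pass frame_rate_override")
        return FrameSequence(stack[..., :3].astype(np.uint8), float(frame_rate_override))

    try:
        props = iio.improps(path, plugin="pyav")  # pragma: no cover - needs av
        frames = iio.imread(path, plugin="pyav")  # pragma: no cover
    except Exception as exc:
        raise ValueError(
            f"cannot decode container {path} (no video plugin available); "
            "convert to a PNG frame directory instead"
        ) from exc
    rate = frame_rate_override  # pragma: no cover
    if rate is None:  # pragma: no cover
        raise ValueError(f"unknown frame rate for {path}; pass frame_rate_override")
    return FrameSequence(np.asarray(frames)[..., :3].astype(np.uint8), float(rate))  # pragma: no cover


def crop_region(frame: np.ndarray, spec: RegionSpec) -> np.ndarray:
    """Crop one named rectangle out of a full frame.

    Output pixel ``(0, 0)`` is frame pixel ``(y_min, x_min)``; output shape
    is ``(y_max - y_min, x_max - x_min)``.
    """
    h, w = frame.shape[:2]
    if spec.x_max > w or spec.y_max > h:
        raise ValueError(
            f"region {spec.name!r} (x<{spec.x_max}, y<{spec.y_max}) exceeds "
            f"frame bounds {w}x{h}"
        )
    return frame[spec.y_min:spec.y_max, spec.x_min:spec.x_max]


def map_mask_between_panels(
    mask: np.ndarray, src_spec: RegionSpec, dst_spec: RegionSpec
) -> np.ndarray:
    """Carry a panel-local mask from one panel to another of equal size.

    The B-mode and contrast panels show the same anatomy at the same scale,
    only at a different horizontal offset within the frame, so a mask drawn
    in B-mode panel coordinates applies verbatim in contrast panel
    coordinates.  Pure bookkeeping: the pixel grid is returned unchanged
    (as a copy) after validating that both panels have identical shape.
    """
    if src_spec.shape != dst_spec.shape:
        raise ValueError(
            f"panel size mismatch: {src_spec.name} is {src_spec.shape}, "
            f"{dst_spec.name} is {dst_spec.shape}"
        )
    mask = np.asarray(mask)
    if mask.shape != src_spec.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match panel {src_spec.name} "
            f"shape {src_spec.shape}"
        )
    return mask.copy()


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as an 8-bit PNG with values 0/255."""
    iio.imwrite(Path(path), (np.asarray(mask, bool) * np.uint8(255)))


def read_mask_png(path: str | Path) -> np.ndarray:
    img = iio.imread(Path(path))
    if img.ndim == 3:
        img = img[..., 0]
    return img > 127


def regions_from_yaml(path: str | Path) -> dict[str, RegionSpec]:
    """Load region rectangles from a YAML mapping name -> [x_min, x_max, y_min, y_max]."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text())
    return {
        name: RegionSpec(name, *[int(v) for v in coords]) for name, coords in raw.items()
    }
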