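"""Calibrated image-stack I/O, background correction and ROI handling.

Coordinate convention used throughout the package: 0-based indices, pixel
centres at integer coordinates, ``x`` = column, ``y`` = row. Intensities are
processed as real numbers regardless of the source bit depth and are never
rescaled; background corrections clip negative results to zero.

Two background-correction schemes are provided, matching the two standard
dark-field preprocessing recipes: subtraction of the per-pixel minimum
projection over time (static background), and per-frame rolling-ball
background subtraction (uneven illumination).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from skimage.restoration import rolling_ball as _sk_rolling_ball


@dataclass
class ImageStack:
    """Time-ordered grayscale frames with physical calibration.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, height, width)``, non-negative reals.
    fps
        Acquisition rate in frames per second.
    pixel_size
        Physical size of one pixel in µm.
    bit_depth
        Bit depth of the source data (informational only; intensities are
        kept as-is).
    """

    frames: np.ndarray
    fps: float
    pixel_size: float
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be (time, row, column), got shape {self.frames.shape}"
            )
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of a single frame."""
        return self.frames.shape[1:]

    @property
    def times(self) -> np.ndarray:
        """Frame acquisition times in seconds."""
        return np.arange(self.n_frames) / self.fps

    def with_frames(self, frames: np.ndarray) -> "ImageStack":
        return ImageStack(frames, self.fps, self.pixel_size, self.bit_depth)


@dataclass
class RoiMask:
    """Binary region-of-interest mask restricting where a flagellum is searched."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be 2-D")
        if not self.mask.any():
            raise ValueError("ROI mask must contain at least one pixel")

    @classmethod
    def from_rectangle(
        cls, shape: tuple[int, int], x0: int, y0: int, width: int, height: int
    ) -> "RoiMask":
        mask = np.zeros(shape, dtype=bool)
        mask[y0 : y0 + height, x0 : x0 + width] = True
        return cls(mask)

    @classmethod
    def from_polygon(cls, shape: tuple[int, int], xy: np.ndarray) -> "RoiMask":
        from skimage.draw import polygon

        xy = np.asarray(xy, dtype=float)
        rr, cc = polygon(xy[:, 1], xy[:, 0], shape=shape)
        mask = np.zeros(shape, dtype=bool)
        mask[rr, cc] = True
        return cls(mask)

    @classmethod
    def from_tiff(cls, path: str | Path) -> "RoiMask":
        return cls(tifffile.imread(path) > 0)


def pixel_size_from_camera(camera_pixel_um: float, magnification: float) -> float:
    """Physical sampling step in the specimen plane, µm per pixel.

    An 11 µm camera pixel behind a 20× magnification samples the specimen at
    11/20 = 0.55 µm per pixel, which is also the step at which normal-line
    intensity profiles are sampled.
    """
    if camera_pixel_um <= 0 or magnification <= 0:
        raise ValueError("camera pixel size and magnification must be > 0")
    return camera_pixel_um / magnification


def load_stack(path: str | Path, fps: float, pixel_size: float) -> ImageStack:
    """Load a multi-page grayscale TIFF as a calibrated :class:`ImageStack`.

    Raises
    ------
    ValueError
        For RGB input or stacks with fewer than 2 frames (time-resolved
        analysis, in particular any frequency analysis, is impossible).
    """
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        raise ValueError("at least 2 frames required for time-resolved analysis")
    if data.ndim != 3:
        raise ValueError(
            f"expected a grayscale multi-page TIFF, got array of shape {data.shape}"
        )
    if data.shape[-1] in (3, 4) and data.shape[-1] < min(data.shape[:2]):
        raise ValueError("RGB input not supported; provide a grayscale stack")
    if data.shape[0] < 2:
        raise ValueError("at least 2 frames required for time-resolved analysis")
    bit_depth = data.dtype.itemsize * 8 if data.dtype.kind in "ui" else 32
    return ImageStack(data.astype(np.float64), fps, pixel_size, bit_depth)


def write_stack(path: str | Path, stack: ImageStack) -> None:
    """Write a stack as 16-bit multi-page TIFF (values clipped to uint16 range)."""
    data = np.clip(np.round(stack.frames), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")


def min_projection_subtract(stack: ImageStack) -> ImageStack:
    """Subtract the per-pixel minimum over time; clip negatives to zero.

    Removes any strictly static background (each pixel's darkest value over
    the movie), the standard correction for tethered-cell dark-field movies.
    """
    if stack.n_frames < 2:
        raise ValueError("at least 2 frames required")
    background = stack.frames.min(axis=0)
    return stack.with_frames(np.maximum(stack.frames - background, 0.0))


def rolling_ball_background_subtract(stack: ImageStack, radius_px: float) -> ImageStack:
    """Per-frame rolling-ball background subtraction; clip negatives to zero.

    The background under each frame is estimated by rolling a ball of the
    given radius under the intensity surface and is then subtracted, the
    standard correction for unevenly illuminated movies of swimming cells.
    No pre-smoothing and no light-background mode are applied.
    """
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    if radius_px > min(stack.shape):
        raise ValueError(
            f"radius {radius_px} px exceeds the shorter image side {min(stack.shape)} px"
        )
    out = np.empty_like(stack.frames)
    for i, frame in enumerate(stack.frames):
        background = _sk_rolling_ball(frame, radius=radius_px)
        out[i] = np.maximum(frame - background, 0.0)
    return stack.with_frames(out)


_BACKGROUND_MODES = ("none", "min-projection", "rolling-ball")


def correct_background(
    stack: ImageStack, mode: str, rolling_ball_radius_px: float = 10.0
) -> ImageStack:
    """Dispatch to one of the background-correction schemes by name."""
    if mode == "none":
        return stack
    if mode == "min-projection":
        return min_projection_subtract(stack)
    if mode == "rolling-ball":
        return rolling_ball_background_subtract(stack, rolling_ball_radius_px)
    raise ValueError(f"background mode must be one of {_BACKGROUND_MODES}, got {mode!r}")
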