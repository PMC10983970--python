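"""In-memory containers for fluorescence images, masks, and time-lapse stacks.

Images carry a physical pixel size so that downstream measurements (punctae
areas, cell spreading areas) can be reported in square microns.  Pixel values
are unsigned integers; the dtype maximum (``bit_max``) doubles as the upper
bound of interval thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile


def _dtype_max(arr: np.ndarray) -> int:
    if not np.issubdtype(arr.dtype, np.integer):
        raise TypeError(f"expected an integer image, got dtype {arr.dtype}")
    return int(np.iinfo(arr.dtype).max)


@dataclass
class PlaneImage:
    """A single 2-D fluorescence frame with physical pixel size.

    Parameters
    ----------
    pixels : ndarray
        2-D array of non-negative integer intensities.
    pixel_size_um : float
        Edge length of one pixel in microns (must be positive).
    bit_max : int, optional
        Maximum representable intensity; defaults to the dtype maximum
        (65535 for 16-bit).
    """

    pixels: np.ndarray
    pixel_size_um: float
    bit_max: int = field(default=0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("PlaneImage requires a 2-D pixel array")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if not self.bit_max:
            self.bit_max = _dtype_max(self.pixels)
        if self.pixels.min() < 0 or self.pixels.max() > self.bit_max:
            raise ValueError("pixel values must lie in [0, bit_max]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um ** 2

    def save(self, path) -> None:
        tifffile.imwrite(path, self.pixels)

    @classmethod
    def load(cls, path, pixel_size_um: float) -> "PlaneImage":
        arr = tifffile.imread(path)
        if arr.ndim == 3 and arr.shape[0] == 1:
            arr = arr[0]
        return cls(arr, pixel_size_um)


@dataclass
class CellMask:
    """Boolean footprint of a single cell, same shape as its image."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("CellMask requires a 2-D boolean array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def n_pixels(self) -> int:
        return int(self.pixels.sum())

    def save(self, path) -> None:
        tifffile.imwrite(path, self.pixels.astype(np.uint8) * 255)

    @classmethod
    def load(cls, path) -> "CellMask":
        arr = tifffile.imread(path)
        return cls(arr > 0)


@dataclass
class ImageStack:
    """Ordered time-lapse of frames with a uniform frame interval.

    Frames are stored as a 3-D (t, row, col) integer array.
    """

    frames: np.ndarray
    pixel_size_um: float
    frame_interval_s: float = 0.75
    bit_max: int = field(default=0)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("ImageStack requires a 3-D (t, row, col) array")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if not self.bit_max:
            self.bit_max = _dtype_max(self.frames)

    def __len__(self) -> int:
        return self.frames.shape[0]

    def plane(self, i: int) -> PlaneImage:
        return PlaneImage(self.frames[i], self.pixel_size_um, self.bit_max)

    @property
    def times_s(self) -> np.ndarray:
        """Frame acquisition times; frame k is acquired at k * interval."""
        return np.arange(len(self)) * self.frame_interval_s

    def save(self, path) -> None:
        tifffile.imwrite(path, self.frames)

    @classmethod
    def load(cls, path, pixel_size_um: float, frame_interval_s: float = 0.75) -> "ImageStack":
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
        return cls(arr, pixel_size_um, frame_interval_s)
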