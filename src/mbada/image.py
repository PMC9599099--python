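"""Canonical in-memory image container and lossless raster I/O.

Pixel intensities are held as ``float64`` in the unit interval, the
canonical range every transform and metric in this package works in.
8-bit rasters are mapped to ``[0, 1]`` by division with 255 on load and
re-quantised by round-half-to-even on save.
"""

from __future__ import annotations

from dataclasses import InitVar, dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["IntensityImage"]


@dataclass(frozen=True)
class IntensityImage:
    """An ``H x W`` (grayscale) or ``H x W x 3`` (RGB) intensity grid.

    Parameters
    ----------
    pixels
        Array of finite reals; values must lie in ``[0, 1]`` unless
        ``check_range=False`` (used internally for raw reconstructions).
    source_bit_depth
        Bit depth of the raster the image came from (default 8).
    """

    pixels: np.ndarray
    source_bit_depth: int = 8
    check_range: InitVar[bool] = True

    def __post_init__(self, check_range: bool) -> None:
        arr = np.asarray(self.pixels, dtype=np.float64)
        if arr.ndim == 3 and arr.shape[2] == 1:
            arr = arr[:, :, 0]
        if arr.ndim not in (2, 3):
            raise ValueError(f"pixels must be 2-D or 3-D, got ndim={arr.ndim}")
        if arr.ndim == 3 and arr.shape[2] != 3:
            raise ValueError(f"channel count must be 1 or 3, got {arr.shape[2]}")
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError(f"image dimensions must be >= 1, got {arr.shape}")
        if not np.isfinite(arr).all():
            raise ValueError("pixels contain non-finite values")
        if check_range and (arr.min() < 0.0 or arr.max() > 1.0):
            raise ValueError(
                f"pixels must lie in [0, 1]; found range "
                f"[{arr.min():.4g}, {arr.max():.4g}]"
            )
        arr = arr.copy()
        arr.setflags(write=False)
        object.__setattr__(self, "pixels", arr)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]

    def channel_stack(self) -> np.ndarray:
        """Pixels as a ``(C, H, W)`` view for per-channel processing."""
        if self.pixels.ndim == 2:
            return self.pixels[None]
        return np.moveaxis(self.pixels, -1, 0)

    @classmethod
    def from_channel_stack(
        cls, stack: np.ndarray, *, check_range: bool = True
    ) -> "IntensityImage":
        arr = stack[0] if stack.shape[0] == 1 else np.moveaxis(stack, 0, -1)
        return cls(arr, check_range=check_range)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "IntensityImage":
        """Build from a float array in [0,1] or an integer 8/16-bit array."""
        arr = np.asarray(arr)
        if arr.dtype == np.uint8:
            return cls(arr.astype(np.float64) / 255.0, source_bit_depth=8)
        if arr.dtype == np.uint16:
            return cls(arr.astype(np.float64) / 65535.0, source_bit_depth=16)
        return cls(arr.astype(np.float64))

    @classmethod
    def load(cls, path: str | Path) -> "IntensityImage":
        """Read a PNG/TIFF/JPEG raster (grayscale or RGB)."""
        arr = iio.imread(Path(path))
        if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        return cls.from_array(arr)

    def to_uint8(self) -> np.ndarray:
        """Quantise to 8 bits: clip to [0,1], scale by 255, round half-to-even."""
        return np.rint(np.clip(self.pixels, 0.0, 1.0) * 255.0).astype(np.uint8)

    def quantized(self) -> "IntensityImage":
        """The image after an 8-bit round trip (values on the 255ths grid)."""
        return IntensityImage(self.to_uint8() / 255.0, self.source_bit_depth)

    def save(self, path: str | Path, encoding: str = "eight_bit") -> Path:
        """Write losslessly: 8-bit PNG/TIFF or float32 TIFF.

        ``encoding='eight_bit'`` quantises; ``'float'`` stores float32
        (TIFF only).
        """
        path = Path(path)
        if encoding == "eight_bit":
            iio.imwrite(path, self.to_uint8())
        elif encoding == "float":
            if path.suffix.lower() not in (".tif", ".tiff"):
                raise ValueError("float encoding requires a .tif/.tiff path")
            iio.imwrite(path, self.pixels.astype(np.float32))
        else:
            raise ValueError(f"unknown encoding {encoding!r}")
        return path


def as_image(obj) -> IntensityImage:
    """Coerce an IntensityImage or array-like into an IntensityImage."""
    if isinstance(obj, IntensityImage):
        return obj
    return IntensityImage.from_array(np.asarray(obj))
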