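"""Calibrated 2-D grayscale images and their file I/O.

The whole pipeline operates on :class:`Image2D`: a float intensity grid plus
a microns-per-pixel calibration. Files are read with tifffile/imageio and
written as 16-bit grayscale TIFF.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["Image2D", "read_image", "write_tiff"]


@dataclass
class Image2D:
    """A rectangular grid of non-negative intensities with spatial calibration.

    Parameters
    ----------
    pixels
        2-D float array, indexed ``[row, col]`` = ``[y, x]``.
    microns_per_px
        Physical side length of one pixel, in microns.
    """

    pixels: np.ndarray
    microns_per_px: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D image, got ndim={self.pixels.ndim}")
        if not self.microns_per_px > 0:
            raise ValueError("microns_per_px must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    @property
    def width_um(self) -> float:
        return self.width_px * self.microns_per_px

    @property
    def height_um(self) -> float:
        return self.height_px * self.microns_per_px

    def px_to_um(self, x_px, y_px):
        return (np.asarray(x_px) * self.microns_per_px, np.asarray(y_px) * self.microns_per_px)

    def um_to_px(self, x_um, y_um):
        return (np.asarray(x_um) / self.microns_per_px, np.asarray(y_um) / self.microns_per_px)

    def copy(self) -> "Image2D":
        return Image2D(self.pixels.copy(), self.microns_per_px)

    def to_uint16(self) -> np.ndarray:
        """Clip to [0, 65535] and round to an unsigned 16-bit raster."""
        return np.clip(np.rint(self.pixels), 0, 65535).astype(np.uint16)


def read_image(path: str | Path, microns_per_px: float = 1.0) -> Image2D:
    """Read a TIFF/PNG grayscale image; multi-channel inputs are averaged."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr.mean(axis=-1)
    return Image2D(arr, microns_per_px)


def write_tiff(image: Image2D, path: str | Path) -> None:
    """Write as 16-bit grayscale TIFF with the pixel size in the metadata."""
    import tifffile

    tifffile.imwrite(
        Path(path),
        image.to_uint16(),
        resolution=(1e4 / image.microns_per_px, 1e4 / image.microns_per_px),
        resolutionunit="CENTIMETER",
    )
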