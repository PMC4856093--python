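"""Reading microscopy images into the pipeline's canonical 8-bit grayscale raster.

Bright-field and SEM images enter as TIFF/PNG/JPEG; both are reduced to a
single 8-bit channel.  Bright-field eyes carry one bright reflection spot per
ommatidium, SEM eyes one dark center per ommatidium, so the modality travels
with the raster and downstream stages normalize polarity accordingly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from enum import Enum

import imageio.v3 as iio
import numpy as np

MIN_IMAGE_SIDE = 64

#: ITU-R BT.601 luma weights for RGB -> gray reduction.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


class Modality(str, Enum):
    """Imaging modality; decides eye-localization path and center polarity."""

    BRIGHTFIELD = "brightfield"
    SEM = "sem"


@dataclass(frozen=True)
class GrayImage:
    """A 2-D uint8 intensity raster plus its imaging modality."""

    pixels: np.ndarray
    modality: Modality

    def __post_init__(self) -> None:
        px = self.pixels
        if px.ndim != 2:
            raise ValueError(f"expected a 2-D raster, got shape {px.shape}")
        if px.dtype != np.uint8:
            raise ValueError(f"expected uint8 pixels, got {px.dtype}")
        if px.shape[0] < MIN_IMAGE_SIDE or px.shape[1] < MIN_IMAGE_SIDE:
            raise ValueError(
                f"image {px.shape[0]}x{px.shape[1]} is smaller than the "
                f"{MIN_IMAGE_SIDE}x{MIN_IMAGE_SIDE} minimum"
            )
        object.__setattr__(self, "modality", Modality(self.modality))

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


def _to_uint8(arr: np.ndarray) -> np.ndarray:
    """Rescale any integer/float raster linearly onto the 8-bit display range."""
    if arr.dtype == np.uint8:
        return arr
    arr = arr.astype(np.float64)
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        return np.zeros(arr.shape, dtype=np.uint8)
    return np.floor((arr - lo) / (hi - lo) * 255.0 + 0.5).astype(np.uint8)


def _luma(rgb: np.ndarray) -> np.ndarray:
    w = np.asarray(LUMA_WEIGHTS, dtype=np.float64)
    gray = rgb.astype(np.float64) @ w
    # round half away from zero (values are non-negative)
    return np.floor(gray + 0.5).astype(np.uint8)


def load_image(path: str | os.PathLike, modality: Modality | str) -> GrayImage:
    """Read a TIFF/PNG/JPEG eye image and convert it to grayscale.

    RGB inputs are reduced with BT.601 luma weights (alpha dropped first);
    single-channel inputs pass through unchanged.  Rasters deeper than 8 bits
    are linearly mapped min->0, max->255 before any color reduction.

    Raises
    ------
    OSError
        If the file is missing or not a decodable raster.
    ValueError
        If the decoded image is smaller than 64x64.
    """
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # imageio raises assorted decode errors
        raise OSError(f"could not decode image file {path!r}: {exc}") from exc

    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        if arr.shape[2] == 1:
            arr = arr[:, :, 0]
    if arr.ndim == 3:
        if arr.dtype != np.uint8:
            arr = _to_uint8(arr)
        gray = _luma(arr)
    elif arr.ndim == 2:
        gray = _to_uint8(arr)
    else:
        raise OSError(f"unsupported raster layout with shape {arr.shape}")

    return GrayImage(pixels=gray, modality=Modality(modality))


def invert(img: GrayImage) -> GrayImage:
    """Return the photographic negative (p -> 255 - p); an exact involution."""
    return GrayImage(pixels=(255 - img.pixels).astype(np.uint8), modality=img.modality)
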