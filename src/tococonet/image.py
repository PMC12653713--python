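"""8-bit RGB image handling: validation, quantization, and PNG/JPEG I/O.

The whole pipeline trades in H×W×3 uint8 arrays in R, G, B channel order.
All arithmetic happens in floating point; :func:`quantize` is the single
place where values are rounded and clamped back to 8 bits.
"""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np

__all__ = ["validate_rgb", "quantize", "to_float", "load_image", "save_image"]


def validate_rgb(img: np.ndarray, name: str = "image") -> np.ndarray:
    """Check that ``img`` is a valid H×W×3 8-bit RGB array and return it as uint8.

    Raises ``ValueError`` on wrong rank/channel count or out-of-range values.
    Alpha channels are rejected rather than silently dropped.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(
            f"{name} must be H×W×3 RGB; got shape {img.shape}"
            + (" (alpha channels are not supported)" if img.ndim == 3 and img.shape[2] == 4 else "")
        )
    if img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError(f"{name} must have height ≥ 1 and width ≥ 1")
    if img.dtype != np.uint8:
        arr = np.asarray(img, dtype=np.float64)
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError(f"{name} has values outside [0, 255]")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError(f"{name} has non-integer levels; quantize first")
        img = arr.astype(np.uint8)
    return img


def quantize(arr: np.ndarray) -> np.ndarray:
    """Round half away from zero, clamp to [0, 255], and cast to uint8.

    Applied exactly once at the float → 8-bit boundary of every transform.
    """
    rounded = np.sign(arr) * np.floor(np.abs(arr) + 0.5)
    return np.clip(rounded, 0, 255).astype(np.uint8)


def to_float(img: np.ndarray) -> np.ndarray:
    """uint8 levels → float64 copy on the 0–255 scale."""
    return np.asarray(img, dtype=np.float64)


def load_image(path: str | os.PathLike) -> np.ndarray:
    """Read a PNG or JPEG file as 8-bit RGB. Alpha channels are rejected."""
    img = iio.imread(path)
    if img.ndim == 2:  # grayscale file: promote so downstream math is uniform
        img = np.stack([img] * 3, axis=-1)
    return validate_rgb(img, name=str(path))


def save_image(path: str | os.PathLike, img: np.ndarray) -> None:
    """Write an 8-bit RGB image to PNG or JPEG (format chosen by extension)."""
    iio.imwrite(path, validate_rgb(img))
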