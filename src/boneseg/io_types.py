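"""Shared domain types and image/mask I/O.

Conventions used throughout the package:

* arrays are row-major ``(row, col)`` with 0-based indices; an image's
  conventional ``(x, y)`` maps to ``(col, row)``;
* intensities are non-negative floats in arbitrary MR units;
* binary masks are ``uint8`` arrays of {0, 1} with the same shape as the
  image they refer to.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pydicom


class UnsupportedInputError(ValueError):
    """Input parses but is not a single 2D grayscale frame."""


@dataclass
class Image2D:
    """A single 2D grayscale MR slice.

    Parameters
    ----------
    pixels : ndarray
        2D float array of non-negative intensities (arbitrary MR units).
    pixel_spacing : float, optional
        In-plane spacing in mm/pixel (isotropic); purely informational.
    """

    pixels: np.ndarray
    pixel_spacing: float = 1.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=float)
        if arr.ndim != 2:
            raise UnsupportedInputError(f"expected a 2D array, got ndim={arr.ndim}")
        if arr.shape[0] < 8 or arr.shape[1] < 8:
            raise ValueError(f"image too small: {arr.shape} (minimum 8x8)")
        if not np.all(np.isfinite(arr)):
            raise ValueError("image contains non-finite values")
        if arr.min() < 0:
            raise ValueError("image contains negative intensities")
        self.pixels = arr

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class BinaryMask:
    """A {0,1} pixel mask tied to the shape of its source image."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValueError("mask must be 2D")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be strictly binary {0,1}")
        self.pixels = arr.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def astype_bool(self) -> np.ndarray:
        return self.pixels.astype(bool)

    @classmethod
    def from_bool(cls, arr: np.ndarray) -> "BinaryMask":
        return cls(np.asarray(arr, dtype=bool).astype(np.uint8))


@dataclass
class SegmentationResult:
    """Final foreground mask plus its traced boundary and evaluation."""

    mask: BinaryMask
    boundary: list[tuple[int, int]]
    method_name: str
    iterations_run: int
    dice: Optional[float] = None
    dice_pre_postprocess: Optional[float] = None
    circle: Optional[tuple[float, float, float]] = None  # (row, col, radius)
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dice is not None and not (0.0 <= self.dice <= 1.0):
            raise ValueError(f"dice out of [0,1]: {self.dice}")

    def to_record(self) -> dict:
        rec = {
            "method": self.method_name,
            "iterations": int(self.iterations_run),
            "dice": None if self.dice is None else float(self.dice),
        }
        if self.dice_pre_postprocess is not None:
            rec["dice_pre_postprocess"] = float(self.dice_pre_postprocess)
        if self.circle is not None:
            r, c, rad = self.circle
            rec["circle"] = [float(c), float(r), float(rad)]  # [cx, cy, r]
        rec.update(self.extras)
        return rec

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_record(), indent=2) + "\n")


def _load_dicom(path: Path) -> np.ndarray:
    ds = pydicom.dcmread(path)
    arr = ds.pixel_array
    if arr.ndim != 2:
        raise UnsupportedInputError(
            f"multi-frame or non-grayscale DICOM not supported (shape {arr.shape})"
        )
    arr = arr.astype(float)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    arr = arr * slope + intercept
    # MR intensities are physically non-negative; clamp negative rescales.
    return np.maximum(arr, 0.0)


def _load_raster(path: Path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3:
        if arr.shape[2] in (3, 4) and np.all(arr[..., 0] == arr[..., 1]) and np.all(
            arr[..., 0] == arr[..., 2]
        ):
            arr = arr[..., 0]  # gray stored as RGB
        else:
            raise UnsupportedInputError("RGB/multi-channel input not supported")
    if arr.ndim != 2:
        raise UnsupportedInputError(f"expected 2D grayscale, got shape {arr.shape}")
    return np.maximum(arr.astype(float), 0.0)


def load_image(path: str | Path, format: str = "auto") -> Image2D:
    """Load a single-frame 2D grayscale image.

    ``format`` is one of ``{"dicom", "png", "tiff", "auto"}``; with ``auto``
    the file suffix decides (``.dcm``/``.dicom`` → DICOM, else raster).
    DICOM rescale slope/intercept is applied and the result clamped at 0.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    fmt = format.lower()
    if fmt == "auto":
        fmt = "dicom" if path.suffix.lower() in (".dcm", ".dicom") else "raster"
    if fmt == "dicom":
        arr = _load_dicom(path)
    elif fmt in ("png", "tiff", "raster"):
        arr = _load_raster(path)
    else:
        raise ValueError(f"unknown format: {format!r}")
    spacing = 1.0
    return Image2D(arr, pixel_spacing=spacing)


def save_image(image: Image2D, path: str | Path) -> None:
    """Write an image as 16-bit grayscale PNG/TIFF (suffix decides)."""
    arr = image.pixels
    out = np.clip(np.round(arr), 0, 65535).astype(np.uint16)
    iio.imwrite(Path(path), out)


def save_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask losslessly as an 8-bit PNG with values {0, 255}."""
    out = (mask.pixels * 255).astype(np.uint8)
    try:
        iio.imwrite(Path(path), out)
    except OSError as exc:  # pragma: no cover - depends on filesystem
        raise IOError(f"cannot write mask to {path}: {exc}") from exc


def load_mask(path: str | Path) -> BinaryMask:
    """Read a mask PNG written by :func:`save_mask` (any nonzero → 1)."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return BinaryMask.from_bool(arr > 0)


def save_boundary_csv(boundary: Sequence[tuple[int, int]], path: str | Path) -> None:
    lines = ["row,col"] + [f"{r},{c}" for r, c in boundary]
    Path(path).write_text("\n".join(lines) + "\n")


def save_overlay(image: Image2D, boundary: Sequence[tuple[int, int]],
                 path: str | Path) -> None:
    """Write an RGB PNG of the image with the boundary drawn in red."""
    arr = image.pixels
    lo, hi = arr.min(), arr.max()
    gray = np.zeros_like(arr) if hi <= lo else (arr - lo) / (hi - lo)
    rgb = np.stack([gray] * 3, axis=-1)
    for r, c in boundary:
        rgb[r, c] = (1.0, 0.0, 0.0)
    iio.imwrite(Path(path), (rgb * 255).astype(np.uint8))
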