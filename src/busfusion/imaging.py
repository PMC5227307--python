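"""Image/mask containers, file I/O, resampling and gray-level quantization.

Conventions fixed here for the whole package:

* arrays are row-major, 0-based, origin at the top-left; ``spacing_mm`` is a
  ``(row_mm, col_mm)`` pair;
* GLCM orientations are measured as in standard co-occurrence practice
  (0 deg = horizontal offset, 90 deg = vertical), see :mod:`busfusion.texture`;
* intensities are integers in ``[0, levels - 1]``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .errors import DataError, FormatError, SizingError

__all__ = [
    "GrayscaleImage",
    "TumorMask",
    "BUSCase",
    "read_case",
    "write_case",
    "resample_to_spacing",
    "quantize_gray_levels",
]


@dataclass(frozen=True)
class GrayscaleImage:
    """Integer-valued 2-D image with a known gray-level count and pixel spacing."""

    pixels: np.ndarray
    levels: int
    spacing_mm: tuple[float, float]

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise FormatError(f"image must be 2-D and non-empty, got shape {px.shape}")
        if self.levels < 2:
            raise FormatError(f"levels must be >= 2, got {self.levels}")
        if px.min() < 0 or px.max() >= self.levels:
            raise FormatError("pixel values must lie in [0, levels-1]")
        if min(self.spacing_mm) <= 0:
            raise FormatError(f"spacing must be positive, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class TumorMask:
    """Binary tumor mask paired with an image of identical shape."""

    pixels: np.ndarray
    spacing_mm: tuple[float, float]

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise FormatError(f"mask must be 2-D, got shape {px.shape}")
        if px.dtype != bool:
            object.__setattr__(self, "pixels", px.astype(bool))
        if not self.pixels.any():
            raise DataError("mask has no foreground pixels")
        if min(self.spacing_mm) <= 0:
            raise FormatError(f"spacing must be positive, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class BUSCase:
    """One breast-ultrasound case: image, tumor mask and (optional) label."""

    case_id: str
    image: GrayscaleImage
    mask: TumorMask
    label: str = "unknown"

    def __post_init__(self) -> None:
        if self.image.shape != self.mask.shape:
            raise FormatError(
                f"{self.case_id}: image shape {self.image.shape} != mask shape "
                f"{self.mask.shape}"
            )
        if self.label not in ("benign", "malignant", "unknown"):
            raise DataError(f"{self.case_id}: unknown label {self.label!r}")


def _load_gray(path: str | Path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3:  # collapse RGB(A) from grayscale-saved files
        arr = arr[..., :3].astype(np.float64).mean(axis=2)
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a 2-D grayscale image, got shape {arr.shape}")
    return arr


def read_case(
    image_path: str | Path,
    mask_path: str | Path,
    spacing_mm: tuple[float, float],
    case_id: str | None = None,
    label: str = "unknown",
    levels: int = 256,
) -> BUSCase:
    """Read an image/mask pair from PNG or TIFF files.

    8-bit inputs are taken verbatim (``levels=256``). Inputs with a wider range
    (e.g. 16-bit TIFF) are rescaled linearly so that the observed minimum maps
    to 0 and the observed maximum to ``levels - 1``; a constant image maps to 0.
    Any nonzero mask pixel is foreground.
    """
    img = _load_gray(image_path)
    msk = _load_gray(mask_path)
    if img.shape != msk.shape:
        raise FormatError(
            f"image shape {img.shape} does not match mask shape {msk.shape}"
        )
    if img.max() >= levels or img.min() < 0 or np.issubdtype(img.dtype, np.floating):
        lo, hi = float(img.min()), float(img.max())
        if hi > lo:
            img = np.round((img - lo) / (hi - lo) * (levels - 1))
        else:
            img = np.zeros_like(img)
    mask_bool = msk != 0
    if not mask_bool.any():
        raise DataError(f"{mask_path}: mask has no foreground pixels")
    cid = case_id or Path(image_path).stem
    return BUSCase(
        case_id=cid,
        image=GrayscaleImage(img.astype(np.int64), levels, tuple(spacing_mm)),
        mask=TumorMask(mask_bool, tuple(spacing_mm)),
        label=label,
    )


def write_case(case: BUSCase, image_path: str | Path, mask_path: str | Path) -> None:
    """Write an 8-bit PNG image and PNG mask (255 = foreground)."""
    if case.image.levels > 256:
        raise FormatError("write_case supports up to 256 gray levels")
    iio.imwrite(image_path, case.image.pixels.astype(np.uint8))
    iio.imwrite(mask_path, np.where(case.mask.pixels, 255, 0).astype(np.uint8))


def _nearest_indices(n_in: int, n_out: int) -> np.ndarray:
    # Output pixel centers (i + 0.5) * n_in / n_out mapped to input pixel index.
    centers = (np.arange(n_out) + 0.5) * (n_in / n_out)
    return np.clip(np.floor(centers).astype(int), 0, n_in - 1)


def resample_to_spacing(case: BUSCase, target_mm: float) -> BUSCase:
    """Resample a case to isotropic ``target_mm`` pixel spacing.

    The image is interpolated bilinearly and re-quantized to integers; the mask
    is resampled nearest-neighbor (pixel-center rule) and stays binary. A case
    already at the target spacing is returned unchanged.
    """
    if target_mm <= 0:
        raise SizingError(f"target spacing must be positive, got {target_mm}")
    sr, sc = case.image.spacing_mm
    if sr == target_mm and sc == target_mm:
        return case
    rows, cols = case.image.shape
    n_r = int(round(rows * sr / target_mm))
    n_c = int(round(cols * sc / target_mm))
    if n_r < 1 or n_c < 1:
        raise SizingError(
            f"{case.case_id}: resampling to {target_mm} mm yields {n_r}x{n_c} image"
        )
    zoom = (n_r / rows, n_c / cols)
    img = ndimage.zoom(case.image.pixels.astype(np.float64), zoom, order=1,
                       grid_mode=True, mode="nearest")
    img = np.clip(np.round(img), 0, case.image.levels - 1).astype(np.int64)
    ri = _nearest_indices(rows, n_r)
    ci = _nearest_indices(cols, n_c)
    msk = case.mask.pixels[np.ix_(ri, ci)]
    if not msk.any():
        raise SizingError(f"{case.case_id}: mask vanished during resampling")
    spacing = (float(target_mm), float(target_mm))
    return replace(
        case,
        image=GrayscaleImage(img, case.image.levels, spacing),
        mask=TumorMask(msk, spacing),
    )


def quantize_gray_levels(image: GrayscaleImage, G: int) -> GrayscaleImage:
    """Uniformly bin ``[0, levels-1]`` into ``G`` gray levels.

    The mapping ``v -> floor(v * G / levels)`` is monotone non-decreasing, maps
    0 to 0 and ``levels - 1`` to ``G - 1``, and is the identity when
    ``G == levels``.
    """
    if G < 2:
        raise ValueError(f"G must be >= 2, got {G}")
    q = (image.pixels.astype(np.int64) * G) // image.levels
    q = np.minimum(q, G - 1)
    return GrayscaleImage(q, G, image.spacing_mm)
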