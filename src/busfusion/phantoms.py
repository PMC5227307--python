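"""Synthetic breast-ultrasound phantoms.

The clinical cohort this package was designed around (110 B-mode images, 64
benign and 46 malignant tumors, tumor maximum diameters 14.7 +/- 6.0 mm,
resampled to 0.1 mm/pixel) is not publicly deposited, so this module
generates image/mask pairs that emulate its statistics well enough to
exercise every stage of the pipeline:

* **benign** tumors: smooth elliptical contours, a single homogeneous
  speckle texture inside the tumor;
* **malignant** tumors: spiculated contours (radial sinusoid perturbation
  with random phases) and several contiguous texture regions (random Voronoi
  partition of the interior), each with its own speckle correlation length,
  i.e. distinct second-order gray-level statistics, not just mean shifts.

Speckle is emulated as multiplicative Rayleigh-like noise: the envelope of
two independent smoothed Gaussian fields, normalized to unit mean.  Tumor
geometry is drawn in millimetres and only rasterized at the requested pixel
spacing, so the same seed yields the same physical tumor at any resolution.
No physical ultrasound propagation (attenuation, shadowing, TGC) is modeled:
the downstream pipeline consumes second-order gray-level statistics only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import DataError, SizingError
from .imaging import BUSCase, GrayscaleImage, TumorMask, read_case, write_case

__all__ = [
    "PhantomParams",
    "generate_phantom",
    "generate_phantom_with_regions",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

# Cohort geometry statistics emulated by the generator (mm).
COHORT_DIAMETER_MEAN_MM = 14.7
COHORT_DIAMETER_SD_MM = 6.0
_DIAMETER_RANGE_MM = (6.0, 28.0)   # truncation keeps images a tractable size
_MARGIN_MM = 2.5                   # clearance between tumor and image border

# Speckle correlation lengths (pixels at 0.1 mm spacing).  The background and
# the homogeneous benign interior differ; malignant texture regions cycle
# through scales distinct from both, giving each region its own second-order
# statistics.
_BACKGROUND_SIGMA = 2.2
_BENIGN_SIGMA = 1.0
_MALIGNANT_SIGMAS = (0.5, 1.8, 3.0, 0.8, 2.4)
_BACKGROUND_LEVEL = 0.55


@dataclass(frozen=True)
class PhantomParams:
    """Generation parameters for one synthetic case.

    ``contour_irregularity`` is the relative amplitude of the radial contour
    perturbation (0 = smooth ellipse); ``n_texture_regions`` is the number of
    Voronoi texture patches inside the tumor; ``texture_contrast`` scales the
    separation between tumor and background gray-level distributions.
    ``image_size_px`` of ``None`` sizes the image to fit the tumor with the
    standard margin.
    """

    label: str
    tumor_diameter_mm: float
    seed: int
    image_size_px: tuple[int, int] | None = None
    spacing_mm: tuple[float, float] = (0.1, 0.1)
    contour_irregularity: float | None = None
    n_texture_regions: int | None = None
    texture_contrast: float = 1.0

    def __post_init__(self) -> None:
        if self.label not in ("benign", "malignant"):
            raise DataError(f"label must be benign or malignant, got {self.label!r}")
        if self.tumor_diameter_mm <= 0:
            raise DataError("tumor diameter must be positive")
        if min(self.spacing_mm) <= 0:
            raise DataError("spacing must be strictly positive")
        if self.texture_contrast < 0:
            raise DataError("texture_contrast must be >= 0")
        # Class defaults: benign = smooth and homogeneous, malignant =
        # spiculated with several texture regions.
        if self.contour_irregularity is None:
            object.__setattr__(
                self, "contour_irregularity", 0.0 if self.label == "benign" else 0.25
            )
        if self.n_texture_regions is None:
            object.__setattr__(
                self, "n_texture_regions", 1 if self.label == "benign" else 3
            )
        if self.contour_irregularity < 0:
            raise DataError("contour_irregularity must be >= 0")
        if self.n_texture_regions < 1:
            raise DataError("n_texture_regions must be >= 1")


def _auto_size(params: PhantomParams) -> tuple[int, int]:
    s = params.spacing_mm[0]
    extent_mm = params.tumor_diameter_mm * (1.0 + params.contour_irregularity) \
        + 2.0 * _MARGIN_MM
    side = max(96, int(np.ceil(extent_mm / s)))
    return side, side


def _contour_radius_fn(rng: np.random.Generator, params: PhantomParams):
    """Radial contour rho(theta) in mm, drawn in physical units."""
    a = params.tumor_diameter_mm / 2.0
    axis_ratio = rng.uniform(1.1, 1.7)
    b = a / axis_ratio
    phi = rng.uniform(0.0, np.pi)
    n_harmonics = 3
    ks = rng.choice(np.arange(4, 10), size=n_harmonics, replace=False)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_harmonics)
    weights = rng.uniform(0.5, 1.0, size=n_harmonics)

    def rho(theta: np.ndarray) -> np.ndarray:
        t = theta - phi
        base = a * b / np.sqrt((b * np.cos(t)) ** 2 + (a * np.sin(t)) ** 2)
        if params.contour_irregularity > 0:
            s = sum(w * np.cos(k * theta + p) for w, k, p in zip(weights, ks, phases))
            s = s / np.abs(weights).sum()  # |s| <= 1
            base = base * np.maximum(1.0 + params.contour_irregularity * s, 0.25)
        return base

    return rho


def _speckle(rng: np.random.Generator, shape: tuple[int, int], sigma_px: float) -> np.ndarray:
    """Unit-mean multiplicative speckle field with correlation length sigma_px."""
    g1 = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_px)
    g2 = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_px)
    amp = np.hypot(g1, g2)
    return amp / amp.mean()


def _synthesize(params: PhantomParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render (image_uint8, mask_bool, region_map_int) for one phantom."""
    rng = np.random.default_rng(params.seed)
    rho = _contour_radius_fn(rng, params)  # physical draws come first

    size = params.image_size_px or _auto_size(params)
    rows, cols = size
    sr, sc = params.spacing_mm
    max_rho = params.tumor_diameter_mm / 2.0 * (1.0 + params.contour_irregularity)
    half_extent = min(rows * sr, cols * sc) / 2.0
    if max_rho + _MARGIN_MM * 0.8 > half_extent:
        raise SizingError(
            f"tumor (max radius {max_rho:.1f} mm) does not fit in a "
            f"{rows}x{cols} px image at {sr} mm/px with the required margin"
        )

    center = ((rows - 1) / 2.0, (cols - 1) / 2.0)
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    y = (rr - center[0]) * sr
    x = (cc - center[1]) * sc
    theta = np.arctan2(-y, x)  # rows grow downward; flip for math angles
    radius = np.hypot(y, x)
    mask = radius <= rho(theta)

    # Enforce a single 4-connected component with no holes.
    mask = ndimage.binary_fill_holes(mask)
    labeled, n = ndimage.label(mask)  # default structure = 4-connectivity
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, np.arange(1, n + 1))
        mask = labeled == (1 + int(np.argmax(sizes)))
    if not mask.any():
        raise SizingError("degenerate phantom: empty tumor mask")

    # Voronoi texture regions inside the tumor.
    region_map = np.zeros((rows, cols), dtype=np.int32)
    tumor_px = np.argwhere(mask)
    n_regions = params.n_texture_regions
    if n_regions == 1:
        region_map[mask] = 1
    else:
        seeds = tumor_px[rng.choice(len(tumor_px), size=n_regions, replace=False)]
        d2 = ((tumor_px[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
        region_map[tuple(tumor_px.T)] = 1 + np.argmin(d2, axis=1)

    # Mean gray level per compartment (fraction of dynamic range).
    c = params.texture_contrast
    mu_bg = _BACKGROUND_LEVEL
    mu_tumor = max(0.08, mu_bg * (1.0 - 0.55 * c))
    if params.label == "benign":
        sigmas = [_BENIGN_SIGMA] * n_regions
    else:
        sigmas = [_MALIGNANT_SIGMAS[k % len(_MALIGNANT_SIGMAS)] for k in range(n_regions)]
    region_mu = mu_tumor * (1.0 + rng.uniform(-0.05, 0.05, size=n_regions) * c)

    image = mu_bg * _speckle(rng, (rows, cols), _BACKGROUND_SIGMA)
    for k in range(n_regions):
        sel = region_map == (k + 1)
        image[sel] = region_mu[k] * _speckle(rng, (rows, cols), sigmas[k])[sel]
    image = np.clip(image, 0.0, 1.0)
    return np.round(image * 255).astype(np.uint8), mask, region_map


def generate_phantom(params: PhantomParams, case_id: str | None = None) -> BUSCase:
    """Generate one synthetic case; deterministic for a fixed seed."""
    image, mask, _ = _synthesize(params)
    cid = case_id or f"{params.label}_{params.seed}"
    return BUSCase(
        case_id=cid,
        image=GrayscaleImage(image.astype(np.int64), 256, params.spacing_mm),
        mask=TumorMask(mask, params.spacing_mm),
        label=params.label,
    )


def generate_phantom_with_regions(
    params: PhantomParams, case_id: str | None = None
) -> tuple[BUSCase, np.ndarray]:
    """Like :func:`generate_phantom`, also returning the texture-region map
    (0 = background, 1..n = tumor texture regions)."""
    image, mask, region_map = _synthesize(params)
    cid = case_id or f"{params.label}_{params.seed}"
    case = BUSCase(
        case_id=cid,
        image=GrayscaleImage(image.astype(np.int64), 256, params.spacing_mm),
        mask=TumorMask(mask, params.spacing_mm),
        label=params.label,
    )
    return case, region_map


def generate_cohort(n_benign: int, n_malignant: int, seed: int,
                    texture_contrast: float = 1.0) -> list[BUSCase]:
    """Generate a labeled cohort with per-case derived seeds.

    Tumor maximum diameters are drawn from a truncated normal emulating the
    clinical cohort (mean 14.7 mm, sd 6.0 mm, truncated to 6-28 mm); malignant
    contour irregularity and texture-region counts vary case to case.
    """
    if n_benign < 0 or n_malignant < 0:
        raise ValueError("case counts must be non-negative")
    if n_benign + n_malignant < 1:
        raise ValueError("cohort must contain at least one case")
    rng = np.random.default_rng(seed)
    cases: list[BUSCase] = []
    specs = [("benign", i) for i in range(n_benign)] + \
            [("malignant", i) for i in range(n_malignant)]
    for label, i in specs:
        lo, hi = _DIAMETER_RANGE_MM
        diam = float(np.clip(rng.normal(COHORT_DIAMETER_MEAN_MM, COHORT_DIAMETER_SD_MM),
                             lo, hi))
        case_seed = int(rng.integers(0, 2**31 - 1))
        if label == "malignant":
            irregularity = float(rng.uniform(0.18, 0.32))
            n_regions = int(rng.integers(2, 5))
        else:
            irregularity, n_regions = 0.0, 1
        params = PhantomParams(
            label=label,
            tumor_diameter_mm=diam,
            seed=case_seed,
            contour_irregularity=irregularity,
            n_texture_regions=n_regions,
            texture_contrast=texture_contrast,
        )
        cases.append(generate_phantom(params, case_id=f"{label}_{i:03d}"))
    return cases


def write_cohort(cases: list[BUSCase], out_dir: str | Path) -> Path:
    """Write a cohort as PNG image/mask pairs plus an index CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for case in cases:
        img_name = f"{case.case_id}_image.png"
        msk_name = f"{case.case_id}_mask.png"
        write_case(case, out / img_name, out / msk_name)
        rows.append(
            {
                "case_id": case.case_id,
                "label": case.label,
                "image_file": img_name,
                "mask_file": msk_name,
                "spacing_row_mm": case.image.spacing_mm[0],
                "spacing_col_mm": case.image.spacing_mm[1],
            }
        )
    csv_path = out / "cohort.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    return csv_path


def read_cohort(cohort_dir: str | Path) -> list[BUSCase]:
    """Read a cohort written by :func:`write_cohort`."""
    root = Path(cohort_dir)
    csv_path = root / "cohort.csv"
    if not csv_path.exists():
        raise DataError(f"no cohort.csv under {root}")
    table = pd.read_csv(csv_path)
    cases = []
    for rec in table.itertuples():
        cases.append(
            read_case(
                root / rec.image_file,
                root / rec.mask_file,
                (rec.spacing_row_mm, rec.spacing_col_mm),
                case_id=rec.case_id,
                label=rec.label,
            )
        )
    return cases
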