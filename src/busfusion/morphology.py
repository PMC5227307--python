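"""Whole-tumor morphological features MF1..MF18.

Ten features come directly from the outlined tumor (area, perimeter, form
factor, roundness, aspect ratio, convexity, solidity, extent, undulation,
compactness), six from the best-fit ellipse matched to the region's second
moments, and two from the normalized radial length (NRL) of the boundary.

Geometric conventions:

* the boundary is the ordered 8-connected pixel chain traced around the
  foreground (Moore neighbor tracing); the perimeter is its polygonal length
  with diagonal steps counted as sqrt(2) pixel units;
* the tumor center used for the NRL is the area centroid of the foreground;
* angles are reported in degrees in [0, 180), measured counterclockwise from
  the horizontal (column) axis with the row axis pointing up, i.e. axis
  orientation modulo 180 degrees;
* lengths are in mm, areas in mm^2 (isotropic pixel spacing required).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage.morphology import convex_hull_image

from .errors import DataError, DegenerateShapeError
from .imaging import TumorMask
from .roi import bounding_rectangle

__all__ = [
    "MORPH_FEATURES",
    "trace_boundary",
    "basic_morph_features",
    "best_fit_ellipse",
    "ellipse_features",
    "nrl_features",
    "morph_vector",
    "BestFitEllipse",
]

MORPH_FEATURES: tuple[str, ...] = tuple(f"MF{i}" for i in range(1, 19))

# Moore neighborhood in clockwise order starting east (row-down image coords).
_MOORE = np.array(
    [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]
)


def trace_boundary(mask: TumorMask | np.ndarray) -> np.ndarray:
    """Ordered (N, 2) array of boundary pixel coordinates (row, col).

    Moore-neighbor tracing with Jacob's stopping criterion; works for any
    8-connected foreground of more than one pixel.  A single-pixel mask
    returns that pixel.
    """
    px = mask.pixels if isinstance(mask, TumorMask) else np.asarray(mask, bool)
    if not px.any():
        raise DataError("cannot trace an empty mask")
    if px.sum() == 1:
        return np.argwhere(px)
    pad = np.pad(px, 1)
    # Start at the first foreground pixel in raster order; its west neighbor
    # is guaranteed background.
    start = tuple(np.argwhere(pad)[0])
    boundary = [start]
    # Index into _MOORE of the backtrack direction (west = 4).
    prev_dir = 4
    cur = start
    first_move = None
    max_steps = 4 * pad.size
    for _ in range(max_steps):
        found = False
        # Scan clockwise starting just after the backtrack direction.
        for k in range(1, 9):
            d = (prev_dir + k) % 8
            nxt = (cur[0] + _MOORE[d][0], cur[1] + _MOORE[d][1])
            if pad[nxt]:
                move = d
                found = True
                break
        if not found:  # isolated pixel (cannot happen: handled above)
            break
        if cur == start and first_move is not None and move == first_move:
            break  # back at the start, leaving in the same direction: done
        if first_move is None:
            first_move = move
        cur = nxt
        # New backtrack = direction pointing back to the previous pixel.
        prev_dir = (move + 4) % 8
        boundary.append(cur)
    # Drop the duplicated closing vertex if present.
    if len(boundary) > 1 and boundary[-1] == boundary[0]:
        boundary.pop()
    return np.asarray(boundary) - 1  # undo padding offset


def _polygon_length(points: np.ndarray, closed: bool = True) -> float:
    diffs = np.diff(points.astype(float), axis=0)
    length = float(np.hypot(diffs[:, 0], diffs[:, 1]).sum())
    if closed and len(points) > 1:
        d = points[0] - points[-1]
        length += float(np.hypot(*d.astype(float)))
    return length


def _spacing(mask: TumorMask) -> float:
    sr, sc = mask.spacing_mm
    if abs(sr - sc) > 1e-9:
        raise DataError("morphology requires isotropic spacing; resample first")
    return float(sr)


def _single_component(mask: TumorMask, on_multicomponent: str) -> TumorMask:
    labeled, n = ndimage.label(mask.pixels)
    if n <= 1:
        return mask
    if on_multicomponent == "largest":
        sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, np.arange(1, n + 1))
        keep = 1 + int(np.argmax(sizes))
        return TumorMask(labeled == keep, mask.spacing_mm)
    raise DataError(f"mask has {n} connected components; expected one")


def _hull_vertices(boundary: np.ndarray) -> np.ndarray:
    try:
        hull = ConvexHull(boundary.astype(float))
    except QhullError as exc:
        raise DegenerateShapeError(f"degenerate (collinear) region: {exc}") from exc
    return boundary[hull.vertices]


def _max_diameter(points: np.ndarray) -> tuple[float, np.ndarray]:
    """Maximum pairwise distance among points and its unit direction."""
    pts = points.astype(float)
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    a, b = np.unravel_index(np.argmax(d2), d2.shape)
    vec = pts[b] - pts[a]
    dist = float(np.sqrt(d2[a, b]))
    return dist, vec / (dist if dist > 0 else 1.0)


def _dist_to_segments(points: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Min distance from each point to the closed polygon given by vertices."""
    p = points.astype(float)
    v0 = vertices.astype(float)
    v1 = np.roll(v0, -1, axis=0)
    seg = v1 - v0                                     # (S, 2)
    seg_len2 = (seg**2).sum(axis=1)
    seg_len2[seg_len2 == 0] = 1.0
    diff = p[:, None, :] - v0[None, :, :]             # (N, S, 2)
    t = np.clip((diff * seg).sum(axis=2) / seg_len2, 0.0, 1.0)
    proj = v0[None] + t[..., None] * seg[None]
    return np.sqrt(((p[:, None, :] - proj) ** 2).sum(axis=2)).min(axis=1)


def _count_runs(flags: np.ndarray) -> int:
    """Number of maximal True runs in a circular boolean sequence."""
    if flags.all():
        return 1
    if not flags.any():
        return 0
    # Rotate so the sequence starts on a False; then count rising edges.
    start = int(np.argmin(flags))
    rolled = np.roll(flags, -start)
    return int((np.diff(rolled.astype(int)) == 1).sum())


def basic_morph_features(
    mask: TumorMask,
    undulation_threshold_mm: float = 0.3,
    on_multicomponent: str = "error",
) -> pd.Series:
    """MF1..MF10: direct tumor descriptors.

    Undulation (MF9) is operationalized as the number of maximal boundary runs
    whose distance from the convex hull exceeds ``undulation_threshold_mm``,
    i.e. the number of distinct concavity segments of the contour.
    """
    mask = _single_component(mask, on_multicomponent)
    s = _spacing(mask)
    boundary = trace_boundary(mask)
    if len(boundary) < 3:
        raise DegenerateShapeError("mask too small for morphological analysis")
    area = mask.area_px * s * s
    perimeter = _polygon_length(boundary) * s
    hull_v = _hull_vertices(boundary)
    hull_perimeter = _polygon_length(hull_v) * s
    hull_area = float(convex_hull_image(mask.pixels).sum()) * s * s
    max_diam_px, direction = _max_diameter(hull_v)
    max_diam = max_diam_px * s
    ortho = np.array([-direction[1], direction[0]])
    proj = boundary.astype(float) @ ortho
    width = (proj.max() - proj.min()) * s
    r0, c0, h, w = bounding_rectangle(mask)
    dists = _dist_to_segments(boundary, hull_v) * s
    undulation = _count_runs(dists > undulation_threshold_mm)
    return pd.Series(
        {
            "MF1": area,
            "MF2": perimeter,
            "MF3": 4.0 * np.pi * area / perimeter**2,
            "MF4": 4.0 * area / (np.pi * max_diam**2),
            "MF5": max_diam / width if width > 0 else np.inf,
            "MF6": hull_perimeter / perimeter,
            "MF7": area / hull_area,
            "MF8": mask.area_px / (h * w),
            "MF9": float(undulation),
            "MF10": perimeter**2 / area,
        }
    )


class BestFitEllipse:
    """Moment-matched ellipse of the tumor region (same area, same axes ratio).

    Axis lengths are full lengths in pixels; ``orientation_deg`` follows the
    package angle convention (degrees in [0, 180), counterclockwise from the
    column axis with rows pointing up).
    """

    def __init__(self, center: tuple[float, float], major_px: float,
                 minor_px: float, orientation_deg: float):
        if not (major_px >= minor_px > 0):
            raise DegenerateShapeError("ellipse axes must satisfy major >= minor > 0")
        self.center = center
        self.major_px = major_px
        self.minor_px = minor_px
        self.orientation_deg = orientation_deg % 180.0

    def rasterize(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean image of the ellipse interior on a pixel grid."""
        rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
        dy = -(rr - self.center[0])  # row axis points down; flip to math-up
        dx = cc - self.center[1]
        th = np.deg2rad(self.orientation_deg)
        u = dx * np.cos(th) + dy * np.sin(th)
        v = -dx * np.sin(th) + dy * np.cos(th)
        return (u / (self.major_px / 2)) ** 2 + (v / (self.minor_px / 2)) ** 2 <= 1.0


def best_fit_ellipse(mask: TumorMask) -> BestFitEllipse:
    """Ellipse matching the region's centroid, orientation, axis ratio and area."""
    coords = np.argwhere(mask.pixels).astype(float)
    if len(coords) < 3:
        raise DegenerateShapeError("mask too small to fit an ellipse")
    centroid = coords.mean(axis=0)
    d = coords - centroid
    mu_rr = (d[:, 0] ** 2).mean() + 1.0 / 12.0  # pixel extent correction
    mu_cc = (d[:, 1] ** 2).mean() + 1.0 / 12.0
    mu_rc = (d[:, 0] * d[:, 1]).mean()
    cov = np.array([[mu_cc, -mu_rc], [-mu_rc, mu_rr]])  # x = col, y = -row
    evals, evecs = np.linalg.eigh(cov)
    # A one-pixel-thick (collinear) region has exactly the single-pixel
    # moment 1/12 along its minor axis.
    if evals[0] <= 1.0 / 12.0 + 1e-9:
        raise DegenerateShapeError("collinear region: cannot fit an ellipse")
    # Moment-equivalent full axis lengths, then rescale to match region area.
    major = 4.0 * np.sqrt(evals[1])
    minor = 4.0 * np.sqrt(evals[0])
    scale = np.sqrt(len(coords) / (np.pi * major * minor / 4.0))
    major *= scale
    minor *= scale
    vx, vy = evecs[:, 1]  # principal axis in (x, y-up) coords
    angle = np.degrees(np.arctan2(vy, vx)) % 180.0
    return BestFitEllipse((centroid[0], centroid[1]), major, minor, angle)


def _ramanujan_perimeter(semi_a: float, semi_b: float) -> float:
    return np.pi * (3 * (semi_a + semi_b)
                    - np.sqrt((3 * semi_a + semi_b) * (semi_a + 3 * semi_b)))


def ellipse_features(mask: TumorMask) -> pd.Series:
    """MF11..MF16: best-fit-ellipse descriptors.

    MF14 uses Ramanujan's closed-form ellipse-perimeter approximation; MF15 is
    the area overlap |ellipse & tumor| / |ellipse | tumor| of the rasterized
    regions (intersection over union).
    """
    s = _spacing(mask)
    ell = best_fit_ellipse(mask)
    boundary = trace_boundary(mask)
    perimeter = _polygon_length(boundary) * s
    ell_perimeter = _ramanujan_perimeter(ell.major_px / 2, ell.minor_px / 2) * s
    raster = ell.rasterize(mask.shape)
    inter = float(np.logical_and(raster, mask.pixels).sum())
    union = float(np.logical_or(raster, mask.pixels).sum())
    return pd.Series(
        {
            "MF11": ell.major_px * s,
            "MF12": ell.minor_px * s,
            "MF13": ell.major_px / ell.minor_px,
            "MF14": ell_perimeter / perimeter,
            "MF15": inter / union if union > 0 else 0.0,
            "MF16": ell.orientation_deg,
        }
    )


def nrl_features(mask: TumorMask, n_bins: int = 10) -> pd.Series:
    """MF17 (NRL entropy) and MF18 (NRL variance).

    The normalized radial length is the distance from the area centroid to
    each traced boundary pixel, divided by its maximum; MF17 is the Shannon
    entropy (natural log) of its ``n_bins``-bin histogram on [0, 1] and MF18
    its (population) variance.
    """
    boundary = trace_boundary(mask)
    if len(boundary) < 3:
        raise DegenerateShapeError("mask too small for NRL analysis")
    centroid = np.argwhere(mask.pixels).mean(axis=0)
    radii = np.sqrt(((boundary - centroid) ** 2).sum(axis=1))
    rmax = radii.max()
    if rmax <= 0:
        raise DegenerateShapeError("degenerate boundary: zero maximum radius")
    nrl = radii / rmax
    counts, _ = np.histogram(nrl, bins=n_bins, range=(0.0, 1.0))
    p = counts[counts > 0] / counts.sum()
    entropy = float(-(p * np.log(p)).sum())
    return pd.Series({"MF17": entropy, "MF18": float(nrl.var())})


def morph_vector(
    mask: TumorMask,
    undulation_threshold_mm: float = 0.3,
    nrl_bins: int = 10,
    on_multicomponent: str = "error",
) -> pd.Series:
    """Full MF1..MF18 morphology vector for one tumor."""
    mask = _single_component(mask, on_multicomponent)
    parts = [
        basic_morph_features(mask, undulation_threshold_mm),
        ellipse_features(mask),
        nrl_features(mask, nrl_bins),
    ]
    vec = pd.concat(parts)
    return vec.reindex(list(MORPH_FEATURES))
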