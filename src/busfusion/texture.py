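"""Gray-level co-occurrence texture analysis.

For every ROI, co-occurrence matrices are accumulated at four pixel distances
(d = 1..4) and four orientations (theta = 0, 45, 90, 135 degrees) — sixteen
GLCMs — and twenty scalar features (TF1..TF20) are computed from each, giving
the 320-value texture vector of the ROI.

Orientation convention: 0 deg pairs a pixel with its right neighbor at
distance d, 90 deg with the pixel d rows above, 45 deg up-right, 135 deg
up-left (the usual co-occurrence convention with image rows growing
downwards).  With symmetric accumulation (the default) each offset and its
opposite are pooled, so the matrix is symmetric and Haralick's marginal-based
features are well defined.

Feature set (0-based gray levels i, j in [0, G-1]; natural logarithms;
0*log(0) := 0):

======  =============================================  ==================================
code    name                                           formula sketch
======  =============================================  ==================================
TF1     autocorrelation                                sum i*j*P(i,j)
TF2     contrast                                       sum (i-j)^2 P
TF3     correlation                                    (TF1 - mu_x mu_y)/(s_x s_y)
TF4     cluster prominence                             sum (i+j-mu_x-mu_y)^4 P
TF5     cluster shade                                  sum (i+j-mu_x-mu_y)^3 P
TF6     dissimilarity                                  sum |i-j| P
TF7     energy (angular second moment)                 sum P^2
TF8     entropy                                        -sum P ln P
TF9     homogeneity (inverse difference moment)        sum P/(1+(i-j)^2)
TF10    maximum probability                            max P
TF11    sum of squares: variance                       sum (i-mu_x)^2 P
TF12    sum average                                    sum k p_{x+y}(k)
TF13    sum entropy                                    -sum p_{x+y} ln p_{x+y}
TF14    sum variance                                   sum (k-TF12)^2 p_{x+y}(k)
TF15    difference variance                            Var of p_{x-y}
TF16    difference entropy                             -sum p_{x-y} ln p_{x-y}
TF17    information measure of correlation I           (HXY-HXY1)/max(HX,HY)
TF18    information measure of correlation II          sqrt(1-exp(-2(HXY2-HXY)))
TF19    inverse difference normalized                  sum P/(1+|i-j|/G)
TF20    inverse difference moment normalized           sum P/(1+(i-j)^2/G^2)
======  =============================================  ==================================

Degenerate limits are defined so that every feature is finite on every
achievable patch: on a constant patch TF3 := 1 (perfect correlation) and
TF17 := TF18 := 0 (zero marginal entropy); TF15 follows the
difference-histogram variance variant.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from .errors import DataError
from .imaging import GrayscaleImage, quantize_gray_levels
from .roi import Tile

__all__ = [
    "GLCMatrix",
    "DEFAULT_DISTANCES",
    "DEFAULT_ANGLES_DEG",
    "FEATURE_CODES",
    "feature_names",
    "compute_glcm",
    "glcm_features",
    "texture_vector",
    "texture_table",
]

DEFAULT_DISTANCES: tuple[int, ...] = (1, 2, 3, 4)
DEFAULT_ANGLES_DEG: tuple[int, ...] = (0, 45, 90, 135)
FEATURE_CODES: tuple[str, ...] = tuple(f"TF{i}" for i in range(1, 21))
_EPS = 1e-12


@dataclass(frozen=True)
class GLCMatrix:
    """Normalized co-occurrence matrix at one (distance, orientation) offset."""

    P: np.ndarray
    d: int
    theta: int
    G: int

    def __post_init__(self) -> None:
        if self.P.shape != (self.G, self.G):
            raise DataError(f"GLCM shape {self.P.shape} does not match G={self.G}")
        if abs(float(self.P.sum()) - 1.0) > 1e-8 or self.P.min() < 0:
            raise DataError("GLCM must be a normalized probability matrix")


def feature_names(
    d_set: tuple[int, ...] = DEFAULT_DISTANCES,
    theta_set: tuple[int, ...] = DEFAULT_ANGLES_DEG,
) -> list[str]:
    """Canonical texture-feature column names, e.g. ``TF1_4,90``.

    The subscript gives the GLCM offset: distance d, then orientation theta in
    degrees.  Order: distances outer, orientations inner, TF1..TF20 innermost.
    """
    return [
        f"{code}_{d},{theta}"
        for d in d_set
        for theta in theta_set
        for code in FEATURE_CODES
    ]


# Unit offsets (drow, dcol) per orientation; diagonals use the Chebyshev
# convention of Haralick's nearest-neighbor sets, so distance d at 45 deg is
# the offset (-d, d), not a rounded Euclidean step.
_OFFSETS: dict[int, tuple[int, int]] = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def _pair_counts(patch: np.ndarray, drow: int, dcol: int, G: int) -> np.ndarray:
    """G x G counts of gray-level pairs (reference, neighbor) at one offset."""
    rows, cols = patch.shape
    r0, r1 = max(0, -drow), min(rows, rows - drow)
    c0, c1 = max(0, -dcol), min(cols, cols - dcol)
    if r1 <= r0 or c1 <= c0:
        return np.zeros((G, G), dtype=np.int64)
    ref = patch[r0:r1, c0:c1]
    nbr = patch[r0 + drow:r1 + drow, c0 + dcol:c1 + dcol]
    codes = ref.ravel().astype(np.int64) * G + nbr.ravel()
    return np.bincount(codes, minlength=G * G).reshape(G, G)


def _raw_glcms(
    patch: np.ndarray,
    d_set: tuple[int, ...],
    theta_set: tuple[int, ...],
    G: int,
    symmetric: bool,
) -> np.ndarray:
    """Un-normalized pair counts, shape (G, G, len(d_set), len(theta_set))."""
    patch = np.ascontiguousarray(patch)
    if patch.size == 0:
        raise DataError("empty patch")
    if patch.min() < 0 or patch.max() >= G:
        raise DataError(f"patch values must lie in [0, {G - 1}]")
    out = np.empty((G, G, len(d_set), len(theta_set)), dtype=np.float64)
    for a, d in enumerate(d_set):
        for b, theta in enumerate(theta_set):
            try:
                ur, uc = _OFFSETS[theta]
            except KeyError:
                raise ValueError(f"unsupported orientation {theta}; use 0/45/90/135") from None
            counts = _pair_counts(patch, ur * d, uc * d, G)
            if symmetric:
                counts = counts + counts.T
            out[:, :, a, b] = counts
    return out


def compute_glcm(
    patch: np.ndarray, d: int, theta: int, G: int, symmetric: bool = True
) -> GLCMatrix:
    """Normalized GLCM of an integer patch at offset (d, theta degrees)."""
    counts = _raw_glcms(np.asarray(patch), (d,), (theta,), G, symmetric)[:, :, 0, 0]
    total = counts.sum()
    if total == 0:
        raise DataError(
            f"patch of shape {np.asarray(patch).shape} has no pixel pair at "
            f"offset (d={d}, theta={theta})"
        )
    return GLCMatrix(counts / total, d, theta, G)


@lru_cache(maxsize=8)
def _grids(G: int):
    """Precomputed index grids and aggregation matrices for gray-level count G."""
    i, j = np.meshgrid(np.arange(G), np.arange(G), indexing="ij")
    i = i.ravel()
    j = j.ravel()
    # One-hot aggregators: p_{x+y}(k) = S_plus @ P.ravel(), likewise x-y.
    s_plus = np.zeros((2 * G - 1, G * G))
    s_plus[i + j, np.arange(G * G)] = 1.0
    s_diff = np.zeros((G, G * G))
    s_diff[np.abs(i - j), np.arange(G * G)] = 1.0
    weights = {
        "ij": (i * j).astype(np.float64),
        "diff2": ((i - j) ** 2).astype(np.float64),
        "absdiff": np.abs(i - j).astype(np.float64),
        "homog": 1.0 / (1.0 + (i - j) ** 2),
        "idn": 1.0 / (1.0 + np.abs(i - j) / G),
        "idmn": 1.0 / (1.0 + (i - j) ** 2 / G**2),
    }
    return i, j, s_plus, s_diff, weights


def _xlogx(p: np.ndarray) -> np.ndarray:
    """p * ln(p) with the 0*ln(0) = 0 convention."""
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log(p[nz])
    return out


def _features_batch(P: np.ndarray) -> np.ndarray:
    """TF1..TF20 for a stack of normalized GLCMs.

    Parameters
    ----------
    P : (G, G, M) array of M normalized co-occurrence matrices.

    Returns
    -------
    (20, M) array of feature values.
    """
    G, _, M = P.shape
    i, j, s_plus, s_diff, w = _grids(G)
    flat = P.reshape(G * G, M)

    px = P.sum(axis=1)  # (G, M) marginal over columns
    py = P.sum(axis=0)
    lv = np.arange(G, dtype=np.float64)[:, None]
    mu_x = (lv * px).sum(axis=0)
    mu_y = (lv * py).sum(axis=0)
    var_x = ((lv - mu_x) ** 2 * px).sum(axis=0)
    var_y = ((lv - mu_y) ** 2 * py).sum(axis=0)
    sd_xy = np.sqrt(var_x * var_y)

    p_plus = s_plus @ flat  # (2G-1, M)
    p_diff = s_diff @ flat  # (G, M)

    out = np.empty((20, M))
    out[0] = w["ij"] @ flat                                   # TF1
    out[1] = w["diff2"] @ flat                                # TF2
    corr = np.ones(M)
    ok = sd_xy > _EPS
    corr[ok] = (out[0, ok] - mu_x[ok] * mu_y[ok]) / sd_xy[ok]
    out[2] = corr                                             # TF3
    cdev = (i[:, None] + j[:, None]) - (mu_x + mu_y)          # (G*G, M)
    out[3] = (cdev**4 * flat).sum(axis=0)                     # TF4
    out[4] = (cdev**3 * flat).sum(axis=0)                     # TF5
    out[5] = w["absdiff"] @ flat                              # TF6
    out[6] = (flat**2).sum(axis=0)                            # TF7
    hxy = -_xlogx(flat).sum(axis=0)
    out[7] = hxy                                              # TF8
    out[8] = w["homog"] @ flat                                # TF9
    out[9] = flat.max(axis=0)                                 # TF10
    out[10] = ((i[:, None] - mu_x) ** 2 * flat).sum(axis=0)   # TF11
    k_plus = np.arange(2 * G - 1, dtype=np.float64)[:, None]
    sa = (k_plus * p_plus).sum(axis=0)
    out[11] = sa                                              # TF12
    out[12] = -_xlogx(p_plus).sum(axis=0)                     # TF13
    out[13] = ((k_plus - sa) ** 2 * p_plus).sum(axis=0)       # TF14
    k_diff = np.arange(G, dtype=np.float64)[:, None]
    mu_d = (k_diff * p_diff).sum(axis=0)
    out[14] = ((k_diff - mu_d) ** 2 * p_diff).sum(axis=0)     # TF15
    out[15] = -_xlogx(p_diff).sum(axis=0)                     # TF16
    hx = -_xlogx(px).sum(axis=0)
    hy = -_xlogx(py).sum(axis=0)
    pxpy = px[:, None, :] * py[None, :, :]                    # (G, G, M)
    log_pxpy = np.zeros_like(pxpy)
    nz = pxpy > 0
    log_pxpy[nz] = np.log(pxpy[nz])
    hxy1 = -(P * log_pxpy).sum(axis=(0, 1))
    hxy2 = -(pxpy * log_pxpy).sum(axis=(0, 1))
    hmax = np.maximum(hx, hy)
    imc1 = np.zeros(M)
    ok = hmax > _EPS
    imc1[ok] = (hxy[ok] - hxy1[ok]) / hmax[ok]
    out[16] = imc1                                            # TF17
    out[17] = np.sqrt(np.clip(1.0 - np.exp(-2.0 * (hxy2 - hxy)), 0.0, None))  # TF18
    out[18] = w["idn"] @ flat                                 # TF19
    out[19] = w["idmn"] @ flat                                # TF20
    return out


def glcm_features(glcm: GLCMatrix) -> pd.Series:
    """The twenty texture features of one normalized GLCM."""
    values = _features_batch(glcm.P[:, :, None])[:, 0]
    return pd.Series(values, index=list(FEATURE_CODES))


def _patch_vector(
    patch: np.ndarray,
    d_set: tuple[int, ...],
    theta_set: tuple[int, ...],
    G: int,
    symmetric: bool,
) -> np.ndarray:
    counts = _raw_glcms(patch, d_set, theta_set, G, symmetric)
    M = len(d_set) * len(theta_set)
    counts = counts.reshape(G * G, M)
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        bad = int(np.argmin(totals))
        d = d_set[bad // len(theta_set)]
        t = theta_set[bad % len(theta_set)]
        raise DataError(
            f"patch of shape {patch.shape} has no pixel pair at offset (d={d}, theta={t})"
        )
    P = (counts / totals).reshape(G, G, M)
    return _features_batch(P).T.ravel()  # (d,theta)-major, TF1..20 inner


def texture_vector(
    image: GrayscaleImage,
    tile: Tile | tuple[int, int, int, int],
    d_set: tuple[int, ...] = DEFAULT_DISTANCES,
    theta_set: tuple[int, ...] = DEFAULT_ANGLES_DEG,
    G: int = 32,
    symmetric: bool = True,
) -> pd.Series:
    """Full texture feature vector of one ROI.

    ``tile`` is a square :class:`Tile` or a (row0, col0, height, width)
    rectangle (used for the conventional bounding-box ROI).  The image is
    quantized to ``G`` gray levels if necessary (global uniform binning).
    A constant patch is not an error: features take their limit values.
    """
    if image.levels != G:
        image = quantize_gray_levels(image, G)
    if isinstance(tile, Tile):
        sl = tile.slices()
    else:
        r0, c0, h, w = tile
        sl = (slice(r0, r0 + h), slice(c0, c0 + w))
    patch = image.pixels[sl]
    if patch.size == 0:
        raise DataError("tile lies outside the image")
    values = _patch_vector(patch, tuple(d_set), tuple(theta_set), G, symmetric)
    return pd.Series(values, index=feature_names(tuple(d_set), tuple(theta_set)))


def texture_table(
    image: GrayscaleImage,
    tiles: list[Tile],
    case_id: str = "",
    d_set: tuple[int, ...] = DEFAULT_DISTANCES,
    theta_set: tuple[int, ...] = DEFAULT_ANGLES_DEG,
    G: int = 32,
    symmetric: bool = True,
) -> pd.DataFrame:
    """Per-ROI texture features for all tiles of one tumor.

    Returns a frame with case/tile coordinates followed by the canonical
    feature columns; one row per tile.
    """
    if image.levels != G:
        image = quantize_gray_levels(image, G)
    d_set, theta_set = tuple(d_set), tuple(theta_set)
    rows = np.empty((len(tiles), 20 * len(d_set) * len(theta_set)))
    for k, tile in enumerate(tiles):
        patch = image.pixels[tile.slices()]
        rows[k] = _patch_vector(patch, d_set, theta_set, G, symmetric)
    df = pd.DataFrame(rows, columns=feature_names(d_set, theta_set))
    df.insert(0, "case_id", case_id)
    df.insert(1, "row0", [t.row0 for t in tiles])
    df.insert(2, "col0", [t.col0 for t in tiles])
    df.insert(3, "side_px", [t.side_px for t in tiles])
    return df
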