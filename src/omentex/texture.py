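"""ROI rasterization and texture features of omental CT slices.

Images are 2D integer arrays of stored gray values (Hounsfield units + 1024,
so omental fat sits near 920).  A region of interest is a simple polygon in
continuous 0-based pixel coordinates (x rightward, y downward); a pixel
belongs to the ROI iff its center (x+0.5, y+0.5) lies inside the polygon.

Seven per-patient features are computed from the ROI gray values: four
first-order histogram statistics (mean, sample SD, skewness, excess
kurtosis), first-order Shannon entropy in bits, and two gray-level
co-occurrence matrix (GLCM) functionals, contrast and correlation.  GLCM
pairs are restricted to the mask: both pixels of an offset pair must lie
inside the ROI.

Degenerate statistics (skewness/kurtosis/correlation of a constant ROI)
are reported as NaN, never coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import shapely

__all__ = [
    "GLCM",
    "TextureFeatureSet",
    "rasterize_polygon",
    "first_order_stats",
    "histogram_entropy",
    "compute_glcm",
    "glcm_contrast",
    "glcm_correlation",
    "extract_features",
    "CANONICAL_DIRECTIONS",
]

#: (dy, dx) offsets for the four canonical directions 0, 45, 90, 135 degrees
#: at unit distance (y axis points down, so 45 degrees is up-right).
CANONICAL_DIRECTIONS: tuple[tuple[int, int], ...] = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

MAX_GRAY = 65535


def _as_image(image) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError(f"image must be 2D, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("image must hold integer gray values")
        arr = np.round(arr).astype(np.int64)
    if arr.size and (arr.min() < 0 or arr.max() > MAX_GRAY):
        raise ValueError(f"gray values must lie in [0, {MAX_GRAY}]")
    return arr


def rasterize_polygon(vertices: Sequence[Sequence[float]], image_shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a simple polygon to a boolean mask.

    A pixel (row y, column x) is inside iff its center ``(x + 0.5, y + 0.5)``
    lies strictly inside the polygon.  The mask is clipped to the image.

    Parameters
    ----------
    vertices
        Ordered ``(x, y)`` vertex coordinates, at least 3, forming a
        non-self-intersecting polygon.
    image_shape
        ``(n_rows, n_cols)`` of the target image.

    Raises
    ------
    ValueError
        For fewer than 3 vertices, a self-intersecting polygon, or a
        polygon whose rasterization is empty.
    """
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
        raise ValueError("polygon needs >= 3 (x, y) vertices")
    poly = shapely.Polygon(verts)
    if not poly.is_valid:
        raise ValueError("polygon is self-intersecting or degenerate")
    nrows, ncols = int(image_shape[0]), int(image_shape[1])
    if nrows <= 0 or ncols <= 0:
        raise ValueError("image_shape must be positive")

    mask = np.zeros((nrows, ncols), dtype=bool)
    minx, miny, maxx, maxy = poly.bounds
    c0 = max(int(np.floor(minx - 0.5)), 0)
    c1 = min(int(np.ceil(maxx)) + 1, ncols)
    r0 = max(int(np.floor(miny - 0.5)), 0)
    r1 = min(int(np.ceil(maxy)) + 1, nrows)
    if c1 > c0 and r1 > r0:
        xs = np.arange(c0, c1) + 0.5
        ys = np.arange(r0, r1) + 0.5
        gx, gy = np.meshgrid(xs, ys)
        inside = shapely.contains_xy(poly, gx.ravel(), gy.ravel())
        mask[r0:r1, c0:c1] = inside.reshape(r1 - r0, c1 - c0)
    if not mask.any():
        raise ValueError("polygon rasterized to an empty mask")
    return mask


def _roi_values(image, mask) -> np.ndarray:
    arr = _as_image(image)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != arr.shape:
        raise ValueError("mask shape must match image shape")
    vals = arr[mask]
    if vals.size == 0:
        raise ValueError("empty ROI mask")
    return vals


def first_order_stats(image, mask) -> tuple[float, float, float, float]:
    """Mean, sample SD (n-1), moment skewness and excess kurtosis of the ROI.

    Skewness is the Fisher-Pearson coefficient ``m3 / m2**1.5`` and kurtosis
    the excess form ``m4 / m2**2 - 3``, both on bias-uncorrected central
    moments.  A constant ROI yields NaN skewness and kurtosis.
    """
    vals = _roi_values(image, mask).astype(float)
    n = vals.size
    average = float(vals.mean())
    std_dev = float(vals.std(ddof=1)) if n >= 2 else float("nan")
    centered = vals - average
    m2 = float(np.mean(centered**2))
    if n >= 3 and m2 > 0:
        m3 = float(np.mean(centered**3))
        m4 = float(np.mean(centered**4))
        skewness = m3 / m2**1.5
        kurtosis = m4 / m2**2 - 3.0
    else:
        skewness = float("nan")
        kurtosis = float("nan")
    return average, std_dev, skewness, kurtosis


def histogram_entropy(image, mask) -> float:
    """Shannon entropy (bits) of the ROI gray-level histogram.

    One bin per distinct integer gray value; ``0 * log 0 == 0``.
    """
    vals = _roi_values(image, mask)
    _, counts = np.unique(vals, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log2(p)))


@dataclass(frozen=True)
class GLCM:
    """Normalized gray-level co-occurrence matrix restricted to an ROI.

    ``levels[i]`` is the gray value mapped to row/column ``i`` of ``matrix``;
    entries are probabilities summing to 1.
    """

    levels: np.ndarray
    matrix: np.ndarray
    distance: int
    directions: tuple[tuple[int, int], ...]
    symmetric: bool

    def __post_init__(self):
        total = self.matrix.sum()
        if not np.isclose(total, 1.0, atol=1e-12):
            raise ValueError("GLCM probabilities must sum to 1")
        if (self.matrix < 0).any():
            raise ValueError("GLCM probabilities must be non-negative")


def compute_glcm(
    image,
    mask,
    distance: int = 1,
    directions: Sequence[tuple[int, int]] | None = None,
    symmetric: bool = True,
    levels: int | None = None,
) -> GLCM:
    """Build the ROI-masked GLCM pooled over directions.

    Both pixels of an offset pair must lie inside the mask to count.  With
    ``symmetric`` each pair is counted in both orders.  By default the matrix
    is indexed by the raw integer gray values present in the ROI; ``levels``
    requantizes the ROI range into that many equal-width bins first.

    Raises
    ------
    ValueError
        If no valid pixel pair exists (e.g. a scattered 1-pixel mask).
    """
    arr = _as_image(image)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != arr.shape:
        raise ValueError("mask shape must match image shape")
    if int(distance) < 1:
        raise ValueError("distance must be >= 1")
    distance = int(distance)
    if directions is None:
        directions = CANONICAL_DIRECTIONS
    directions = tuple((int(dy), int(dx)) for dy, dx in directions)

    roi_vals = arr[mask]
    if roi_vals.size == 0:
        raise ValueError("empty ROI mask")
    if levels is not None:
        lo, hi = int(roi_vals.min()), int(roi_vals.max())
        edges = np.linspace(lo, hi + 1, int(levels) + 1)
        quant = np.clip(np.digitize(arr, edges) - 1, 0, int(levels) - 1)
        arr = quant
        roi_vals = arr[mask]
    uniq = np.unique(roi_vals)
    ng = uniq.size
    index = np.searchsorted(uniq, arr)  # valid only where mask is True

    counts = np.zeros((ng, ng), dtype=float)
    nrows, ncols = arr.shape
    for dy, dx in directions:
        oy, ox = dy * distance, dx * distance
        src_r0, src_r1 = max(0, -oy), min(nrows, nrows - oy)
        src_c0, src_c1 = max(0, -ox), min(ncols, ncols - ox)
        if src_r0 >= src_r1 or src_c0 >= src_c1:
            continue
        src = (slice(src_r0, src_r1), slice(src_c0, src_c1))
        dst = (slice(src_r0 + oy, src_r1 + oy), slice(src_c0 + ox, src_c1 + ox))
        valid = mask[src] & mask[dst]
        i = index[src][valid]
        j = index[dst][valid]
        if i.size:
            np.add.at(counts, (i, j), 1.0)
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid pixel pairs inside the mask at this offset")
    return GLCM(
        levels=uniq.astype(float),
        matrix=counts / total,
        distance=distance,
        directions=directions,
        symmetric=symmetric,
    )


def glcm_contrast(g: GLCM) -> float:
    """Contrast ``sum p(i,j) (L_i - L_j)^2`` over gray-level values."""
    diff = g.levels[:, None] - g.levels[None, :]
    return float(np.sum(g.matrix * diff**2))


def glcm_correlation(g: GLCM, variant: str = "standard") -> float:
    """GLCM correlation: linear dependence of co-occurring gray levels.

    ``standard`` is the Pearson form, covariance over the product of
    marginal SDs, in [-1, 1].  ``paper_scale`` divides the same covariance
    by the product of marginal *variances* instead; this reproduces the
    order of magnitude (~1e-3) of correlation values reported by some
    clinical texture-analysis software, but is not scale-invariant.

    Returns NaN when a marginal variance is zero.
    """
    if variant not in ("standard", "paper_scale"):
        raise ValueError(f"unknown correlation variant {variant!r}")
    px = g.matrix.sum(axis=1)
    py = g.matrix.sum(axis=0)
    mu_x = float(px @ g.levels)
    mu_y = float(py @ g.levels)
    var_x = float(px @ (g.levels - mu_x) ** 2)
    var_y = float(py @ (g.levels - mu_y) ** 2)
    if var_x <= 0 or var_y <= 0:
        return float("nan")
    cov = float(np.sum(g.matrix * np.outer(g.levels - mu_x, g.levels - mu_y)))
    if variant == "standard":
        return cov / np.sqrt(var_x * var_y)
    return cov / (var_x * var_y)


@dataclass(frozen=True)
class TextureFeatureSet:
    """The seven ROI texture features plus extraction settings.

    ``correlation_variant`` selects which correlation value the generic
    ``correlation`` accessor reports; both variants are always stored.
    """

    average: float
    std_dev: float
    kurtosis: float
    skewness: float
    entropy: float
    correlation_standard: float
    correlation_paper_scale: float
    contrast: float
    n_pixels: int
    distance: int = 1
    correlation_variant: str = "paper_scale"
    directions: tuple[tuple[int, int], ...] = field(default=CANONICAL_DIRECTIONS)

    @property
    def correlation(self) -> float:
        if self.correlation_variant == "standard":
            return self.correlation_standard
        return self.correlation_paper_scale

    def as_dict(self) -> dict[str, float]:
        return {
            "average": self.average,
            "std_dev": self.std_dev,
            "kurtosis": self.kurtosis,
            "skewness": self.skewness,
            "entropy": self.entropy,
            "correlation_standard": self.correlation_standard,
            "correlation_paper_scale": self.correlation_paper_scale,
            "contrast": self.contrast,
            "n_pixels": self.n_pixels,
        }


def extract_features(
    image,
    roi,
    distance: int = 1,
    levels: int | None = None,
    correlation_variant: str = "paper_scale",
) -> TextureFeatureSet:
    """Compute all seven texture features for a polygon ROI (or boolean mask).

    ``roi`` may be a vertex list (rasterized here) or a boolean mask of the
    image's shape.  Deterministic for fixed inputs.
    """
    arr = _as_image(image)
    roi_arr = np.asarray(roi)
    if roi_arr.dtype == bool and roi_arr.shape == arr.shape:
        mask = roi_arr
    else:
        mask = rasterize_polygon(roi, arr.shape)
    if int(mask.sum()) < 2:
        raise ValueError("ROI must contain at least 2 pixels")

    average, std_dev, skewness, kurtosis = first_order_stats(arr, mask)
    entropy = histogram_entropy(arr, mask)
    g = compute_glcm(arr, mask, distance=distance, levels=levels)
    return TextureFeatureSet(
        average=average,
        std_dev=std_dev,
        kurtosis=kurtosis,
        skewness=skewness,
        entropy=entropy,
        correlation_standard=glcm_correlation(g, "standard"),
        correlation_paper_scale=glcm_correlation(g, "paper_scale"),
        contrast=glcm_contrast(g),
        n_pixels=int(mask.sum()),
        distance=distance,
        correlation_variant=correlation_variant,
    )
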