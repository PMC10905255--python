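"""Tissue-region extraction from the gene-expression heatmap.

The expression matrix is rasterized into a per-bin total-count image and
segmented with a classical grayscale chain: log1p intensity transform,
Gaussian smoothing, 8-bit rescale, Otsu (or fixed) thresholding,
morphological closing then opening, small-component removal, hole filling.
Contours are traced from the final binary mask and matrix records outside
the mask are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, measure, morphology

from .expr_matrix import ExpressionMatrix, GEM_COLUMNS


@dataclass
class HeatmapImage:
    """Total MID counts per bin; pixels[y, x] indexes row y, column x."""

    pixels: np.ndarray  # 2D, non-negative
    bin_size: int

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class TissueMask:
    mask: np.ndarray  # 2D bool, aligned to the heatmap
    bin_size: int
    contours: list[np.ndarray]  # closed polygons in (row, col) bin coords


@dataclass(frozen=True)
class SegmentationParams:
    """Knobs of the grayscale segmentation chain.

    gaussian_sigma: smoothing radius in bins.
    threshold: None for Otsu, or a fixed 8-bit cut.
    closing_radius / opening_radius: structuring-disk radii in bins.
    min_area_fraction: connected components smaller than this fraction of
    the image area are treated as noise and removed.
    """

    gaussian_sigma: float = 1.0
    threshold: Optional[int] = None
    closing_radius: int = 2
    opening_radius: int = 1
    min_area_fraction: float = 0.001


def expression_to_heatmap(
    matrix: ExpressionMatrix,
    bin_size: int,
    chip_width: Optional[int] = None,
    chip_height: Optional[int] = None,
) -> HeatmapImage:
    """Rasterize the bin1 matrix: pixel (row j, col i) sums counts of all
    genes in bin (i, j).  Total intensity equals the matrix total."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    df = matrix.records
    if df.empty:
        w = -(-chip_width // bin_size) if chip_width else 1
        h = -(-chip_height // bin_size) if chip_height else 1
        return HeatmapImage(np.zeros((h, w), dtype=np.int64), bin_size)
    bx = df["x"].to_numpy() // bin_size
    by = df["y"].to_numpy() // bin_size
    w = -(-chip_width // bin_size) if chip_width else int(bx.max()) + 1
    h = -(-chip_height // bin_size) if chip_height else int(by.max()) + 1
    img = np.zeros((h, w), dtype=np.int64)
    np.add.at(img, (by, bx), df["MIDCount"].to_numpy())
    return HeatmapImage(img, bin_size)


def segment_tissue(
    image: HeatmapImage, params: SegmentationParams = SegmentationParams()
) -> TissueMask:
    """Run the grayscale segmentation chain on a heatmap.

    An all-zero image yields an empty mask; a constant positive image
    yields a full-frame mask (Otsu is undefined on one gray level).
    """
    raw = image.pixels.astype(np.float64)
    if raw.max() == 0:
        empty = np.zeros(raw.shape, dtype=bool)
        return TissueMask(empty, image.bin_size, [])
    smooth = filters.gaussian(np.log1p(raw), sigma=params.gaussian_sigma,
                              preserve_range=True)
    lo, hi = smooth.min(), smooth.max()
    if hi > lo:
        gray8 = np.round(255 * (smooth - lo) / (hi - lo)).astype(np.uint8)
    else:
        gray8 = np.full(smooth.shape, 255, dtype=np.uint8)
    if params.threshold is not None:
        cut = params.threshold
        binary = gray8 >= cut
    elif hi == lo:
        binary = np.ones(gray8.shape, dtype=bool)
    else:
        binary = gray8 > filters.threshold_otsu(gray8)
    if params.closing_radius > 0:
        binary = morphology.closing(binary, morphology.disk(params.closing_radius))
    if params.opening_radius > 0:
        binary = morphology.opening(binary, morphology.disk(params.opening_radius))
    min_area = max(1, int(params.min_area_fraction * binary.size))
    binary = _drop_small_components(binary, min_area)
    binary = ndi.binary_fill_holes(binary)
    # pad so regions touching the border still yield closed contours
    padded = np.pad(binary.astype(np.uint8), 1)
    contours = [
        np.clip(c - 1.0, -0.5, np.array(binary.shape) - 0.5)
        for c in measure.find_contours(padded, 0.5)
    ]
    return TissueMask(binary, image.bin_size, contours)


def _drop_small_components(binary: np.ndarray, min_area: int) -> np.ndarray:
    """Remove connected components with area < min_area (8-connectivity)."""
    labels, n = ndi.label(binary, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return binary
    areas = np.bincount(labels.ravel())
    keep = areas >= min_area
    keep[0] = False
    return keep[labels]


def extract_tissue_records(
    matrix: ExpressionMatrix, tissue: TissueMask
) -> tuple[ExpressionMatrix, dict]:
    """Subset a bin1 matrix to records whose bin falls inside the mask."""
    df = matrix.records
    if df.empty:
        return matrix, {"bins_in_tissue": int(tissue.mask.sum()),
                        "records_retained": 0, "retained_count_fraction": 0.0}
    bx = df["x"].to_numpy() // tissue.bin_size
    by = df["y"].to_numpy() // tissue.bin_size
    h, w = tissue.mask.shape
    inside = (bx >= 0) & (bx < w) & (by >= 0) & (by < h)
    keep = np.zeros(len(df), dtype=bool)
    keep[inside] = tissue.mask[by[inside], bx[inside]]
    sub = ExpressionMatrix(
        df.loc[keep, GEM_COLUMNS], matrix.chip_name, matrix.bin_size
    )
    total = matrix.total_count
    stats = {
        "bins_in_tissue": int(tissue.mask.sum()),
        "records_retained": len(sub),
        "retained_count_fraction": sub.total_count / total if total else 0.0,
    }
    return sub, stats


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of two binary masks of equal shape."""
    a = a.astype(bool)
    b = b.astype(bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def write_mask_png(tissue: TissueMask, path) -> None:
    from PIL import Image

    img = Image.fromarray((tissue.mask.astype(np.uint8)) * 255)
    img.save(str(path))


def write_contours_tsv(tissue: TissueMask, path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("contour\trow\tcol\n")
        for i, contour in enumerate(tissue.contours):
            for row, col in contour:
                fh.write(f"{i}\t{row:.1f}\t{col:.1f}\n")
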