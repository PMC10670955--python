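"""ROI-based fluorescence quantification.

Two densitometric readouts over polygonal regions of interest drawn on a
single channel: the arithmetic mean intensity (with fold change against a
negative-control section), and the summed gray value normalized to
10,000 um^2 of region area.

A pixel belongs to an ROI when its center lies strictly inside the
polygon; this rule is deterministic and additive when a region is split
along lines between pixel centers.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import shapely
from shapely.geometry import Polygon

__all__ = [
    "ROI",
    "IntensityQuant",
    "roi_mean_intensity",
    "fold_change_vs_negative",
    "gray_per_area",
    "quantify_roi",
]


@dataclass(frozen=True)
class ROI:
    """Simple polygon in (row, col) pixel coordinates with a pixel size."""

    vertices: tuple[tuple[float, float], ...]
    pixel_size_um: float
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise ValueError("ROI polygon needs at least 3 vertices")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        poly = self.polygon
        if not poly.is_valid or poly.area == 0:
            raise ValueError("ROI polygon must be simple with nonzero area")

    @property
    def polygon(self) -> Polygon:
        # shapely works in (x, y) = (col, row)
        return Polygon([(c, r) for r, c in self.vertices])


def _pixels_inside(image: np.ndarray, roi: ROI) -> tuple[np.ndarray, np.ndarray]:
    """(rows, cols) of pixels whose centers fall inside the ROI polygon."""
    h, w = image.shape
    poly = roi.polygon
    minx, miny, maxx, maxy = poly.bounds
    if minx < -0.5 or miny < -0.5 or maxx > w - 0.5 or maxy > h - 0.5:
        raise ValueError("ROI extends outside the image bounds")
    c0, c1 = max(0, int(np.floor(minx))), min(w - 1, int(np.ceil(maxx)))
    r0, r1 = max(0, int(np.floor(miny))), min(h - 1, int(np.ceil(maxy)))
    cols, rows = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
    inside = shapely.contains_xy(poly, cols.ravel(), rows.ravel())
    if not inside.any():
        raise ValueError("ROI covers no pixel centers")
    return rows.ravel()[inside], cols.ravel()[inside]


def roi_mean_intensity(image: np.ndarray, roi: ROI) -> float:
    """Arithmetic mean gray value of the pixels inside the ROI."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("image must be a single-channel 2D raster")
    rows, cols = _pixels_inside(image, roi)
    return float(image[rows, cols].mean())


def fold_change_vs_negative(mean_fi: float, negative_mean_fi: float) -> float:
    """Mean intensity expressed relative to the negative-control mean."""
    if negative_mean_fi <= 0:
        raise ValueError("negative-control mean intensity must be positive")
    if mean_fi < 0:
        raise ValueError("mean_fi must be non-negative")
    return mean_fi / negative_mean_fi


def gray_per_area(image: np.ndarray, roi: ROI, mode: str = "sum") -> float:
    """Gray value of the ROI normalized to 10,000 um^2.

    Default ``mode="sum"`` is densitometric: summed pixel gray values
    divided by the ROI area (included pixels x pixel_size^2) and scaled to
    10,000 um^2.  ``mode="mean"`` normalizes the mean gray value instead.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("image must be a single-channel 2D raster")
    rows, cols = _pixels_inside(image, roi)
    area_um2 = len(rows) * roi.pixel_size_um ** 2
    if area_um2 <= 0:
        raise ValueError("ROI area must be positive")
    values = image[rows, cols].astype(float)
    gray = values.sum() if mode == "sum" else values.mean() * 1.0
    if mode not in ("sum", "mean"):
        raise ValueError("mode must be 'sum' or 'mean'")
    return float(gray / area_um2 * 10_000.0)


@dataclass(frozen=True)
class IntensityQuant:
    """Per-ROI quantification bundle."""

    label: str
    mean_fi: float
    fold_change: float | None
    gray_per_10k_um2: float


def quantify_roi(
    image: np.ndarray,
    roi: ROI,
    negative_mean_fi: float | None = None,
    gray_mode: str = "sum",
) -> IntensityQuant:
    """Mean FI, optional fold change, and gray value per 10,000 um^2."""
    mean_fi = roi_mean_intensity(image, roi)
    fc = (fold_change_vs_negative(mean_fi, negative_mean_fi)
          if negative_mean_fi is not None else None)
    return IntensityQuant(
        label=roi.label, mean_fi=mean_fi, fold_change=fc,
        gray_per_10k_um2=gray_per_area(image, roi, mode=gray_mode),
    )
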