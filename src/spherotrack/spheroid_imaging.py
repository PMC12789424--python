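"""Endpoint image analysis: from two-channel z-stacks to infiltration counts.

The endpoint assay images a dye-labelled neural spheroid (channel 1)
and dye-labelled invading cells (channel 2) as a short z-stack.  The
pipeline mirrors standard high-content practice: maximum projection of
each channel, spheroid ROI segmentation on channel 1, spot detection
on channel 2, and a count of detected cells whose centroid falls
inside the ROI.  Shape metrics (area, diameters, aspect ratio,
roundness) serve both spheroid quality control and the morphology
counter-screen on single cells.

Conventions: pixel indices are 0-based; physical coordinates are
pixel-centre × pixel size; channel 0 is the spheroid label and
channel 1 the cell label in ``(channel, plane, row, col)`` stacks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import filters, measure, morphology, segmentation
from skimage.feature import peak_local_max

__all__ = [
    "SpheroidROI",
    "ShapeMetrics",
    "DetectedCell",
    "EmptyROIError",
    "max_projection",
    "segment_spheroid",
    "shape_metrics",
    "detect_cells",
    "count_infiltrating",
    "detections_table",
]


class EmptyROIError(RuntimeError):
    """Segmentation found no usable foreground."""


@dataclass(frozen=True)
class ShapeMetrics:
    """Moment-ellipse shape descriptors of a binary object.

    ``roundness = 4·area/(π·major²)`` and ``aspect_ratio =
    major/minor`` from the second-moment equivalent ellipse; for an
    exact ellipse mask ``roundness × aspect_ratio = 1``.  The maximum
    Feret diameter is the longest caliper distance across the object.
    All lengths in µm, area in µm².
    """

    area: float
    equivalent_diameter: float
    feret_diameter_max: float
    aspect_ratio: float
    roundness: float

    @property
    def width_to_length(self) -> float:
        return 1.0 / self.aspect_ratio


@dataclass(frozen=True)
class SpheroidROI:
    mask: np.ndarray  # bool, single filled connected component
    centroid_px: tuple[float, float]  # (row, col)
    pixel_size: float  # µm / px
    metrics: ShapeMetrics

    def contains(self, row_px: float, col_px: float) -> bool:
        r, c = int(round(row_px)), int(round(col_px))
        if not (0 <= r < self.mask.shape[0] and 0 <= c < self.mask.shape[1]):
            return False
        return bool(self.mask[r, c])


@dataclass(frozen=True)
class DetectedCell:
    centroid_px: tuple[float, float]  # (row, col)
    x_um: float
    y_um: float
    area_um2: float
    mean_intensity: float
    inside_roi: bool | None = None


def max_projection(stack: np.ndarray, channel: int) -> np.ndarray:
    """Pixel-wise maximum across z-planes of one channel.

    ``stack`` has shape (channels, planes, rows, cols); a 3-D
    (planes, rows, cols) array is treated as a single channel.
    """
    arr = np.asarray(stack)
    if arr.ndim == 3:
        arr = arr[None]
    if arr.ndim != 4:
        raise ValueError("stack must be (channels, planes, rows, cols)")
    if not 0 <= channel < arr.shape[0]:
        raise ValueError(f"channel {channel} out of range")
    if arr.shape[1] == 0:
        raise ValueError("stack has no planes")
    return arr[channel].max(axis=0)


def segment_spheroid(
    image: np.ndarray,
    pixel_size: float,
    *,
    threshold: float | None = None,
    closing_radius: int = 3,
    min_area_um2: float = 1000.0,
) -> SpheroidROI:
    """Segment the spheroid ROI from a projected channel-1 image.

    Global threshold (Otsu by default, or the fixed ``threshold``),
    morphological closing, hole filling, and retention of the largest
    connected component.  Raises :class:`EmptyROIError` when nothing
    above the minimum area survives.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D projected image")
    if threshold is None:
        if np.ptp(img) == 0:
            raise EmptyROIError("image is constant; no spheroid found")
        threshold = filters.threshold_otsu(img)
    fg = img > threshold
    if not fg.any():
        raise EmptyROIError("no foreground above threshold")
    if closing_radius > 0:
        fg = morphology.closing(fg, morphology.disk(closing_radius))
    fg = ndi.binary_fill_holes(fg)
    labels, n = ndi.label(fg)
    if n == 0:
        raise EmptyROIError("no connected component after morphology")
    sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    mask = labels == best
    metrics = shape_metrics(mask, pixel_size)
    if metrics.area < min_area_um2:
        raise EmptyROIError(
            f"largest component area {metrics.area:.0f} µm² below "
            f"minimum {min_area_um2:.0f} µm²"
        )
    r, c = ndi.center_of_mass(mask)
    return SpheroidROI(
        mask=mask, centroid_px=(float(r), float(c)), pixel_size=pixel_size, metrics=metrics
    )


def shape_metrics(mask: np.ndarray, pixel_size: float) -> ShapeMetrics:
    """Shape descriptors of a binary mask (single object assumed)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    props = measure.regionprops(mask.astype(np.uint8))[0]
    area = props.area * pixel_size**2
    major = props.axis_major_length * pixel_size
    minor = props.axis_minor_length * pixel_size
    if minor == 0:  # degenerate (line-like) object
        aspect = math.inf
        roundness = 0.0
    else:
        aspect = major / minor
        roundness = 4.0 * area / (math.pi * major**2)
    return ShapeMetrics(
        area=float(area),
        equivalent_diameter=float(math.sqrt(4.0 * area / math.pi)),
        feret_diameter_max=float(props.feret_diameter_max * pixel_size),
        aspect_ratio=float(aspect),
        roundness=float(roundness),
    )


def detect_cells(
    image: np.ndarray,
    pixel_size: float,
    *,
    threshold: float | None = None,
    smooth_sigma_px: float = 1.5,
    tophat_radius_px: int = 8,
    min_area_um2: float = 20.0,
    max_single_area_um2: float = 150.0,
    noise_floor_k: float = 6.0,
    roi: SpheroidROI | None = None,
) -> list[DetectedCell]:
    """Detect labelled cells in a projected channel-2 image.

    The image is smoothed with a Gaussian roughly matched to the spot
    size (suppressing projection noise), background is flattened by a
    white top-hat whose radius exceeds the cell radius, and the result
    is thresholded (Otsu, floored at ``noise_floor_k`` robust noise
    SDs above zero so a pure-noise image yields no detections).
    Connected components are filtered by area, and components larger
    than ``max_single_area_um2`` are split by distance-transform
    watershed.  Centroids are returned in pixel and physical
    coordinates; if ``roi`` is given each detection is flagged
    inside/outside.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D projected image")
    smoothed = ndi.gaussian_filter(img, smooth_sigma_px) if smooth_sigma_px > 0 else img
    flat = morphology.white_tophat(smoothed, morphology.disk(tophat_radius_px))
    # robust noise scale from the median absolute deviation
    mad = np.median(np.abs(flat - np.median(flat)))
    noise_sd = 1.4826 * mad
    if threshold is None:
        if np.ptp(flat) == 0:
            return []
        threshold = max(filters.threshold_otsu(flat), noise_floor_k * noise_sd)
    fg = flat > threshold
    if not fg.any():
        return []

    labels, _ = ndi.label(fg)
    min_area_px = min_area_um2 / pixel_size**2
    max_area_px = max_single_area_um2 / pixel_size**2

    # split oversized components with a distance-transform watershed
    oversized = []
    for p in measure.regionprops(labels):
        if p.area > max_area_px:
            oversized.append(p.label)
    if oversized:
        big = np.isin(labels, oversized)
        dist = ndi.distance_transform_edt(big)
        # one marker per distance maximum, spaced at least half a cell
        # diameter apart
        half_diam_px = max(
            int(round(math.sqrt(max_single_area_um2 / math.pi) / pixel_size / 2)), 2
        )
        coords = peak_local_max(dist, min_distance=half_diam_px, labels=big)
        if len(coords) > 0:
            markers = np.zeros(labels.shape, dtype=int)
            markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
            split = segmentation.watershed(-dist, markers, mask=big)
            offset = labels.max()
            labels = np.where(big, np.where(split > 0, split + offset, 0), labels)

    cells: list[DetectedCell] = []
    for p in measure.regionprops(labels, intensity_image=img):
        if p.area < min_area_px:
            continue
        r, c = p.centroid_weighted
        cell = DetectedCell(
            centroid_px=(float(r), float(c)),
            x_um=float(c * pixel_size),
            y_um=float(r * pixel_size),
            area_um2=float(p.area * pixel_size**2),
            mean_intensity=float(p.intensity_mean),
            inside_roi=roi.contains(r, c) if roi is not None else None,
        )
        cells.append(cell)
    return cells


def count_infiltrating(cells: list[DetectedCell], roi: SpheroidROI) -> int:
    """Number of detected cells whose centroid lies inside the ROI mask."""
    return sum(1 for c in cells if roi.contains(*c.centroid_px))


def detections_table(cells: list[DetectedCell]) -> pd.DataFrame:
    """Tidy table of detections (x_um, y_um, area_um2, mean_intensity,
    inside_roi)."""
    return pd.DataFrame(
        [
            {
                "x_um": c.x_um,
                "y_um": c.y_um,
                "area_um2": c.area_um2,
                "mean_intensity": c.mean_intensity,
                "inside_roi": c.inside_roi,
            }
            for c in cells
        ],
        columns=["x_um", "y_um", "area_um2", "mean_intensity", "inside_roi"],
    )
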