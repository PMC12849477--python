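"""Single-cell fluorescence quantification from microscopy fields.

The pipeline mirrors a standard reporter-microscopy analysis for coccoid
bacteria: a percentile contrast stretch feeds segmentation only; per-cell
mean intensities are always measured on the *raw* image; debris is
removed by excluding the smallest 3% of objects by area; edge artifacts
are avoided by keeping only cells whose centroid falls inside a central
circular region of interest; and intensities are min-max scaled per
image to a relative 0-100% scale so that fields with different exposure
or background remain comparable.

Stage order is fixed: contrast_stretch -> segment_cells ->
filter_small_objects -> central_roi_filter -> measure_intensities (raw)
-> normalize_per_image.  The size filter runs before the ROI filter
because debris exclusion is a global property of the field while the ROI
is purely geometric.

Segmentation defaults to an in-repo classical method (Gaussian smoothing,
Otsu threshold, distance transform, peak-seeded watershed).  External
segmenters (e.g. a pretrained deep-learning model) can be plugged in via
:func:`register_segmenter` and are never required.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, measure, morphology, segmentation
from skimage.feature import peak_local_max

from ._conventions import percentile


@dataclass
class SegObject:
    label: int
    area: float  # px^2
    centroid_x: float  # column, 0-based px
    centroid_y: float  # row, 0-based px
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col)


@dataclass
class SegmentationResult:
    """Labelled objects over a field; label 0 is background."""

    label_map: np.ndarray
    objects: list[SegObject]

    @property
    def n_objects(self) -> int:
        return len(self.objects)

    def labels(self) -> list[int]:
        return [o.label for o in self.objects]


@dataclass
class CellRecord:
    """One segmented cell with raw and relative intensity."""

    source_id: str
    label: int
    area: float
    centroid_x: float
    centroid_y: float
    mean_raw_intensity: float
    relative_intensity: float | None = None  # percent in [0, 100]
    strain: str = ""
    timepoint_h: float = float("nan")


@dataclass
class QuantConfig:
    """Tunable parameters of the quantification pipeline."""

    p_low: float = 2.0
    p_high: float = 98.0
    excluded_fraction: float = 0.03
    roi_fraction: float = 0.5
    method: str = "classical"
    smooth_sigma: float = 2.0
    min_distance: int = 7
    min_size: int = 4


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def contrast_stretch(
    image: np.ndarray, p_low: float = 2.0, p_high: float = 98.0
) -> np.ndarray:
    """Percentile contrast stretch to [0, 1], for segmentation input only.

    Values at or below the ``p_low`` percentile map to 0, at or above
    ``p_high`` to 1, linearly in between.  A constant image has no
    contrast to stretch and returns all zeros with a warning.  The
    result must never be used for intensity measurement.
    """
    if p_low >= p_high:
        raise ValueError("p_low must be < p_high")
    img = np.asarray(image, dtype=float)
    lo, hi = percentile(img.ravel(), [p_low, p_high])
    if hi <= lo:
        warnings.warn(
            "degenerate contrast stretch (low == high percentile); returning zeros",
            stacklevel=2,
        )
        return np.zeros_like(img)
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0)


def _segment_classical(
    stretched: np.ndarray,
    smooth_sigma: float = 2.0,
    min_distance: int = 7,
    min_size: int = 4,
) -> np.ndarray:
    """Gaussian smoothing -> Otsu -> distance transform -> watershed."""
    smoothed = filters.gaussian(stretched, sigma=smooth_sigma, preserve_range=True)
    if np.ptp(smoothed) == 0:
        return np.zeros(stretched.shape, dtype=np.int32)
    thresh = filters.threshold_otsu(smoothed)
    mask = smoothed > thresh
    mask = morphology.remove_small_objects(mask, max_size=min_size - 1)
    mask = ndi.binary_fill_holes(mask)
    if not mask.any():
        return np.zeros(stretched.shape, dtype=np.int32)
    distance = ndi.distance_transform_edt(mask)
    peaks = peak_local_max(
        distance, min_distance=min_distance, labels=mask, exclude_border=False
    )
    markers = np.zeros(stretched.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        labels, _ = ndi.label(mask)
        return labels.astype(np.int32)
    labels = segmentation.watershed(-distance, markers, mask=mask)
    return labels.astype(np.int32)


SegmenterFn = Callable[[np.ndarray], np.ndarray]
_SEGMENTERS: dict[str, SegmenterFn] = {}


def register_segmenter(name: str, fn: SegmenterFn) -> None:
    """Register an external segmenter: stretched [0,1] image -> label map."""
    _SEGMENTERS[name] = fn


def _objects_from_labels(label_map: np.ndarray) -> list[SegObject]:
    objects = []
    for rp in measure.regionprops(label_map):
        cy, cx = rp.centroid
        objects.append(
            SegObject(
                label=int(rp.label),
                area=float(rp.area),
                centroid_x=float(cx),
                centroid_y=float(cy),
                bbox=tuple(int(v) for v in rp.bbox),
            )
        )
    objects.sort(key=lambda o: o.label)
    return objects


def segment_cells(
    stretched: np.ndarray, method: str = "classical", **params
) -> SegmentationResult:
    """Segment cells in a contrast-stretched image.

    ``method`` selects the in-repo classical segmenter or any segmenter
    previously added with :func:`register_segmenter`.  A blank image
    yields an empty result.
    """
    stretched = np.asarray(stretched, dtype=float)
    if stretched.min() < 0 or stretched.max() > 1:
        raise ValueError("segmentation input must be a stretched image in [0, 1]")
    if method == "classical":
        label_map = _segment_classical(stretched, **params)
    elif method in _SEGMENTERS:
        label_map = np.asarray(_SEGMENTERS[method](stretched))
    else:
        raise ValueError(
            f"unknown segmentation method {method!r}; "
            f"registered: {['classical', *sorted(_SEGMENTERS)]}"
        )
    return SegmentationResult(label_map=label_map, objects=_objects_from_labels(label_map))


def filter_small_objects(
    seg: SegmentationResult, excluded_fraction: float = 0.03
) -> SegmentationResult:
    """Drop exactly floor(excluded_fraction * N) smallest objects by area.

    Removes debris and partial detections.  Ties in area break by label
    order (smaller label removed first), so the result is deterministic.
    Every removed area is <= every retained area (up to the tie group).
    """
    if not (0.0 <= excluded_fraction < 1.0):
        raise ValueError("excluded_fraction must lie in [0, 1)")
    n = seg.n_objects
    n_remove = math.floor(excluded_fraction * n)
    if n_remove == 0:
        return SegmentationResult(label_map=seg.label_map.copy(), objects=list(seg.objects))
    order = sorted(seg.objects, key=lambda o: (o.area, o.label))
    removed = {o.label for o in order[:n_remove]}
    retained = [o for o in seg.objects if o.label not in removed]
    label_map = seg.label_map.copy()
    label_map[np.isin(label_map, list(removed))] = 0
    return SegmentationResult(label_map=label_map, objects=retained)


def central_roi_filter(
    seg: SegmentationResult,
    width: int,
    height: int,
    fraction: float = 0.5,
) -> SegmentationResult:
    """Keep objects whose centroid lies strictly inside the central circle.

    The circle is centered at (width/2, height/2) with radius
    ``fraction * min(width, height)``; with the default fraction of 0.5
    this is the largest circle inscribed in the frame, which minimizes
    edge and illumination artifacts.  Applied as a centroid test after
    segmentation so boundary cells are wholly in or out.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    radius = fraction * min(width, height)
    cx, cy = width / 2.0, height / 2.0
    retained, removed = [], set()
    for o in seg.objects:
        if (o.centroid_x - cx) ** 2 + (o.centroid_y - cy) ** 2 < radius**2:
            retained.append(o)
        else:
            removed.add(o.label)
    label_map = seg.label_map.copy()
    if removed:
        label_map[np.isin(label_map, list(removed))] = 0
    return SegmentationResult(label_map=label_map, objects=retained)


def measure_intensities(raw: np.ndarray, seg: SegmentationResult) -> dict[int, float]:
    """Mean raw intensity under each label, measured on the raw image."""
    raw = np.asarray(raw, dtype=float)
    if raw.shape != seg.label_map.shape:
        raise ValueError(
            f"raw image shape {raw.shape} != label map shape {seg.label_map.shape}"
        )
    labels = seg.labels()
    if not labels:
        return {}
    means = ndi.mean(raw, labels=seg.label_map, index=labels)
    return {lab: float(m) for lab, m in zip(labels, np.atleast_1d(means))}


def normalize_per_image(records: list[CellRecord]) -> list[CellRecord]:
    """Min-max scale mean raw intensities to relative percent per image.

    The dimmest cell maps to 0, the brightest to 100.  A single cell (or
    all-equal intensities) has no dynamic range: all set to 0 with a
    warning.
    """
    if not records:
        return []
    vals = np.array([r.mean_raw_intensity for r in records], dtype=float)
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        warnings.warn(
            "all cells share one intensity; relative intensities set to 0",
            stacklevel=2,
        )
        rel = np.zeros_like(vals)
    else:
        rel = 100.0 * (vals - lo) / (hi - lo)
    return [replace(r, relative_intensity=float(v)) for r, v in zip(records, rel)]


def quantify_image(
    raw: np.ndarray,
    config: QuantConfig | None = None,
    source_id: str = "",
    strain: str = "",
    timepoint_h: float = float("nan"),
) -> list[CellRecord]:
    """Run the full quantification pipeline on one raw field.

    Composition (fixed order): contrast_stretch -> segment_cells ->
    filter_small_objects -> central_roi_filter -> measure_intensities on
    the raw image -> normalize_per_image.
    """
    cfg = config or QuantConfig()
    raw = np.asarray(raw)
    if raw.ndim != 2 or min(raw.shape) < 16:
        raise ValueError("expected a single-channel image of at least 16x16 px")
    stretched = contrast_stretch(raw, cfg.p_low, cfg.p_high)
    seg = segment_cells(
        stretched,
        method=cfg.method,
        smooth_sigma=cfg.smooth_sigma,
        min_distance=cfg.min_distance,
        min_size=cfg.min_size,
    )
    seg = filter_small_objects(seg, cfg.excluded_fraction)
    height, width = raw.shape
    seg = central_roi_filter(seg, width=width, height=height, fraction=cfg.roi_fraction)
    means = measure_intensities(raw, seg)
    records = [
        CellRecord(
            source_id=source_id,
            label=o.label,
            area=o.area,
            centroid_x=o.centroid_x,
            centroid_y=o.centroid_y,
            mean_raw_intensity=means[o.label],
            strain=strain,
            timepoint_h=timepoint_h,
        )
        for o in seg.objects
    ]
    return normalize_per_image(records)
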