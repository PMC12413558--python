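"""Per-frame, per-organ confidence and geometry features.

For one organ probability map three groups of statistics are computed:

* full-map statistics — mean, SD, max, min of every pixel's confidence;
* thresholded statistics — the same four, but only over pixels with
  confidence strictly greater than 0.5.  When the full-map values are much
  lower than the thresholded ones the segmenter is confident (background is
  near zero); when the two groups are similar, high confidence leaked outside
  the organ and the segmentation is uncertain;
* bounding-box geometry — over the same > 0.5 binarization: row/column
  minima and maxima, box centroid, width, height and area.  These capture
  whether the organ's location, size and aspect ratio are where a correctly
  captured plane puts them.

That is 4 + 4 + 9 = 17 numeric features per (frame, organ), plus a boolean
flag marking an empty thresholded set (the flag is metadata, not one of the
17).  All SDs are population SDs (divide by the pixel count), so single-pixel
sets have SD 0.  An empty thresholded set yields zeros for all thresholded
and box features — a finite sentinel maximally distinct from valid confident
statistics, which always exceed 0.5.

Box width/height use inclusive pixel counts (max − min + 1) and the centroid
is the box center (midpoint of the bounds), not the mask center of mass.
"""

from __future__ import annotations

import dataclasses

import numpy as np

#: Detection threshold: pixels with confidence strictly above this belong to
#: the predicted segmentation.
DEFAULT_TAU = 0.5

#: Canonical order of the 17 per-frame features.
FRAME_FEATURE_NAMES: tuple[str, ...] = (
    "pred_mean",
    "pred_sd",
    "pred_max",
    "pred_min",
    "thr_mean",
    "thr_sd",
    "thr_max",
    "thr_min",
    "bbox_row_min",
    "bbox_row_max",
    "bbox_col_min",
    "bbox_col_max",
    "bbox_centroid_row",
    "bbox_centroid_col",
    "bbox_height",
    "bbox_width",
    "bbox_area",
)

N_FRAME_FEATURES = len(FRAME_FEATURE_NAMES)  # 17


class EmptyMapError(ValueError):
    """Raised for a map with no pixels."""


@dataclasses.dataclass(frozen=True)
class FrameOrganFeatures:
    """The 17 per-frame features for one organ, plus the empty-set flag."""

    pred_mean: float
    pred_sd: float
    pred_max: float
    pred_min: float
    thr_mean: float
    thr_sd: float
    thr_max: float
    thr_min: float
    bbox_row_min: float
    bbox_row_max: float
    bbox_col_min: float
    bbox_col_max: float
    bbox_centroid_row: float
    bbox_centroid_col: float
    bbox_height: float
    bbox_width: float
    bbox_area: float
    thr_empty: bool

    def as_vector(self) -> np.ndarray:
        """The 17 numeric features in canonical order (flag excluded)."""
        return np.array(
            [getattr(self, name) for name in FRAME_FEATURE_NAMES], dtype=float
        )


def _validate_map(prob_map: np.ndarray) -> np.ndarray:
    arr = np.asarray(prob_map, dtype=float)
    if arr.size == 0:
        raise EmptyMapError("probability map has no pixels")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError("probability map values must lie in [0, 1]")
    return arr


def full_map_stats(prob_map: np.ndarray) -> tuple[float, float, float, float]:
    """(mean, population SD, max, min) over every pixel of the map."""
    arr = _validate_map(prob_map)
    return (
        float(arr.mean()),
        float(arr.std()),
        float(arr.max()),
        float(arr.min()),
    )


def thresholded_stats(
    prob_map: np.ndarray, tau: float = DEFAULT_TAU
) -> tuple[float, float, float, float, bool]:
    """(mean, SD, max, min, empty-flag) over pixels with value strictly > tau.

    Pixels exactly at tau are excluded.  An empty subset returns four zeros
    with the flag set.
    """
    arr = _validate_map(prob_map)
    subset = arr[arr > tau]
    if subset.size == 0:
        return (0.0, 0.0, 0.0, 0.0, True)
    return (
        float(subset.mean()),
        float(subset.std()),
        float(subset.max()),
        float(subset.min()),
        False,
    )


def bounding_box_features(
    prob_map: np.ndarray, tau: float = DEFAULT_TAU
) -> tuple[float, float, float, float, float, float, float, float, float]:
    """Nine geometry features of the box containing all pixels with value > tau.

    Returns (row_min, row_max, col_min, col_max, centroid_row, centroid_col,
    height, width, area); all zeros when no pixel qualifies.
    """
    arr = _validate_map(prob_map)
    rows, cols = np.nonzero(arr > tau)
    if rows.size == 0:
        return (0.0,) * 9
    row_min, row_max = float(rows.min()), float(rows.max())
    col_min, col_max = float(cols.min()), float(cols.max())
    height = row_max - row_min + 1.0
    width = col_max - col_min + 1.0
    return (
        row_min,
        row_max,
        col_min,
        col_max,
        (row_min + row_max) / 2.0,
        (col_min + col_max) / 2.0,
        height,
        width,
        height * width,
    )


def extract_frame_features(
    prob_map: np.ndarray, tau: float = DEFAULT_TAU
) -> FrameOrganFeatures:
    """All 17 per-frame features (plus empty flag) for one probability map."""
    pred_mean, pred_sd, pred_max, pred_min = full_map_stats(prob_map)
    thr_mean, thr_sd, thr_max, thr_min, empty = thresholded_stats(prob_map, tau)
    (
        row_min,
        row_max,
        col_min,
        col_max,
        c_row,
        c_col,
        height,
        width,
        area,
    ) = bounding_box_features(prob_map, tau)
    return FrameOrganFeatures(
        pred_mean=pred_mean,
        pred_sd=pred_sd,
        pred_max=pred_max,
        pred_min=pred_min,
        thr_mean=thr_mean,
        thr_sd=thr_sd,
        thr_max=thr_max,
        thr_min=thr_min,
        bbox_row_min=row_min,
        bbox_row_max=row_max,
        bbox_col_min=col_min,
        bbox_col_max=col_max,
        bbox_centroid_row=c_row,
        bbox_centroid_col=c_col,
        bbox_height=height,
        bbox_width=width,
        bbox_area=area,
        thr_empty=empty,
    )


def extract_stack_features(stack: np.ndarray, tau: float = DEFAULT_TAU) -> np.ndarray:
    """Per-frame features for a whole (n_frames, H, W) stack of one organ.

    Returns an array of shape (n_frames, 17) in canonical feature order.
    """
    stack = np.asarray(stack)
    return np.stack(
        [extract_frame_features(stack[i], tau).as_vector() for i in range(stack.shape[0])]
    )
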