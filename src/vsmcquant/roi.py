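"""Automated ROI identification in 2-D fluorescence image sequences.

A pixel is called *active* when its temporally smoothed intensity rises above
its own pre-stimulus baseline by more than the one-sided normal quantile
``z_(1-alpha)`` baseline standard deviations at any frame after the control
addition.  Active pixels are grouped into 4-connected components; components
below a minimum size are discarded.  This realizes detection "above
statistical noise" at significance level alpha (default 0.01).

Baseline statistics (per-pixel mean and SD) are estimated from the raw
frames recorded strictly before ``control_time``; the threshold is applied
to the smoothed trace, which makes the per-pixel test conservative at level
alpha (smoothing shrinks the noise SD).
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.stats import norm
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .types import FluorescenceTrace, Roi, TimeSeriesStack

__all__ = ["detect_rois", "active_pixel_frames", "extract_trace", "count_total_cells"]

logger = logging.getLogger(__name__)

MIN_BASELINE_FRAMES = 5
SMOOTH_WINDOW = 3


def _smooth(frames: np.ndarray, window: int) -> np.ndarray:
    return uniform_filter1d(frames.astype(float), size=window, axis=0, mode="nearest")


def active_pixel_frames(
    stack: TimeSeriesStack,
    alpha: float = 0.01,
    smooth_window: int = SMOOTH_WINDOW,
) -> np.ndarray:
    """Per-pixel, per-frame activity flags for the post-control window.

    Returns a boolean array of shape (n_post_frames, h, w): True where the
    smoothed intensity exceeds baseline mean + z_(1-alpha) * baseline SD.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    times = stack.times
    baseline_sel = times < stack.protocol.control_time
    post_sel = times > stack.protocol.control_time
    if baseline_sel.sum() < MIN_BASELINE_FRAMES:
        raise ValueError(
            f"pre-control window has {int(baseline_sel.sum())} frames; "
            f"need >= {MIN_BASELINE_FRAMES}"
        )
    base = stack.frames[baseline_sel].astype(float)
    mu = base.mean(axis=0)
    sd = base.std(axis=0, ddof=1)
    z = norm.ppf(1.0 - alpha)
    smoothed = _smooth(stack.frames, smooth_window)
    return smoothed[post_sel] > mu + z * sd


def detect_rois(
    stack: TimeSeriesStack,
    alpha: float = 0.01,
    min_size: int = 9,
    smooth_window: int = SMOOTH_WINDOW,
) -> list:
    """Detect active ROIs in a recording.

    Parameters
    ----------
    stack : TimeSeriesStack
        The recording with its stimulus protocol.
    alpha : float
        Per-pixel significance level for the activity test (default 0.01).
    min_size : int
        Minimum component size in pixels; smaller components are discarded.

    Returns
    -------
    list of Roi
        Pairwise disjoint 4-connected components of active pixels, ids
        assigned in raster order of their centroids.
    """
    flags = active_pixel_frames(stack, alpha=alpha, smooth_window=smooth_window)
    active = flags.any(axis=0)
    labeled = cc_label(active, connectivity=1)
    regions = [r for r in regionprops(labeled) if r.area >= min_size]
    regions.sort(key=lambda r: (r.centroid[0], r.centroid[1]))
    rois = []
    for i, r in enumerate(regions):
        pixels = frozenset((int(a), int(b)) for a, b in r.coords)
        rois.append(Roi(roi_id=i, pixel_set=pixels, centroid=tuple(r.centroid)))
    logger.info("detected %d ROIs (alpha=%g, min_size=%d)", len(rois), alpha, min_size)
    return rois


def extract_trace(stack: TimeSeriesStack, roi: Roi) -> FluorescenceTrace:
    """Mean raw intensity over the ROI's pixel set, per frame."""
    h, w = stack.shape
    coords = np.array(sorted(roi.pixel_set))
    if (
        coords[:, 0].min() < 0
        or coords[:, 1].min() < 0
        or coords[:, 0].max() >= h
        or coords[:, 1].max() >= w
    ):
        raise ValueError("ROI pixel outside image bounds")
    raw = stack.frames[:, coords[:, 0], coords[:, 1]].astype(float).mean(axis=1)
    return FluorescenceTrace(
        roi_id=roi.roi_id, raw=raw, frame_interval=stack.frame_interval
    )


def count_total_cells(
    reference_frame: np.ndarray,
    min_size: int = 9,
    threshold: Optional[float] = None,
) -> int:
    """Count dye-loaded cells in a reference frame.

    Global Otsu threshold (unless an explicit threshold is given) followed by
    4-connected component labeling with the same minimum-size filter as ROI
    detection.  This provides the denominator of the responding fraction.
    A blank (constant) frame yields 0 with a warning.
    """
    frame = np.asarray(reference_frame, dtype=float)
    if frame.size == 0:
        raise ValueError("empty frame")
    if np.ptp(frame) == 0:
        logger.warning("blank reference frame; returning 0 cells")
        return 0
    if threshold is None:
        from skimage.filters import threshold_otsu

        threshold = threshold_otsu(frame)
    labeled = cc_label(frame > threshold, connectivity=1)
    return sum(1 for r in regionprops(labeled) if r.area >= min_size)
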