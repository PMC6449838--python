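"""Per-cell contraction from three-state calcein image sequences.

Cells are segmented in each of the pre-stimulus, post-control and post-drug
frames by a global Otsu threshold followed by 4-connected component
labeling; components below a minimum size or touching the image border are
discarded.  Objects are linked state-to-state by maximal pixel overlap
(ties broken by nearest centroid, then smaller label), and each complete
track yields the two relative area changes

    delta_control = (S1 - S2) / S1        (medium-only addition)
    delta_drug    = (S2 - S3) / S2        (vasoconstrictor addition)

where S1, S2, S3 are the cell areas in the three states.  Positive values
mean contraction; area increases give negative values.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.segmentation import clear_border

from .compare import PopulationSummary, rank_test, summarize_distribution
from .types import CellTrack, ContractionMeasure

__all__ = [
    "segment_cells",
    "track_cells",
    "compute_contraction",
    "contraction_population",
]

logger = logging.getLogger(__name__)


def segment_cells(
    frame: np.ndarray, min_size: int = 9, threshold: Optional[float] = None
) -> np.ndarray:
    """Segment bright cells in one frame.

    Returns an int32 label image; labels are assigned in raster order of the
    surviving components.  Border-touching components are excluded because
    their area is censored by the field of view.  A blank frame yields an
    empty labeling with a warning.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValueError("empty frame")
    out = np.zeros(frame.shape, dtype=np.int32)
    if np.ptp(frame) == 0:
        logger.warning("blank frame; no objects segmented")
        return out
    if threshold is None:
        threshold = threshold_otsu(frame)
    labeled = clear_border(cc_label(frame > threshold, connectivity=1))
    regions = [r for r in regionprops(labeled) if r.area >= min_size]
    regions.sort(key=lambda r: (r.centroid[0], r.centroid[1]))
    for new_label, r in enumerate(regions, start=1):
        out[tuple(r.coords.T)] = new_label
    return out


def _link(mask_from: np.ndarray, mask_to: np.ndarray) -> dict:
    """Greedy one-to-one linking by maximal pixel overlap.

    Ties are broken by centroid distance, then by the smaller target label.
    Returns {label_from: label_to}.
    """
    props_from = {r.label: r for r in regionprops(mask_from)}
    props_to = {r.label: r for r in regionprops(mask_to)}
    candidates = []
    for lf, rf in props_from.items():
        overlap_labels, overlap_counts = np.unique(
            mask_to[tuple(rf.coords.T)], return_counts=True
        )
        for lt, cnt in zip(overlap_labels, overlap_counts):
            if lt == 0:
                continue
            dist = float(
                np.hypot(
                    rf.centroid[0] - props_to[lt].centroid[0],
                    rf.centroid[1] - props_to[lt].centroid[1],
                )
            )
            candidates.append((-int(cnt), dist, int(lt), int(lf)))
    links: dict = {}
    used_to: set = set()
    for neg_cnt, dist, lt, lf in sorted(candidates):
        if lf in links or lt in used_to:
            continue
        links[lf] = lt
        used_to.add(lt)
    # objects without any overlap: nearest-centroid fallback among unused targets
    for lf, rf in props_from.items():
        if lf in links:
            continue
        best = None
        for lt, rt in props_to.items():
            if lt in used_to:
                continue
            dist = float(
                np.hypot(rf.centroid[0] - rt.centroid[0], rf.centroid[1] - rt.centroid[1])
            )
            key = (dist, lt)
            if best is None or key < best[0]:
                best = (key, lt)
        if best is not None and best[0][0] <= _max_link_distance(rf):
            links[lf] = best[1]
            used_to.add(best[1])
            logger.info("object %d linked by centroid fallback to %d", lf, best[1])
    return links


def _max_link_distance(region) -> float:
    """Fallback links only within one equivalent radius of the source object."""
    return float(np.sqrt(region.area / np.pi))


def track_cells(masks: Sequence[np.ndarray]) -> list:
    """Link segmented objects across the three states into cell tracks.

    Incomplete tracks (cells missing from any state) are kept but flagged;
    only complete tracks proceed to contraction measures.
    """
    if len(masks) != 3:
        raise ValueError("exactly three state masks are required")
    if not (masks[0].shape == masks[1].shape == masks[2].shape):
        raise ValueError("state masks must share the image shape")
    props = [{r.label: r for r in regionprops(np.asarray(m))} for m in masks]
    links01 = _link(np.asarray(masks[0]), np.asarray(masks[1]))
    links12 = _link(np.asarray(masks[1]), np.asarray(masks[2]))
    tracks = []
    used1: set = set()
    tid = 0
    for l0 in sorted(props[0]):
        l1 = links01.get(l0)
        l2 = links12.get(l1) if l1 is not None else None
        if l1 is not None:
            used1.add(l1)
        chain = (l0, l1, l2)
        areas = tuple(
            float(props[s][lbl].area) if lbl is not None else None
            for s, lbl in enumerate(chain)
        )
        cents = tuple(
            tuple(props[s][lbl].centroid) if lbl is not None else None
            for s, lbl in enumerate(chain)
        )
        tracks.append(CellTrack(track_id=tid, areas=areas, centroids=cents))
        tid += 1
    # objects first appearing in later states form incomplete tracks
    for l1 in sorted(set(props[1]) - used1):
        l2 = links12.get(l1)
        areas = (None, float(props[1][l1].area),
                 float(props[2][l2].area) if l2 is not None else None)
        cents = (None, tuple(props[1][l1].centroid),
                 tuple(props[2][l2].centroid) if l2 is not None else None)
        tracks.append(CellTrack(track_id=tid, areas=areas, centroids=cents))
        tid += 1
    n_incomplete = sum(1 for t in tracks if not t.complete)
    if n_incomplete:
        logger.info("%d of %d tracks incomplete; excluded from measures",
                    n_incomplete, len(tracks))
    return tracks


def compute_contraction(track: CellTrack) -> ContractionMeasure:
    """Relative area changes of one complete track."""
    if not track.complete:
        raise ValueError("contraction requires a complete track")
    s1, s2, s3 = track.areas
    return ContractionMeasure(
        track_id=track.track_id,
        delta_control=(s1 - s2) / s1,
        delta_drug=(s2 - s3) / s2,
    )


def contraction_population(measures: Sequence[ContractionMeasure]):
    """Population view of the contraction measures.

    Returns ``(control, drug, summary_control, summary_drug, p_value)``:
    the two sample vectors, their box-plot summaries, and the two-sided
    Mann-Whitney p-value comparing control vs drug area changes.
    """
    if len(measures) < 2:
        raise ValueError("at least two complete measures are required")
    control = np.array([m.delta_control for m in measures])
    drug = np.array([m.delta_drug for m in measures])
    return (
        control,
        drug,
        summarize_distribution(control),
        summarize_distribution(drug),
        rank_test(control, drug),
    )
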