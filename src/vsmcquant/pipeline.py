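"""End-to-end assay pipelines and the comparison report.

``run_calcium_pipeline`` composes ROI detection -> trace extraction ->
F/F0 normalization -> event detection -> MP/SP classification -> half-max
kinetics, and reports the responding fraction (ROIs with an MP over the
total cell count in the field of view).  ``run_contraction_pipeline``
composes segmentation -> three-state tracking -> per-cell delta-S/S.
``run_compare`` computes the D value and category for the standard
measurement set of two analyzed groups.  Every run writes CSV tables, PNG
figures and a JSON manifest recording the full configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .compare import compare_populations
from .config import RunConfig
from .contraction import (
    compute_contraction,
    contraction_population,
    segment_cells,
    track_cells,
)
from .kinetics import (
    classify_events,
    detect_events,
    event_count_per_roi,
    measure_all_kinetics,
    normalize_trace,
    responding_fraction,
)
from .roi import count_total_cells, detect_rois, extract_trace
from .types import MP, TimeSeriesStack

__all__ = [
    "CalciumResult",
    "ContractionResult",
    "run_calcium_pipeline",
    "run_contraction_pipeline",
    "run_compare",
    "load_stack",
    "EVENTS_CSV_COLUMNS",
]

logger = logging.getLogger(__name__)

EVENTS_CSV_COLUMNS = [
    "roi_id",
    "label",
    "onset_s",
    "peak_s",
    "peak_f_over_f0",
    "time_to_peak_s",
    "decay_s",
    "duration_s",
    "censored",
]


def load_stack(path, config: RunConfig) -> TimeSeriesStack:
    """Read a multi-page TIFF recording under a run configuration."""
    frames = tifffile.imread(str(path))
    if frames.ndim == 2:
        raise ValueError("a recording needs more than one frame")
    return TimeSeriesStack(
        frames=frames,
        frame_interval=config.frame_interval,
        protocol=config.protocol(),
    )


@dataclass
class CalciumResult:
    rois: list
    events: pd.DataFrame
    counts_per_roi: dict
    n_responding: int
    n_total_cells: int
    responding_fraction: float


def run_calcium_pipeline(
    stack: TimeSeriesStack,
    config: Optional[RunConfig] = None,
    out_dir: Optional[str] = None,
    reference_frame: Optional[np.ndarray] = None,
    write_plots: bool = True,
) -> CalciumResult:
    """Analyze one Ca2+ recording end to end.

    ``reference_frame`` is the dye-loaded frame used to count the total
    number of cells (denominator of the responding fraction); by default the
    maximum-intensity projection of the stack is used.
    """
    config = config or RunConfig()
    protocol = stack.protocol
    rois = detect_rois(stack, alpha=config.alpha, min_size=config.min_size)
    rows = []
    all_events = []
    for roi in rois:
        trace = normalize_trace(extract_trace(stack, roi), protocol)
        events = detect_events(trace, alpha=config.alpha, protocol=protocol)
        classify_events(events, protocol)
        kin = measure_all_kinetics(trace, events)
        for ev, k in zip(events, kin):
            all_events.append(ev)
            rows.append(
                {
                    "roi_id": roi.roi_id,
                    "label": ev.label,
                    "onset_s": round(ev.onset_time, 6),
                    "peak_s": round(ev.peak_index * trace.frame_interval, 6),
                    "peak_f_over_f0": round(ev.peak_value, 6),
                    "time_to_peak_s": round(k.time_to_peak, 6),
                    "decay_s": round(k.decay, 6) if not k.censored else "",
                    "duration_s": round(k.duration, 6) if not k.censored else "",
                    "censored": k.censored,
                }
            )
    events_df = pd.DataFrame(rows, columns=EVENTS_CSV_COLUMNS)
    counts = event_count_per_roi(all_events)
    n_responding = sum(1 for ev in all_events if ev.label == MP)
    if reference_frame is None:
        # mean projection: dye-loaded cells stand out against background
        # without the activity bias of a maximum projection
        reference_frame = np.asarray(stack.frames).mean(axis=0)
    n_total = count_total_cells(reference_frame, min_size=config.min_size)
    if n_total < n_responding:
        logger.warning(
            "total-cell count (%d) below responding ROI count (%d); "
            "using the responding count as denominator", n_total, n_responding,
        )
        n_total = n_responding
    frac = responding_fraction(n_responding, n_total) if n_total > 0 else 0.0

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        events_df.to_csv(out / "events.csv", index=False)
        pd.DataFrame(
            [
                {
                    "roi_id": r.roi_id,
                    "centroid_row": round(r.centroid[0], 3),
                    "centroid_col": round(r.centroid[1], 3),
                    "n_pixels": r.n_pixels,
                }
                for r in rois
            ],
            columns=["roi_id", "centroid_row", "centroid_col", "n_pixels"],
        ).to_csv(out / "rois.csv", index=False)
        _write_manifest(
            out,
            config,
            assay="calcium",
            counts={
                "n_rois": len(rois),
                "n_events": len(events_df),
                "n_responding": n_responding,
                "n_total_cells": n_total,
                "responding_fraction": frac,
            },
        )
        if write_plots:
            from .plots import plot_histogram

            mp = events_df[events_df["label"] == "MP"]
            plot_histogram(
                list(counts.values()), "Events within ROI", "events per ROI",
                out / "events_per_roi.png", bins=config.n_bins,
            )
            for col, name in [
                ("time_to_peak_s", "time to peak (s)"),
                ("decay_s", "decay (s)"),
                ("duration_s", "duration (s)"),
            ]:
                vals = pd.to_numeric(mp[col], errors="coerce").dropna()
                plot_histogram(
                    vals, f"MP {name}", name, out / f"mp_{col}.png", bins=config.n_bins
                )
    return CalciumResult(
        rois=rois,
        events=events_df,
        counts_per_roi=counts,
        n_responding=n_responding,
        n_total_cells=n_total,
        responding_fraction=frac,
    )


@dataclass
class ContractionResult:
    tracks: list
    measures: list
    table: pd.DataFrame
    summary_control: object
    summary_drug: object
    p_value: float


def run_contraction_pipeline(
    frames: np.ndarray,
    config: Optional[RunConfig] = None,
    out_dir: Optional[str] = None,
    write_plots: bool = True,
) -> ContractionResult:
    """Analyze a three-state contraction sequence end to end."""
    config = config or RunConfig(assay="contraction")
    frames = np.asarray(frames)
    if frames.shape[0] != 3:
        raise ValueError("three state frames are required (pre, control, drug)")
    masks = [segment_cells(f, min_size=config.min_size) for f in frames]
    tracks = track_cells(masks)
    complete = [t for t in tracks if t.complete]
    measures = [compute_contraction(t) for t in complete]
    rows = []
    for t in tracks:
        m = compute_contraction(t) if t.complete else None
        s1, s2, s3 = t.areas
        rows.append(
            {
                "track_id": t.track_id,
                "s1_px": s1 if s1 is not None else "",
                "s2_px": s2 if s2 is not None else "",
                "s3_px": s3 if s3 is not None else "",
                "delta_control": round(m.delta_control, 6) if m else "",
                "delta_drug": round(m.delta_drug, 6) if m else "",
                "complete": t.complete,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["track_id", "s1_px", "s2_px", "s3_px",
                 "delta_control", "delta_drug", "complete"],
    )
    if len(measures) >= 2:
        control, drug, sum_c, sum_d, p = contraction_population(measures)
    else:
        control = drug = np.array([])
        sum_c = sum_d = None
        p = float("nan")
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "tracks.csv", index=False)
        _write_manifest(
            out,
            config,
            assay="contraction",
            counts={
                "n_tracks": len(tracks),
                "n_complete": len(complete),
                "p_value_control_vs_drug": None if np.isnan(p) else p,
            },
        )
        if write_plots and len(measures) >= 2:
            from .plots import plot_box_pair, plot_histogram

            plot_histogram(100 * drug, "Relative area decrease (drug)",
                           "delta S/S (%)", out / "delta_drug.png", bins=config.n_bins)
            plot_box_pair(100 * control, 100 * drug, "delta S/S",
                          "delta S/S (%)", out / "delta_box.png")
    return ContractionResult(
        tracks=tracks,
        measures=measures,
        table=table,
        summary_control=sum_c,
        summary_drug=sum_d,
        p_value=p,
    )


# Measurement set reported by the comparison step: events-within-ROI counts
# plus MP and SP half-max kinetics (and delta S/S when present).
_KINETIC_COLS = [
    ("time_to_peak_s", "time_to_peak"),
    ("decay_s", "decay"),
    ("duration_s", "duration"),
]


def _group_samples(events: pd.DataFrame) -> dict:
    """Extract the comparable sample vectors from an events table."""
    out = {}
    counts = events[events["label"].isin(["MP", "SP"])].groupby("roi_id").size()
    out[("events_within_roi", "events_within_roi")] = counts.to_numpy(dtype=float)
    for label in ("MP", "SP"):
        sub = events[events["label"] == label]
        for col, name in _KINETIC_COLS:
            vals = pd.to_numeric(sub[col], errors="coerce").dropna().to_numpy()
            out[("ca_kinetics", f"{label.lower()}_{name}")] = vals
    return out


def run_compare(
    events_a: pd.DataFrame,
    events_b: pd.DataFrame,
    config: Optional[RunConfig] = None,
    out_dir: Optional[str] = None,
    deltas_a: Optional[Sequence[float]] = None,
    deltas_b: Optional[Sequence[float]] = None,
    group_names: tuple = ("A", "B"),
) -> pd.DataFrame:
    """D-metric comparison report between two analyzed groups.

    Compares the events-within-ROI counts and the MP/SP kinetic parameters
    of two event tables (plus delta S/S vectors when given), all on shared
    ``n_bins`` equal-width bins.
    """
    config = config or RunConfig(assay="compare")
    sa = _group_samples(events_a)
    sb = _group_samples(events_b)
    rows = []
    for key in sa:
        mtype, name = key
        a, b = sa[key], sb[key]
        if a.size == 0 or b.size == 0:
            continue
        cmp_res = compare_populations(a, b, mtype, n_bins=config.n_bins)
        rows.append(_compare_row(name, cmp_res, group_names))
    if deltas_a is not None and deltas_b is not None:
        cmp_res = compare_populations(
            deltas_a, deltas_b, "contraction", n_bins=config.n_bins
        )
        rows.append(_compare_row("delta_s_over_s", cmp_res, group_names))
    table = pd.DataFrame(
        rows,
        columns=["measurement", "measurement_type", "group_a", "group_b",
                 "n_a", "n_b", "n_bins", "d_value", "category"],
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "comparison.csv", index=False)
        _write_manifest(out, config, assay="compare",
                        counts={"n_comparisons": len(table)})
    return table


def _compare_row(name, cmp_res, group_names) -> dict:
    return {
        "measurement": name,
        "measurement_type": cmp_res.measurement_type,
        "group_a": group_names[0],
        "group_b": group_names[1],
        "n_a": cmp_res.n_a,
        "n_b": cmp_res.n_b,
        "n_bins": cmp_res.n_bins,
        "d_value": round(cmp_res.d_value, 6),
        "category": cmp_res.category,
    }


def _write_manifest(out: Path, config: RunConfig, assay: str, counts: dict) -> None:
    manifest = {
        "package": "vsmcquant",
        "version": __version__,
        "assay": assay,
        "config": config.to_dict(),
        "counts": counts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
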