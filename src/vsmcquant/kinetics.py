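"""Per-trace Ca2+ event detection, MP/SP classification and peak kinetics.

Definitions:

* F/F0: raw intensity divided by the mean over the pre-control baseline
  window, so the resting level is 1.0;
* an event is a local maximum of the smoothed F/F0 trace exceeding
  ``1 + z_(1-alpha) * CV`` where CV is the baseline coefficient of variation;
  two maxima separated by a dip below the half-maximum level are distinct
  events, otherwise they merge into one;
* MP (main peak): the first event whose half-max onset falls within the MP
  window (default ~100 s) after vasoconstrictor administration; SPs are the
  later events of an ROI with two or more classified peaks; events with
  onsets at or before the drug time stay unclassified;
* kinetics are referenced to the half-maximum level (baseline + peak)/2 with
  the baseline fixed at F/F0 = 1: time to peak is the interval from the last
  upward half-max crossing to the peak, decay from the peak to the first
  downward crossing, duration their sum (the full width at half maximum).
  Crossing times use linear interpolation between frames.  When the trace
  never re-crosses the half-max before the next event or the recording end,
  the decay is censored and decay/duration are omitted downstream.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks
from scipy.stats import norm

from .types import MP, SP, UNCLASSIFIED, CalciumEvent, FluorescenceTrace, PeakKinetics, StimulusProtocol

__all__ = [
    "normalize_trace",
    "detect_events",
    "classify_events",
    "measure_kinetics",
    "measure_all_kinetics",
    "responding_fraction",
    "event_count_per_roi",
]

BASELINE_LEVEL = 1.0
MIN_BASELINE_FRAMES = 5
SMOOTH_WINDOW = 3


def normalize_trace(trace: FluorescenceTrace, protocol: StimulusProtocol) -> FluorescenceTrace:
    """Normalize a raw trace to F/F0.

    F0 is the mean raw intensity over the frames acquired strictly before
    ``control_time``; at least five baseline frames are required and F0 must
    be positive.
    """
    baseline_sel = trace.times < protocol.control_time
    n_base = int(baseline_sel.sum())
    if n_base < MIN_BASELINE_FRAMES:
        raise ValueError(f"baseline window has {n_base} frames; need >= {MIN_BASELINE_FRAMES}")
    f0 = float(trace.raw[baseline_sel].mean())
    if f0 <= 0:
        raise ValueError("non-positive baseline F0")
    return trace.with_f0(f0, n_base)


def _baseline_frames(trace: FluorescenceTrace, protocol: Optional[StimulusProtocol]) -> int:
    if protocol is not None:
        return int((trace.times < protocol.control_time).sum())
    if trace.baseline_frames is not None:
        return trace.baseline_frames
    return max(MIN_BASELINE_FRAMES, trace.n_frames // 10)


def detect_events(
    trace: FluorescenceTrace,
    alpha: float = 0.01,
    protocol: Optional[StimulusProtocol] = None,
    smooth_window: int = SMOOTH_WINDOW,
) -> list:
    """Detect Ca2+ release events on a normalized trace.

    Returns events sorted by peak time; an event-free trace yields an empty
    list.  Peak indices and values are refined on the unsmoothed F/F0 trace.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    y = trace.normalized
    n_base = _baseline_frames(trace, protocol)
    if n_base < MIN_BASELINE_FRAMES:
        raise ValueError("baseline window too short for noise estimation")
    sm = uniform_filter1d(y, size=smooth_window, mode="nearest")
    # CV from the unsmoothed baseline, threshold applied to the smoothed
    # trace: smoothing shrinks the noise SD, so the per-point test is
    # conservative at level alpha (same scheme as ROI detection)
    base = y[:n_base]
    cv = float(base.std(ddof=1) / base.mean()) if base.mean() > 0 else 0.0
    threshold = BASELINE_LEVEL + norm.ppf(1.0 - alpha) * cv
    peaks, _ = find_peaks(sm, height=max(threshold, np.nextafter(BASELINE_LEVEL, 2.0)))
    if peaks.size == 0:
        return []

    # merge maxima not separated by a dip below the pairwise half-max level
    kept = [int(peaks[0])]
    for q in peaks[1:]:
        p = kept[-1]
        valley = sm[p : q + 1].min()
        half = (BASELINE_LEVEL + min(sm[p], sm[q])) / 2.0
        if valley < half:
            kept.append(int(q))
        elif sm[q] > sm[p]:
            kept[-1] = int(q)

    half_w = smooth_window // 2 + 1
    events = []
    seen = set()
    for p in kept:
        lo = max(0, p - half_w)
        hi = min(len(y), p + half_w + 1)
        pk = lo + int(np.argmax(y[lo:hi]))
        if pk in seen:
            continue
        seen.add(pk)
        pv = float(y[pk])
        if pv <= BASELINE_LEVEL:
            continue
        hm = (BASELINE_LEVEL + pv) / 2.0
        onset_idx, onset_time = _upward_crossing(y, pk, hm, trace.frame_interval)
        events.append(
            CalciumEvent(
                roi_id=trace.roi_id,
                onset_index=onset_idx,
                peak_index=pk,
                peak_value=pv,
                onset_time=onset_time,
            )
        )
    events.sort(key=lambda e: e.peak_index)
    return events


def _upward_crossing(y: np.ndarray, peak: int, level: float, fi: float):
    """Last upward crossing of ``level`` before ``peak`` (linear interpolation)."""
    for j in range(peak - 1, -1, -1):
        if y[j] < level <= y[j + 1]:
            frac = (level - y[j]) / (y[j + 1] - y[j])
            return j, (j + frac) * fi
    return 0, 0.0


def _downward_crossing(y: np.ndarray, peak: int, limit: int, level: float, fi: float):
    """First downward crossing of ``level`` after ``peak``, before ``limit``."""
    for i in range(peak, min(limit, len(y)) - 1):
        if y[i] >= level > y[i + 1]:
            frac = (y[i] - level) / (y[i] - y[i + 1])
            return (i + frac) * fi
    return None


def classify_events(events: list, protocol: StimulusProtocol) -> list:
    """Assign MP/SP labels following the main-peak window rule.

    The first event whose onset falls in ``(drug_time, drug_time + mp_window]``
    is the MP; later events become SPs when the ROI has two or more
    classified peaks in total.  Events with onsets at or before the drug time
    stay unclassified, as do all events of an ROI whose first post-drug event
    misses the window (a non-responding ROI).
    """
    if any(events[i].peak_index > events[i + 1].peak_index for i in range(len(events) - 1)):
        raise ValueError("events must be sorted by peak time")
    for ev in events:
        ev.label = UNCLASSIFIED
    post = [ev for ev in events if ev.onset_time > protocol.drug_time]
    if not post:
        return events
    first = post[0]
    if first.onset_time <= protocol.drug_time + protocol.mp_window:
        first.label = MP
        if len(post) >= 2:
            for ev in post[1:]:
                ev.label = SP
    return events


def measure_kinetics(
    trace: FluorescenceTrace,
    event: CalciumEvent,
    next_event: Optional[CalciumEvent] = None,
) -> PeakKinetics:
    """Half-maximum kinetics of one event.

    The decay search stops at the next event's peak (or the recording end);
    if the trace has not re-crossed the half-max by then the decay is
    censored.
    """
    y = trace.normalized
    fi = trace.frame_interval
    pk = event.peak_index
    if pk >= len(y):
        raise ValueError("event peak outside the trace")
    pv = float(y[pk])
    if pv <= BASELINE_LEVEL:
        raise ValueError("peak value must exceed the baseline level")
    hm = (BASELINE_LEVEL + pv) / 2.0
    _, t_up = _upward_crossing(y, pk, hm, fi)
    time_to_peak = pk * fi - t_up
    limit = next_event.peak_index if next_event is not None else len(y)
    t_down = _downward_crossing(y, pk, limit, hm, fi)
    if t_down is None:
        return PeakKinetics(
            time_to_peak=time_to_peak,
            decay=None,
            duration=None,
            half_max_level=hm,
            censored=True,
        )
    decay = t_down - pk * fi
    return PeakKinetics(
        time_to_peak=time_to_peak,
        decay=decay,
        duration=time_to_peak + decay,
        half_max_level=hm,
        censored=False,
    )


def measure_all_kinetics(trace: FluorescenceTrace, events: list) -> list:
    """Kinetics for every event of a trace, censoring across neighbours."""
    out = []
    for i, ev in enumerate(events):
        nxt = events[i + 1] if i + 1 < len(events) else None
        kin = measure_kinetics(trace, ev, next_event=nxt)
        ev.decay_censored = kin.censored
        out.append(kin)
    return out


def responding_fraction(n_responding: int, n_total: int) -> float:
    """Fraction of cells with a detected main peak."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_responding <= n_total:
        raise ValueError("need 0 <= n_responding <= n_total")
    return n_responding / n_total


def event_count_per_roi(events: list) -> dict:
    """Number of classified (MP + SP) events per ROI."""
    counts: dict = {}
    for ev in events:
        if ev.label in (MP, SP):
            counts[ev.roi_id] = counts.get(ev.roi_id, 0) + 1
    return counts
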