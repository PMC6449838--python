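"""Seeded synthetic data with attached ground truth.

This module emulates the statistical structure the downstream analysis
assumes so that every stage can be validated without microscope recordings:

* per-ROI F/F0 traces: baseline ~= 1, additive Gaussian noise, and 0..N
  Ca2+ transients whose half-maximum kinetics are known analytically
  (linear rise, exponential or triangular fall);
* population structure: event counts per ROI drawn from a geometric family
  (the discrete analog of an exponential count histogram), time-to-peak and
  decay from positively skewed log-normals, optionally a two-component
  mixture to produce bimodal time-to-peak histograms;
* Fluo-4-like image stacks: disk-shaped cells whose pixels follow their
  trace at camera scale, on a noisy background;
* calcein-like contraction sequences: bright ellipses rendered at three
  prescribed areas (pre-stimulus, post-control, post-drug) with optional
  centroid jitter to exercise tracking.

All generators take a seed and are bit-reproducible for a fixed seed.
Events are placed on the frame grid so that, for noiseless traces, the
half-maximum crossings on the linear rise are recovered exactly by linear
interpolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from .types import FluorescenceTrace, StimulusProtocol, TimeSeriesStack

__all__ = [
    "EventSpec",
    "TraceGroundTruth",
    "ContractionGroundTruth",
    "KineticsDistributions",
    "generate_trace",
    "generate_population",
    "generate_calcium_stack",
    "generate_contraction_sequence",
    "write_stack",
    "write_population",
]


@dataclass(frozen=True)
class EventSpec:
    """One prescribed Ca2+ transient.

    The pulse rises linearly from the baseline at ``onset_time`` to
    ``peak_amplitude`` at ``peak_time`` and falls back with a shape chosen at
    generation time.  ``half_max_duration`` is the full width of the pulse at
    the half-maximum level; for a linear rise the upward half-max crossing
    sits at the midpoint of the rise, so the analytic time-to-peak is
    ``(peak_time - onset_time) / 2`` and the analytic decay is
    ``half_max_duration - time_to_peak``.
    """

    onset_time: float
    peak_time: float
    peak_amplitude: float
    half_max_duration: float

    @property
    def rise_time(self) -> float:
        return self.peak_time - self.onset_time

    @property
    def time_to_peak(self) -> float:
        """Half-max-referenced rise interval (s)."""
        return self.rise_time / 2.0

    @property
    def decay(self) -> float:
        """Half-max-referenced fall interval (s)."""
        return self.half_max_duration - self.time_to_peak

    @property
    def half_onset_time(self) -> float:
        """Time of the upward half-maximum crossing (s)."""
        return self.onset_time + self.time_to_peak


@dataclass
class TraceGroundTruth:
    roi_id: int
    events: list  # of EventSpec, sorted by onset_time
    baseline_level: float = 1.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.baseline_level <= 0:
            raise ValueError("baseline_level must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        prev = -np.inf
        for ev in self.events:
            if ev.onset_time < prev:
                raise ValueError("events must be sorted by onset_time")
            prev = ev.onset_time
            if not ev.peak_time > ev.onset_time >= 0:
                raise ValueError("need 0 <= onset_time < peak_time")
            if ev.peak_amplitude <= self.baseline_level:
                raise ValueError("peak_amplitude must exceed the baseline")
            if ev.decay <= 0:
                raise ValueError(
                    "half_max_duration must exceed half the rise time"
                )


@dataclass(frozen=True)
class ContractionGroundTruth:
    """Prescribed areas of one cell in the three stimulation states."""

    cell_id: int
    true_areas: tuple  # (S1, S2, S3) in pixels

    def __post_init__(self) -> None:
        if len(self.true_areas) != 3 or any(a <= 0 for a in self.true_areas):
            raise ValueError("three positive areas are required")

    @property
    def true_delta_control(self) -> float:
        s1, s2, _ = self.true_areas
        return (s1 - s2) / s1

    @property
    def true_delta_drug(self) -> float:
        _, s2, s3 = self.true_areas
        return (s2 - s3) / s2


def _pulse(t: np.ndarray, ev: EventSpec, baseline: float, shape: str) -> np.ndarray:
    """Additive contribution of one event, zero outside its support."""
    amp = ev.peak_amplitude - baseline
    out = np.zeros_like(t)
    rising = (t >= ev.onset_time) & (t <= ev.peak_time)
    out[rising] = amp * (t[rising] - ev.onset_time) / ev.rise_time
    falling = t > ev.peak_time
    dt = t[falling] - ev.peak_time
    if shape == "exp":
        # decay equals one half-life of the amplitude above baseline
        out[falling] = amp * 0.5 ** (dt / ev.decay)
    elif shape == "triangle":
        fall_total = 2.0 * ev.decay
        out[falling] = amp * np.clip(1.0 - dt / fall_total, 0.0, None)
    else:
        raise ValueError(f"unknown pulse shape {shape!r}")
    return out


def generate_trace(
    ground_truth: TraceGroundTruth,
    duration: float,
    frame_interval: float,
    seed: int = 0,
    shape: str = "exp",
) -> FluorescenceTrace:
    """Sample a synthetic F/F0 trace from its ground truth.

    Parameters
    ----------
    ground_truth : TraceGroundTruth
        Baseline, noise level and prescribed events.
    duration : float
        Recording length (s); must cover all event peaks.
    frame_interval : float
        Sampling interval (s).
    seed : int
        Seed for the Gaussian noise stream.
    shape : {"exp", "triangle"}
        Fall shape: exponential with a half-life equal to the analytic decay,
        or linear with a matched half-max width.
    """
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    for ev in ground_truth.events:
        if ev.peak_time >= duration:
            raise ValueError("event outside the recording window")
    n = int(round(duration / frame_interval))
    t = np.arange(n) * frame_interval
    y = np.full(n, ground_truth.baseline_level, dtype=float)
    for ev in ground_truth.events:
        y += _pulse(t, ev, ground_truth.baseline_level, shape)
    if ground_truth.noise_sd > 0:
        rng = np.random.default_rng(seed)
        y += rng.normal(0.0, ground_truth.noise_sd, n)
    return FluorescenceTrace(
        roi_id=ground_truth.roi_id,
        raw=y,
        frame_interval=frame_interval,
        f0=1.0,
        ground_truth=ground_truth,
    )


@dataclass
class KineticsDistributions:
    """Log-normal families for the per-event kinetic parameters.

    ``ttp_*`` parametrize the half-max time-to-peak, ``decay_*`` the half-max
    decay, ``amp_*`` the peak amplitude above baseline; all log-space
    mean/sigma.  A second time-to-peak component with weight
    ``ttp_mix_weight`` produces the bimodal histograms seen in slow/fast
    responder subpopulations.
    """

    ttp_log_mean: float = np.log(8.0)
    ttp_log_sd: float = 0.35
    ttp_mix_log_mean: Optional[float] = None
    ttp_mix_log_sd: float = 0.2
    ttp_mix_weight: float = 0.0
    decay_log_mean: float = np.log(10.0)
    decay_log_sd: float = 0.4
    amp_log_mean: float = np.log(1.5)
    amp_log_sd: float = 0.3

    def __post_init__(self) -> None:
        if min(self.ttp_log_sd, self.ttp_mix_log_sd, self.decay_log_sd, self.amp_log_sd) < 0:
            raise ValueError("log-space standard deviations must be >= 0")
        if not 0.0 <= self.ttp_mix_weight <= 1.0:
            raise ValueError("ttp_mix_weight must lie in [0, 1]")
        if self.ttp_mix_weight > 0 and self.ttp_mix_log_mean is None:
            raise ValueError("mixture weight set but no second component given")

    def sample_time_to_peak(self, rng: np.random.Generator, size: int) -> np.ndarray:
        base = rng.lognormal(self.ttp_log_mean, self.ttp_log_sd, size)
        if self.ttp_mix_weight > 0:
            alt = rng.lognormal(self.ttp_mix_log_mean, self.ttp_mix_log_sd, size)
            pick = rng.random(size) < self.ttp_mix_weight
            base = np.where(pick, alt, base)
        return base

    def sample_decay(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.lognormal(self.decay_log_mean, self.decay_log_sd, size)

    def sample_amplitude(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return np.maximum(rng.lognormal(self.amp_log_mean, self.amp_log_sd, size), 0.4)


DEFAULT_PROTOCOL = StimulusProtocol(control_time=60.0, drug_time=120.0, mp_window=100.0)


def generate_population(
    n_rois: int,
    event_count_mean: float = 2.0,
    kinetics: Optional[KineticsDistributions] = None,
    seed: int = 0,
    protocol: StimulusProtocol = DEFAULT_PROTOCOL,
    duration: float = 600.0,
    frame_interval: float = 1.0,
    noise_sd: float = 0.0,
    shape: str = "exp",
    late_fraction: float = 0.0,
) -> list:
    """Generate a population of per-ROI traces with known events.

    Event counts per ROI follow a geometric distribution on {0, 1, 2, ...}
    with the given mean.  The first event of a responding ROI is placed so
    that its half-max onset falls inside the MP window after ``drug_time``;
    with probability ``late_fraction`` an ROI is instead a late responder
    whose first onset falls after the window closes.  Subsequent events are
    spaced beyond the previous pulse's extent so transients do not merge.
    Onset and peak times are snapped to the frame grid.

    Returns a list of :class:`FluorescenceTrace` with ``ground_truth``
    attached.
    """
    if n_rois < 1:
        raise ValueError("n_rois must be >= 1")
    if event_count_mean < 0:
        raise ValueError("event_count_mean must be >= 0")
    if not 0.0 <= late_fraction <= 1.0:
        raise ValueError("late_fraction must lie in [0, 1]")
    kin = kinetics or KineticsDistributions()
    rng = np.random.default_rng(seed)
    fi = frame_interval
    margin = max(5.0, 2 * fi)
    traces = []
    for i in range(n_rois):
        # geometric on {1, 2, ...} shifted down: mean = event_count_mean
        count = int(rng.geometric(1.0 / (1.0 + event_count_mean)) - 1)
        late = rng.random() < late_fraction
        events = []
        cursor = None
        for k in range(count):
            ttp = float(kin.sample_time_to_peak(rng, 1)[0])
            rise_frames = max(2, int(round(2.0 * ttp / fi)))
            rise = rise_frames * fi
            decay = float(np.maximum(kin.sample_decay(rng, 1)[0], 1.5 * fi))
            amp = 1.0 + float(kin.sample_amplitude(rng, 1)[0])
            if k == 0:
                if late:
                    half_onset = protocol.drug_time + protocol.mp_window + rng.uniform(
                        margin + 2 * fi, 60.0
                    )
                else:
                    half_onset = protocol.drug_time + rng.uniform(
                        margin, protocol.mp_window - margin
                    )
                onset = half_onset - rise / 2.0
            else:
                onset = cursor + rng.uniform(5.0, 15.0)
            onset = round(onset / fi) * fi
            onset = max(onset, protocol.drug_time + fi)
            peak = onset + rise
            if peak + 5.0 * decay > duration - 2 * fi:
                break
            events.append(
                EventSpec(
                    onset_time=onset,
                    peak_time=peak,
                    peak_amplitude=amp,
                    half_max_duration=rise / 2.0 + decay,
                )
            )
            cursor = peak + 5.0 * decay
        gt = TraceGroundTruth(roi_id=i, events=events, noise_sd=noise_sd)
        traces.append(
            generate_trace(
                gt,
                duration=duration,
                frame_interval=fi,
                seed=int(rng.integers(2**31)),
                shape=shape,
            )
        )
    return traces


def _disk_mask(shape, row, col, radius) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw_disk((row, col), radius, shape=None)
    if rr.min() < 0 or cc.min() < 0 or rr.max() >= shape[0] or cc.max() >= shape[1]:
        raise ValueError("cell footprint extends outside the image")
    mask[rr, cc] = True
    return mask


def generate_calcium_stack(
    traces: Sequence[FluorescenceTrace],
    layout: Sequence[tuple],
    image_shape: tuple,
    protocol: StimulusProtocol = DEFAULT_PROTOCOL,
    seed: int = 0,
    cell_scale: float = 1000.0,
    background: float = 100.0,
    read_noise_sd: float = 0.0,
    n_frames: Optional[int] = None,
    frame_interval: float = 1.0,
):
    """Render traces as a Fluo-4-like image stack.

    ``layout`` is one ``(row, col, radius)`` disk per trace; footprints must
    fit inside the image and may not overlap.  Inside a cell the pixel value
    is ``cell_scale * F/F0``; elsewhere it is ``background``, plus optional
    Gaussian read noise everywhere, quantized to the 16-bit camera range.

    Returns ``(stack, masks)`` where ``masks`` are the true boolean
    footprints used for detection-recall tests.  With no traces a pure-noise
    stack of ``n_frames`` frames is produced.
    """
    if len(traces) != len(layout):
        raise ValueError("one layout entry per trace is required")
    if traces:
        n = traces[0].n_frames
        fi = traces[0].frame_interval
        if any(tr.n_frames != n or tr.frame_interval != fi for tr in traces):
            raise ValueError("all traces must share length and frame interval")
    else:
        if n_frames is None:
            raise ValueError("n_frames is required for a zero-cell stack")
        n, fi = n_frames, frame_interval
    masks = [_disk_mask(image_shape, r, c, rad) for r, c, rad in layout]
    for a in range(len(masks)):
        for b in range(a + 1, len(masks)):
            if np.any(masks[a] & masks[b]):
                raise ValueError("cell footprints may not overlap")
    rng = np.random.default_rng(seed)
    frames = np.full((n, *image_shape), background, dtype=float)
    for tr, mask in zip(traces, masks):
        frames[:, mask] = cell_scale * tr.normalized[:, None]
    if read_noise_sd > 0:
        frames += rng.normal(0.0, read_noise_sd, frames.shape)
    frames = np.clip(np.round(frames), 0, 65535).astype(np.uint16)
    stack = TimeSeriesStack(frames=frames, frame_interval=fi, protocol=protocol)
    return stack, masks


def _grid_centers(n: int, image_shape: tuple, max_radius: float) -> list:
    """Deterministic grid placement leaving a margin around each cell."""
    pitch = int(np.ceil(2 * max_radius + 6))
    per_row = max(1, (image_shape[1] - pitch // 2) // pitch)
    centers = []
    for i in range(n):
        r = pitch // 2 + 2 + (i // per_row) * pitch
        c = pitch // 2 + 2 + (i % per_row) * pitch
        if r + max_radius + 2 >= image_shape[0] or c + max_radius + 2 >= image_shape[1]:
            raise ValueError("image too small for the requested number of cells")
        centers.append((float(r), float(c)))
    return centers


def generate_contraction_sequence(
    ground_truths: Sequence[ContractionGroundTruth],
    image_shape: tuple,
    seed: int = 0,
    centers: Optional[Sequence[tuple]] = None,
    jitter: float = 0.0,
    aspect: float = 1.5,
    cell_level: float = 3000.0,
    background: float = 100.0,
    noise_sd: float = 0.0,
):
    """Render the three-state calcein-like contraction sequence.

    Each cell is an ellipse (axis ratio ``aspect``) whose rasterized area
    tracks the prescribed S1/S2/S3; centroids are perturbed per state by
    Gaussian jitter of the given SD (pixels).  Ellipses must not touch.

    Returns ``(frames, labels)``: a ``(3, h, w)`` uint16 image array and a
    ``(3, h, w)`` int32 label array with cell ids 1..n.
    """
    rng = np.random.default_rng(seed)
    max_r = max(
        np.sqrt(max(gt.true_areas) * aspect / np.pi) for gt in ground_truths
    ) if ground_truths else 0.0
    if centers is None:
        centers = _grid_centers(len(ground_truths), image_shape, max_r)
    if len(centers) != len(ground_truths):
        raise ValueError("one center per cell is required")
    frames = np.full((3, *image_shape), background, dtype=float)
    labels = np.zeros((3, *image_shape), dtype=np.int32)
    for s in range(3):
        state_masks = []
        for gt, (r0, c0) in zip(ground_truths, centers):
            area = gt.true_areas[s]
            a = np.sqrt(area * aspect / np.pi)
            b = np.sqrt(area / (aspect * np.pi))
            dr = rng.normal(0.0, jitter) if jitter > 0 else 0.0
            dc = rng.normal(0.0, jitter) if jitter > 0 else 0.0
            rr, cc = draw_ellipse(r0 + dr, c0 + dc, a, b, shape=None)
            if (
                rr.min() <= 0
                or cc.min() <= 0
                or rr.max() >= image_shape[0] - 1
                or cc.max() >= image_shape[1] - 1
            ):
                raise ValueError("ellipse extends outside the image interior")
            mask = np.zeros(image_shape, dtype=bool)
            mask[rr, cc] = True
            state_masks.append(mask)
        # touching cells would merge under connected-component labeling
        for i in range(len(state_masks)):
            grown = np.zeros(image_shape, dtype=bool)
            m = state_masks[i]
            grown[:-1] |= m[1:]
            grown[1:] |= m[:-1]
            grown[:, :-1] |= m[:, 1:]
            grown[:, 1:] |= m[:, :-1]
            grown |= m
            for j in range(i + 1, len(state_masks)):
                if np.any(grown & state_masks[j]):
                    raise ValueError("ellipses may not touch")
        for cell_idx, mask in enumerate(state_masks):
            frames[s][mask] = cell_level
            labels[s][mask] = cell_idx + 1
    if noise_sd > 0:
        frames += rng.normal(0.0, noise_sd, frames.shape)
    frames = np.clip(np.round(frames), 0, 65535).astype(np.uint16)
    return frames, labels


# ---------------------------------------------------------------------------
# On-disk fixtures: TIFF stack + ground-truth CSV + JSON sidecar


def write_stack(stack: TimeSeriesStack, path) -> None:
    """Write a stack as a multi-page TIFF (one page per frame)."""
    tifffile.imwrite(str(path), np.asarray(stack.frames), photometric="minisblack")


def write_population(traces: Sequence[FluorescenceTrace], out_dir, seed: int,
                     protocol: StimulusProtocol = DEFAULT_PROTOCOL) -> None:
    """Write per-ROI traces, ground-truth events and a protocol sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for tr in traces:
        for frame, value in enumerate(tr.raw):
            rows.append({"roi_id": tr.roi_id, "frame": frame, "raw_intensity": value})
    pd.DataFrame(rows).to_csv(out / "traces.csv", index=False)
    ev_rows = []
    for tr in traces:
        gt = tr.ground_truth
        if gt is None:
            continue
        for ev in gt.events:
            ev_rows.append(
                {
                    "roi_id": gt.roi_id,
                    "onset_s": ev.onset_time,
                    "peak_s": ev.peak_time,
                    "peak_amplitude": ev.peak_amplitude,
                    "half_max_duration_s": ev.half_max_duration,
                }
            )
    pd.DataFrame(
        ev_rows,
        columns=["roi_id", "onset_s", "peak_s", "peak_amplitude", "half_max_duration_s"],
    ).to_csv(out / "ground_truth_events.csv", index=False)
    sidecar = {
        "seed": seed,
        "control_time_s": protocol.control_time,
        "drug_time_s": protocol.drug_time,
        "mp_window_s": protocol.mp_window,
        "frame_interval_s": traces[0].frame_interval if traces else None,
    }
    (out / "sidecar.json").write_text(json.dumps(sidecar, indent=2))
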