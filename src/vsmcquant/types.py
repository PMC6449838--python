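"""Core data structures shared by the Ca2+ and contraction assays.

Conventions used throughout the package:

* images are ``(row, col)`` arrays, 0-based, origin top-left;
* stacks are ``(time, row, col)`` with frame ``i`` acquired at ``i * frame_interval``
  seconds;
* fluorescence traces are normalized to the pre-stimulus baseline mean ``F0``,
  so the resting level of ``F/F0`` is 1.0 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "StimulusProtocol",
    "TimeSeriesStack",
    "FluorescenceTrace",
    "Roi",
    "CalciumEvent",
    "PeakKinetics",
    "CellTrack",
    "ContractionMeasure",
]


@dataclass(frozen=True)
class StimulusProtocol:
    """Timing of the two-step stimulation used in both assays.

    Parameters
    ----------
    control_time : float
        Time (s) at which medium only is added (negative control).
    drug_time : float
        Time (s) at which the vasoconstrictor is added.
    mp_window : float
        Length (s) of the window after ``drug_time`` in which the first
        Ca2+ release counts as the main peak (MP).  Default 100 s.
    """

    control_time: float
    drug_time: float
    mp_window: float = 100.0

    def __post_init__(self) -> None:
        if not 0 <= self.control_time < self.drug_time:
            raise ValueError(
                f"need 0 <= control_time < drug_time, got "
                f"{self.control_time} / {self.drug_time}"
            )
        if self.mp_window <= 0:
            raise ValueError("mp_window must be positive")


@dataclass
class TimeSeriesStack:
    """A fluorescence recording: frames x height x width intensities."""

    frames: np.ndarray
    frame_interval: float
    protocol: StimulusProtocol

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("frames must be a (time, h, w) array with >= 2 frames")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if not np.all(np.isfinite(self.frames)) or np.any(self.frames < 0):
            raise ValueError("intensities must be finite and non-negative")
        if self.protocol.drug_time >= self.duration:
            raise ValueError("protocol times must lie inside the recording")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def times(self) -> np.ndarray:
        """Acquisition time (s) of every frame."""
        return np.arange(self.n_frames) * self.frame_interval

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_interval


@dataclass
class FluorescenceTrace:
    """Per-ROI intensity over time, optionally baseline-normalized.

    ``raw`` holds camera-scale intensities; after normalization ``f0`` is the
    baseline mean and ``normalized`` returns ``raw / f0`` (F/F0).  Synthetic
    traces are generated directly in F/F0 units with ``f0 = 1``.
    """

    roi_id: int
    raw: np.ndarray
    frame_interval: float
    f0: Optional[float] = None
    baseline_frames: Optional[int] = None
    ground_truth: Optional[object] = None  # TraceGroundTruth for synthetic traces

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.ndim != 1 or self.raw.size < 2:
            raise ValueError("trace must be a 1-D array with >= 2 samples")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.f0 is not None and self.f0 <= 0:
            raise ValueError("f0 must be positive")

    @property
    def normalized(self) -> np.ndarray:
        """F/F0 trace; requires ``f0`` to be set."""
        if self.f0 is None:
            raise ValueError("trace is not normalized; call normalize_trace first")
        return self.raw / self.f0

    @property
    def n_frames(self) -> int:
        return self.raw.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def with_f0(self, f0: float, baseline_frames: int) -> "FluorescenceTrace":
        return replace(self, f0=f0, baseline_frames=baseline_frames)


@dataclass(frozen=True)
class Roi:
    """A spatially connected set of active pixels."""

    roi_id: int
    pixel_set: frozenset  # of (row, col)
    centroid: tuple  # (row, col), floats

    def __post_init__(self) -> None:
        if not self.pixel_set:
            raise ValueError("pixel_set must be non-empty")

    @property
    def n_pixels(self) -> int:
        return len(self.pixel_set)


# Event labels
MP = "MP"
SP = "SP"
UNCLASSIFIED = "UNCLASSIFIED"


@dataclass
class CalciumEvent:
    """One detected Ca2+ release transient within an ROI.

    ``onset_time`` is the last upward half-maximum crossing before the peak
    (linear interpolation, sub-frame resolution); ``onset_index`` is the frame
    containing that crossing.
    """

    roi_id: int
    onset_index: int
    peak_index: int
    peak_value: float
    onset_time: float
    label: str = UNCLASSIFIED
    decay_censored: bool = False

    def __post_init__(self) -> None:
        if self.onset_index > self.peak_index:
            raise ValueError("onset_index must not exceed peak_index")
        if self.label not in (MP, SP, UNCLASSIFIED):
            raise ValueError(f"unknown label {self.label!r}")


@dataclass(frozen=True)
class PeakKinetics:
    """Half-maximum-referenced shape parameters of one Ca2+ peak.

    time_to_peak: peak time minus the last upward half-max crossing (s).
    decay: first downward half-max crossing after the peak minus peak time (s);
        None when censored (trace never re-crosses before the next event or
        the end of the recording).
    duration: time_to_peak + decay (full width at half maximum, s); None when
        decay is censored.
    """

    time_to_peak: float
    decay: Optional[float]
    duration: Optional[float]
    half_max_level: float
    censored: bool = False

    def __post_init__(self) -> None:
        if self.time_to_peak < 0:
            raise ValueError("time_to_peak must be >= 0")
        if not self.censored:
            if self.decay is None or self.duration is None:
                raise ValueError("uncensored kinetics require decay and duration")
            if self.decay < 0:
                raise ValueError("decay must be >= 0")


@dataclass
class CellTrack:
    """One cell followed across the pre-stimulus / post-control / post-drug states."""

    track_id: int
    areas: tuple  # (S1, S2, S3); entries None when the cell is missing in a state
    centroids: tuple  # ((r, c) or None) per state

    @property
    def complete(self) -> bool:
        return all(a is not None for a in self.areas)

    def __post_init__(self) -> None:
        if len(self.areas) != 3 or len(self.centroids) != 3:
            raise ValueError("tracks span exactly three states")
        for a in self.areas:
            if a is not None and a <= 0:
                raise ValueError("areas must be positive where present")


@dataclass(frozen=True)
class ContractionMeasure:
    """Relative surface-area change of one tracked cell.

    delta_control = (S1 - S2) / S1 and delta_drug = (S2 - S3) / S2, where the
    S are the cell areas in the pre-stimulus, post-control and post-drug
    states.  Positive values mean contraction; negative values (area increase)
    are permitted.
    """

    track_id: int
    delta_control: float
    delta_drug: float

    def __post_init__(self) -> None:
        if self.delta_control > 1 or self.delta_drug > 1:
            raise ValueError("a fractional area decrease cannot exceed 1")
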