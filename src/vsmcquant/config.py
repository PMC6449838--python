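"""Run configuration with lossless YAML round-tripping."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .compare import CATEGORY_RANGES
from .types import StimulusProtocol

__all__ = ["RunConfig"]

_ASSAYS = ("calcium", "contraction", "compare", "simulate")


def _default_ranges() -> dict:
    return {k: list(v) for k, v in CATEGORY_RANGES.items()}


@dataclass
class RunConfig:
    """All tunables of one analysis run.

    Times are seconds, sizes are pixels.  ``category_ranges`` holds the
    (low-upper, moderate-upper) D boundaries per measurement type.
    """

    assay: str = "calcium"
    input_paths: list = field(default_factory=list)
    output_dir: str = "vsmcquant_out"
    control_time: float = 60.0
    drug_time: float = 120.0
    mp_window: float = 100.0
    frame_interval: float = 1.0
    alpha: float = 0.01
    n_bins: int = 30
    min_size: int = 9
    seed: int = 0
    category_ranges: dict = field(default_factory=_default_ranges)

    def __post_init__(self) -> None:
        if self.assay not in _ASSAYS:
            raise ValueError(f"assay must be one of {_ASSAYS}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_bins < 2 or self.min_size < 1:
            raise ValueError("n_bins >= 2 and min_size >= 1 are required")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        # constructs and thereby validates the protocol
        self.protocol()

    def protocol(self) -> StimulusProtocol:
        return StimulusProtocol(
            control_time=self.control_time,
            drug_time=self.drug_time,
            mp_window=self.mp_window,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)
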