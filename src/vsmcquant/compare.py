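"""Population-histogram comparison via the D-metric.

Two measurement populations are compared by binning both onto shared
equal-width bin edges, normalizing each histogram to probabilities A_i and
B_i, and evaluating

    D = 1/2 * sum_i |A_i - B_i|

the total-variation divergence between the two discrete distributions.
D = 0 for identical histograms and D = 1 when the histograms do not overlap
at all.  D values are interpreted with measurement-type-specific category
ranges (low / moderate / high) calibrated on intrapopulation replicate
comparisons; the printed two-decimal range boundaries are made half-open at
the midpoints of their gaps so every D in [0, 1] maps to exactly one
category.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import mannwhitneyu

__all__ = [
    "NormalizedHistogram",
    "DComparison",
    "CATEGORY_RANGES",
    "build_histogram_pair",
    "d_metric",
    "classify_d",
    "compare_populations",
    "summarize_distribution",
    "rank_test",
    "PopulationSummary",
]


@dataclass(frozen=True)
class NormalizedHistogram:
    """A probability histogram on explicit bin edges."""

    bin_edges: np.ndarray
    probabilities: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        probs = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "probabilities", probs)
        if probs.size != edges.size - 1:
            raise ValueError("need len(probabilities) == len(bin_edges) - 1")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if self.n_samples > 0 and abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1")


# Printed category boundaries per measurement type; intervals half-open at
# the midpoint of the printed gaps (e.g. 0.1 / 0.11 -> 0.105) so that
# [0, 1] is partitioned with no gaps.
CATEGORY_RANGES = {
    "events_within_roi": (0.105, 0.205),
    "ca_kinetics": (0.305, 0.455),
    "contraction": (0.255, 0.505),
}


@dataclass(frozen=True)
class DComparison:
    d_value: float
    measurement_type: str
    category: str
    n_a: int = 0
    n_b: int = 0
    n_bins: int = 0


def build_histogram_pair(samples_a, samples_b, n_bins: int = 30):
    """Histogram two sample sets on shared equal-width bins.

    Edges span the pooled min-max of both sets; the last bin is closed on
    the right (numpy convention).  A degenerate pooled range (all samples
    equal) yields a single unit-width bin containing everything, so the two
    histograms are identical and D = 0.
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both sample sets must be non-empty")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if lo == hi:
        edges = np.array([lo - 0.5, lo + 0.5])
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
    counts_a, _ = np.histogram(a, bins=edges)
    counts_b, _ = np.histogram(b, bins=edges)
    return (
        NormalizedHistogram(edges, counts_a / a.size, int(a.size)),
        NormalizedHistogram(edges, counts_b / b.size, int(b.size)),
    )


def d_metric(a: NormalizedHistogram, b: NormalizedHistogram) -> float:
    """D = 1/2 * sum_i |A_i - B_i| on shared bins."""
    if a.bin_edges.shape != b.bin_edges.shape or not np.allclose(
        a.bin_edges, b.bin_edges
    ):
        raise ValueError("histograms must share bin edges")
    return 0.5 * float(np.abs(a.probabilities - b.probabilities).sum())


def classify_d(d_value: float, measurement_type: str) -> str:
    """Map a D value to its low / moderate / high category."""
    if not 0.0 <= d_value <= 1.0:
        raise ValueError("D must lie in [0, 1]")
    try:
        lo_hi = CATEGORY_RANGES[measurement_type]
    except KeyError:
        raise ValueError(f"unknown measurement_type {measurement_type!r}") from None
    low_upper, moderate_upper = lo_hi
    if d_value < low_upper:
        return "low"
    if d_value < moderate_upper:
        return "moderate"
    return "high"


def compare_populations(
    samples_a, samples_b, measurement_type: str, n_bins: int = 30
) -> DComparison:
    """Build shared-bin histograms, compute D and categorize it."""
    ha, hb = build_histogram_pair(samples_a, samples_b, n_bins=n_bins)
    d = d_metric(ha, hb)
    return DComparison(
        d_value=d,
        measurement_type=measurement_type,
        category=classify_d(d, measurement_type),
        n_a=ha.n_samples,
        n_b=hb.n_samples,
        n_bins=ha.probabilities.size,
    )


@dataclass(frozen=True)
class PopulationSummary:
    """Box-plot summary: quartiles plus 10th/90th percentile whiskers."""

    q1: float
    median: float
    q3: float
    p10: float
    p90: float
    n: int


def summarize_distribution(samples) -> PopulationSummary:
    """Quartiles and 10th/90th percentiles (linear interpolation)."""
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("samples must be non-empty")
    p10, q1, med, q3, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    return PopulationSummary(
        q1=float(q1), median=float(med), q3=float(q3),
        p10=float(p10), p90=float(p90), n=int(x.size),
    )


def rank_test(samples_a, samples_b) -> float:
    """Two-sided Mann-Whitney rank-test p-value between two samples."""
    res = mannwhitneyu(samples_a, samples_b, alternative="two-sided")
    return float(res.pvalue)
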