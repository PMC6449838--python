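# Methods

This note records the models, conventions and design choices behind
`vsmcquant`, and what the synthetic-data tests do and do not establish
about real recordings.

## Recording model and conventions

A recording is a `(time, row, col)` intensity stack with a fixed frame
interval; frame *i* is taken at `i · frame_interval` seconds. The stimulus
protocol has two time points: `control_time` (medium-only addition, the
negative control) and `drug_time` (vasoconstrictor addition), with a
`mp_window` (default 100 s) after the drug during which the first Ca²⁺
release counts as the main peak. Frames strictly before `control_time`
form the baseline window; at least five baseline frames are required.
Defaults of 1 frame/s and 600 s recordings are configuration choices for
the synthetic conditions, not claims about any particular microscope.

## ROI detection

Per pixel, the baseline mean μ and standard deviation σ are estimated from
the raw pre-control frames. The stack is smoothed along time with a 3-frame
moving average, and a pixel is flagged active at a post-control frame when
its smoothed value exceeds μ + z₍₁₋α₎σ (one-sided normal quantile,
α = 0.01 default). Estimating σ on the unsmoothed frames while thresholding
the smoothed trace makes the per-pixel test conservative at level α: the
moving average shrinks the noise SD by √3, so the realized flag rate on
noise is far below α (the calibration test asserts the ≤ α bound over
≥ 10⁵ pixel-frames). Active pixels are grouped by 4-connectivity,
components smaller than `min_size` (default 9 px) are dropped, and ROI ids
are assigned in raster order of the centroids — a deterministic tie-break.

Trace-level event detection uses the same scheme: threshold
`1 + z₍₁₋α₎·CV` with the coefficient of variation taken from the unsmoothed
baseline of the F/F₀ trace, applied to the 3-frame-smoothed trace. Whether
thresholding should happen per pixel or per ROI trace is genuinely open;
both are implemented (per-pixel for ROI discovery, per-trace for event
calling on extracted traces), and both are exposed.

## Event model and half-maximum kinetics

Candidate events are local maxima of the smoothed F/F₀ trace above the
threshold. Two maxima are distinct events only when the valley between them
dips below their pairwise half-maximum level; otherwise they merge and the
higher maximum is kept. Peak index and value are then refined on the
unsmoothed trace.

Kinetics are referenced to the half-maximum level `(1 + (F/F₀)max) / 2`,
with the baseline fixed at F/F₀ = 1 — the normalization defines 1.0 as the
resting level, so a per-event local baseline is deliberately not used.
Crossing times are located by linear interpolation between frames, giving
sub-frame resolution and exact recovery on piecewise-linear pulses. If the
trace does not re-cross the half-max before the next event's peak or the
end of the recording, the decay is censored and decay/duration are excluded
from histograms; `duration = time_to_peak + decay` holds exactly for every
uncensored event by construction.

MP/SP labels follow the window rule applied to the detected half-max onset:
the first event with onset in `(drug_time, drug_time + mp_window]` is the
MP; later events are SPs when the ROI has ≥ 2 classified peaks. Events with
onsets at or before the drug time stay unclassified (control-period
activity), as do all events of an ROI whose first post-drug event misses
the window — such an ROI is non-responding, and leaving its later events
unclassified keeps SP statistics conditional on an MP existing. The window
is nominally "about 100 s"; it is configurable and defaults to exactly
100 s.

## Contraction

Segmentation is a global Otsu threshold followed by 4-connected labeling;
components under `min_size` or touching the image border (area censored by
the field of view) are discarded. Linking across the three states is
greedy maximal pixel overlap with deterministic tie-breaks (centroid
distance, then smaller label); objects with no overlap may still link to
the nearest unused object within one equivalent radius — adherent cells
move little between states, so overlap dominates in practice. Only
complete tracks enter ΔS/S; incomplete tracks are counted in the log
(cells that divide or detach are thereby excluded automatically). ΔS/S is
invariant to uniform intensity rescaling because Otsu's threshold scales
with the image.

## D-metric and category ranges

`D = ½ Σ|Aᵢ − Bᵢ|` is the total-variation divergence between two discrete
probability histograms on shared bins; it is a metric on probability
vectors and equals the largest difference in probability any set of bins
can receive (verified against brute-force subset enumeration in the tests).
D depends on the binning, so the bin count is a mandatory, logged
configuration value; the default is 30 equal-width bins over the pooled
range of both samples. A degenerate pooled range (all values identical)
yields one unit-width bin and D = 0. The low/moderate/high category ranges
are taken as given configuration per measurement type; the printed
two-decimal boundaries leave gaps (0.10 → 0.11), so the intervals are made
half-open at the gap midpoints (0.105, 0.205, …), partitioning [0, 1]
exactly. Control-vs-drug contraction distributions are compared with a
two-sided Mann–Whitney rank test, chosen because the distributions are
skewed and summarized by medians/quartiles.

## Synthetic data: what it emulates

Traces are `baseline (=1) + Σ pulses + N(0, noise_sd)`. Each pulse rises
linearly from its onset to its peak and falls either exponentially (decay
equals one half-life of the excursion) or linearly with a matched half-max
width — the simplest family in which time-to-peak, decay and duration are
analytically known. Event counts per ROI are geometric on {0, 1, 2, …}
(the discrete analog of an exponential count histogram); time-to-peak and
decay are log-normal (positively skewed), with an optional two-component
mixture producing bimodal time-to-peak histograms. First onsets are placed
so the half-max onset lands inside the MP window (or beyond it for a
configurable late-responder fraction); subsequent events are spaced past
the previous pulse's extent so transients do not merge. Onsets and peaks
are snapped to the frame grid so noiseless recovery of half-max crossings
is exact on the linear rise.

Image stacks render each trace on a disk footprint at 1000 counts per F/F₀
unit over a 100-count background with optional Gaussian read noise,
quantized to the 16-bit camera range; footprints may not overlap.
Contraction sequences render ellipses (axis ratio 1.5) with prescribed
areas per state and optional centroid jitter; ellipses may not touch, and
rasterized areas match prescriptions within a perimeter-order bound.

Not emulated: photobleaching, baseline drift, flow-induced motion, cell
overlap or division, Ca²⁺ waves within a cell, and shot-noise scaling with
intensity. Passing the recovery tests therefore shows the measurement
chain is correct for well-separated, photostable cells; it does not
validate robustness to those artifacts.

## Problem sizes and numerical choices

The test and acceptance workloads use desk-scale conditions chosen to make
the statistical assertions sharp: 500 single-pulse traces for kinetic
recovery, 200 ROIs for MP/SP labeling, ≈ 1.7·10⁵ pixel-frames for the
false-positive calibration, 100 cells for contraction recovery, and 10³
ROIs per group for same-distribution D comparisons (at a few hundred ROIs
the events-within-ROI D from sampling noise alone sits near its low/moderate
boundary of 0.105). All generators and pipelines are deterministic given a
seed; ROI and track ordering, link tie-breaks and histogram edges are fully
specified, and rerunning a pipeline with the same configuration and seed
reproduces byte-identical CSV outputs.
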