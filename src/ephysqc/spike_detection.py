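"""Rule-based spike detection on intracellular voltage traces.

Pipeline: moving-average filter -> forward-difference derivative (mV/ms) ->
percentile-derived up/down thresholds -> candidate events (consecutive-run
criteria) -> per-event characterisation against a local baseline -> two
eligibility rules (half-height return and relative-height cutoff).

Conventions used throughout the package:

* percentiles use linear interpolation between order statistics;
* derivatives of the *filtered* trace drive detection and slope features,
  while spike maximum, baseline, height and width are read off the raw trace;
* millisecond windows convert to sample counts by rounding half away from
  zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .trace_io import Trace

__all__ = [
    "DetectionParams",
    "SpikeEvent",
    "ms_to_samples",
    "moving_average",
    "derivative",
    "detection_thresholds",
    "find_candidate_events",
    "characterize_event",
    "eligibility_filter",
    "detect_spikes",
]


@dataclass(frozen=True)
class DetectionParams:
    """Tunable constants of the detector (defaults follow the method)."""

    filter_window_ms: float = 3.0        # moving-average span
    t_spike_max_ms: float = 3.0          # max gap between up- and down-run
    up_percentile: float = 80.0
    down_percentile: float = 20.0
    threshold_multiplier: float = 3.0
    baseline_near_ms: float = 3.0        # baseline windows: [near, far] ms on
    baseline_far_ms: float = 6.0         # both sides of the spike time
    run_length: int = 3                  # consecutive samples beyond threshold
    height_fraction: float = 0.5         # half-height rule
    height_percentile: float = 95.0      # relative-height cutoff basis

    def __post_init__(self) -> None:
        if self.filter_window_ms <= 0 or self.t_spike_max_ms <= 0:
            raise ValueError("windows must be positive")
        for p in (self.up_percentile, self.down_percentile, self.height_percentile):
            if not 0 < p < 100:
                raise ValueError("percentiles must lie in (0, 100)")
        if self.run_length < 1:
            raise ValueError("run_length must be >= 1")


DEFAULT_PARAMS = DetectionParams()


@dataclass
class SpikeEvent:
    """One characterised spike candidate.

    ``width`` is NaN when no half-height crossing exists on one side;
    such events fail the first eligibility rule.
    """

    t_spike: float          # time of the raw-trace maximum, seconds
    peak_index: int
    v_max: float            # mV
    baseline: float         # mV, mean over flanking windows
    height: float           # mV, v_max - baseline
    width: float            # ms, half-height width (NaN if undefined)
    max_slope: float        # mV/ms, on the filtered trace within the event
    min_slope: float        # mV/ms
    onset_index: int
    offset_index: int
    half_height_ok: bool = True  # rule (i): returns below half height +-3 ms


def ms_to_samples(ms: float, sampling_rate: float) -> int:
    """Convert a millisecond span to samples, rounding half away from zero."""
    x = ms * sampling_rate / 1000.0
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def filter_half_width(sampling_rate: float, params: DetectionParams = DEFAULT_PARAMS) -> int:
    """Half-width L of the moving-average window in samples (window = 2L+1)."""
    return ms_to_samples(params.filter_window_ms / 2.0, sampling_rate)


def moving_average(
    samples: np.ndarray, sampling_rate: float, window_ms: float = 3.0
) -> np.ndarray:
    """Centred moving average with edge shrink; output length = input length.

    The full window is 2L+1 samples with L = round(window_ms/2 * rate/1000);
    near the edges the window is clipped to the available samples and the
    mean taken over what remains.
    """
    v = np.asarray(samples, dtype=float)
    n = v.size
    L = ms_to_samples(window_ms / 2.0, sampling_rate)
    if L == 0:
        return v.copy()
    if n < 2 * L + 1:
        raise ValueError(f"trace of {n} samples shorter than filter window {2 * L + 1}")
    c = np.concatenate(([0.0], np.cumsum(v)))
    idx = np.arange(n)
    lo = np.maximum(idx - L, 0)
    hi = np.minimum(idx + L, n - 1)
    return (c[hi + 1] - c[lo]) / (hi - lo + 1)


def derivative(filtered: np.ndarray, sampling_rate: float) -> np.ndarray:
    """Forward difference in mV/ms; length n-1."""
    v = np.asarray(filtered, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 samples")
    return np.diff(v) * sampling_rate / 1000.0


def detection_thresholds(
    derivs: np.ndarray, params: DetectionParams = DEFAULT_PARAMS
) -> tuple[float, float]:
    """Up/down derivative thresholds: multiplier x P80 / multiplier x P20."""
    d = np.asarray(derivs, dtype=float)
    if d.size == 0:
        raise ValueError("empty derivative sequence")
    theta_up = params.threshold_multiplier * float(np.percentile(d, params.up_percentile))
    theta_down = params.threshold_multiplier * float(np.percentile(d, params.down_percentile))
    return theta_up, theta_down


def _is_degenerate(derivs: np.ndarray, theta_up: float, theta_down: float) -> bool:
    # A usable trace must contain both rising and falling stretches. Strictly
    # monotone or flat traces yield thresholds of the wrong sign (or no
    # strictly positive/negative derivatives at all) and carry no spikes.
    if theta_up < 0 or theta_down > 0:
        return True
    d = np.asarray(derivs)
    return not (np.any(d > theta_up) and np.any(d < theta_down))


def _runs_mask(condition: np.ndarray, run_length: int) -> np.ndarray:
    """mask[i] True iff condition holds at i, i+1, ..., i+run_length-1."""
    c = condition.astype(bool)
    if run_length == 1:
        return c
    out = c[: c.size - run_length + 1].copy()
    for k in range(1, run_length):
        out &= c[k : c.size - run_length + 1 + k]
    return np.concatenate([out, np.zeros(run_length - 1, dtype=bool)])


def find_candidate_events(
    derivs: np.ndarray,
    theta_up: float,
    theta_down: float,
    sampling_rate: float,
    params: DetectionParams = DEFAULT_PARAMS,
) -> list[tuple[int, int]]:
    """Locate candidate spike windows as (onset_index, offset_index).

    An event needs ``run_length`` consecutive derivatives above ``theta_up``
    starting at the onset and, within ``t_spike_max_ms`` of that first
    up-crossing, ``run_length`` consecutive derivatives below ``theta_down``.
    The offset is the last derivative below ``theta_down`` inside the window;
    scanning resumes after it, so events never overlap.
    """
    d = np.asarray(derivs, dtype=float)
    n = d.size
    r = params.run_length
    W = ms_to_samples(params.t_spike_max_ms, sampling_rate)
    up_runs = _runs_mask(d > theta_up, r)
    down_runs = _runs_mask(d < theta_down, r)
    below = d < theta_down

    events: list[tuple[int, int]] = []
    up_positions = np.nonzero(up_runs)[0]
    pos = 0
    i = 0
    while pos < up_positions.size:
        i = int(up_positions[pos])
        end = min(i + W, n - 1)
        # a full down-run must start inside [onset, onset + W]
        if np.any(down_runs[i : min(end, n - r) + 1]):
            below_idx = np.nonzero(below[i : end + 1])[0]
            offset = i + int(below_idx[-1])
            events.append((i, offset))
            pos = int(np.searchsorted(up_positions, offset + 1))
        else:
            pos += 1
    return events


def characterize_event(
    trace: Trace,
    filtered: np.ndarray,
    derivs: np.ndarray,
    event: tuple[int, int],
    params: DetectionParams = DEFAULT_PARAMS,
) -> SpikeEvent | None:
    """Measure one candidate event; None if its baseline windows fall
    entirely outside the trace."""
    onset, offset = event
    v = trace.samples
    rate = trace.sampling_rate
    n = v.size

    # derivative index i spans raw samples i..i+1
    seg = v[onset : offset + 2]
    peak_local = int(np.argmax(seg))
    p = onset + peak_local
    v_max = float(v[p])
    t_spike = p / rate

    near = ms_to_samples(params.baseline_near_ms, rate)
    far = ms_to_samples(params.baseline_far_ms, rate)
    left = np.arange(max(p - far, 0), max(p - near + 1, 0))
    right = np.arange(min(p + near, n), min(p + far + 1, n))
    base_idx = np.concatenate([left, right])
    if base_idx.size == 0:
        return None
    baseline = float(np.mean(v[base_idx]))
    height = v_max - baseline
    half = baseline + params.height_fraction * height

    # half-height width on the raw trace: nearest below-half samples around p
    before = np.nonzero(v[:p] < half)[0]
    after_rel = np.nonzero(v[p + 1 :] < half)[0]
    if before.size and after_rel.size:
        t_before = before[-1]
        t_after = p + 1 + after_rel[0]
        width = (t_after - t_before) * 1000.0 / rate
    else:
        width = float("nan")

    # rule (i): a below-half sample within 3 ms on each side of the spike time
    w3 = ms_to_samples(params.baseline_near_ms, rate)
    left_ok = bool(np.any(v[max(p - w3, 0) : p] < half))
    right_ok = bool(np.any(v[p + 1 : min(p + w3 + 1, n)] < half))

    dseg = derivs[onset : offset + 1]
    return SpikeEvent(
        t_spike=t_spike,
        peak_index=p,
        v_max=v_max,
        baseline=baseline,
        height=height,
        width=width,
        max_slope=float(np.max(dseg)),
        min_slope=float(np.min(dseg)),
        onset_index=onset,
        offset_index=offset,
        half_height_ok=left_ok and right_ok,
    )


def eligibility_filter(
    candidates: Sequence[SpikeEvent], params: DetectionParams = DEFAULT_PARAMS
) -> list[SpikeEvent]:
    """Apply the two acceptance rules to characterised candidates.

    (i) the potential drops below half height within 3 ms on both sides of
    the spike time (rejects step-like artefacts); (ii) the height exceeds
    half the 95th percentile of all candidate heights in the trace (rejects
    small secondary events). The percentile is computed over all candidates
    first, then both rules are applied.
    """
    if not candidates:
        return []
    heights = np.array([c.height for c in candidates])
    cutoff = params.height_fraction * float(
        np.percentile(heights, params.height_percentile)
    )
    return [
        c
        for c in candidates
        if c.half_height_ok and c.height > cutoff and c.height > 0
    ]


def detect_spikes(
    trace: Trace, params: DetectionParams = DEFAULT_PARAMS
) -> list[SpikeEvent]:
    """Full detector: filter, differentiate, threshold, characterise, filter.

    Returns accepted spikes in time order; deterministic.
    """
    filtered = moving_average(trace.samples, trace.sampling_rate, params.filter_window_ms)
    derivs = derivative(filtered, trace.sampling_rate)
    theta_up, theta_down = detection_thresholds(derivs, params)
    if _is_degenerate(derivs, theta_up, theta_down):
        return []
    windows = find_candidate_events(
        derivs, theta_up, theta_down, trace.sampling_rate, params
    )
    candidates = []
    for w in windows:
        ev = characterize_event(trace, filtered, derivs, w, params)
        if ev is not None:
            candidates.append(ev)
    return eligibility_filter(candidates, params)
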