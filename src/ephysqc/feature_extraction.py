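"""The 16 per-recording features used by the quality classifier.

All standard deviations here are population standard deviations (divide by
N). Degenerate traces (fewer than 2 accepted spikes) take fill values that
keep the vector finite: spike-shape means/CVs/slopes and drifts are 0 and
the minimum ISI equals the trace duration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .spike_detection import (
    DEFAULT_PARAMS,
    DetectionParams,
    SpikeEvent,
    detect_spikes,
    filter_half_width,
    moving_average,
    ms_to_samples,
)
from .trace_io import Trace

log = logging.getLogger(__name__)

__all__ = [
    "FEATURE_NAMES",
    "NoiseTrace",
    "short_timescale_noise",
    "linear_drift",
    "extract_features",
    "extract_feature_table",
]

#: Canonical column order of the feature table.
FEATURE_NAMES: list[str] = [
    "f01_mean_spike_height",
    "f02_mean_spike_width",
    "f03_cv_spike_height",
    "f04_cv_spike_width",
    "f05_mean_baseline_voltage",
    "f06_std_baseline",
    "f07_short_timescale_noise",
    "f08_std_noise_level",
    "f09_drift_spike_height",
    "f10_drift_spike_width",
    "f11_drift_noise_amplitude",
    "f12_min_isi",
    "f13_max_spike_slope",
    "f14_min_spike_slope",
    "f15_std_max_spike_slope",
    "f16_std_min_spike_slope",
]


@dataclass
class NoiseTrace:
    """Per-sample short-timescale noise level, NaN inside spike exclusion
    zones (+-3 ms around each accepted spike time)."""

    values: np.ndarray  # mV, NaN where undefined

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def defined_values(self) -> np.ndarray:
        return self.values[self.defined]


def _pop_std(x: np.ndarray) -> float:
    return float(np.std(x))  # ddof=0: population convention


def short_timescale_noise(
    trace: Trace,
    filtered: np.ndarray,
    spikes: Sequence[SpikeEvent],
    params: DetectionParams = DEFAULT_PARAMS,
) -> NoiseTrace:
    """RMS deviation of the raw trace from its moving average.

    n(t) = sqrt( sum_{|t'-t| <= L} (V(t') - V_avg(t'))^2 / (2L+1) ) with L
    the filter half-width, i.e. the window spans two filter lengths. Samples
    within +-3 ms of an accepted spike time are undefined (NaN); windows at
    the trace edges are clipped but keep the 2L+1 normalisation.
    """
    v = trace.samples
    rate = trace.sampling_rate
    n = v.size
    L = filter_half_width(rate, params)
    r2 = (v - filtered) ** 2
    c = np.concatenate(([0.0], np.cumsum(r2)))
    idx = np.arange(n)
    lo = np.maximum(idx - L, 0)
    hi = np.minimum(idx + L, n - 1)
    values = np.sqrt((c[hi + 1] - c[lo]) / (2 * L + 1))

    excl = ms_to_samples(params.baseline_near_ms, rate)
    for sp in spikes:
        a = max(sp.peak_index - excl, 0)
        b = min(sp.peak_index + excl + 1, n)
        values[a:b] = np.nan
    return NoiseTrace(values=values)


def linear_drift(values: np.ndarray, times: np.ndarray) -> float:
    """Ordinary-least-squares slope of ``values`` against ``times`` (per s).

    Returns NaN if fewer than 2 distinct time points are available.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 2 or np.ptp(t) == 0:
        return float("nan")
    tm = t - t.mean()
    return float(np.dot(tm, y - y.mean()) / np.dot(tm, tm))


def extract_features(
    trace: Trace,
    spikes: Sequence[SpikeEvent],
    params: DetectionParams = DEFAULT_PARAMS,
) -> dict[str, float]:
    """Compute the 16 features of one recording from its accepted spikes."""
    filtered = moving_average(trace.samples, trace.sampling_rate, params.filter_window_ms)
    noise = short_timescale_noise(trace, filtered, spikes, params)
    nv = noise.defined_values()
    rate = trace.sampling_rate

    f = dict.fromkeys(FEATURE_NAMES, 0.0)

    # baseline statistics: filtered samples between their own P5 and P95
    p5, p95 = np.percentile(filtered, [5, 95])
    trimmed = filtered[(filtered >= p5) & (filtered <= p95)]
    if trimmed.size:
        f["f05_mean_baseline_voltage"] = float(np.mean(trimmed))
        f["f06_std_baseline"] = _pop_std(trimmed)

    if nv.size:
        f["f07_short_timescale_noise"] = float(np.mean(nv))
        f["f08_std_noise_level"] = _pop_std(nv)
        t_noise = np.nonzero(noise.defined)[0] / rate
        slope = linear_drift(nv, t_noise)
        f["f11_drift_noise_amplitude"] = 0.0 if np.isnan(slope) else slope

    f["f12_min_isi"] = trace.duration  # fill; overwritten when >= 2 spikes

    if len(spikes) >= 2:
        heights = np.array([s.height for s in spikes])
        widths = np.array([s.width for s in spikes])
        tsp = np.array([s.t_spike for s in spikes])
        mx = np.array([s.max_slope for s in spikes])
        mn = np.array([s.min_slope for s in spikes])

        f["f01_mean_spike_height"] = float(np.mean(heights))
        f["f02_mean_spike_width"] = float(np.mean(widths))
        if f["f01_mean_spike_height"] != 0:
            f["f03_cv_spike_height"] = _pop_std(heights) / abs(f["f01_mean_spike_height"])
        if f["f02_mean_spike_width"] != 0:
            f["f04_cv_spike_width"] = _pop_std(widths) / abs(f["f02_mean_spike_width"])
        f["f09_drift_spike_height"] = linear_drift(heights, tsp)
        f["f10_drift_spike_width"] = linear_drift(widths, tsp)
        f["f12_min_isi"] = float(np.min(np.diff(tsp)))
        f["f13_max_spike_slope"] = float(np.mean(mx))
        f["f14_min_spike_slope"] = float(np.mean(mn))
        f["f15_std_max_spike_slope"] = _pop_std(mx)
        f["f16_std_min_spike_slope"] = _pop_std(mn)

    # total fill policy: never emit NaN/inf
    for k, val in f.items():
        if not np.isfinite(val):
            f[k] = 0.0
    return f


def extract_feature_table(
    traces: Sequence[Trace], params: DetectionParams = DEFAULT_PARAMS
) -> pd.DataFrame:
    """Detect spikes and extract features for each trace.

    Returns a DataFrame indexed by trace id with FEATURE_NAMES columns;
    per-trace failures are logged and the row filled with zeros (flagged in
    the log), so batch extraction never aborts.
    """
    rows = {}
    for tr in traces:
        try:
            spikes = detect_spikes(tr, params)
            rows[tr.id] = extract_features(tr, spikes, params)
        except Exception:  # pragma: no cover - defensive batch path
            log.exception("feature extraction failed for trace %r", tr.id)
            rows[tr.id] = dict.fromkeys(FEATURE_NAMES, 0.0)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=FEATURE_NAMES)
    df.index.name = "id"
    return df
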