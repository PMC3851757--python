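"""Synthetic sharp-electrode-style recordings with known ground truth.

Traces are a constant baseline plus double-exponential spike bumps, Gaussian
noise, optional linear drifts, slow baseline wander and step/transient
artefacts. Spike times come from a thinned Poisson process with a refractory
period and a rate multiplier inside the stimulus window. Everything is
deterministic under a seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .trace_io import LabelTable, Trace

__all__ = [
    "GeneratorProfile",
    "GroundTruth",
    "default_profiles",
    "generate_trace",
    "generate_dataset",
    "scenario_trace",
    "DEFAULT_COUNTS",
]

#: good / intermediate / bad trace counts of the reference corpus.
DEFAULT_COUNTS: dict[str, int] = {"good": 100, "intermediate": 54, "bad": 29}


@dataclass(frozen=True)
class GeneratorProfile:
    """All knobs of the trace generator for one quality class."""

    label: str = "good"
    spike_height_mean: float = 40.0   # mV
    spike_height_cv: float = 0.08
    spike_width_mean: float = 2.0     # ms, half-height width of the bump
    spike_width_cv: float = 0.08
    firing_rate: float = 12.0         # Hz outside the stimulus window
    refractory_ms: float = 15.0
    baseline: float = -60.0           # mV
    noise_sigma: float = 0.4          # mV
    height_drift: float = 0.0         # mV/s added to spike heights over time
    noise_drift: float = 0.0          # mV/s added to the noise sigma over time
    baseline_drift: float = 0.0       # mV/s linear baseline trend
    baseline_wander: float = 0.0      # mV amplitude of slow sinusoidal wander
    step_prob: float = 0.0
    step_amplitude: float = 0.0       # mV, sign randomised
    transient_prob: float = 0.0
    transient_amplitude: float = 0.0  # mV, one-sided decaying artefact
    duration: float = 5.0             # s
    sampling_rate: float = 10000.0    # Hz
    stim_onset: float = 1.5           # s
    stim_duration: float = 0.5        # s
    stim_rate_multiplier: float = 2.0

    def __post_init__(self) -> None:
        if min(self.firing_rate, self.duration, self.noise_sigma,
               self.refractory_ms, self.spike_height_cv, self.spike_width_cv) < 0:
            raise ValueError("rates, durations, sigma, refractory and CVs must be >= 0")


@dataclass
class GroundTruth:
    """What the generator actually placed in a trace."""

    spike_times: np.ndarray          # s, strictly increasing
    spike_heights: np.ndarray        # mV
    spike_widths: np.ndarray         # ms
    artefact_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    label: str = "good"


def default_profiles() -> dict[str, GeneratorProfile]:
    """Class profiles: statistically separated but overlapping.

    good: tall clean regular spikes; intermediate: smaller, noisier spikes
    with drifts and occasional artefacts; bad: few small spikes, heavy noise,
    unstable baseline and frequent artefacts.
    """
    return {
        "good": GeneratorProfile(
            label="good",
            spike_height_mean=40.0, spike_height_cv=0.08,
            spike_width_mean=2.0, spike_width_cv=0.08,
            firing_rate=12.0, noise_sigma=0.4, baseline_wander=0.3,
        ),
        "intermediate": GeneratorProfile(
            label="intermediate",
            spike_height_mean=14.0, spike_height_cv=0.3,
            spike_width_mean=2.6, spike_width_cv=0.3,
            firing_rate=7.0, noise_sigma=1.8,
            height_drift=-0.8, noise_drift=0.1, baseline_wander=2.0,
            step_prob=0.3, step_amplitude=6.0,
            transient_prob=0.3, transient_amplitude=10.0,
        ),
        "bad": GeneratorProfile(
            label="bad",
            spike_height_mean=6.0, spike_height_cv=0.5,
            spike_width_mean=3.0, spike_width_cv=0.5,
            firing_rate=1.2, noise_sigma=3.5,
            height_drift=-1.0, noise_drift=0.3, baseline_wander=6.0,
            baseline_drift=2.0,
            step_prob=0.6, step_amplitude=15.0,
            transient_prob=0.7, transient_amplitude=25.0,
        ),
    }


# double-exponential bump with decay tau = 2 x rise tau; unit-peak shape
_TAU_RATIO = 2.0


def _bump_shape(t: np.ndarray, tau_r: float) -> np.ndarray:
    tau_d = _TAU_RATIO * tau_r
    tt = np.maximum(t, 0.0)  # clip before exp to avoid spurious overflow
    return np.where(t >= 0, np.exp(-tt / tau_d) - np.exp(-tt / tau_r), 0.0)


def _bump_constants(tau_r: float = 1.0) -> tuple[float, float, float]:
    """(peak time, peak value, half-height width) of the unit shape, for
    tau_r = 1; all three scale linearly with tau_r."""
    tau_d = _TAU_RATIO * tau_r
    t_peak = tau_r * tau_d / (tau_d - tau_r) * np.log(tau_d / tau_r)
    peak = float(_bump_shape(np.array([t_peak]), tau_r)[0])
    tt = np.linspace(0, 12 * tau_d, 20001)
    k = _bump_shape(tt, tau_r) / peak
    above = np.nonzero(k >= 0.5)[0]
    fwhm = float(tt[above[-1]] - tt[above[0]])
    return float(t_peak), peak, fwhm


_T_PEAK1, _PEAK1, _FWHM1 = _bump_constants(1.0)


def _draw_spike_times(profile: GeneratorProfile, rng: np.random.Generator) -> np.ndarray:
    """Thinned Poisson process with refractory period and stimulus boost."""
    p = profile
    if p.firing_rate <= 0:
        return np.empty(0)
    rmax = p.firing_rate * max(1.0, p.stim_rate_multiplier)
    refr = p.refractory_ms / 1000.0
    margin = 0.02  # keep spikes away from the very edges
    t = margin
    times: list[float] = []
    while True:
        t += rng.exponential(1.0 / rmax)
        if t >= p.duration - margin:
            break
        in_stim = p.stim_onset <= t < p.stim_onset + p.stim_duration
        rate = p.firing_rate * (p.stim_rate_multiplier if in_stim else 1.0)
        if rng.uniform() > rate / rmax:
            continue
        if times and t - times[-1] < refr:
            continue
        times.append(t)
    return np.asarray(times)


def generate_trace(
    profile: GeneratorProfile, seed, trace_id: str = "sim"
) -> tuple[Trace, GroundTruth]:
    """Render one labelled trace plus its ground truth; bit-reproducible
    under the same seed."""
    p = profile
    rng = np.random.default_rng(seed)
    n = int(round(p.duration * p.sampling_rate))
    t = np.arange(n) / p.sampling_rate

    times = _draw_spike_times(p, rng)
    heights = np.empty(times.size)
    widths = np.empty(times.size)
    v = np.full(n, p.baseline, dtype=float)

    for i, ts in enumerate(times):
        h = rng.normal(p.spike_height_mean, p.spike_height_cv * p.spike_height_mean)
        h = max(h + p.height_drift * ts, 0.2 * p.spike_height_mean)
        w = rng.normal(p.spike_width_mean, p.spike_width_cv * p.spike_width_mean)
        w = max(w, 0.3)
        heights[i] = h
        widths[i] = w
        tau_r = (w / _FWHM1) / 1000.0       # seconds; FWHM scales with tau_r
        t_peak = _T_PEAK1 * tau_r
        start = ts - t_peak
        i0 = max(int(np.floor(start * p.sampling_rate)), 0)
        i1 = min(int(np.ceil((start + 14 * _TAU_RATIO * tau_r) * p.sampling_rate)), n)
        seg_t = t[i0:i1] - start
        v[i0:i1] += h * _bump_shape(seg_t, tau_r) / _PEAK1

    # drifts and slow wander
    v += p.baseline_drift * t
    if p.baseline_wander > 0:
        freq = rng.uniform(0.3, 1.2)
        phase = rng.uniform(0, 2 * np.pi)
        v += p.baseline_wander * np.sin(2 * np.pi * freq * t + phase)

    # noise with optional linear amplitude drift
    sigma_t = np.maximum(p.noise_sigma + p.noise_drift * t, 0.0)
    if np.any(sigma_t > 0):
        v += rng.standard_normal(n) * sigma_t

    # artefacts
    artefacts: list[float] = []
    edge = min(0.3, 0.25 * p.duration)
    if p.step_prob > 0 and rng.uniform() < p.step_prob:
        ta = rng.uniform(edge, p.duration - edge)
        sign = 1.0 if rng.uniform() < 0.5 else -1.0
        v[t >= ta] += sign * p.step_amplitude
        artefacts.append(ta)
    if p.transient_prob > 0 and rng.uniform() < p.transient_prob:
        ta = rng.uniform(edge, p.duration - edge)
        tau = rng.uniform(0.01, 0.05)
        mask = t >= ta
        v[mask] += p.transient_amplitude * np.exp(-(t[mask] - ta) / tau)
        artefacts.append(ta)

    trace = Trace(
        id=trace_id,
        samples=v,
        sampling_rate=p.sampling_rate,
        stim_onset=p.stim_onset,
        stim_duration=p.stim_duration,
    )
    truth = GroundTruth(
        spike_times=times,
        spike_heights=heights,
        spike_widths=widths,
        artefact_times=np.asarray(artefacts),
        label=p.label,
    )
    return trace, truth


def generate_dataset(
    counts: dict[str, int] | None = None,
    profiles: dict[str, GeneratorProfile] | None = None,
    seed: int = 0,
    jitter: float = 0.15,
) -> tuple[list[Trace], LabelTable, dict[str, GroundTruth]]:
    """Generate a labelled corpus of traces.

    ``counts`` maps class -> number of traces (default 100/54/29 for
    good/intermediate/bad). Per-trace lognormal jitter of the profile means
    makes recordings within a class vary; ``jitter=0`` disables it.
    """
    counts = dict(DEFAULT_COUNTS if counts is None else counts)
    profiles = default_profiles() if profiles is None else profiles
    root = np.random.SeedSequence(seed)
    traces: list[Trace] = []
    labels: dict[str, str] = {}
    truths: dict[str, GroundTruth] = {}
    k = 0
    for label in ("good", "intermediate", "bad"):
        cnt = counts.get(label, 0)
        if cnt == 0:
            continue
        base = profiles[label]
        for _ in range(cnt):
            child = root.spawn(1)[0]
            jrng = np.random.default_rng(child)
            prof = base
            if jitter > 0:
                prof = dataclasses.replace(
                    base,
                    spike_height_mean=base.spike_height_mean
                    * jrng.lognormal(0, jitter),
                    spike_width_mean=base.spike_width_mean * jrng.lognormal(0, jitter),
                    firing_rate=base.firing_rate * jrng.lognormal(0, jitter),
                    noise_sigma=base.noise_sigma * jrng.lognormal(0, jitter),
                )
            rid = f"r{k:04d}"
            trace, truth = generate_trace(prof, jrng, trace_id=rid)
            traces.append(trace)
            labels[rid] = label
            truths[rid] = truth
            k += 1
    return traces, LabelTable(labels), truths


#: named regression scenarios for hard-to-judge recordings
_SCENARIOS = {
    # large artefact, no genuine spikes
    "artefact_no_spikes": GeneratorProfile(
        label="bad", firing_rate=0.0, noise_sigma=1.0,
        transient_prob=1.0, transient_amplitude=40.0,
    ),
    # reliable spikes on a wildly unstable baseline
    "unstable_baseline": GeneratorProfile(
        label="bad", spike_height_mean=35.0, firing_rate=8.0,
        noise_sigma=0.8, baseline_wander=15.0, baseline_drift=4.0,
    ),
    # a few large spikes among many small secondary events
    "few_spikes_secondary_events": GeneratorProfile(
        label="good", spike_height_mean=40.0, spike_height_cv=0.05,
        firing_rate=1.0, noise_sigma=0.5,
    ),
}


def scenario_trace(name: str, seed=0) -> tuple[Trace, GroundTruth]:
    """Generate one of the named failure-archetype traces.

    ``few_spikes_secondary_events`` additionally injects a dense train of
    quarter-height secondary spikes that are not in the ground truth.
    """
    if name not in _SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; choose from {sorted(_SCENARIOS)}")
    profile = _SCENARIOS[name]
    trace, truth = generate_trace(profile, seed, trace_id=name)
    if name == "few_spikes_secondary_events":
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
        sec_profile = dataclasses.replace(
            profile,
            spike_height_mean=profile.spike_height_mean / 4,
            firing_rate=10.0,
            noise_sigma=0.0,
            baseline=0.0,
        )
        sec, _ = generate_trace(sec_profile, rng.integers(2**31))
        trace.samples = trace.samples + sec.samples
    return trace, truth
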