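"""Spike extraction and rate signals.

Extracellular traces are high-pass filtered (zero phase), candidate events
are taken as robust-threshold crossings, and a 2-cluster k-means on
waveform features separates spikes from residual noise events, mirroring
the usual loose-patch workflow.  Rates are spike-count histograms divided
by bin width; cycle averaging supports the F1 analysis downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

__all__ = [
    "RecordingTrace",
    "SpikeTrain",
    "SpikeRate",
    "DetectConfig",
    "highpass_filter",
    "detect_spikes",
    "bin_spike_rate",
    "cycle_average",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RecordingTrace:
    """An extracellular voltage trace, default 10 kHz sampling.

    ``true_spike_times`` carries simulation ground truth when available.
    """

    sample_rate: float
    voltage: np.ndarray
    true_spike_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.voltage, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("voltage contains non-finite samples")
        object.__setattr__(self, "voltage", v)
        if self.sample_rate <= 0:
            raise ValueError("sample rate must be positive")
        if self.true_spike_times is not None:
            object.__setattr__(
                self, "true_spike_times", np.asarray(self.true_spike_times, dtype=float)
            )

    @property
    def duration(self) -> float:
        return self.voltage.size / self.sample_rate


@dataclass(frozen=True)
class SpikeTrain:
    spike_times: np.ndarray  # seconds, sorted ascending
    duration: float

    def __post_init__(self) -> None:
        t = np.sort(np.unique(np.asarray(self.spike_times, dtype=float)))
        if t.size and (t[0] < 0 or t[-1] > self.duration + 1e-12):
            raise ValueError("spike times fall outside [0, duration]")
        object.__setattr__(self, "spike_times", t)

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)


@dataclass(frozen=True)
class SpikeRate:
    """Binned firing rate in spikes/s."""

    bin_rate: float
    rates: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        r = np.asarray(self.rates, dtype=float)
        if np.any(r < -1e-9):
            raise ValueError("rates must be non-negative")
        object.__setattr__(self, "rates", r)

    @property
    def bin_width(self) -> float:
        return 1.0 / self.bin_rate

    @property
    def duration(self) -> float:
        return self.rates.size / self.bin_rate

    def bin_times(self) -> np.ndarray:
        return self.start_time + (np.arange(self.rates.size) + 0.5) / self.bin_rate


def highpass_filter(trace: RecordingTrace, cutoff_hz: float, order: int = 4) -> RecordingTrace:
    """Zero-phase Butterworth high-pass (forward-backward) filter.

    Zero-phase filtering avoids latency bias in spike times and in any
    filter-trough estimate computed downstream.
    """
    nyq = trace.sample_rate / 2
    if not 0 < cutoff_hz < nyq:
        raise ValueError(f"cutoff must lie in (0, {nyq}) Hz")
    sos = signal.butter(order, cutoff_hz, btype="highpass", fs=trace.sample_rate, output="sos")
    filtered = signal.sosfiltfilt(sos, trace.voltage)
    return replace(trace, voltage=filtered)


@dataclass(frozen=True)
class DetectConfig:
    """Spike-detection settings.

    The candidate threshold is ``threshold_mult`` times the robust SD of
    the trace (MAD scaled to Gaussian SD).  k-means with k=2 on snippet
    principal components plus peak amplitude separates spikes from noise;
    when the two clusters' mean amplitudes differ by less than
    ``amplitude_separation``-fold the events are treated as a single spike
    population and all are kept.
    """

    threshold_mult: float = 4.0
    snippet_ms: float = 1.0  # half-window around the peak
    refractory_ms: float = 1.0
    highpass_cutoff: float | None = None
    use_kmeans: bool = True
    amplitude_separation: float = 2.0
    amplitude_threshold: float | None = None
    seed: int = 0


def detect_spikes(trace: RecordingTrace, config: DetectConfig = DetectConfig()):
    """Extract spikes from an extracellular trace.

    Returns ``(SpikeTrain, amplitudes)`` with one absolute peak amplitude
    per spike.  Spike time convention: the sample of the event's absolute
    peak, in seconds.  An empty train (no threshold crossings) is a valid
    result, not an error.
    """
    if config.highpass_cutoff is not None:
        trace = highpass_filter(trace, config.highpass_cutoff)
    x = trace.voltage
    sr = trace.sample_rate
    mad = np.median(np.abs(x - np.median(x)))
    robust_sd = 1.4826 * mad
    if robust_sd == 0:
        robust_sd = x.std() or 1.0
    thr = config.threshold_mult * robust_sd
    dist = max(1, int(round(config.refractory_ms * 1e-3 * sr)))
    peaks, _ = signal.find_peaks(np.abs(x), height=thr, distance=dist)
    half = max(1, int(round(config.snippet_ms * 1e-3 * sr)))
    peaks = peaks[(peaks >= half) & (peaks < x.size - half)]
    if peaks.size == 0:
        return SpikeTrain(np.array([]), trace.duration), np.array([])

    amplitudes = np.abs(x[peaks])
    keep = np.ones(peaks.size, dtype=bool)
    if config.use_kmeans and peaks.size >= 4:
        snippets = np.stack([x[p - half : p + half + 1] for p in peaks])
        keep = _kmeans_spike_mask(snippets, amplitudes, config)
    if config.amplitude_threshold is not None:
        keep &= amplitudes >= config.amplitude_threshold
    times = peaks[keep] / sr
    return SpikeTrain(times, trace.duration), amplitudes[keep]


def _kmeans_spike_mask(snippets, amplitudes, config: DetectConfig):
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    n_pc = min(2, snippets.shape[0], snippets.shape[1])
    pcs = PCA(n_components=n_pc, random_state=config.seed).fit_transform(snippets)
    feats = np.column_stack([pcs, amplitudes])
    feats = (feats - feats.mean(0)) / np.where(feats.std(0) > 0, feats.std(0), 1.0)
    km = KMeans(n_clusters=2, random_state=config.seed, n_init=10).fit(feats)
    labels = km.labels_
    sizes = np.bincount(labels, minlength=2)
    if sizes.min() == 0:  # degenerate clustering
        warnings.warn("k-means produced an empty cluster; falling back to threshold-only detection")
        return np.ones(amplitudes.size, dtype=bool)
    means = np.array([amplitudes[labels == k].mean() for k in range(2)])
    hi, lo = means.max(), means.min()
    if lo > 0 and hi / lo < config.amplitude_separation:
        # single amplitude population: everything above threshold is a spike
        return np.ones(amplitudes.size, dtype=bool)
    return labels == int(np.argmax(means))


def bin_spike_rate(spikes: SpikeTrain, bin_rate: float, duration: float | None = None) -> SpikeRate:
    """Histogram spike times into bins of 1/bin_rate s; rate = count / width."""
    if bin_rate <= 0:
        raise ValueError("bin rate must be positive")
    duration = spikes.duration if duration is None else duration
    n_bins = max(1, round(duration * bin_rate))
    edges = np.arange(n_bins + 1) / bin_rate
    counts, _ = np.histogram(spikes.spike_times, bins=edges)
    return SpikeRate(bin_rate, counts * bin_rate)


def cycle_average(rate: SpikeRate, period: float) -> SpikeRate:
    """Average a rate signal across complete stimulus cycles.

    When the period is an integer number of bins the cycles are averaged
    directly; otherwise each complete cycle is resampled onto a common
    phase grid by linear interpolation (e.g. 4 Hz at 60 Hz bins is 15
    bins/cycle and exact, but 4 Hz at 360 Hz gives 90 and 2 Hz at 60 gives
    30 — all exact; 3 Hz at 50 Hz would interpolate).  The partial final
    cycle is discarded.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    bins_per_cycle = period * rate.bin_rate
    n_cycles = int(np.floor(rate.rates.size / bins_per_cycle + 1e-9))
    if n_cycles < 1:
        raise ValueError("rate covers less than one complete cycle")
    if abs(bins_per_cycle - round(bins_per_cycle)) < 1e-9:
        b = round(bins_per_cycle)
        avg = rate.rates[: n_cycles * b].reshape(n_cycles, b).mean(axis=0)
        return SpikeRate(rate.bin_rate, avg)
    # resample each cycle onto round(bins_per_cycle) phase bins
    b = max(1, round(bins_per_cycle))
    t = (np.arange(rate.rates.size) + 0.5) / rate.bin_rate
    cycles = []
    for k in range(n_cycles):
        phase_t = k * period + (np.arange(b) + 0.5) * period / b
        cycles.append(np.interp(phase_t, t, rate.rates))
    return SpikeRate(b / period, np.mean(cycles, axis=0))
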