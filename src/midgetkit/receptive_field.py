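"""Receptive-field characterization.

Two complementary analyses of center-surround organization:

1. Area summation — F1 response amplitudes to spots of increasing
   diameter, fit with a Difference-of-Gaussians (DoG) model

       R(f) = R0 + Kc*pi*sigma_c^2 * exp(-(pi*sigma_c*f)^2)
                 - Ks*pi*sigma_s^2 * exp(-(pi*sigma_s*f)^2)

   where f is the spot diameter, R0 the baseline response, (Kc, sigma_c)
   the center strength and size parameter and (Ks, sigma_s) the surround.
   In this form a *larger* sigma rolls off at *smaller* f, so the
   spatially broad surround has sigma_s >= sigma_c and the response first
   grows with spot size (escaping the surround term) and then declines to
   R0 — the classic spatial-opponency signature.  Note the sigmas act as
   inverse lengths against a diameter in um; they are descriptive shape
   parameters, not Gaussian SDs in um.

2. Reverse correlation — the temporal linear filter of the response to
   Gaussian contrast noise, estimated in the Fourier domain as
   F~(w) = s~*(w) r~(w) (optionally divided by the stimulus power
   spectrum, omitted by default because Gaussian frame noise is nearly
   white).  The filter is the average stimulus preceding a spike; a
   negative extremum marks an OFF cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .spikes import SpikeRate, cycle_average
from .stimulus import StimulusTrace

__all__ = [
    "DoGParams",
    "AreaSummationCurve",
    "LinearFilter",
    "FilterConfig",
    "DoGFit",
    "f1_amplitude",
    "dog_predict",
    "fit_dog",
    "estimate_linear_filter",
    "classify_filter",
]


@dataclass(frozen=True)
class DoGParams:
    """Difference-of-Gaussians area-summation parameters.

    r0: baseline response (spikes/s); kc, ks: center/surround strengths;
    sigma_c, sigma_s: center/surround size parameters (inverse-length
    scale; constraint sigma_s >= sigma_c enforced by the fitter).
    """

    r0: float
    kc: float
    sigma_c: float
    ks: float
    sigma_s: float

    def __post_init__(self) -> None:
        if self.sigma_c <= 0 or self.sigma_s <= 0:
            raise ValueError("sigma_c and sigma_s must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.r0, self.kc, self.sigma_c, self.ks, self.sigma_s])


@dataclass(frozen=True)
class AreaSummationCurve:
    """F1 amplitude versus spot diameter."""

    diameters_um: np.ndarray
    f1_amplitudes: np.ndarray
    sem: np.ndarray | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.diameters_um, dtype=float)
        a = np.asarray(self.f1_amplitudes, dtype=float)
        if d.ndim != 1 or d.size != a.size:
            raise ValueError("diameters and amplitudes must be 1-D and equal length")
        if np.any(d <= 0) or np.any(np.diff(d) <= 0):
            raise ValueError("diameters must be positive and strictly increasing")
        object.__setattr__(self, "diameters_um", d)
        object.__setattr__(self, "f1_amplitudes", a)
        if self.sem is not None:
            object.__setattr__(self, "sem", np.asarray(self.sem, dtype=float))


@dataclass(frozen=True)
class LinearFilter:
    """Temporal linear filter from reverse correlation."""

    lags_ms: np.ndarray
    values: np.ndarray
    bin_rate: float
    n_spikes_used: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "lags_ms", np.asarray(self.lags_ms, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def normalized(self) -> "LinearFilter":
        """Unit-L2 copy, convenient for overlaying cells in plots."""
        norm = np.linalg.norm(self.values)
        v = self.values / norm if norm > 0 else self.values
        return LinearFilter(self.lags_ms, v, self.bin_rate, self.n_spikes_used)


def f1_amplitude(rate: SpikeRate, modulation_frequency: float) -> float:
    """Response amplitude at the stimulus modulation frequency.

    The rate is cycle-averaged at the modulation period and the amplitude
    of the fundamental Fourier component, 2|X_1|/N, is returned — for a
    pure sinusoid ``m + A sin(2 pi f t)`` this is exactly A.
    """
    if modulation_frequency > rate.bin_rate / 2:
        raise ValueError("modulation frequency above the Nyquist rate of the binned signal")
    period = 1.0 / modulation_frequency
    if rate.duration < 2 * period - 1e-9:
        raise ValueError("rate must cover at least two modulation cycles")
    cyc = cycle_average(rate, period)
    spectrum = np.fft.rfft(cyc.rates)
    return 2.0 * np.abs(spectrum[1]) / cyc.rates.size


def dog_predict(params: DoGParams, f) -> np.ndarray:
    """Evaluate the DoG area-summation model at spot diameter(s) f."""
    f = np.asarray(f, dtype=float)
    c = params.kc * np.pi * params.sigma_c**2 * np.exp(-((np.pi * params.sigma_c * f) ** 2))
    s = params.ks * np.pi * params.sigma_s**2 * np.exp(-((np.pi * params.sigma_s * f) ** 2))
    return params.r0 + c - s


@dataclass(frozen=True)
class DoGFit:
    params: DoGParams
    rss: float
    converged: bool
    n_starts: int


_SIGMA_C_GRID = (0.0025, 0.005, 0.01, 0.02, 0.04, 0.08)
_RATIO_GRID = (2.0, 4.0, 8.0)


def fit_dog(
    curve: AreaSummationCurve,
    sigma_c_grid=_SIGMA_C_GRID,
    ratio_grid=_RATIO_GRID,
) -> DoGFit:
    """Least-squares DoG fit to an area-summation curve.

    Multi-start trust-region fit in (r0, kc, ks, sigma_c, ratio) with the
    surround constrained to be the broader mechanism (ratio = sigma_s /
    sigma_c >= 1).  The best residual sum of squares wins; exact ties go
    to the smaller sigma_c.  Strength initializations are scaled from the
    curve's amplitude at each gridded sigma_c.
    """
    if curve.diameters_um.size < 5:
        raise ValueError("need at least five distinct spot diameters")
    d = curve.diameters_um
    y = curve.f1_amplitudes

    def residuals(x):
        r0, kc, ks, sc, ratio = x
        p = DoGParams(r0, kc, sc, ks, sc * ratio)
        return dog_predict(p, d) - y

    r0_init = max(float(y[-1]), 0.0)
    amp = max(float(y.max() - y.min()), 1e-6)
    lower = [0.0, 0.0, 0.0, 1e-6, 1.0]
    upper = [np.inf, np.inf, np.inf, 10.0, 1e3]
    best = None
    any_ok = False
    for sc0 in sigma_c_grid:
        for ratio0 in ratio_grid:
            kc0 = amp / (np.pi * sc0**2)
            ks0 = 0.3 * kc0 / ratio0**2
            x0 = [r0_init, kc0, ks0, sc0, ratio0]
            try:
                sol = optimize.least_squares(
                    residuals, x0, bounds=(lower, upper), xtol=1e-14, ftol=1e-14, gtol=1e-14
                )
            except Exception:
                continue
            any_ok = True
            rss = float(np.sum(sol.fun**2))
            sc = sol.x[3]
            if best is None or rss < best[0] - 1e-15 or (abs(rss - best[0]) <= 1e-15 and sc < best[1]):
                best = (rss, sc, sol)
    if not any_ok or best is None:
        raise RuntimeError("DoG fit failed to converge from every initialization")
    rss, _, sol = best
    r0, kc, ks, sc, ratio = sol.x
    ss = sc * ratio
    # a surround whose contribution vanishes at every probed diameter is
    # unidentifiable; report it as absent rather than with arbitrary strength
    surround_term = ks * np.pi * ss**2 * np.exp(-((np.pi * ss * d) ** 2))
    if surround_term.max() <= 1e-9 * max(np.max(np.abs(y)), 1.0):
        ks = 0.0
    params = DoGParams(r0, kc, sc, ks, ss)
    n_starts = len(sigma_c_grid) * len(ratio_grid)
    return DoGFit(params=params, rss=rss, converged=bool(sol.success), n_starts=n_starts)


@dataclass(frozen=True)
class FilterConfig:
    """Reverse-correlation settings: 360 Hz rate bins, first second of each
    epoch dropped to control for adaptation, lags kept to 500 ms."""

    bin_rate: float = 360.0
    max_lag_s: float = 0.5
    omit_s: float = 1.0
    divide_power_spectrum: bool = False


def _upsample_frames(stim: StimulusTrace, bin_rate: float, n_bins: int) -> np.ndarray:
    """Sample-and-hold the frame contrasts onto the rate's bin grid.

    Frame indices are computed in integer arithmetic so that exact rate
    ratios (e.g. 60 -> 360 Hz, or equal rates) map bins to frames without
    float rounding at bin boundaries.
    """
    num = int(round(stim.frame_rate * 1e6))
    den = int(round(bin_rate * 1e6))
    idx = (np.arange(n_bins, dtype=np.int64) * num) // den
    idx = np.minimum(idx, stim.n_frames - 1)
    return stim.contrasts[idx]


def estimate_linear_filter(
    stimuli,
    rates,
    config: FilterConfig = FilterConfig(),
) -> LinearFilter:
    """Fourier-domain reverse correlation of stimulus and spike rate.

    Accepts a single epoch or matched sequences of epochs; per-epoch
    filters are averaged with equal weight.  Within each epoch the first
    ``omit_s`` seconds of both signals are discarded, the stimulus frames
    are sample-and-hold upsampled to the rate's bin grid, both signals are
    mean-subtracted, and the filter is ifft(conj(fft(s)) * fft(r)) / N —
    i.e. the stimulus-rate cross-correlation, with the division by the
    (nearly flat) stimulus power spectrum omitted unless requested.
    """
    if isinstance(stimuli, StimulusTrace):
        stimuli = [stimuli]
    if isinstance(rates, SpikeRate):
        rates = [rates]
    if len(stimuli) != len(rates):
        raise ValueError("need one rate epoch per stimulus epoch")
    if not stimuli:
        raise ValueError("no epochs supplied")
    filters = []
    n_spikes = 0.0
    n_lag = None
    for stim, rate in zip(stimuli, rates):
        if abs(rate.bin_rate - config.bin_rate) > 1e-9:
            raise ValueError(
                f"rate binned at {rate.bin_rate} Hz but config expects {config.bin_rate} Hz"
            )
        if abs(stim.duration - rate.duration) > 0.5 / config.bin_rate + 1e-9:
            raise ValueError("stimulus and rate epochs have mismatched durations")
        n_bins = rate.rates.size
        skip = round(config.omit_s * config.bin_rate)
        if n_bins - skip < config.bin_rate:
            raise ValueError("need at least one second of data after the omitted segment")
        s = _upsample_frames(stim, config.bin_rate, n_bins)[skip:]
        r = rate.rates[skip:]
        n_spikes += r.sum() / config.bin_rate
        s = s - s.mean()
        r = r - r.mean()
        n = s.size
        s_f = np.fft.fft(s)
        r_f = np.fft.fft(r)
        num = np.conj(s_f) * r_f
        if config.divide_power_spectrum:
            power = np.abs(s_f) ** 2
            floor = 1e-3 * power.max()
            filt = np.fft.ifft(num / np.maximum(power, floor)).real
        else:
            filt = np.fft.ifft(num).real / n
        if n_lag is None:
            n_lag = min(n, int(round(config.max_lag_s * config.bin_rate)))
        filters.append(filt[:n_lag])
    values = np.mean(filters, axis=0)
    lags_ms = np.arange(n_lag) / config.bin_rate * 1e3
    return LinearFilter(lags_ms, values, config.bin_rate, n_spikes_used=n_spikes)


@dataclass(frozen=True)
class FilterClassification:
    polarity: str  # "ON" | "OFF"
    latency_ms: float
    extremum_value: float


def classify_filter(filt: LinearFilter, window_ms: float = 100.0) -> FilterClassification:
    """Polarity and latency of the filter's dominant lobe.

    OFF if the global absolute extremum within the first ``window_ms`` is
    negative (the cell fires after contrast decrements), else ON.  The
    latency is refined by 3-point parabolic interpolation around the
    extremum bin.
    """
    mask = filt.lags_ms <= window_ms
    if not np.any(mask):
        raise ValueError("empty filter window")
    v = filt.values[mask]
    lags = filt.lags_ms[mask]
    if np.allclose(v, 0):
        raise ValueError("all-zero filter has undefined polarity")
    i = int(np.argmax(np.abs(v)))
    latency = lags[i]
    if 0 < i < v.size - 1:
        y0, y1, y2 = v[i - 1], v[i], v[i + 1]
        denom = y0 - 2 * y1 + y2
        if abs(denom) > 0:
            delta = 0.5 * (y0 - y2) / denom
            latency = lags[i] + delta * (lags[1] - lags[0])
    polarity = "OFF" if v[i] < 0 else "ON"
    return FilterClassification(polarity=polarity, latency_ms=float(latency), extremum_value=float(v[i]))
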