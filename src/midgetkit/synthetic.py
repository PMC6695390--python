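"""Synthetic data with known ground truth.

Every analysis stage in the package has a generator here that produces
its input from first principles: a linear-nonlinear-Poisson (LNP) neuron
for spike responses, template-plus-noise extracellular voltage traces for
spike sorting, linked-disc neuron skeletons and closed-curve pedicles for
morphometry, and normal-mixture ribbon-synapse counts for the bimodality
test.  All generators are deterministic given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .morphometry import (
    AnnotationDisc,
    ClosedCurveAnnotation,
    NeuronAnnotation,
    pedicle_area,
)
from .receptive_field import AreaSummationCurve, DoGParams, dog_predict
from .spikes import RecordingTrace, SpikeTrain
from .stimulus import StimulusTrace

__all__ = [
    "TemporalKernel",
    "SpatialRF",
    "LNPModel",
    "SyntheticAnnotationSpec",
    "off_temporal_kernel",
    "simulate_lnp_spikes",
    "area_summation_ground_truth",
    "default_spike_template",
    "simulate_extracellular_trace",
    "generate_neuron_annotation",
    "generate_pedicle_curve",
    "generate_ribbon_counts",
]


@dataclass(frozen=True)
class TemporalKernel:
    """A temporal filter sampled on a uniform grid starting at 0 ms."""

    time_ms: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_ms, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.size != v.size or t.size < 2:
            raise ValueError("kernel needs matching time and value arrays")
        dt = np.diff(t)
        if abs(t[0]) > 1e-12 or np.any(np.abs(dt - dt[0]) > 1e-9):
            raise ValueError("kernel grid must be uniform and start at 0")
        object.__setattr__(self, "time_ms", t)
        object.__setattr__(self, "values", v)

    @property
    def dt_ms(self) -> float:
        return float(self.time_ms[1] - self.time_ms[0])

    def resample(self, dt_ms: float) -> "TemporalKernel":
        t = np.arange(0.0, self.time_ms[-1] + dt_ms / 2, dt_ms)
        return TemporalKernel(t, np.interp(t, self.time_ms, self.values))


def off_temporal_kernel(
    tau_ms: float = 5.0,
    n: int = 5,
    dt_ms: float = 0.1,
    duration_ms: float = 100.0,
) -> TemporalKernel:
    """Monophasic OFF kernel K(t) = -(t/tau)^n exp(n - t/tau), unit trough.

    The (negative) extremum sits at t = n * tau; the defaults (n = 5,
    tau = 5 ms) place it at 25 ms, matching the filter-trough latency of
    an S-OFF midget ganglion cell.  Values are rescaled to a trough of -1
    so the LNP gain alone sets the response magnitude.
    """
    t = np.arange(0.0, duration_ms + dt_ms / 2, dt_ms)
    v = -((t / tau_ms) ** n) * np.exp(n - t / tau_ms)
    return TemporalKernel(t, v / np.max(np.abs(v)))


@dataclass(frozen=True)
class SpatialRF:
    """Real-space center-surround profile for the simulator's spatial drive.

    Two concentric 2D Gaussians with SDs in um.  Kept deliberately
    separate from the descriptive area-summation DoG form so that fits of
    that form are never validated against themselves.
    """

    center_strength: float = 1.0
    center_sigma_um: float = 10.0
    surround_strength: float = 0.6
    surround_sigma_um: float = 60.0

    def spot_weight(self, diameter_um: float | None) -> float:
        """Integral of the profile over a centered disc (None = full field)."""
        cs, ss = self.center_sigma_um, self.surround_sigma_um
        cw = self.center_strength * 2 * np.pi * cs**2
        sw = self.surround_strength * 2 * np.pi * ss**2
        if diameter_um is None:
            return cw - sw
        r2 = (diameter_um / 2.0) ** 2
        return cw * (1 - np.exp(-r2 / (2 * cs**2))) - sw * (1 - np.exp(-r2 / (2 * ss**2)))


@dataclass(frozen=True)
class LNPModel:
    """Linear-nonlinear-Poisson neuron.

    rate(t) = max(0, baseline + gain * w_spot * (K * s)(t)), spikes drawn
    as an inhomogeneous Poisson process by thinning.  The rectified-linear
    nonlinearity is the simplest form consistent with tonic OFF responses.
    """

    temporal: TemporalKernel
    baseline_rate: float = 20.0
    gain: float = 8.0
    spatial: SpatialRF | None = None

    def __post_init__(self) -> None:
        if self.baseline_rate < 0:
            raise ValueError("baseline rate must be non-negative")
        if not np.isfinite(self.gain):
            raise ValueError("gain must be finite")


def lnp_rate(
    model: LNPModel,
    stimulus: StimulusTrace,
    sample_rate: float = 10_000.0,
    spot_diameter_um: float | None = None,
) -> np.ndarray:
    """Instantaneous firing rate (spikes/s) of the LNP model, pre-spiking.

    The frame contrasts are sample-and-hold upsampled to ``sample_rate``
    and convolved with the temporal kernel; the convolution is a Riemann
    sum (kernel x signal x dt in ms), so halving dt does not change the
    drive.  Spot weight is normalized to the full-field weight = 1 when a
    spatial profile is attached.
    """
    if stimulus.n_frames == 0:
        raise ValueError("empty stimulus")
    n = round(stimulus.duration * sample_rate)
    idx = np.minimum(
        (np.arange(n) / sample_rate * stimulus.frame_rate).astype(int), stimulus.n_frames - 1
    )
    s = stimulus.contrasts[idx]
    dt_ms = 1e3 / sample_rate
    kern = model.temporal.resample(dt_ms)
    drive = fftconvolve(s, kern.values)[:n] * dt_ms
    w = 1.0
    if model.spatial is not None:
        full = model.spatial.spot_weight(None)
        w = model.spatial.spot_weight(spot_diameter_um) / full if full != 0 else 1.0
    return np.maximum(0.0, model.baseline_rate + model.gain * w * drive)


def simulate_lnp_spikes(
    model: LNPModel,
    stimulus: StimulusTrace,
    seed: int | None = 0,
    sample_rate: float = 10_000.0,
    spot_diameter_um: float | None = None,
) -> SpikeTrain:
    """Sample spikes from the LNP model by Poisson thinning.

    Thinning is exact for an inhomogeneous Poisson process with a bounded,
    piecewise-constant rate (constant over each 1/sample_rate step).
    """
    rate = lnp_rate(model, stimulus, sample_rate, spot_diameter_um)
    rng = np.random.default_rng(seed)
    duration = rate.size / sample_rate
    rmax = float(rate.max())
    if rmax <= 0:
        return SpikeTrain(np.array([]), duration)
    n_cand = rng.poisson(rmax * duration)
    t_cand = np.sort(rng.uniform(0.0, duration, n_cand))
    accept = rng.uniform(0.0, rmax, n_cand) < rate[np.minimum((t_cand * sample_rate).astype(int), rate.size - 1)]
    return SpikeTrain(t_cand[accept], duration)


def area_summation_ground_truth(
    params: DoGParams,
    diameters_um,
    noise_sd: float = 0.0,
    seed: int | None = 0,
) -> AreaSummationCurve:
    """Evaluate the DoG area-summation model and add i.i.d. Gaussian noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    d = np.asarray(diameters_um, dtype=float)
    y = dog_predict(params, d)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, d.size)
    return AreaSummationCurve(d, y)


def default_spike_template(sample_rate: float = 10_000.0, width_ms: float = 1.0) -> np.ndarray:
    """Biphasic extracellular spike waveform, 1 ms, negative peak of 1."""
    n = max(3, round(width_ms * 1e-3 * sample_rate))
    t = (np.arange(n) - n // 3) / sample_rate * 1e3  # ms, trough near 1/3
    w = -np.exp(-((t / 0.12) ** 2)) + 0.35 * np.exp(-(((t - 0.3) / 0.2) ** 2))
    return w / np.max(np.abs(w))


def simulate_extracellular_trace(
    spike_times,
    duration: float,
    waveform_template: np.ndarray | None = None,
    noise_sd: float = 0.1,
    amplitude: float | np.ndarray = 1.0,
    sample_rate: float = 10_000.0,
    seed: int | None = 0,
) -> RecordingTrace:
    """Template-plus-Gaussian-noise voltage trace with known spike times.

    Each spike adds ``amplitude * template`` aligned so the template's
    absolute peak lands at the spike time; overlapping templates sum.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    times = np.asarray(spike_times, dtype=float)
    if times.size and (times.min() < 0 or times.max() > duration):
        raise ValueError("spike times must lie within the trace duration")
    if waveform_template is None:
        waveform_template = default_spike_template(sample_rate)
    template = np.asarray(waveform_template, dtype=float)
    n = round(duration * sample_rate)
    if template.size >= n:
        raise ValueError("template must be shorter than the trace")
    rng = np.random.default_rng(seed)
    v = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
    amps = np.broadcast_to(np.asarray(amplitude, dtype=float), times.shape)
    peak_off = int(np.argmax(np.abs(template)))
    for t, a in zip(times, amps):
        start = int(round(t * sample_rate)) - peak_off
        lo, hi = max(start, 0), min(start + template.size, n)
        if hi > lo:
            v[lo:hi] += a * template[lo - start : hi - start]
    return RecordingTrace(sample_rate, v, true_spike_times=times)


@dataclass(frozen=True)
class SyntheticAnnotationSpec:
    """Geometry of a synthetic disc-annotated neuron.

    ``dendrite_diameter_um`` is either a constant or a list of
    (path_distance_um, diameter_um) breakpoints interpolated linearly;
    path distance is measured from the soma boundary.
    """

    soma_diameter_um: float = 9.0
    dendrite_diameter_um: float | tuple = 0.5
    dendrite_length_um: float = 5.0
    disc_spacing_um: float = 0.25
    section_thickness_nm: float = 90.0
    n_ribbon_synapses: int = 0
    pedicle_area_um2: float | None = None
    neuron_id: int = 1

    def __post_init__(self) -> None:
        if min(self.soma_diameter_um, self.dendrite_length_um, self.disc_spacing_um) <= 0:
            raise ValueError("geometry parameters must be positive")
        if self.section_thickness_nm <= 0:
            raise ValueError("section thickness must be positive")

    def diameter_at(self, path_um: float) -> float:
        prof = self.dendrite_diameter_um
        if np.isscalar(prof):
            return float(prof)
        pts = np.asarray(prof, dtype=float)
        return float(np.interp(path_um, pts[:, 0], pts[:, 1]))


def generate_neuron_annotation(
    spec: SyntheticAnnotationSpec, seed: int | None = 0
) -> NeuronAnnotation:
    """Linked-disc neuron: one soma disc plus a straight dendrite of discs.

    The dendrite leaves the soma in a random in-plane direction with discs
    every ``disc_spacing_um`` of path distance from the soma boundary, so
    boundary distances are exact by construction and the measured
    primary-dendrite diameter equals the specified profile.
    """
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0, 2 * np.pi)
    ux, uy = np.cos(theta), np.sin(theta)
    soma_r_nm = spec.soma_diameter_um / 2 * 1e3
    discs = [AnnotationDisc(id=1, x_nm=0.0, y_nm=0.0, z_section=0, radius_nm=soma_r_nm)]
    links = []
    path = spec.disc_spacing_um
    next_id = 2
    prev_id = 1
    while path <= spec.dendrite_length_um + 1e-9:
        r_nm = spec.diameter_at(path) / 2 * 1e3
        c_nm = soma_r_nm + path * 1e3
        discs.append(
            AnnotationDisc(id=next_id, x_nm=ux * c_nm, y_nm=uy * c_nm, z_section=0, radius_nm=r_nm)
        )
        links.append((prev_id, next_id))
        prev_id = next_id
        next_id += 1
        path += spec.disc_spacing_um
    link_map = {d.id: [] for d in discs}
    for a, b in links:
        link_map[a].append(b)
        link_map[b].append(a)
    discs = [
        AnnotationDisc(d.id, d.x_nm, d.y_nm, d.z_section, d.radius_nm, tuple(link_map[d.id]))
        for d in discs
    ]
    curves = ()
    if spec.pedicle_area_um2 is not None:
        curves = (
            generate_pedicle_curve(
                spec.pedicle_area_um2, seed=None if seed is None else seed + 1
            ),
        )
    from .morphometry import SynapseLink

    synapses = tuple(
        SynapseLink(pre_neuron=spec.neuron_id, post_neuron=-1, kind="ribbon")
        for _ in range(spec.n_ribbon_synapses)
    )
    return NeuronAnnotation(
        neuron_id=spec.neuron_id,
        discs=tuple(discs),
        curves=curves,
        synapse_links=synapses,
        section_thickness_nm=spec.section_thickness_nm,
    )


def generate_pedicle_curve(
    target_area_um2: float,
    n_control_points: int = 16,
    irregularity: float = 0.0,
    seed: int | None = 0,
    curve_id: int = 1,
    z_section: int = 0,
) -> ClosedCurveAnnotation:
    """Closed-curve pedicle outline with a known spline-enclosed area.

    Control points sit on a radially perturbed circle (relative radial
    jitter ``irregularity``) and are rescaled so that the centripetal
    Catmull-Rom spline through them encloses ``target_area_um2``; the
    rescale is exact because area scales with the square of a similarity.
    """
    if n_control_points < 4:
        raise ValueError("need at least 4 control points")
    if target_area_um2 <= 0:
        raise ValueError("target area must be positive")
    if irregularity < 0:
        raise ValueError("irregularity must be non-negative")
    rng = np.random.default_rng(seed)
    angles = np.linspace(0, 2 * np.pi, n_control_points, endpoint=False)
    radii = 1.0 + irregularity * rng.uniform(-1.0, 1.0, n_control_points)
    if np.any(radii <= 0):
        raise ValueError("irregularity too large: negative radii")
    r0_nm = np.sqrt(target_area_um2 / np.pi) * 1e3
    pts = r0_nm * radii[:, None] * np.column_stack([np.cos(angles), np.sin(angles)])
    curve = ClosedCurveAnnotation(curve_id, z_section, pts)
    try:
        area = pedicle_area(curve)
    except ValueError as err:
        raise ValueError(f"irregularity {irregularity} produced a self-intersecting outline") from err
    scale = np.sqrt(target_area_um2 / area)
    curve = ClosedCurveAnnotation(curve_id, z_section, pts * scale)
    final = pedicle_area(curve)
    if abs(final - target_area_um2) > 0.005 * target_area_um2:
        raise RuntimeError("pedicle rescaling failed to reach the target area")
    return curve


def generate_ribbon_counts(
    group_means,
    group_sds,
    group_ns,
    seed: int | None = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Integer synapse counts drawn from one or more normal components.

    Returns ``(counts, labels)`` where labels index the generating group.
    With all SDs zero the counts are the rounded means exactly, which
    makes the generator usable as a fixed-value fixture.
    """
    means = np.atleast_1d(np.asarray(group_means, dtype=float))
    sds = np.atleast_1d(np.asarray(group_sds, dtype=float))
    ns = np.atleast_1d(np.asarray(group_ns, dtype=int))
    if not (means.size == sds.size == ns.size):
        raise ValueError("group means, sds and ns must align")
    if np.any(sds < 0):
        raise ValueError("group SDs must be non-negative")
    rng = np.random.default_rng(seed)
    counts, labels = [], []
    for g, (m, s, k) in enumerate(zip(means, sds, ns)):
        draws = rng.normal(m, s, k) if s > 0 else np.full(k, m)
        counts.append(np.rint(draws).astype(int))
        labels.append(np.full(k, g, dtype=int))
    return np.concatenate(counts), np.concatenate(labels)
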