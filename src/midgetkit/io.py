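"""Readers/writers for the package's plain-text containers, run configs
and the end-to-end pipeline.

All containers are text: two-column spectra, '#'-header stimulus and
filter files, single-column spike-time files, and a JSON annotation
schema (discs, links, curves, synapses per neuron).  Writers followed by
readers are identity maps on the data model, and pipeline reruns with the
same config and seeds are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .morphometry import (
    AnnotationDisc,
    ClosedCurveAnnotation,
    NeuronAnnotation,
    SynapseLink,
)
from .receptive_field import AreaSummationCurve, FilterConfig, LinearFilter, classify_filter, estimate_linear_filter
from .spikes import DetectConfig, RecordingTrace, SpikeRate, SpikeTrain, bin_spike_rate, detect_spikes
from .stimulus import SpectralFunction, StimulusTrace, gaussian_noise_stimulus
from . import synthetic

__all__ = [
    "read_spectrum",
    "write_stimulus",
    "read_stimulus",
    "write_spike_train",
    "read_spike_train",
    "write_linear_filter",
    "read_linear_filter",
    "write_area_summation",
    "read_area_summation",
    "write_annotations",
    "read_annotations",
    "RunConfig",
    "run_pipeline",
]

log = logging.getLogger(__name__)


def read_spectrum(path, name: str = "") -> SpectralFunction:
    """Two-column (wavelength_nm, value) delimited text; '#' comments."""
    data = np.loadtxt(path, comments="#")
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (wavelength_nm, value)")
    return SpectralFunction(data[:, 0], data[:, 1], name=name or Path(path).stem)


def _write_header(fh, meta: dict) -> None:
    for k, v in meta.items():
        fh.write(f"# {k}: {v}\n")


def _read_header(path) -> tuple[dict, int]:
    meta, n_header = {}, 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line[1:].strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip()] = v.strip()
    return meta, n_header


def write_stimulus(path, stim: StimulusTrace) -> None:
    with open(path, "w") as fh:
        _write_header(
            fh,
            {
                "frame_rate": repr(float(stim.frame_rate)),
                "mean_level": repr(float(stim.mean_level)),
                "seed": stim.seed,
                "clipped_fraction": repr(float(stim.clipped_fraction)),
            },
        )
        for c in stim.contrasts:
            fh.write(f"{float(c)!r}\n")


def read_stimulus(path) -> StimulusTrace:
    meta, skip = _read_header(path)
    contrasts = np.loadtxt(path, comments="#", ndmin=1)
    seed = None if meta.get("seed") in (None, "None") else int(meta["seed"])
    return StimulusTrace(
        frame_rate=float(meta["frame_rate"]),
        mean_level=float(meta["mean_level"]),
        contrasts=contrasts,
        seed=seed,
        clipped_fraction=float(meta.get("clipped_fraction", 0.0)),
    )


def write_spike_train(path, spikes: SpikeTrain) -> None:
    with open(path, "w") as fh:
        _write_header(fh, {"duration": repr(float(spikes.duration))})
        for t in spikes.spike_times:
            fh.write(f"{float(t)!r}\n")


def read_spike_train(path) -> SpikeTrain:
    meta, _ = _read_header(path)
    times = np.loadtxt(path, comments="#", ndmin=1)
    return SpikeTrain(times, float(meta["duration"]))


def write_linear_filter(path, filt: LinearFilter) -> None:
    with open(path, "w") as fh:
        _write_header(
            fh,
            {
                "bin_rate": repr(float(filt.bin_rate)),
                "n_spikes_used": repr(float(filt.n_spikes_used)),
                "columns": "lag_ms value",
            },
        )
        for lag, v in zip(filt.lags_ms, filt.values):
            fh.write(f"{float(lag)!r} {float(v)!r}\n")


def read_linear_filter(path) -> LinearFilter:
    meta, _ = _read_header(path)
    data = np.loadtxt(path, comments="#", ndmin=2)
    return LinearFilter(
        data[:, 0], data[:, 1], float(meta["bin_rate"]), float(meta.get("n_spikes_used", 0.0))
    )


def write_area_summation(path, curve: AreaSummationCurve) -> None:
    with open(path, "w") as fh:
        _write_header(fh, {"columns": "diameter_um f1 sem"})
        sem = curve.sem if curve.sem is not None else np.full(curve.diameters_um.size, np.nan)
        for d, a, s in zip(curve.diameters_um, curve.f1_amplitudes, sem):
            fh.write(f"{float(d)!r} {float(a)!r} {float(s)!r}\n")


def read_area_summation(path) -> AreaSummationCurve:
    data = np.loadtxt(path, comments="#", ndmin=2)
    sem = data[:, 2] if data.shape[1] > 2 and not np.all(np.isnan(data[:, 2])) else None
    return AreaSummationCurve(data[:, 0], data[:, 1], sem)


# --- annotation schema ------------------------------------------------------

def _neuron_to_dict(n: NeuronAnnotation) -> dict:
    return {
        "neuron_id": n.neuron_id,
        "discs": [
            {"id": d.id, "x_nm": d.x_nm, "y_nm": d.y_nm, "z_section": d.z_section, "radius_nm": d.radius_nm}
            for d in n.discs
        ],
        "links": sorted({tuple(sorted((d.id, l))) for d in n.discs for l in d.links}),
        "curves": [
            {
                "curve_id": c.curve_id,
                "z_section": c.z_section,
                "points_nm": c.control_points_nm.tolist(),
            }
            for c in n.curves
        ],
        "synapses": [
            {"pre_neuron": s.pre_neuron, "post_neuron": s.post_neuron, "kind": s.kind, "z_section": s.z_section}
            for s in n.synapse_links
        ],
    }


def write_annotations(path, neurons, section_thickness_nm: float | None = None) -> None:
    """Write a set of NeuronAnnotation objects to the JSON schema."""
    neurons = list(neurons)
    if section_thickness_nm is None:
        section_thickness_nm = neurons[0].section_thickness_nm if neurons else 90.0
    doc = {
        "section_thickness_nm": section_thickness_nm,
        "neurons": [_neuron_to_dict(n) for n in neurons],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_annotations(path) -> list[NeuronAnnotation]:
    """Read the JSON annotation schema; validates link referential integrity.

    An orphan link (referencing a disc id not present in the neuron) is a
    schema violation and raises with the offending id.
    """
    with open(path) as fh:
        doc = json.load(fh)
    thickness = float(doc.get("section_thickness_nm", 90.0))
    neurons = []
    for nd in doc.get("neurons", []):
        disc_ids = {d["id"] for d in nd.get("discs", [])}
        link_map: dict[int, list[int]] = {i: [] for i in disc_ids}
        for a, b in nd.get("links", []):
            for x in (a, b):
                if x not in disc_ids:
                    raise ValueError(
                        f"neuron {nd.get('neuron_id')}: link ({a}, {b}) references unknown disc id {x}"
                    )
            link_map[a].append(b)
            link_map[b].append(a)
        discs = tuple(
            AnnotationDisc(
                id=d["id"],
                x_nm=float(d["x_nm"]),
                y_nm=float(d["y_nm"]),
                z_section=int(d["z_section"]),
                radius_nm=float(d["radius_nm"]),
                links=tuple(sorted(link_map[d["id"]])),
            )
            for d in nd.get("discs", [])
        )
        curves = tuple(
            ClosedCurveAnnotation(c["curve_id"], int(c["z_section"]), np.asarray(c["points_nm"]))
            for c in nd.get("curves", [])
        )
        synapses = tuple(
            SynapseLink(s["pre_neuron"], s["post_neuron"], s["kind"], int(s.get("z_section", 0)))
            for s in nd.get("synapses", [])
        )
        neurons.append(
            NeuronAnnotation(
                neuron_id=nd["neuron_id"],
                discs=discs,
                curves=curves,
                synapse_links=synapses,
                section_thickness_nm=thickness,
            )
        )
    return neurons


# --- run configuration and pipeline ----------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Configuration for the simulate -> detect -> filter pipeline.

    Every stochastic stage carries an explicit seed; unknown config keys
    are rejected so typos cannot silently fall back to defaults.
    """

    seed: int = 0
    n_epochs: int = 5
    epoch_duration: float = 10.0
    frame_rate: float = 60.0
    mean_level: float = 0.5
    noise_sd: float = 0.3
    baseline_rate: float = 20.0
    gain: float = 8.0
    kernel_tau_ms: float = 5.0
    kernel_n: int = 5
    spike_snr: float = 10.0
    highpass_cutoff: float = 100.0
    threshold_mult: float = 4.0
    bin_rate: float = 360.0
    max_lag_s: float = 0.5
    output_dir: str = "midgetkit_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict:
    """Run the full synthetic physiology chain and write its artifacts.

    Stages: Gaussian-noise stimulus -> LNP spike simulation -> synthetic
    extracellular trace -> high-pass + k-means spike detection -> 360 Hz
    rate binning -> reverse-correlation filter estimate.  Returns a result
    bundle (paths, filter classification, config hash); all outputs carry
    the config hash and stage seeds in their headers/metadata.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seeds = np.random.SeedSequence(config.seed).generate_state(3) % (2**31)
    stim_seed, lnp_seed, trace_seed = (int(s) for s in rng_seeds)

    log.info("stage=stimulus seed=%d", stim_seed)
    epochs = gaussian_noise_stimulus(
        mean_level=config.mean_level,
        sd=config.noise_sd,
        frame_rate=config.frame_rate,
        epoch_duration=config.epoch_duration,
        n_epochs=config.n_epochs,
        seed=stim_seed,
    )
    kernel = synthetic.off_temporal_kernel(tau_ms=config.kernel_tau_ms, n=config.kernel_n)
    model = synthetic.LNPModel(kernel, baseline_rate=config.baseline_rate, gain=config.gain)

    detected_rates = []
    n_true = n_detected = 0
    for i, stim in enumerate(epochs):
        spikes = synthetic.simulate_lnp_spikes(model, stim, seed=lnp_seed + i)
        trace = synthetic.simulate_extracellular_trace(
            spikes.spike_times,
            duration=stim.duration,
            noise_sd=1.0 / config.spike_snr,
            seed=trace_seed + i,
        )
        det, _ = detect_spikes(
            trace,
            DetectConfig(
                highpass_cutoff=config.highpass_cutoff,
                threshold_mult=config.threshold_mult,
                seed=config.seed,
            ),
        )
        n_true += spikes.n_spikes
        n_detected += det.n_spikes
        detected_rates.append(bin_spike_rate(det, config.bin_rate, duration=stim.duration))
        write_stimulus(out / f"stimulus_epoch{i:02d}.txt", stim)
        write_spike_train(out / f"spikes_epoch{i:02d}.txt", det)

    filt = estimate_linear_filter(
        epochs, detected_rates, FilterConfig(bin_rate=config.bin_rate, max_lag_s=config.max_lag_s)
    )
    write_linear_filter(out / "linear_filter.txt", filt)
    cls = classify_filter(filt)
    bundle = {
        "config_hash": config.config_hash(),
        "seeds": {"stimulus": stim_seed, "lnp": lnp_seed, "trace": trace_seed},
        "n_true_spikes": int(n_true),
        "n_detected_spikes": int(n_detected),
        "polarity": cls.polarity,
        "trough_latency_ms": cls.latency_ms,
        "filter_path": str(out / "linear_filter.txt"),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(bundle, fh, indent=1, sort_keys=True)
    log.info("pipeline complete: polarity=%s latency=%.2f ms", cls.polarity, cls.latency_ms)
    return bundle
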