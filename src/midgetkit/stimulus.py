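"""Cone-isolating stimulus design.

Silent substitution: with three display primaries and three cone classes,
the relative quantal catch of each cone from each primary defines a 3x3
transformation matrix A.  Solving ``A^T w = c`` gives the LED weight
vector ``w`` producing an arbitrary cone-contrast triple ``c`` — e.g.
(0, 0, 1) modulates S-cones while holding L- and M-cones silent.

Also provides the temporal stimuli used downstream: Gaussian contrast
noise (for reverse correlation) and square-wave modulations (for F1
analysis), plus Weber-contrast and photoisomerization-rate helpers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpectralFunction",
    "QuantalCatchMatrix",
    "StimulusTrace",
    "SpotStimulusSpec",
    "cone_fundamentals",
    "govardovskii_template",
    "build_catch_matrix",
    "solve_led_weights",
    "isolation_report",
    "gaussian_noise_stimulus",
    "squarewave_modulation",
    "weber_contrast",
    "isomerization_rate",
]

log = logging.getLogger(__name__)

CONE_NAMES = ("L", "M", "S")


@dataclass(frozen=True)
class SpectralFunction:
    """A sampled function of wavelength: LED emission or cone sensitivity.

    Parameters
    ----------
    wavelengths : array
        Sample wavelengths in nm, strictly increasing.
    values : array
        Non-negative relative power or sensitivity at each wavelength.
    name : str
        Optional label (e.g. ``"405nm LED"`` or ``"S"``).
    """

    wavelengths: np.ndarray
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or v.ndim != 1 or wl.size != v.size:
            raise ValueError("wavelengths and values must be 1-D and equal length")
        if wl.size == 0:
            raise ValueError("empty spectrum")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(v < 0):
            raise ValueError("spectral values must be non-negative")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", v)

    def resample(self, grid: np.ndarray) -> np.ndarray:
        """Linear interpolation onto ``grid``; zero outside the support."""
        return np.interp(grid, self.wavelengths, self.values, left=0.0, right=0.0)


def govardovskii_template(wavelengths: np.ndarray, lambda_max: float) -> np.ndarray:
    """A1 visual-pigment absorbance template (alpha + beta band).

    Standard rhodopsin nomogram parameterized only by the peak wavelength;
    returned curve is normalized to unit peak.  Used to construct cone
    fundamentals when a measured set is not supplied.
    """
    wl = np.asarray(wavelengths, dtype=float)
    x = lambda_max / wl
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )
    lam_b = 189.0 + 0.315 * lambda_max
    b_b = -40.5 + 0.195 * lambda_max
    beta = 0.26 * np.exp(-(((wl - lam_b) / b_b) ** 2))
    s = alpha + beta
    return s / s.max()


def cone_fundamentals(
    wavelengths: np.ndarray | None = None,
    peaks: tuple[float, float, float] = (561.0, 531.0, 419.0),
) -> tuple[SpectralFunction, SpectralFunction, SpectralFunction]:
    """Macaque/human L-, M- and S-cone sensitivity templates (unit peak).

    Default peaks are 561, 531 and 419 nm.  Any measured fundamental set
    can be substituted anywhere these are accepted; the templates exist so
    the package is self-contained.
    """
    if wavelengths is None:
        wavelengths = np.arange(360.0, 781.0, 1.0)
    out = []
    for name, peak in zip(CONE_NAMES, peaks):
        out.append(SpectralFunction(wavelengths, govardovskii_template(wavelengths, peak), name=name))
    return tuple(out)


@dataclass(frozen=True)
class QuantalCatchMatrix:
    """3x3 relative quantal catches: rows = LED primaries, columns = (L, M, S)."""

    entries: np.ndarray
    led_names: tuple[str, str, str] = ("R", "G", "B")
    condition_threshold: float = 1e8

    def __post_init__(self) -> None:
        e = np.asarray(self.entries, dtype=float)
        if e.shape != (3, 3):
            raise ValueError("catch matrix must be 3x3")
        if np.any(e < 0):
            raise ValueError("quantal catches must be non-negative")
        object.__setattr__(self, "entries", e)

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.entries))

    @property
    def is_singular(self) -> bool:
        return (
            np.linalg.matrix_rank(self.entries) < 3
            or self.condition_number > self.condition_threshold
        )


def build_catch_matrix(
    led_spectra,
    fundamentals=None,
    grid_step_nm: float = 1.0,
    normalize_per_cone: bool = False,
) -> QuantalCatchMatrix:
    """Integrate LED spectra against cone sensitivities.

    Entry (p, c) = trapezoid( primary_p(lambda) * cone_c(lambda) ) on a
    common wavelength grid covering the overlap of all six supports.

    Parameters
    ----------
    led_spectra : sequence of 3 SpectralFunction
    fundamentals : sequence of 3 SpectralFunction, optional
        Order (L, M, S).  Defaults to the packaged templates.
    normalize_per_cone : bool
        If True, scale each cone column to unit maximum.
    """
    if fundamentals is None:
        fundamentals = cone_fundamentals()
    led_spectra = tuple(led_spectra)
    fundamentals = tuple(fundamentals)
    if len(led_spectra) != 3 or len(fundamentals) != 3:
        raise ValueError("need exactly three LED spectra and three cone fundamentals")
    lo = max(s.wavelengths[0] for s in led_spectra + fundamentals)
    hi = min(s.wavelengths[-1] for s in led_spectra + fundamentals)
    if hi <= lo:
        raise ValueError(
            f"spectra share no overlapping wavelength range ({lo:.1f} > {hi:.1f} nm)"
        )
    grid = np.arange(lo, hi + grid_step_nm / 2, grid_step_nm)
    entries = np.empty((3, 3))
    for p, led in enumerate(led_spectra):
        lp = led.resample(grid)
        for c, cone in enumerate(fundamentals):
            entries[p, c] = np.trapezoid(lp * cone.resample(grid), grid)
    if normalize_per_cone:
        colmax = entries.max(axis=0)
        entries = np.where(colmax > 0, entries / np.where(colmax > 0, colmax, 1.0), entries)
    names = tuple(s.name or d for s, d in zip(led_spectra, ("R", "G", "B")))
    return QuantalCatchMatrix(entries, led_names=names)


def solve_led_weights(matrix: QuantalCatchMatrix, target) -> np.ndarray:
    """Solve for LED weights producing the target (L, M, S) cone contrasts.

    Raises ``np.linalg.LinAlgError`` (naming the condition number) when the
    catch matrix is singular or too ill-conditioned to trust.
    """
    target = np.asarray(target, dtype=float)
    if target.shape != (3,):
        raise ValueError("target must be an (L, M, S) triple")
    if matrix.is_singular:
        raise np.linalg.LinAlgError(
            "catch matrix is singular or ill-conditioned "
            f"(condition number {matrix.condition_number:.3g})"
        )
    # rows are primaries: catches from weight vector w are A^T w
    return np.linalg.solve(matrix.entries.T, target)


def catches_from_weights(matrix: QuantalCatchMatrix, weights) -> np.ndarray:
    """Cone catches (L, M, S) produced by an LED weight triple."""
    return matrix.entries.T @ np.asarray(weights, dtype=float)


@dataclass(frozen=True)
class IsolationReport:
    primary: str
    relative_catches: np.ndarray  # normalized to the max cone catch
    target_cone: str
    purity: float


def isolation_report(matrix: QuantalCatchMatrix, primary_index: int) -> IsolationReport:
    """Descriptive cone isolation of a single primary used alone.

    Purity is defined as ``1 - max(other catches) / target catch`` where the
    target cone is the one with the largest catch.  A primary exciting one
    cone exclusively scores 1; equal catches score 0.
    """
    row = matrix.entries[primary_index]
    if not np.any(row > 0):
        raise ValueError("primary has an all-zero catch row")
    rel = row / row.max()
    t = int(np.argmax(row))
    others = np.delete(row, t)
    purity = 1.0 - float(others.max() / row[t])
    return IsolationReport(
        primary=matrix.led_names[primary_index],
        relative_catches=rel,
        target_cone=CONE_NAMES[t],
        purity=purity,
    )


@dataclass(frozen=True)
class StimulusTrace:
    """A frame-based temporal stimulus.

    ``contrasts`` holds the Weber contrast of each frame relative to
    ``mean_level``; intensity of frame k is ``mean_level * (1 + contrasts[k])``.
    """

    frame_rate: float
    mean_level: float
    contrasts: np.ndarray
    seed: int | None = None
    clipped_fraction: float = 0.0

    def __post_init__(self) -> None:
        c = np.asarray(self.contrasts, dtype=float)
        object.__setattr__(self, "contrasts", c)
        if not 0.0 <= self.mean_level <= 1.0:
            raise ValueError("mean_level must lie in [0, 1]")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.contrasts.size)

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def intensities(self) -> np.ndarray:
        return self.mean_level * (1.0 + self.contrasts)

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


@dataclass(frozen=True)
class SpotStimulusSpec:
    """Spot stimulus: diameter, temporal modulation, and chromatic target."""

    diameter_um: float
    temporal_frequency: float
    contrast: float
    waveform: str = "square"
    chromatic_target: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise ValueError("diameter must be positive")
        if self.temporal_frequency <= 0:
            raise ValueError("temporal frequency must be positive")
        if abs(self.contrast) > 1:
            raise ValueError("|contrast| must be <= 1")
        if self.waveform not in ("square", "sinusoid"):
            raise ValueError("waveform must be 'square' or 'sinusoid'")


def gaussian_noise_stimulus(
    mean_level: float = 0.5,
    sd: float = 0.3,
    frame_rate: float = 60.0,
    epoch_duration: float = 10.0,
    n_epochs: int = 1,
    seed: int | None = 0,
) -> list[StimulusTrace]:
    """Gaussian temporal noise: i.i.d. Normal(mean, sd) intensity per frame.

    Defaults match the reverse-correlation stimulus used throughout: 60 Hz
    frames at mean intensity 0.5 with SD 0.3, in 10 s epochs.  Draws falling
    outside the displayable range [0, 1] are clipped; the clipped fraction
    is recorded per epoch and logged.
    """
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if epoch_duration <= 0:
        raise ValueError("epoch duration must be positive")
    if n_epochs < 1:
        raise ValueError("need at least one epoch")
    rng = np.random.default_rng(seed)
    n_frames = round(frame_rate * epoch_duration)
    epochs = []
    for _ in range(n_epochs):
        intens = rng.normal(mean_level, sd, n_frames)
        clipped = float(np.mean((intens < 0) | (intens > 1)))
        intens = np.clip(intens, 0.0, 1.0)
        if clipped > 0:
            log.debug("gaussian_noise_stimulus: clipped %.2f%% of frames", 100 * clipped)
        contrasts = (intens - mean_level) / mean_level
        epochs.append(
            StimulusTrace(frame_rate, mean_level, contrasts, seed=seed, clipped_fraction=clipped)
        )
    return epochs


def squarewave_modulation(
    spec: SpotStimulusSpec,
    frame_rate: float = 60.0,
    duration: float = 1.0,
    mean_level: float = 0.5,
    first_half_sign: int = 1,
    quantization: str = "nearest",
) -> StimulusTrace:
    """Square (or sinusoidal) temporal modulation at +/- spec.contrast.

    Half-cycles that are not an integer number of frames are quantized by
    evaluating the ideal waveform at each frame time (``quantization=
    'nearest'``); pass ``'strict'`` to require exact representability.
    """
    f = spec.temporal_frequency
    if f >= frame_rate / 2:
        raise ValueError("temporal frequency must be below the frame Nyquist rate")
    half_frames = frame_rate / (2 * f)
    if quantization == "strict" and abs(half_frames - round(half_frames)) > 1e-9:
        raise ValueError(
            f"{f} Hz is not representable at {frame_rate} Hz frames "
            f"({half_frames} frames per half-cycle)"
        )
    n_frames = round(frame_rate * duration)
    t = np.arange(n_frames) / frame_rate
    if spec.waveform == "sinusoid":
        wave = np.sin(2 * np.pi * f * t)
    else:
        phase = (f * t) % 1.0
        wave = np.where(phase < 0.5, 1.0, -1.0)
    contrasts = first_half_sign * spec.contrast * wave
    return StimulusTrace(frame_rate, mean_level, contrasts)


def weber_contrast(intensity, background: float):
    """(I - I_b) / I_b.  Background must be positive."""
    if background <= 0:
        raise ValueError("background intensity must be positive")
    return (np.asarray(intensity, dtype=float) - background) / background


def isomerization_rate(photon_flux: float, collecting_area_um2: float) -> float:
    """Photoisomerizations per photoreceptor per second: flux x collecting area.

    Typical cone collecting areas are 0.37 or 1 um^2; photopic experiments
    run around 3e3 to 3e5 R*/s.
    """
    if photon_flux < 0 or collecting_area_um2 < 0:
        raise ValueError("flux and collecting area must be non-negative")
    return photon_flux * collecting_area_um2
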