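# Methods

This note documents the models, conventions and numerical choices behind
midgetkit, and what the synthetic-data tests do and do not establish about
real recordings.

## Silent-substitution stimulus design

Quantal catches are computed by trapezoidal quadrature of LED spectrum ×
cone sensitivity on a common 1 nm wavelength grid (linear interpolation for
resampling, zero outside a spectrum's support). The 3×3 catch matrix *A*
has primaries as rows and cones (L, M, S) as columns; the catch produced by
LED weights *w* is *Aᵀw*, and cone-isolating weights solve *Aᵀw = c*
directly. Solving refuses matrices whose condition number exceeds 10⁸ and
reports the condition number in the error.

Cone fundamentals default to A1-pigment nomogram templates (alpha and beta
bands) peaking at 561, 531 and 419 nm, normalized to unit peak. These are
closed-form standards, adequate for design work: against them a 15 nm FWHM
405 nm primary yields relative catches 1.0 : 0.204 : 0.219 (S : M : L),
i.e. ~78% S-cone isolating under the purity metric below. Any measured
fundamental set can be passed in instead; catch ratios shift at the few
percent level depending on the template family, so third-decimal agreement
between template sets should not be expected.

**Isolation purity** of a single primary is defined as
`1 − max(non-target catch) / target catch` — 1 for perfect isolation, 0
when another cone is caught equally. This is one of several defensible
ratio conventions; it is descriptive only and plays no role in solving.

**Gaussian noise stimulus** (defaults: 60 Hz frames, mean intensity 0.5,
SD 0.3, 10 s epochs): each frame is an i.i.d. normal intensity draw,
clipped to the displayable [0, 1]; at the default settings ~10% of draws
clip, the clipped fraction is recorded on the trace, and the contrast
sequence is therefore very slightly platykurtic relative to a true normal.
**Square waves** at frequencies whose half-cycle is not an integer frame
count are quantized frame-by-frame against the ideal waveform (every frame
is exactly ± the nominal contrast; cycle lengths jitter by one frame), or
rejected in strict mode.

**Photoisomerization rate** is photon flux × collecting area (0.37 or
1 µm² are the usual cone values); purely multiplicative, provided for unit
bookkeeping.

## LNP simulator and other generators

The simulated neuron is a linear-nonlinear-Poisson cascade:
`rate(t) = max(0, baseline + gain · w_spot · (K ∗ s)(t))`. The temporal
kernel is sampled at the simulation step (default 10 kHz) and the
convolution is a Riemann sum (× dt in ms), so the drive is invariant to the
step size. The packaged OFF kernel is the gamma-like form
`K(t) = −(t/τ)ⁿ e^{n−t/τ}` rescaled to a trough of −1; its extremum sits at
t = nτ (defaults n = 5, τ = 5 ms → 25 ms), matching the filter-trough
latency typical of S-OFF midget cells. Defaults baseline 20 spikes/s and
gain 8 give strongly modulated firing (mean ≈ 50 spikes/s, peaks ≈ 200)
under the default noise stimulus — a deliberately robust OFF response; the
rectifier is engaged a substantial fraction of the time, as for a real
tonic OFF cell driven at high contrast.

Spikes are drawn by thinning a homogeneous Poisson process at the rate
maximum — exact for a piecewise-constant rate. Spot-size drive uses a
separate real-space center-surround profile (two concentric 2D Gaussians
with σ in µm, disc integrals in closed form), kept deliberately distinct
from the descriptive area-summation form below so fits of that form are
never validated against themselves.

Extracellular traces are a biphasic ~1 ms unit-peak template added at each
spike time plus white Gaussian noise; overlapping templates sum. Synthetic
annotation neurons place one soma disc and a straight in-plane dendrite
with discs every 0.25 µm of path distance, so shell distances and disc
diameters are exact by construction. Pedicle outlines are radially
perturbed circles rescaled so the spline-enclosed area equals the target
(exact under similarity scaling, verified to 0.5%). All generators are
bit-reproducible given (spec, seed); every stochastic function takes an
explicit seed and no global random state is used.

What the generators do *not* emulate: correlated noise and drift in
recordings, bursting or refractory spike statistics, electrode motion,
multi-neuron traces, curved dendrites crossing sections, and annotation
error. Passing tests establish correctness of the analysis code under the
stated model, not performance on degraded real data.

## Spike extraction

Traces are zero-phase (forward-backward) Butterworth high-pass filtered —
zero phase so that detection does not bias downstream latency estimates.
Candidate events are local extrema of |v| above `threshold_mult` (default
4) × the robust SD (1.4826 × median absolute deviation), with a 1 ms
minimum separation. At 10 kHz this yields <1 false event/s on pure
Gaussian noise. Snippets of ±1 ms around each peak are reduced to two
principal components plus peak amplitude (standardized) and clustered with
k-means, k = 2, fixed seed. The cluster with the larger mean |peak| is
kept as spikes *only* when the two clusters' mean amplitudes differ at
least 2-fold; otherwise all events are treated as one spike population —
without this rule a homogeneous spike train would lose about half of its
events to an arbitrary split. A manual amplitude threshold can be applied
after (or instead of) clustering. Spike time = sample of the absolute
peak. The threshold, window and feature choices are configurable defaults,
not field-standard constants.

## Rates, F1 and cycle averaging

Rates are spike-count histograms divided by bin width (360 Hz for filter
estimation, 60 Hz for F1 work). Cycle averaging drops the partial final
cycle; when the period is not an integer number of bins, each cycle is
linearly resampled onto a common phase grid of round(bins/cycle) bins. F1
is the amplitude of the fundamental DFT component of the cycle-averaged
rate (2|X₁|/N): exactly A for `m + A sin(2πft)`, A/2 for a half-wave
rectified sinusoid, and invariant to rate offsets.

## DoG area-summation fit

The response-vs-spot-diameter curve is fit with
`R(f) = R₀ + K_c πσ_c² e^{−(πσ_c f)²} − K_s πσ_s² e^{−(πσ_s f)²}` evaluated
literally with f the spot diameter in µm. In this form the σ parameters
act as *inverse* length scales (working values ~0.003–0.08 against
diameters of 2–300 µm): the mechanism with the larger σ rolls off at
smaller f, so the spatially broad surround satisfies σ_s ≥ σ_c (enforced
via σ_s = ratio · σ_c, ratio ≥ 1) and the curve rises as the spot escapes
the surround term before decaying to R₀ — the spatial-opponency signature.
The σ values are descriptive shape parameters, not Gaussian SDs in µm, and
should be compared only within this parameterization.

Fitting is bounded trust-region least squares (all strengths ≥ 0, R₀ ≥ 0)
multi-started over σ_c ∈ {0.0025, 0.005, 0.01, 0.02, 0.04, 0.08} ×
ratio ∈ {2, 4, 8}, with strengths initialized from the curve amplitude;
best RSS wins, exact ties to the smaller σ_c. Noiseless synthetic curves
are recovered to optimizer tolerance (≪0.1%). A surround whose
contribution is below 10⁻⁹ of the data scale at every probed diameter is
unidentifiable and reported as K_s = 0 rather than with arbitrary
strength. Five or more distinct diameters are required.

## Reverse-correlation filter

Per epoch: the first 1 s of stimulus and rate is dropped (adaptation
guard), the frame contrasts are sample-and-hold upsampled onto the rate's
bin grid (integer index arithmetic, so exact rate ratios introduce no
rounding), both signals are mean-subtracted, and the filter is
`ifft(conj(fft(s)) · fft(r)) / N` truncated to 500 ms of lags — the
stimulus–rate cross-correlation. Division by the stimulus power spectrum
is available by config (with a 10⁻³ relative power floor) and agrees with
the omitted-denominator default to <2% RMS on exactly-white stimuli; it is
omitted by default because Gaussian frame noise is nearly white. Epoch
filters are averaged with equal weight; raw amplitudes are kept (units are
arbitrary), with an optional unit-L2 copy for plotting overlays.

Classification: OFF if the global absolute extremum in the first 100 ms is
negative, else ON; latency is the extremum lag refined by 3-point
parabolic interpolation. Note that a 60 Hz frame stimulus correlates the
kernel with the frame-hold autocorrelation (a ±1-frame triangle), which
smooths the estimate and biases the recovered trough late by ~1–2 ms at
360 Hz binning; the simulated 25 ms kernel is recovered at ≈26–27 ms,
within one bin.

## Morphometry

Coordinates are nm with z a section index; z distances use section index ×
section thickness (default 90 nm). Soma diameter is twice the largest disc
radius (ties to the lowest id). Primary dendrite diameter is the median
disc diameter in a shell 0.5–1.5 µm (inclusive) from the **soma boundary**
(center distance − soma radius): soma radii (~4.5 µm) exceed 1.5 µm, so a
center-based shell would always be empty; the boundary convention is the
reading that yields a measurement, and the bounds are configurable.
Pedicle area is the shoelace area of a closed centripetal (α = 0.5)
Catmull-Rom spline through the control points, 20 samples per segment by
default; sampled outlines are checked for self-intersection and rejected
with the offending location. Areas converge monotonically with sampling
density and are invariant to rigid motion to <0.1%. When a pedicle spans
several sections, the per-pedicle area is the maximum single-section
area — the simplest per-pedicle aggregate. Ribbon-synapse counts filter
links by kind; basal contacts are excluded.

## Bootstrap bimodality test

Given integer counts in two labeled groups, the observed statistic is the
average of the two within-group sample SDs. The null is a normal with the
pooled mean and SD (n−1) of all counts ignoring labels; each of the 10,000
default iterations draws n values, rounds them half-to-even, splits them at
*their own* sample mean (mirroring how observed data are labeled; splitting
at the null mean is available by option), and averages the two group SDs,
with groups of size <2 contributing SD 0. Bimodal data form tight clusters
and give a *small* average within-group SD, so the p-value is the
lower-tail fraction of null statistics ≤ observed. For the reconstructed
seven-count example (groups {39, 40, 40} and {50, 52, 52, 53}) the median p
over 20 seeds is ≈0.013.

Two caveats, established by simulation in the test suite:

1. **Conservatism.** Because the null parameters are estimated from the
   very data being split, the test is conservative: on truly unimodal data
   the rejection rate at α = 0.05 is ≈0.01–0.02. Re-running the identical
   machinery with *known* null parameters gives an exactly uniform p
   (measured 0.0505 at α = 0.05), isolating the plug-in estimation as the
   sole source. Small p-values therefore understate the evidence for
   bimodality; nominal-level calibration is not attainable for the plug-in
   procedure itself.
2. **Tail direction.** Only the lower tail produces small p for clustered
   data; the upper tail is retained as an option for sensitivity checks.

The fraction of bootstrap iterations with a singleton/empty group is
reported as a diagnostic. p is an exact fraction with denominator n_boot
and runs are deterministic given the seed.

Rank-sum comparisons use exact enumeration of all label assignments (with
midranks, so ties are handled) for n ≤ 12, and the tie- and
continuity-corrected normal approximation above that. Two-sided exact
convention: P(|U − μ_U| ≥ |U_obs − μ_U|).

## Problem sizes and determinism

Simulation-based checks use twenty 10-s epochs (filter-trough recovery),
100-spike traces at SNR 10 (detection), 30 noisy curves (DoG noise study)
and 1000 null datasets × 1000 bootstrap iterations (test calibration) —
sizes at which the measured quantities are stable to well within their
acceptance tolerances while the whole suite runs in well under a minute.
All stochastic stages take explicit seeds; pipeline reruns with identical
config are byte-identical.
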