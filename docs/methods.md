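# Methods

This note documents the models, numerical choices and known limitations of
`pacemap`. It is written for users who need to judge what the package's
outputs — and its passing tests — do and do not establish.

## Signal model and activation detection

Unipolar extracellular electrograms of a propagating excitation are
biphasic: a positive phase as the wavefront approaches, a rapid downstroke
(typically < 1 ms) as the tissue under the electrode depolarises, and a
negative phase as it recedes. Local activation time is defined
operationally as the instant of the steepest downstroke — the minimum of
the first derivative, computed with centred finite differences (one-sided
at the trace ends).

The conditioning chain before detection:

1. **3-sample sliding median** (edge replication): removes single-sample
   acquisition glitches exactly, without smearing the downstroke.
2. **AC coupling**: the discrete first-order high pass
   `y[k] = a·y[k−1] + a·(x[k] − x[k−1])` with `a = τ/(τ + Tₛ)`, τ = 3 ms.
   This is the canonical digital realisation of an analog AC-coupling
   stage with the stated time constant. Because the downstroke is much
   faster than τ, the filter's effect on detected timing is small; with
   the default synthetic waveform it is ≈ 0.2 samples at 10 kHz.
3. **Kaiser-window FIR low pass**, default cutoff 2 kHz (configurable in
   [500, 3000] Hz or disabled), 60 dB stopband, 500 Hz transition. The
   kernel is symmetric and odd-length and is applied with its group delay
   compensated (edge-replicated convolution), so it is exactly zero-phase:
   filtering does not move activation times. Its purpose is noise
   rejection — the derivative operator amplifies high-frequency noise by
   ≈ f, so removing content above 2 kHz sharply lowers the derivative's
   noise floor while the sub-millisecond downstroke (spectral content
   ≲ 1 kHz) passes.

**Detection threshold.** Events are local minima of the derivative below
−k·σ̂, with σ̂ = 1.4826 × median absolute deviation of the derivative and
k = 5 by default (per-channel override available). This replaces the
manually tuned, manually curated thresholds of interactive workflows with
a reproducible rule. Consequences to be aware of:

* On a *noiseless* trace σ̂ collapses towards zero and every ripple of the
  waveform is "detected"; the dominant-weight rule during beat clustering
  (below) keeps the true downstroke. Detection quality statements are
  therefore phrased in terms of recovered activation times, not raw event
  counts.
* On realistic noise, ~5σ excursions still occur at a rate of roughly one
  per channel-minute at 10 kHz. These surface as single-electrode beats.
  They are flagged ineligible for spatial analysis but are retained in the
  IBI series (see below), which is the main respect in which the automated
  pipeline differs from a curated analysis.
* Events within half a filter kernel of either trace end are discarded:
  boundary handling (edge replication) contaminates those samples.

**Fractionation fusion.** Electrograms whose downstroke has several
derivative minima within 1 ms are fused into one activation at the
derivative-magnitude-weighted mean time; the fused weight is the sum of
member weights, making fusion idempotent and order-independent.

**Sub-sample refinement** (parabolic interpolation of the derivative
minimum) exists but is off by default: activation times are reported at
sample resolution.

## Beats, IBIs and the instantaneous beat rate

Excitations appear as clusters of events across electrodes separated by
silent intervals. Events with consecutive gaps below 50 ms form one beat:
propagation across the 8-mm disc at ~30 cm/s takes ≲ 27 ms, while beats
are ≥ 500 ms apart at the rates observed, so the gap separates scales
safely; it is configurable. Within a beat at most one event per electrode
is kept (largest derivative magnitude, with a warning). Beats with fewer
than 4 electrodes cannot support the planar fit and are excluded from
spatial analysis but retained in the IBI series; long pauses (multi-second
IBIs) are retained, not censored.

The IBI series is the difference series of the per-beat mean activation
times mᵢ. Because it is irregularly sampled, epoch averaging uses the
uniformly resampled **instantaneous beat rate**: with
f(t) = 1/(mᵢ₊₁ − mᵢ) on [mᵢ, mᵢ₊₁), bin i is rᵢ = (1/Δt)∫ f over the i-th
Δt interval, Δt = 0.5 s. The cumulative integral of f is the
piecewise-linear beat-count function F (F(mᵢ) = i), so bins are computed
exactly as differences of a linear interpolant, and conservation
Σ rᵢ·Δt = number of covered IBIs holds to round-off. Bins are anchored at
the first beat (f is undefined earlier); the anchor is configurable, and
epoch analysis re-anchors at motor start (exact, since the IBR carries its
underlying beat times). The trailing, partially covered bin is flagged.

## Slowness, entropy, PCA

With 12 electrodes the pacemaker focus cannot be localised; each beat's
pattern is summarised by the slowness vector from the OLS plane fit of
activation time on electrode position (≥ 4 non-collinear electrodes
required). Slowness — the spatial gradient of activation time, in s/cm —
is preferred over velocity because a symmetric or near-simultaneous
pattern has ‖s⃗‖ → 0, where velocity diverges; `slowness_to_velocity`
(v⃗ = s⃗/‖s⃗‖²) raises an explicit error at ‖s⃗‖ = 0 rather than
returning infinity.

Pattern complexity over a recording is the Shannon entropy (nats) of the
2-D histogram of slowness tips on a square grid of side 0.005 s/cm. The
grid is anchored at the origin of the slowness plane with half-open bins
[k·b, (k+1)·b) — a fixed, reproducible choice; a data-adaptive origin
would change E slightly. Entropy is computed over occupied bins, is
permutation-invariant, and cannot decrease when a cluster is split across
finer bins.

PCA operates on the beats × electrodes matrix of mean-offset activation
times t′ᵢⱼ = tᵢⱼ − mᵢ (complete beats only, since the matrix admits no
holes), via SVD of the column-centred matrix. Planar wavefronts make this
matrix effectively rank-2 (the x- and y-gradient directions), which is why
the first two components carry ≳ 90% of variance whenever activity is
wave-like rather than jitter-dominated.

## Detrended fluctuation analysis

The IBI series is partitioned into non-overlapping, left-anchored segments
of length n (trailing remainder discarded); each segment is cumulatively
summed and linearly detrended. Per-segment cumulative summation with
linear detrending is algebraically identical to the classic formulation
(integrate the whole mean-subtracted series, then detrend per segment):
the segment's starting offset and the global-mean ramp are absorbed by the
per-segment linear fit.

DF(n) combines the detrended residuals; two conventions exist and differ
only at small n, where the per-segment RMS distribution is skewed:

* **pooled** (default): DF(n) = RMS over all residuals of all segments —
  the classic fluctuation function;
* **segment_mean**: DF(n) = mean of per-segment RMS values.

α is the least-squares slope of log DF(n) vs log n over the grid
{4, 8, 16, 32, 64, 128} (factor configurable, e.g. √2, recorded in the
result metadata). On this grid, linear detrending is known to bias the
smallest scales; measured on 512-sample series (means over 50 seeds), the
pooled convention yields α ≈ 0.53 for white noise and ≈ 1.47 for Brownian
noise, against theoretical values 0.5 and 1.5, while segment_mean drifts
further (≈ 0.55 for white noise). The pooled convention is the default for
that reason. A constant series detrends to exactly zero residuals and
raises a degenerate-series error. Scaling the series by c > 0 scales every
DF(n) by c and leaves α unchanged.

## Stretch/release epoch analysis

Motor stages emit a pulse on a dedicated channel while they move; edges
(half-amplitude threshold) give motor start/end stamps, labelled
stretch/release alternately from the first movement (protocols begin with
a stretch). Per intervention, IBR bins are re-integrated on a grid
anchored at motor start, normalised to the mean rate over [−5, 0) s, and
averaged across repeats. Bins not fully covered by beats are missing
(NaN), not zero — a pause spanning the baseline window would otherwise
bias the normalisation — and repeats with no usable baseline are excluded
with a record. The **peak** is the bin ending at the first bin edge at or
after motor end: bin [1.5, 2.0) s for a ~2-s movement (conventionally
plotted at 1.75 s), bin [1.0, 1.5) s for a 1.5-s biaxial movement; whether
to use the bin value or an instantaneous reading at that instant is a
convention, and the bin value is used. Across preparations, mean peak
fold-changes are summarised by median/IQR and tested against 1 with the
Shapiro–Wilk-gated one-sample t / Wilcoxon choice.

Areal strain is 100·((1+εₓₓ)(1+ε_yy)−1): 5% for 5% uniaxial strain with
the orthogonal in-plane constriction compensated, 4.04% for 2% equibiaxial
strain. Under incompressibility the same figure, negated, is the
out-of-plane constriction, which is why release — a transient z-stretch —
can itself perturb beat rate.

## Statistics

Normality of (differences of) samples is assessed by Shapiro–Wilk at
0.05; normal data use Student's t (paired or one-sample), otherwise the
Wilcoxon signed rank test. All tests are two-tailed. The Wilcoxon p-value
uses the large-sample normal approximation
z = (W⁺ − n(n+1)/4)/√(n(n+1)(2n+1)/24) with mid-ranks and *no* continuity
correction — with correction, 25 all-positive differences give
p = 1.30 × 10⁻⁵ instead of the expected 1.23 × 10⁻⁵. Exact ties with the
null are dropped (standard signed-rank convention). The approximation is
coarse at very small n: against exact enumeration at n = 8 the worst-case
gap is ≈ 0.07 in the mid-range of p (≤ 0.03 where p < 0.05); use it for
n ≳ 10.

Spearman's ρ is the Pearson correlation of mid-ranks. The accompanying
density map counts pairs in 0.2 × 0.2 quantile rectangles (rank/n
quantiles, boundary points to the lower rectangle, ties sharing a
quantile) divided by the count expected under independence, n·0.04;
its 0.04-weighted mean is 1 by construction.

## The simulator

The generator produces recordings with the statistical structure the
analysis assumes, plus full ground truth, so the pipeline can be validated
in closed loop.

**Clock model.** Each of n_foci pacemaker foci on the boundary of the
8-mm disc carries a phase clock with instantaneous period
Tₖ = base_period · scaleₖ · exp(noiseₖ); at every cycle the focus reaching
threshold first fires the beat and resets all clocks. This
winner-resets-all rule is the simplest caricature of mutual entrainment —
the network follows its fastest oscillator — and reproduces the observed
behaviour: the firing site switches when the leading focus drifts slow,
and because (under temporally persistent noise) a crossing of two period
traces happens at an elevated period, switch beats coincide with longer
IBIs. This is the mechanism behind the positive IBI/slowness-difference
correlation, and it vanishes when takeover is disabled (single active
focus — emulating the reduced spatial complexity seen when active force
generation is blocked pharmacologically). A consequence of min-of-k
sampling is that the network rate slightly exceeds the intrinsic rate
(≈ +4% for three foci at noise SD 0.1); rate-recovery guarantees are
stated for one or two foci.

**Noise.** Per-focus log-period noise is synthesised spectrally:
Hermitian-symmetric complex-Gaussian Fourier coefficients with power
spectral density ∝ 1/f^β, β = 2α − 1, inverse-transformed and standardised
— giving exact control of the target DFA exponent α (recovered within
±0.1 for α ∈ [0.3, 1.6] at series length 512). Foci noises are
independent by default; a common-mode fraction is configurable (0 by
default — nothing is known about cross-focus correlation). Defaults
α = 1.0, SD = 0.1 yield IBI series with measured DFA exponents ≈ 0.9–1.0
and visible takeover dynamics at 2–3 foci.

**Defaults and what they emulate.** 12 electrodes on a 2-mm-pitch 4×4
grid with corners removed (all inside the 8-mm disc; exact published
coordinates are not tabulated, so the layout is overridable by file);
base period 0.8 s; conduction 30 cm/s; sampling 10 kHz; activation jitter
0.5 ms SD. The biphasic template is two opposed Gaussian lobes (positive
1.0 ms, negative 1.8 ms FWHM) separated by a 0.4-ms downstroke, placed so
the steepest downstroke of the continuous waveform falls exactly at each
true activation time; lobes are kept short relative to the 3-ms AC time
constant so that conditioning shifts detected times by well under one
sample, which is what makes the noise-free round trip (every activation
recovered within 0.1 ms) achievable by the stated pipeline rather than by
construction. White noise floor (SD 0.02 of unit amplitude), optional
sinusoidal drift and optional 12-bit quantisation (off by default — tests
are cleaner in continuous amplitude) complete the signal model.

**Stretch protocol.** Strain is applied for 60 s and released for 120 s,
4–5 times, with 2-s (uniaxial) or 1.5-s (biaxial) motor movements flagged
on a pulse channel. All foci rates are multiplied by a gain g(t) ramping
linearly to its target during the movement and decaying exponentially
afterwards (τ = 2 s, so the transient dissipates within ~8 s); the gain is
evaluated at the interval midpoint (fixed-point iteration) so the clock
tracks g(t) without a one-beat lag. Default gains 2.0 (stretch) and 1.4
(release) mirror the magnitudes of reported responses; the measured epoch
peak is necessarily the *bin average* of the ramp (≈ 1.875 for gain 2 over
a 2-s ramp with 0.5-s bins), not the raw gain. Stretch modulation is
uniform across foci — a global rate effect with no focal localisation.

**What the simulator does not capture.** No biophysical membrane model
(ion currents, Ca²⁺-clock dynamics), no mechanical substrate model, no
curved wavefronts or conduction heterogeneity (propagation is radial at
constant speed), no electrode dropout or drifting contact quality, and no
fractionation except where templates overlap. Passing round-trip tests
therefore demonstrate the correctness of the *analysis* under the stated
signal model; they do not validate detection against the full morphology
diversity of real recordings, whose curated event sets an automated
threshold will not exactly replicate.

## Numerical conventions and degenerate inputs

* OLS fits use `numpy.linalg.lstsq`; rank-deficient (collinear) electrode
  subsets and < 4 points raise errors rather than returning pseudoinverse
  artefacts.
* Fewer than 2 beats → no rate defined (error); constant IBI series →
  degenerate DFA (error); constant input series → undefined correlation
  (error); all values at the null → degenerate test (error).
* Filters use edge replication; derivative edges use one-sided
  differences; detections within half a kernel of trace ends are dropped.
* Beat clustering breaks exact time ties by electrode id, making it
  invariant to input ordering.
* All simulation randomness flows from a single integer seed through
  `numpy.random.default_rng`; reports are JSON with sorted keys, so a
  fixed seed and config reproduce byte-identical output.

## Problem sizes used in the test suite

Test and calibration runs are sized for a laptop-class single core: DFA
calibration uses 50 series of length 512; PCA dimensionality uses 300
simulated beats; the correlation contrast uses a 720-s two-focus
simulation (~950 beats); the full-length detection round trip uses one
15-min recording at 10 kHz; the conservation property uses 1000 random
beat series. These sizes leave the statistical conclusions
seed-insensitive at the stated tolerances.
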