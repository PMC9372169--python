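# Methods

This note documents the model behind `isarestore`, the numerical choices
made where the design was genuinely open, what the synthetic signals do and
do not emulate, and the package's known limitations. Every number quoted
here is computed by the test suite or by `scripts/acceptance.py`; nothing is
asserted that the code does not itself reproduce.

## Model and assumptions

The recording chain is treated as a causal, linear, time-invariant (LTI)
system. The recorded output is the discrete convolution of the input with
the system's unit impulse response (UIR), so the input is recovered by
deconvolution. Two assumptions follow:

- **Linearity.** Amplifier saturation (clipping) breaks the model; the
  forward simulator can emulate clipping precisely so tests can probe what
  the inverse filter does *not* fix. Recordings suspected of saturation
  should not be inverse-filtered blindly.
- **Time invariance.** The UIR is a property of the hardware, valid until
  the hardware changes; it is characterized once per machine and reused.

The method is deliberately non-parametric: the UIR comes from a measured
step response, not from assumed filter topology or nominal RC values, so it
applies to any system whose step or calibration response can be recorded.

## UIR estimation

The measured step (or the average of three onset-aligned, baseline-
subtracted rising-edge responses of a calibration square wave) is fitted
with a polynomial of order 9 by least squares. The fit is performed on a
centred, unit-scaled time axis: a raw-axis 9th-order Vandermonde system
over thousands of samples is numerically singular, while the normalized fit
is well conditioned; the derivative is mapped back through the chain rule.
The fit window runs from the detected onset to 1.2× the time at which the
response settles within 1% of baseline (windowing is not standardized
anywhere; this choice keeps the polynomial from wasting degrees of freedom
on the settled tail). The residual RMS of the fit is stored with the model.

For *discrete* deconvolution the UIR must carry the onset discontinuity of
the step response, which a smooth polynomial derivative alone would miss.
With `p` the fitted response and onset at `t0`:

```
h[0] = rate · p(t0)                      (the jump from zero baseline)
h[n] = rate · (p(t_n) − p(t_{n−1}))      (n ≥ 1)
```

The interior samples are the exact interval averages of the analytic
polynomial derivative (for the 0.1 Hz first-order chain they match
−(1/τ)·e^(−t/τ) within 2%), and `cumsum(h)/rate` reproduces the fitted step
response sample-for-sample — the property that makes the round trip
(convolve the recovered input by `h`, get the recording back) exact up to
fit error. `h[0]` dominates for any high-pass-dominated system, which is
precisely the regime in which recursive inversion by `h` is stable.

A scalar `norm` calibrates the overall gain: deconvolving the system's own
(fitted) step response must yield a flat plateau at the height of the
response's onset jump. Units are arbitrary throughout, so gain is
referenced to what the system itself reports for a step; a known physical
step amplitude can be supplied to pin absolute units. Characterization ends
with a self-check — deconvolve the averaged measured step and require the
recovered plateau's |slope| below 1% of its level per second — which fails
loudly rather than returning a bad UIR.

**Onset detection** locates edges by clusters of sample-to-sample jumps
exceeding half the largest observed jump, then refines each onset by linear
interpolation of the local 50% crossing. A global-threshold detector fails
on high-pass-recorded square waves (the decay after each edge re-approaches
the global midline without being a step); the jump-cluster detector does
not. Monte-Carlo tests place detected onsets within 2 samples of truth at
SNR 100 over 100 seeds.

## Deconvolution

Time-domain recursive inverse filtering (`lfilter([1], h, y)`) — forward
substitution on the lower-triangular Toeplitz system `y = T(h)·x`, the same
arithmetic as polynomial long division. Equivalence with an explicit
triangular solve is enforced to 1e−8 relative over random dominant-lead
systems up to n = 256. The full input-length reconstruction is returned:
its first `len(y) − len(h) + 1` samples coincide with the long-division
quotient, and unlike a truncated quotient it stays valid to the last
sample, which matters for spectra and for wavelet overlays. All arithmetic
is double precision — the drift described next grows from rounding and
model error, and reduced precision would inflate it.

A frequency-domain route with Tikhonov regularization
(`deconvolve_frequency`) exists for UIRs whose leading sample does not
dominate; it is explicitly non-default (implicit periodicity makes its
epoch edges less faithful).

**Truncation horizon.** The UIR is stored over its fit window (≈ 8.8 s for
the 0.1 Hz chain at the 1% settling rule). The tiny truncated tail means
recovered DC levels sag very slowly over horizons much longer than the
window (≈ 4% over 45 s in the step self-test); plateau *shape* and
step *contrast* are unaffected, and the drift filter removes the common-mode
component. Applications needing longer DC holds can widen the fit window.

## Drift removal and the minimum-length rule

Deconvolving a zero-meaned finite epoch introduces a slow, roughly
triangular drift with fundamental frequency `1/(2·epoch length)`: the
zero-mean step leaves a small DC residue, and an impulse response with
near-zero DC gain maps a constant onto a ramp. The reconstruction is
therefore high-pass filtered at 0.005 Hz (2nd-order Butterworth). Two
choices here were open:

- **Zero-phase application** (forward–backward). A causal drift filter
  would re-introduce exactly the kind of phase distortion the deconvolution
  just removed; `drift_zero_phase=False` is available for strict-causality
  workflows.
- **Reflect padding on the cutoff's own timescale** (up to 3 periods,
  capped at the signal length). The library default of a few samples of
  padding leaves large edge transients when the cutoff period (200 s) dwarfs
  the default pad.

Epochs must span at least `min_periods` (default 3) periods of the lowest
frequency of interest — 600 s for 0.005 Hz — so the deconvolution drift
cannot masquerade as ISA; shorter inputs raise an error naming the required
duration unless forced, and every run logs the predicted drift frequency
for its epoch length so users can recognize the artifact if they override.

Long recordings can be processed as overlapping chunks that are
inverse-filtered independently and cross-faded linearly; the overlap must
cover at least three UIR durations so chunk-edge transients stay out of the
blend. Interior agreement with whole-signal processing is held to 5% RMS in
tests.

## Validation metrics

Amplitude/phase spectra are computed on mean-removed, Hann-windowed epochs
with amplitude correction (a sine of amplitude A peaks at A); Hann
windowing controls leakage from finite epochs, which matters most a few
bins from DC where the ISA components live. Phases are reported only at
bins above 1% of the spectral maximum — empty bins carry numerical-noise
phases. Fidelity is summarized as six Pearson correlations (input vs
recorded and input vs reconstruction, for time series, amplitude spectrum,
phase spectrum). Phase correlations use *wrapped* phases at above-floor
bins: unwrapping over non-contiguous bins converts small deviations into
spurious 2π branch disagreements (circular correlation would be the formal
alternative; plain Pearson is kept for interpretability).

Time-frequency analysis uses an amplitude-calibrated complex Morlet wavelet
(default 6 cycles; 5 are used in the seizure band-power examples to keep
the edge cone inside a 600 s epoch at 0.03 Hz), truncated at ±4σ, with the
per-frequency cone of edge influence reported on every scalogram. Band
power integrates the scalogram over a frequency band (default: the ISA band
below 0.1 Hz) per time sample; its frequency grid is log-spaced and its
lower edge is raised to `n_cycles/duration`, the slowest wavelet that fits
the epoch.

## Synthetic signals and the forward model

The forward model applies causal (single-pass) digital filters initialized
at steady state for the pre-signal baseline — real amplifiers are causal,
and the measured phase distortion of the recording process is part of what
the method must undo, so simulating it zero-phase would be circular. The
default chain is a single first-order RC high-pass at 0.1 Hz (the AC input
stage); gain, hard clipping and seeded Gaussian noise are optional. SNR is
defined as the linear variance ratio of signal to added noise, with noise
added to the *recorded* signal (the measurement is what is noisy).

Generators cover the standard validation set: step, double step (a
DC-shift stand-in), step + 10 Hz sine, the 8-component mixed sine
(0.01–10 Hz), a square calibration wave (with a default half-period zero
baseline so all rising edges are observable transitions), and a surrogate
seizure. The surrogate combines a smoothly ramped sustained DC shift
beginning just before onset, an 8 Hz ictal burst, a post-ictal biphasic
slow wave (Gaussian-derivative shape, standing in for spreading
depolarization), and a white-noise floor; default amplitudes (shift 40,
burst 20, slow wave 30, noise SD 2, arbitrary units) give the shift the
dominant-but-not-overwhelming prominence seen in DC-coupled ictal
recordings. It is a waveform-level surrogate only: it makes no biophysical
claim, contains no 1/f background, no electrode drift, and no artifacts.
Passing tests on it therefore demonstrate that the *pipeline* restores
known sub-0.1 Hz structure through a known chain — not that every clinical
recording will be artifact-free or that the hardware is exactly first-order.

Problem sizes in the test suite and acceptance script — 60 s double-steps,
600 s mixed-sine/seizure epochs at 1000 samples/s, correlation analysis of
noisy reconstructions at the 256 samples/s analysis rate, 20 noise seeds
per SNR level — are the package's chosen desk-scale study conditions; the
600 s epochs are the shortest consistent with the minimum-length rule at
the 0.005 Hz drift cutoff.

## Known limitations

- One UIR per amplifier model; hardware changes require re-characterization.
- Clipped (saturated) segments violate LTI and are not recoverable.
- The inverse filter amplifies whatever occupies the attenuated band,
  artifacts included; reconstructions need artifact screening.
- Recovered absolute DC levels sag over horizons ≫ the UIR window (see
  truncation horizon above).
- EDF storage is 16-bit; the writer warns when a channel's dynamic range
  makes the quantization step exceed 1% of its standard deviation.
  Processing is float64 throughout.
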