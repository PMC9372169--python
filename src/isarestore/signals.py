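"""Synthetic test-signal generators.

Every validation of the inverse filter runs against signals with a known
ground truth: steps (DC shifts), a step with a 10 Hz oscillation riding on
top, a mixed sine spanning 0.01-10 Hz, a square calibration wave, and a
surrogate seizure with a pre-ictal DC shift and post-ictal spreading-
depolarization-like slow wave.  Generators are pure functions of their
arguments; any randomness is drawn from an explicit seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import DomainError, TimeSeries

__all__ = [
    "NoiseSpec",
    "MIXED_SINE_FREQS_HZ",
    "make_step",
    "make_double_step",
    "make_step_with_sine",
    "make_mixed_sine",
    "make_square_calibration",
    "add_noise",
    "SurrogateSeizure",
    "make_surrogate_seizure",
]

#: Frequencies (Hz) of the standard mixed-sine validation signal.
MIXED_SINE_FREQS_HZ = (0.01, 0.05, 0.07, 0.15, 0.2, 1.0, 6.0, 10.0)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise at a given signal-to-noise ratio.

    ``snr_linear`` is the ratio of signal variance to noise variance
    (``math.inf`` disables the noise entirely).
    """

    snr_linear: float = math.inf
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.snr_linear > 0:
            raise DomainError("snr_linear must be > 0")


def _grid(rate: float, duration_s: float) -> np.ndarray:
    n = int(round(duration_s * rate))
    if n < 1:
        raise DomainError("duration too short for one sample")
    return np.arange(n) / rate


def make_step(rate: float, duration_s: float, step_time_s: float,
              amplitude: float = 1.0, baseline: float = 0.0,
              label: str = "step") -> TimeSeries:
    """Step of height *amplitude* on *baseline*, switching at *step_time_s*.

    Samples at times ``t >= step_time_s`` take the value
    ``baseline + amplitude``.
    """
    if not 0 <= step_time_s < duration_s:
        raise DomainError(f"step_time_s={step_time_s} must lie in [0, {duration_s})")
    t = _grid(rate, duration_s)
    x = np.full(t.size, float(baseline))
    x[t >= step_time_s - 1e-12] += amplitude
    return TimeSeries(x, rate, label=label)


def make_double_step(rate: float, duration_s: float, on1: float, off1: float,
                     on2: float, off2: float, amplitude: float = 1.0,
                     label: str = "double_step") -> TimeSeries:
    """Two rectangular pulses of height *amplitude* on a zero baseline.

    The pulses occupy the half-open intervals ``[on1, off1)`` and
    ``[on2, off2)``; degenerate (zero-width) pulses are allowed, overlapping
    ones are not.
    """
    if not (0 <= on1 <= off1 <= on2 <= off2 <= duration_s):
        raise DomainError("pulse times must satisfy 0 <= on1 <= off1 <= on2 <= off2 <= duration")
    t = _grid(rate, duration_s)
    x = np.zeros(t.size)
    eps = 1e-12
    x[(t >= on1 - eps) & (t < off1 - eps)] = amplitude
    x[(t >= on2 - eps) & (t < off2 - eps)] = amplitude
    return TimeSeries(x, rate, label=label)


def make_step_with_sine(rate: float, duration_s: float, step_time_s: float,
                        amplitude: float = 1.0, baseline: float = 0.0,
                        sine_freq_hz: float = 10.0, sine_amp: float = 0.25,
                        label: str = "step_sine") -> TimeSeries:
    """A sine oscillation riding on top of a step (default 10 Hz)."""
    if not sine_freq_hz < rate / 2:
        raise DomainError("sine frequency must be below Nyquist")
    step = make_step(rate, duration_s, step_time_s, amplitude, baseline, label=label)
    t = step.times
    return step.with_samples(step.samples + sine_amp * np.sin(2 * np.pi * sine_freq_hz * t))


def make_mixed_sine(rate: float, duration_s: float,
                    freqs_hz=MIXED_SINE_FREQS_HZ, amps=None, phases_rad=None,
                    label: str = "mixed_sine") -> TimeSeries:
    """Sum of sines; defaults to the standard 8-component validation signal.

    The default frequencies are 0.01, 0.05, 0.07, 0.15, 0.2, 1, 6 and 10 Hz
    with unit amplitudes and zero phases.  For the infraslow components to be
    resolvable the duration should cover at least three periods of the lowest
    frequency (see :func:`isarestore.invfilter.min_length_for`).
    """
    f = np.asarray(freqs_hz, dtype=float)
    a = np.ones_like(f) if amps is None else np.asarray(amps, dtype=float)
    p = np.zeros_like(f) if phases_rad is None else np.asarray(phases_rad, dtype=float)
    if not (f.shape == a.shape == p.shape):
        raise DomainError("freqs, amps and phases must have equal lengths")
    if np.any(f >= rate / 2):
        raise DomainError("all frequencies must be below Nyquist")
    t = _grid(rate, duration_s)
    x = np.zeros(t.size)
    for fk, ak, pk in zip(f, a, p):
        x += ak * np.sin(2 * np.pi * fk * t + pk)
    return TimeSeries(x, rate, label=label)


def make_square_calibration(rate: float, period_s: float, amplitude: float = 1.0,
                            n_cycles: int = 3, baseline_s: float | None = None,
                            label: str = "calibration") -> TimeSeries:
    """50% duty-cycle square calibration wave with levels 0 / *amplitude*.

    Each cycle is high for the first half-period then low.  A flat zero
    baseline of ``baseline_s`` seconds (default half a period) precedes the
    first cycle so that every one of the ``n_cycles`` rising edges — the
    first included — is an observable transition for onset detection and for
    a causally simulated recording chain.  Pass ``baseline_s=0`` for a bare
    square wave starting high.
    """
    if n_cycles < 1:
        raise DomainError("n_cycles must be >= 1")
    if not period_s > 0:
        raise DomainError("period_s must be > 0")
    if baseline_s is None:
        baseline_s = period_s / 2
    n_base = int(round(baseline_s * rate))
    t = _grid(rate, n_cycles * period_s)
    phase = np.mod(t, period_s)
    wave = np.where(phase < period_s / 2 - 1e-12, amplitude, 0.0)
    x = np.concatenate([np.zeros(n_base), wave])
    return TimeSeries(x, rate, label=label)


def add_noise(ts: TimeSeries, noise: NoiseSpec) -> TimeSeries:
    """Add Gaussian noise with variance ``var(ts) / snr_linear``.

    Deterministic for a given seed; an infinite SNR returns an identical
    copy.  A zero-variance signal has no defined SNR and is rejected.
    """
    if math.isinf(noise.snr_linear):
        return ts.with_samples(ts.samples.copy())
    var = float(np.var(ts.samples))
    if var == 0.0:
        raise DomainError("cannot scale noise to a zero-variance signal with finite SNR")
    rng = np.random.default_rng(noise.seed)
    sigma = math.sqrt(var / noise.snr_linear)
    return ts.with_samples(ts.samples + rng.normal(0.0, sigma, ts.samples.size))


@dataclass(frozen=True)
class SurrogateSeizure:
    """A surrogate ictal recording plus its separable ground-truth parts.

    ``signal`` is the sum of the component series, which are exposed so that
    reconstruction tests can compare against the known DC shift.
    """

    signal: TimeSeries
    dc_shift: TimeSeries
    oscillation: TimeSeries
    sd_wave: TimeSeries
    noise: TimeSeries
    onset_s: float
    offset_s: float


def make_surrogate_seizure(rate: float, duration_s: float, onset_s: float,
                           offset_s: float, dc_shift_amp: float = 40.0,
                           osc_freq_hz: float = 8.0, osc_amp: float = 20.0,
                           sd_wave_amp: float = 30.0, sd_wave_tau_s: float = 20.0,
                           noise_std: float = 2.0, seed: int = 0,
                           label: str = "surrogate_seizure") -> SurrogateSeizure:
    """Surrogate of a DC-coupled seizure recording.

    Emulates the qualitative structure of an ictal trace recorded with a DC
    amplifier: a sustained negative DC shift ramping up just before seizure
    onset and released after offset, an oscillatory ictal burst between onset
    and offset, a slow biphasic wave after offset standing in for spreading
    depolarization, and a white Gaussian noise floor.  It makes no
    biophysical claim; it exists so the sub-0.1 Hz content a high-pass
    recording chain removes is known exactly.
    """
    if not (0 < onset_s < offset_s < duration_s):
        raise DomainError("require 0 < onset_s < offset_s < duration_s")
    t = _grid(rate, duration_s)
    ramp = max(onset_s / 20.0, 2.0)  # DC shift develops over a few seconds

    def smoothstep(t0: float) -> np.ndarray:
        return 0.5 * (1 + np.tanh((t - t0) / (ramp / 2)))

    # sustained negative shift: engages just before onset, releases at offset
    dc = -dc_shift_amp * smoothstep(onset_s - ramp) * (1 - smoothstep(offset_s + ramp))

    # ictal oscillatory burst with a smooth (Tukey-like) envelope
    env = smoothstep(onset_s) * (1 - smoothstep(offset_s))
    rng = np.random.default_rng(seed)
    osc = osc_amp * env * np.sin(2 * np.pi * osc_freq_hz * t + rng.uniform(0, 2 * np.pi))

    # post-ictal slow biphasic wave (Gaussian-derivative shape)
    tp = t - (offset_s + sd_wave_tau_s)
    sd = np.where(
        t >= offset_s,
        -sd_wave_amp * (tp / sd_wave_tau_s) * np.exp(0.5 - 0.5 * (tp / sd_wave_tau_s) ** 2),
        0.0,
    )

    noise = rng.normal(0.0, noise_std, t.size) if noise_std > 0 else np.zeros(t.size)

    mk = lambda x, lab: TimeSeries(x, rate, label=lab)
    total = mk(dc + osc + sd + noise, label)
    return SurrogateSeizure(
        signal=total,
        dc_shift=mk(dc, "dc_shift"),
        oscillation=mk(osc, "oscillation"),
        sd_wave=mk(sd, "sd_wave"),
        noise=mk(noise, "noise"),
        onset_s=onset_s,
        offset_s=offset_s,
    )
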