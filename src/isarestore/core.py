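"""Shared domain types and elementary signal arithmetic.

The package works on uniformly sampled, real-valued time series in arbitrary
units (clinical EEG amplitudes are carried through unchanged; no unit
conversion is attempted).  Sample ``i`` of a series lives at time
``t0 + i / rate`` seconds and epochs are half-open ``[start, end)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy import signal as _sig

__all__ = [
    "TimeSeries",
    "FilterSpec",
    "Spectrum",
    "Scalogram",
    "zero_mean",
    "downsample",
    "design_sos",
    "DomainError",
]


class DomainError(ValueError):
    """A precondition on a signal-processing operation was violated."""


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled real-valued signal.

    Parameters
    ----------
    samples : array-like of float
        Signal values in arbitrary units.
    rate : float
        Sampling frequency in samples/s, > 0.
    label : str
        Free-text channel name (e.g. ``"RHD4"``).
    t0 : float
        Time of the first sample in seconds (default 0).
    """

    samples: np.ndarray
    rate: float
    label: str = ""
    t0: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=np.float64)
        if arr.ndim != 1 or arr.size < 1:
            raise DomainError("samples must be a 1-D sequence of length >= 1")
        if not np.all(np.isfinite(arr)):
            raise DomainError("samples must all be finite")
        if not (self.rate > 0 and math.isfinite(self.rate)):
            raise DomainError(f"rate must be positive and finite, got {self.rate}")
        object.__setattr__(self, "samples", arr)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Signal duration in seconds (length / rate)."""
        return self.samples.size / self.rate

    @property
    def times(self) -> np.ndarray:
        """Time of every sample in seconds."""
        return self.t0 + np.arange(self.samples.size) / self.rate

    def with_samples(self, samples: np.ndarray, *, rate: float | None = None,
                     t0: float | None = None) -> "TimeSeries":
        """Copy of this series with new sample values (and optionally rate/t0)."""
        return replace(
            self,
            samples=np.asarray(samples, dtype=np.float64),
            rate=self.rate if rate is None else rate,
            t0=self.t0 if t0 is None else t0,
        )


_FILTER_KINDS = ("butterworth_highpass", "first_order_rc_highpass", "allpass")


@dataclass(frozen=True)
class FilterSpec:
    """Parametric description of a one-sided frequency-selective filter.

    ``first_order_rc_highpass`` is the single-pole RC (capacitive input)
    stage of an AC-coupled amplifier; its magnitude response coincides with a
    first-order Butterworth high-pass.  ``cutoff_hz`` is ignored for
    ``allpass``.
    """

    kind: str
    order: int = 1
    cutoff_hz: float = 0.1
    zero_phase: bool = False

    def __post_init__(self) -> None:
        if self.kind not in _FILTER_KINDS:
            raise DomainError(f"unknown filter kind {self.kind!r}; expected one of {_FILTER_KINDS}")
        if self.kind == "first_order_rc_highpass" and self.order != 1:
            raise DomainError("first_order_rc_highpass must have order 1")
        if self.order < 1:
            raise DomainError("order must be a positive integer")
        if self.kind != "allpass" and not self.cutoff_hz > 0:
            raise DomainError("cutoff_hz must be > 0")


def design_sos(spec: FilterSpec, rate: float) -> np.ndarray | None:
    """Second-order-section coefficients for *spec* at sampling rate *rate*.

    Returns ``None`` for an allpass spec (no filtering required).
    Raises :class:`DomainError` when the cutoff is at or above Nyquist.
    """
    if spec.kind == "allpass":
        return None
    if not spec.cutoff_hz < rate / 2:
        raise DomainError(
            f"cutoff {spec.cutoff_hz} Hz must be below Nyquist ({rate / 2} Hz)"
        )
    return _sig.butter(spec.order, spec.cutoff_hz, btype="highpass", fs=rate, output="sos")


@dataclass(frozen=True)
class Spectrum:
    """Single-sided frequency-domain representation.

    ``amplitude`` is calibrated so a pure sine of amplitude A yields a peak of
    about A at its bin.  ``phase_rad`` lies in (-pi, pi]; bins whose amplitude
    falls below a reporting floor may carry NaN phase.
    """

    freqs_hz: np.ndarray
    amplitude: np.ndarray
    phase_rad: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs_hz, dtype=np.float64)
        a = np.asarray(self.amplitude, dtype=np.float64)
        p = np.asarray(self.phase_rad, dtype=np.float64)
        if not (f.shape == a.shape == p.shape):
            raise DomainError("freqs, amplitude and phase must have equal length")
        if f.size and (np.any(np.diff(f) <= 0) or f[0] < 0):
            raise DomainError("freqs_hz must be increasing and nonnegative")
        if np.any(a < 0):
            raise DomainError("amplitude must be nonnegative")
        object.__setattr__(self, "freqs_hz", f)
        object.__setattr__(self, "amplitude", a)
        object.__setattr__(self, "phase_rad", p)


@dataclass(frozen=True)
class Scalogram:
    """Wavelet power as a function of time and frequency.

    ``power`` has shape (n_freqs, n_times).  ``cone_s`` gives, per frequency,
    the half-length of the analysing wavelet in seconds; samples closer than
    this to either edge sit inside the edge cone and should not be
    interpreted.
    """

    times_s: np.ndarray
    freqs_hz: np.ndarray
    power: np.ndarray
    cone_s: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=np.float64)
        f = np.asarray(self.freqs_hz, dtype=np.float64)
        p = np.asarray(self.power, dtype=np.float64)
        if p.shape != (f.size, t.size):
            raise DomainError(f"power shape {p.shape} must be (n_freqs, n_times) = ({f.size}, {t.size})")
        if np.any(p < 0):
            raise DomainError("power must be nonnegative")
        cone = self.cone_s
        cone = np.zeros(f.size) if cone is None else np.asarray(cone, dtype=np.float64)
        if cone.shape != f.shape:
            raise DomainError("cone_s must have one entry per frequency")
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "freqs_hz", f)
        object.__setattr__(self, "power", p)
        object.__setattr__(self, "cone_s", cone)

    def interior_mask(self) -> np.ndarray:
        """Boolean (n_freqs, n_times) mask of samples outside the edge cone."""
        t = self.times_s
        lo, hi = t[0], t[-1]
        return (t[None, :] >= lo + self.cone_s[:, None]) & (t[None, :] <= hi - self.cone_s[:, None])


def zero_mean(ts: TimeSeries) -> TimeSeries:
    """Subtract the mean of the signal (required before deconvolution)."""
    return ts.with_samples(ts.samples - ts.samples.mean())


def downsample(ts: TimeSeries, target_rate: float) -> TimeSeries:
    """Resample *ts* to a lower rate with polyphase anti-alias filtering.

    Rational rate ratios are handled by up/down polyphase resampling.  The
    anti-alias FIR is zero-phase, so sub-Nyquist content keeps both its
    amplitude (within ~1%) and its phase.

    Raises
    ------
    DomainError
        If ``target_rate > ts.rate`` (upsampling is not supported).
    """
    if not target_rate > 0:
        raise DomainError("target_rate must be > 0")
    if target_rate > ts.rate * (1 + 1e-12):
        raise DomainError(
            f"upsampling not supported: target {target_rate} > source {ts.rate} samples/s"
        )
    frac = Fraction(target_rate / ts.rate).limit_denominator(10_000)
    if frac == 1:
        return ts.with_samples(ts.samples.copy())
    up, down = frac.numerator, frac.denominator
    out = _sig.resample_poly(ts.samples, up, down, padtype="line")
    return ts.with_samples(out, rate=ts.rate * up / down)
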