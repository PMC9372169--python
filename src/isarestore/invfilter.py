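"""The deconvolution-based inverse filter.

Recovering the input ``x`` of an LTI recording chain from its output ``y``
amounts to deconvolving ``y`` by the system's unit impulse response.  The
deconvolution is performed in the time domain as recursive inverse filtering
by ``h`` (forward substitution on the lower-triangular Toeplitz system
``y = T(h) x`` — the same arithmetic as polynomial long division), which is
stable whenever ``h[0]`` dominates, as it does for high-pass-dominated
systems.

Deconvolution of finite epochs introduces a slow triangular drift whose
fundamental frequency is ``1 / (2 * epoch length)``: the zero-meaned output
retains a small DC residue, and a near-zero-DC-gain impulse response maps a
constant onto a ramp.  The drift is removed after deconvolution with a
2nd-order high-pass Butterworth filter at 0.005 Hz, applied zero-phase so
the phase relationships the deconvolution restores are not re-broken.  To
keep this drift distinguishable from genuine infraslow activity, epochs must
span at least three periods of the lowest frequency of interest (600 s for
0.005 Hz).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

from .core import DomainError, FilterSpec, TimeSeries, design_sos, zero_mean
from .uir import UIRModel

__all__ = [
    "InverseFilterConfig",
    "UnstableUirError",
    "RateMismatchError",
    "TooShortError",
    "deconvolve",
    "deconvolve_frequency",
    "drift_frequency",
    "min_length_for",
    "remove_drift",
    "inverse_filter",
    "chunked_inverse_filter",
]

logger = logging.getLogger(__name__)


class UnstableUirError(DomainError):
    """UIR cannot drive a stable long division (leading sample is zero)."""


class RateMismatchError(DomainError):
    """UIR and signal sampling rates differ and resampling is disabled."""


class TooShortError(DomainError):
    """Signal is shorter than the minimum-length rule allows."""

    def __init__(self, msg: str, required_s: float):
        super().__init__(msg)
        self.required_s = required_s


@dataclass(frozen=True)
class InverseFilterConfig:
    """Tunables of the inverse-filter pipeline.

    ``drift_cutoff_hz``/``drift_order`` parameterize the post-deconvolution
    drift-removal high-pass (defaults 0.005 Hz, order 2); it doubles as the
    lowest frequency of interest for the minimum-length rule with
    ``min_periods`` periods (default 3).  Chunked operation cuts the signal
    into ``chunk_len_s`` windows overlapping by ``chunk_overlap_s``.
    """

    drift_cutoff_hz: float = 0.005
    drift_order: int = 2
    drift_zero_phase: bool = True
    min_periods: int = 3
    chunk_len_s: float | None = None
    chunk_overlap_s: float | None = None

    def __post_init__(self) -> None:
        if not self.drift_cutoff_hz > 0:
            raise DomainError("drift_cutoff_hz must be > 0")
        if self.min_periods < 1:
            raise DomainError("min_periods must be >= 1")
        if self.chunk_len_s is not None and self.chunk_overlap_s is not None:
            if not self.chunk_overlap_s < self.chunk_len_s:
                raise DomainError("chunk overlap must be smaller than chunk length")


def drift_frequency(epoch_length_s: float) -> float:
    """Fundamental frequency (Hz) of the deconvolution drift: 1 / (2 * epoch)."""
    if not epoch_length_s > 0:
        raise DomainError("epoch length must be > 0")
    return 1.0 / (2.0 * epoch_length_s)


def min_length_for(f_low_hz: float, min_periods: int = 3) -> float:
    """Minimum epoch length (s) to analyse frequencies down to *f_low_hz*.

    Three periods of the lowest frequency of interest by default; e.g.
    600 s for 0.005 Hz.
    """
    if not f_low_hz > 0:
        raise DomainError("f_low_hz must be > 0")
    return min_periods / f_low_hz


def _prepare_uir(y: TimeSeries, uir: UIRModel, resample_uir: bool) -> UIRModel:
    if not np.isclose(uir.rate, y.rate, rtol=1e-9):
        if not resample_uir:
            raise RateMismatchError(
                f"UIR rate {uir.rate} != signal rate {y.rate} and resampling is disabled"
            )
        uir = uir.resampled(y.rate)
    if uir.h[0] == 0.0 or uir.degenerate:
        raise UnstableUirError("uir.h[0] is (near) zero; long division would be unstable")
    if uir.h.size >= len(y):
        raise DomainError("UIR must be shorter than the signal being deconvolved")
    return uir


def deconvolve(y: TimeSeries, uir: UIRModel, resample_uir: bool = True) -> TimeSeries:
    """Deconvolve the recorded signal *y* by *uir* (time-domain long division).

    Returns ``x`` scaled by ``uir.norm`` such that ``conv(x / norm, h)``
    reproduces ``y.samples`` over the full epoch.  The reconstruction is
    computed by recursive inverse filtering, whose first
    ``len(y) - len(h) + 1`` samples coincide with the polynomial
    long-division quotient; unlike a truncated quotient it remains valid to
    the last sample.  *y* should be zero-meaned first (see
    :func:`isarestore.core.zero_mean`); the caller owns that step so the
    subtracted constant can be tracked.
    """
    uir = _prepare_uir(y, uir, resample_uir)
    x = _sig.lfilter([1.0], uir.h, y.samples) * uir.norm
    return y.with_samples(x)


def deconvolve_frequency(y: TimeSeries, uir: UIRModel, reg: float = 1e-6,
                         resample_uir: bool = True) -> TimeSeries:
    """Frequency-domain deconvolution with Tikhonov regularization.

    Non-default alternative for ill-conditioned UIRs:
    ``X = Y conj(H) / (|H|^2 + reg * max|H|^2)``.  Implicitly periodic, so
    edges are less faithful than the time-domain route; prefer
    :func:`deconvolve` unless the long division is unstable.
    """
    uir = _prepare_uir(y, uir, resample_uir)
    n = len(y)
    H = np.fft.rfft(uir.h / uir.rate, n)
    Y = np.fft.rfft(y.samples)
    lam = reg * float(np.max(np.abs(H)) ** 2)
    X = Y * np.conj(H) / (np.abs(H) ** 2 + lam)
    x = np.fft.irfft(X, n) * uir.norm / uir.rate
    return y.with_samples(x)


def remove_drift(ts: TimeSeries, config: InverseFilterConfig = InverseFilterConfig()) -> TimeSeries:
    """High-pass the deconvolution drift out of a reconstructed signal.

    2nd-order Butterworth at 0.005 Hz by default, zero-phase
    (forward-backward) so the reconstruction's restored phase spectrum is
    preserved.  A signal shorter than three periods of the cutoff triggers a
    warning (the filter cannot settle within the epoch).
    """
    if not ts.rate > 2 * config.drift_cutoff_hz:
        raise DomainError("sampling rate must exceed twice the drift cutoff")
    warm_up = 3.0 / config.drift_cutoff_hz
    if ts.duration < warm_up:
        warnings.warn(
            f"signal ({ts.duration:.6g} s) is shorter than the drift filter warm-up "
            f"({warm_up:.6g} s); drift removal below {config.drift_cutoff_hz} Hz is partial",
            stacklevel=2,
        )
    spec = FilterSpec("butterworth_highpass", config.drift_order, config.drift_cutoff_hz,
                      zero_phase=config.drift_zero_phase)
    sos = design_sos(spec, ts.rate)
    if config.drift_zero_phase:
        # reflect-pad on the scale of the cutoff period: the default pad of a
        # few samples leaves large edge transients at infraslow cutoffs
        padlen = min(len(ts) - 1, int(3 * ts.rate / config.drift_cutoff_hz))
        x = _sig.sosfiltfilt(sos, ts.samples, padlen=padlen)
    else:
        zi = _sig.sosfilt_zi(sos) * ts.samples[0]
        x, _ = _sig.sosfilt(sos, ts.samples, zi=zi)
    return ts.with_samples(x)


def inverse_filter(y: TimeSeries, uir: UIRModel,
                   config: InverseFilterConfig = InverseFilterConfig(),
                   f_low_hz: float | None = None, force: bool = False) -> TimeSeries:
    """Full pipeline: zero-mean, deconvolve by the UIR, remove drift.

    ``f_low_hz`` (default: the drift cutoff) sets the lowest frequency of
    interest for the minimum-length guard; a too-short epoch raises
    :class:`TooShortError` naming the required duration unless ``force``.
    """
    f_low = config.drift_cutoff_hz if f_low_hz is None else f_low_hz
    required = min_length_for(f_low, config.min_periods)
    if y.duration < required and not force:
        raise TooShortError(
            f"epoch of {y.duration:.6g} s is shorter than the {required:.6g} s required "
            f"to analyse frequencies down to {f_low:.6g} Hz "
            f"({config.min_periods} periods); pass force=True to override",
            required,
        )
    logger.info(
        "inverse_filter: uir(source=%s, rate=%g, taps=%d) epoch=%.6gs "
        "predicted drift frequency=%.6g Hz drift cutoff=%g Hz",
        uir.source, uir.rate, uir.h.size, y.duration,
        drift_frequency(y.duration), config.drift_cutoff_hz,
    )
    x = deconvolve(zero_mean(y), uir)
    return remove_drift(x, config)


def chunked_inverse_filter(y: TimeSeries, uir: UIRModel,
                           config: InverseFilterConfig,
                           f_low_hz: float | None = None,
                           force: bool = False) -> TimeSeries:
    """Inverse-filter long recordings in overlapping chunks.

    Each ``chunk_len_s`` window is inverse-filtered independently and the
    results are cross-faded (linear ramp) across the ``chunk_overlap_s``
    overlap.  Chunks must still satisfy the minimum-length rule, and the
    overlap must cover at least three UIR durations so edge transients stay
    out of the blend.  A chunk length covering the whole signal reduces to
    :func:`inverse_filter` exactly.
    """
    if config.chunk_len_s is None or config.chunk_overlap_s is None:
        raise DomainError("chunked operation requires chunk_len_s and chunk_overlap_s")
    if not config.chunk_overlap_s > 0:
        raise DomainError("chunk overlap must be positive (non-overlapping chunks are not supported)")
    chunk_n = int(round(config.chunk_len_s * y.rate))
    overlap_n = int(round(config.chunk_overlap_s * y.rate))
    if overlap_n >= chunk_n:
        raise DomainError("chunk overlap must be smaller than chunk length")
    uir_r = uir.resampled(y.rate) if not np.isclose(uir.rate, y.rate) else uir
    if config.chunk_overlap_s < 3 * uir_r.duration:
        raise DomainError(
            f"chunk overlap ({config.chunk_overlap_s:.6g} s) must span at least three "
            f"UIR durations ({3 * uir_r.duration:.6g} s)"
        )
    n = len(y)
    if chunk_n >= n:
        return inverse_filter(y, uir, config, f_low_hz=f_low_hz, force=force)

    step = chunk_n - overlap_n
    starts = list(range(0, max(n - chunk_n, 0) + 1, step))
    if starts[-1] + chunk_n < n:
        starts.append(n - chunk_n)

    out = np.zeros(n)
    weight = np.zeros(n)
    for s in starts:
        seg = TimeSeries(y.samples[s:s + chunk_n], y.rate, label=y.label,
                         t0=y.t0 + s / y.rate)
        rec = inverse_filter(seg, uir_r, config, f_low_hz=f_low_hz, force=force)
        w = np.ones(chunk_n)
        ramp = np.linspace(0.0, 1.0, overlap_n)
        if s > 0:
            w[:overlap_n] = ramp
        if s + chunk_n < n:
            w[-overlap_n:] = np.minimum(w[-overlap_n:], ramp[::-1])
        out[s:s + chunk_n] += rec.samples * w
        weight[s:s + chunk_n] += w
    weight[weight == 0] = 1.0
    return y.with_samples(out / weight)
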