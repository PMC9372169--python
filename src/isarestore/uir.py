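"""Unit-impulse-response characterization from a measured step response.

The UIR of an LTI recording system is the derivative of its step response.
The workflow mirrors the bench procedure for a clinical EEG machine:

1. record the system's response to a step (or to its built-in square-wave
   calibration signal, which is a series of steps),
2. detect the step onsets and average the aligned, baseline-subtracted
   responses,
3. fit the averaged response with a polynomial (9th order by default) on a
   normalized time axis,
4. differentiate the fit analytically to obtain the UIR.

For discrete deconvolution the UIR must also carry the onset discontinuity
of the step response — the sharp initial transient visible as the dominant
first sample ``h[0]``.  Here ``h[0] = rate * p(t0)`` (the jump from the zero
pre-step baseline to the fitted response) and, for n >= 1,
``h[n] = rate * (p(t_n) - p(t_{n-1}))``: the exact average of the analytic
polynomial derivative over each sample interval, so that
``cumsum(h) / rate`` reproduces the fitted step response sample-for-sample.

The method is non-parametric: nothing about the system's internal filter
topology is assumed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import signal as _sig

from .core import DomainError, TimeSeries

__all__ = [
    "StepResponseFit",
    "UIRModel",
    "OnsetError",
    "InsufficientStepsError",
    "UirValidationError",
    "detect_step_onsets",
    "extract_and_average_steps",
    "fit_step_response",
    "differentiate_fit",
    "characterize_uir",
    "save_uir",
    "load_uir",
]


class OnsetError(DomainError):
    """No step transition could be located in the signal."""


class InsufficientStepsError(DomainError):
    """Fewer usable step onsets than requested for averaging."""


class UirValidationError(DomainError):
    """The round-trip self-check of a characterized UIR failed."""

    def __init__(self, msg: str, flatness: float):
        super().__init__(msg)
        self.flatness = flatness


@dataclass(frozen=True)
class StepResponseFit:
    """Polynomial model of a step response on a normalized time axis.

    The model is ``p(u)`` with ``u = (t - t_shift) / t_scale`` evaluated with
    ascending coefficients ``coeffs``; normalization keeps the high-order
    Vandermonde system well conditioned.  ``fit_window_s`` is relative to the
    step onset (onset at 0).
    """

    coeffs: np.ndarray
    t_shift: float
    t_scale: float
    fit_window_s: tuple[float, float]
    order: int
    residual_rms: float
    rate: float

    def __post_init__(self) -> None:
        c = np.asarray(self.coeffs, dtype=np.float64)
        object.__setattr__(self, "coeffs", c)
        if self.order < 0 or c.size != self.order + 1:
            raise DomainError("coeffs must have order + 1 entries")
        if not np.isfinite(self.residual_rms):
            raise DomainError("residual_rms must be finite")
        if not self.fit_window_s[0] >= 0:
            raise DomainError("fit window must start at or after the onset")

    def __call__(self, t) -> np.ndarray:
        u = (np.asarray(t, dtype=float) - self.t_shift) / self.t_scale
        return np.polynomial.polynomial.polyval(u, self.coeffs)

    def derivative_coeffs(self) -> np.ndarray:
        """Ascending coefficients of dp/du on the normalized axis."""
        return np.polynomial.polynomial.polyder(self.coeffs)

    def derivative(self, t) -> np.ndarray:
        """Analytic dp/dt (chain rule through the time normalization)."""
        u = (np.asarray(t, dtype=float) - self.t_shift) / self.t_scale
        return np.polynomial.polynomial.polyval(u, self.derivative_coeffs()) / self.t_scale


@dataclass(frozen=True)
class UIRModel:
    """Discrete unit impulse response of a recording system.

    ``h`` carries continuous-derivative units except for the first sample,
    which encodes the step-onset discontinuity (``h[0] = rate * step(t0)``);
    ``norm`` rescales a raw long-division quotient so that deconvolving the
    system's own step response yields a plateau at the calibrating input
    amplitude.
    """

    h: np.ndarray
    rate: float
    norm: float
    source: str = "measured_step"

    def __post_init__(self) -> None:
        h = np.asarray(self.h, dtype=np.float64)
        if h.ndim != 1 or h.size < 1:
            raise DomainError("h must be a nonempty 1-D array")
        object.__setattr__(self, "h", h)
        if self.source not in ("measured_step", "calibration_square", "analytic"):
            raise DomainError(f"unknown UIR source {self.source!r}")

    @property
    def duration(self) -> float:
        return self.h.size / self.rate

    @property
    def degenerate(self) -> bool:
        """True when the leading sample is too small for stable inversion."""
        scale = max(float(np.max(np.abs(self.h))), 1e-30)
        return abs(self.h[0]) <= 1e-9 * max(scale, self.rate)

    def step_response(self) -> np.ndarray:
        """The step response implied by h (its running integral)."""
        return np.cumsum(self.h) / self.rate

    def trimmed(self, rel_tol: float = 1e-6) -> "UIRModel":
        """Drop trailing samples below ``rel_tol * max|h|`` to shorten deconvolution."""
        thr = rel_tol * np.max(np.abs(self.h))
        keep = np.nonzero(np.abs(self.h) > thr)[0]
        n = int(keep[-1]) + 1 if keep.size else 1
        return replace(self, h=self.h[:n].copy())

    def resampled(self, new_rate: float) -> "UIRModel":
        """UIR re-expressed at a different sampling rate.

        Works through the implied step response: past the onset jump the
        step response is smooth and slow, so it is interpolated (cubic) onto
        the new grid and re-differenced, which rebuilds the onset
        discontinuity crisply.  An anti-alias decimation filter would smear
        the onset over several samples and bias the deconvolution gain.
        """
        if np.isclose(new_rate, self.rate):
            return self
        from scipy.interpolate import CubicSpline

        s = self.step_response()
        t_old = np.arange(s.size) / self.rate
        n_new = max(int(round(s.size / self.rate * new_rate)), 2)
        t_new = np.arange(n_new) / new_rate
        s2 = CubicSpline(t_old, s)(np.clip(t_new, 0.0, t_old[-1]))
        h2 = np.empty(n_new)
        h2[0] = new_rate * s2[0]
        h2[1:] = new_rate * np.diff(s2)
        return replace(self, h=h2, rate=new_rate, norm=self.norm * new_rate / self.rate)


def detect_step_onsets(ts: TimeSeries, polarity: str = "rising",
                       min_separation_s: float = 0.0) -> list[float]:
    """Times where the signal crosses 50% of its step height.

    Steps are located by their sample-to-sample jumps (clusters of
    differences exceeding half the largest observed jump, of the requested
    polarity), which is robust both for clean steps and for the bipolar
    transients of a high-pass-recorded square wave, where the slow post-edge
    decay re-approaches the global 50% level without ever being a step.
    Each edge is then refined locally: the crossing of the midpoint between
    the pre- and post-edge levels is linearly interpolated.
    """
    if polarity not in ("rising", "falling"):
        raise DomainError("polarity must be 'rising' or 'falling'")
    x = ts.samples
    if float(x.max() - x.min()) <= 0:
        raise OnsetError("signal has no amplitude range; no step present")
    sign = 1.0 if polarity == "rising" else -1.0
    d = sign * np.diff(x)
    if d.max() <= 0:
        raise OnsetError(f"no {polarity} transition found")
    big = np.nonzero(d > 0.5 * d.max())[0]

    # group consecutive above-threshold jumps into one edge each
    clusters: list[tuple[int, int]] = []
    start = prev = int(big[0])
    for i in big[1:]:
        if i == prev + 1:
            prev = int(i)
        else:
            clusters.append((start, prev))
            start = prev = int(i)
    clusters.append((start, prev))

    onsets: list[float] = []
    last = -np.inf
    for i0, i1 in clusters:
        pre = float(np.median(x[max(i0 - 5, 0):i0 + 1]))
        post = float(np.median(x[i1 + 1:min(i1 + 6, x.size)]))
        level = 0.5 * (pre + post)
        t_cross = None
        for i in range(i0, i1 + 1):
            if sign * (x[i] - level) < 0 <= sign * (x[i + 1] - level):
                frac = (level - x[i]) / (x[i + 1] - x[i])
                t_cross = ts.t0 + (i + frac) / ts.rate
                break
        if t_cross is None:  # monotone jump past the level within one sample
            t_cross = ts.t0 + (i0 + 0.5) / ts.rate
        if t_cross - last >= min_separation_s:
            onsets.append(float(t_cross))
            last = t_cross
    if not onsets:
        raise OnsetError("no 50% crossing of the requested polarity found")
    return onsets


def extract_and_average_steps(ts: TimeSeries, onsets: list[float], pre_s: float,
                              post_s: float, n_average: int = 3) -> TimeSeries:
    """Onset-aligned average of step responses, baseline subtracted.

    Takes the first ``n_average`` onsets whose window
    ``[onset - pre_s, onset + post_s)`` lies fully inside the recording,
    averages the aligned segments and subtracts the pre-onset mean of the
    average.  The result's ``t0`` is ``-pre_s`` (onset at time 0).
    """
    if n_average < 1:
        raise DomainError("n_average must be >= 1")
    n_pre = int(round(pre_s * ts.rate))
    n_post = int(round(post_s * ts.rate))
    if n_post < 1:
        raise DomainError("post_s must cover at least one sample")
    segs = []
    for onset in onsets:
        # first sample at/after the interpolated crossing time
        i0 = int(math.ceil((onset - ts.t0) * ts.rate - 1e-9))
        if i0 - n_pre >= 0 and i0 + n_post <= len(ts):
            segs.append(ts.samples[i0 - n_pre:i0 + n_post])
        if len(segs) == n_average:
            break
    if len(segs) < n_average:
        raise InsufficientStepsError(
            f"need {n_average} fully contained step segments, found {len(segs)}"
        )
    avg = np.mean(segs, axis=0)
    if n_pre > 0:
        avg = avg - avg[:n_pre].mean()
    return TimeSeries(avg, ts.rate, label=f"{ts.label}:step_avg", t0=-pre_s)


def fit_step_response(step: TimeSeries, order: int = 9,
                      fit_window_s: tuple[float, float] | None = None) -> StepResponseFit:
    """Least-squares polynomial fit of a (baseline-subtracted) step response.

    *step* should have its onset at time 0 (as produced by
    :func:`extract_and_average_steps`).  The fit is performed on a centred,
    unit-scaled time axis; a raw-axis 9th-order fit over many seconds would
    be numerically singular.  The window defaults to everything from the
    onset to the end of the segment and must contain at least
    ``10 * (order + 1)`` samples.
    """
    if fit_window_s is None:
        fit_window_s = (0.0, step.t0 + step.duration)
    w0, w1 = fit_window_s
    if not (0 <= w0 < w1):
        raise DomainError("fit window must satisfy 0 <= start < end (relative to onset)")
    t = step.times
    mask = (t >= w0 - 1e-12) & (t < w1 - 1e-12)
    tt, yy = t[mask], step.samples[mask]
    if tt.size < 10 * (order + 1):
        raise DomainError(
            f"fit window holds {tt.size} samples; need >= {10 * (order + 1)} for order {order}"
        )
    t_shift = float(tt.mean())
    t_scale = float(max(tt.max() - t_shift, 1e-12))
    u = (tt - t_shift) / t_scale
    coeffs = np.polynomial.polynomial.polyfit(u, yy, deg=order)
    resid = np.polynomial.polynomial.polyval(u, coeffs) - yy
    return StepResponseFit(
        coeffs=coeffs, t_shift=t_shift, t_scale=t_scale,
        fit_window_s=(float(w0), float(tt[-1] + 1 / step.rate)),
        order=order, residual_rms=float(np.sqrt(np.mean(resid ** 2))), rate=step.rate,
    )


def differentiate_fit(fit: StepResponseFit, source: str = "measured_step",
                      amplitude: float = 1.0) -> UIRModel:
    """UIR from the analytic derivative of a step-response fit.

    The interior samples are the interval-averaged analytic derivative of
    the polynomial; the first sample carries the onset discontinuity (see
    module docstring).  ``norm`` is calibrated so that deconvolving the
    fitted step response itself recovers a flat plateau at *amplitude* — the
    nominal height of the calibrating input step.
    """
    w0, w1 = fit.fit_window_s
    n = max(int(round((w1 - w0) * fit.rate)), 1)
    t = w0 + np.arange(n) / fit.rate
    p = fit(t)
    h = np.empty(n)
    h[0] = fit.rate * p[0]
    if n > 1:
        h[1:] = fit.rate * np.diff(p)
    uir = UIRModel(h=h, rate=fit.rate, norm=1.0, source=source)
    if uir.degenerate:
        return uir  # flagged degenerate; norm meaningless
    # raw long division of the fitted step by h; plateau sets the gain
    q = _sig.lfilter([1.0], h, p)
    tail = q[n // 4:]
    plateau = float(np.median(tail)) if tail.size else float(q[-1])
    if plateau == 0.0:
        return uir
    return replace(uir, norm=amplitude / plateau)


def _settling_end(step: TimeSeries, frac: float = 0.01) -> float:
    """Time (s, onset-relative) after which |response| stays below frac * peak."""
    t = step.times
    post = t >= 0
    x = np.abs(step.samples[post])
    peak = x.max()
    above = np.nonzero(x > frac * peak)[0]
    if above.size == 0:
        return t[post][-1] + 1 / step.rate
    end_idx = min(above[-1] + 1, x.size - 1)
    return float(t[post][end_idx] + 1 / step.rate)


def characterize_uir(ts: TimeSeries, mode: str = "measured_step", order: int = 9,
                     n_average: int = 3, pre_s: float | None = None,
                     fit_window_s: tuple[float, float] | None = None,
                     flatness_threshold: float = 0.01,
                     amplitude: float | None = None) -> UIRModel:
    """Full characterization: detect -> extract/average -> fit -> differentiate.

    ``mode='measured_step'`` expects a recording containing one (or more)
    step responses and averages as many as are available (up to
    ``n_average``); ``mode='calibration_square'`` expects a square-wave
    calibration recording and averages ``n_average`` rising-edge responses
    (three by default).  The calibrating step height defaults to the fitted
    response's onset jump (units are arbitrary, so the gain is referenced
    to what the system itself reports for a step); pass ``amplitude`` to
    pin it to a known input amplitude instead.

    A round-trip self-check deconvolves the averaged measured step by the
    candidate UIR; the recovered input must be a flat plateau, with fitted
    |slope| below ``flatness_threshold`` (fraction of the plateau amplitude
    per second).  Failure raises :class:`UirValidationError` carrying the
    measured flatness.
    """
    if mode not in ("measured_step", "calibration_square"):
        raise DomainError(f"unknown characterization mode {mode!r}")
    min_sep = 1.0 / ts.rate * 10
    onsets = detect_step_onsets(ts, "rising", min_separation_s=min_sep)

    if mode == "calibration_square":
        if len(onsets) < n_average:
            raise InsufficientStepsError(
                f"calibration recording holds {len(onsets)} rising edges; need {n_average}"
            )
        period = float(np.min(np.diff(onsets))) if len(onsets) > 1 else ts.duration
        post_s = 0.49 * period  # stop before the falling edge hits
        navg = n_average
    else:
        navg = min(n_average, len(onsets))
        nxt = np.diff(onsets + [ts.t0 + ts.duration])
        post_s = float(np.min(nxt)) * 0.98
    if pre_s is None:
        pre_s = min(1.0, 0.2 * post_s)
        pre_s = max(pre_s, 2.0 / ts.rate)

    avg = extract_and_average_steps(ts, onsets, pre_s, post_s, n_average=navg)

    if fit_window_s is None:
        fit_window_s = (0.0, min(_settling_end(avg) * 1.2, avg.t0 + avg.duration))
    fit = fit_step_response(avg, order=order, fit_window_s=fit_window_s)

    if amplitude is None:
        amplitude = float(fit(fit.fit_window_s[0]))
    uir = differentiate_fit(fit, source=mode, amplitude=amplitude)
    if uir.degenerate:
        return uir

    # self-check: deconvolve the averaged measured step; demand a flat plateau
    i_on = int(round(-avg.t0 * avg.rate))
    n_h = uir.h.size
    rec = _sig.lfilter([1.0], uir.h, avg.samples[i_on:i_on + n_h]) * uir.norm
    k0 = max(int(0.1 * rec.size), 1)
    seg = rec[k0:]
    tseg = np.arange(seg.size) / avg.rate
    slope = float(np.polyfit(tseg, seg, 1)[0]) if seg.size > 2 else 0.0
    level = float(np.median(seg))
    flatness = abs(slope) / max(abs(level), 1e-30)
    if flatness > flatness_threshold:
        raise UirValidationError(
            f"UIR self-check failed: plateau slope {flatness:.3g}/s exceeds "
            f"threshold {flatness_threshold:.3g}/s", flatness,
        )
    return uir


def save_uir(uir: UIRModel, path: str | Path) -> None:
    """Serialize a UIR to a small self-describing JSON file."""
    payload = {
        "format": "isarestore-uir-v1",
        "source": uir.source,
        "rate": uir.rate,
        "norm": uir.norm,
        "h": uir.h.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_uir(path: str | Path) -> UIRModel:
    """Load a UIR saved by :func:`save_uir`."""
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "isarestore-uir-v1":
        raise DomainError(f"{path} is not an isarestore UIR file")
    return UIRModel(h=np.asarray(payload["h"], dtype=float), rate=float(payload["rate"]),
                    norm=float(payload["norm"]), source=payload["source"])
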