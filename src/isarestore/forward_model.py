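"""Simulated AC-coupled acquisition chain.

An EEG recording system is modelled as a causal LTI chain — typically the
0.1 Hz high-pass input stage of an AC amplifier — followed by a gain,
optional hard clipping (amplifier saturation) and optional additive noise.
The chain produces "recorded outputs" from known inputs so the inverse
filter can be validated without hardware.  It is a test scaffold, not a
claim about any particular instrument: the inverse filter itself never sees
these parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

from .core import DomainError, FilterSpec, TimeSeries, design_sos
from .signals import NoiseSpec, add_noise

__all__ = ["RecordingChain", "default_chain", "simulate_recording", "analytic_attenuation"]


@dataclass(frozen=True)
class RecordingChain:
    """Ordered causal filter chain with gain, clipping and noise.

    Filters are applied single-pass (causally) in order, emulating real-time
    hardware; zero-phase specs are rejected because hardware cannot look
    ahead.  ``clip_range`` models amplifier saturation as hard limits.
    """

    filters: tuple[FilterSpec, ...] = ()
    gain: float = 1.0
    clip_range: tuple[float, float] | None = None
    noise: NoiseSpec | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "filters", tuple(self.filters))
        for f in self.filters:
            if f.zero_phase:
                raise DomainError("hardware chain filters must be causal (zero_phase=False)")
        if self.clip_range is not None:
            lo, hi = self.clip_range
            if not lo < hi:
                raise DomainError("clip_range must satisfy lo < hi")

    @property
    def is_linear(self) -> bool:
        return self.clip_range is None and self.noise is None


def default_chain(cutoff_hz: float = 0.1) -> RecordingChain:
    """The default fixture chain: one first-order RC high-pass (0.1 Hz)."""
    return RecordingChain(filters=(FilterSpec("first_order_rc_highpass", 1, cutoff_hz),))


def simulate_recording(ts: TimeSeries, chain: RecordingChain) -> TimeSeries:
    """Pass *ts* through the chain; the result is the "recorded output".

    Each filter is initialized at its steady state for the first sample's
    value, so a signal that starts on a flat baseline produces no artificial
    start-up transient.  Output has the same rate and length as the input.
    """
    x = ts.samples.copy()
    for spec in chain.filters:
        sos = design_sos(spec, ts.rate)
        if sos is None:
            continue
        zi = _sig.sosfilt_zi(sos) * x[0]
        x, _ = _sig.sosfilt(sos, x, zi=zi)
    x = chain.gain * x
    if chain.clip_range is not None:
        x = np.clip(x, *chain.clip_range)
    out = ts.with_samples(x)
    if chain.noise is not None:
        out = add_noise(out, chain.noise)
    return out


def analytic_attenuation(spec: FilterSpec, f_hz: float) -> float:
    """Closed-form magnitude |H(f)| of the parametric filter, in [0, 1].

    High-pass (Butterworth of order n, or the order-1 RC stage):
    ``|H(f)| = 1 / sqrt(1 + (fc / f)**(2 n))``; zero at f = 0.  Allpass
    returns 1 at every frequency.
    """
    if f_hz < 0:
        raise DomainError("frequency must be >= 0")
    if spec.kind == "allpass":
        return 1.0
    if f_hz == 0.0:
        return 0.0
    return 1.0 / np.sqrt(1.0 + (spec.cutoff_hz / f_hz) ** (2 * spec.order))
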