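"""File I/O: EDF and two-column text signals, plus run configuration.

EDF (European Data Format) is the clinical interchange format the pipeline
targets; signals are stored as 16-bit integers with per-channel physical
scaling, in fixed-duration data records, under a fixed-width ASCII header.
The reader and writer here cover plain EDF (no EDF+ annotations are
written; an EDF+ annotation channel on read is skipped) and preserve
per-channel sampling rates.  Because EDF quantizes to 16 bits, a warning is
emitted on write when the quantization step is visible against the signal's
own scale; processing always happens at float64 internally.

The text format is two full-precision columns (time_s, value) for
inspection and for feeding external tools.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import asdict, dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
import yaml

from .core import DomainError, TimeSeries
from .invfilter import InverseFilterConfig

__all__ = [
    "FormatError",
    "MissingChannelError",
    "read_edf",
    "write_edf",
    "read_text",
    "write_text",
    "RunConfig",
]


class FormatError(DomainError):
    """File contents do not conform to the expected format."""


class MissingChannelError(KeyError):
    """A requested channel label is absent from the file."""


def _ascii_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise FormatError(f"field {s!r} exceeds EDF width {width}")
    return s.ljust(width).encode("ascii")


def _fmt_float(x: float, width: int = 8) -> str:
    """Format a float into EDF's 8-char ASCII numeric fields."""
    for prec in range(7, -1, -1):
        s = f"{x:.{prec}g}"
        if len(s) <= width and "inf" not in s and "nan" not in s:
            return s
    raise FormatError(f"cannot represent {x} in {width} ASCII characters")


def _record_duration(rates: list[float], max_record_s: int = 60) -> int:
    """Smallest integer record duration (s) giving whole samples per record."""
    for dur in range(1, max_record_s + 1):
        if all(abs(r * dur - round(r * dur)) < 1e-9 and 1 <= round(r * dur) <= 61440
               for r in rates):
            return dur
    raise FormatError(f"no EDF record duration <= {max_record_s} s holds an integer "
                      f"number of samples at rates {rates}")


def write_edf(path: str | Path, series: list[TimeSeries] | TimeSeries,
              patient: str = "X", recording: str = "isarestore",
              start: datetime | None = None) -> None:
    """Write one or more channels to a plain EDF file.

    Channels may have different sampling rates (each gets its own
    samples-per-record count) but must share a common record duration and
    total duration.  The last partial record, if any, is padded by holding
    each channel's final value; physical min/max are taken from the data.
    """
    if isinstance(series, TimeSeries):
        series = [series]
    if not series:
        raise DomainError("need at least one channel")
    rec_dur = _record_duration([ts.rate for ts in series])
    spr = [int(round(ts.rate * rec_dur)) for ts in series]
    n_records = max(math.ceil(len(ts) / s) for ts, s in zip(series, spr))

    dig_min, dig_max = -32768, 32767
    phys: list[tuple[float, float]] = []
    digital: list[np.ndarray] = []
    for ts, s in zip(series, spr):
        x = ts.samples
        pmin, pmax = float(x.min()), float(x.max())
        if pmax - pmin <= 0:
            pmin, pmax = pmin - 1.0, pmax + 1.0
        # the header stores limits as 8-char ASCII; scale against what the
        # reader will actually see, widened so no sample falls outside
        span = pmax - pmin
        pmin_h = float(_fmt_float(pmin))
        pmax_h = float(_fmt_float(pmax))
        step = max(span, abs(pmin), abs(pmax)) * 1e-4
        while pmin_h > pmin:
            pmin_h = float(_fmt_float(pmin_h - step))
        while pmax_h < pmax:
            pmax_h = float(_fmt_float(pmax_h + step))
        q = (pmax_h - pmin_h) / (dig_max - dig_min)
        sd = float(x.std())
        if sd > 0 and q > 0.01 * sd:
            warnings.warn(
                f"channel {ts.label!r}: EDF 16-bit quantization step ({q:.3g}) exceeds "
                f"1% of the signal's standard deviation; expect visible quantization",
                stacklevel=2,
            )
        pad = n_records * s - x.size
        if pad:
            x = np.concatenate([x, np.full(pad, x[-1])])
        d = np.round((x - pmin_h) / (pmax_h - pmin_h) * (dig_max - dig_min) + dig_min)
        digital.append(np.clip(d, dig_min, dig_max).astype("<i2"))
        phys.append((pmin_h, pmax_h))

    start = start or datetime(2000, 1, 1)
    ns = len(series)
    header = b"".join([
        _ascii_field("0", 8),
        _ascii_field(patient[:80], 80),
        _ascii_field(recording[:80], 80),
        _ascii_field(start.strftime("%d.%m.%y"), 8),
        _ascii_field(start.strftime("%H.%M.%S"), 8),
        _ascii_field(256 * (1 + ns), 8),
        _ascii_field("", 44),
        _ascii_field(n_records, 8),
        _ascii_field(_fmt_float(float(rec_dur)), 8),
        _ascii_field(ns, 4),
    ])
    sig_fields = []
    for ts, (pmin, pmax), s in zip(series, phys, spr):
        sig_fields.append([
            _ascii_field(ts.label[:16] or "ch", 16),
            _ascii_field("", 80),
            _ascii_field("au", 8),
            _ascii_field(_fmt_float(pmin), 8),
            _ascii_field(_fmt_float(pmax), 8),
            _ascii_field(dig_min, 8),
            _ascii_field(dig_max, 8),
            _ascii_field("", 80),
            _ascii_field(s, 8),
            _ascii_field("", 32),
        ])
    for col in range(10):
        header += b"".join(sf[col] for sf in sig_fields)

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            for d, s in zip(digital, spr):
                fh.write(d[r * s:(r + 1) * s].tobytes())


def read_edf(path: str | Path, channels: list[str] | None = None) -> list[TimeSeries]:
    """Read channels from an EDF/EDF+ file as float64 TimeSeries.

    Physical scaling from the header is applied; per-channel sampling rates
    are preserved.  ``channels=None`` returns every ordinary signal
    (annotation channels are skipped).  Requesting an absent label raises
    :class:`MissingChannelError` listing what is available.
    """
    raw = Path(path).read_bytes()
    if len(raw) < 256:
        raise FormatError(f"{path}: too short to hold an EDF header")
    try:
        n_records = int(raw[236:244].decode("ascii").strip())
        rec_dur = float(raw[244:252].decode("ascii").strip())
        ns = int(raw[252:256].decode("ascii").strip())
    except (UnicodeDecodeError, ValueError) as exc:
        raise FormatError(f"{path}: malformed EDF header ({exc})") from exc
    if ns < 1 or len(raw) < 256 * (1 + ns):
        raise FormatError(f"{path}: header truncated (ns={ns})")

    def sig_field(offset: int, width: int, idx: int) -> str:
        base = 256 + offset * ns + idx * width
        return raw[base:base + width].decode("ascii", "replace").strip()

    labels = [sig_field(0, 16, i) for i in range(ns)]
    pmin = [float(sig_field(16 + 80 + 8, 8, i)) for i in range(ns)]
    pmax = [float(sig_field(16 + 80 + 8 + 8, 8, i)) for i in range(ns)]
    dmin = [int(sig_field(16 + 80 + 8 + 16, 8, i)) for i in range(ns)]
    dmax = [int(sig_field(16 + 80 + 8 + 24, 8, i)) for i in range(ns)]
    spr = [int(sig_field(16 + 80 + 8 + 32 + 80, 8, i)) for i in range(ns)]

    data_start = 256 * (1 + ns)
    rec_len = sum(spr) * 2
    avail = (len(raw) - data_start) // rec_len if rec_len else 0
    if n_records < 0:  # -1 means "unknown" per the standard
        n_records = avail
    n_records = min(n_records, avail)

    keep = [i for i, lab in enumerate(labels) if not lab.startswith("EDF Annotations")]
    if channels is not None:
        available = [labels[i] for i in keep]
        missing = [c for c in channels if c not in available]
        if missing:
            raise MissingChannelError(
                f"channel(s) {missing} not in file; available: {available}"
            )
        keep = [i for i in keep if labels[i] in channels]

    out: list[TimeSeries] = []
    offsets = np.concatenate([[0], np.cumsum(spr)]) * 2
    for i in keep:
        chunks = []
        for r in range(n_records):
            base = data_start + r * rec_len + int(offsets[i])
            chunks.append(np.frombuffer(raw, dtype="<i2", count=spr[i], offset=base))
        dig = np.concatenate(chunks).astype(np.float64)
        scale = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
        out.append(TimeSeries(pmin[i] + (dig - dmin[i]) * scale,
                              rate=spr[i] / rec_dur, label=labels[i]))
    return out


def write_text(path: str | Path, ts: TimeSeries) -> None:
    """Write a signal as two full-precision columns: time_s, value."""
    data = np.column_stack([ts.times, ts.samples])
    np.savetxt(path, data, fmt="%.17g", delimiter="\t",
               header="time_s\tvalue", comments="# ")


def read_text(path: str | Path) -> TimeSeries:
    """Read a two-column (time_s, value) delimited text signal.

    The time column must be uniformly spaced within 1e-6 relative; the rate
    is inferred from the median spacing.
    """
    data = np.loadtxt(path, delimiter=None, comments="#", ndmin=2)
    if data.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (time_s, value)")
    t, x = data[:, 0], data[:, 1]
    if t.size < 2:
        return TimeSeries(x, rate=1.0, t0=float(t[0]) if t.size else 0.0,
                          label=Path(path).stem)
    dt = np.diff(t)
    med = float(np.median(dt))
    if med <= 0:
        raise FormatError(f"{path}: time column is not increasing")
    worst = float(np.max(np.abs(dt - med)))
    if worst > 1e-6 * med:
        i = int(np.argmax(np.abs(dt - med)))
        raise FormatError(
            f"{path}: non-uniform sampling; worst gap {dt[i]:.9g} s at row {i} "
            f"vs median {med:.9g} s"
        )
    return TimeSeries(x, rate=1.0 / med, t0=float(t[0]), label=Path(path).stem)


@dataclass
class RunConfig:
    """Configuration of one inverse-filter run (flags or YAML file).

    ``uir_file`` points at a saved UIR; alternatively ``characterize_from``
    + ``characterize_mode`` derive one from a step/calibration recording.
    """

    inputs: list[str] = field(default_factory=list)
    channels: list[str] | None = None
    uir_file: str | None = None
    characterize_from: str | None = None
    characterize_mode: str = "measured_step"
    drift_cutoff_hz: float = 0.005
    drift_order: int = 2
    drift_zero_phase: bool = True
    min_periods: int = 3
    chunk_len_s: float | None = None
    chunk_overlap_s: float | None = None
    output: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def inverse_filter_config(self) -> InverseFilterConfig:
        return InverseFilterConfig(
            drift_cutoff_hz=self.drift_cutoff_hz, drift_order=self.drift_order,
            drift_zero_phase=self.drift_zero_phase, min_periods=self.min_periods,
            chunk_len_s=self.chunk_len_s, chunk_overlap_s=self.chunk_overlap_s,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(payload) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)
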