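"""Time-series containers, lighting schedules, file I/O, and time-frame conversion.

The package works on three in-memory containers:

* :class:`ActivityTrace` — uniformly binned locomotor counts (wheel revolutions
  or infrared a.u.) with an absolute minute timebase.
* :class:`ImmobilityTrace` — per-second 0/1 immobility flags (1 Hz), the raw
  input to immobility-defined sleep scoring.
* :class:`LightSchedule` — a piecewise lighting protocol (LD, DD, skeleton
  photoperiod, extra light pulses) that defines the Zeitgeber-Time (ZT) frame.

Conventions
-----------
All absolute times are minutes from the start of the recording; the recording
starts at ZT0 (lights-on) of day 0 unless the schedule says otherwise.  Bins
are half-open ``[t, t + bin)`` and timestamps are bin starts.  Days run
ZT0 -> ZT24.  ZT0 = lights-on, ZT12 = lights-off; in constant darkness the ZT
frame is undefined and Circadian Time (CT) — anchored so that CT12 is the
regression-predicted activity onset — is used instead.

Files are a plain CSV dialect with ``# key: value`` comment headers::

    # kind: activity
    # start_min: 0
    # bin_min: 1
    # units: rev
    timestamp,value
    0,12
    1,0

Missing values are encoded as an empty field, excluded from means, and counted;
more than 10% missing in an analysis window triggers a warning.
"""

from __future__ import annotations

import io as _stdio
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "ActivityTrace",
    "ImmobilityTrace",
    "LightSchedule",
    "ScheduleSegment",
    "TraceFormatError",
    "read_trace",
    "write_trace",
    "to_zt",
    "to_ct",
    "fold_daily",
]

MIN_PER_DAY = 1440.0


class TraceFormatError(ValueError):
    """Malformed trace file (bad header, negative count, non-monotone time...)."""


# ---------------------------------------------------------------------------
# Light schedules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScheduleSegment:
    """One homogeneous stretch of the lighting protocol.

    ``zt0_min`` is the absolute minute of a reference lights-on; ZT for any
    time t inside the segment is ``((t - zt0_min)/60) mod 24``.  It is ``None``
    for constant darkness, where ZT is undefined.
    """

    start_min: float
    end_min: float
    kind: str                      # 'LD' | 'DD' | 'SPP'
    zt0_min: float | None
    light_hours: float = 12.0      # LD photoperiod length
    pulse_hours: float = 1.0       # SPP pulse length

    def contains(self, t_min: float) -> bool:
        return self.start_min <= t_min < self.end_min


@dataclass
class LightSchedule:
    """Piecewise lighting protocol covering a recording.

    ``pulses`` are extra light intervals (absolute minutes) layered on top of
    the segments — masking pulses at a fixed ZT, or phase-shifting pulses at a
    CT resolved per animal by the simulator.
    """

    segments: list[ScheduleSegment]
    pulses: list[tuple[float, float]] = field(default_factory=list)
    feeding_zt: tuple[float, float] | None = None

    @property
    def start_min(self) -> float:
        return self.segments[0].start_min

    @property
    def end_min(self) -> float:
        return self.segments[-1].end_min

    def segment_at(self, t_min: float) -> ScheduleSegment:
        for seg in self.segments:
            if seg.contains(t_min):
                return seg
        if self.segments and t_min == self.end_min:
            return self.segments[-1]
        raise ValueError(f"time {t_min} min outside schedule span "
                         f"[{self.start_min}, {self.end_min})")

    def is_light(self, t_min) -> np.ndarray | bool:
        """Lights on at time(s) ``t_min`` (absolute minutes); vectorized."""
        t = np.asarray(t_min, dtype=float)
        out = np.zeros(t.shape, dtype=bool)
        for seg in self.segments:
            in_seg = (t >= seg.start_min) & (t < seg.end_min)
            if not in_seg.any() or seg.zt0_min is None:
                continue
            zt = ((t - seg.zt0_min) / 60.0) % 24.0
            if seg.kind == "LD":
                out |= in_seg & (zt < seg.light_hours)
            elif seg.kind == "SPP":
                # dawn pulse at ZT0, dusk pulse ending at ZT12
                p = seg.pulse_hours
                out |= in_seg & ((zt < p) | ((zt >= 12.0 - p) & (zt < 12.0)))
        for a, b in self.pulses:
            out |= (t >= a) & (t < b)
        return out if out.shape else bool(out)

    def with_pulse(self, start_min: float, duration_min: float) -> "LightSchedule":
        return LightSchedule(
            segments=list(self.segments),
            pulses=self.pulses + [(start_min, start_min + duration_min)],
            feeding_zt=self.feeding_zt,
        )


# ---------------------------------------------------------------------------
# Traces
# ---------------------------------------------------------------------------

@dataclass
class ActivityTrace:
    """Uniformly binned activity counts with absolute minute timebase."""

    start_min: float
    bin_min: float
    counts: np.ndarray                      # float; NaN marks missing
    schedule: LightSchedule | None = None
    units: str = "rev"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.bin_min <= 0:
            raise ValueError("bin_min must be positive")
        finite = self.counts[np.isfinite(self.counts)]
        if (finite < 0).any():
            raise ValueError("activity counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def duration_min(self) -> float:
        return self.n_bins * self.bin_min

    @property
    def n_days(self) -> float:
        return self.duration_min / MIN_PER_DAY

    def timestamps(self) -> np.ndarray:
        return self.start_min + self.bin_min * np.arange(self.n_bins)

    def rebin(self, bin_min: float) -> "ActivityTrace":
        """Sum counts into coarser bins (``bin_min`` a multiple of the current)."""
        ratio = bin_min / self.bin_min
        if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
            raise ValueError("new bin width must be an integer multiple of the old")
        r = int(round(ratio))
        n = (self.n_bins // r) * r
        c = self.counts[:n].reshape(-1, r)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            summed = np.nansum(c, axis=1)
            summed[np.all(np.isnan(c), axis=1)] = np.nan
        return replace(self, bin_min=float(bin_min), counts=summed)

    def per_minute(self) -> "ActivityTrace":
        """Rates at 1-min resolution (counts spread evenly within a bin)."""
        if self.bin_min == 1.0:
            return self
        r = self.bin_min
        if abs(r - round(r)) > 1e-9:
            raise ValueError("bin width must be an integer number of minutes")
        per = np.repeat(self.counts / r, int(round(r)))
        return replace(self, bin_min=1.0, counts=per)


@dataclass
class ImmobilityTrace:
    """Per-second immobility flags (1 = immobile), sampled at 1 Hz."""

    start_min: float
    flags: np.ndarray
    schedule: LightSchedule | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags)
        vals = np.unique(self.flags[~np.isnan(np.asarray(self.flags, dtype=float))])
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("immobility flags must be binary 0/1")
        self.flags = self.flags.astype(np.uint8)

    @property
    def n_seconds(self) -> int:
        return len(self.flags)

    @property
    def n_days(self) -> float:
        return self.n_seconds / 86400.0


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

_REQUIRED_HEADER = ("kind", "start_min", "bin_min", "units")


def write_trace(trace: ActivityTrace | ImmobilityTrace, path) -> None:
    """Write a trace in the package CSV dialect (see module docstring)."""
    buf = _stdio.StringIO()
    if isinstance(trace, ActivityTrace):
        kind, bin_min, units = "activity", trace.bin_min, trace.units
        values = trace.counts
        fmt = lambda v: "" if np.isnan(v) else repr(float(v)) if v % 1 else str(int(v))
    else:
        kind, bin_min, units = "immobility", 1.0 / 60.0, "flag"
        values = trace.flags
        fmt = lambda v: str(int(v))
    buf.write(f"# kind: {kind}\n# start_min: {trace.start_min}\n")
    buf.write(f"# bin_min: {bin_min}\n# units: {units}\n")
    for key, val in sorted(trace.meta.items()):
        buf.write(f"# {key}: {val}\n")
    buf.write("timestamp,value\n")
    ts = trace.start_min + bin_min * np.arange(len(values))
    for t, v in zip(ts, values):
        t_str = repr(float(t)) if t % 1 else str(int(t))
        buf.write(f"{t_str},{fmt(v)}\n")
    Path(path).write_text(buf.getvalue())


def read_trace(path) -> ActivityTrace | ImmobilityTrace:
    """Read a trace written by :func:`write_trace`; bit-exact round trip.

    Malformed rows are rejected with their line number; required header keys
    are ``kind``, ``start_min``, ``bin_min``, ``units``.
    """
    header: dict[str, str] = {}
    times: list[float] = []
    values: list[float] = []
    lines = Path(path).read_text().splitlines()
    data_started = False
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if line.startswith("#"):
            if data_started:
                raise TraceFormatError(f"line {lineno}: header after data")
            body = line.lstrip("#").strip()
            if ":" not in body:
                raise TraceFormatError(f"line {lineno}: malformed header {line!r}")
            key, _, val = body.partition(":")
            header[key.strip()] = val.strip()
            continue
        if line.strip() == "timestamp,value":
            data_started = True
            continue
        if not data_started:
            raise TraceFormatError(f"line {lineno}: expected 'timestamp,value' row")
        parts = line.split(",")
        if len(parts) != 2:
            raise TraceFormatError(f"line {lineno}: expected 2 fields, got {len(parts)}")
        try:
            t = float(parts[0])
        except ValueError:
            raise TraceFormatError(f"line {lineno}: bad timestamp {parts[0]!r}") from None
        v_raw = parts[1].strip()
        if v_raw == "":
            v = np.nan
        else:
            try:
                v = float(v_raw)
            except ValueError:
                raise TraceFormatError(f"line {lineno}: bad value {v_raw!r}") from None
            if v < 0:
                raise TraceFormatError(f"line {lineno}: negative count {v_raw}")
        if times and t <= times[-1]:
            raise TraceFormatError(f"line {lineno}: non-monotone timestamp {t}")
        times.append(t)
        values.append(v)

    missing = [k for k in _REQUIRED_HEADER if k not in header]
    if missing:
        raise TraceFormatError(f"missing header fields: {', '.join(missing)}")
    start = float(header["start_min"])
    bin_min = float(header["bin_min"])
    meta = {k: v for k, v in header.items() if k not in _REQUIRED_HEADER}
    arr = np.array(values, dtype=float)
    n_missing = int(np.isnan(arr).sum())
    if len(arr) and n_missing / len(arr) > 0.10:
        warnings.warn(f"{n_missing}/{len(arr)} values missing (> 10%)", stacklevel=2)
    if header["kind"] == "activity":
        return ActivityTrace(start_min=start, bin_min=bin_min, counts=arr,
                             units=header["units"], meta=meta)
    if header["kind"] == "immobility":
        if np.isnan(arr).any():
            raise TraceFormatError("immobility traces cannot have missing samples")
        return ImmobilityTrace(start_min=start, flags=arr.astype(np.uint8), meta=meta)
    raise TraceFormatError(f"unknown trace kind {header['kind']!r}")


# ---------------------------------------------------------------------------
# Time-frame conversion
# ---------------------------------------------------------------------------

def to_zt(t_min: float, schedule: LightSchedule) -> float:
    """Zeitgeber Time (hours, [0, 24)) of an absolute time under a schedule.

    Raises if the time falls in a constant-darkness epoch, where ZT is
    undefined and CT should be used.
    """
    seg = schedule.segment_at(t_min)
    if seg.zt0_min is None:
        raise ValueError("ZT undefined in constant darkness; use to_ct")
    return float(((t_min - seg.zt0_min) / 60.0) % 24.0)


def zt_to_abs(zt_h: float, day: int, schedule: LightSchedule) -> float:
    """Absolute minute of clock ZT ``zt_h`` on recording day ``day``.

    The day's ZT frame is taken from the schedule segment covering the middle
    of that day.
    """
    t_mid = (day + 0.5) * MIN_PER_DAY
    seg = schedule.segment_at(t_mid)
    if seg.zt0_min is None:
        raise ValueError("ZT undefined in constant darkness")
    base = seg.zt0_min + zt_h * 60.0
    # bring into the requested day
    k = np.floor((day * MIN_PER_DAY - base) / MIN_PER_DAY + 1e-9) + 1
    t = base + k * MIN_PER_DAY
    if t >= (day + 1) * MIN_PER_DAY:
        t -= MIN_PER_DAY
    return float(t)


def to_ct(t_min: float, onset_series) -> float:
    """Circadian Time (hours, [0, 24)) of an absolute time in free run.

    CT12 is the regression-predicted activity onset for the covering cycle and
    the circadian hour is ``tau/24`` clock hours long, so a time ``d`` minutes
    after predicted onset maps to ``12 + (d/60)·(24/tau)`` (mod 24).
    """
    fit = onset_series.fit()
    tau_min = fit.slope  # absolute onsets drift by one full cycle per day index
    if not (18 * 60 < tau_min < 30 * 60):
        raise ValueError("onset fit does not describe a circadian cycle")
    # cycle index whose predicted onset most recently precedes t
    k = np.floor((t_min - fit.intercept) / tau_min)
    onset_pred = fit.intercept + k * tau_min
    dt_h = (t_min - onset_pred) / 60.0
    return float((12.0 + dt_h * (24.0 * 60.0 / tau_min)) % 24.0)


def ct_to_abs(ct_h: float, cycle: int, onset_series) -> float:
    """Absolute minute of CT ``ct_h`` on free-running cycle ``cycle``."""
    fit = onset_series.fit()
    tau_min = fit.slope
    onset_pred = fit.intercept + cycle * tau_min
    return float(onset_pred + ((ct_h - 12.0) % 24.0) / 24.0 * tau_min)


# ---------------------------------------------------------------------------
# Daily folding
# ---------------------------------------------------------------------------

def fold_daily(trace: ActivityTrace, period_h: float = 24.0,
               n_days: int | None = None, out_bin_h: float = 1.0):
    """Fold a trace at ``period_h`` and average across cycles.

    Returns ``(bin_starts_h, mean, sem)`` with ``out_bin_h``-wide output bins
    (1 h by default).  Only complete cycles are used; the period and the output
    bin must be multiples of the trace bin width.
    """
    period_min = period_h * 60.0
    out_bin_min = out_bin_h * 60.0
    for name, width in (("period", period_min), ("output bin", out_bin_min)):
        if abs(width / trace.bin_min - round(width / trace.bin_min)) > 1e-9:
            raise ValueError(f"{name} is not a multiple of the trace bin width")
    bins_per_cycle = int(round(period_min / trace.bin_min))
    bins_per_out = int(round(out_bin_min / trace.bin_min))
    if bins_per_cycle % bins_per_out:
        raise ValueError("period is not a multiple of the output bin")
    n_cycles = trace.n_bins // bins_per_cycle
    if n_days is not None:
        n_cycles = min(n_cycles, n_days)
    if n_cycles < 1:
        raise ValueError("need at least one complete cycle")
    x = trace.counts[: n_cycles * bins_per_cycle].reshape(n_cycles, -1, bins_per_out)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        per_cycle = np.nansum(x, axis=2)          # (cycles, out bins)
        per_cycle[np.all(np.isnan(x), axis=2)] = np.nan
        mean = np.nanmean(per_cycle, axis=0)
        n_ok = np.sum(~np.isnan(per_cycle), axis=0)
        sd = np.nanstd(per_cycle, axis=0, ddof=1) if n_cycles > 1 else np.zeros_like(mean)
    sem = np.where(n_ok > 1, sd / np.sqrt(np.maximum(n_ok, 1)), 0.0)
    starts = np.arange(bins_per_cycle // bins_per_out) * out_bin_h
    return starts, mean, sem
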