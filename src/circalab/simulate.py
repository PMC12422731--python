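"""Virtual-mouse simulator: activity, immobility, profiles, and group tables.

The simulator produces records with *known ground truth* so every analysis
stage in the package can be validated by parameter recovery.  A virtual mouse
is a nocturnal oscillator reduced to its behavioral readouts:

* its activity onset is anchored to lights-off while entrained, free-runs with
  period ``tau_hours`` in darkness, and carries day-to-day Gaussian jitter
  (``onset_jitter_min``) — the quantity the onset-variability statistic
  estimates;
* activity is Poisson per bin, at ``active_rate`` counts/min for half a cycle
  from onset and at a low rest rate otherwise; light falling inside the active
  window suppresses the rate by the masking coefficient ``m`` (negative
  masking);
* after an LD-cycle shift the anchor moves toward the new lights-off at most
  ``reentrain_rate_h_per_day`` hours per day (first-order re-entrainment); a
  light pulse at CT16 in free run delays the anchor by
  ``phase_shift_delay_min``, applied over two transient cycles;
* immobility alternates exponential immobile/mobile bouts whose means switch
  between rest-phase ("day") and active-phase ("night") values.

Everything is a pure function of ``(params, protocol, seed)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import ActivityTrace, ImmobilityTrace, LightSchedule, ScheduleSegment

__all__ = [
    "MouseParams",
    "Protocol",
    "LD",
    "DD",
    "SPP",
    "PhaseAdvance",
    "LightPulse",
    "PRESETS",
    "make_params",
    "simulate_activity",
    "simulate_immobility",
    "simulate_profiles",
    "simulate_group_table",
    "load_protocol",
    "save_protocol",
]

MIN_PER_DAY = 1440


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MouseParams:
    """Ground-truth behavioral parameters of one virtual mouse.

    ``rest_rate`` may be ``None``, in which case it is derived from
    ``activity_frac_night`` so that, over a 12 h active / 12 h rest cycle, the
    expected fraction of counts emitted in the active (dark) phase equals
    ``activity_frac_night``.
    """

    tau_hours: float = 23.6
    onset_jitter_min: float = 8.0
    active_rate: float = 20.0            # counts/min while active
    rest_rate: float | None = None       # counts/min at rest; derived if None
    activity_frac_night: float = 0.98
    masking_coeff: float = 0.78          # m: fraction of activity suppressed by light
    phase_shift_delay_min: float = 136.0  # CT16 pulse -> asymptotic onset delay
    reentrain_rate_h_per_day: float = 1.0
    sleep_bout_mean_day_min: float = 22.0
    sleep_bout_mean_night_min: float = 9.0
    wake_bout_mean_day_min: float = 12.4
    wake_bout_mean_night_min: float = 27.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 20.0 <= self.tau_hours <= 28.0:
            raise ValueError("tau_hours must lie in [20, 28]")
        if not 0.0 <= self.masking_coeff <= 1.0:
            raise ValueError("masking coefficient must lie in [0, 1]")
        if self.active_rate < 0 or (self.rest_rate is not None and self.rest_rate < 0):
            raise ValueError("rates must be non-negative")
        if not 0.0 < self.activity_frac_night <= 1.0:
            raise ValueError("activity_frac_night must lie in (0, 1]")
        for name in ("sleep_bout_mean_day_min", "sleep_bout_mean_night_min",
                     "wake_bout_mean_day_min", "wake_bout_mean_night_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.onset_jitter_min < 0:
            raise ValueError("onset_jitter_min must be non-negative")

    @property
    def rest_rate_effective(self) -> float:
        if self.rest_rate is not None:
            return self.rest_rate
        f = self.activity_frac_night
        return self.active_rate * (1.0 - f) / f


#: Named parameter sets mirroring the direction of the wild-type vs Fmr1-KO
#: contrasts (qualitative, not fitted): the KO-like mouse has noisier onsets,
#: more daytime activity leak, weaker masking, a smaller light-evoked phase
#: delay, slower re-entrainment, and shorter daytime sleep bouts.
PRESETS: dict[str, dict] = {
    "wt_like": dict(
        tau_hours=23.6, onset_jitter_min=8.0, active_rate=20.0,
        activity_frac_night=0.98, masking_coeff=0.78,
        phase_shift_delay_min=136.0, reentrain_rate_h_per_day=1.0,
        sleep_bout_mean_day_min=22.0, sleep_bout_mean_night_min=9.0,
        wake_bout_mean_day_min=12.4, wake_bout_mean_night_min=27.0,
    ),
    "ko_like": dict(
        tau_hours=23.4, onset_jitter_min=30.0, active_rate=20.0,
        activity_frac_night=0.92, masking_coeff=0.33,
        phase_shift_delay_min=64.0, reentrain_rate_h_per_day=0.53,
        sleep_bout_mean_day_min=15.0, sleep_bout_mean_night_min=9.5,
        wake_bout_mean_day_min=11.8, wake_bout_mean_night_min=34.7,
    ),
}


def make_params(preset: str, seed: int = 0, **overrides) -> MouseParams:
    """A :class:`MouseParams` from a named preset with optional overrides."""
    if preset not in PRESETS:
        raise KeyError(f"unknown preset {preset!r}; have {sorted(PRESETS)}")
    kw = dict(PRESETS[preset])
    kw.update(overrides)
    return MouseParams(seed=seed, **kw)


# ---------------------------------------------------------------------------
# Protocols
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LD:
    """Light-dark cycle segment; lights on ZT0 to ``light_hours``."""
    days: float
    light_hours: float = 12.0


@dataclass(frozen=True)
class DD:
    """Constant darkness segment."""
    days: float


@dataclass(frozen=True)
class SPP:
    """Skeleton photoperiod: two short pulses framing the subjective day
    (1hL:11hD:1hL:11hD by default — dawn pulse at ZT0, dusk pulse ending ZT12)."""
    days: float
    pulse_hours: float = 1.0


@dataclass(frozen=True)
class PhaseAdvance:
    """Instantaneous advance of the LD cycle by ``hours`` (new lights-on is
    ``hours`` earlier); applies to all subsequent segments."""
    hours: float


@dataclass(frozen=True)
class LightPulse:
    """A timed light pulse on the day at the current protocol cursor.

    Give either ``zt`` (resolved against the schedule when it is built) or
    ``ct`` (resolved against the simulated animal's free-running phase)."""
    duration_min: float
    zt: float | None = None
    ct: float | None = None


Segment = LD | DD | SPP
Event = PhaseAdvance | LightPulse


@dataclass
class Protocol:
    """Ordered lighting segments with zero-duration events in between, plus an
    optional daily feeding window in ZT hours (e.g. ``(15, 21)`` for TRF)."""

    segments: list
    feeding: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        for seg in self.segments:
            if isinstance(seg, (LD, DD, SPP)) and seg.days <= 0:
                raise ValueError("segment durations must be positive")
            if isinstance(seg, SPP) and seg.pulse_hours * 2 >= 12.0:
                raise ValueError("SPP pulses overlap")
            if isinstance(seg, LightPulse):
                if (seg.zt is None) == (seg.ct is None):
                    raise ValueError("LightPulse needs exactly one of zt/ct")
                if seg.duration_min <= 0:
                    raise ValueError("pulse duration must be positive")
        if self.feeding is not None:
            a, b = self.feeding
            if not (0 <= a < b <= 24):
                raise ValueError("feeding window must lie within 0-24 h")

    @property
    def total_days(self) -> float:
        return sum(s.days for s in self.segments if isinstance(s, (LD, DD, SPP)))

    def build_schedule(self):
        """Compile to a :class:`~circalab.io.LightSchedule`.

        Returns ``(schedule, ct_pulse_markers)`` where the markers are
        ``(day_index, ct_hours, duration_min)`` for pulses that can only be
        placed once the animal's free-running phase is known.
        """
        segments: list[ScheduleSegment] = []
        pulses: list[tuple[float, float]] = []
        ct_markers: list[tuple[int, float, float]] = []
        cursor = 0.0
        zt0 = 0.0
        for seg in self.segments:
            if isinstance(seg, LD):
                segments.append(ScheduleSegment(cursor, cursor + seg.days * MIN_PER_DAY,
                                                "LD", zt0, light_hours=seg.light_hours))
                cursor += seg.days * MIN_PER_DAY
            elif isinstance(seg, SPP):
                segments.append(ScheduleSegment(cursor, cursor + seg.days * MIN_PER_DAY,
                                                "SPP", zt0, pulse_hours=seg.pulse_hours))
                cursor += seg.days * MIN_PER_DAY
            elif isinstance(seg, DD):
                segments.append(ScheduleSegment(cursor, cursor + seg.days * MIN_PER_DAY,
                                                "DD", None))
                cursor += seg.days * MIN_PER_DAY
            elif isinstance(seg, PhaseAdvance):
                zt0 -= seg.hours * 60.0
            elif isinstance(seg, LightPulse):
                if seg.zt is not None:
                    start = cursor + (seg.zt * 60.0 - (cursor - zt0)) % MIN_PER_DAY
                    pulses.append((start, start + seg.duration_min))
                else:
                    ct_markers.append((int(round(cursor / MIN_PER_DAY)), seg.ct,
                                       seg.duration_min))
            else:
                raise TypeError(f"unknown protocol element {seg!r}")
        sched = LightSchedule(segments=segments, pulses=pulses,
                              feeding_zt=self.feeding)
        return sched, ct_markers


# --- YAML round trip -------------------------------------------------------

_SEG_TAGS = {"LD": LD, "DD": DD, "SPP": SPP,
             "phase_advance": PhaseAdvance, "light_pulse": LightPulse}


def protocol_to_dict(protocol: Protocol) -> dict:
    out = []
    for seg in protocol.segments:
        tag = {LD: "LD", DD: "DD", SPP: "SPP",
               PhaseAdvance: "phase_advance", LightPulse: "light_pulse"}[type(seg)]
        d = {"kind": tag}
        d.update({k: v for k, v in vars(seg).items() if v is not None})
        out.append(d)
    return {"segments": out,
            "feeding": list(protocol.feeding) if protocol.feeding else None}


def protocol_from_dict(data: dict) -> Protocol:
    segs = []
    for d in data["segments"]:
        d = dict(d)
        cls = _SEG_TAGS[d.pop("kind")]
        segs.append(cls(**d))
    feeding = tuple(data["feeding"]) if data.get("feeding") else None
    return Protocol(segments=segs, feeding=feeding)


def save_protocol(protocol: Protocol, path) -> None:
    Path(path).write_text(yaml.safe_dump(protocol_to_dict(protocol)))


def load_protocol(path) -> Protocol:
    return protocol_from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Anchor dynamics (shared by activity and immobility generators)
# ---------------------------------------------------------------------------

def _anchor_path(params: MouseParams, protocol: Protocol):
    """Deterministic daily onset anchor (time of day, min) and active-window
    lengths, with CT-referenced pulses resolved to absolute times.

    Returns ``(anchors_min, act_len_min, entrained, pulse_intervals)`` over the
    protocol's whole-day timeline.
    """
    sched, ct_markers = protocol.build_schedule()
    n_days = int(math.floor(protocol.total_days + 1e-9))
    anchors = np.empty(n_days)
    act_len = np.empty(n_days)
    entrained = np.zeros(n_days, dtype=bool)
    delay_queue = np.zeros(n_days + 3)
    pulse_ivals: list[tuple[float, float]] = []
    markers = {day: (ct, dur) for day, ct, dur in ct_markers}
    o: float | None = None
    step = params.reentrain_rate_h_per_day * 60.0
    for d in range(n_days):
        seg = sched.segment_at((d + 0.5) * MIN_PER_DAY)
        lockable = seg.kind == "LD" or (seg.kind == "SPP"
                                        and params.masking_coeff >= 0.5)
        if lockable:
            off_h = seg.light_hours if seg.kind == "LD" else 12.0
            target = (seg.zt0_min + off_h * 60.0) % MIN_PER_DAY
            if o is None:
                o = target
            else:
                diff = ((target - o + 720.0) % MIN_PER_DAY) - 720.0
                o = target if abs(diff) <= step else (o + math.copysign(step, diff)) % MIN_PER_DAY
            entrained[d] = abs(((target - o + 720.0) % MIN_PER_DAY) - 720.0) < 1e-9
            act_len[d] = 720.0
        else:
            o = 720.0 if o is None else (o + (params.tau_hours - 24.0) * 60.0) % MIN_PER_DAY
            act_len[d] = params.tau_hours * 30.0
        o = (o + delay_queue[d]) % MIN_PER_DAY
        anchors[d] = o
        if d in markers:
            ct, dur = markers[d]
            onset_abs = d * MIN_PER_DAY + o
            t_pulse = onset_abs + (ct - 12.0) % 24.0 * (params.tau_hours / 24.0) * 60.0
            pulse_ivals.append((t_pulse, t_pulse + dur))
            # first-order transient: the delay accrues at the re-entrainment
            # rate, over at most two cycles
            first = min(params.phase_shift_delay_min, step)
            delay_queue[d + 1] += first
            delay_queue[d + 2] += params.phase_shift_delay_min - first
    return sched, anchors, act_len, entrained, pulse_ivals


def _active_mask(anchors, act_len, onset_abs, total_min):
    """Per-minute boolean active mask from absolute onsets and window lengths."""
    mask = np.zeros(int(total_min), dtype=bool)
    for d in range(len(anchors)):
        a = int(round(onset_abs[d]))
        b = int(round(onset_abs[d] + act_len[d]))
        mask[max(a, 0):min(b, len(mask))] = True
    return mask


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def simulate_activity(params: MouseParams, protocol: Protocol,
                      bin_min: int = 1) -> ActivityTrace:
    """Simulate a binned locomotor-activity record.

    Counts are Poisson per bin with a per-minute rate of ``active_rate``
    inside the daily active window (half a cycle starting at the jittered
    onset) and the rest rate elsewhere; light inside the active window
    multiplies the rate by ``1 - m``.  Deterministic given ``params.seed``.
    """
    if bin_min <= 0 or 60 % bin_min:
        raise ValueError("bin_min must be a positive divisor of 60")
    if protocol.total_days < 3:
        raise ValueError("protocol must span at least 3 days")
    sched, anchors, act_len, _, ct_pulses = _anchor_path(params, protocol)
    for a, b in ct_pulses:
        sched = sched.with_pulse(a, b - a)
    n_days = len(anchors)
    total_min = n_days * MIN_PER_DAY
    rng = np.random.default_rng([params.seed, 0])
    jitter = rng.normal(0.0, params.onset_jitter_min, size=n_days) \
        if params.onset_jitter_min > 0 else np.zeros(n_days)
    onset_abs = np.arange(n_days) * MIN_PER_DAY + anchors + jitter
    active = _active_mask(anchors, act_len, onset_abs, total_min)
    rate = np.where(active, params.active_rate, params.rest_rate_effective)
    lit = sched.is_light(np.arange(total_min) + 0.5)
    rate = np.where(lit & active, rate * (1.0 - params.masking_coeff), rate)
    lam = rate.reshape(-1, bin_min).sum(axis=1)
    counts = rng.poisson(lam).astype(float)
    meta = {"seed": params.seed, "tau_hours": params.tau_hours,
            "true_onsets_min": onset_abs.tolist()}
    return ActivityTrace(start_min=0.0, bin_min=float(bin_min), counts=counts,
                         schedule=sched, units="rev", meta=meta)


def simulate_immobility(params: MouseParams, protocol: Protocol) -> ImmobilityTrace:
    """Simulate a 1-Hz immobility trace as alternating exponential bouts.

    Bout-duration means switch between the "day" (rest-phase) and "night"
    (active-phase) parameters according to the animal's subjective phase at
    bout start.  The record starts mobile.  Deterministic given ``params.seed``.
    """
    if protocol.total_days < 2:
        raise ValueError("protocol must span at least 2 days")
    sched, anchors, act_len, _, _ = _anchor_path(params, protocol)
    n_days = len(anchors)
    total_min = n_days * MIN_PER_DAY
    onset_abs = np.arange(n_days) * MIN_PER_DAY + anchors   # phase: no jitter
    active_min = _active_mask(anchors, act_len, onset_abs, total_min)
    total_s = int(total_min) * 60
    rng = np.random.default_rng([params.seed, 1])
    flags = np.zeros(total_s, dtype=np.uint8)
    t = 0
    immobile = False   # animals introduced to the cage move first
    while t < total_s:
        rest_phase = not active_min[t // 60]
        if immobile:
            mean = (params.sleep_bout_mean_day_min if rest_phase
                    else params.sleep_bout_mean_night_min)
        else:
            mean = (params.wake_bout_mean_day_min if rest_phase
                    else params.wake_bout_mean_night_min)
        if math.isinf(mean):
            dur = total_s - t
        else:
            dur = max(1, int(round(rng.exponential(mean * 60.0))))
        if immobile:
            flags[t:t + dur] = 1
        t += dur
        immobile = not immobile
    return ImmobilityTrace(start_min=0.0, flags=flags, schedule=sched,
                           meta={"seed": params.seed})


def simulate_profiles(n_sections: int, peak_pos: float, peak_sd: float,
                      amplitude: float, noise_sd: float, jitter_bins: float,
                      seed: int, n_bins: int = 256, baseline: float = 10.0,
                      side: str = "left"):
    """Synthetic 1-D intensity profiles: Gaussian bump + baseline + noise,
    with the per-section peak position jittered ``~ N(0, jitter_bins)``."""
    from .densitometry import IntensityProfile
    if n_sections < 1:
        raise ValueError("need at least one section")
    if peak_sd <= 0 or n_bins <= 0:
        raise ValueError("widths must be positive")
    if noise_sd < 0 or jitter_bins < 0 or amplitude < 0:
        raise ValueError("amplitude, noise_sd and jitter_bins must be >= 0")
    rng = np.random.default_rng(seed)
    x = np.arange(n_bins, dtype=float)
    profiles = []
    for i in range(n_sections):
        center = peak_pos + (rng.normal(0.0, jitter_bins) if jitter_bins > 0 else 0.0)
        y = baseline + amplitude * np.exp(-0.5 * ((x - center) / peak_sd) ** 2)
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, size=n_bins)
        profiles.append(IntensityProfile(y=np.clip(y, 0.0, None),
                                         section_id=f"s{i}", side=side,
                                         true_peak=center))
    return profiles


def simulate_group_table(n_per_group: int, group_effects: dict, seed: int) -> pd.DataFrame:
    """Per-animal metric table with independent normal draws per cell.

    ``group_effects`` maps group label -> {metric: (mean, sd)}.  All groups
    must declare the same metrics.  Rows carry ``animal`` and ``group``
    columns; suitable input for the stats layer.
    """
    if n_per_group < 2:
        raise ValueError("need n >= 2 per group")
    rng = np.random.default_rng(seed)
    metrics = None
    rows = []
    for group, effects in group_effects.items():
        if metrics is None:
            metrics = list(effects)
        elif list(effects) != metrics:
            raise ValueError("all groups must define the same metrics")
        for sd in (v[1] for v in effects.values()):
            if sd < 0:
                raise ValueError("SD must be non-negative")
        for i in range(n_per_group):
            row = {"animal": f"{group}_{i}", "group": group}
            for metric, (mean, sd) in effects.items():
                row[metric] = rng.normal(mean, sd)
            rows.append(row)
    return pd.DataFrame(rows)
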