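"""Immobility-defined sleep scoring and fragmentation metrics.

Behavioral sleep is scored from 1-Hz immobility flags: a second counts as
sleep iff it lies inside some run of seconds that is at least ``min_run_s``
(40 s) long and at least ``immobile_frac`` (95%) immobile — a criterion
validated against EEG-defined sleep in mice.  Scored seconds are aggregated
into a per-minute *sleep count* (one count per 10 s of scored sleep, 0-6 per
minute), and sleep bouts are maximal runs of minutes with a count above 3.

The 95% criterion is temporal: the fraction of immobile *seconds* within the
candidate run.  (The upstream tracker's spatial 95%-of-the-animal rule is
applied before export and only the temporal trace survives.)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ImmobilityTrace, LightSchedule, zt_to_abs

__all__ = [
    "SleepSeries",
    "SleepBout",
    "SleepMetrics",
    "score_sleep",
    "detect_sleep_bouts",
    "sleep_metrics",
]

SECONDS_PER_COUNT = 10      # sleep-count unit: 1 count per 10 scored seconds
COUNT_THRESHOLD = 3         # bout criterion: count strictly greater than 3


@dataclass
class SleepSeries:
    """Per-minute sleep counts derived from scored sleep seconds."""

    start_min: float
    counts: np.ndarray                  # int, 0..6 per minute
    asleep_s: np.ndarray                # per-second scored-sleep flags
    schedule: LightSchedule | None = None
    params: dict = field(default_factory=lambda: {
        "min_immobile_s": 40, "immobile_frac": 0.95,
        "seconds_per_count": SECONDS_PER_COUNT})

    @property
    def n_minutes(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class SleepBout:
    start_min: int          # minute index from series start
    end_min: int            # exclusive
    @property
    def duration_min(self) -> int:
        return self.end_min - self.start_min


@dataclass
class SleepMetrics:
    """Per-day sleep metrics over an analysis window."""
    window: str
    duration_min: float     # scored sleep minutes per day
    n_bouts: float          # bouts per day (bout start inside window)
    mean_bout_min: float    # 0 with empty=True when there are no bouts
    max_bout_min: float
    n_days: int
    empty: bool = False


def _scored_sleep_seconds(flags: np.ndarray, min_run_s: int,
                          immobile_frac: float) -> np.ndarray:
    """Boolean per-second scored-sleep mask.

    A second is asleep iff some interval ``[i, j)`` containing it has
    ``j - i >= min_run_s``, an immobile fraction ``>= immobile_frac``, and
    begins and ends on an immobile second (mobile padding cannot extend a run
    past the length threshold).  Works on the integer lattice: with weights
    ``w_k = q·x_k − p`` (fraction p/q), an interval qualifies iff its weight
    sum is ``>= 0``, i.e. iff the prefix sums satisfy ``S_j >= S_i``.  For
    each admissible right end j the earliest admissible left end is found by
    binary search on the (non-increasing) prefix-minimum sequence over
    immobile start positions; the union of the resulting intervals is the
    scored mask.  O(n log n).
    """
    x = np.asarray(flags, dtype=np.int64)
    n = len(x)
    if n < min_run_s or not x.any():
        return np.zeros(n, dtype=bool)
    # represent immobile_frac as a fraction p/q on a small lattice
    q = 10_000
    p = int(round(immobile_frac * q))
    S = np.concatenate([[0], np.cumsum(q * x - p)])          # length n+1
    starts_ok = np.flatnonzero(x == 1)                       # admissible i
    premin_a = np.minimum.accumulate(S[starts_ok])
    js = np.arange(min_run_s, n + 1)
    # admissible left ends per j: immobile i with i <= j - min_run_s
    cnt = np.searchsorted(starts_ok, js - min_run_s, side="right")
    rank = np.searchsorted(-premin_a, -S[js], side="left")
    feasible = (x[js - 1] == 1) & (cnt > 0)
    feasible[feasible] &= premin_a[cnt[feasible] - 1] <= S[js[feasible]]
    i0 = starts_ok[np.minimum(rank, len(starts_ok) - 1)]
    starts = np.where(feasible, i0, n + 1)                   # cover [starts, j)
    # second t is asleep iff min over j > t of starts[j] <= t
    suff = np.minimum.accumulate(starts[::-1])[::-1]
    # suff[k] = min starts over js[k:]; for t, relevant js are j >= t+1
    asleep = np.zeros(n, dtype=bool)
    t = np.arange(n)
    # position of first j >= t+1 in js (js = min_run_s..n)
    pos = np.maximum(t + 1, min_run_s) - min_run_s
    valid = pos < len(js)
    asleep[valid] = suff[pos[valid]] <= t[valid]
    return asleep


def score_sleep(immobility: ImmobilityTrace, min_immobile_s: int = 40,
                immobile_frac: float = 0.95) -> SleepSeries:
    """Score behavioral sleep from a 1-Hz immobility trace.

    Returns the per-minute sleep-count series (``floor(scored seconds / 10)``,
    0-6 per minute) together with the per-second scored mask.
    """
    if immobility.n_seconds < 86400:
        raise ValueError("need at least one day of 1-Hz immobility data")
    asleep = _scored_sleep_seconds(immobility.flags, min_immobile_s, immobile_frac)
    n_min = len(asleep) // 60
    per_min = asleep[: n_min * 60].reshape(n_min, 60).sum(axis=1)
    counts = per_min // SECONDS_PER_COUNT
    return SleepSeries(start_min=immobility.start_min, counts=counts,
                       asleep_s=asleep, schedule=immobility.schedule,
                       params={"min_immobile_s": min_immobile_s,
                               "immobile_frac": immobile_frac,
                               "seconds_per_count": SECONDS_PER_COUNT})


def detect_sleep_bouts(series: SleepSeries, min_bout_min: int = 1) -> list[SleepBout]:
    """Maximal runs of consecutive minutes with sleep count > 3.

    Runs shorter than ``min_bout_min`` (60 s) are discarded.  The inequality
    is strict: a minute at exactly 3 counts breaks a bout.
    """
    above = np.asarray(series.counts) > COUNT_THRESHOLD
    bouts: list[SleepBout] = []
    if not above.any():
        return bouts
    d = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [len(above)]])
    for a, b in zip(starts, ends):
        if b - a >= min_bout_min:
            bouts.append(SleepBout(int(a), int(b)))
    return bouts


def _window_minute_mask(series: SleepSeries, schedule: LightSchedule,
                        window: str, n_days: int) -> np.ndarray:
    """Boolean mask over series minutes selecting the requested ZT window."""
    mask = np.zeros(series.n_minutes, dtype=bool)
    for day in range(n_days):
        if window == "24h":
            lo, hi = day * 1440.0, (day + 1) * 1440.0
        else:
            zt0_abs = zt_to_abs(0.0, day, schedule)
            if window == "day":
                lo, hi = zt0_abs, zt0_abs + 720.0
            elif window == "night":
                lo, hi = zt0_abs + 720.0, zt0_abs + 1440.0
            else:
                raise ValueError("window must be one of day/night/24h")
        a = int(max(0, np.ceil(lo - series.start_min)))
        b = int(min(series.n_minutes, np.floor(hi - series.start_min + 1e-9)))
        mask[a:b] = True
    return mask


def sleep_metrics(series: SleepSeries, schedule: LightSchedule | None = None,
                  window: str = "24h") -> SleepMetrics:
    """Duration and fragmentation metrics per day over a ZT window.

    Duration is the total scored sleep (minutes) inside the window; bout
    statistics cover bouts whose *start minute* lies in the window (bouts
    spanning the day/night boundary are not split).  Multi-day records are
    averaged per day.
    """
    schedule = schedule or series.schedule
    if window != "24h" and schedule is None:
        raise ValueError("day/night windows need a light schedule")
    n_days = series.n_minutes // 1440
    if n_days < 1:
        raise ValueError("window outside record: need at least one full day")
    n_min = n_days * 1440
    mask = _window_minute_mask(series, schedule, window, n_days)
    asleep_min = series.asleep_s[: n_min * 60].reshape(-1, 60).sum(axis=1) / 60.0
    duration = float(np.sum(asleep_min[:n_min] * mask[:n_min])) / n_days
    bouts = [b for b in detect_sleep_bouts(series)
             if b.start_min < n_min and mask[b.start_min]]
    if bouts:
        durs = np.array([b.duration_min for b in bouts], dtype=float)
        return SleepMetrics(window=window, duration_min=duration,
                            n_bouts=len(bouts) / n_days,
                            mean_bout_min=float(durs.mean()),
                            max_bout_min=float(durs.max()), n_days=n_days)
    return SleepMetrics(window=window, duration_min=duration, n_bouts=0.0,
                        mean_bout_min=0.0, max_bout_min=0.0,
                        n_days=n_days, empty=True)
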