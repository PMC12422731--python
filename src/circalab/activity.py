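"""Activity-onset detection, onset variability, and fragmentation metrics.

Activity onset is the behavioral phase marker of the circadian clock: the
time each cycle at which a nocturnal animal starts sustained locomotion.
Onsets are detected per cycle by correlating the per-minute activity profile
with a step template (6 h of -1 followed by 6 h of +1) inside a +/-6 h window
around the expected onset, then refined to the first minute at or above the
activity threshold (3 counts/min) that follows a quiescent stretch.  Onset
variability — "imprecision" — is the SD of residuals about the least-squares
line through the daily onsets, and fragmentation is the number of activity
bouts per day, where a bout ends only when activity stays below 3 counts/min
for 21 min or more.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ActivityTrace, zt_to_abs

__all__ = [
    "OnsetSeries",
    "OnsetFit",
    "ActivityBout",
    "detect_onsets",
    "onset_variability",
    "segment_activity_bouts",
    "count_activity_bouts",
    "windowed_activity",
    "actogram_matrix",
]

TEMPLATE_HALF_MIN = 360          # step template: 6 h low, 6 h high
ONSET_THRESHOLD = 3.0            # counts/min
QUIESCENCE_MIN = 240             # >= 4 h of low activity before onset
SEARCH_HALF_MIN = 360            # +/- 6 h search window around expectation
REFINE_HALF_MIN = 90             # threshold refinement window around template peak


@dataclass(frozen=True)
class OnsetFit:
    slope: float          # min per day index: ~ cycle length (tau * 60)
    intercept: float      # predicted onset (abs min) at day 0
    resid_sd: float       # SD of residuals, denominator n - 2
    n: int

    def predict(self, day) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(day, dtype=float)

    @property
    def drift_min_per_day(self) -> float:
        """Onset drift in time-of-day minutes per day (negative = advancing)."""
        return self.slope - 1440.0


@dataclass
class OnsetSeries:
    """Daily activity onsets in absolute minutes (NaN = missing day)."""

    days: np.ndarray
    onset_min: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=int)
        self.onset_min = np.asarray(self.onset_min, dtype=float)

    @property
    def n_valid(self) -> int:
        return int(np.sum(np.isfinite(self.onset_min)))

    def valid(self):
        ok = np.isfinite(self.onset_min)
        return self.days[ok], self.onset_min[ok]

    def fit(self) -> OnsetFit:
        d, o = self.valid()
        if len(d) < 2:
            raise ValueError("need at least 2 onsets to fit a line")
        slope, intercept = np.polyfit(d, o, 1)
        resid = o - (intercept + slope * d)
        sd = float(np.sqrt(np.sum(resid ** 2) / (len(d) - 2))) if len(d) > 2 else 0.0
        return OnsetFit(float(slope), float(intercept), sd, len(d))

    def shifted(self, delta_min: float) -> "OnsetSeries":
        return OnsetSeries(self.days.copy(), self.onset_min + delta_min)


def _refine_onset(x: np.ndarray, peak: int) -> int:
    """Snap a template-peak estimate to the first sustained threshold crossing.

    Looks +/- REFINE_HALF_MIN around the peak for the first minute m with
    x[m] >= threshold, a sustained crossing over the next 10 min, and a prior
    4-h stretch averaging below threshold.  Falls back to the peak itself.
    """
    lo = max(peak - REFINE_HALF_MIN, 0)
    hi = min(peak + REFINE_HALF_MIN, len(x) - 10)
    for m in range(lo, hi):
        if np.any(x[m:m + 3] < ONSET_THRESHOLD):
            continue
        nxt = x[m:m + 10]
        if nxt.mean() < ONSET_THRESHOLD or np.sum(nxt >= ONSET_THRESHOLD) < 6:
            continue
        prev = x[max(m - QUIESCENCE_MIN, 0):m]
        if len(prev) >= 60 and prev.mean() < ONSET_THRESHOLD:
            return m
    return peak


def detect_onsets(trace: ActivityTrace, expected_period_h: float = 24.0) -> OnsetSeries:
    """Detect one activity onset per cycle of an activity trace.

    Template correlation (6 h low / 6 h high step) within +/-6 h of the
    previous onset plus the expected period, refined by the first sustained
    crossing of 3 counts/min after a quiescent stretch.  Days without a
    candidate (e.g. arrhythmic or all-zero) get NaN and are skipped by the
    downstream regression.
    """
    if trace.n_days < 3:
        raise ValueError("need at least 3 days of data")
    per_min = trace.per_minute()
    x = np.nan_to_num(np.asarray(per_min.counts, dtype=float))
    n = len(x)
    C = np.concatenate([[0.0], np.cumsum(x)])

    def corr(t: np.ndarray) -> np.ndarray:
        return C[t + TEMPLATE_HALF_MIN] - 2.0 * C[t] + C[t - TEMPLATE_HALF_MIN]

    period_min = expected_period_h * 60.0
    n_cycles = int(n // period_min)
    days = np.arange(n_cycles)
    onsets = np.full(n_cycles, np.nan)
    prev: float | None = None
    for d in range(n_cycles):
        center = (prev + period_min) if prev is not None \
            else d * period_min + period_min / 2.0
        lo = int(max(center - SEARCH_HALF_MIN, TEMPLATE_HALF_MIN))
        hi = int(min(center + SEARCH_HALF_MIN, n - TEMPLATE_HALF_MIN))
        if hi <= lo:
            continue
        ts = np.arange(lo, hi)
        scores = corr(ts)
        if scores.max() <= 0:        # no activity rise anywhere in the window
            continue
        peak = int(ts[np.argmax(scores)])
        m = _refine_onset(x, peak)
        onsets[d] = float(m)
        prev = float(m)
    return OnsetSeries(days=days, onset_min=onsets + trace.start_min)


def onset_variability(onsets: OnsetSeries) -> float:
    """Onset imprecision: SD (denominator n-2) of residuals about the
    least-squares line through the daily onsets.  Needs >= 5 onsets."""
    if onsets.n_valid < 5:
        raise ValueError("need at least 5 non-missing onsets")
    return onsets.fit().resid_sd


# ---------------------------------------------------------------------------
# Fragmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ActivityBout:
    start_min: int        # minute index into the trace
    end_min: int          # exclusive; last active minute + 1
    total_counts: float


def segment_activity_bouts(trace: ActivityTrace, threshold: float = 3.0,
                           max_gap_min: int = 21) -> list[ActivityBout]:
    """Segment activity into bouts.

    A minute is active at >= ``threshold`` counts/min; a bout ends only when
    ``max_gap_min`` or more consecutive sub-threshold minutes separate it from
    the next active minute.  Sub-threshold minutes inside a bout contribute
    their counts to the bout total.
    """
    x = np.nan_to_num(np.asarray(trace.per_minute().counts, dtype=float))
    idx = np.flatnonzero(x >= threshold)
    if len(idx) == 0:
        return []
    gap_after = np.diff(idx) - 1                  # quiet minutes between actives
    breaks = np.flatnonzero(gap_after >= max_gap_min)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks] + 1, [idx[-1] + 1]])
    return [ActivityBout(int(a), int(b), float(x[a:b].sum()))
            for a, b in zip(starts, ends)]


def count_activity_bouts(trace: ActivityTrace, threshold: float = 3.0,
                         max_gap_min: int = 21) -> float:
    """Fragmentation: mean number of activity bouts per day."""
    if trace.n_days < 1:
        raise ValueError("need at least one day of data")
    bouts = segment_activity_bouts(trace, threshold, max_gap_min)
    return len(bouts) / trace.n_days


# ---------------------------------------------------------------------------
# Phase-windowed activity
# ---------------------------------------------------------------------------

def windowed_activity(trace: ActivityTrace, zt_window=(0.0, 3.0),
                      n_days: int | None = None) -> float:
    """Mean daily total counts inside a ZT window (e.g. ZT0-3 light-phase
    activity).  Requires a schedule with a defined ZT frame."""
    if trace.schedule is None:
        raise ValueError("trace has no light schedule; ZT undefined")
    zt_a, zt_b = zt_window
    total_days = int(trace.n_days)
    if n_days is not None:
        total_days = min(total_days, n_days)
    if total_days < 1:
        raise ValueError("need at least one full day")
    ts = trace.timestamps()
    per_day = []
    for day in range(total_days):
        a = zt_to_abs(zt_a, day, trace.schedule)
        b = a + (zt_b - zt_a) * 60.0
        sel = (ts >= a) & (ts < b)
        vals = trace.counts[sel]
        per_day.append(np.nansum(vals))
    return float(np.mean(per_day))


def actogram_matrix(trace: ActivityTrace, period_h: float = 24.0,
                    double: bool = True) -> np.ndarray:
    """Raster of daily activity for plotting: one row per cycle, optionally
    double-plotted (each row holds two consecutive cycles)."""
    bins_per_cycle = int(round(period_h * 60.0 / trace.bin_min))
    n_cycles = trace.n_bins // bins_per_cycle
    m = trace.counts[: n_cycles * bins_per_cycle].reshape(n_cycles, bins_per_cycle)
    if not double:
        return m
    nxt = np.vstack([m[1:], np.full((1, bins_per_cycle), np.nan)])
    return np.hstack([m, nxt])
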