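"""The four photic-response assays: masking, re-entrainment, skeleton
photoperiod, and light-evoked phase shift.

Sign conventions
----------------
* Masking is reported as *percent suppression*,
  ``100 * (baseline - light) / baseline``: positive values mean light
  suppressed nocturnal activity.  (The raw percent-change formula
  ``(light - baseline)/baseline`` yields negative values under suppression;
  the sign is flipped so suppression reads positive.)
* Phase shifts are ``pre-line minus post-line`` on the day after the pulse:
  delays (onset moved later) are negative, advances positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .activity import OnsetSeries, onset_variability, windowed_activity
from .io import ActivityTrace, zt_to_abs
from .periodogram import chi2_periodogram

__all__ = [
    "PhoticAssayResult",
    "masking_suppression",
    "days_to_reentrain",
    "phase_shift",
    "spp_metrics",
    "NOT_REENTRAINED",
]

NOT_REENTRAINED = -1      # sentinel: criterion never met within the record


@dataclass
class PhoticAssayResult:
    assay: str                          # masking | reentrainment | spp | phase_shift
    value: float                        # percent, days, or minutes
    support: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)


def masking_suppression(trace: ActivityTrace, pulse_day: int,
                        zt_start: float = 14.0, duration_h: float = 1.0) -> PhoticAssayResult:
    """Photic suppression of nocturnal activity (negative masking).

    Counts during the light exposure (``zt_start`` for ``duration_h`` on
    ``pulse_day``) are compared with the same ZT hour on the preceding day:
    ``suppression % = 100 * (baseline - light) / baseline``.
    """
    if pulse_day < 1:
        raise ValueError("need a baseline day before the pulse day")
    ts = trace.timestamps()

    def window_counts(day: int) -> float:
        a = zt_to_abs(zt_start, day, trace.schedule)
        b = a + duration_h * 60.0
        return float(np.nansum(trace.counts[(ts >= a) & (ts < b)]))

    light = window_counts(pulse_day)
    baseline = window_counts(pulse_day - 1)
    if baseline == 0:
        return PhoticAssayResult("masking", float("nan"),
                                 {"baseline": 0.0, "light": light},
                                 flags=["undefined: zero baseline"])
    pct = 100.0 * (baseline - light) / baseline
    return PhoticAssayResult("masking", pct,
                             {"baseline": baseline, "light": light})


def days_to_reentrain(onsets: OnsetSeries, new_lights_off_min: float,
                      tol_min: float = 30.0, run: int = 5) -> PhoticAssayResult:
    """Days needed to re-entrain after an LD shift.

    ``onsets`` are the post-shift daily onsets (absolute minutes, day 0 = the
    first full cycle under the new schedule); ``new_lights_off_min`` is the
    new lights-off as time of day.  An animal is re-entrained on the first
    (1-based) day d such that the onset stays within ``tol_min`` of the new
    lights-off for ``run`` consecutive days.  Returns the sentinel
    ``NOT_REENTRAINED`` (-1) if the criterion is never met.
    """
    days, o = onsets.valid()
    if len(o) < run:
        raise ValueError(f"need at least {run} post-shift onsets")
    tod = o % 1440.0
    dev = np.abs(((tod - new_lights_off_min + 720.0) % 1440.0) - 720.0)
    aligned = dev <= tol_min
    # deviations on the full day grid (missing days break a run)
    grid = np.zeros(int(days.max()) + 1, dtype=bool)
    grid[days] = aligned
    for d in range(len(grid) - run + 1):
        if grid[d:d + run].all():
            return PhoticAssayResult("reentrainment", float(d + 1),
                                     {"deviation_min": dev.tolist(),
                                      "days": days.tolist()})
    return PhoticAssayResult("reentrainment", float(NOT_REENTRAINED),
                             {"deviation_min": dev.tolist(), "days": days.tolist()},
                             flags=["not re-entrained"])


def phase_shift(onsets_pre: OnsetSeries, onsets_post: OnsetSeries,
                pulse_day: float) -> PhoticAssayResult:
    """Light-evoked phase shift from pre/post onset regressions.

    Both series must be in the same absolute day/minute frame.  Best-fit lines
    through the pre-pulse and post-pulse onsets are evaluated on the day after
    the pulse; the shift is ``pre - post`` in minutes, so a delayed onset
    yields a negative value.
    """
    if onsets_pre.n_valid < 5 or onsets_post.n_valid < 5:
        raise ValueError("need at least 5 onsets on each side of the pulse")
    d_eval = pulse_day + 1.0
    pre = onsets_pre.fit()
    post = onsets_post.fit()
    shift = float(pre.predict(d_eval) - post.predict(d_eval))
    return PhoticAssayResult("phase_shift", shift,
                             {"pre": vars(pre), "post": vars(post),
                              "eval_day": d_eval})


def spp_metrics(trace: ActivityTrace, n_days: int = 10,
                start_day: int = 0) -> dict:
    """Rhythm metrics under a skeleton photoperiod.

    The two 1-h pulses span the subjective day ZT0-12; reported are the
    periodogram period and rhythmic power, the percentage of activity falling
    in the subjective day, and the onset variability.  A free-running animal
    (tau below the 24-h grid line) is flagged as not entrained.
    """
    from .activity import detect_onsets
    pg = chi2_periodogram(trace, n_days=n_days, start_day=start_day)
    day_counts = windowed_activity(trace, (0.0, 12.0))
    total = windowed_activity(trace, (0.0, 24.0))
    day_pct = 100.0 * day_counts / total if total else float("nan")
    onsets = detect_onsets(trace, expected_period_h=24.0)
    try:
        ov = onset_variability(onsets)
    except ValueError:
        ov = float("nan")
    entrained = (not pg.arrhythmic) and abs(pg.tau_h - 24.0) < 0.15
    return {"tau_h": pg.tau_h, "rhythmic_power": pg.rhythmic_power,
            "day_activity_pct": day_pct, "onset_variability_min": ov,
            "entrained": entrained, "arrhythmic": pg.arrhythmic}
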