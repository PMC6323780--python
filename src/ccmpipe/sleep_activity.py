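"""Sleep scoring and sleep/activity summaries.

Fly sleep is behaviorally defined: any run of at least 5 consecutive
minutes without a beam break counts as a sleep bout, and every minute
inside such a run is a sleep minute.  Weekly summaries include only
flies that survived the entire week; the full-life summary drops the
last three days of life, when moribund inactivity is indistinguishable
from sleep.  Activity and sleep profiles fold a week of data onto the
zeitgeber cycle (30-min bins over [0, T)) and average across flies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .dam_io import BeamBreakSeries, Cohort
from .schedule import LightSchedule

__all__ = [
    "SLEEP_MIN_MINUTES",
    "SleepSeries",
    "WeeklySummary",
    "ProfileBin",
    "CorrelationResult",
    "score_sleep",
    "weekly_sleep_summary",
    "weekly_activity_summary",
    "fulllife_summary",
    "activity_profile",
    "sleep_profile",
    "normalized_actogram",
    "correlate_sleep_longevity",
]

SLEEP_MIN_MINUTES = 5
MINUTES_PER_WEEK = 10080
HOURS_PER_WEEK = 168.0
LAST_DAYS_EXCLUDED_MINUTES = 3 * 1440


@dataclass
class SleepSeries:
    """Per-minute sleep flags plus the maximal bout list."""

    fly_id: str
    asleep: np.ndarray  # bool, aligned to the source BeamBreakSeries
    bouts: list[tuple[int, int]]  # (start index, length >= 5)


@dataclass
class WeeklySummary:
    fly_id: str
    week: int  # 1-based
    included: bool  # fly survived the entire week
    sleep_min_per_hr: Optional[float] = None
    activity_counts_per_min: Optional[float] = None


@dataclass
class ProfileBin:
    zt_start_hours: float
    mean: float
    sem: float
    n: int


@dataclass
class CorrelationResult:
    rho: float
    ci: tuple[float, float]
    p: float
    n: int


def score_sleep(series: BeamBreakSeries) -> SleepSeries:
    """Mark every minute inside a >=5-min zero-count run as sleep.

    The series should already be ghost-filtered and truncated at the
    called death: minutes after death are neither sleep nor wake.
    """
    counts = series.counts
    asleep = np.zeros(len(counts), dtype=bool)
    bouts: list[tuple[int, int]] = []
    # run-length scan over the zero/nonzero partition
    is_zero = counts == 0
    boundaries = np.flatnonzero(np.diff(is_zero.astype(np.int8))) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(counts)]))
    for s, e in zip(starts, ends):
        if is_zero[s] and e - s >= SLEEP_MIN_MINUTES:
            asleep[s:e] = True
            bouts.append((int(s), int(e - s)))
    return SleepSeries(fly_id=series.fly_id, asleep=asleep, bouts=bouts)


def _week_window(week: int) -> tuple[int, int]:
    if week < 1:
        raise ValueError("weeks are 1-based")
    start = (week - 1) * MINUTES_PER_WEEK
    return start, start + MINUTES_PER_WEEK


def weekly_sleep_summary(
    series: BeamBreakSeries, week: int, lifespan_minutes: int
) -> WeeklySummary:
    """Mean sleep (min/hr) over one calendar week, for week survivors only."""
    start, end = _week_window(week)
    if lifespan_minutes < end or len(series) < end:
        return WeeklySummary(series.fly_id, week, included=False)
    sleep = score_sleep(series)
    total = int(sleep.asleep[start:end].sum())
    return WeeklySummary(
        series.fly_id, week, included=True, sleep_min_per_hr=total / HOURS_PER_WEEK
    )


def weekly_activity_summary(
    series: BeamBreakSeries, week: int, lifespan_minutes: int
) -> WeeklySummary:
    """Mean beam breaks/min over one calendar week, for week survivors only."""
    start, end = _week_window(week)
    if lifespan_minutes < end or len(series) < end:
        return WeeklySummary(series.fly_id, week, included=False)
    total = int(series.counts[start:end].sum())
    return WeeklySummary(
        series.fly_id,
        week,
        included=True,
        activity_counts_per_min=total / MINUTES_PER_WEEK,
    )


def fulllife_summary(
    series: BeamBreakSeries, lifespan_minutes: int
) -> tuple[float, float]:
    """(sleep min/hr, counts/min) over life excluding the final three days.

    Moribund flies barely move, which would be scored as sleep; the
    window is therefore [0, lifespan - 3 days).  Lifespans of 3 days or
    less leave no window and raise ``ValueError``.
    """
    end = lifespan_minutes - LAST_DAYS_EXCLUDED_MINUTES
    if end <= 0:
        raise ValueError(
            f"fly {series.fly_id}: lifespan <= 3 days; full-life metrics undefined"
        )
    sleep = score_sleep(series)
    hours = end / 60.0
    sleep_rate = float(sleep.asleep[:end].sum()) / hours
    activity_rate = float(series.counts[:end].sum()) / end
    return sleep_rate, activity_rate


# ---------------------------------------------------------------------------
# ZT-folded profiles


def _fold_week(
    values: np.ndarray,
    series: BeamBreakSeries,
    schedule: LightSchedule,
    week: int,
    bin_minutes: int,
    offset_hours: float,
) -> np.ndarray:
    """Per-ZT-bin mean of *values* across the week's complete cycles."""
    epoch = schedule.epoch_at(series.origin)
    period_min = int(round(epoch.period_hours * 60))
    n_cycles = int(HOURS_PER_WEEK * 60) // period_min
    start, _ = _week_window(week)
    start += int(offset_hours * 60)
    end = start + n_cycles * period_min
    if end > len(values):
        raise ValueError("series too short for the requested week window")
    window = values[start:end].astype(float)
    anchor_min = (epoch.zt0_anchor - series.origin).total_seconds() / 60.0
    minute_idx = np.arange(start, end)
    zt_min = np.mod(minute_idx - anchor_min, period_min)
    bins = (zt_min // bin_minutes).astype(int)
    n_bins = period_min // bin_minutes
    sums = np.bincount(bins, weights=window, minlength=n_bins)
    ns = np.bincount(bins, minlength=n_bins)
    return sums / ns


def _across_fly_bins(
    per_fly: list[np.ndarray], bin_minutes: int
) -> list[ProfileBin]:
    if not per_fly:
        return []
    mat = np.vstack(per_fly)
    mean = mat.mean(axis=0)
    n = mat.shape[0]
    sem = mat.std(axis=0, ddof=1) / math.sqrt(n) if n > 1 else np.zeros_like(mean)
    return [
        ProfileBin(
            zt_start_hours=i * bin_minutes / 60.0,
            mean=float(mean[i]),
            sem=float(sem[i]),
            n=n,
        )
        for i in range(mat.shape[1])
    ]


def activity_profile(
    cohort: Cohort,
    week: int,
    treatment: str,
    lifespans: Mapping[str, int],
    bin_minutes: int = 30,
    offset_hours: float = 0.0,
) -> list[ProfileBin]:
    """Mean beam breaks/min per 30-min ZT bin, averaged across a week.

    Each surviving fly's counts are folded over the week's complete
    cycles (7 for T = 24 h, 6 for T = 28 h), then averaged across flies
    (mean +/- SEM, n = flies).  A T = 28 h schedule yields 56 bins
    spanning ZT 0-28.
    """
    per_fly = []
    schedule = cohort.schedules[treatment]
    _, week_end = _week_window(week)
    for fid, (series, meta) in cohort.included(treatment).items():
        if lifespans.get(fid, -1) < week_end:
            continue
        per_fly.append(
            _fold_week(series.counts, series, schedule, week, bin_minutes, offset_hours)
        )
    return _across_fly_bins(per_fly, bin_minutes)


def sleep_profile(
    cohort: Cohort,
    week: int,
    treatment: str,
    lifespans: Mapping[str, int],
    bin_minutes: int = 30,
    offset_hours: float = 0.0,
) -> list[ProfileBin]:
    """Mean sleep minutes per 30-min ZT bin (0-30), averaged as above."""
    per_fly = []
    schedule = cohort.schedules[treatment]
    _, week_end = _week_window(week)
    for fid, (series, meta) in cohort.included(treatment).items():
        if lifespans.get(fid, -1) < week_end:
            continue
        asleep = score_sleep(series).asleep.astype(float)
        folded = _fold_week(asleep, series, schedule, week, bin_minutes, offset_hours)
        per_fly.append(folded * bin_minutes)  # sleep min per bin
    return _across_fly_bins(per_fly, bin_minutes)


def normalized_actogram(
    series_list: Sequence[BeamBreakSeries],
    window: tuple[int, int],
) -> np.ndarray:
    """Mean normalized activity in 24-h rows over *window* (minute indices).

    Each fly's minute counts are divided by that fly's window mean (so
    the result is scale-invariant per fly), averaged across flies, and
    reshaped into single-plotted 24-h lines.  Flies with zero activity
    in the window are excluded.  The window length must be a whole
    number of days.
    """
    start, end = window
    n = end - start
    if n <= 0 or n % 1440:
        raise ValueError("window must span a positive whole number of days")
    rows = []
    for series in series_list:
        seg = series.counts[start:end].astype(float)
        m = seg.mean()
        if m == 0:
            continue
        rows.append(seg / m)
    if not rows:
        raise ValueError("no flies with nonzero activity in window")
    mean = np.vstack(rows).mean(axis=0)
    return mean.reshape(n // 1440, 1440)


# ---------------------------------------------------------------------------
# sleep-longevity correlation


def correlate_sleep_longevity(
    sleep_min_per_hr: Mapping[str, float],
    lifespan_days: Mapping[str, float],
) -> CorrelationResult:
    """Spearman rank correlation between early-life sleep and lifespan.

    The 95% CI uses the Fisher z transform with SE 1/sqrt(n - 3); an
    approximation, but adequate at cohort sizes.  Constant inputs have
    degenerate ranks and raise ``ValueError``.
    """
    common = sorted(set(sleep_min_per_hr) & set(lifespan_days))
    if len(common) < 4:
        raise ValueError("need at least 4 flies with both sleep and lifespan")
    x = np.array([sleep_min_per_hr[f] for f in common])
    y = np.array([lifespan_days[f] for f in common])
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("constant input; rank correlation undefined")
    rho, p = stats.spearmanr(x, y)
    n = len(common)
    z = np.arctanh(np.clip(rho, -1 + 1e-15, 1 - 1e-15))
    half = 1.959963984540054 / math.sqrt(n - 3)
    ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    return CorrelationResult(rho=float(rho), ci=ci, p=float(p), n=n)
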