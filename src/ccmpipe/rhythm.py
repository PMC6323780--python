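"""Chi-squared periodogram (Sokolove-Bushell) rhythm analysis.

For each integer trial period P (minutes) the N-bin series is folded
into P phase columns with means ``M_h``, each covered by ``n_h`` rows
(unequal when the final cycle is partial); the statistic is

    Q(P) = N * sum_h n_h * (M_h - M)^2 / sum_i (x_i - M)^2

with ``M`` the grand mean, i.e. the between-column sum of squares over
the plug-in variance estimate.  Under the null of no rhythm, Q(P) is
approximately chi-squared with P - 1 degrees of freedom, giving a
per-period significance line.  The dominant period is the argmax of Q
over the searched range, and rhythm power is Q at the dominant period
minus the significance line there (alpha = 0.01): a positive power
marks a significantly rhythmic fly, and the signed value serves as a
continuous per-fly index of rhythm strength either way.

Partial final cycles are kept: a column's mean uses however many rows
cover it, so unequal column counts are allowed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dam_io import BeamBreakSeries
from .schedule import LightSchedule

__all__ = [
    "PeriodogramResult",
    "chi2_periodogram",
    "weekly_ld_rhythm",
    "dd_rhythm",
]

MINUTES_PER_DAY = 1440
MINUTES_PER_WEEK = 10080
LD_SEARCH_HOURS = (16.0, 36.0)  # brackets both 24-h and 28-h entrainment
DD_SEARCH_HOURS = (18.0, 31.0)


@dataclass
class PeriodogramResult:
    periods: np.ndarray  # trial periods, minutes
    q: np.ndarray  # Q statistic per trial period
    significance: np.ndarray  # chi2 quantile(1 - alpha, P - 1) per period
    dominant_period: int  # minutes; smallest P on ties
    power: float  # Q(dominant) - significance(dominant)
    alpha: float

    @property
    def rhythmic(self) -> bool:
        return self.power > 0


def chi2_periodogram(
    series: BeamBreakSeries,
    period_range_minutes: tuple[int, int],
    alpha: float = 0.01,
) -> PeriodogramResult:
    """Q statistic over every integer trial period in the given range.

    Requires the series to span at least twice the longest trial period
    and to have nonzero variance.
    """
    x = series.counts.astype(float)
    n = x.size
    p_lo, p_hi = int(period_range_minutes[0]), int(period_range_minutes[1])
    if p_lo < 2 or p_hi < p_lo:
        raise ValueError(f"invalid period range {period_range_minutes}")
    if n < 2 * p_hi:
        raise ValueError(
            f"series length {n} min is shorter than twice the longest trial "
            f"period ({p_hi} min)"
        )
    grand_mean = x.mean()
    denom = float(((x - grand_mean) ** 2).sum())
    if denom == 0.0:
        raise ValueError("series has zero variance; periodogram undefined")

    periods = np.arange(p_lo, p_hi + 1)
    q = np.empty(periods.size)
    phase = np.arange(n)
    for j, p in enumerate(periods):
        cols = phase % p
        col_sums = np.bincount(cols, weights=x, minlength=p)
        col_ns = np.bincount(cols, minlength=p)
        col_means = col_sums / col_ns
        q[j] = n * float((col_ns * (col_means - grand_mean) ** 2).sum()) / denom
    significance = stats.chi2.ppf(1.0 - alpha, periods - 1)
    best = int(np.argmax(q))  # argmax returns the first (smallest P) on ties
    return PeriodogramResult(
        periods=periods,
        q=q,
        significance=significance,
        dominant_period=int(periods[best]),
        power=float(q[best] - significance[best]),
        alpha=alpha,
    )


def weekly_ld_rhythm(
    series: BeamBreakSeries,
    week: int,
    lifespan_minutes: int,
    search_hours: tuple[float, float] = LD_SEARCH_HOURS,
    alpha: float = 0.01,
) -> PeriodogramResult:
    """Periodogram over one calendar week of LD data (week survivors only).

    The default search range brackets both the 24-h control and the
    28-h misalignment cycle so the dominant period is free to land on
    either.
    """
    if week < 1:
        raise ValueError("weeks are 1-based")
    start = (week - 1) * MINUTES_PER_WEEK
    end = start + MINUTES_PER_WEEK
    if lifespan_minutes < end or len(series) < end:
        raise ValueError(
            f"fly {series.fly_id} did not survive week {week}; excluded from rhythm analysis"
        )
    sub = BeamBreakSeries(
        fly_id=series.fly_id, origin=series.origin, counts=series.counts[start:end]
    )
    rng = (int(search_hours[0] * 60), int(search_hours[1] * 60))
    return chi2_periodogram(sub, rng, alpha=alpha)


def dd_rhythm(
    series: BeamBreakSeries,
    schedule: LightSchedule,
    search_hours: tuple[float, float] = DD_SEARCH_HOURS,
    alpha: float = 0.01,
    exclude_first_day: bool = True,
) -> PeriodogramResult:
    """Free-running periodogram over the constant-darkness epoch.

    Transfer between LD and DD incubators perturbs behavior, so the
    first 24 h of DD are excluded; at least 6 further days of DD data
    are required.
    """
    dd_epochs = [e for e in schedule.epochs if e.mode == "DD"]
    if not dd_epochs:
        raise ValueError("schedule has no DD epoch")
    dd_start_minute = series.minute_of(dd_epochs[0].start)
    if dd_start_minute < 0:
        dd_start_minute = 0
    start = dd_start_minute + (MINUTES_PER_DAY if exclude_first_day else 0)
    available = len(series) - start
    if available < 6 * MINUTES_PER_DAY:
        raise ValueError(
            f"only {available / MINUTES_PER_DAY:.1f} DD days available after "
            "exclusion; need at least 6"
        )
    sub = BeamBreakSeries(
        fly_id=series.fly_id, origin=series.origin, counts=series.counts[start:]
    )
    rng = (int(search_hours[0] * 60), int(search_hours[1] * 60))
    return chi2_periodogram(sub, rng, alpha=alpha)
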