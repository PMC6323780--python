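"""Death calling and survival analysis.

The DAM system cannot observe death directly; a fly's lifespan is the
last minute in which it broke the beam.  Before that call, isolated
"ghost" counts — single beam breaks more than 12 h away from any other
activity, a known sensor artifact — are removed so they cannot inflate
lifespan.  Survival comparisons use Kaplan-Meier curves, the log-rank
test, and Cox proportional-hazards models (via ``lifelines``), plus the
sleep-matched cohort construction used to separate the effect of a
treatment from the effect of the sleep loss it causes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import median_survival_times

from .dam_io import BeamBreakSeries

__all__ = [
    "LifespanRecord",
    "SurvivalFit",
    "HazardModel",
    "CovariateEffect",
    "MatchedSet",
    "GHOST_GAP_MINUTES",
    "filter_ghosts",
    "call_death",
    "km_fit",
    "logrank_test",
    "cox_fit",
    "sleep_match",
    "percent_median_reduction",
    "hazard_percent",
    "equivalent_sleep_loss",
]

GHOST_GAP_MINUTES = 720  # ">12 h" isolation threshold, in 1-min bins
MINUTES_PER_DAY = 1440.0


@dataclass
class LifespanRecord:
    fly_id: str
    lifespan_minutes: int
    event: bool = True  # death observed (censoring supported for generality)
    ghost_bins_removed: list[int] = field(default_factory=list)

    @property
    def lifespan_days(self) -> float:
        return self.lifespan_minutes / MINUTES_PER_DAY


@dataclass
class SurvivalFit:
    """Kaplan-Meier product-limit fit with Greenwood/log-log 95% CIs."""

    times: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    median: float  # inf when survival never reaches 0.5
    median_ci: tuple[float, float]
    n: int


@dataclass
class CovariateEffect:
    name: str
    coef: float
    hazard_ratio: float
    ci_lower: float
    ci_upper: float
    p: float


@dataclass
class HazardModel:
    effects: list[CovariateEffect]
    model_type: str  # "univariate" | "multivariate"
    n: int
    n_events: int

    def __getitem__(self, name: str) -> CovariateEffect:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)


@dataclass
class MatchedSet:
    pairs: list[tuple[str, str]]  # (control fly, CCM fly)
    tolerance: float

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# ghost filtering and death calling


def filter_ghosts(
    series: BeamBreakSeries, gap_minutes: int = GHOST_GAP_MINUTES
) -> tuple[BeamBreakSeries, list[int]]:
    """Zero out isolated post-gap activity bins; return (filtered, ghost bins).

    A nonzero bin is a ghost iff the nearest *retained* nonzero bin
    before it is more than ``gap_minutes`` earlier AND the nearest
    nonzero bin after it is more than ``gap_minutes`` later (or absent).
    The scan runs left to right, so a bin following a just-removed ghost
    is judged against the last retained activity — a burst of several
    counts within the gap window protects all of them ("isolated" means
    truly alone).  The first activity of the record is always retained:
    with no prior activity there is no death for it to post-date.
    """
    counts = series.counts
    nonzero = np.flatnonzero(counts)
    ghosts: list[int] = []
    last_retained: Optional[int] = None
    for k, i in enumerate(nonzero):
        i = int(i)
        nxt = int(nonzero[k + 1]) if k + 1 < len(nonzero) else None
        isolated_before = last_retained is not None and i - last_retained > gap_minutes
        isolated_after = nxt is None or nxt - i > gap_minutes
        if isolated_before and isolated_after:
            ghosts.append(i)
        else:
            last_retained = i
    if not ghosts:
        return series, []
    filtered = counts.copy()
    filtered[ghosts] = 0
    return (
        BeamBreakSeries(fly_id=series.fly_id, origin=series.origin, counts=filtered),
        ghosts,
    )


def call_death(series: BeamBreakSeries, ghost_bins: Sequence[int] = ()) -> LifespanRecord:
    """Lifespan = index (minutes since origin) of the last nonzero bin.

    Expects a ghost-filtered series.  An all-zero series carries no
    evidence the fly was ever alive and raises ``ValueError``.
    """
    nonzero = np.flatnonzero(series.counts)
    if nonzero.size == 0:
        raise ValueError(f"fly {series.fly_id}: no beam breaks; cannot call death")
    return LifespanRecord(
        fly_id=series.fly_id,
        lifespan_minutes=int(nonzero[-1]),
        event=True,
        ghost_bins_removed=list(ghost_bins),
    )


# ---------------------------------------------------------------------------
# survival statistics


def km_fit(durations: Sequence[float], events: Optional[Sequence[bool]] = None) -> SurvivalFit:
    """Kaplan-Meier estimate with 95% CIs and median survival time.

    The median is the smallest time at which estimated survival drops to
    0.5 or below; it is ``inf`` (flagged undefined) if survival never
    does, e.g. when too many observations are censored.
    """
    durations = np.asarray(durations, dtype=float)
    if durations.size == 0:
        raise ValueError("need at least one observation")
    if events is None:
        events = np.ones_like(durations, dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=np.asarray(events, dtype=bool))
    sf = kmf.survival_function_
    ci = kmf.confidence_interval_
    med_ci = median_survival_times(ci)
    return SurvivalFit(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(dtype=float),
        ci_lower=ci.iloc[:, 0].to_numpy(dtype=float),
        ci_upper=ci.iloc[:, 1].to_numpy(dtype=float),
        median=float(kmf.median_survival_time_),
        median_ci=(float(med_ci.iloc[0, 0]), float(med_ci.iloc[0, 1])),
        n=int(durations.size),
    )


def logrank_test(
    durations_a: Sequence[float],
    durations_b: Sequence[float],
    events_a: Optional[Sequence[bool]] = None,
    events_b: Optional[Sequence[bool]] = None,
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p), 1 df."""
    a = np.asarray(durations_a, dtype=float)
    b = np.asarray(durations_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ev_a = np.ones_like(a, dtype=bool) if events_a is None else np.asarray(events_a, bool)
    ev_b = np.ones_like(b, dtype=bool) if events_b is None else np.asarray(events_b, bool)
    res = _ll_logrank(a, b, event_observed_A=ev_a, event_observed_B=ev_b)
    return float(res.test_statistic), float(res.p_value)


def cox_fit(
    durations: Sequence[float],
    events: Sequence[bool],
    covariates: pd.DataFrame | Mapping[str, Sequence[float]],
) -> HazardModel:
    """Cox proportional-hazards fit (Efron handling of tied event times).

    Day-resolution lifespans are heavily tied, so the Efron partial
    likelihood is used throughout.  Hazard ratios are ``exp(coef)`` with
    Wald 95% CIs and p-values.  A covariate with fewer than two distinct
    values is unidentifiable and raises ``ValueError`` up front.
    """
    cov = pd.DataFrame(covariates).reset_index(drop=True)
    for name in cov.columns:
        if cov[name].nunique() < 2:
            raise ValueError(f"covariate {name!r} is constant; hazard ratio unidentifiable")
    df = cov.copy()
    df["duration"] = np.asarray(durations, dtype=float)
    df["event"] = np.asarray(events, dtype=bool)
    if not df["event"].any():
        raise ValueError("no events observed; cannot fit a hazard model")
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="duration", event_col="event")
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        raise ValueError(f"Cox model failed to converge: {exc}") from exc
    summary = cph.summary
    effects = [
        CovariateEffect(
            name=str(name),
            coef=float(row["coef"]),
            hazard_ratio=float(row["exp(coef)"]),
            ci_lower=float(np.exp(row["coef lower 95%"])),
            ci_upper=float(np.exp(row["coef upper 95%"])),
            p=float(row["p"]),
        )
        for name, row in summary.iterrows()
    ]
    return HazardModel(
        effects=effects,
        model_type="univariate" if len(effects) == 1 else "multivariate",
        n=len(df),
        n_events=int(df["event"].sum()),
    )


# ---------------------------------------------------------------------------
# sleep matching


def sleep_match(
    control_sleep: Mapping[str, float],
    ccm_sleep: Mapping[str, float],
    tolerance: float = 0.5,
) -> MatchedSet:
    """Pair each control fly with a CCM fly of similar sleep time.

    Greedy without-replacement matching: controls are processed in order
    of sleep time (ties by fly id); each takes the nearest unmatched CCM
    fly within *tolerance* (min/hr), nearer-then-lower-id on ties.
    Unmatched flies on either side are dropped.  Deterministic by
    construction.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    remaining = dict(ccm_sleep)
    pairs: list[tuple[str, str]] = []
    for cid, cs in sorted(control_sleep.items(), key=lambda kv: (kv[1], kv[0])):
        best = min(
            (
                (abs(ms - cs), mid)
                for mid, ms in remaining.items()
                if abs(ms - cs) <= tolerance
            ),
            default=None,
        )
        if best is not None:
            pairs.append((cid, best[1]))
            del remaining[best[1]]
    return MatchedSet(pairs=pairs, tolerance=tolerance)


# ---------------------------------------------------------------------------
# worked-example arithmetic on printed statistics


def _round_half_up(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent_median_reduction(ctrl_median_days: float, ccm_median_days: float) -> float:
    """Percent reduction in median lifespan, rounded half-up to one decimal."""
    if ctrl_median_days <= 0:
        raise ValueError("control median must be > 0")
    pct = 100.0 * (ctrl_median_days - ccm_median_days) / ctrl_median_days
    return _round_half_up(pct, 1)


def hazard_percent(hazard_ratio: float) -> int:
    """Signed percent change in instantaneous death risk implied by an HR.

    HR 1.94 -> +94 ("94% more likely to die at any point in time");
    HR 0.74 -> -26.
    """
    if hazard_ratio <= 0:
        raise ValueError("hazard ratio must be > 0")
    return int(_round_half_up(100.0 * (hazard_ratio - 1.0), 0))


def equivalent_sleep_loss(hr_treatment: float, hr_sleep_per_hour: float) -> float:
    """Hours of lost daily sleep carrying the same hazard as the treatment.

    Solves ``hr_sleep_per_hour ** (-h) = hr_treatment`` for ``h``; with
    the multivariate HRs 1.49 (treatment) and 0.77 (per hour of daily
    sleep) this is ~1.5 h.  Requires sleep to be protective (HR < 1).
    """
    if hr_sleep_per_hour >= 1.0 or hr_sleep_per_hour <= 0.0:
        raise ValueError("sleep hazard ratio must be in (0, 1) (protective)")
    if hr_treatment <= 0:
        raise ValueError("treatment hazard ratio must be > 0")
    hours = math.log(hr_treatment) / (-math.log(hr_sleep_per_hour))
    return _round_half_up(hours, 1)
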