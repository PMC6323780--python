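"""Synthetic DAM cohorts with known ground truth.

Each fly's minute-by-minute behavior is a two-state (active/rest) Markov
chain whose stationary rest probability follows the light schedule:
consolidated night rest, a midday siesta, and anticipation ramps that
begin a fixed lag after the previous lighting transition.  On top of
the chain, sharp clock-driven morning and evening activity peaks
(asymmetric in size, as in real flies) fire at dawn and dusk — at the
subjective phases of the internal clock when the fly free-runs in
darkness — which is what phase-locks the record tightly enough for a
periodogram to recover the cycle length to the minute.  Active minutes
emit Poisson-distributed beam breaks; rest minutes emit none.  The
two-state structure (rather than a pure inhomogeneous Poisson process)
produces rest bouts long enough to be scored as sleep at realistic
frequencies.

Mortality is Gompertz with a proportional-hazards treatment effect, so
the programmed median lifespan has a closed form and a Cox fit on a
simulated cohort should recover the programmed hazard ratio.  After
death the record is silent except for optional "ghost" counts — rare
isolated beam breaks long after the last real activity, mimicking the
sensor artifact that death-calling must filter out.

All randomness flows from integer seeds through ``numpy`` Generator
streams; per-fly streams are derived from (master seed, fly index) so a
cohort is reproducible regardless of simulation order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from datetime import timedelta
from typing import Optional

import numpy as np
from numba import njit

from .dam_io import BeamBreakSeries, Cohort, FlyMeta
from .schedule import Epoch, LightSchedule

logger = logging.getLogger(__name__)

__all__ = [
    "SimParams",
    "SimFly",
    "simulate_fly",
    "simulate_cohort",
    "inject_ghosts",
    "gompertz_median_days",
    "rest_probability",
]

MINUTES_PER_DAY = 1440
MINUTES_PER_WEEK = 10080


@dataclass(frozen=True)
class SimParams:
    """Generative parameters for one simulated cohort.

    Rates are per minute, times in hours unless noted.  Defaults give a
    moderately rhythmic fly sleeping ~30-40 min/hr overall, a control
    median lifespan of ~23 days, and a CCM hazard ratio of 1.94.
    """

    baseline_rate: float = 3.0  # expected beam breaks/min while active
    day_rest: float = 0.50  # stationary rest probability in daytime
    night_rest: float = 0.92  # ... at night (flies are near-silent at night)
    siesta_rest: float = 0.85  # ... during the midday siesta
    siesta_halfwidth_h: float = 1.5  # siesta spans photoperiod midpoint +/- this
    anticipation_lag_h: float = 8.5  # ramp onset after the previous transition
    anticipation_depth: float = 0.85  # fractional rest suppression at transition
    persistence_minutes: float = 8.0  # switching time scale; sets bout lengths
    morning_peak_rate: float = 6.0  # extra counts/min in the morning activity peak
    evening_peak_rate: float = 2.5  # ... in the evening peak (asymmetric on purpose)
    peak_width_min: float = 20.0  # duration of each clock-driven peak
    rhythm_amplitude: float = 1.0  # week-0 scale of the rhythmic component
    amplitude_decay: float = 0.8  # per-week multiplier on that scale
    internal_period_h: float = 24.0  # free-running period expressed in DD
    gompertz_a: float = 0.0034  # baseline hazard per day at age 0
    gompertz_b: float = 0.15  # hazard growth rate per day
    treatment_log_hr: float = math.log(1.94)  # log hazard ratio for CCM flies
    ghost_prob: float = 0.05  # per-fly chance of one post-mortem ghost count

    def __post_init__(self) -> None:
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        for name in ("day_rest", "night_rest", "siesta_rest", "ghost_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.gompertz_b <= 0:
            raise ValueError("gompertz_b must be > 0")
        if self.persistence_minutes < 1:
            raise ValueError("persistence_minutes must be >= 1")


@dataclass
class SimFly:
    """A simulated fly: its series, ground-truth death, and metadata.

    ``true_death_minute`` is the bin of the last genuine beam break (the
    quantity death-calling should recover); ``biological_death_minute``
    is the sampled Gompertz event after which the fly emits nothing.
    Counts after ``true_death_minute`` are zero except injected ghosts.
    """

    series: BeamBreakSeries
    true_death_minute: int
    meta: FlyMeta
    biological_death_minute: int
    ghost_minute: Optional[int] = None


# ---------------------------------------------------------------------------
# rest-probability landscape


def rest_probability(
    zt_hours: np.ndarray,
    period_h: float,
    photoperiod_h: float,
    params: SimParams,
    amplitude: float = 1.0,
) -> np.ndarray:
    """Stationary rest probability as a function of zeitgeber time.

    Builds the cycle shape (night rest, siesta, anticipation ramps
    starting ``anticipation_lag_h`` after the previous lights-on/off
    transition) and shrinks it toward its cycle mean by ``amplitude``
    in [0, 1], which is how age-related rhythm decline is modeled.
    """
    zt = np.asarray(zt_hours, dtype=float)
    day = zt < photoperiod_h
    shape = np.where(day, params.day_rest, params.night_rest)
    mid = photoperiod_h / 2.0
    shape = np.where(
        day & (np.abs(zt - mid) < params.siesta_halfwidth_h), params.siesta_rest, shape
    )
    # anticipation: within each light segment, rest falls off linearly once
    # the lag has elapsed, bottoming out at the next transition
    since_transition = np.where(day, zt, zt - photoperiod_h)
    segment_len = np.where(day, photoperiod_h, period_h - photoperiod_h)
    ramp_len = np.maximum(segment_len - params.anticipation_lag_h, 1e-9)
    w = np.clip((since_transition - params.anticipation_lag_h) / ramp_len, 0.0, 1.0)
    shape = shape * (1.0 - params.anticipation_depth * w)

    amplitude = float(np.clip(amplitude, 0.0, 1.0))
    mean = shape.mean()
    return np.clip(mean + amplitude * (shape - mean), 0.0, 1.0)


def _peak_rate(
    zt_hours: np.ndarray, photoperiod_h: float, params: SimParams
) -> np.ndarray:
    """Extra Poisson rate from the clock-driven morning/evening peaks."""
    zt = np.asarray(zt_hours, dtype=float)
    width_h = params.peak_width_min / 60.0
    rate = np.zeros_like(zt)
    rate[zt < width_h] = params.morning_peak_rate
    rate[(zt >= photoperiod_h) & (zt < photoperiod_h + width_h)] = params.evening_peak_rate
    return rate


def _minute_curves(
    params: SimParams, schedule: LightSchedule, n_minutes: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-minute (stationary rest probability, peak rate) over the horizon."""
    start = schedule.start
    minutes = np.arange(n_minutes, dtype=float)
    out = np.empty(n_minutes, dtype=float)
    peaks = np.empty(n_minutes, dtype=float)
    for k, epoch in enumerate(schedule.epochs):
        lo = max(int((epoch.start - start).total_seconds() // 60), 0)
        if k + 1 < len(schedule.epochs):
            hi = min(int((schedule.epochs[k + 1].start - start).total_seconds() // 60), n_minutes)
        else:
            hi = n_minutes
        if hi <= lo:
            continue
        seg_minutes = minutes[lo:hi]
        if epoch.mode == "LD":
            anchor_min = (epoch.zt0_anchor - start).total_seconds() / 60.0
            zt = ((seg_minutes - anchor_min) / 60.0) % epoch.period_hours
            period, photoperiod = epoch.period_hours, epoch.photoperiod_hours
        else:
            # free-run: subjective cycle at the internal period, phase
            # continued proportionally from entrainment at DD onset
            tau = params.internal_period_h
            prior = schedule.epochs[k - 1] if k > 0 else None
            if prior is not None and prior.mode == "LD":
                zt_onset = schedule.zt_of(epoch.start - timedelta(minutes=1))
                phase0 = zt_onset / prior.period_hours * tau
            else:
                phase0 = 0.0
            hours_in_dd = (seg_minutes - lo) / 60.0
            zt = (phase0 + hours_in_dd) % tau
            period, photoperiod = tau, tau / 2.0
        week = np.floor(seg_minutes / MINUTES_PER_WEEK)
        amp = np.clip(
            params.rhythm_amplitude * params.amplitude_decay**week, 0.0, 1.0
        )
        # amplitude varies by week; evaluate shape once, rescale per minute
        base = rest_probability(zt, period, photoperiod, params, amplitude=1.0)
        mean = base.mean()
        out[lo:hi] = np.clip(mean + amp * (base - mean), 0.0, 1.0)
        peaks[lo:hi] = amp * _peak_rate(zt, photoperiod, params)
    return out, peaks


# ---------------------------------------------------------------------------
# mortality


def gompertz_median_days(a: float, b: float, hazard_ratio: float = 1.0) -> float:
    """Closed-form median of a Gompertz lifetime with hazard ``a*hr*exp(b*t)``."""
    return math.log1p(b * math.log(2.0) / (a * hazard_ratio)) / b


def _draw_death_day(params: SimParams, is_ccm: bool, rng: np.random.Generator) -> float:
    hr = math.exp(params.treatment_log_hr) if is_ccm else 1.0
    e = rng.exponential()  # -log U
    return math.log1p(params.gompertz_b * e / (params.gompertz_a * hr)) / params.gompertz_b


# ---------------------------------------------------------------------------
# the activity chain


@njit(cache=False)
def _run_chain(enter_rest: np.ndarray, exit_rest: np.ndarray, u: np.ndarray, start_active: bool):
    """Sequential two-state chain; returns 1 where the fly is active."""
    n = u.shape[0]
    active = np.empty(n, dtype=np.uint8)
    s = 1 if start_active else 0
    for i in range(n):
        if s == 1:
            if u[i] < enter_rest[i]:
                s = 0
        else:
            if u[i] < exit_rest[i]:
                s = 1
        active[i] = s
    return active


def simulate_fly(
    params: SimParams,
    schedule: LightSchedule,
    meta: FlyMeta,
    seed: int,
    horizon_days: float = 40.0,
) -> SimFly:
    """Simulate one fly's full per-minute record.

    Deterministic given *seed*.  The chain's per-minute switching
    probabilities are ``p/tau`` into rest and ``(1-p)/tau`` out of rest,
    with ``p`` the stationary rest probability for that minute and
    ``tau = persistence_minutes``, so mean rest-bout length is roughly
    ``tau / (1 - p)`` minutes.
    """
    if horizon_days < 1.0:
        raise ValueError("simulation horizon must be at least 1 day")
    n_minutes = int(round(horizon_days * MINUTES_PER_DAY))
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF]))

    death_day = _draw_death_day(params, meta.treatment == "CCM", rng)
    biological_death = min(int(death_day * MINUTES_PER_DAY), n_minutes)

    counts = np.zeros(n_minutes, dtype=np.int64)
    if biological_death > 0:
        p, peaks = _minute_curves(params, schedule, biological_death)
        tau = params.persistence_minutes
        enter_rest = np.clip(p / tau, 0.0, 1.0)
        exit_rest = np.clip((1.0 - p) / tau, 0.0, 1.0)
        u = rng.random(biological_death)
        active = _run_chain(enter_rest, exit_rest, u, True)
        idx = np.flatnonzero(active)
        if params.baseline_rate > 0 and idx.size:
            counts[idx] = rng.poisson(params.baseline_rate, idx.size)
        pk = np.flatnonzero(peaks)
        if pk.size:
            counts[pk] += rng.poisson(peaks[pk])

    nonzero = np.flatnonzero(counts)
    true_death = int(nonzero[-1]) if nonzero.size else 0
    series = BeamBreakSeries(fly_id=meta.fly_id, origin=schedule.start, counts=counts)
    return SimFly(
        series=series,
        true_death_minute=true_death,
        meta=meta,
        biological_death_minute=biological_death,
    )


def inject_ghosts(fly: SimFly, params: SimParams, seed: int) -> SimFly:
    """Possibly add one isolated post-mortem count to a simulated fly.

    With probability ``ghost_prob`` a single count of 1 is placed at a
    uniformly drawn minute more than 12 h after ``true_death_minute``.
    If the record ends within 12 h of death no ghost fits; a warning is
    logged and the fly is returned unchanged.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 1]))
    if rng.random() >= params.ghost_prob:
        return fly
    lo = fly.true_death_minute + 721  # strictly more than 12 h after death
    hi = len(fly.series)
    if lo >= hi:
        logger.warning(
            "fly %s: record ends within 12 h of death; no ghost placed",
            fly.meta.fly_id,
        )
        return fly
    minute = int(rng.integers(lo, hi))
    counts = fly.series.counts.copy()
    counts[minute] = 1
    series = BeamBreakSeries(
        fly_id=fly.series.fly_id, origin=fly.series.origin, counts=counts
    )
    return replace(fly, series=series, ghost_minute=minute)


def simulate_cohort(
    n_per_group: int,
    params: SimParams,
    schedule_control: LightSchedule,
    schedule_ccm: LightSchedule,
    seed: int,
    horizon_days: float = 40.0,
    sex: str = "male",
    with_ghosts: bool = True,
) -> tuple[Cohort, list[SimFly]]:
    """Simulate a two-arm cohort (control + CCM), one fly per channel.

    Returns the assembled :class:`~ccmpipe.dam_io.Cohort` plus the
    underlying :class:`SimFly` truth records for recovery tests.  Fly
    ``i`` of each arm uses the stream derived from ``(seed, arm, i)``.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    flies: dict[str, tuple[BeamBreakSeries, FlyMeta]] = {}
    truths: list[SimFly] = []
    master = int(seed) & 0x7FFFFFFF
    for arm_idx, (group, sched) in enumerate(
        [("control", schedule_control), ("CCM", schedule_ccm)]
    ):
        for i in range(n_per_group):
            meta = FlyMeta(
                fly_id=f"{'c' if group == 'control' else 'm'}{i:04d}",
                sex=sex,
                treatment=group,
                monitor=f"M{arm_idx + 1}{i // 32:02d}",
                channel=i % 32 + 1,
            )
            fly_seed = int(
                np.random.SeedSequence([master, arm_idx, i]).generate_state(1)[0]
                & 0x7FFFFFFF
            )
            fly = simulate_fly(params, sched, meta, fly_seed, horizon_days)
            if with_ghosts:
                fly = inject_ghosts(fly, params, fly_seed)
            truths.append(fly)
            flies[meta.fly_id] = (fly.series, meta)
    cohort = Cohort(
        flies=flies, schedules={"control": schedule_control, "CCM": schedule_ccm}
    )
    return cohort, truths
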