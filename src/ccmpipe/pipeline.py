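"""End-to-end orchestration: simulate/ingest -> survival -> sleep -> rhythm -> DE.

A single config dict (usually loaded from YAML) drives every stage; all
randomness flows from one master seed, so re-running a config produces
a byte-identical report.  The report JSON gathers the quantities the
individual stages compute: per-arm Kaplan-Meier medians, the log-rank
comparison, univariate/multivariate/sleep-matched Cox hazard ratios,
weekly sleep and activity summaries, weekly dominant periods and rhythm
power, and (when DE tables are supplied) the regulation-class counts.
"""

from __future__ import annotations

import json
import logging
from datetime import datetime
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import de_postprocess, rhythm, sleep_activity, vitality
from .dam_io import (
    Cohort,
    FlyMeta,
    RawReading,
    extract_series,
    read_metadata,
    read_monitor_file,
    write_metadata,
    write_monitor_file,
)
from .schedule import LightSchedule
from .synthetic import SimParams, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = [
    "default_config",
    "load_config",
    "run_pipeline",
    "write_cohort_monitors",
    "load_cohort",
]

_EPOCH0 = datetime(2024, 1, 1, 9, 0)  # default lights-on at experiment start


def default_config() -> dict[str, Any]:
    """Baseline config: simulated two-arm cohort under the study schedules."""
    return {
        "seed": 0,
        "simulate": {
            "n_per_group": 40,
            "horizon_days": 40.0,
            "sex": "male",
            "params": {},  # SimParams overrides
        },
        "schedules": {
            "control": {"period_hours": 24.0, "photoperiod_hours": 12.0},
            "CCM": {"period_hours": 28.0, "photoperiod_hours": 14.0},
        },
        "analysis": {
            "weeks": [1, 2],
            "rhythm_flies_per_arm": 16,
            "sleep_match_tolerance": 0.5,
        },
        "de": {"ccm_table": None, "aging_table": None},
        "out": None,
    }


def load_config(path: str | Path) -> dict[str, Any]:
    cfg = default_config()
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    for key, value in user.items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def _build_schedules(cfg: dict[str, Any]) -> dict[str, LightSchedule]:
    return {
        name: LightSchedule.ld(
            _EPOCH0,
            period_hours=entry["period_hours"],
            photoperiod_hours=entry["photoperiod_hours"],
        )
        for name, entry in cfg["schedules"].items()
    }


# ---------------------------------------------------------------------------
# cohort I/O in DAM format


def write_cohort_monitors(cohort: Cohort, out_dir: str | Path) -> None:
    """Write a cohort as per-monitor DAM files plus a metadata TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_monitor: dict[str, list[tuple[int, np.ndarray]]] = {}
    origin = None
    n_minutes = 0
    for fid, (series, meta) in cohort.flies.items():
        by_monitor.setdefault(meta.monitor, []).append((meta.channel, series.counts))
        origin = series.origin
        n_minutes = max(n_minutes, len(series))
    for monitor, channels in sorted(by_monitor.items()):
        sched = None
        for fid, (series, meta) in cohort.flies.items():
            if meta.monitor == monitor:
                sched = cohort.schedule_for(fid)
                break
        counts = np.zeros((n_minutes, 32), dtype=np.int64)
        for ch, c in channels:
            counts[: len(c), ch - 1] = c
        readings = []
        from datetime import timedelta

        for i in range(n_minutes):
            ts = origin + timedelta(minutes=i)
            readings.append(
                RawReading(
                    index=i + 1,
                    timestamp=ts,
                    status=1,
                    light_flag=1 if sched.lights_state(ts) == "on" else 0,
                    counts=tuple(int(v) for v in counts[i]),
                )
            )
        write_monitor_file(readings, out_dir / f"{monitor}.txt")
    write_metadata(
        (meta for _, meta in cohort.flies.values()), out_dir / "metadata.tsv"
    )


def load_cohort(
    monitors_dir: str | Path,
    metadata_path: str | Path,
    schedules: dict[str, LightSchedule],
) -> Cohort:
    """Assemble a cohort from DAM monitor files and a metadata TSV."""
    monitors_dir = Path(monitors_dir)
    metas = read_metadata(metadata_path)
    cache: dict[str, list[RawReading]] = {}
    flies = {}
    for meta in metas:
        if meta.monitor not in cache:
            cache[meta.monitor] = read_monitor_file(monitors_dir / f"{meta.monitor}.txt")
        readings = cache[meta.monitor]
        window = (
            readings[0].timestamp,
            readings[-1].timestamp + pd.Timedelta(minutes=1).to_pytimedelta(),
        )
        series = extract_series(readings, meta.channel, window, fly_id=meta.fly_id)
        flies[meta.fly_id] = (series, meta)
    return Cohort(flies=flies, schedules=schedules)


# ---------------------------------------------------------------------------
# the pipeline


def run_pipeline(config: dict[str, Any]) -> dict[str, Any]:
    """Run every stage and return the machine-readable report dict.

    Deterministic given the config's master seed.  If ``config["out"]``
    is set, writes ``report.json``, a lifespan TSV, and weekly summary
    TSVs there.
    """
    cfg = {**default_config(), **config}
    seed = int(cfg["seed"])
    schedules = _build_schedules(cfg)

    if cfg.get("monitors_dir"):
        cohort = load_cohort(cfg["monitors_dir"], cfg["metadata"], schedules)
    else:
        sim = cfg["simulate"]
        params = SimParams(**sim.get("params", {}))
        cohort, _ = simulate_cohort(
            sim["n_per_group"],
            params,
            schedules["control"],
            schedules["CCM"],
            seed=seed,
            horizon_days=sim["horizon_days"],
            sex=sim.get("sex", "male"),
        )

    report: dict[str, Any] = {"seed": seed, "n_flies": len(cohort.included())}

    # --- death calling -----------------------------------------------------
    lifespans: dict[str, vitality.LifespanRecord] = {}
    filtered_series = {}
    for fid, (series, meta) in cohort.included().items():
        fseries, ghosts = vitality.filter_ghosts(series)
        rec = vitality.call_death(fseries, ghosts)
        lifespans[fid] = rec
        filtered_series[fid] = fseries
    report["ghost_bins_removed"] = sum(
        len(r.ghost_bins_removed) for r in lifespans.values()
    )

    # --- survival ----------------------------------------------------------
    def arm_days(treatment: str) -> list[float]:
        return [
            lifespans[fid].lifespan_days
            for fid in cohort.included(treatment)
        ]

    ctrl_days, ccm_days = arm_days("control"), arm_days("CCM")
    km_ctrl = vitality.km_fit(ctrl_days)
    km_ccm = vitality.km_fit(ccm_days)
    chi2, p = vitality.logrank_test(ctrl_days, ccm_days)
    report["survival"] = {
        "control_median_days": km_ctrl.median,
        "ccm_median_days": km_ccm.median,
        "percent_median_reduction": vitality.percent_median_reduction(
            km_ctrl.median, km_ccm.median
        ),
        "logrank_chi2": chi2,
        "logrank_p": p,
    }

    # --- sleep and hazard models ------------------------------------------
    week1_sleep: dict[str, float] = {}
    for fid, fs in filtered_series.items():
        s = sleep_activity.weekly_sleep_summary(fs, 1, lifespans[fid].lifespan_minutes)
        if s.included:
            week1_sleep[fid] = s.sleep_min_per_hr
    flies_with_sleep = sorted(week1_sleep)
    durations = [lifespans[f].lifespan_days for f in flies_with_sleep]
    events = [True] * len(flies_with_sleep)
    is_ccm = [
        1.0 if cohort.flies[f][1].treatment == "CCM" else 0.0 for f in flies_with_sleep
    ]
    sleep_h_per_day = [week1_sleep[f] * 24.0 / 60.0 for f in flies_with_sleep]

    hazard: dict[str, Any] = {}
    if len(set(is_ccm)) > 1:
        uni = vitality.cox_fit(durations, events, {"CCM": is_ccm})
        hazard["ccm_univariate"] = _effect_dict(uni["CCM"])
        multi = vitality.cox_fit(
            durations, events, {"CCM": is_ccm, "sleep_h": sleep_h_per_day}
        )
        hazard["multivariate"] = {
            "CCM": _effect_dict(multi["CCM"]),
            "sleep_per_hour": _effect_dict(multi["sleep_h"]),
        }
    sleep_uni = vitality.cox_fit(durations, events, {"sleep_h": sleep_h_per_day})
    hazard["sleep_univariate"] = _effect_dict(sleep_uni["sleep_h"])

    ctrl_sleep = {
        f: week1_sleep[f]
        for f in flies_with_sleep
        if cohort.flies[f][1].treatment == "control"
    }
    ccm_sleep = {
        f: week1_sleep[f]
        for f in flies_with_sleep
        if cohort.flies[f][1].treatment == "CCM"
    }
    matched = vitality.sleep_match(
        ctrl_sleep, ccm_sleep, tolerance=cfg["analysis"]["sleep_match_tolerance"]
    )
    hazard["n_matched_pairs"] = len(matched)
    if len(matched) >= 10:
        m_flies = [f for pair in matched.pairs for f in pair]
        m_dur = [lifespans[f].lifespan_days for f in m_flies]
        m_ccm = [1.0 if cohort.flies[f][1].treatment == "CCM" else 0.0 for f in m_flies]
        try:
            m_fit = vitality.cox_fit(m_dur, [True] * len(m_flies), {"CCM": m_ccm})
            hazard["ccm_sleep_matched"] = _effect_dict(m_fit["CCM"])
        except ValueError as exc:
            hazard["ccm_sleep_matched"] = {"error": str(exc)}
    report["hazard_models"] = hazard

    corr = None
    if len(ctrl_sleep) >= 4:
        try:
            corr = sleep_activity.correlate_sleep_longevity(
                ctrl_sleep,
                {f: lifespans[f].lifespan_days for f in ctrl_sleep},
            )
        except ValueError:
            corr = None
    report["sleep_longevity_spearman"] = (
        None
        if corr is None
        else {"rho": corr.rho, "ci": list(corr.ci), "p": corr.p, "n": corr.n}
    )

    # --- weekly summaries and rhythm --------------------------------------
    weekly: dict[str, Any] = {}
    for week in cfg["analysis"]["weeks"]:
        wk: dict[str, Any] = {}
        for treatment in ("control", "CCM"):
            sleeps, acts = [], []
            periods, powers = [], []
            n_rhythm = 0
            for fid in sorted(cohort.included(treatment)):
                fs = filtered_series[fid]
                life = lifespans[fid].lifespan_minutes
                ss = sleep_activity.weekly_sleep_summary(fs, week, life)
                aa = sleep_activity.weekly_activity_summary(fs, week, life)
                if ss.included:
                    sleeps.append(ss.sleep_min_per_hr)
                    acts.append(aa.activity_counts_per_min)
                    if n_rhythm < cfg["analysis"]["rhythm_flies_per_arm"]:
                        pg = rhythm.weekly_ld_rhythm(fs, week, life)
                        periods.append(pg.dominant_period)
                        powers.append(pg.power)
                        n_rhythm += 1
            wk[treatment] = {
                "n_survivors": len(sleeps),
                "mean_sleep_min_per_hr": float(np.mean(sleeps)) if sleeps else None,
                "mean_activity_per_min": float(np.mean(acts)) if acts else None,
                "mean_dominant_period_min": float(np.mean(periods)) if periods else None,
                "mean_rhythm_power": float(np.mean(powers)) if powers else None,
            }
        weekly[f"week{week}"] = wk
    report["weekly"] = weekly

    # --- DE cross-classification ------------------------------------------
    de_cfg = cfg.get("de") or {}
    if de_cfg.get("ccm_table") and de_cfg.get("aging_table"):
        ccm_tbl = de_postprocess.read_de_table(de_cfg["ccm_table"])
        aging_tbl = de_postprocess.read_de_table(de_cfg["aging_table"])
        _, counts = de_postprocess.classify_table(ccm_tbl, aging_tbl)
        report["de_classification"] = counts

    if cfg.get("out"):
        _write_outputs(cfg["out"], report, lifespans)
    return report


def _effect_dict(e: vitality.CovariateEffect) -> dict[str, float]:
    return {
        "hazard_ratio": e.hazard_ratio,
        "ci_lower": e.ci_lower,
        "ci_upper": e.ci_upper,
        "p": e.p,
    }


def _write_outputs(
    out_dir: str | Path,
    report: dict[str, Any],
    lifespans: dict[str, vitality.LifespanRecord],
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    pd.DataFrame(
        [
            {
                "fly_id": fid,
                "lifespan_days": rec.lifespan_days,
                "ghost_count": len(rec.ghost_bins_removed),
            }
            for fid, rec in sorted(lifespans.items())
        ]
    ).to_csv(out / "lifespans.tsv", sep="\t", index=False)
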