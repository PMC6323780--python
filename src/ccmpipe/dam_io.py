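"""Reading and writing TriKinetics-style DAM monitor files.

A monitor file is tab-delimited with one row per minute and 42 columns:
reading index, date (``D Mon YY``), time (``HH:MM:SS``), a status code
(1 = valid), five reserved columns (written as 0), a light flag, and 32
per-channel beam-break counts.  One channel holds one fly; the per-fly
record assembled here (:class:`BeamBreakSeries`) is the dense 1-minute
count vector every downstream statistic operates on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .schedule import LightSchedule

logger = logging.getLogger(__name__)

__all__ = [
    "RawReading",
    "BeamBreakSeries",
    "FlyMeta",
    "Cohort",
    "MonitorParseError",
    "GapError",
    "read_monitor_file",
    "write_monitor_file",
    "extract_series",
    "concatenate_weeks",
    "read_metadata",
    "write_metadata",
]

N_CHANNELS = 32
_DATE_FMT = "%b %y"  # day is formatted without zero padding, parsed separately


class MonitorParseError(ValueError):
    """A monitor-file row could not be parsed; message names the line."""


class GapError(ValueError):
    """Minutes missing inside a requested window."""


@dataclass(frozen=True)
class RawReading:
    """One monitor row: a timestamped vector of 32 channel counts."""

    index: int
    timestamp: datetime
    status: int
    light_flag: int
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.counts) != N_CHANNELS:
            raise ValueError(f"expected {N_CHANNELS} counts, got {len(self.counts)}")
        if any(c < 0 for c in self.counts):
            raise ValueError("beam-break counts must be non-negative")

    @property
    def valid(self) -> bool:
        return self.status == 1


@dataclass
class BeamBreakSeries:
    """One fly's gap-free per-minute beam-break counts.

    Bin *i* covers the minute starting at ``origin + i`` minutes.
    """

    fly_id: str
    origin: datetime
    counts: np.ndarray
    bin_minutes: int = 1

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if (self.counts < 0).any():
            raise ValueError("beam-break counts must be non-negative")

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def end(self) -> datetime:
        """Timestamp one bin past the last count."""
        return self.origin + timedelta(minutes=len(self.counts) * self.bin_minutes)

    def minute_of(self, timestamp: datetime) -> int:
        """Bin index of *timestamp* (may lie outside the series)."""
        return int((timestamp - self.origin).total_seconds() // 60)


@dataclass(frozen=True)
class FlyMeta:
    """Per-fly experimental metadata."""

    fly_id: str
    sex: str  # "female" | "male"
    treatment: str  # "control" | "CCM"
    monitor: str
    channel: int
    excluded: bool = False  # escaped flies; never enter analyses

    def __post_init__(self) -> None:
        if not 1 <= self.channel <= N_CHANNELS:
            raise ValueError(f"channel must be in [1, {N_CHANNELS}], got {self.channel}")
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if self.treatment not in ("control", "CCM"):
            raise ValueError(f"treatment must be 'control' or 'CCM', got {self.treatment!r}")


@dataclass
class Cohort:
    """All per-fly series and metadata for one experiment, plus its schedules.

    ``schedules`` maps treatment name to the light schedule that group
    experienced.  Excluded flies are carried but skipped by
    :meth:`included`.
    """

    flies: dict[str, tuple[BeamBreakSeries, FlyMeta]]
    schedules: dict[str, LightSchedule]

    def included(self, treatment: Optional[str] = None) -> dict[str, tuple[BeamBreakSeries, FlyMeta]]:
        return {
            fid: (series, meta)
            for fid, (series, meta) in self.flies.items()
            if not meta.excluded and (treatment is None or meta.treatment == treatment)
        }

    def schedule_for(self, fly_id: str) -> LightSchedule:
        return self.schedules[self.flies[fly_id][1].treatment]


# ---------------------------------------------------------------------------
# monitor files


def _format_date(ts: datetime) -> str:
    return f"{ts.day} {ts.strftime(_DATE_FMT)}"


def _format_row(r: RawReading) -> str:
    fields = [
        str(r.index),
        _format_date(r.timestamp),
        r.timestamp.strftime("%H:%M:%S"),
        str(r.status),
        "0",
        "0",
        "0",
        "0",
        "0",
        str(r.light_flag),
        *(str(c) for c in r.counts),
    ]
    return "\t".join(fields)


def read_monitor_file(path: str | Path) -> list[RawReading]:
    """Parse a DAM monitor file into :class:`RawReading` rows.

    Rows with a non-1 status code are retained but flagged invalid (they
    are zero-filled later by :func:`extract_series`).  Malformed rows
    raise :class:`MonitorParseError` naming the line number.
    """
    readings: list[RawReading] = []
    prev_ts: Optional[datetime] = None
    with open(path, "r", encoding="ascii") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 10 + N_CHANNELS:
                raise MonitorParseError(
                    f"{path}:{lineno}: expected {10 + N_CHANNELS} columns, got {len(parts)}"
                )
            try:
                ts = datetime.strptime(f"{parts[1]} {parts[2]}", "%d %b %y %H:%M:%S")
                reading = RawReading(
                    index=int(parts[0]),
                    timestamp=ts,
                    status=int(parts[3]),
                    light_flag=int(parts[9]),
                    counts=tuple(int(c) for c in parts[10 : 10 + N_CHANNELS]),
                )
            except (ValueError, IndexError) as exc:
                raise MonitorParseError(f"{path}:{lineno}: {exc}") from exc
            if prev_ts is not None and reading.timestamp <= prev_ts:
                raise MonitorParseError(
                    f"{path}:{lineno}: timestamps not strictly increasing"
                )
            prev_ts = reading.timestamp
            readings.append(reading)
    return readings


def write_monitor_file(readings: Sequence[RawReading], path: str | Path) -> None:
    """Write rows in the dialect accepted by :func:`read_monitor_file`.

    Round-trips byte-for-byte with :func:`read_monitor_file` for
    canonical files.  Input must be sorted by timestamp.
    """
    timestamps = [r.timestamp for r in readings]
    if timestamps != sorted(timestamps):
        raise ValueError("readings must be sorted by timestamp")
    with open(path, "w", encoding="ascii") as fh:
        for r in readings:
            fh.write(_format_row(r) + "\n")


def extract_series(
    readings: Sequence[RawReading],
    channel: int,
    window: tuple[datetime, datetime],
    fly_id: str = "",
) -> BeamBreakSeries:
    """Pull one channel's dense 1-minute series over *window*.

    Invalid-status minutes are filled with zero counts (and logged) so
    downstream sleep and death logic always sees a dense series.
    Minutes missing inside the window raise :class:`GapError`; use
    :func:`concatenate_weeks` to bridge tube-transfer gaps.
    """
    if not 1 <= channel <= N_CHANNELS:
        raise ValueError(f"channel must be in [1, {N_CHANNELS}]")
    start, end = window
    n_minutes = int((end - start).total_seconds() // 60)
    if n_minutes <= 0:
        raise ValueError("window must span at least one minute")
    counts = np.zeros(n_minutes, dtype=np.int64)
    seen = np.zeros(n_minutes, dtype=bool)
    invalid: list[int] = []
    for r in readings:
        i = int((r.timestamp - start).total_seconds() // 60)
        if 0 <= i < n_minutes:
            seen[i] = True
            if r.valid:
                counts[i] = r.counts[channel - 1]
            else:
                invalid.append(i)
    if not seen.all():
        missing = np.flatnonzero(~seen)
        raise GapError(
            f"{len(missing)} minute(s) missing inside window "
            f"(first at {start + timedelta(minutes=int(missing[0]))})"
        )
    if invalid:
        logger.info(
            "channel %d: %d invalid-status minute(s) zero-filled", channel, len(invalid)
        )
    return BeamBreakSeries(fly_id=fly_id or f"ch{channel}", origin=start, counts=counts)


def concatenate_weeks(
    parts: Sequence[BeamBreakSeries],
    max_gap_minutes: int = 120,
) -> BeamBreakSeries:
    """Join chronologically ordered weekly series into one record.

    Flies are moved to fresh tubes each week; the minutes a fly spends
    off-monitor form a short gap, filled here with zeros and logged as
    transfer time.  Gaps beyond *max_gap_minutes* indicate data loss and
    raise :class:`GapError`; overlapping parts raise ``ValueError``.
    """
    if not parts:
        raise ValueError("no series to concatenate")
    if len(parts) == 1:
        return parts[0]
    chunks: list[np.ndarray] = [parts[0].counts]
    transfer_bins = 0
    for prev, nxt in zip(parts, parts[1:]):
        if nxt.fly_id != prev.fly_id:
            raise ValueError(f"fly_id mismatch: {prev.fly_id!r} vs {nxt.fly_id!r}")
        gap = int((nxt.origin - prev.end).total_seconds() // 60)
        if gap < 0:
            raise ValueError(f"parts overlap at {nxt.origin}")
        if gap > max_gap_minutes:
            raise GapError(
                f"gap of {gap} min between parts exceeds transfer limit "
                f"({max_gap_minutes} min)"
            )
        if gap:
            chunks.append(np.zeros(gap, dtype=np.int64))
            transfer_bins += gap
        chunks.append(nxt.counts)
    if transfer_bins:
        logger.info(
            "fly %s: %d transfer-gap minute(s) zero-filled", parts[0].fly_id, transfer_bins
        )
    return BeamBreakSeries(
        fly_id=parts[0].fly_id,
        origin=parts[0].origin,
        counts=np.concatenate(chunks),
    )


# ---------------------------------------------------------------------------
# metadata tables

_META_COLS = ["fly_id", "sex", "treatment", "monitor", "channel", "excluded"]


def read_metadata(path: str | Path) -> list[FlyMeta]:
    """Read the fly-metadata TSV (fly_id, sex, treatment, monitor, channel, excluded)."""
    df = pd.read_csv(path, sep="\t", dtype={"fly_id": str, "monitor": str})
    missing = set(_META_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata table missing columns: {sorted(missing)}")
    return [
        FlyMeta(
            fly_id=row.fly_id,
            sex=row.sex,
            treatment=row.treatment,
            monitor=row.monitor,
            channel=int(row.channel),
            excluded=bool(row.excluded),
        )
        for row in df.itertuples()
    ]


def write_metadata(metas: Iterable[FlyMeta], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "fly_id": m.fly_id,
                "sex": m.sex,
                "treatment": m.treatment,
                "monitor": m.monitor,
                "channel": m.channel,
                "excluded": m.excluded,
            }
            for m in metas
        ],
        columns=_META_COLS,
    ).to_csv(path, sep="\t", index=False)
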