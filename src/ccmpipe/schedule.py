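"""Light schedules and zeitgeber time.

A schedule is an ordered sequence of epochs, each either light-dark
cycling (LD) with a cycle length ``T`` (hours) and a photoperiod
(lights-on hours per cycle), or constant darkness (DD).  Zeitgeber time
(ZT) is hours since the most recent lights-on event, modulo ``T``; it is
defined only inside LD epochs.  Intervals are half-open: lights are on
for ZT in [0, photoperiod) and off for ZT in [photoperiod, T).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Optional

__all__ = ["Epoch", "LightSchedule", "ScheduleError"]


class ScheduleError(ValueError):
    """Raised for timestamps outside the schedule or undefined ZT."""


@dataclass(frozen=True)
class Epoch:
    """One homogeneous segment of a light schedule.

    Parameters
    ----------
    start
        Absolute start of the epoch.
    mode
        ``"LD"`` for light-dark cycling, ``"DD"`` for constant darkness.
    period_hours
        Cycle length T in hours (ignored for DD).
    photoperiod_hours
        Lights-on hours per cycle, 0 < photoperiod < T (ignored for DD).
    zt0_anchor
        Absolute time of a lights-on event; defaults to ``start``.
    """

    start: datetime
    mode: str = "LD"
    period_hours: float = 24.0
    photoperiod_hours: float = 12.0
    zt0_anchor: Optional[datetime] = None

    def __post_init__(self) -> None:
        if self.mode not in ("LD", "DD"):
            raise ValueError(f"epoch mode must be 'LD' or 'DD', got {self.mode!r}")
        if self.mode == "LD" and not (0 < self.photoperiod_hours < self.period_hours):
            raise ValueError(
                "LD epoch requires 0 < photoperiod < T, got "
                f"photoperiod={self.photoperiod_hours}, T={self.period_hours}"
            )
        if self.zt0_anchor is None:
            object.__setattr__(self, "zt0_anchor", self.start)


@dataclass
class LightSchedule:
    """Ordered, contiguous epochs covering the experiment span.

    The final epoch is open-ended.  Epochs must be sorted by start time
    and non-overlapping (contiguity is implied: each epoch ends where
    the next begins).
    """

    epochs: list[Epoch] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("schedule needs at least one epoch")
        starts = [e.start for e in self.epochs]
        if starts != sorted(starts) or len(set(starts)) != len(starts):
            raise ValueError("epochs must be sorted by start and non-overlapping")

    # -- construction helpers -------------------------------------------------

    @classmethod
    def ld(
        cls,
        start: datetime,
        period_hours: float = 24.0,
        photoperiod_hours: float = 12.0,
    ) -> "LightSchedule":
        """A single open-ended LD epoch (e.g. LD12:12 control, LD14:14 CCM)."""
        return cls([Epoch(start, "LD", period_hours, photoperiod_hours)])

    @classmethod
    def ld_then_dd(
        cls,
        start: datetime,
        ld_days: float,
        period_hours: float = 24.0,
        photoperiod_hours: float = 12.0,
    ) -> "LightSchedule":
        """An LD epoch followed by open-ended constant darkness."""
        dd_start = start + timedelta(hours=24.0 * ld_days)
        return cls(
            [
                Epoch(start, "LD", period_hours, photoperiod_hours),
                Epoch(dd_start, "DD"),
            ]
        )

    # -- queries --------------------------------------------------------------

    @property
    def start(self) -> datetime:
        return self.epochs[0].start

    def epoch_at(self, timestamp: datetime) -> Epoch:
        """Epoch containing *timestamp*; error if before the schedule start."""
        if timestamp < self.start:
            raise ScheduleError(f"{timestamp} precedes schedule start {self.start}")
        current = self.epochs[0]
        for epoch in self.epochs[1:]:
            if timestamp < epoch.start:
                break
            current = epoch
        return current

    def zt_of(self, timestamp: datetime) -> float:
        """Zeitgeber time in hours, in [0, T).

        Hours since the most recent lights-on event of the containing LD
        epoch, modulo that epoch's cycle length.  ZT is undefined in DD.
        """
        epoch = self.epoch_at(timestamp)
        if epoch.mode != "LD":
            raise ScheduleError(
                f"{timestamp} falls in a DD epoch; zeitgeber time is undefined "
                "(use hours since DD onset instead)"
            )
        elapsed_h = (timestamp - epoch.zt0_anchor).total_seconds() / 3600.0
        return elapsed_h % epoch.period_hours

    def lights_state(self, timestamp: datetime) -> str:
        """``"on"`` or ``"off"`` at *timestamp* (always off throughout DD)."""
        epoch = self.epoch_at(timestamp)
        if epoch.mode == "DD":
            return "off"
        return "on" if self.zt_of(timestamp) < epoch.photoperiod_hours else "off"

    def full_cycles_in(self, window_hours: float, at: Optional[datetime] = None) -> int:
        """Number of complete LD cycles in a window of *window_hours*.

        Under LD14:14 (T = 28 h) a 168-h week holds 6 full cycles; under
        LD12:12 (T = 24 h) it holds 7, so weekly light and dark exposure
        is equal across the two schedules.
        """
        epoch = self.epoch_at(at) if at is not None else self.epochs[0]
        if epoch.mode != "LD":
            raise ScheduleError("full_cycles_in requires an LD epoch")
        return int(window_hours // epoch.period_hours)
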