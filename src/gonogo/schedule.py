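"""Session availability logic: cage rotation, habituation blocks, light cycle.

Cages housed on a common rack cannot be sound-isolated from each other, so
only one cage is allowed to run trials at a time.  With the default four
cages each becomes active for 60 min and then inactive for 180 min, staggered
so that the four active windows tile the day with no overlap and no gap,
giving every cage 6 h of training per 24 h.

The 12 h dark phase does not gate the trial engine -- training runs around
the clock and the mice self-gate by sleeping -- but it is exposed to the
virtual-mouse model, which is more active in the dark.

The session epoch is ``t = 0`` seconds; hour-of-day 0 coincides with it.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

from pydantic import BaseModel, Field, model_validator

MINUTE = 60.0
DAY_SECONDS = 86400.0


class CageSchedule(BaseModel):
    """Rotation of cage activity plus the light/dark cycle.

    ``active_block`` and ``inactive_block`` are minutes; ``cage_offsets`` are
    minutes from the epoch at which each cage's first active block starts
    (default: cage ``i`` starts at ``i * active_block``, i.e. back-to-back).
    ``dark_cycle`` is the (start, end) hour-of-day of the 12 h dark phase.
    """

    n_cages: int = Field(default=4, ge=1)
    active_block: float = Field(default=60.0, ge=0.0)
    inactive_block: float = Field(default=180.0, ge=0.0)
    cage_offsets: Optional[List[float]] = None
    dark_cycle: Tuple[float, float] = (18.0, 6.0)

    @property
    def period(self) -> float:
        """Rotation period in minutes."""
        return self.active_block + self.inactive_block

    @model_validator(mode="after")
    def _check(self) -> "CageSchedule":
        if self.period <= 0:
            raise ValueError("active_block + inactive_block must be positive")
        if self.cage_offsets is None:
            self.cage_offsets = [i * self.active_block for i in range(self.n_cages)]
        if len(self.cage_offsets) != self.n_cages:
            raise ValueError("cage_offsets must have one entry per cage")
        for off in self.cage_offsets:
            if not 0 <= off < self.period:
                raise ValueError("cage offsets must lie within one rotation period")
        start, end = self.dark_cycle
        if (end - start) % 24.0 != 12.0:
            raise ValueError("dark_cycle must span exactly 12 h")
        return self


def cage_active(schedule: CageSchedule, cage_index: int, t: float) -> bool:
    """True iff ``cage_index`` is in its active block at session time ``t`` (s)."""
    if not 0 <= cage_index < schedule.n_cages:
        raise IndexError(f"cage_index {cage_index} out of range (n_cages={schedule.n_cages})")
    offset = schedule.cage_offsets[cage_index]
    return ((t / MINUTE - offset) % schedule.period) < schedule.active_block


def active_block_starts(schedule: CageSchedule, cage_index: int, day_index: int) -> List[float]:
    """Start times (s) of the cage's active blocks that begin on the given day."""
    if not 0 <= cage_index < schedule.n_cages:
        raise IndexError(f"cage_index {cage_index} out of range (n_cages={schedule.n_cages})")
    period_s = schedule.period * MINUTE
    offset_s = schedule.cage_offsets[cage_index] * MINUTE
    day0 = day_index * DAY_SECONDS
    day1 = day0 + DAY_SECONDS
    import math

    k0 = math.ceil((day0 - offset_s) / period_s)
    starts = []
    k = k0
    while offset_s + k * period_s < day1:
        if offset_s + k * period_s >= day0:
            starts.append(offset_s + k * period_s)
        k += 1
    return starts


def habituation_block_active(config, t: float) -> bool:
    """True iff habituation trials run at time ``t`` (s from session start).

    Habituation alternates ``on_block`` minutes of trials with ``off_block``
    minutes of rest, starting with an on-block.
    """
    on = config.on_block
    off = config.off_block
    return (t / MINUTE) % (on + off) < on


def next_habituation_block_start(config, t: float) -> float:
    """Earliest time >= ``t`` at which an on-block is running (s)."""
    if habituation_block_active(config, t):
        return t
    cycle = (config.on_block + config.off_block) * MINUTE
    n = t // cycle
    return (n + 1) * cycle


def daily_training_minutes(schedule: CageSchedule, cage_index: int = 0) -> float:
    """Total active minutes for one cage in a 24 h window."""
    if schedule.active_block == 0:
        return 0.0
    period = schedule.period
    offset = schedule.cage_offsets[cage_index]
    total = 0.0
    t = 0.0
    pos = (-offset) % period
    while t < 1440.0:
        if pos < schedule.active_block:
            seg = min(schedule.active_block - pos, 1440.0 - t)
            total += seg
            t += seg
            pos += seg
            if pos >= schedule.active_block:
                pos = schedule.active_block
        else:
            seg = min(period - pos, 1440.0 - t)
            t += seg
            pos = 0.0
    return total


def is_dark(schedule: CageSchedule, t: float) -> bool:
    """True iff session time ``t`` (s) falls in the 12 h dark phase."""
    hour = (t / 3600.0) % 24.0
    start, end = schedule.dark_cycle
    if start < end:
        return start <= hour < end
    return hour >= start or hour < end
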