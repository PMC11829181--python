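"""Calendar-method baseline: ovulation from period history alone.

The estimate is ``period_start + (typical_length - typical_luteal - 1)``
days, where the typical cycle length is the median over the trailing six
months (lengths under 12 or over 90 days discarded as outliers) and the
typical luteal length is the population mean of 12 days.  The extra day
subtracted places the estimate on the *last follicular day*, matching the
ovulation-date convention used throughout the package: under 1-based
cycle-day numbering the estimate lands on cycle day
``typical_length - 12``, leaving exactly 12 luteal days in a cycle of
typical length.
"""
from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import CycleRecord, FailureReason, Method, OvulationEstimate

__all__ = ["CalendarConfig", "typical_cycle_length", "calendar_estimate", "CalendarEstimator"]


@dataclass(frozen=True)
class CalendarConfig:
    typical_luteal_days: int = 12
    history_days: int = 183          # trailing window, ~6 months
    min_len: int = 12                # cycle-length outlier floor, days
    max_len: int = 90                # outlier ceiling, days

    def __post_init__(self) -> None:
        if self.min_len >= self.max_len:
            raise ValueError("min_len must be below max_len")


def typical_cycle_length(
    prior_lengths: Sequence[int], config: Optional[CalendarConfig] = None
) -> Optional[int]:
    """Median prior cycle length after outlier removal, in whole days.

    Lengths outside [min_len, max_len] are discarded; returns None when
    nothing survives.  The median of an even count (mean of the two
    middle values, possibly a half day) is rounded half toward the
    longer length so the estimate stays a calendar date.
    """
    cfg = config or CalendarConfig()
    kept = [l for l in prior_lengths if cfg.min_len <= l <= cfg.max_len]
    if not kept:
        return None
    med = float(np.median(kept))
    return int(math.floor(med + 0.5))


def calendar_estimate(
    cycle: CycleRecord,
    typical_length: Optional[int],
    config: Optional[CalendarConfig] = None,
) -> OvulationEstimate:
    """Calendar-method ovulation estimate for one cycle.

    Returns a ``no_history`` failure when no typical length is available.
    """
    cfg = config or CalendarConfig()
    if typical_length is None:
        return OvulationEstimate(
            cycle, Method.CALENDAR, False, None, FailureReason.NO_HISTORY
        )
    offset = typical_length - cfg.typical_luteal_days - 1
    return OvulationEstimate(
        cycle, Method.CALENDAR, True,
        cycle.period_start + dt.timedelta(days=offset),
    )


class CalendarEstimator:
    """Model object: calendar-method estimates from a user's period history.

    Parameters
    ----------
    history : sequence of (period_start, cycle_length) pairs
        Completed cycles of the user, chronological.
    config : CalendarConfig, optional

    The typical length for a target cycle is computed from history cycles
    whose start falls within the trailing ``history_days`` before the
    target's own start (the target cycle itself is never used).
    """

    def __init__(
        self,
        history: Sequence[tuple[dt.date, int]],
        config: Optional[CalendarConfig] = None,
    ) -> None:
        self.history = sorted(history, key=lambda h: h[0])
        self.config = config or CalendarConfig()

    def typical_length_asof(self, target_start: dt.date) -> Optional[int]:
        lo = target_start - dt.timedelta(days=self.config.history_days)
        lengths = [
            length for start, length in self.history
            if lo <= start < target_start
        ]
        return typical_cycle_length(lengths, self.config)

    def fit(self, cycle: CycleRecord) -> OvulationEstimate:
        """Estimate ovulation for ``cycle`` from its trailing history."""
        return calendar_estimate(
            cycle, self.typical_length_asof(cycle.period_start), self.config
        )
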