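"""Reference-ovulation construction and inclusion/exclusion screening.

The benchmark reference date is the day after the last positive LH test
in a cycle.  Screening applies, in a fixed order: the complete-cycle
requirement, presence of an LH reference, reference-implied phase-length
plausibility (follicular 10-90, luteal 8-20 days), rejection of cycles
whose algorithm input windows overlap a previously accepted cycle of the
same user, physiology sufficiency (at most 40% missing nights in the
60-night lookback), hormone use, and pregnancy.  Each excluded cycle
carries exactly one reason — the first rule it trips.
"""
from __future__ import annotations

import datetime as dt
import enum
import logging
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .core import ONE_DAY, CycleRecord, ReferenceOvulation, TemperatureSeries

__all__ = [
    "ExclusionReason",
    "EligibilityResult",
    "reference_date",
    "follicular_length",
    "luteal_length",
    "check_reference_plausibility",
    "check_physiology_sufficiency",
    "build_dataset",
    "FOLLICULAR_RANGE",
    "LUTEAL_RANGE",
    "SUFFICIENCY_WINDOW_DAYS",
    "MAX_MISSING_FRACTION",
]

log = logging.getLogger(__name__)

FOLLICULAR_RANGE = (10, 90)   # acceptable follicular phase length, days
LUTEAL_RANGE = (8, 20)        # acceptable luteal phase length, days
SUFFICIENCY_WINDOW_DAYS = 60
MAX_MISSING_FRACTION = 0.40   # exclusion requires strictly more than this


class ExclusionReason(str, enum.Enum):
    NONE = "none"
    NO_LH = "no_lh"
    INCOMPLETE_CYCLE = "incomplete_cycle"
    IMPLAUSIBLE_FOLLICULAR_REF = "implausible_follicular_ref"
    IMPLAUSIBLE_LUTEAL_REF = "implausible_luteal_ref"
    INSUFFICIENT_PHYSIOLOGY = "insufficient_physiology"
    HORMONE_USE = "hormone_use"
    PREGNANCY = "pregnancy"
    OVERLAPPING_WINDOW = "overlapping_window"


@dataclass(frozen=True)
class EligibilityResult:
    cycle: CycleRecord
    eligible: bool
    exclusion_reason: ExclusionReason = ExclusionReason.NONE

    def __post_init__(self) -> None:
        if self.eligible != (self.exclusion_reason is ExclusionReason.NONE):
            raise ValueError("eligible=True iff exclusion_reason is 'none'")


def reference_date(positive_lh_dates: Sequence[dt.date]) -> Optional[dt.date]:
    """Day after the last positive LH test; None for an empty log."""
    if not positive_lh_dates:
        return None
    return max(positive_lh_dates) + ONE_DAY


def follicular_length(cycle: CycleRecord, ovulation: dt.date) -> int:
    """Follicular phase length in days = 1-based cycle-day index of the
    ovulation date (the last follicular day)."""
    return cycle.cycle_day(ovulation)


def luteal_length(cycle: CycleRecord, ovulation: dt.date) -> int:
    """Luteal phase length = cycle_length - follicular_length, so the two
    phases tile the cycle exactly."""
    if cycle.cycle_length is None:
        raise ValueError("luteal length requires a complete cycle")
    return cycle.cycle_length - follicular_length(cycle, ovulation)


def check_reference_plausibility(cycle: CycleRecord, ref: dt.date) -> EligibilityResult:
    """Screen a reference date against plausible phase lengths.

    Follicular must fall in [10, 90] days and luteal in [8, 20] days.
    """
    foll = follicular_length(cycle, ref)
    lut = luteal_length(cycle, ref)
    if not (FOLLICULAR_RANGE[0] <= foll <= FOLLICULAR_RANGE[1]):
        return EligibilityResult(cycle, False, ExclusionReason.IMPLAUSIBLE_FOLLICULAR_REF)
    if not (LUTEAL_RANGE[0] <= lut <= LUTEAL_RANGE[1]):
        return EligibilityResult(cycle, False, ExclusionReason.IMPLAUSIBLE_LUTEAL_REF)
    return EligibilityResult(cycle, True)


def check_physiology_sufficiency(
    series: TemperatureSeries,
    as_of: dt.date,
    window_days: int = SUFFICIENCY_WINDOW_DAYS,
    max_missing_fraction: float = MAX_MISSING_FRACTION,
) -> bool:
    """True iff the missing-night fraction over the ``window_days`` nights
    ending at ``as_of`` does not exceed ``max_missing_fraction``.

    Exclusion requires *strictly more than* the threshold missing, so a
    window at exactly 40% missing is still sufficient.  Nights absent
    from the series count as missing.
    """
    win = series.window(as_of, window_days)
    missing = 1.0 - win.valid.sum() / window_days
    return missing <= max_missing_fraction


def _input_window(cycle: CycleRecord, window_days: int) -> tuple[dt.date, dt.date]:
    # Lookback ending the night before the next menses onset — the window
    # the detector would consume for this cycle.
    end = cycle.next_period_start - ONE_DAY
    return (end - dt.timedelta(days=window_days - 1), end)


def build_dataset(
    cycles: Sequence[CycleRecord],
    lh_logs: Mapping[str, Sequence[dt.date]],
    series: Mapping[str, TemperatureSeries],
    window_days: int = SUFFICIENCY_WINDOW_DAYS,
) -> tuple[list[tuple[CycleRecord, ReferenceOvulation]], Counter]:
    """Apply the screening rules and return the evaluable dataset.

    Parameters
    ----------
    cycles : sequence of CycleRecord
        Candidate cycles (may be incomplete).
    lh_logs : mapping user_id -> positive LH test dates
    series : mapping user_id -> TemperatureSeries
    window_days : int
        Length of the algorithm input window used for both the overlap
        rule and the sufficiency check.

    Returns
    -------
    eligible : list of (CycleRecord, ReferenceOvulation)
    tally : Counter of ExclusionReason
        Includes ``ExclusionReason.NONE`` counting the eligible cycles,
        so values sum to the number of input cycles with a known user.
    """
    tally: Counter = Counter()
    eligible: list[tuple[CycleRecord, ReferenceOvulation]] = []
    accepted_windows: dict[str, list[tuple[dt.date, dt.date]]] = {}

    for cycle in sorted(cycles, key=lambda c: (c.user_id, c.period_start)):
        if cycle.user_id not in series and cycle.user_id not in lh_logs:
            log.warning("unknown user_id %r: skipping cycle", cycle.user_id)
            continue
        reason = _screen_cycle(cycle, lh_logs, series, accepted_windows, window_days)
        tally[reason] += 1
        if reason is ExclusionReason.NONE:
            in_cycle = [
                d for d in lh_logs.get(cycle.user_id, [])
                if cycle.period_start <= d < cycle.next_period_start
            ]
            eligible.append((cycle, ReferenceOvulation(cycle, max(in_cycle))))
            accepted_windows.setdefault(cycle.user_id, []).append(
                _input_window(cycle, window_days)
            )
    return eligible, tally


def _screen_cycle(
    cycle: CycleRecord,
    lh_logs: Mapping[str, Sequence[dt.date]],
    series: Mapping[str, TemperatureSeries],
    accepted_windows: Mapping[str, list[tuple[dt.date, dt.date]]],
    window_days: int,
) -> ExclusionReason:
    if not cycle.complete:
        return ExclusionReason.INCOMPLETE_CYCLE
    in_cycle = [
        d for d in lh_logs.get(cycle.user_id, [])
        if cycle.period_start <= d < cycle.next_period_start
    ]
    ref = reference_date(in_cycle)
    if ref is None:
        return ExclusionReason.NO_LH
    plaus = check_reference_plausibility(cycle, ref)
    if not plaus.eligible:
        return plaus.exclusion_reason
    lo, hi = _input_window(cycle, window_days)
    for (plo, phi) in accepted_windows.get(cycle.user_id, []):
        if lo <= phi and plo <= hi:
            return ExclusionReason.OVERLAPPING_WINDOW
    ser = series.get(cycle.user_id)
    if ser is None or not check_physiology_sufficiency(ser, hi, window_days):
        return ExclusionReason.INSUFFICIENT_PHYSIOLOGY
    if cycle.hormone_use:
        return ExclusionReason.HORMONE_USE
    if cycle.pregnant:
        return ExclusionReason.PREGNANCY
    return ExclusionReason.NONE
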