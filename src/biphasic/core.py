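"""Domain types and cycle bookkeeping shared across the package.

Everything operates at nightly (calendar-date) resolution: one temperature
sample per night, keyed to the wake date.  Cycle days are 1-based from the
period start, and the ovulation date is defined as the *last follicular
day*, so ``follicular_length + luteal_length == cycle_length`` exactly.
"""
from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "TemperatureSeries",
    "CycleRecord",
    "ReferenceOvulation",
    "OvulationEstimate",
    "SubgroupLabel",
    "Method",
    "FailureReason",
    "LengthClass",
    "VariabilityClass",
    "AgeClass",
    "classify_cycle_length",
    "classify_variability",
    "classify_age",
]

ONE_DAY = dt.timedelta(days=1)


class Method(str, enum.Enum):
    PHYSIOLOGY = "physiology"
    CALENDAR = "calendar"


class FailureReason(str, enum.Enum):
    NONE = "none"
    INSUFFICIENT_DATA = "insufficient_data"
    IMPLAUSIBLE_LUTEAL = "implausible_luteal"
    IMPLAUSIBLE_FOLLICULAR = "implausible_follicular"
    NO_HISTORY = "no_history"


class LengthClass(str, enum.Enum):
    ABNORMALLY_SHORT = "abnormally_short"
    SHORT = "short"
    MEDIUM = "medium"
    LONG = "long"
    ABNORMALLY_LONG = "abnormally_long"


class VariabilityClass(str, enum.Enum):
    TYPICAL = "typical"
    MODERATELY_IRREGULAR = "moderately_irregular"
    ABNORMALLY_IRREGULAR = "abnormally_irregular"
    UNKNOWN = "unknown"


class AgeClass(str, enum.Enum):
    A18_26 = "18-26"
    A27_34 = "27-34"
    A35_43 = "35-43"
    A44_PLUS = ">=44"


@dataclass
class TemperatureSeries:
    """A per-user sequence of nightly temperatures.

    Parameters
    ----------
    user_id : str
        Opaque identifier.
    dates : sequence of datetime.date
        Strictly increasing calendar dates, one per night.  Gaps are
        allowed on construction; :meth:`regularize` expands them to
        explicit invalid nights.
    values : ndarray of float
        Temperature in degrees Celsius (absolute or deviation; the
        pipeline mean-centers, so only relative structure matters).
        Must be finite wherever ``valid`` is true.
    valid : ndarray of bool
        Per-night validity flag; false marks missing or rejected nights.
    """

    user_id: str
    dates: Sequence[dt.date]
    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.dates = list(self.dates)
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (len(self.dates) == len(self.values) == len(self.valid)):
            raise ValueError("dates, values and valid must have equal length")
        for a, b in zip(self.dates, self.dates[1:]):
            if b <= a:
                raise ValueError("dates must be strictly increasing")
        if not np.all(np.isfinite(self.values[self.valid])):
            raise ValueError("values must be finite wherever valid")

    def __len__(self) -> int:
        return len(self.dates)

    @classmethod
    def from_records(
        cls, user_id: str, records: Iterable[tuple[dt.date, float]]
    ) -> "TemperatureSeries":
        """Build a series from (date, value) pairs; NaN values become invalid."""
        recs = sorted(records, key=lambda r: r[0])
        dates = [r[0] for r in recs]
        values = np.array([r[1] for r in recs], dtype=float)
        valid = np.isfinite(values)
        values = np.where(valid, values, np.nan)
        return cls(user_id, dates, values, valid)

    def regularize(
        self, start: Optional[dt.date] = None, end: Optional[dt.date] = None
    ) -> "TemperatureSeries":
        """Return a copy on a contiguous nightly grid over [start, end].

        Nights absent from the series become explicit invalid entries.
        """
        if len(self.dates) == 0 and (start is None or end is None):
            raise ValueError("cannot regularize an empty series without bounds")
        start = start or self.dates[0]
        end = end or self.dates[-1]
        n = (end - start).days + 1
        if n < 1:
            raise ValueError("end precedes start")
        grid = [start + dt.timedelta(days=i) for i in range(n)]
        lookup = {d: i for i, d in enumerate(self.dates)}
        values = np.full(n, np.nan)
        valid = np.zeros(n, dtype=bool)
        for j, d in enumerate(grid):
            i = lookup.get(d)
            if i is not None and self.valid[i]:
                values[j] = self.values[i]
                valid[j] = True
        return TemperatureSeries(self.user_id, grid, values, valid)

    def window(self, end: dt.date, n_nights: int) -> "TemperatureSeries":
        """The contiguous ``n_nights`` lookback ending at ``end`` (inclusive)."""
        start = end - dt.timedelta(days=n_nights - 1)
        return self.regularize(start, end)

    def replace(self, **kw) -> "TemperatureSeries":
        d = dict(user_id=self.user_id, dates=self.dates, values=self.values, valid=self.valid)
        d.update(kw)
        return TemperatureSeries(**d)


@dataclass(frozen=True)
class CycleRecord:
    """One menstrual cycle delimited by consecutive menses onsets.

    ``cycle_length`` follows the half-open convention
    ``[period_start, next_period_start)``: the number of days between the
    two onsets.  ``period_end``/``next_period_start`` may be None for
    incomplete cycles, which eligibility screening rejects.
    """

    user_id: str
    period_start: dt.date
    period_end: Optional[dt.date] = None
    next_period_start: Optional[dt.date] = None
    age_years: Optional[int] = None
    hormone_use: bool = False
    pregnant: bool = False

    def __post_init__(self) -> None:
        if self.period_end is not None and self.period_end < self.period_start:
            raise ValueError("period_end before period_start")
        if self.next_period_start is not None:
            if self.next_period_start <= self.period_start:
                raise ValueError("next_period_start must follow period_start")
            if self.period_end is not None and self.next_period_start <= self.period_end:
                raise ValueError("next_period_start must follow period_end")

    @property
    def complete(self) -> bool:
        return self.period_end is not None and self.next_period_start is not None

    @property
    def cycle_length(self) -> Optional[int]:
        if self.next_period_start is None:
            return None
        return (self.next_period_start - self.period_start).days

    def cycle_day(self, date: dt.date) -> int:
        """1-based cycle-day index of ``date`` (period_start is day 1)."""
        return (date - self.period_start).days + 1

    @property
    def cycle_id(self) -> tuple[str, str]:
        return (self.user_id, self.period_start.isoformat())


@dataclass(frozen=True)
class ReferenceOvulation:
    """Benchmark ovulation date: the day after the last positive LH test."""

    cycle: CycleRecord
    last_positive_lh: dt.date

    @property
    def reference_date(self) -> dt.date:
        return self.last_positive_lh + ONE_DAY


@dataclass(frozen=True)
class OvulationEstimate:
    """A method's output for one cycle: a date, or an explicit failure."""

    cycle: CycleRecord
    method: Method
    detected: bool
    estimated_date: Optional[dt.date] = None
    failure_reason: FailureReason = FailureReason.NONE

    def __post_init__(self) -> None:
        ok = self.detected and self.estimated_date is not None and self.failure_reason is FailureReason.NONE
        fail = (not self.detected) and self.estimated_date is None and self.failure_reason is not FailureReason.NONE
        if not (ok or fail):
            raise ValueError(
                "detected=True requires a date and reason 'none'; "
                "detected=False requires no date and a failure reason"
            )


@dataclass(frozen=True)
class SubgroupLabel:
    length_class: LengthClass
    variability_class: VariabilityClass
    age_class: Optional[AgeClass]


def classify_cycle_length(cycle_length: int) -> LengthClass:
    """Bin a cycle length (days) into the five clinical classes.

    <=21 abnormally short; 22-26 short; 27-31 medium; 32-35 long;
    >=36 abnormally long.
    """
    if cycle_length < 1:
        raise ValueError(f"cycle length must be >= 1 day, got {cycle_length}")
    if cycle_length <= 21:
        return LengthClass.ABNORMALLY_SHORT
    if cycle_length <= 26:
        return LengthClass.SHORT
    if cycle_length <= 31:
        return LengthClass.MEDIUM
    if cycle_length <= 35:
        return LengthClass.LONG
    return LengthClass.ABNORMALLY_LONG


def cycle_variability(prior_cycle_lengths: Sequence[float]) -> Optional[float]:
    """Median absolute difference between consecutive cycle lengths.

    None when fewer than two lengths are available.
    """
    if len(prior_cycle_lengths) < 2:
        return None
    diffs = np.abs(np.diff(np.asarray(prior_cycle_lengths, dtype=float)))
    return float(np.median(diffs))


def classify_variability(prior_cycle_lengths: Sequence[float]) -> VariabilityClass:
    """Bin cycle variability: 0-3 typical, 4-7 moderately irregular, >7
    abnormally irregular; unknown with fewer than two prior lengths.

    The median of an even number of absolute differences can be a
    half-integer; bin edges are applied to the real-valued median with
    half-values resolved downward (m <= 3 typical, 3 < m <= 7 moderate,
    m > 7 abnormal).
    """
    m = cycle_variability(prior_cycle_lengths)
    if m is None:
        return VariabilityClass.UNKNOWN
    if m <= 3:
        return VariabilityClass.TYPICAL
    if m <= 7:
        return VariabilityClass.MODERATELY_IRREGULAR
    return VariabilityClass.ABNORMALLY_IRREGULAR


def classify_age(age_years: int) -> AgeClass:
    """Bin age into 18-26 / 27-34 / 35-43 / >=44 years.

    Raises for ages under 18: the method is unvalidated in adolescents.
    """
    if age_years < 18:
        raise ValueError(
            f"age {age_years} is outside the validated range (>= 18 years)"
        )
    if age_years <= 26:
        return AgeClass.A18_26
    if age_years <= 34:
        return AgeClass.A27_34
    if age_years <= 43:
        return AgeClass.A35_43
    return AgeClass.A44_PLUS
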