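"""Physiology-based ovulation detection from nightly skin temperature.

The detector estimates the most recent ovulation date from a fixed-length
lookback of nightly finger skin-temperature readings plus the user's
period-start log.  The pipeline has six stages:

1. mean-center the valid nights (``normalize``),
2. reject nights more than ``outlier_sd`` standard deviations from the
   window mean (``reject_outliers``),
3. linearly impute missing or rejected nights (``impute_linear``),
4. zero-phase Butterworth bandpass to isolate the ~monthly biphasic wave
   while removing slow drift and night-to-night noise (``bandpass``),
5. hysteresis thresholding to segment follicular vs luteal nights
   (``hysteresis_segment``),
6. postprocessing: the candidate ovulation date is the last follicular
   day before the final follicular-to-luteal transition of the current
   cycle; detections implying a luteal phase outside 7-17 days or a
   follicular phase outside 10-90 days are rejected as failures.

The post-ovulatory signature is a maintained rise of roughly 0.3-0.7 degC.
Filter cutoffs and hysteresis thresholds are engineering defaults exposed
in :class:`DetectorConfig`; override them freely.

Use :class:`PhysiologyDetector` (a model object over one user's data) and
its :meth:`~PhysiologyDetector.fit`, or the one-shot
:func:`detect_ovulation`.
"""
from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .core import (
    ONE_DAY,
    CycleRecord,
    FailureReason,
    Method,
    OvulationEstimate,
    TemperatureSeries,
)
from .eligibility import check_physiology_sufficiency

__all__ = [
    "DetectorConfig",
    "Phase",
    "SegmentedSeries",
    "InsufficientDataError",
    "normalize",
    "reject_outliers",
    "impute_linear",
    "bandpass",
    "hysteresis_segment",
    "detect_ovulation",
    "PhysiologyDetector",
    "PhysiologyResults",
]


class InsufficientDataError(ValueError):
    """Raised by pipeline stages whose input carries too few valid nights."""


@dataclass(frozen=True)
class DetectorConfig:
    """Tunable parameters of the physiology pipeline.

    Attributes
    ----------
    lookback_days : int
        Nights of input consumed, ending at the analysis date.
    outlier_sd : float
        Rejection threshold as a multiple of the window SD (strict ``>``).
    bp_low_cut, bp_high_cut : float
        Butterworth passband edges in cycles/day.  The defaults pass the
        fundamental of a ~monthly biphasic wave and its low harmonics
        while removing multi-month drift and nightly noise.
    bp_order : int
        Butterworth filter order (applied forward-backward).
    hyst_high, hyst_low : float
        Hysteresis thresholds in degC on the filtered, centered signal:
        the state switches to luteal at ``>= hyst_high`` and back to
        follicular at ``<= hyst_low``.
    luteal_range, follicular_range : (int, int)
        Biological plausibility gates in days; estimates implying phase
        lengths outside these are rejected.
    max_missing_fraction : float
        More than this fraction of missing nights in the lookback is an
        insufficient-data failure.
    """

    lookback_days: int = 60
    outlier_sd: float = 2.0
    bp_low_cut: float = 1.0 / 60.0
    bp_high_cut: float = 1.0 / 5.0
    bp_order: int = 2
    hyst_high: float = 0.05
    hyst_low: float = -0.10
    luteal_range: tuple[int, int] = (7, 17)
    follicular_range: tuple[int, int] = (10, 90)
    max_missing_fraction: float = 0.40

    def __post_init__(self) -> None:
        if not (0.0 < self.bp_low_cut < self.bp_high_cut < 0.5):
            raise ValueError("need 0 < bp_low_cut < bp_high_cut < 0.5 cycles/day")
        if self.hyst_low > self.hyst_high:
            raise ValueError("hyst_low must not exceed hyst_high")


class Phase(str, enum.Enum):
    FOLLICULAR = "follicular"
    LUTEAL = "luteal"
    UNDETERMINED = "undetermined"


@dataclass
class SegmentedSeries:
    """Filtered window plus a per-night follicular/luteal label."""

    dates: Sequence[dt.date]
    filtered_values: np.ndarray
    phase_labels: list[Phase]

    def transitions(self) -> list[dt.date]:
        """Dates of follicular-to-luteal switches (first luteal night)."""
        out = []
        for i in range(1, len(self.phase_labels)):
            if (
                self.phase_labels[i] is Phase.LUTEAL
                and self.phase_labels[i - 1] is Phase.FOLLICULAR
            ):
                out.append(self.dates[i])
        return out


# ---------------------------------------------------------------------------
# pipeline stages


def normalize(series: TemperatureSeries) -> TemperatureSeries:
    """Center the series: subtract the mean of the valid nights."""
    if series.valid.sum() < 1:
        raise InsufficientDataError("no valid nights to normalize")
    mean = series.values[series.valid].mean()
    values = series.values.copy()
    values[series.valid] -= mean
    return series.replace(values=values)


def reject_outliers(series: TemperatureSeries, sd_multiple: float = 2.0) -> TemperatureSeries:
    """Invalidate nights strictly more than ``sd_multiple`` SDs from the
    mean of the window's valid nights.  Zero SD rejects nothing."""
    vals = series.values[series.valid]
    if vals.size == 0:
        return series
    mean, sd = vals.mean(), vals.std()
    if sd == 0:
        return series
    valid = series.valid & ~(np.abs(series.values - mean) > sd_multiple * sd)
    return series.replace(valid=valid)


def impute_linear(series: TemperatureSeries) -> TemperatureSeries:
    """Fill invalid nights by linear interpolation between valid neighbours.

    Leading/trailing invalid nights take the nearest valid value (linear
    fill is undefined there).  Requires at least two valid nights.
    """
    if series.valid.sum() < 2:
        raise InsufficientDataError("linear imputation needs >= 2 valid nights")
    idx = np.arange(len(series))
    # np.interp performs the interior linear fill and constant edge extension
    values = np.interp(idx, idx[series.valid], series.values[series.valid])
    return series.replace(values=values, valid=np.ones(len(series), dtype=bool))


def bandpass(series: TemperatureSeries, cfg: DetectorConfig) -> TemperatureSeries:
    """Zero-phase Butterworth bandpass at nightly sampling (fs = 1/day).

    Forward-backward application (``filtfilt``) avoids the phase lag that
    a causal filter would add to the estimated transition date.
    """
    if not series.valid.all():
        raise ValueError("bandpass requires a fully imputed series")
    sos = signal.butter(
        cfg.bp_order, [cfg.bp_low_cut, cfg.bp_high_cut], btype="bandpass",
        fs=1.0, output="sos",
    )
    # filtfilt pads by reflection; require a window a few times the filter
    # impulse-response scale for the edges to be meaningful
    padlen = 3 * (2 * cfg.bp_order + 1)
    if len(series) <= padlen:
        raise InsufficientDataError(
            f"window of {len(series)} nights too short for order-{cfg.bp_order} bandpass"
        )
    filtered = signal.sosfiltfilt(sos, series.values)
    return series.replace(values=filtered)


def hysteresis_segment(series: TemperatureSeries, cfg: DetectorConfig) -> SegmentedSeries:
    """Two-threshold segmentation of the filtered signal.

    Scanning forward in time from an initial follicular state, the state
    switches to luteal when the value reaches ``hyst_high`` and back to
    follicular when it falls to ``hyst_low``; between the thresholds the
    previous state persists, suppressing flicker from residual noise.
    """
    labels: list[Phase] = []
    state = Phase.FOLLICULAR
    for v in series.values:
        if state is Phase.FOLLICULAR and v >= cfg.hyst_high:
            state = Phase.LUTEAL
        elif state is Phase.LUTEAL and v <= cfg.hyst_low:
            state = Phase.FOLLICULAR
        labels.append(state)
    return SegmentedSeries(list(series.dates), series.values.copy(), labels)


# ---------------------------------------------------------------------------
# model / results


@dataclass
class PhysiologyResults:
    """Output of :meth:`PhysiologyDetector.fit` for one analysis date.

    Attributes
    ----------
    estimate : OvulationEstimate
        The detection outcome (date or explicit failure).
    segmented : SegmentedSeries or None
        Per-night phase labels over the lookback window (None when the
        pipeline stopped at the sufficiency gate).
    diagnostics : dict
        Stage bookkeeping: nights in window, valid nights, outliers
        rejected, nights imputed, transition dates, candidate phase
        lengths.
    """

    estimate: OvulationEstimate
    segmented: Optional[SegmentedSeries]
    diagnostics: dict

    @property
    def detected(self) -> bool:
        return self.estimate.detected

    @property
    def estimated_date(self) -> Optional[dt.date]:
        return self.estimate.estimated_date

    def summary(self) -> str:
        e = self.estimate
        d = self.diagnostics
        lines = [
            "Physiology ovulation detection",
            "==============================",
            f"cycle start:        {e.cycle.period_start}",
            f"analysis date:      {d.get('as_of')}",
            f"window:             {d.get('window_nights')} nights, "
            f"{d.get('valid_nights')} valid",
            f"outliers rejected:  {d.get('n_outliers', 0)}",
            f"nights imputed:     {d.get('n_imputed', 0)}",
            f"transitions:        {', '.join(map(str, d.get('transitions', []))) or 'none'}",
            f"detected:           {e.detected}",
        ]
        if e.detected:
            lines += [
                f"estimated ovulation: {e.estimated_date}",
                f"follicular length:  {d.get('follicular_length')} d",
                f"luteal length:      {d.get('luteal_length')} d",
            ]
        else:
            lines.append(f"failure reason:     {e.failure_reason.value}")
        return "\n".join(lines)


class PhysiologyDetector:
    """Model object binding one user's temperature series and period log.

    Parameters
    ----------
    series : TemperatureSeries
        Nightly temperatures (gaps allowed; regularized internally).
    period_starts : sequence of datetime.date
        Menses onset dates for the user, including the current cycle's.
    config : DetectorConfig, optional

    Examples
    --------
    >>> det = PhysiologyDetector(series, period_starts)       # doctest: +SKIP
    >>> res = det.fit(as_of=date(2024, 3, 1))                 # doctest: +SKIP
    >>> res.estimated_date, res.estimate.failure_reason       # doctest: +SKIP
    """

    def __init__(
        self,
        series: TemperatureSeries,
        period_starts: Sequence[dt.date],
        config: Optional[DetectorConfig] = None,
    ) -> None:
        if not period_starts:
            raise ValueError("need at least one period start")
        self.series = series
        self.period_starts = sorted(period_starts)
        self.config = config or DetectorConfig()

    def _current_cycle(self, as_of: dt.date) -> tuple[dt.date, Optional[dt.date]]:
        starts = [p for p in self.period_starts if p <= as_of]
        if not starts:
            raise ValueError(f"no period start on or before {as_of}")
        cur = starts[-1]
        later = [p for p in self.period_starts if p > cur]
        return cur, (later[0] if later else None)

    def fit(self, as_of: Optional[dt.date] = None) -> PhysiologyResults:
        """Run the pipeline over the lookback ending at ``as_of``.

        ``as_of`` defaults to the last night of the series.  The luteal
        plausibility check uses the true cycle length when the next
        period start is known, and the days elapsed since the candidate
        date otherwise.
        """
        cfg = self.config
        if as_of is None:
            as_of = self.series.dates[-1]
        cycle_start, next_start = self._current_cycle(as_of)
        cycle = CycleRecord(
            self.series.user_id, cycle_start,
            period_end=None, next_period_start=next_start,
        )
        diags: dict = {"as_of": as_of, "window_nights": cfg.lookback_days}

        def failure(reason: FailureReason) -> PhysiologyResults:
            est = OvulationEstimate(cycle, Method.PHYSIOLOGY, False, None, reason)
            return PhysiologyResults(est, diags.pop("_segmented", None), diags)

        window = self.series.window(as_of, cfg.lookback_days)
        diags["valid_nights"] = int(window.valid.sum())
        if not check_physiology_sufficiency(
            self.series, as_of, cfg.lookback_days, cfg.max_missing_fraction
        ):
            return failure(FailureReason.INSUFFICIENT_DATA)

        try:
            centered = normalize(window)
            cleaned = reject_outliers(centered, cfg.outlier_sd)
            diags["n_outliers"] = int(centered.valid.sum() - cleaned.valid.sum())
            imputed = impute_linear(cleaned)
            diags["n_imputed"] = int(len(imputed) - cleaned.valid.sum())
            filtered = bandpass(imputed, cfg)
        except InsufficientDataError:
            return failure(FailureReason.INSUFFICIENT_DATA)

        segmented = hysteresis_segment(filtered, cfg)
        diags["_segmented"] = segmented
        diags["transitions"] = segmented.transitions()

        # candidate = day before the LAST follicular->luteal switch that
        # falls inside the current cycle (most recent ovulation wins)
        in_cycle = [t for t in diags["transitions"] if t > cycle_start]
        if not in_cycle:
            return failure(FailureReason.IMPLAUSIBLE_LUTEAL)  # no sustained rise
        candidate = in_cycle[-1] - ONE_DAY

        foll = cycle.cycle_day(candidate)
        if next_start is not None:
            lut = cycle.cycle_length - foll
        else:
            lut = (as_of - candidate).days
        diags["follicular_length"] = foll
        diags["luteal_length"] = lut
        if not (cfg.follicular_range[0] <= foll <= cfg.follicular_range[1]):
            return failure(FailureReason.IMPLAUSIBLE_FOLLICULAR)
        if not (cfg.luteal_range[0] <= lut <= cfg.luteal_range[1]):
            return failure(FailureReason.IMPLAUSIBLE_LUTEAL)

        est = OvulationEstimate(cycle, Method.PHYSIOLOGY, True, candidate)
        return PhysiologyResults(est, segmented, diags)


def detect_ovulation(
    series: TemperatureSeries,
    period_starts: Sequence[dt.date],
    config: Optional[DetectorConfig] = None,
    as_of: Optional[dt.date] = None,
) -> OvulationEstimate:
    """One-shot convenience wrapper around :class:`PhysiologyDetector`."""
    return PhysiologyDetector(series, period_starts, config).fit(as_of).estimate
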