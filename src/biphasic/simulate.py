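"""Synthetic cohorts of nightly temperature series with known ovulations.

The generative model mirrors the biphasic physiology the detector
assumes: each cycle holds a follicular baseline followed by a maintained
post-ovulatory rise of 0.3-0.7 degC reached through a short sigmoid ramp
centered on the day after ovulation, with Gaussian night-to-night noise
and i.i.d. missing nights.  Cycle lengths are drawn per user around a
population mean of 29.1 (SD 3.4) days, with within-user irregularity
controlling the spread of consecutive-length differences; luteal lengths
center on 12 days and are constrained so the reference-plausibility
ranges (follicular >= 10, luteal in [8, 20]) hold by construction.

Ground truth is exported as an LH log with a positive test the day
*before* each true ovulation, so the reference pipeline (day after last
positive) reconstructs the truth exactly rather than being bypassed.

Each simulated user receives one unlogged burn-in cycle before their
first reported cycle so every reported cycle has a full lookback of
physiology.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .core import ONE_DAY, CycleRecord, TemperatureSeries

__all__ = ["SimConfig", "SimulatedCycle", "SimulatedCohort", "simulate_cycle", "simulate_cohort"]


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level generative parameters.

    Population defaults: cycle length 29.1 (SD 3.4) days and luteal
    length centered on 12 days; the post-ovulatory rise magnitude is
    uniform on [0.3, 0.7] degC.  ``irregularity`` is the target SD of
    consecutive cycle-length differences within a user (per-cycle jitter
    SD = irregularity / sqrt(2)).  ``rise_ramp_days`` nights separate
    the last fully-follicular level from the full luteal plateau;
    0 gives a hard step.  ``anovulatory_prob`` draws no-rise cycles for
    fuzzing only — no accuracy claim attaches to them.
    """

    n_users: int = 50
    cycles_per_user: int = 3
    burn_in_cycles: int = 1
    start_date: dt.date = dt.date(2023, 1, 1)
    cycle_length_mean: float = 29.1
    cycle_length_sd: float = 3.4          # between-user SD of mean length
    irregularity: float = 2.0             # SD of consecutive length diffs, days
    luteal_mean: float = 12.0
    luteal_sd: float = 1.0
    luteal_clip: tuple[int, int] = (8, 20)
    rise_low: float = 0.3                 # degC
    rise_high: float = 0.7
    rise_ramp_days: float = 1.0
    noise_sd: float = 0.1                 # degC, nightly
    missing_prob: float = 0.1
    baseline_mean: float = 36.4           # degC, follicular skin temperature
    baseline_sd: float = 0.15             # between-user
    age_mean: float = 32.8
    age_sd: float = 5.5
    age_range: tuple[int, int] = (18, 52)
    menses_days: tuple[int, int] = (4, 6)
    anovulatory_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.missing_prob <= 1.0):
            raise ValueError("missing_prob must lie in [0, 1]")
        if self.noise_sd < 0 or self.irregularity < 0 or self.luteal_sd < 0:
            raise ValueError("SDs must be non-negative")
        if not (0.0 < self.rise_low <= self.rise_high):
            raise ValueError("rise magnitudes must be positive with low <= high")


@dataclass
class SimulatedCycle:
    cycle: CycleRecord
    true_ovulation: Optional[dt.date]     # None for anovulatory fuzz cycles
    rise_magnitude: float


def _rise_fraction(day: np.ndarray, ovulation_day: int, ramp_days: float) -> np.ndarray:
    """Fraction of the luteal rise reached on each 1-based cycle day.

    Exactly 0 through the ovulation day and exactly 1 from day
    ``ovulation + 1 + ramp_days`` on, with a smooth sigmoid (smoothstep)
    ramp centered near ovulation + 1 in between.
    """
    x = np.clip((day - ovulation_day) / (ramp_days + 1.0), 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _draw_luteal(rng: np.random.Generator, cfg: SimConfig, cycle_length: int) -> int:
    lo, hi = cfg.luteal_clip
    hi = min(hi, cycle_length - 10)   # keep follicular >= 10 by construction
    if hi < lo:
        raise ValueError(
            f"cycle length {cycle_length} cannot host luteal >= {lo} with follicular >= 10"
        )
    for _ in range(100):
        lut = int(round(rng.normal(cfg.luteal_mean, cfg.luteal_sd)))
        if lo <= lut <= hi:
            return lut
    return int(np.clip(round(cfg.luteal_mean), lo, hi))


def simulate_cycle(
    cfg: SimConfig,
    rng: np.random.Generator,
    start: dt.date,
    cycle_length: int,
    baseline: float,
    user_id: str = "u0",
    age: Optional[int] = None,
) -> tuple[np.ndarray, SimulatedCycle]:
    """Generate one cycle's nightly temperatures and ground truth.

    Returns the temperature values for the cycle's ``cycle_length``
    nights (noise included, missingness *not* applied — the cohort
    generator masks nights) plus the cycle record and true ovulation.
    """
    days = np.arange(1, cycle_length + 1)
    anovulatory = rng.random() < cfg.anovulatory_prob
    rise = float(rng.uniform(cfg.rise_low, cfg.rise_high))
    if anovulatory:
        profile = np.zeros(cycle_length)
        true_ov = None
    else:
        luteal = _draw_luteal(rng, cfg, cycle_length)
        ov_day = cycle_length - luteal
        profile = rise * _rise_fraction(days, ov_day, cfg.rise_ramp_days)
        true_ov = start + dt.timedelta(days=ov_day - 1)
    temps = baseline + profile
    if cfg.noise_sd > 0:
        temps = temps + rng.normal(0.0, cfg.noise_sd, size=cycle_length)
    menses = int(rng.integers(cfg.menses_days[0], cfg.menses_days[1] + 1))
    record = CycleRecord(
        user_id=user_id,
        period_start=start,
        period_end=start + dt.timedelta(days=menses - 1),
        next_period_start=start + dt.timedelta(days=cycle_length),
        age_years=age,
    )
    return temps, SimulatedCycle(record, true_ov, rise)


@dataclass
class SimulatedCohort:
    """In-memory cohort: series per user plus cycle records and truth."""

    config: SimConfig
    series: dict[str, TemperatureSeries]
    cycles: list[SimulatedCycle]
    ages: dict[str, int]

    @property
    def records(self) -> list[CycleRecord]:
        return [c.cycle for c in self.cycles]

    def lh_logs(self) -> dict[str, list[dt.date]]:
        """Positive-LH dates encoding truth (test on ovulation - 1 day)."""
        logs: dict[str, list[dt.date]] = {}
        for c in self.cycles:
            if c.true_ovulation is not None:
                logs.setdefault(c.cycle.user_id, []).append(c.true_ovulation - ONE_DAY)
        return logs

    def to_csv(self, out_dir: str | Path) -> dict[str, Path]:
        """Write temperatures/periods/lh_tests/users CSVs; returns paths."""
        from . import io as _io
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "temperatures": out / "temperatures.csv",
            "periods": out / "periods.csv",
            "lh_tests": out / "lh_tests.csv",
            "users": out / "users.csv",
        }
        _io.write_temperatures(paths["temperatures"], self.series.values())
        _io.write_periods(paths["periods"], self.records)
        _io.write_lh_tests(paths["lh_tests"], self.lh_logs())
        _io.write_users(
            paths["users"],
            {u: {"age": a, "hormone_use": False, "pregnant": False} for u, a in self.ages.items()},
        )
        return paths


def simulate_cohort(cfg: SimConfig) -> SimulatedCohort:
    """Generate a full cohort under ``cfg`` (deterministic in ``cfg.seed``).

    Per user: a mean cycle length is drawn from the population
    distribution, then ``burn_in_cycles + cycles_per_user`` cycle lengths
    around it; only post-burn-in cycles are reported as records, but
    temperatures cover the whole span so every reported cycle has full
    lookback physiology.
    """
    rng = np.random.default_rng(cfg.seed)
    series: dict[str, TemperatureSeries] = {}
    cycles: list[SimulatedCycle] = []
    ages: dict[str, int] = {}
    min_len = 23  # floor keeping luteal>=8 and follicular>=10 satisfiable with margin

    for u in range(cfg.n_users):
        uid = f"u{u:04d}"
        age = int(np.clip(round(rng.normal(cfg.age_mean, cfg.age_sd)), *cfg.age_range))
        ages[uid] = age
        baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd)
        user_mean = rng.normal(cfg.cycle_length_mean, cfg.cycle_length_sd)
        jitter_sd = cfg.irregularity / np.sqrt(2.0)
        n_cycles = cfg.burn_in_cycles + cfg.cycles_per_user
        lengths = [
            max(min_len, int(round(rng.normal(user_mean, jitter_sd)))) if jitter_sd > 0
            else max(min_len, int(round(user_mean)))
            for _ in range(n_cycles)
        ]
        # stagger cohort start dates so cycles do not all align
        start = cfg.start_date + dt.timedelta(days=int(rng.integers(0, 28)))
        all_temps: list[float] = []
        first_night = start
        for k, L in enumerate(lengths):
            temps, sim = simulate_cycle(cfg, rng, start, L, baseline, uid, age)
            all_temps.extend(temps.tolist())
            if k >= cfg.burn_in_cycles:
                cycles.append(sim)
            start = sim.cycle.next_period_start
        n_nights = len(all_temps)
        dates = [first_night + dt.timedelta(days=i) for i in range(n_nights)]
        valid = rng.random(n_nights) >= cfg.missing_prob
        values = np.where(valid, np.asarray(all_temps), np.nan)
        series[uid] = TemperatureSeries(uid, dates, values, valid)

    return SimulatedCohort(cfg, series, cycles, ages)
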