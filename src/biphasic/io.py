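"""CSV readers/writers for the package's four input dialects.

All files are comma-separated with a header row and ISO-8601 dates:

- ``temperatures.csv``: user_id,date,temp_c (blank temp = missing night)
- ``periods.csv``: user_id,period_start,period_end
- ``lh_tests.csv``: user_id,date,result (result in {positive, negative})
- ``users.csv``: user_id,age,hormone_use,pregnant

Cycle records are derived from consecutive period starts per user: each
start's cycle ends at the user's next logged start; the last logged
period yields an incomplete cycle.
"""
from __future__ import annotations

import datetime as dt
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import CycleRecord, OvulationEstimate, TemperatureSeries

__all__ = [
    "read_temperatures",
    "read_periods",
    "read_lh_tests",
    "read_users",
    "write_temperatures",
    "write_periods",
    "write_lh_tests",
    "write_users",
    "write_estimates",
]


def _to_date(s) -> dt.date:
    return pd.Timestamp(s).date()


def read_temperatures(path: str | Path) -> dict[str, TemperatureSeries]:
    df = pd.read_csv(path, dtype={"user_id": str})
    out: dict[str, TemperatureSeries] = {}
    for uid, sub in df.groupby("user_id", sort=True):
        records = [
            (_to_date(r.date), float(r.temp_c) if pd.notna(r.temp_c) else float("nan"))
            for r in sub.itertuples()
        ]
        out[uid] = TemperatureSeries.from_records(uid, records)
    return out


def read_periods(
    path: str | Path, users: Optional[Mapping[str, dict]] = None
) -> list[CycleRecord]:
    """Periods CSV -> cycle records (user metadata merged when given)."""
    df = pd.read_csv(path, dtype={"user_id": str})
    cycles: list[CycleRecord] = []
    for uid, sub in df.groupby("user_id", sort=True):
        sub = sub.sort_values("period_start")
        starts = [_to_date(s) for s in sub["period_start"]]
        ends = [
            _to_date(e) if pd.notna(e) else None for e in sub["period_end"]
        ]
        meta = (users or {}).get(uid, {})
        for i, (start, end) in enumerate(zip(starts, ends)):
            nxt = starts[i + 1] if i + 1 < len(starts) else None
            cycles.append(
                CycleRecord(
                    user_id=uid,
                    period_start=start,
                    period_end=end,
                    next_period_start=nxt,
                    age_years=meta.get("age"),
                    hormone_use=bool(meta.get("hormone_use", False)),
                    pregnant=bool(meta.get("pregnant", False)),
                )
            )
    return cycles


def read_lh_tests(path: str | Path) -> dict[str, list[dt.date]]:
    """Positive LH test dates per user (negative rows are ignored)."""
    df = pd.read_csv(path, dtype={"user_id": str})
    pos = df[df["result"].str.lower() == "positive"]
    out: dict[str, list[dt.date]] = {}
    for uid, sub in pos.groupby("user_id", sort=True):
        out[uid] = sorted(_to_date(d) for d in sub["date"])
    return out


def read_users(path: str | Path) -> dict[str, dict]:
    df = pd.read_csv(path, dtype={"user_id": str})
    out = {}
    for r in df.itertuples():
        out[r.user_id] = {
            "age": int(r.age) if pd.notna(r.age) else None,
            "hormone_use": bool(r.hormone_use),
            "pregnant": bool(r.pregnant),
        }
    return out


def write_temperatures(path: str | Path, series: Iterable[TemperatureSeries]) -> None:
    rows = []
    for s in series:
        for d, v, ok in zip(s.dates, s.values, s.valid):
            rows.append(
                {"user_id": s.user_id, "date": d.isoformat(),
                 "temp_c": round(float(v), 4) if ok else ""}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_periods(path: str | Path, cycles: Iterable[CycleRecord]) -> None:
    # merge by onset: the closing onset of one cycle is the start of the
    # next, and a row with a logged period_end wins over a bare onset
    ends: dict[tuple, str] = {}
    for c in cycles:
        key = (c.user_id, c.period_start.isoformat())
        end = c.period_end.isoformat() if c.period_end else ""
        ends[key] = ends.get(key) or end
        if c.next_period_start is not None:
            nxt = (c.user_id, c.next_period_start.isoformat())
            ends.setdefault(nxt, "")
    rows = [
        {"user_id": u, "period_start": s, "period_end": e}
        for (u, s), e in sorted(ends.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_lh_tests(path: str | Path, logs: Mapping[str, Sequence[dt.date]]) -> None:
    rows = [
        {"user_id": uid, "date": d.isoformat(), "result": "positive"}
        for uid in sorted(logs) for d in sorted(logs[uid])
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_users(path: str | Path, users: Mapping[str, dict]) -> None:
    rows = [
        {"user_id": uid, "age": meta.get("age", ""),
         "hormone_use": bool(meta.get("hormone_use", False)),
         "pregnant": bool(meta.get("pregnant", False))}
        for uid, meta in sorted(users.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_estimates(path: str | Path, estimates: Iterable[OvulationEstimate]) -> None:
    rows = [
        {
            "user_id": e.cycle.user_id,
            "period_start": e.cycle.period_start.isoformat(),
            "method": e.method.value,
            "detected": e.detected,
            "estimated_date": e.estimated_date.isoformat() if e.estimated_date else "",
            "failure_reason": e.failure_reason.value,
        }
        for e in estimates
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
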