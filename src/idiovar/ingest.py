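"""Diary-log ingestion: derive analysis variables and align daily series.

Three analysis variables are derived per patient-day:

* time in bed (TIB, minutes) — elapsed time from the go-to-bed clock time to
  the next occurrence of the get-up clock time (24 h wrap across midnight);
* total sleep time (TST, minutes) — the self-reported minutes slept;
* depression core symptoms — the mean of the two 0–10 evening items.

The alignment convention is lag-0 contemporaneity: the sleep episode ending
on the morning of day *t* shares index *t* with that day's evening depression
rating, so a lag-1 VAR coefficient is last night's sleep predicting today's
rating (and yesterday's rating predicting last night's sleep).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import RawDiaryLog

__all__ = [
    "PatientSeries",
    "InclusionDecision",
    "compute_time_in_bed",
    "compute_depression_score",
    "align_series",
    "inclusion_filter",
    "read_diary_csv",
    "frame_to_logs",
]

ANALYSIS_VARIABLES = ("tib_min", "tst_min", "dep_score")


@dataclass
class PatientSeries:
    """Aligned daily series for one patient; missing entries are NaN."""

    patient_id: str
    dates: pd.DatetimeIndex
    tib_min: np.ndarray
    tst_min: np.ndarray
    dep_score: np.ndarray
    invalid_days: list = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.dates)
        for name in ANALYSIS_VARIABLES:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} length {arr.shape} != {n} dates")
            setattr(self, name, arr)

    @property
    def n_days(self) -> int:
        return len(self.dates)

    @property
    def missing_mask(self) -> dict[str, np.ndarray]:
        return {v: np.isnan(getattr(self, v)) for v in ANALYSIS_VARIABLES}

    def missing_fractions(self) -> dict[str, float]:
        return {v: float(np.isnan(getattr(self, v)).mean()) for v in ANALYSIS_VARIABLES}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": self.patient_id,
                "date": self.dates.strftime("%Y-%m-%d"),
                "tib_min": self.tib_min,
                "tst_min": self.tst_min,
                "dep_score": self.dep_score,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PatientSeries":
        pid = str(frame["patient_id"].iloc[0])
        return cls(
            patient_id=pid,
            dates=pd.DatetimeIndex(pd.to_datetime(frame["date"])),
            tib_min=frame["tib_min"].to_numpy(dtype=float),
            tst_min=frame["tst_min"].to_numpy(dtype=float),
            dep_score=frame["dep_score"].to_numpy(dtype=float),
        )


def _parse_clock(value: str) -> int:
    try:
        t = _dt.datetime.strptime(value.strip(), "%H:%M")
    except (ValueError, AttributeError) as exc:
        raise ValueError(f"invalid clock time {value!r}; expected HH:MM") from exc
    return t.hour * 60 + t.minute


def compute_time_in_bed(go_to_bed: str, get_up: str) -> int:
    """Minutes from ``go_to_bed`` to the next occurrence of ``get_up``.

    Crossing midnight is handled by a 24 h wrap; equal clock times denote a
    zero-length bed interval and are rejected as an invalid entry.
    """
    start = _parse_clock(go_to_bed)
    end = _parse_clock(get_up)
    if start == end:
        raise ValueError(
            f"go_to_bed and get_up are both {go_to_bed!r}: zero-length bed interval"
        )
    return (end - start) % 1440


def compute_depression_score(
    item_interest: float | None, item_mood: float | None
) -> float:
    """Mean of the two 0–10 items; missing if either item is missing."""
    if item_interest is None or item_mood is None:
        return float("nan")
    if np.isnan(item_interest) or np.isnan(item_mood):
        return float("nan")
    return (float(item_interest) + float(item_mood)) / 2.0


def align_series(logs: list[RawDiaryLog]) -> PatientSeries:
    """Align raw logs for one patient onto a gap-free daily index.

    Calendar gaps become all-missing days.  Days where the reported sleep
    minutes exceed the derived time in bed are internally inconsistent and
    both sleep variables are invalidated (it cannot be determined which entry
    is wrong); the offending dates are recorded in ``invalid_days``.
    """
    if not logs:
        raise ValueError("no logs supplied")
    pids = {r.patient_id for r in logs}
    if len(pids) > 1:
        raise ValueError(f"logs span multiple patients: {sorted(pids)}")
    by_date: dict[_dt.date, RawDiaryLog] = {}
    dupes = []
    for r in logs:
        if r.date in by_date:
            dupes.append(r.date)
        by_date[r.date] = r
    if dupes:
        raise ValueError(f"duplicate dates: {sorted(set(dupes))}")

    first, last = min(by_date), max(by_date)
    dates = pd.date_range(first, last, freq="D")
    n = len(dates)
    tib = np.full(n, np.nan)
    tst = np.full(n, np.nan)
    dep = np.full(n, np.nan)
    invalid = []
    for i, ts in enumerate(dates):
        r = by_date.get(ts.date())
        if r is None:
            continue
        if r.go_to_bed is not None and r.get_up is not None:
            tib_i = float(compute_time_in_bed(r.go_to_bed, r.get_up))
            tst_i = float(r.sleep_minutes) if r.sleep_minutes is not None else np.nan
            if not np.isnan(tst_i) and (tst_i > tib_i or tst_i < 0):
                invalid.append(ts.date())
            else:
                tib[i] = tib_i
                tst[i] = tst_i
        dep_i = compute_depression_score(r.item_interest, r.item_mood)
        if not np.isnan(dep_i) and not 0.0 <= dep_i <= 10.0:
            invalid.append(ts.date())
        else:
            dep[i] = dep_i
    return PatientSeries(
        patient_id=logs[0].patient_id,
        dates=dates,
        tib_min=tib,
        tst_min=tst,
        dep_score=dep,
        invalid_days=sorted(set(invalid)),
    )


@dataclass
class InclusionDecision:
    """Outcome of the cohort inclusion filter, with reasons."""

    patient_id: str
    include: bool
    n_days: int
    missing_fractions: dict[str, float]
    reasons: list[str]


def inclusion_filter(
    series: PatientSeries,
    min_days: int = 130,
    max_missing_frac: float = 0.30,
) -> InclusionDecision:
    """Apply the cohort inclusion rule to one aligned series.

    A patient is included iff the continuous recording span reaches
    ``min_days`` and no analysis variable is missing on more than
    ``max_missing_frac`` of the days (assessed per variable).
    """
    fracs = series.missing_fractions()
    reasons = []
    if series.n_days < min_days:
        reasons.append(f"span {series.n_days} days < {min_days}")
    for var, frac in fracs.items():
        if frac > max_missing_frac:
            reasons.append(f"{var} missing fraction {frac:.3f} > {max_missing_frac}")
    return InclusionDecision(
        patient_id=series.patient_id,
        include=not reasons,
        n_days=series.n_days,
        missing_fractions=fracs,
        reasons=reasons,
    )


def frame_to_logs(frame: pd.DataFrame) -> list[RawDiaryLog]:
    """Rebuild :class:`RawDiaryLog` records from the long CSV layout."""

    def _opt(v, cast):
        if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
            return None
        return cast(v)

    logs = []
    for row in frame.itertuples(index=False):
        logs.append(
            RawDiaryLog(
                patient_id=str(row.patient_id),
                date=pd.Timestamp(row.date).date(),
                go_to_bed=_opt(row.go_to_bed, str),
                get_up=_opt(row.get_up, str),
                sleep_minutes=_opt(row.sleep_minutes, lambda v: int(float(v))),
                item_interest=_opt(row.item_interest, float),
                item_mood=_opt(row.item_mood, float),
            )
        )
    return logs


def read_diary_csv(path) -> dict[str, list[RawDiaryLog]]:
    """Read a long-format diary CSV, returning logs grouped by patient."""
    frame = pd.read_csv(path, dtype={"patient_id": str})
    return {
        pid: frame_to_logs(sub) for pid, sub in frame.groupby("patient_id", sort=True)
    }
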