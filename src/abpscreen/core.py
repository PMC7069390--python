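"""Ambulatory and office blood-pressure record handling.

Ingests raw timestamped cuff readings, applies completeness-based quality
control, and computes daytime, nighttime, and time-weighted 24-hour summary
pressures, plus triplicate office-session means.

Clock-time analysis windows follow the IDACO completeness convention:
daytime is 10:00-20:00 and nighttime 00:00-06:00, both half-open, and a
record is usable when it holds at least 10 daytime and 5 nighttime readings.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from datetime import datetime, time, timedelta
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Half-open clock windows used for completeness counts and window means.
DAY_WINDOW = (time(10, 0), time(20, 0))
NIGHT_WINDOW = (time(0, 0), time(6, 0))

#: Completeness minima: readings required inside each window for a usable record.
MIN_DAY_READINGS = 10
MIN_NIGHT_READINGS = 5

#: Optional plausibility bounds (disabled by default).
PLAUSIBILITY_SBP = (60, 260)
PLAUSIBILITY_DBP = (40, 160)
PLAUSIBILITY_MIN_PULSE_PRESSURE = 10


@dataclass(frozen=True)
class Reading:
    """One cuff inflation: a timestamped systolic/diastolic pair in mmHg."""

    timestamp: datetime
    sbp: int
    dbp: int


@dataclass
class ABPMRecord:
    """One subject's ordered 24-h ambulatory monitoring record."""

    subject_id: str
    readings: list[Reading]
    fit_time: Optional[datetime] = None

    def __post_init__(self) -> None:
        self.readings = sorted(self.readings, key=lambda r: r.timestamp)
        if self.fit_time is None and self.readings:
            self.fit_time = self.readings[0].timestamp


@dataclass
class QCResult:
    n_day: int
    n_night: int
    qc_pass: bool


@dataclass
class ABPMSummary:
    """Window means plus the time-weighted 24-h mean for one record."""

    subject_id: str
    n_day: int
    n_night: int
    qc_pass: bool
    day_sbp: float = math.nan
    day_dbp: float = math.nan
    night_sbp: float = math.nan
    night_dbp: float = math.nan
    wt24_sbp: float = math.nan
    wt24_dbp: float = math.nan


@dataclass
class OfficeSession:
    """Triplicate unattended office measurement; the screening test.

    ``complete`` is False when only two readings were usable; sessions with
    fewer than two valid readings are excluded upstream.
    """

    subject_id: str
    readings: list[Reading]
    mean_sbp: float = field(init=False)
    mean_dbp: float = field(init=False)
    complete: bool = field(init=False)

    def __post_init__(self) -> None:
        if len(self.readings) < 2:
            raise ValueError(
                f"office session for {self.subject_id!r} has "
                f"{len(self.readings)} valid readings; at least 2 required"
            )
        self.mean_sbp = float(np.mean([r.sbp for r in self.readings]))
        self.mean_dbp = float(np.mean([r.dbp for r in self.readings]))
        self.complete = len(self.readings) >= 3


def in_clock_window(ts: datetime, window: tuple[time, time]) -> bool:
    """True when the clock time of ``ts`` falls in the half-open ``window``.

    Windows with start > end wrap past midnight.
    """
    start, end = window
    t = ts.time()
    if start <= end:
        return start <= t < end
    return t >= start or t < end


def _plausible(sbp: int, dbp: int) -> bool:
    return (
        PLAUSIBILITY_SBP[0] <= sbp <= PLAUSIBILITY_SBP[1]
        and PLAUSIBILITY_DBP[0] <= dbp <= PLAUSIBILITY_DBP[1]
        and sbp - dbp >= PLAUSIBILITY_MIN_PULSE_PRESSURE
    )


def parse_readings(path, plausibility_filter: bool = False) -> list[ABPMRecord]:
    """Parse an ambulatory readings CSV into per-subject records.

    Expected columns: ``subject_id, timestamp, sbp, dbp`` with ISO-8601 local
    timestamps. Malformed rows (bad timestamp, non-numeric pressure,
    systolic not above diastolic, duplicate timestamp within a subject) are
    excluded and logged with their line number; surviving rows are kept.
    """
    groups: dict[str, list[Reading]] = {}
    seen: dict[str, set[datetime]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for lineno, row in enumerate(reader, start=2):
            sid = (row.get("subject_id") or "").strip()
            if not sid:
                logger.warning("line %d: missing subject_id; row excluded", lineno)
                continue
            try:
                ts = datetime.fromisoformat(row["timestamp"].strip())
            except (KeyError, ValueError, AttributeError):
                logger.warning("line %d: unparseable timestamp; row excluded", lineno)
                continue
            try:
                sbp = int(float(row["sbp"]))
                dbp = int(float(row["dbp"]))
            except (KeyError, ValueError, TypeError):
                logger.warning("line %d: non-numeric pressure; row excluded", lineno)
                continue
            if sbp <= dbp:
                logger.warning(
                    "line %d: sbp %d <= dbp %d; row excluded", lineno, sbp, dbp
                )
                continue
            if plausibility_filter and not _plausible(sbp, dbp):
                logger.warning("line %d: implausible reading; row excluded", lineno)
                continue
            if ts in seen.setdefault(sid, set()):
                logger.warning(
                    "line %d: duplicate timestamp for %s; row excluded", lineno, sid
                )
                continue
            seen[sid].add(ts)
            groups.setdefault(sid, []).append(Reading(ts, sbp, dbp))
    return [ABPMRecord(sid, readings) for sid, readings in groups.items()]


def parse_office(path) -> tuple[list[OfficeSession], list[str]]:
    """Parse the wide office CSV (sbp1..dbp3 columns; blanks = missing).

    Returns usable sessions plus the ids of subjects excluded for having
    fewer than two valid readings.
    """
    sessions: list[OfficeSession] = []
    excluded: list[str] = []
    anchor = datetime(2000, 1, 1)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            sid = row["subject_id"].strip()
            readings = []
            for i in (1, 2, 3):
                s_raw = (row.get(f"sbp{i}") or "").strip()
                d_raw = (row.get(f"dbp{i}") or "").strip()
                if not s_raw or not d_raw:
                    continue
                readings.append(
                    Reading(anchor + timedelta(minutes=i), int(float(s_raw)), int(float(d_raw)))
                )
            if len(readings) < 2:
                logger.warning(
                    "subject %s: %d valid office readings; excluded", sid, len(readings)
                )
                excluded.append(sid)
                continue
            sessions.append(OfficeSession(sid, readings))
    return sessions, excluded


def truncate_record(record: ABPMRecord, hours: float = 24.0) -> ABPMRecord:
    """Return the record restricted to the first ``hours`` from fit time."""
    if record.fit_time is None:
        return record
    end = record.fit_time + timedelta(hours=hours)
    kept = [r for r in record.readings if record.fit_time <= r.timestamp <= end]
    return ABPMRecord(record.subject_id, kept, record.fit_time)


def quality_filter(record: ABPMRecord) -> QCResult:
    """Count window readings and apply the completeness criteria.

    A record passes when it has >= 10 readings with clock time in
    [10:00, 20:00) and >= 5 in [00:00, 06:00).
    """
    n_day = sum(in_clock_window(r.timestamp, DAY_WINDOW) for r in record.readings)
    n_night = sum(in_clock_window(r.timestamp, NIGHT_WINDOW) for r in record.readings)
    return QCResult(n_day, n_night, n_day >= MIN_DAY_READINGS and n_night >= MIN_NIGHT_READINGS)


def window_mean(
    record: ABPMRecord, window: tuple[time, time]
) -> Optional[tuple[float, float]]:
    """Unweighted mean of readings whose clock time falls in ``window``.

    Returns None (flagged missing) when the window holds no readings.
    """
    vals = [(r.sbp, r.dbp) for r in record.readings if in_clock_window(r.timestamp, window)]
    if not vals:
        return None
    arr = np.asarray(vals, dtype=float)
    return float(arr[:, 0].mean()), float(arr[:, 1].mean())


def _interval_weights(seconds: np.ndarray, span_end: float) -> np.ndarray:
    """Represented-interval weight for each reading time (seconds from fit).

    Each reading represents the stretch from the midpoint with its
    predecessor to the midpoint with its successor; the first and last
    intervals are clipped at the record's span [0, span_end].
    """
    mids = (seconds[:-1] + seconds[1:]) / 2.0
    edges = np.concatenate(([0.0], mids, [span_end]))
    edges = np.clip(edges, 0.0, span_end)
    return np.diff(edges)


def weighted_24h_mean(
    record: ABPMRecord, mode: str = "interval"
) -> Optional[tuple[float, float]]:
    """Time-weighted 24-h mean pressure for one record.

    ``interval`` mode weights each reading by the duration it represents
    (midpoint-to-midpoint, clipped at the 24-h span from fit time), which
    compensates for the sparser nighttime sampling schedule. ``hourly`` mode
    instead averages hourly means. Returns None with fewer than 2 readings.
    """
    record = truncate_record(record)
    if len(record.readings) < 2:
        return None
    assert record.fit_time is not None
    secs = np.array(
        [(r.timestamp - record.fit_time).total_seconds() for r in record.readings]
    )
    sbp = np.array([r.sbp for r in record.readings], dtype=float)
    dbp = np.array([r.dbp for r in record.readings], dtype=float)
    if mode == "interval":
        span_end = 24.0 * 3600.0
        w = _interval_weights(secs, span_end)
        return float(np.average(sbp, weights=w)), float(np.average(dbp, weights=w))
    if mode == "hourly":
        hour = np.floor(secs / 3600.0).astype(int)
        df = pd.DataFrame({"hour": hour, "sbp": sbp, "dbp": dbp})
        by_hour = df.groupby("hour").mean()
        return float(by_hour["sbp"].mean()), float(by_hour["dbp"].mean())
    raise ValueError(f"unknown weighting mode {mode!r}")


def office_mean(session: OfficeSession) -> tuple[float, float]:
    """Arithmetic mean of the session's readings (the recorded clinic BP)."""
    return session.mean_sbp, session.mean_dbp


def summarize_record(record: ABPMRecord, weighting_mode: str = "interval") -> ABPMSummary:
    """QC counts plus all window and 24-h means for one record."""
    qc = quality_filter(record)
    summary = ABPMSummary(record.subject_id, qc.n_day, qc.n_night, qc.qc_pass)
    day = window_mean(record, DAY_WINDOW)
    night = window_mean(record, NIGHT_WINDOW)
    wt24 = weighted_24h_mean(record, mode=weighting_mode)
    if day is not None:
        summary.day_sbp, summary.day_dbp = day
    if night is not None:
        summary.night_sbp, summary.night_dbp = night
    if wt24 is not None:
        summary.wt24_sbp, summary.wt24_dbp = wt24
    return summary


def summarize_records(
    records: Iterable[ABPMRecord], weighting_mode: str = "interval"
) -> pd.DataFrame:
    """Summaries for many records as a DataFrame (one row per subject)."""
    rows = [vars(summarize_record(r, weighting_mode)) for r in records]
    cols = [
        "subject_id", "n_day", "n_night", "qc_pass",
        "day_sbp", "day_dbp", "night_sbp", "night_dbp", "wt24_sbp", "wt24_dbp",
    ]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)[cols]


def office_means_frame(sessions: Sequence[OfficeSession]) -> pd.DataFrame:
    rows = [
        {
            "subject_id": s.subject_id,
            "office_sbp": s.mean_sbp,
            "office_dbp": s.mean_dbp,
            "office_complete": s.complete,
        }
        for s in sessions
    ]
    return pd.DataFrame(
        rows, columns=["subject_id", "office_sbp", "office_dbp", "office_complete"]
    )
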