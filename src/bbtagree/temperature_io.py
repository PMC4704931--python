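"""Reading, writing and reduction of temperature logs.

Two plain-CSV formats are supported:

* **daily log** — one row per participant-day and device::

      participant_id,date,cycle_day,device,temp_c,illness,irregular_wake

* **minute stream** — overnight skin-temperature samples at 1-minute
  resolution::

      participant_id,timestamp,temp_c,on_body

Both files may start with ``#``-prefixed comment lines (used to record the
simulation seed).  The dialect is strict: comma separators, period decimal
point, ISO-8601 dates/timestamps, mandatory header row.  Malformed rows are
rejected with their line number.

The module also reduces a minute stream to the daily "basal" values the
analysis runs on: the waking time is located (last on-body minute) and the
mean skin temperature over the 10/30/60/90/120 minutes *preceding* waking is
computed for each night.
"""

from __future__ import annotations

import csv
import datetime as dt
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: recognised device labels in the daily log
DEVICES = (
    "oral",
    "armband-10",
    "armband-30",
    "armband-60",
    "armband-90",
    "armband-120",
)

#: pre-waking averaging windows, minutes
PREWAKING_INTERVALS = (10, 30, 60, 90, 120)

# hard sanity bounds for any recorded temperature, degC
TEMP_MIN = 25.0
TEMP_MAX = 43.0

DAILY_HEADER = [
    "participant_id",
    "date",
    "cycle_day",
    "device",
    "temp_c",
    "illness",
    "irregular_wake",
]
MINUTE_HEADER = ["participant_id", "timestamp", "temp_c", "on_body"]


class SchemaError(ValueError):
    """A CSV file violates the expected schema; ``line`` is 1-based."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class NonWearNightError(ValueError):
    """Raised when an operation needs on-body samples but the night has none."""


@dataclass
class DailyRecord:
    """One participant-day temperature entry for one device."""

    participant_id: str
    date: dt.date
    cycle_day: int
    device: str
    temp_c: float | None  # None = recorded as missing
    illness: bool = False
    irregular_wake: bool = False

    def __post_init__(self) -> None:
        if self.cycle_day < 1:
            raise ValueError(f"cycle_day must be >= 1, got {self.cycle_day}")
        if self.device not in DEVICES:
            raise ValueError(f"unknown device label {self.device!r}")
        if self.temp_c is not None and not (TEMP_MIN <= self.temp_c <= TEMP_MAX):
            raise ValueError(
                f"temp_c {self.temp_c} outside sanity bounds [{TEMP_MIN}, {TEMP_MAX}]"
            )


@dataclass
class CycleSeries:
    """One participant's ordered daily temperatures for one menstrual cycle.

    Day 1 is the first day of menses; ``temps[i]`` is the reading on cycle
    day ``i + 1`` with NaN marking a missing day.  ``next_menses_known``
    records whether the cycle end (and hence its length) was observed, which
    anchors the expected ovulation day.
    """

    participant_id: str
    temps: np.ndarray
    start_date: dt.date
    device: str = "oral"
    illness: np.ndarray | None = None
    irregular_wake: np.ndarray | None = None
    next_menses_known: bool = True

    def __post_init__(self) -> None:
        self.temps = np.asarray(self.temps, dtype=float)
        n = len(self.temps)
        if n == 0:
            raise ValueError("empty cycle series")
        if self.illness is None:
            self.illness = np.zeros(n, dtype=bool)
        else:
            self.illness = np.asarray(self.illness, dtype=bool)
        if self.irregular_wake is None:
            self.irregular_wake = np.zeros(n, dtype=bool)
        else:
            self.irregular_wake = np.asarray(self.irregular_wake, dtype=bool)
        if len(self.illness) != n or len(self.irregular_wake) != n:
            raise ValueError("flag arrays must match temps length")
        finite = self.temps[np.isfinite(self.temps)]
        if finite.size and (finite.min() < TEMP_MIN or finite.max() > TEMP_MAX):
            raise ValueError("temperature outside sanity bounds [25, 43] degC")

    @property
    def cycle_length(self) -> int:
        return len(self.temps)

    @property
    def n_present(self) -> int:
        """Number of days with a recorded (non-missing) temperature."""
        return int(np.isfinite(self.temps).sum())

    def usable_mask(self) -> np.ndarray:
        """Days usable for ovulation criteria: present and not fever-flagged."""
        return np.isfinite(self.temps) & ~self.illness

    def date_of_day(self, cycle_day: int) -> dt.date:
        return self.start_date + dt.timedelta(days=cycle_day - 1)

    def to_records(self) -> list[DailyRecord]:
        out = []
        for i, t in enumerate(self.temps):
            out.append(
                DailyRecord(
                    participant_id=self.participant_id,
                    date=self.date_of_day(i + 1),
                    cycle_day=i + 1,
                    device=self.device,
                    temp_c=None if not np.isfinite(t) else float(t),
                    illness=bool(self.illness[i]),
                    irregular_wake=bool(self.irregular_wake[i]),
                )
            )
        return out


@dataclass
class MinuteStream:
    """Overnight minute-resolution skin-temperature samples for one night.

    ``night_date`` is the calendar date of the *morning* the night ends on,
    i.e. the cycle day the stream's pre-waking means are paired with.
    Off-body samples carry NaN temperatures.  ``wake_time`` may be supplied
    explicitly (e.g. from vendor software); otherwise it is detected as the
    last on-body minute.
    """

    participant_id: str
    night_date: dt.date
    timestamps: np.ndarray  # datetime64[m], strictly increasing
    temp_c: np.ndarray
    on_body: np.ndarray
    wake_time: np.datetime64 | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype="datetime64[m]")
        self.temp_c = np.asarray(self.temp_c, dtype=float)
        self.on_body = np.asarray(self.on_body, dtype=bool)
        if not (len(self.timestamps) == len(self.temp_c) == len(self.on_body)):
            raise ValueError("stream arrays must have equal length")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > np.timedelta64(0, "m")):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def is_worn(self) -> bool:
        return bool(self.on_body.any())

    def wear_episodes(self) -> int:
        """Number of off->on transitions (>=2 means the band was re-worn)."""
        ob = self.on_body.astype(int)
        starts = int(ob[0] == 1) + int(np.sum(np.diff(ob) == 1))
        return starts


# ---------------------------------------------------------------------------
# CSV writing
# ---------------------------------------------------------------------------

def _fmt_temp(t: float | None) -> str:
    if t is None or (isinstance(t, float) and not np.isfinite(t)):
        return ""
    return repr(float(t))


def write_daily_csv(
    series: Iterable[CycleSeries],
    path: str | Path,
    header_comments: dict[str, object] | None = None,
) -> None:
    """Write cycle series to the daily-log CSV format (lossless round-trip)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        for k, v in (header_comments or {}).items():
            fh.write(f"# {k}={v}\n")
        w = csv.writer(fh)
        w.writerow(DAILY_HEADER)
        for s in series:
            for r in s.to_records():
                w.writerow(
                    [
                        r.participant_id,
                        r.date.isoformat(),
                        r.cycle_day,
                        r.device,
                        _fmt_temp(r.temp_c),
                        int(r.illness),
                        int(r.irregular_wake),
                    ]
                )


def write_minute_csv(
    streams: Iterable[MinuteStream],
    path: str | Path,
    header_comments: dict[str, object] | None = None,
) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        for k, v in (header_comments or {}).items():
            fh.write(f"# {k}={v}\n")
        w = csv.writer(fh)
        w.writerow(MINUTE_HEADER)
        for s in streams:
            for ts, t, ob in zip(s.timestamps, s.temp_c, s.on_body):
                w.writerow(
                    [
                        s.participant_id,
                        np.datetime_as_string(ts, unit="m"),
                        _fmt_temp(float(t)),
                        int(ob),
                    ]
                )


# ---------------------------------------------------------------------------
# CSV reading
# ---------------------------------------------------------------------------

def _parse_float(text: str, line: int, what: str) -> float | None:
    text = text.strip()
    if text == "":
        return None
    # strict dialect: reject comma decimals and anything float() cannot parse
    try:
        value = float(text)
    except ValueError:
        raise SchemaError(f"cannot parse {what} {text!r} (period-decimal required)", line)
    return value


def _parse_bool(text: str, line: int, what: str) -> bool:
    t = text.strip().lower()
    if t in ("0", "false"):
        return False
    if t in ("1", "true"):
        return True
    raise SchemaError(f"cannot parse {what} {text!r} as boolean (use 0/1)", line)


def _iter_csv_rows(path: Path, header: list[str]):
    """Yield (line_number, row) for data rows, validating the header."""
    with path.open(newline="") as fh:
        lineno = 0
        reader = csv.reader(fh)
        header_seen = False
        for row in reader:
            lineno += 1
            if row and row[0].startswith("#"):
                continue
            if not header_seen:
                if [c.strip() for c in row] != header:
                    raise SchemaError(f"header {row!r} does not match {header!r}", lineno)
                header_seen = True
                continue
            if not row or all(c.strip() == "" for c in row):
                continue
            if len(row) != len(header):
                raise SchemaError(f"expected {len(header)} fields, got {len(row)}", lineno)
            yield lineno, row
        if not header_seen:
            raise SchemaError("file is empty (no header row)")


def read_daily_csv(path: str | Path) -> list[CycleSeries]:
    """Read a daily-log CSV into one :class:`CycleSeries` per (participant, device).

    Rows for a participant-device pair may appear in any order; days absent
    from the file are treated as missing up to the maximum observed cycle
    day.  Duplicate (participant, cycle_day, device) rows and unknown device
    labels are errors.
    """
    path = Path(path)
    rows: dict[tuple[str, str], dict[int, DailyRecord]] = {}
    for lineno, row in _iter_csv_rows(path, DAILY_HEADER):
        pid, date_s, day_s, device, temp_s, ill_s, irr_s = [c.strip() for c in row]
        try:
            date = dt.date.fromisoformat(date_s)
        except ValueError:
            raise SchemaError(f"cannot parse date {date_s!r} (ISO-8601 required)", lineno)
        try:
            day = int(day_s)
        except ValueError:
            raise SchemaError(f"cannot parse cycle_day {day_s!r}", lineno)
        if device not in DEVICES:
            raise SchemaError(f"unknown device label {device!r}", lineno)
        temp = _parse_float(temp_s, lineno, "temp_c")
        try:
            rec = DailyRecord(
                participant_id=pid,
                date=date,
                cycle_day=day,
                device=device,
                temp_c=temp,
                illness=_parse_bool(ill_s, lineno, "illness"),
                irregular_wake=_parse_bool(irr_s, lineno, "irregular_wake"),
            )
        except ValueError as exc:
            raise SchemaError(str(exc), lineno)
        key = (pid, device)
        per = rows.setdefault(key, {})
        if day in per:
            raise SchemaError(
                f"duplicate (participant={pid}, cycle_day={day}, device={device})", lineno
            )
        per[day] = rec

    out: list[CycleSeries] = []
    for (pid, device), per in sorted(rows.items()):
        n = max(per)
        temps = np.full(n, np.nan)
        illness = np.zeros(n, dtype=bool)
        irregular = np.zeros(n, dtype=bool)
        start = None
        for day, rec in per.items():
            if rec.temp_c is not None:
                temps[day - 1] = rec.temp_c
            illness[day - 1] = rec.illness
            irregular[day - 1] = rec.irregular_wake
            start = rec.date - dt.timedelta(days=day - 1)
        out.append(
            CycleSeries(
                participant_id=pid,
                temps=temps,
                start_date=start,
                device=device,
                illness=illness,
                irregular_wake=irregular,
            )
        )
    return out


def read_minute_csv(path: str | Path) -> list[MinuteStream]:
    """Read a minute-stream CSV into one :class:`MinuteStream` per night.

    A night is a (participant_id, date-of-last-timestamp) group; samples must
    be contiguous per night in the file (the writer guarantees this).
    """
    path = Path(path)
    groups: dict[tuple[str, str], list[tuple[np.datetime64, float, bool]]] = {}
    for lineno, row in _iter_csv_rows(path, MINUTE_HEADER):
        pid, ts_s, temp_s, ob_s = [c.strip() for c in row]
        try:
            ts = np.datetime64(ts_s, "m")
        except ValueError:
            raise SchemaError(f"cannot parse timestamp {ts_s!r}", lineno)
        temp = _parse_float(temp_s, lineno, "temp_c")
        ob = _parse_bool(ob_s, lineno, "on_body")
        # group key: participant + calendar date of the sample's morning;
        # samples before 12:00 belong to the same night as the following wake
        day = np.datetime64(ts, "D")
        hour = (ts - day).astype("timedelta64[m]").astype(int) // 60
        morning = day if hour < 12 else day + np.timedelta64(1, "D")
        groups.setdefault((pid, str(morning)), []).append(
            (ts, np.nan if temp is None else temp, ob)
        )

    out = []
    for (pid, morning), samples in sorted(groups.items()):
        samples.sort(key=lambda s: s[0])
        ts = np.array([s[0] for s in samples], dtype="datetime64[m]")
        out.append(
            MinuteStream(
                participant_id=pid,
                night_date=dt.date.fromisoformat(morning),
                timestamps=ts,
                temp_c=np.array([s[1] for s in samples]),
                on_body=np.array([s[2] for s in samples], dtype=bool),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Stream reduction
# ---------------------------------------------------------------------------

def detect_waking_time(stream: MinuteStream) -> np.datetime64:
    """Locate the waking time of one night.

    The protocol has the wearer remove the band immediately on waking, so the
    wake time is the timestamp of the last on-body minute.  An explicitly
    recorded ``wake_time`` on the stream takes precedence.  Two or more wear
    episodes trigger a warning and the last episode's end is used.
    """
    if stream.wake_time is not None:
        return np.datetime64(stream.wake_time, "m")
    if not stream.is_worn:
        raise NonWearNightError(
            f"{stream.participant_id} {stream.night_date}: no on-body samples"
        )
    if stream.wear_episodes() > 1:
        warnings.warn(
            f"{stream.participant_id} {stream.night_date}: multiple wear episodes; "
            "using the end of the final episode as wake time",
            stacklevel=2,
        )
    last_on = np.nonzero(stream.on_body)[0][-1]
    return stream.timestamps[last_on]


def prewaking_mean(stream: MinuteStream, interval_minutes: int) -> float:
    """Mean on-body temperature over ``[wake - interval, wake)``.

    Off-body samples inside the window are excluded; if fewer than 50% of the
    window's minutes carry an on-body sample the value is NaN (insufficient
    wear).  ``interval_minutes`` must be one of 10/30/60/90/120.
    """
    if interval_minutes not in PREWAKING_INTERVALS:
        raise ValueError(
            f"interval must be one of {PREWAKING_INTERVALS}, got {interval_minutes}"
        )
    try:
        wake = detect_waking_time(stream)
    except NonWearNightError:
        return float("nan")
    lo = wake - np.timedelta64(interval_minutes, "m")
    in_window = (stream.timestamps >= lo) & (stream.timestamps < wake)
    usable = in_window & stream.on_body & np.isfinite(stream.temp_c)
    if usable.sum() < 0.5 * interval_minutes:
        return float("nan")
    return float(stream.temp_c[usable].mean())


def daily_basal_table(
    cycles: Sequence[CycleSeries],
    streams: Sequence[MinuteStream],
) -> pd.DataFrame:
    """Merge oral daily logs with per-night pre-waking interval means.

    Returns one row per participant-day with columns ``oral`` and
    ``armband_10`` ... ``armband_120``; sorted by (participant_id, cycle_day)
    so the result is invariant to input order.  Streams with no matching
    participant-day in the daily logs are reported with a warning and
    dropped.
    """
    oral = {s.participant_id: s for s in cycles if s.device == "oral"}
    rows = {}
    for s in oral.values():
        for day in range(1, s.cycle_length + 1):
            t = s.temps[day - 1]
            rows[(s.participant_id, day)] = {
                "participant_id": s.participant_id,
                "cycle_day": day,
                "date": s.date_of_day(day),
                "oral": float(t) if np.isfinite(t) else np.nan,
                "illness": bool(s.illness[day - 1]),
                "irregular_wake": bool(s.irregular_wake[day - 1]),
                **{f"armband_{k}": np.nan for k in PREWAKING_INTERVALS},
            }

    orphans = []
    for st in streams:
        series = oral.get(st.participant_id)
        key = None
        if series is not None:
            day = (st.night_date - series.start_date).days + 1
            if 1 <= day <= series.cycle_length:
                key = (st.participant_id, day)
        if key is None or key not in rows:
            orphans.append((st.participant_id, st.night_date))
            continue
        for k in PREWAKING_INTERVALS:
            rows[key][f"armband_{k}"] = prewaking_mean(st, k)
    if orphans:
        warnings.warn(
            f"{len(orphans)} minute stream(s) had no matching daily-log day: "
            f"{orphans[:5]}{'...' if len(orphans) > 5 else ''}",
            stacklevel=2,
        )

    cols = [
        "participant_id",
        "cycle_day",
        "date",
        "oral",
        *[f"armband_{k}" for k in PREWAKING_INTERVALS],
        "illness",
        "irregular_wake",
    ]
    df = pd.DataFrame(sorted(rows.values(), key=lambda r: (r["participant_id"], r["cycle_day"])))
    return df[cols].reset_index(drop=True)


def armband_series(
    table: pd.DataFrame,
    cycles: Sequence[CycleSeries],
    interval_minutes: int = 60,
) -> list[CycleSeries]:
    """Build per-participant daily series from one armband interval column.

    The resulting series carry the oral log's illness/irregular flags so the
    same fever-exclusion rules apply to both devices.
    """
    col = f"armband_{interval_minutes}"
    if col not in table.columns:
        raise ValueError(f"no column {col!r} in basal table")
    oral = {s.participant_id: s for s in cycles if s.device == "oral"}
    out = []
    for pid, grp in table.groupby("participant_id", sort=True):
        src = oral[pid]
        temps = np.full(src.cycle_length, np.nan)
        days = grp["cycle_day"].to_numpy()
        temps[days - 1] = grp[col].to_numpy()
        out.append(
            CycleSeries(
                participant_id=pid,
                temps=temps,
                start_date=src.start_date,
                device=f"armband-{interval_minutes}",
                illness=src.illness.copy(),
                irregular_wake=src.irregular_wake.copy(),
                next_menses_known=src.next_menses_known,
            )
        )
    return out
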