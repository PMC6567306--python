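"""Binary-sensor event logs: parsing, preprocessing and hourly place counts.

The monitored home is abstracted to a handful of behaviorally significant
*places* (bedroom, kitchen, bathroom, living room).  Raw logs from PIR motion
detectors, magnetic door contacts and pressure sensors are cleaned with three
rules, mapped onto places, and reduced to per-place hourly event counts:

1. OFF events of motion detectors are discarded (the sensor turns itself off
   a few seconds after triggering, so OFF carries no activity information);
2. repeated firings of the same sensor closer than one minute apart are
   debounced to a single event;
3. pressure sensors (under beds/couches, firing continuously while the person
   rests) are muted for 10 minutes after each accounted event.

The pipeline order is fixed: OFF-filter -> debounce -> pressure mute ->
place mapping -> hourly binning.  Every stage is idempotent.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SensorEvent",
    "EventLog",
    "ParseReport",
    "PlaceMapping",
    "HourlyCounts",
    "read_casas_log",
    "read_generic_csv",
    "write_casas_log",
    "filter_off_events",
    "debounce_events",
    "mute_pressure_sensors",
    "map_to_places",
    "hourly_counts",
    "inject_sensor_fault",
    "preprocess",
    "counts_frame",
    "write_daily_activity_csv",
    "read_daily_activity_csv",
]

SENSOR_TYPES = ("motion", "door", "pressure", "other")

#: values that mean "sensor released" for a motion detector
_MOTION_OFF_VALUES = frozenset({"OFF", "0", "FALSE"})
#: values that mean "closed" for a door contact (filtered only on request)
_DOOR_CLOSE_VALUES = frozenset({"CLOSE", "CLOSED", "OFF", "0", "FALSE"})

_COLUMNS = ["timestamp", "sensor_id", "value", "sensor_type"]


@dataclass(frozen=True)
class SensorEvent:
    """One timestamped firing of a named binary sensor."""

    timestamp: dt.datetime
    sensor_id: str
    value: str
    sensor_type: str = "other"
    place: str | None = None

    def __post_init__(self) -> None:
        if not self.sensor_id:
            raise ValueError("sensor_id must be non-empty")
        if self.sensor_type not in SENSOR_TYPES:
            raise ValueError(f"unknown sensor_type {self.sensor_type!r}")


@dataclass
class ParseReport:
    """Per-file account of what the lenient parser skipped."""

    n_lines: int = 0
    n_parsed: int = 0
    skipped: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_skipped(self) -> int:
        return len(self.skipped)


class EventLog:
    """A time-sorted sequence of sensor events, backed by a DataFrame.

    Columns: ``timestamp`` (datetime64), ``sensor_id``, ``value``,
    ``sensor_type`` and, after place mapping, ``place``.
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        dialect: str = "synthetic",
        parse_report: ParseReport | None = None,
    ) -> None:
        frame = frame.copy()
        for col in _COLUMNS:
            if col not in frame.columns:
                raise ValueError(f"event frame missing column {col!r}")
        frame["timestamp"] = pd.to_datetime(frame["timestamp"])
        frame = frame.sort_values("timestamp", kind="stable").reset_index(drop=True)
        self.frame = frame
        self.dialect = dialect
        self.parse_report = parse_report
        self.n_unmapped_dropped: int = 0

    @classmethod
    def from_events(
        cls, events: Iterable[SensorEvent], dialect: str = "synthetic"
    ) -> "EventLog":
        rows = [
            {
                "timestamp": e.timestamp,
                "sensor_id": e.sensor_id,
                "value": e.value,
                "sensor_type": e.sensor_type,
                **({"place": e.place} if e.place is not None else {}),
            }
            for e in events
        ]
        frame = pd.DataFrame(rows, columns=_COLUMNS + (["place"] if rows and "place" in rows[0] else []))
        if not rows:
            frame = pd.DataFrame(columns=_COLUMNS)
        return cls(frame, dialect=dialect)

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self):
        has_place = "place" in self.frame.columns
        for row in self.frame.itertuples(index=False):
            yield SensorEvent(
                timestamp=row.timestamp.to_pydatetime(),
                sensor_id=row.sensor_id,
                value=row.value,
                sensor_type=row.sensor_type,
                place=getattr(row, "place", None) if has_place else None,
            )

    def _with(self, frame: pd.DataFrame) -> "EventLog":
        out = EventLog(frame, dialect=self.dialect, parse_report=self.parse_report)
        out.n_unmapped_dropped = self.n_unmapped_dropped
        return out

    @property
    def events(self) -> list[SensorEvent]:
        return list(self)


def infer_sensor_type(sensor_id: str) -> str:
    """CASAS convention: ids starting with M are motion, D are door."""
    if sensor_id.startswith("M"):
        return "motion"
    if sensor_id.startswith("D"):
        return "door"
    return "other"


def read_casas_log(
    path: str | Path,
    strict: bool = False,
    type_overrides: Mapping[str, str] | None = None,
) -> EventLog:
    """Read a CASAS-style whitespace-delimited log.

    Each non-blank line is ``date time sensor value [annotation ...]``; extra
    trailing fields are ignored.  Malformed lines are skipped and recorded in
    the returned log's :class:`ParseReport` (``strict=True`` raises instead).
    """
    path = Path(path)
    report = ParseReport()
    rows: list[dict] = []
    overrides = dict(type_overrides or {})
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            report.n_lines += 1
            parts = line.split()
            if len(parts) < 4:
                if strict:
                    raise ValueError(f"{path}:{lineno}: expected >=4 fields, got {len(parts)}")
                report.skipped.append((lineno, "too few fields"))
                continue
            date_s, time_s, sensor_id, value = parts[0], parts[1], parts[2], parts[3]
            try:
                ts = pd.Timestamp(f"{date_s} {time_s}")
            except ValueError:
                if strict:
                    raise ValueError(f"{path}:{lineno}: unparseable timestamp")
                report.skipped.append((lineno, "bad timestamp"))
                continue
            stype = overrides.get(sensor_id, infer_sensor_type(sensor_id))
            rows.append(
                {"timestamp": ts, "sensor_id": sensor_id, "value": value, "sensor_type": stype}
            )
            report.n_parsed += 1
    frame = pd.DataFrame(rows, columns=_COLUMNS)
    return EventLog(frame, dialect="casas", parse_report=report)


def read_generic_csv(path: str | Path) -> EventLog:
    """Read the generic CSV dialect ``timestamp,sensor_id,value,sensor_type``.

    Timestamps are ISO-8601.  This dialect covers Kasteren-style testbeds,
    including pressure sensors (``sensor_type`` column, no prefix inference).
    """
    frame = pd.read_csv(path, dtype={"sensor_id": str, "value": str, "sensor_type": str})
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"generic CSV missing columns {missing}")
    return EventLog(frame[_COLUMNS], dialect="generic_csv")


def write_casas_log(log: EventLog, path: str | Path) -> None:
    """Write a log back out in the CASAS whitespace dialect."""
    with Path(path).open("w") as fh:
        for row in log.frame.itertuples(index=False):
            ts = row.timestamp.strftime("%Y-%m-%d %H:%M:%S.%f")
            fh.write(f"{ts} {row.sensor_id} {row.value}\n")


def write_generic_csv(log: EventLog, path: str | Path) -> None:
    frame = log.frame[_COLUMNS].copy()
    frame["timestamp"] = frame["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S.%f")
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# preprocessing rules
# ---------------------------------------------------------------------------


def filter_off_events(log: EventLog, drop_door_close: bool = False) -> EventLog:
    """Drop motion-detector OFF events (and, optionally, door CLOSE events).

    Motion PIRs reset automatically a few seconds after triggering, so the
    OFF edge says nothing about the occupant.  Door contacts report genuine
    state changes in both directions, so CLOSE is kept by default.
    """
    f = log.frame
    off = (f["sensor_type"] == "motion") & f["value"].str.upper().isin(_MOTION_OFF_VALUES)
    if drop_door_close:
        off |= (f["sensor_type"] == "door") & f["value"].str.upper().isin(_DOOR_CLOSE_VALUES)
    return log._with(f[~off].reset_index(drop=True))


def _greedy_keep(seconds: np.ndarray, min_gap_s: float) -> np.ndarray:
    """Greedy rate limiter: keep an event iff >= min_gap_s after last kept."""
    keep = np.zeros(len(seconds), dtype=bool)
    last = -np.inf
    for i, t in enumerate(seconds):
        if t - last >= min_gap_s:
            keep[i] = True
            last = t
    return keep


def debounce_events(log: EventLog, min_gap_s: float = 60.0) -> EventLog:
    """Suppress repeated firings of the same sensor closer than ``min_gap_s``.

    Greedy forward pass anchored on the last *kept* event of each sensor;
    different sensors never suppress each other.
    """
    f = log.frame
    if f.empty:
        return log._with(f)
    secs = f["timestamp"].astype("int64").to_numpy() / 1e9
    keep = np.ones(len(f), dtype=bool)
    for _, idx in f.groupby("sensor_id", sort=False).indices.items():
        keep[idx] = _greedy_keep(secs[idx], min_gap_s)
    return log._with(f[keep].reset_index(drop=True))


def mute_pressure_sensors(log: EventLog, mute_min: float = 10.0) -> EventLog:
    """Account at most one pressure-sensor event per ``mute_min`` minutes.

    Pressure sensors under beds and couches fire continuously while the
    person rests; only one event per mute window is kept per sensor.  Events
    of other sensor types pass through untouched.
    """
    f = log.frame
    if f.empty:
        return log._with(f)
    secs = f["timestamp"].astype("int64").to_numpy() / 1e9
    keep = np.ones(len(f), dtype=bool)
    pressure = f["sensor_type"].to_numpy() == "pressure"
    sub = f[pressure]
    for _, idx in sub.groupby("sensor_id", sort=False).indices.items():
        abs_idx = sub.index.to_numpy()[idx]
        keep[abs_idx] = _greedy_keep(secs[abs_idx], mute_min * 60.0)
    return log._with(f[keep].reset_index(drop=True))


# ---------------------------------------------------------------------------
# place abstraction
# ---------------------------------------------------------------------------

DEFAULT_PLACES = ("P1", "P2", "P3", "P4")  # bedroom, kitchen, bathroom, living room


@dataclass(frozen=True)
class PlaceMapping:
    """The generic-space abstraction: place names plus sensor -> place map."""

    places: tuple[str, ...]
    sensor_to_place: Mapping[str, str]

    def __post_init__(self) -> None:
        mapped = set(self.sensor_to_place.values())
        unknown = mapped - set(self.places)
        if unknown:
            raise ValueError(f"sensors mapped to unknown places: {sorted(unknown)}")
        empty = [p for p in self.places if p not in mapped]
        if empty:
            raise ValueError(f"places with no sensors: {empty}")

    @classmethod
    def from_dict(cls, d: Mapping) -> "PlaceMapping":
        return cls(places=tuple(d["places"]), sensor_to_place=dict(d["sensors"]))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PlaceMapping":
        with Path(path).open() as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def _from_config(cls, name: str) -> "PlaceMapping":
        text = resources.files("pheromap.configs").joinpath(name).read_text()
        return cls.from_dict(yaml.safe_load(text))

    @classmethod
    def hh126(cls) -> "PlaceMapping":
        """CASAS HH126 layout: bedroom/kitchen/bathroom/living-room motion sensors."""
        return cls._from_config("hh126.yaml")

    @classmethod
    def kasteren_c(cls) -> "PlaceMapping":
        """Kasteren House C layout folded onto the four-place model."""
        return cls._from_config("kasteren_c.yaml")

    def to_yaml(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            yaml.safe_dump(
                {"places": list(self.places), "sensors": dict(self.sensor_to_place)}, fh
            )


def map_to_places(
    log: EventLog, mapping: PlaceMapping, unmapped_policy: str = "drop"
) -> EventLog:
    """Tag each event with its place; drop (default) or reject unmapped sensors."""
    if unmapped_policy not in ("drop", "error"):
        raise ValueError(f"unknown unmapped_policy {unmapped_policy!r}")
    f = log.frame.copy()
    f["place"] = f["sensor_id"].map(dict(mapping.sensor_to_place))
    unmapped = f["place"].isna()
    if unmapped.any() and unmapped_policy == "error":
        ids = sorted(f.loc[unmapped, "sensor_id"].unique())
        raise KeyError(f"unmapped sensors: {ids}")
    out = log._with(f[~unmapped].reset_index(drop=True))
    out.n_unmapped_dropped = log.n_unmapped_dropped + int(unmapped.sum())
    return out


@dataclass(frozen=True)
class HourlyCounts:
    """Per-place event counts for one day; hour bins half-open [h:00, h+1:00)."""

    day: dt.date
    places: tuple[str, ...]
    counts: np.ndarray  # (n_places, 24), non-negative

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.places), 24):
            raise ValueError(f"counts shape {counts.shape} != ({len(self.places)}, 24)")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    def place_counts(self, hour: int) -> dict[str, float]:
        return {p: float(self.counts[i, hour]) for i, p in enumerate(self.places)}


def hourly_counts(
    log: EventLog,
    places: Sequence[str] | None = None,
    day_range: tuple[dt.date, dt.date] | None = None,
) -> list[HourlyCounts]:
    """Bin a place-tagged log into per-day (places x 24) count matrices.

    Days inside ``day_range`` (inclusive; defaults to the log's span) with no
    events yield all-zero matrices — absence of activity is itself data
    (time away from home).
    """
    f = log.frame
    if "place" not in f.columns:
        raise ValueError("log must be place-tagged (run map_to_places first)")
    if places is None:
        places = DEFAULT_PLACES
    places = tuple(places)
    if day_range is None:
        if f.empty:
            return []
        day_range = (f["timestamp"].min().date(), f["timestamp"].max().date())
    start, end = day_range
    if start > end:
        return []
    n_days = (end - start).days + 1
    place_index = {p: i for i, p in enumerate(places)}
    cube = np.zeros((n_days, len(places), 24), dtype=float)
    if not f.empty:
        days = (f["timestamp"].dt.normalize() - pd.Timestamp(start)).dt.days.to_numpy()
        hours = f["timestamp"].dt.hour.to_numpy()
        pidx = f["place"].map(place_index).to_numpy()
        ok = (days >= 0) & (days < n_days)
        np.add.at(cube, (days[ok], pidx[ok].astype(int), hours[ok]), 1.0)
    return [
        HourlyCounts(day=start + dt.timedelta(days=d), places=places, counts=cube[d])
        for d in range(n_days)
    ]


def inject_sensor_fault(
    log: EventLog,
    dead_sensors: Iterable[str],
    date_range: tuple[dt.date, dt.date] | None = None,
) -> EventLog:
    """Simulate dead sensors by removing all their events (optionally only
    within an inclusive date range)."""
    dead = set(dead_sensors)
    f = log.frame
    hit = f["sensor_id"].isin(dead)
    if date_range is not None:
        d = f["timestamp"].dt.date
        hit &= (d >= date_range[0]) & (d <= date_range[1])
    return log._with(f[~hit].reset_index(drop=True))


def preprocess(
    log: EventLog,
    mapping: PlaceMapping,
    min_gap_s: float = 60.0,
    mute_min: float = 10.0,
    drop_door_close: bool = False,
) -> tuple[EventLog, dict[str, int]]:
    """Run the fixed preprocessing pipeline and return (placed log, stage ledger).

    Ledger satisfies: parsed = kept + filtered_off + debounced_away + muted
    + unmapped_dropped.
    """
    n0 = len(log)
    a = filter_off_events(log, drop_door_close=drop_door_close)
    b = debounce_events(a, min_gap_s=min_gap_s)
    c = mute_pressure_sensors(b, mute_min=mute_min)
    d = map_to_places(c, mapping, unmapped_policy="drop")
    ledger = {
        "parsed": n0,
        "filtered_off": n0 - len(a),
        "debounced_away": len(a) - len(b),
        "muted": len(b) - len(c),
        "unmapped_dropped": len(c) - len(d),
        "kept": len(d),
    }
    return d, ledger


# ---------------------------------------------------------------------------
# daily-activity files
# ---------------------------------------------------------------------------


def counts_frame(counts: Sequence[HourlyCounts]) -> pd.DataFrame:
    """Long layout: one row per (day, place), columns date,place,h00..h23."""
    rows = []
    for hc in counts:
        for i, p in enumerate(hc.places):
            row = {"date": hc.day.isoformat(), "place": p}
            row.update({f"h{h:02d}": hc.counts[i, h] for h in range(24)})
            rows.append(row)
    return pd.DataFrame(rows)


def write_daily_activity_csv(counts: Sequence[HourlyCounts], path: str | Path) -> None:
    counts_frame(counts).to_csv(path, index=False)


def read_daily_activity_csv(path: str | Path) -> list[HourlyCounts]:
    frame = pd.read_csv(path, dtype={"place": str})
    out: list[HourlyCounts] = []
    hour_cols = [f"h{h:02d}" for h in range(24)]
    for day_s, grp in frame.groupby("date", sort=True):
        places = tuple(grp["place"])
        mat = grp[hour_cols].to_numpy(dtype=float)
        out.append(HourlyCounts(day=dt.date.fromisoformat(str(day_s)), places=places, counts=mat))
    return out
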