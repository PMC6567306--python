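"""Synthetic daily-routine event streams for end-to-end validation.

The generator emulates a single occupant's day as an inhomogeneous Poisson
process over 4 places x 24 hours: each (place, hour) cell has an expected
number of *accounted* events, events are timed uniformly within their hour
and attributed uniformly to one of the place's sensors.  Motion-sensor
semantics are reproduced so the preprocessing rules have something to do:
every ON is followed by an automatic OFF a few seconds later, and a
configurable fraction of events double-fire within a minute (removed by
debouncing).  Scenarios can inject anomalous days (late sleep, missed
meals, days away, swapped room usage), a mid-series sensor-set upgrade, and
sensor faults.

A sensor upgrade adds ids to a place's pool; each added sensor contributes
its proportional share of events, so the place's rate scales by
(n_old + n_added) / n_old from the change date — the step in the data flow
the monitoring method is supposed to notice.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .events import DEFAULT_PLACES, EventLog

__all__ = [
    "RoutineProfile",
    "Anomaly",
    "SensorChange",
    "FaultSpec",
    "ScenarioSpec",
    "default_profile",
    "apply_anomaly",
    "generate_routine_log",
    "scenario_sleep_durations",
    "standard_scenario",
    "ground_truth",
]

ANOMALY_TYPES = ("shifted_sleep", "missed_meal", "away_day", "profile_swap")

#: breakfast window zeroed by a missed_meal anomaly
MEAL_HOURS = (7, 8, 9)


@dataclass(frozen=True)
class RoutineProfile:
    """Expected accounted events per hour for each place, plus sensor pools."""

    places: tuple[str, ...]
    rates: np.ndarray  # (n_places, 24), non-negative
    sensors_per_place: Mapping[str, tuple[str, ...]]
    sleep_hours: frozenset[int] = frozenset({22, 23, 0, 1, 2, 3, 4, 5, 6})

    def __post_init__(self) -> None:
        rates = np.asarray(self.rates, dtype=float)
        if rates.shape != (len(self.places), 24):
            raise ValueError("rates must be (n_places, 24)")
        if (rates < 0).any():
            raise ValueError("rates must be non-negative")
        for p in self.places:
            if not self.sensors_per_place.get(p):
                raise ValueError(f"place {p} has no sensors")
        object.__setattr__(self, "rates", rates)


def default_profile() -> RoutineProfile:
    """A realistic single-occupant weekday.

    Night bedroom presence, a morning bathroom/kitchen sequence, kitchen
    peaks at meal times, living-room afternoons and evenings, and a low
    background everywhere while the person is awake and moving about.
    Rates are accounted events per hour (post-debounce scale).  The sensor
    pools mirror a four-room home with redundant coverage (4 kitchen
    sensors), which is what makes the fault-tolerance experiments possible.
    """
    rates = np.zeros((4, 24))
    # P1 bedroom: asleep 22:00-07:00 with occasional turning; brief evening
    rates[0, [22, 23, 0, 1, 2, 3, 4, 5, 6]] = 6.0
    rates[0, 7] = 3.0
    rates[0, 21] = 2.0
    rates[0, 8:21] = 0.3
    # P2 kitchen: breakfast, lunch, dinner
    rates[1, [7, 8, 9]] = 12.0
    rates[1, [12, 13]] = 10.0
    rates[1, [18, 19]] = 12.0
    rates[1, [10, 11, 14, 15, 16, 17, 20]] = 1.0
    # P3 bathroom: morning and bedtime routines
    rates[2, 7] = 5.0
    rates[2, 21] = 5.0
    rates[2, [8, 12, 18]] = 1.5
    # P4 living room: daytime and evening
    rates[3, [10, 11]] = 6.0
    rates[3, [14, 15, 16, 17]] = 8.0
    rates[3, [20, 21]] = 8.0
    rates[3, [8, 9, 12, 13, 18, 19]] = 2.0
    return RoutineProfile(
        places=DEFAULT_PLACES,
        rates=rates,
        sensors_per_place={
            "P1": ("M010", "M011", "M013"),
            "P2": ("M003", "M004", "M005", "M015"),
            "P3": ("M012", "M014"),
            "P4": ("M001", "M002", "M006", "M007", "M008", "M009"),
        },
    )


@dataclass(frozen=True)
class Anomaly:
    date: dt.date
    type: str
    magnitude: float = 1.0

    def __post_init__(self) -> None:
        if self.type not in ANOMALY_TYPES:
            raise ValueError(f"unknown anomaly type {self.type!r}")


@dataclass(frozen=True)
class SensorChange:
    """Mid-series sensor upgrade: ids added to place pools from a date on."""

    date: dt.date
    added: Mapping[str, tuple[str, ...]]  # place -> new sensor ids


@dataclass(frozen=True)
class FaultSpec:
    start: dt.date
    end: dt.date
    dead_sensors: frozenset[str]


@dataclass(frozen=True)
class ScenarioSpec:
    n_days: int
    seed: int
    start_date: dt.date = dt.date(2022, 3, 1)
    anomalies: tuple[Anomaly, ...] = ()
    sensor_change: SensorChange | None = None
    faults: tuple[FaultSpec, ...] = ()
    double_fire_rate: float = 0.10
    off_delay_s: float = 5.0

    def __post_init__(self) -> None:
        end = self.start_date + dt.timedelta(days=self.n_days - 1)
        for a in self.anomalies:
            if not (self.start_date <= a.date <= end):
                raise ValueError(f"anomaly date {a.date} outside scenario range")

    @property
    def dates(self) -> list[dt.date]:
        return [self.start_date + dt.timedelta(days=i) for i in range(self.n_days)]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioSpec":
        with Path(path).open() as fh:
            d = yaml.safe_load(fh)
        anomalies = tuple(
            Anomaly(dt.date.fromisoformat(a["date"]), a["type"], float(a.get("magnitude", 1.0)))
            for a in d.get("anomalies", [])
        )
        change = d.get("sensor_change")
        sensor_change = (
            SensorChange(
                dt.date.fromisoformat(change["date"]),
                {p: tuple(ids) for p, ids in change["added"].items()},
            )
            if change
            else None
        )
        faults = tuple(
            FaultSpec(
                dt.date.fromisoformat(f["start"]),
                dt.date.fromisoformat(f["end"]),
                frozenset(f["dead_sensors"]),
            )
            for f in d.get("faults", [])
        )
        return cls(
            n_days=int(d["n_days"]),
            seed=int(d["seed"]),
            start_date=dt.date.fromisoformat(d.get("start_date", "2022-03-01")),
            anomalies=anomalies,
            sensor_change=sensor_change,
            faults=faults,
            double_fire_rate=float(d.get("double_fire_rate", 0.10)),
            off_delay_s=float(d.get("off_delay_s", 5.0)),
        )


def apply_anomaly(
    day_rates: np.ndarray,
    type: str,
    magnitude: float,
    places: Sequence[str] = DEFAULT_PLACES,
    meal_hours: Sequence[int] = MEAL_HOURS,
    swap_places: tuple[str, str] = ("P1", "P4"),
) -> np.ndarray:
    """Modify one day's (places x 24) rate matrix.

    shifted_sleep rotates the bedroom's hourly profile by ``magnitude``
    hours; missed_meal zeroes the kitchen in the meal window; away_day
    scales everything by (1 - magnitude); profile_swap exchanges two
    places' rows (an involution).
    """
    rates = np.asarray(day_rates, dtype=float).copy()
    idx = {p: i for i, p in enumerate(places)}
    if type == "shifted_sleep":
        rates[idx["P1"]] = np.roll(rates[idx["P1"]], int(round(magnitude)))
    elif type == "missed_meal":
        rates[idx["P2"], list(meal_hours)] = 0.0
    elif type == "away_day":
        rates *= max(0.0, 1.0 - magnitude)
    elif type == "profile_swap":
        a, b = (idx[p] for p in swap_places)
        rates[[a, b]] = rates[[b, a]]
    else:
        raise ValueError(f"unknown anomaly type {type!r}")
    return rates


def _day_rates_and_pools(
    profile: RoutineProfile, spec: ScenarioSpec, day: dt.date
) -> tuple[np.ndarray, dict[str, tuple[str, ...]]]:
    """Effective rates and sensor pools for one day (upgrade + anomalies)."""
    rates = profile.rates.copy()
    pools = {p: tuple(profile.sensors_per_place[p]) for p in profile.places}
    change = spec.sensor_change
    if change is not None and day >= change.date:
        for p, added in change.added.items():
            old = pools[p]
            pools[p] = old + tuple(added)
            i = list(profile.places).index(p)
            rates[i] *= len(pools[p]) / len(old)
    for a in spec.anomalies:
        if a.date == day:
            rates = apply_anomaly(rates, a.type, a.magnitude, places=profile.places)
    return rates, pools


def generate_routine_log(profile: RoutineProfile, spec: ScenarioSpec) -> EventLog:
    """Draw a CASAS-dialect event log for the whole scenario.

    Per day, place and hour the accounted-event count is Poisson with the
    (anomaly- and upgrade-adjusted) cell rate; event times are uniform in
    the hour; each event picks a sensor uniformly from the place's pool and
    emits an ON plus an automatic OFF ``off_delay_s`` later.  With
    probability ``double_fire_rate`` an event re-fires within a minute
    (exercises debouncing).  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    dead_by_day: dict[dt.date, set[str]] = {}
    for f in spec.faults:
        d = f.start
        while d <= f.end:
            dead_by_day.setdefault(d, set()).update(f.dead_sensors)
            d += dt.timedelta(days=1)

    rows: list[tuple[dt.datetime, str, str, str]] = []
    for day in spec.dates:
        rates, pools = _day_rates_and_pools(profile, spec, day)
        dead = dead_by_day.get(day, set())
        midnight = dt.datetime.combine(day, dt.time())
        for i, place in enumerate(profile.places):
            pool = pools[place]
            for hour in range(24):
                n = int(rng.poisson(rates[i, hour]))
                if n == 0:
                    continue
                offsets = np.sort(rng.uniform(0.0, 3600.0, size=n))
                sensors = rng.integers(0, len(pool), size=n)
                doubles = rng.uniform(size=n) < spec.double_fire_rate
                gaps = rng.uniform(1.0, 30.0, size=n)
                for j in range(n):
                    sid = pool[int(sensors[j])]
                    if sid in dead:
                        continue
                    t_on = midnight + dt.timedelta(hours=hour, seconds=float(offsets[j]))
                    rows.append((t_on, sid, "ON", "motion"))
                    rows.append(
                        (t_on + dt.timedelta(seconds=spec.off_delay_s), sid, "OFF", "motion")
                    )
                    if doubles[j]:
                        t2 = t_on + dt.timedelta(seconds=float(gaps[j]))
                        rows.append((t2, sid, "ON", "motion"))
                        rows.append(
                            (t2 + dt.timedelta(seconds=spec.off_delay_s), sid, "OFF", "motion")
                        )
    import pandas as pd

    frame = pd.DataFrame(rows, columns=["timestamp", "sensor_id", "value", "sensor_type"])
    return EventLog(frame, dialect="casas")


def scenario_sleep_durations(
    profile: RoutineProfile, spec: ScenarioSpec
) -> dict[dt.date, float]:
    """Ground-truth sleep hours per day, read off the simulated schedule.

    A day's sleep duration is the number of hours in which the bedroom rate
    is at least half its daily maximum (an away day therefore sleeps 0 h at
    home; a shifted sleep keeps its duration).
    """
    out: dict[dt.date, float] = {}
    p1 = list(profile.places).index("P1")
    for day in spec.dates:
        rates, _ = _day_rates_and_pools(profile, spec, day)
        row = rates[p1]
        peak = row.max()
        out[day] = float((row >= peak / 2).sum()) if peak > 0 else 0.0
    return out


def standard_scenario(
    seed: int,
    n_days: int = 60,
    with_anomalies: bool = True,
    with_sensor_change: bool = False,
    start_date: dt.date = dt.date(2022, 3, 1),
) -> ScenarioSpec:
    """The canonical 60-day validation scenario.

    Week 1 is clean (reference quality).  Three anomalous days are injected
    (days 13 and 48: away, magnitude 0.8; day 26: sleep shifted by 4 h) and,
    optionally, a sensor upgrade on day 40 adds four kitchen sensors —
    doubling the kitchen event flow from that date, the analogue of a
    mid-study hardware change.
    """
    anomalies: tuple[Anomaly, ...] = ()
    if with_anomalies:
        anomalies = tuple(
            a
            for a in (
                Anomaly(start_date + dt.timedelta(days=12), "away_day", 0.8),
                Anomaly(start_date + dt.timedelta(days=25), "shifted_sleep", 4.0),
                Anomaly(start_date + dt.timedelta(days=47), "away_day", 0.8),
            )
            if (a.date - start_date).days < n_days
        )
    change = None
    if with_sensor_change:
        change = SensorChange(
            date=start_date + dt.timedelta(days=39),
            added={"P2": ("M016", "M017", "M018", "M019")},
        )
    return ScenarioSpec(
        n_days=n_days,
        seed=seed,
        start_date=start_date,
        anomalies=anomalies,
        sensor_change=change,
    )


def scenario_mapping(profile: RoutineProfile, spec: ScenarioSpec) -> "PlaceMapping":
    """The sensor -> place mapping a deployment of this scenario would use:
    the profile's pools plus any sensors added by the mid-series upgrade
    (the monitoring side knows the full final sensor set, as it did for the
    real mid-study hardware change)."""
    from .events import PlaceMapping

    s2p: dict[str, str] = {}
    for p in profile.places:
        for sid in profile.sensors_per_place[p]:
            s2p[sid] = p
    if spec.sensor_change is not None:
        for p, added in spec.sensor_change.added.items():
            for sid in added:
                s2p[sid] = p
    return PlaceMapping(places=tuple(profile.places), sensor_to_place=s2p)


def ground_truth(spec: ScenarioSpec) -> dict:
    """Machine-readable truth for test assertions."""
    return {
        "start_date": spec.start_date.isoformat(),
        "n_days": spec.n_days,
        "anomaly_days": [a.date.isoformat() for a in spec.anomalies],
        "anomaly_types": [a.type for a in spec.anomalies],
        "change_date": None
        if spec.sensor_change is None
        else spec.sensor_change.date.isoformat(),
    }


def write_ground_truth(spec: ScenarioSpec, path: str | Path) -> None:
    Path(path).write_text(json.dumps(ground_truth(spec), indent=2) + "\n")
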