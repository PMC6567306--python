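"""Log parsing, preprocessing rules, place mapping and hourly binning."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from pheromap.events import (
    EventLog,
    PlaceMapping,
    debounce_events,
    filter_off_events,
    hourly_counts,
    inject_sensor_fault,
    map_to_places,
    mute_pressure_sensors,
    preprocess,
    read_casas_log,
    read_generic_csv,
    write_casas_log,
)

from conftest import T0, make_log


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


def test_casas_line_maps_fields_directly(tmp_path):
    p = tmp_path / "log.txt"
    p.write_text("2014-04-01 07:12:03 M004 ON\n")
    log = read_casas_log(p)
    (e,) = log.events
    assert e.timestamp == dt.datetime(2014, 4, 1, 7, 12, 3)
    assert (e.sensor_id, e.value, e.sensor_type) == ("M004", "ON", "motion")


def test_casas_reader_sorts_and_infers_types(tmp_path):
    p = tmp_path / "log.txt"
    p.write_text(
        "2014-04-01 08:00:00.000001 D001 OPEN extra annotation\n"
        "2014-04-01 07:00:00 X17 1\n"
    )
    log = read_casas_log(p)
    assert [e.sensor_id for e in log] == ["X17", "D001"]
    assert [e.sensor_type for e in log] == ["other", "door"]


def test_casas_lenient_skips_malformed_strict_raises(tmp_path):
    p = tmp_path / "log.txt"
    p.write_text("2014-04-01 07:12:03 M004 ON\nbad line here\n")
    log = read_casas_log(p)
    assert len(log) == 1
    assert log.parse_report.n_skipped == 1
    with pytest.raises(ValueError):
        read_casas_log(p, strict=True)


def test_casas_empty_file_gives_empty_log(tmp_path):
    p = tmp_path / "log.txt"
    p.write_text("")
    assert len(read_casas_log(p)) == 0


def test_generic_csv_roundtrip(tmp_path):
    p = tmp_path / "log.csv"
    p.write_text(
        "timestamp,sensor_id,value,sensor_type\n"
        "2008-11-20T07:00:00,S05,1,pressure\n"
        "2008-11-20T06:59:00,S07,1,motion\n"
    )
    log = read_generic_csv(p)
    assert [e.sensor_id for e in log] == ["S07", "S05"]
    assert log.events[1].sensor_type == "pressure"


def test_casas_writer_roundtrip(tmp_path):
    log = make_log([(0, "M001", "ON", "motion"), (70, "M001", "OFF", "motion")])
    p = tmp_path / "out.txt"
    write_casas_log(log, p)
    back = read_casas_log(p)
    assert [e.timestamp for e in back] == [e.timestamp for e in log]


# ---------------------------------------------------------------------------
# preprocessing rules
# ---------------------------------------------------------------------------


def test_filter_off_removes_motion_off_only():
    log = make_log(
        [(0, "M004", "ON", "motion"), (5, "M004", "OFF", "motion"), (9, "D001", "OPEN", "door")]
    )
    out = filter_off_events(log)
    assert [(e.sensor_id, e.value) for e in out] == [("M004", "ON"), ("D001", "OPEN")]


def test_filter_off_degenerate_and_identity():
    only_off = make_log([(0, "M004", "OFF", "motion"), (5, "M005", "OFF", "motion")])
    assert len(filter_off_events(only_off)) == 0
    no_motion = make_log([(0, "D001", "CLOSE", "door"), (5, "S01", "1", "pressure")])
    assert len(filter_off_events(no_motion)) == 2


def test_filter_off_can_drop_door_close_when_asked():
    log = make_log([(0, "D001", "OPEN", "door"), (5, "D001", "CLOSE", "door")])
    assert len(filter_off_events(log)) == 2
    assert len(filter_off_events(log, drop_door_close=True)) == 1


@pytest.mark.parametrize(
    "offsets, kept",
    [
        ([0, 30, 90], [0, 90]),
        ([0, 59, 61], [0, 61]),
        ([0, 60], [0, 60]),
        ([0], [0]),
    ],
)
def test_debounce_greedy_forward_pass(offsets, kept):
    log = make_log([(s, "M001", "ON", "motion") for s in offsets])
    out = debounce_events(log)
    assert [(e.timestamp - T0).total_seconds() for e in out] == kept


def test_debounce_is_per_sensor():
    log = make_log([(0, "M001", "ON", "motion"), (0, "M002", "ON", "motion")])
    assert len(debounce_events(log)) == 2


def test_mute_pressure_ten_minute_window():
    log = make_log([(m * 60, "S05", "1", "pressure") for m in (0, 5, 12)])
    out = mute_pressure_sensors(log)
    assert [(e.timestamp - T0).total_seconds() / 60 for e in out] == [0, 12]


def test_mute_pressure_leaves_other_types_untouched():
    log = make_log(
        [(0, "S05", "1", "pressure"), (30, "M001", "ON", "motion"), (60, "M001", "ON", "motion")]
    )
    out = mute_pressure_sensors(log)
    assert [e.sensor_id for e in out] == ["S05", "M001", "M001"]


def test_single_pressure_event_kept():
    log = make_log([(0, "S05", "1", "pressure")])
    assert len(mute_pressure_sensors(log)) == 1


# ---------------------------------------------------------------------------
# place mapping
# ---------------------------------------------------------------------------


def test_hh126_mapping_places_sensors(hh126):
    assert hh126.sensor_to_place["M010"] == "P1"
    assert hh126.sensor_to_place["M003"] == "P2"
    assert hh126.sensor_to_place["M012"] == "P3"
    assert hh126.sensor_to_place["M008"] == "P4"


def test_kasteren_mapping_loads():
    m = PlaceMapping.kasteren_c()
    assert m.sensor_to_place["S05"] == "P1"
    assert m.sensor_to_place["S30"] == "P2"


def test_map_to_places_drop_and_error(hh126):
    log = make_log([(0, "M010", "ON", "motion"), (5, "X999", "ON", "motion")])
    out = map_to_places(log, hh126)
    assert [e.place for e in out] == ["P1"]
    assert out.n_unmapped_dropped == 1
    with pytest.raises(KeyError, match="X999"):
        map_to_places(log, hh126, unmapped_policy="error")


def test_mapping_validation_rejects_empty_place():
    with pytest.raises(ValueError, match="no sensors"):
        PlaceMapping(places=("P1", "P2"), sensor_to_place={"M1": "P1"})


# ---------------------------------------------------------------------------
# hourly binning
# ---------------------------------------------------------------------------


def test_hourly_bins_are_half_open(hh126):
    log = make_log(
        [
            (10 * 3600 + 300, "M003", "ON", "motion"),
            (10 * 3600 + 3599, "M003", "ON", "motion"),
            (11 * 3600, "M003", "ON", "motion"),
        ]
    )
    placed = map_to_places(log, hh126)
    (hc,) = hourly_counts(placed)
    p2 = list(hc.places).index("P2")
    assert hc.counts[p2, 10] == 2
    assert hc.counts[p2, 11] == 1


def test_empty_day_yields_zero_matrix(hh126):
    log = make_log([(0, "M010", "ON", "motion")])
    placed = map_to_places(log, hh126)
    day0 = dt.date(2022, 3, 1)
    out = hourly_counts(placed, day_range=(day0, day0 + dt.timedelta(days=2)))
    assert len(out) == 3
    assert out[1].counts.sum() == 0 and out[2].counts.sum() == 0
    assert out[0].counts.sum() == 1


def test_hourly_counts_conserve_events(hh126, rng):
    rows = [
        (int(rng.integers(0, 3 * 86400)), f"M{rng.integers(1, 16):03d}", "ON", "motion")
        for _ in range(200)
    ]
    placed = map_to_places(make_log(rows), hh126)
    out = hourly_counts(placed)
    assert sum(hc.counts.sum() for hc in out) == len(placed)


def test_empty_day_range_gives_empty_sequence(hh126):
    log = map_to_places(make_log([(0, "M010", "ON", "motion")]), hh126)
    day0 = dt.date(2022, 3, 5)
    assert hourly_counts(log, day_range=(day0, day0 - dt.timedelta(days=1))) == []


# ---------------------------------------------------------------------------
# faults, idempotency, oracle equivalence
# ---------------------------------------------------------------------------


def test_inject_sensor_fault():
    log = make_log([(0, "M004", "ON", "motion"), (5, "M008", "ON", "motion")])
    assert [e.sensor_id for e in inject_sensor_fault(log, {"M004"})] == ["M008"]
    assert len(inject_sensor_fault(log, set())) == 2


def _random_log(rng, n):
    sensors = ["M001", "M004", "M010", "D001", "S05", "S06"]
    types = {"M001": "motion", "M004": "motion", "M010": "motion",
             "D001": "door", "S05": "pressure", "S06": "pressure"}
    rows = []
    for _ in range(n):
        sid = sensors[rng.integers(0, len(sensors))]
        val = ["ON", "OFF"][rng.integers(0, 2)] if types[sid] == "motion" else "1"
        rows.append((int(rng.integers(0, 7200)), sid, val, types[sid]))
    return make_log(rows)


def _key(log):
    return [(e.timestamp, e.sensor_id, e.value) for e in log]


def test_each_stage_is_idempotent(rng, hh126):
    log = _random_log(rng, 50)
    for stage in (
        filter_off_events,
        debounce_events,
        mute_pressure_sensors,
        lambda l: map_to_places(l, hh126),
    ):
        once = stage(log)
        assert _key(stage(once)) == _key(once)
        log = once


# independent loop-based reimplementations (no shared code with the package)


def _oracle_filter_off(events):
    return [e for e in events if not (e.sensor_type == "motion" and e.value.upper() in ("OFF", "0", "FALSE"))]


def _oracle_debounce(events, gap=60.0):
    last = {}
    out = []
    for e in events:
        t = e.timestamp.timestamp()
        if e.sensor_id not in last or t - last[e.sensor_id] >= gap:
            out.append(e)
            last[e.sensor_id] = t
    return out


def _oracle_mute(events, gap=600.0):
    last = {}
    out = []
    for e in events:
        if e.sensor_type != "pressure":
            out.append(e)
            continue
        t = e.timestamp.timestamp()
        if e.sensor_id not in last or t - last[e.sensor_id] >= gap:
            out.append(e)
            last[e.sensor_id] = t
    return out


@pytest.mark.parametrize("trial", range(50))
def test_filters_match_loop_oracle(trial):
    rng = np.random.default_rng(1000 + trial)
    log = _random_log(rng, int(rng.integers(0, 51)))
    ev = log.events
    assert _key(filter_off_events(log)) == [
        (e.timestamp, e.sensor_id, e.value) for e in _oracle_filter_off(ev)
    ]
    assert _key(debounce_events(log)) == [
        (e.timestamp, e.sensor_id, e.value) for e in _oracle_debounce(ev)
    ]
    assert _key(mute_pressure_sensors(log)) == [
        (e.timestamp, e.sensor_id, e.value) for e in _oracle_mute(ev)
    ]


@given(st.lists(st.integers(min_value=0, max_value=3600), min_size=1, max_size=40))
def test_debounce_gap_invariant(offsets):
    log = make_log([(s, "M001", "ON", "motion") for s in sorted(offsets)])
    out = debounce_events(log)
    times = [e.timestamp for e in out]
    assert all((b - a).total_seconds() >= 60 for a, b in zip(times, times[1:]))


def test_preprocess_ledger_conservation(rng, hh126):
    log = _random_log(rng, 50)
    placed, ledger = preprocess(log, hh126)
    assert ledger["parsed"] == sum(
        ledger[k] for k in ("kept", "filtered_off", "debounced_away", "muted", "unmapped_dropped")
    )
    assert ledger["kept"] == len(placed)
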