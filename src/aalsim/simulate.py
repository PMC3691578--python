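"""Synthetic nursing-home room: behaviour timelines, sensor streams, faults.

The generator emulates one shared room of a dementia ward: two to four
residents with individual behaviour profiles (sleep window, night toilet
visits, shower habits, tap forgetfulness, night wandering, fall risk), a
washroom with sink / shower / toilet fixtures, and the sensor complement of
the deployed platform — pressure pads under mattresses, PIR motion sensors
(bedroom ceiling, shower, toilet), vibration sensors on the water pipes, a
proximity sensor at the sink, a ceiling-mounted ranging sensor over the
toilet, and RFID readers at the beds and the washroom entrance.

Generation is layered exactly like the evaluation needs it:

``generate_timeline``  ground-truth activity intervals for one resident-day;
``emit_events``        the sensor-event and RFID-read streams those
                       activities would produce (fault-free);
``inject_faults``      degradation per the deployment fault taxonomy
                       (sensor removed / battery out / packet loss /
                       Wi-Fi & ZigBee outages / reasoning crash);
``ground_truth_logsheet``  the hourly caregiver sheet rows used as ground
                       truth in place of video.

All sampling is driven by an explicit ``numpy`` Generator; identical seeds
give byte-identical outputs.  Times are seconds from local midnight at 1 s
resolution; one call covers one simulated day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .identity import RFIDRead

__all__ = [
    "SensorEvent",
    "Interval",
    "ActivityTimeline",
    "ResidentProfile",
    "RoomLayout",
    "FaultConfig",
    "LogSheetRow",
    "Scenario",
    "default_scenario",
    "generate_timeline",
    "emit_events",
    "inject_faults",
    "ground_truth_logsheet",
]

DAY_S = 86400
NIGHT_END = 7 * 3600       # 07:00
NIGHT_START = 21 * 3600    # 21:00
TRANSIT_S = 25             # door-to-fixture walking time inside an excursion
PIR_HOLD_S = 15            # PIR latch: short motion gaps are absorbed
BED_READ_PERIOD_S = 90     # periodic bed-reader reads while a resident is in bed
STANDING_HEIGHT_CM = 170
FALLEN_HEIGHT_CM = 40
HEIGHT_PERIOD_S = 10


class SensorEvent(NamedTuple):
    t: float
    sensor: str
    status: str                  # firing | silent | reading
    value: Optional[float] = None


class Interval(NamedTuple):
    resident: str
    activity: str                # sleep | toilet | shower | tap-use | wander | common-area | fall
    start: float
    end: float
    annotations: tuple = ()      # e.g. ("tap-left-on",), ("shower-too-long",)

    def has(self, key: str) -> bool:
        return key in self.annotations


@dataclass
class ActivityTimeline:
    resident: str
    date: int                            # day index
    intervals: list[Interval]
    asks: list[float] = field(default_factory=list)   # "asked for something" times

    def validate(self) -> None:
        prev_end = -1.0
        for iv in sorted(self.intervals, key=lambda i: i.start):
            if iv.start < 0 or iv.end > DAY_S or iv.end <= iv.start:
                raise ValueError(f"interval out of day bounds: {iv}")
            if iv.start < prev_end:
                raise ValueError(f"overlapping intervals at {iv.start}")
            prev_end = iv.end


@dataclass(frozen=True)
class ResidentProfile:
    """Behaviour parameters for one resident.

    Rates are per day (or per night), durations in seconds.  The defaults
    describe the ward's typical moderate-assistance resident and calibrate
    the default three-resident room to roughly 34 atomic and 7 complex
    context events per day.
    """

    id: str
    sleep_start: int = NIGHT_START
    sleep_end: int = NIGHT_END
    night_toilet_rate: float = 1.0            # Poisson mean, visits per night
    toilet_duration_median_s: float = 240.0
    toilet_duration_sigma: float = 0.3
    showers_per_day: int = 1
    shower_duration_median_s: float = 480.0
    shower_duration_sigma: float = 0.35
    long_shower_prob: float = 0.30
    tap_uses_per_day: float = 1.5             # Poisson mean
    tap_duration_s: float = 90.0
    forget_tap_prob: float = 0.40
    tap_run_on_s: float = 360.0               # how long a forgotten tap keeps running
    flush_forget_prob: float = 0.15
    wander_prob_per_night: float = 0.25
    wander_duration_median_s: float = 600.0
    wander_duration_sigma: float = 0.4
    fall_prob_per_toilet_visit: float = 0.02
    fall_lying_s: float = 300.0
    common_area_hours: float = 4.0
    asks_rate_per_day: float = 1.0
    assistance: str = "moderate"              # minimal | moderate

    def __post_init__(self) -> None:
        for name in ("long_shower_prob", "forget_tap_prob", "flush_forget_prob",
                     "wander_prob_per_night", "fall_prob_per_toilet_visit"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("night_toilet_rate", "tap_uses_per_day", "asks_rate_per_day"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("toilet_duration_median_s", "shower_duration_median_s",
                     "tap_duration_s", "wander_duration_median_s", "fall_lying_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class SensorPlacement:
    sensor: str
    modality: str                # pressure | motion | vibration | proximity | ranging | rfid
    target: str                  # object or location it observes


@dataclass
class RoomLayout:
    """Default sensor and device wiring of one three-bed room."""

    beds: dict[str, str]                      # resident -> bed object
    sensors: list[SensorPlacement]
    reader_location: dict[str, str]           # RFID reader -> location
    sensor_location: dict[str, str]           # occupancy sensor -> location
    devices: dict[str, str]                   # device id -> modality

    def required_ok(self) -> bool:
        mods = {p.modality for p in self.sensors}
        return {"pressure", "motion", "vibration", "proximity", "ranging"} <= mods


def default_layout(residents: Sequence[str]) -> RoomLayout:
    beds = {r: f"bed{i+1}" for i, r in enumerate(residents)}
    sensors = [SensorPlacement(f"pressureBed{i+1}", "pressure", f"bed{i+1}") for i in range(len(residents))]
    sensors += [
        SensorPlacement("pirBedroom", "motion", "bedroom"),
        SensorPlacement("pirShower", "motion", "shower"),
        SensorPlacement("vibShower", "vibration", "shower"),
        SensorPlacement("proxSink", "proximity", "sink"),
        SensorPlacement("vibSink", "vibration", "sink"),
        SensorPlacement("pirToilet", "motion", "toilet"),
        SensorPlacement("proxToilet", "ranging", "toilet"),
    ]
    reader_location = {"rfidEntrance": "washroom"}
    for i in range(len(residents)):
        reader_location[f"rfidBed{i+1}"] = "bedroom"
    sensor_location = {
        "pirShower": "washroom",
        "proxSink": "washroom",
        "pirToilet": "washroom",
    }
    devices = {"speaker1": "speaker", "phoneCaregiver1": "smartphone", "nursingConsole": "console"}
    return RoomLayout(beds, sensors, reader_location, sensor_location, devices)


@dataclass(frozen=True)
class FaultConfig:
    """Per-day rates of the deployment fault taxonomy; zero = fault-free."""

    sensor_removed_rate: float = 0.0
    battery_out_rate: float = 0.0
    packet_loss_rate: float = 0.0          # per event
    reasoning_bug_rate: float = 0.0
    wifi_disconnect_rate: float = 0.0
    zigbee_failure_rate: float = 0.0
    outage_mean_s: float = 3600.0
    recovery_mean_s: float = 600.0

    def __post_init__(self) -> None:
        for name in ("sensor_removed_rate", "battery_out_rate", "packet_loss_rate",
                     "reasoning_bug_rate", "wifi_disconnect_rate", "zigbee_failure_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class LogSheetRow:
    """One hour of ground truth for one patient (the caregiver sheet)."""

    date: int
    patient: str
    hour: int
    location: str               # Bedroom | Bathroom | Dining area | Common area | Other
    shower_too_long: bool = False
    tap_left_on: bool = False
    forgot_flush: bool = False
    wandered: bool = False
    asked_for_something: bool = False
    remark: str = ""


# ---------------------------------------------------------------------------
# timeline generation

def _lognormal(rng: np.random.Generator, median: float, sigma: float) -> float:
    return float(median * math.exp(sigma * rng.standard_normal()))


def _place(rng, busy_lists, lo: float, hi: float, dur: float, tries: int = 40):
    """Uniformly place [t, t+dur] in [lo, hi] avoiding spans in every busy list.

    On success the span is appended to each list; lists may be shared
    between residents (the washroom is single-occupancy)."""
    if hi - lo <= dur:
        return None
    for _ in range(tries):
        t = float(rng.uniform(lo, hi - dur))
        if all(t + dur <= a or t >= b for busy in busy_lists for a, b in busy):
            for busy in busy_lists:
                busy.append((t, t + dur))
                busy.sort()
            return t
    return None


def generate_timeline(
    profile: ResidentProfile,
    date: int,
    rng: np.random.Generator,
    long_shower_guard_s: float = 900.0,
    washroom_busy: Optional[list[tuple[float, float]]] = None,
) -> ActivityTimeline:
    """One resident-day of ground-truth activity.

    The day defaults to in-bed rest (the ward's residents spend unsupervised
    time in bed); excursions — night toilet visits, the morning shower, tap
    uses, one common-area block, a possible night wander — are carved out of
    it.  Deviance annotations are sampled from the profile and are, by
    construction, long enough for the matching service to detect them from
    the fault-free sensor stream.
    """
    busy: list[tuple[float, float]] = []
    shared = washroom_busy if washroom_busy is not None else []
    intervals: list[Interval] = []
    night_lo, night_hi = 900.0, NIGHT_END - 900.0   # keep clear of window edges

    # night toilet visits (+ possible fall)
    n_visits = int(rng.poisson(profile.night_toilet_rate))
    for _ in range(n_visits):
        dur = min(max(_lognormal(rng, profile.toilet_duration_median_s, profile.toilet_duration_sigma), 120.0), 900.0)
        fall = bool(rng.random() < profile.fall_prob_per_toilet_visit)
        total = dur + (profile.fall_lying_s if fall else 0.0) + 2 * TRANSIT_S
        t = _place(rng, [busy, shared], night_lo, night_hi, total + 60.0)
        if t is None:
            continue
        ann = []
        if bool(rng.random() < profile.flush_forget_prob):
            ann.append("forgot-flush")
        if fall:
            ann.append("fall")
        intervals.append(Interval(profile.id, "toilet", t, t + total, tuple(ann)))

    # night wandering
    if rng.random() < profile.wander_prob_per_night:
        dur = min(max(_lognormal(rng, profile.wander_duration_median_s, profile.wander_duration_sigma), 180.0), 3600.0)
        t = _place(rng, [busy], night_lo, night_hi, dur + 60.0)
        if t is not None:
            intervals.append(Interval(profile.id, "wander", t, t + dur))

    # morning shower(s)
    day_busy: list[tuple[float, float]] = []
    for k in range(profile.showers_per_day):
        if rng.random() < profile.long_shower_prob:
            dur = long_shower_guard_s + 300.0 + _lognormal(rng, 300.0, 0.5)
            ann = ("shower-too-long",)
        else:
            dur = min(_lognormal(rng, profile.shower_duration_median_s, profile.shower_duration_sigma),
                      0.85 * long_shower_guard_s)
            ann = ()
        dur += 2 * TRANSIT_S + 30.0
        t = _place(rng, [day_busy, shared], NIGHT_END + 600.0, NIGHT_END + 10800.0, dur + 120.0)
        if t is not None:
            intervals.append(Interval(profile.id, "shower", t, t + dur, ann))

    # common-area block (fixed early-afternoon habit, jittered)
    dur = profile.common_area_hours * 3600.0
    if dur > 0:
        start = 13 * 3600 + float(rng.uniform(-900, 900))
        t = _place(rng, [day_busy], start, start + dur + 1800.0, dur)
        if t is not None:
            intervals.append(Interval(profile.id, "common-area", t, t + dur))

    # tap uses across the day
    n_taps = int(rng.poisson(profile.tap_uses_per_day))
    for _ in range(n_taps):
        dur = profile.tap_duration_s + 2 * TRANSIT_S + 5.0
        forget = bool(rng.random() < profile.forget_tap_prob)
        t = _place(rng, [day_busy, shared], NIGHT_END + 1800.0, NIGHT_START - 1800.0, dur + profile.tap_run_on_s + 120.0)
        if t is None:
            continue
        ann = ("tap-left-on",) if forget else ()
        intervals.append(Interval(profile.id, "tap-use", t, t + dur, ann))

    # "asked for something" has no sensor; sheet analytics only
    asks = sorted(float(rng.uniform(NIGHT_END, NIGHT_START)) for _ in range(int(rng.poisson(profile.asks_rate_per_day))))

    # fill the remainder with in-bed rest/sleep
    carved = sorted((iv.start, iv.end) for iv in intervals)
    cursor = 0.0
    for a, b in carved:
        if a - cursor >= 60.0:
            intervals.append(Interval(profile.id, "sleep", cursor, a))
        cursor = max(cursor, b)
    if DAY_S - cursor >= 60.0:
        intervals.append(Interval(profile.id, "sleep", cursor, DAY_S))

    tl = ActivityTimeline(profile.id, date, sorted(intervals, key=lambda i: i.start), asks)
    tl.validate()
    return tl


# ---------------------------------------------------------------------------
# sensor emission

def _merge_spans(spans: list[tuple[float, float]], hold: float) -> list[tuple[float, float]]:
    if not spans:
        return []
    spans = sorted(spans)
    out = [list(spans[0])]
    for a, b in spans[1:]:
        if a <= out[-1][1] + hold:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [(a, b) for a, b in out]


def _span_events(sensor: str, spans: list[tuple[float, float]]) -> list[SensorEvent]:
    out = []
    for a, b in spans:
        out.append(SensorEvent(a, sensor, "firing"))
        out.append(SensorEvent(b, sensor, "silent"))
    return out


def emit_events(
    timelines: Sequence[ActivityTimeline],
    layout: RoomLayout,
    rng: np.random.Generator,
    *,
    tag_map: Optional[dict[str, str]] = None,
    rfid_miss: float = 0.0,
    caregiver_blocks: Sequence[tuple[str, float, float]] = (),
) -> tuple[list[SensorEvent], list[RFIDRead]]:
    """Fault-free sensor and RFID streams for one simulated day.

    ``caregiver_blocks`` are (caregiver id, start, end) washroom
    cleaning/assistance visits; they fire washroom sensors under the
    caregiver's own tag so identity exclusion is exercised.
    """
    events: list[SensorEvent] = []
    reads: list[RFIDRead] = []
    bedroom_motion: list[tuple[float, float]] = []
    tag_of = {}
    if tag_map:
        for tag, agent in tag_map.items():
            tag_of[agent] = tag

    def entrance_read(agent: str, t: float) -> None:
        if agent in tag_of and rng.random() >= rfid_miss:
            reads.append(RFIDRead(t, "rfidEntrance", tag_of[agent]))

    for tl in timelines:
        resident = tl.resident
        bed = layout.beds.get(resident)
        bed_index = list(layout.beds).index(resident) + 1 if bed else None
        pressure = f"pressureBed{bed_index}" if bed_index else None
        bed_reader = f"rfidBed{bed_index}" if bed_index else None
        for iv in tl.intervals:
            a, b = iv.start, iv.end
            if iv.activity == "sleep" and pressure:
                events.append(SensorEvent(a, pressure, "firing"))
                events.append(SensorEvent(b, pressure, "silent"))
                if bed_reader and bed_reader in layout.reader_location:
                    t = a + 5.0
                    while t < b:
                        if rng.random() >= rfid_miss:
                            reads.append(RFIDRead(t, bed_reader, tag_of.get(resident, resident)))
                        t += BED_READ_PERIOD_S
            elif iv.activity == "wander":
                bedroom_motion.append((a, b))
            elif iv.activity in ("toilet", "shower", "tap-use"):
                bedroom_motion.append((a, a + 20.0))
                bedroom_motion.append((b - 20.0, b))
                entrance_read(resident, a + 22.0)
                entrance_read(resident, b - 23.0)
                pa, pb = a + TRANSIT_S, b - TRANSIT_S
                if iv.activity == "toilet":
                    fall = iv.has("fall")
                    events += _span_events("pirToilet", [(pa, pb)])
                    fall_t = pa + 60.0 + (pb - pa - 120.0) * 0.3 if fall else None
                    t = pa
                    while t < pb:
                        if fall and t >= fall_t:
                            break
                        h = STANDING_HEIGHT_CM + float(rng.integers(-5, 6))
                        events.append(SensorEvent(t, "proxToilet", "reading", h))
                        t += HEIGHT_PERIOD_S
                    if fall:
                        events.append(SensorEvent(fall_t - 1.0, "proxToilet", "reading", STANDING_HEIGHT_CM))
                        t = fall_t
                        while t < pb - 5.0:
                            events.append(SensorEvent(t, "proxToilet", "reading", FALLEN_HEIGHT_CM))
                            t += HEIGHT_PERIOD_S
                        events.append(SensorEvent(pb - 4.0, "proxToilet", "reading", STANDING_HEIGHT_CM))
                elif iv.activity == "shower":
                    events += _span_events("pirShower", [(pa, pb)])
                    events += _span_events("vibShower", [(pa + 30.0, pb)])
                elif iv.activity == "tap-use":
                    events += _span_events("proxSink", [(pa, pb)])
                    run_on = 360.0 if iv.has("tap-left-on") else 0.0
                    events += _span_events("vibSink", [(pa + 5.0, pb - 5.0 + run_on)])

    for caregiver, a, b in caregiver_blocks:
        bedroom_motion.append((a, a + 20.0))
        bedroom_motion.append((b - 20.0, b))
        entrance_read(caregiver, a + 22.0)
        entrance_read(caregiver, b - 23.0)
        pa, pb = a + TRANSIT_S, b - TRANSIT_S
        mid = (pa + pb) / 2.0
        events += _span_events("pirToilet", [(pa, mid - 10.0)])
        events += _span_events("pirShower", [(mid, pb - 120.0)])
        events += _span_events("proxSink", [(pb - 110.0, pb)])
        events += _span_events("vibSink", [(pb - 100.0, pb - 10.0)])

    events += _span_events("pirBedroom", _merge_spans(bedroom_motion, PIR_HOLD_S))
    events.sort(key=lambda e: (e.t, e.sensor, e.status))
    reads.sort()
    return events, reads


# ---------------------------------------------------------------------------
# fault injection

def inject_faults(
    events: Sequence[SensorEvent],
    reads: Sequence[RFIDRead],
    cfg: FaultConfig,
    rng: np.random.Generator,
) -> tuple[list[SensorEvent], list[RFIDRead], list[dict], list[dict]]:
    """Degrade one day of streams per the fault taxonomy.

    Returns (events, reads, fault_log, crash_records).  Sensor outages
    (removal, flat battery) silence one sensor for a sampled window; packet
    loss drops individual events; Wi-Fi/ZigBee outages are logged as
    delivery-outage windows consumed by the action-delivery layer; a
    reasoning bug yields a platform crash record with its recovery time.
    """
    fault_log: list[dict] = []
    crash_records: list[dict] = []
    outages: dict[str, list[tuple[float, float]]] = {}

    sensor_ids = sorted({e.sensor for e in events} | set(r.reader for r in reads))
    for kind, rate in (("sensor_removed", cfg.sensor_removed_rate), ("battery_out", cfg.battery_out_rate)):
        for sensor in sensor_ids:
            if rng.random() < rate:
                start = float(rng.uniform(0, DAY_S))
                dur = float(rng.exponential(cfg.outage_mean_s))
                outages.setdefault(sensor, []).append((start, start + dur))
                fault_log.append({"t": start, "class": kind, "sensor": sensor, "until": start + dur})

    def alive(sensor: str, t: float) -> bool:
        return all(not (a <= t < b) for a, b in outages.get(sensor, ()))

    out_events = []
    for e in events:
        if not alive(e.sensor, e.t):
            continue
        if cfg.packet_loss_rate > 0 and rng.random() < cfg.packet_loss_rate:
            fault_log.append({"t": e.t, "class": "packet_loss", "sensor": e.sensor})
            continue
        out_events.append(e)
    out_reads = []
    for r in reads:
        if not alive(r.reader, r.t):
            continue
        if cfg.packet_loss_rate > 0 and rng.random() < cfg.packet_loss_rate:
            fault_log.append({"t": r.t, "class": "packet_loss", "sensor": r.reader})
            continue
        out_reads.append(r)

    for kind, rate in (("wifi_disconnect", cfg.wifi_disconnect_rate), ("zigbee_failure", cfg.zigbee_failure_rate)):
        if rng.random() < rate:
            start = float(rng.uniform(0, DAY_S))
            dur = float(rng.exponential(cfg.outage_mean_s))
            fault_log.append({"t": start, "class": kind, "until": start + dur, "delivery_outage": True})

    if rng.random() < cfg.reasoning_bug_rate:
        t = float(rng.uniform(0, DAY_S))
        rec = float(rng.exponential(cfg.recovery_mean_s))
        crash_records.append({"t": t, "class": "reasoning_bug", "recovered_t": t + rec})
        fault_log.append({"t": t, "class": "reasoning_bug", "until": t + rec})

    return out_events, out_reads, fault_log, crash_records


# ---------------------------------------------------------------------------
# caregiver log-sheets

_LOCATION_OF = {
    "sleep": "Bedroom",
    "wander": "Bedroom",
    "toilet": "Bathroom",
    "shower": "Bathroom",
    "tap-use": "Bathroom",
    "fall": "Bathroom",
    "common-area": "Common area",
}


def ground_truth_logsheet(
    timelines: Sequence[ActivityTimeline],
    hour_shift_prob: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> list[LogSheetRow]:
    """One sheet row per patient per hour, as the caregivers would fill it.

    With ``hour_shift_prob`` > 0, each recorded abnormal-behaviour flag is
    independently logged in an adjacent hour with that probability,
    mimicking imprecision in the caregivers' logging time.
    """
    if hour_shift_prob and rng is None:
        raise ValueError("hour_shift_prob needs an rng")
    rows: list[LogSheetRow] = []
    for tl in timelines:
        occupancy = np.zeros((24, 5))
        classes = ["Bedroom", "Bathroom", "Dining area", "Common area", "Other"]
        flags: dict[int, dict[str, bool]] = {h: {} for h in range(24)}

        def flag(key: str, t: float) -> None:
            h = int(t // 3600) % 24
            if hour_shift_prob and rng.random() < hour_shift_prob:
                h = max(0, min(23, h + (1 if rng.random() < 0.5 else -1)))
            flags[h][key] = True

        for iv in tl.intervals:
            cls = classes.index(_LOCATION_OF.get(iv.activity, "Other"))
            h0, h1 = int(iv.start // 3600), int(math.ceil(iv.end / 3600))
            for h in range(h0, min(h1, 24)):
                lo, hi = h * 3600.0, (h + 1) * 3600.0
                occupancy[h, cls] += max(0.0, min(iv.end, hi) - max(iv.start, lo))
            if iv.has("shower-too-long"):
                flag("shower_too_long", iv.start)
            if iv.has("tap-left-on"):
                flag("tap_left_on", iv.start)
            if iv.has("forgot-flush"):
                flag("forgot_flush", iv.start)
            if iv.activity == "wander":
                flag("wandered", iv.start)
        for t in tl.asks:
            flag("asked_for_something", t)

        for h in range(24):
            loc = classes[int(np.argmax(occupancy[h]))] if occupancy[h].sum() > 0 else "Bedroom"
            f = flags[h]
            rows.append(
                LogSheetRow(
                    tl.date, tl.resident, h, loc,
                    shower_too_long=f.get("shower_too_long", False),
                    tap_left_on=f.get("tap_left_on", False),
                    forgot_flush=f.get("forgot_flush", False),
                    wandered=f.get("wandered", False),
                    asked_for_something=f.get("asked_for_something", False),
                )
            )
    return rows


# ---------------------------------------------------------------------------
# scenario

@dataclass
class Scenario:
    """A complete study configuration: who lives in the room, the wiring,
    the fault regime, caregiver visits and optional profile change-days."""

    profiles: list[ResidentProfile]
    layout: RoomLayout
    faults: FaultConfig = FaultConfig()
    rfid_miss: float = 0.0
    caregivers: tuple[str, ...] = ("caregiver1",)
    cleaning_hour: float = 9.5                  # daily washroom cleaning start
    logsheet_shift_prob: float = 0.0
    change_day: Optional[int] = None            # deterioration onset day
    changed_profiles: Optional[list[ResidentProfile]] = None

    @property
    def residents(self) -> list[str]:
        return [p.id for p in self.profiles]

    @property
    def tag_map(self) -> dict[str, str]:
        m = {f"tag_{r}": r for r in self.residents}
        for c in self.caregivers:
            m[f"tag_{c}"] = c
        return m

    def profiles_for_day(self, day: int) -> list[ResidentProfile]:
        if self.change_day is not None and self.changed_profiles and day >= self.change_day:
            return self.changed_profiles
        return self.profiles

    def caregiver_blocks(self) -> list[tuple[str, float, float]]:
        start = self.cleaning_hour * 3600.0
        return [(self.caregivers[0], start, start + 1200.0)] if self.caregivers else []

    def generate_day(self, day: int, seed: int):
        """Timelines, fault-degraded streams, sheets and fault logs for one day."""
        rng = np.random.default_rng(seed)
        washroom_busy = [(a, b) for _, a, b in self.caregiver_blocks()]
        timelines = [
            generate_timeline(p, day, rng, washroom_busy=washroom_busy)
            for p in self.profiles_for_day(day)
        ]
        events, reads = emit_events(
            timelines, self.layout, rng,
            tag_map=self.tag_map, rfid_miss=self.rfid_miss,
            caregiver_blocks=self.caregiver_blocks(),
        )
        events, reads, fault_log, crashes = inject_faults(events, reads, self.faults, rng)
        sheets = ground_truth_logsheet(timelines, self.logsheet_shift_prob, rng)
        return timelines, events, reads, sheets, fault_log, crashes


def default_scenario() -> Scenario:
    """The shipped three-resident room (one minimal-assistance resident,
    two moderate), fault-free, with the default sensor complement."""
    profiles = [
        ResidentProfile(id="patient1", assistance="moderate"),
        ResidentProfile(id="patient2", assistance="moderate"),
        ResidentProfile(id="patient3", assistance="minimal"),
    ]
    return Scenario(profiles=profiles, layout=default_layout([p.id for p in profiles]))
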