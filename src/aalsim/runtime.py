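"""Platform assembly and the event-driven reasoning loop.

`build_platform` constructs the in-memory platform for a scenario: the
context model (entities and static structure triples), the rule base, the
service specs and fresh timer state.  `DayRunner` then consumes one day of
sensor events and RFID reads: it maintains sensor-status and attribution
facts in the model, calls the service layer at every event and timer
deadline, tracks each patient's believed location, and collects the run's
actions, deviance detections and atomic usage episodes.

The runner's full mutable state can be snapshotted (`state_dict`) and
restored (`load_state`), which is what the design-for-failure checkpoint /
auto-resume machinery in the CLI is built on: a resumed run replays at most
the span since the last snapshot and produces byte-identical outputs.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

from .context import ContextModel, EntityKind, Triple
from .identity import RFIDRead, resolve
from .rules import RuleSet, parse_ruleset
from .services import (
    Action,
    ServiceSpec,
    TimerState,
    builtin_service_specs,
    next_deadline,
    step,
)
from .simulate import (
    DAY_S,
    NIGHT_END,
    NIGHT_START,
    Scenario,
    SensorEvent,
)

__all__ = [
    "Platform",
    "RunLog",
    "DayRunner",
    "build_platform",
    "default_ruleset",
    "night_wandering_model",
    "EXTRA_VOCABULARY",
]

#: Platform vocabulary extensions over the core relation set: `lastUser`
#: records washroom-fixture attribution, `hasModality` types devices.
EXTRA_VOCABULARY = ("lastUser", "hasModality")

BELIEF_HOLD_S = 60.0        # a new believed location must persist this long
FALL_DROP_CM = 40.0
FALL_DROP_WINDOW_S = 2.0
STANDING_MIN_CM = 100.0

_FIXTURE_OF = {"pirShower": "shower", "vibShower": "shower",
               "proxSink": "sink", "vibSink": "sink",
               "pirToilet": "toilet", "proxToilet": "toilet"}


def default_ruleset() -> RuleSet:
    text = importlib.resources.files("aalsim.data").joinpath("default.rules").read_text()
    return parse_ruleset(text)


@dataclass
class Platform:
    model: ContextModel
    ruleset: RuleSet
    specs: list[ServiceSpec]
    state: TimerState = field(default_factory=TimerState)
    registry: dict = field(default_factory=dict)   # plug & play components
    triple_refs: dict = field(default_factory=dict)  # triple -> refcount (shared sensors)

    def copy_config(self) -> "Platform":
        return Platform(self.model.copy(), self.ruleset.copy(), list(self.specs),
                        TimerState(), dict(self.registry), dict(self.triple_refs))


_DEVIANCES = {"wandering": "wanderingAlert", "longShower": "showerTooLong",
              "tapOn": "tapReminder", "toiletFall": "fallAlert"}


def build_platform(
    scenario: Scenario,
    service_config: Optional[dict] = None,
    ruleset: Optional[RuleSet] = None,
    specs: Optional[Sequence[ServiceSpec]] = None,
) -> Platform:
    m = ContextModel(extra_vocabulary=EXTRA_VOCABULARY)
    layout = scenario.layout

    for loc in ("bedroom", "washroom", "commonArea"):
        m.register_entity(loc, EntityKind.LOCATION)
    for obj in ("sink", "shower", "toilet"):
        m.register_entity(obj, EntityKind.OBJECT)
        m.assert_fact(Triple(obj, "locatedIn", "washroom"))
    for r, bed in layout.beds.items():
        m.register_entity(r, EntityKind.PATIENT)
        m.register_entity(bed, EntityKind.OBJECT)
        m.assert_fact(Triple(bed, "locatedIn", "bedroom"))
        m.assert_fact(Triple(r, "ownsBed", bed))
    for c in scenario.caregivers:
        m.register_entity(c, EntityKind.CAREGIVER)
        m.assert_fact(Triple(c, "monitors", "bedroom"))
        m.assert_fact(Triple(c, "monitors", "washroom"))
    for p in layout.sensors:
        m.register_entity(p.sensor, EntityKind.SENSOR)
        if p.target in ("bedroom", "washroom", "commonArea"):
            m.assert_fact(Triple(p.sensor, "monitors", p.target))
        elif p.modality in ("motion", "proximity"):
            m.assert_fact(Triple(p.sensor, "monitors", p.target))
        else:
            m.assert_fact(Triple(p.sensor, "attachedTo", p.target))
        m.assert_fact(Triple(p.sensor, "hasStatus", "silent"))
    for reader in layout.reader_location:
        m.register_entity(reader, EntityKind.SENSOR)
        m.assert_fact(Triple(reader, "monitors", layout.reader_location[reader]))
    for dev, modality in layout.devices.items():
        m.register_entity(dev, EntityKind.INTERACTION_DEVICE)
        m.assert_fact(Triple(dev, "hasModality", modality))
    for r in layout.beds:
        if "speaker1" in layout.devices:
            m.assert_fact(Triple(r, "usesDevice", "speaker1"))
    if scenario.caregivers and "phoneCaregiver1" in layout.devices:
        m.assert_fact(Triple(scenario.caregivers[0], "usesDevice", "phoneCaregiver1"))

    m.register_entity("sleeping", EntityKind.ACTIVITY)
    for dv, svc in _DEVIANCES.items():
        m.register_entity(dv, EntityKind.DEVIANCE)
        m.register_entity(svc, EntityKind.ASSISTIVE_SERVICE)
        m.assert_fact(Triple(dv, "needService", svc))
    m.assert_fact(Triple("bedroom", "hasPhase", "night"))   # days start at midnight

    return Platform(
        model=m,
        ruleset=ruleset.copy() if ruleset else default_ruleset(),
        specs=list(specs) if specs is not None else builtin_service_specs(service_config),
    )


def night_wandering_model() -> tuple[ContextModel, RuleSet]:
    """The two-resident night scenario: patient2 asleep, patient1's bed
    empty, motion in the bedroom.  Base facts only; reasoning derives the
    wandering/sleeping activities, the service interest and the caregiver
    assignment."""
    m = ContextModel(extra_vocabulary=EXTRA_VOCABULARY)
    m.register_entity("bedroom", EntityKind.LOCATION)
    for i, p in enumerate(("patient1", "patient2"), 1):
        m.register_entity(p, EntityKind.PATIENT)
        m.register_entity(f"bed{i}", EntityKind.OBJECT)
        m.register_entity(f"pressureBed{i}", EntityKind.SENSOR)
        m.assert_fact(Triple(p, "ownsBed", f"bed{i}"))
        m.assert_fact(Triple(f"bed{i}", "locatedIn", "bedroom"))
        m.assert_fact(Triple(f"pressureBed{i}", "attachedTo", f"bed{i}"))
    m.register_entity("pirBedroom", EntityKind.SENSOR)
    m.assert_fact(Triple("pirBedroom", "monitors", "bedroom"))
    m.register_entity("caregiver1", EntityKind.CAREGIVER)
    m.assert_fact(Triple("caregiver1", "monitors", "bedroom"))
    m.register_entity("sleeping", EntityKind.ACTIVITY)
    m.register_entity("wandering", EntityKind.DEVIANCE)
    m.register_entity("wanderingAlert", EntityKind.ASSISTIVE_SERVICE)
    m.assert_fact(Triple("wandering", "needService", "wanderingAlert"))
    m.register_entity("iphoneCaregiver1", EntityKind.INTERACTION_DEVICE)
    m.assert_fact(Triple("iphoneCaregiver1", "hasModality", "smartphone"))
    m.assert_fact(Triple("caregiver1", "usesDevice", "iphoneCaregiver1"))
    m.register_entity("speaker1", EntityKind.INTERACTION_DEVICE)
    m.assert_fact(Triple("speaker1", "hasModality", "speaker"))
    m.assert_fact(Triple("patient1", "usesDevice", "speaker1"))
    # the context update: night, patient1 off the bed, motion in the room
    m.assert_fact(Triple("bedroom", "hasPhase", "night"))
    m.assert_fact(Triple("pressureBed1", "hasStatus", "silent"))
    m.assert_fact(Triple("pressureBed2", "hasStatus", "firing"))
    m.assert_fact(Triple("pirBedroom", "hasStatus", "firing"))
    return m, default_ruleset()


# ---------------------------------------------------------------------------
# the day runner

@dataclass
class RunLog:
    day: int
    actions: list[Action] = field(default_factory=list)
    detections: list[dict] = field(default_factory=list)
    tap_uses: int = 0
    shower_uses: int = 0
    location_changes: int = 0
    context_intervals: list[tuple] = field(default_factory=list)  # (patient, loc, start, end)
    health: list[dict] = field(default_factory=list)
    delayed: list[dict] = field(default_factory=list)

    @property
    def provisions(self) -> int:
        return len({a.episode_id for a in self.actions})

    @property
    def atomic_count(self) -> int:
        return self.tap_uses + self.shower_uses + self.location_changes

    @property
    def complex_count(self) -> int:
        return len(self.detections) + self.provisions

    def actions_jsonl(self) -> str:
        return "".join(json.dumps(asdict(a), sort_keys=True) + "\n" for a in self.actions)


class DayRunner:
    """Event-driven reasoning over one simulated day.

    Deterministic: identical inputs give identical actions and logs.
    ``run(stop_at=...)`` may be called repeatedly; ``state_dict`` /
    ``load_state`` snapshot and restore every piece of mutable state.
    """

    def __init__(
        self,
        platform: Platform,
        events: Sequence[SensorEvent],
        reads: Sequence[RFIDRead],
        scenario: Scenario,
        day: int = 0,
        fault_log: Sequence[dict] = (),
    ):
        self.platform = platform
        self.events = list(events)
        self.scenario = scenario
        self.day = day
        self.outages = [(f["t"], f["until"]) for f in fault_log if f.get("delivery_outage")]
        assignments = resolve(
            self.events, list(reads),
            roster=scenario.residents,
            tag_map=scenario.tag_map,
            sensor_location=scenario.layout.sensor_location,
            reader_location=scenario.layout.reader_location,
        )
        self._assignment_by_event = {a.event_index: a for a in assignments}
        self.log = RunLog(day=day)
        # mutable cursor state
        self.now = 0.0
        self.idx = 0
        self.finished = False
        self.believed: dict[str, str] = {r: "bedroom" for r in scenario.residents}
        self.candidate: dict[str, tuple[str, float]] = {}
        self._belief_since: dict[str, float] = {r: 0.0 for r in scenario.residents}
        self.usage_onset: dict[str, Optional[str]] = {"vibSink": None, "vibShower": None}
        self.last_height: Optional[tuple[float, float]] = None

    # -- helpers ----------------------------------------------------------

    @property
    def model(self) -> ContextModel:
        return self.platform.model

    def _set_status(self, sensor: str, status: str) -> None:
        self.model.retract_where(subject=sensor, predicate="hasStatus")
        self.model.assert_fact(Triple(sensor, "hasStatus", status))

    def _status(self, sensor: str) -> Optional[str]:
        hits = self.model.query((sensor, "hasStatus", "?s"))
        return hits[0]["?s"] if hits else None

    def _set_last_user(self, fixture: str, agent: Optional[str]) -> None:
        self.model.retract_where(subject=fixture, predicate="lastUser")
        if agent is not None:
            self.model.assert_fact(Triple(fixture, "lastUser", agent))

    def _last_user(self, fixture: str) -> Optional[str]:
        hits = self.model.query((fixture, "lastUser", "?a"))
        return hits[0]["?a"] if hits else None

    def _phase(self, t: float) -> str:
        return "night" if (t < NIGHT_END or t >= NIGHT_START) else "day"

    def _default_location(self, t: float) -> str:
        return "bedroom" if self._phase(t) == "night" else "commonArea"

    def _evidence(self, patient: str, loc: str, t: float) -> None:
        if loc == self.believed[patient]:
            self.candidate.pop(patient, None)
            return
        cand = self.candidate.get(patient)
        if cand is None or cand[0] != loc:
            self.candidate[patient] = (loc, t)

    def _commit_beliefs(self, t: float) -> None:
        for patient in list(self.candidate):
            loc, since = self.candidate[patient]
            # compare against the same float expression the deadline uses
            if t >= since + BELIEF_HOLD_S:
                self.log.context_intervals.append(
                    (patient, self.believed[patient], self._belief_since[patient], since)
                )
                self.believed[patient] = loc
                self._belief_since[patient] = since
                self.log.location_changes += 1
                del self.candidate[patient]

    def _next_belief_deadline(self) -> float:
        if not self.candidate:
            return float("inf")
        return min(since + BELIEF_HOLD_S for _, since in self.candidate.values())

    # -- event application ------------------------------------------------

    def _apply_event(self, i: int, ev: SensorEvent) -> None:
        roster = set(self.scenario.residents)
        bed_owner = {f"pressureBed{k+1}": r for k, r in enumerate(self.scenario.layout.beds)}
        if ev.status == "reading" and ev.sensor == "proxToilet":
            prev = self.last_height
            self.last_height = (ev.t, float(ev.value))
            if prev is not None:
                dt = ev.t - prev[0]
                if prev[1] - float(ev.value) >= FALL_DROP_CM and dt <= FALL_DROP_WINDOW_S:
                    self._set_status("proxToilet", "heightDrop")
            if float(ev.value) >= STANDING_MIN_CM and self._status("proxToilet") == "heightDrop":
                self._set_status("proxToilet", "silent")
            return
        if ev.status not in ("firing", "silent"):
            return
        self._set_status(ev.sensor, ev.status)

        fixture = _FIXTURE_OF.get(ev.sensor)
        if ev.status == "firing":
            if ev.sensor in ("pirShower", "proxSink", "pirToilet"):
                a = self._assignment_by_event.get(i)
                if a is not None and a.resident != "Unknown":
                    self._set_last_user(fixture, a.resident)
                    if a.resident in roster:
                        self._evidence(a.resident, "washroom", ev.t)
            if ev.sensor in self.usage_onset:
                self.usage_onset[ev.sensor] = self._last_user(_FIXTURE_OF[ev.sensor])
            if ev.sensor in bed_owner:
                self._evidence(bed_owner[ev.sensor], "bedroom", ev.t)
        else:  # silent
            if ev.sensor in self.usage_onset:
                user = self.usage_onset[ev.sensor] or self._last_user(_FIXTURE_OF[ev.sensor])
                if user in roster:
                    if ev.sensor == "vibSink":
                        self.log.tap_uses += 1
                    else:
                        self.log.shower_uses += 1
                self.usage_onset[ev.sensor] = None
            if ev.sensor == "vibSink":
                self._set_last_user("sink", None)
            if ev.sensor in ("pirShower", "vibShower"):
                if self._status("pirShower") == "silent" and self._status("vibShower") == "silent":
                    self._set_last_user("shower", None)
            if ev.sensor == "pirToilet" and self._status("proxToilet") != "heightDrop":
                self._set_last_user("toilet", None)
            if ev.sensor in bed_owner:
                patient = bed_owner[ev.sensor]
                self._evidence(patient, self._default_location(ev.t), ev.t)

    def _set_phase(self, phase: str) -> None:
        self.model.retract_where(subject="bedroom", predicate="hasPhase")
        self.model.assert_fact(Triple("bedroom", "hasPhase", phase))

    def _deliver(self, actions: list[Action]) -> None:
        for a in actions:
            for lo, hi in self.outages:
                if lo <= a.t < hi:
                    self.log.delayed.append({"episode": a.episode_id, "t": a.t, "delivered_t": hi})
                    break
            self.log.actions.append(a)

    # -- main loop --------------------------------------------------------

    def run(self, stop_at: Optional[float] = None, checkpoint_cb=None) -> RunLog:
        p = self.platform
        next_hour = (int(self.now // 3600) + 1) * 3600.0
        while True:
            t_event = self.events[self.idx].t if self.idx < len(self.events) else float("inf")
            t_dead = next_deadline(p.specs, p.state)
            t_dead = float("inf") if t_dead is None else max(t_dead, self.now)
            t_phase = min(b for b in (NIGHT_END, NIGHT_START, float("inf")) if b > self.now)
            t_belief = self._next_belief_deadline()
            t = min(t_event, t_dead, t_phase, t_belief)
            if t == float("inf") or t >= DAY_S:
                break
            if stop_at is not None and t > stop_at:
                return self.log
            while checkpoint_cb is not None and t >= next_hour:
                self.now = next_hour
                checkpoint_cb(self)
                next_hour += 3600.0
            self.now = t
            if t in (NIGHT_END, NIGHT_START):
                self._set_phase("day" if t == NIGHT_END else "night")
            while self.idx < len(self.events) and self.events[self.idx].t == t:
                self._apply_event(self.idx, self.events[self.idx])
                self.idx += 1
            self._commit_beliefs(t)
            actions, _ = step(p.model, p.ruleset, p.specs, p.state, t)
            self._deliver(actions)
        # close out context intervals and logs
        if not self.finished:
            for patient in self.scenario.residents:
                self.log.context_intervals.append(
                    (patient, self.believed[patient], self._belief_since[patient], float(DAY_S))
                )
            self.log.detections = list(p.state.detections)
            self.log.health = list(p.state.health_log)
            self.finished = True
        return self.log

    # -- checkpointing ----------------------------------------------------

    def state_dict(self) -> dict:
        return {
            "day": self.day,
            "now": self.now,
            "idx": self.idx,
            "finished": self.finished,
            "model": self.platform.model.to_text(),
            "timer": self.platform.state.to_dict(),
            "believed": dict(self.believed),
            "candidate": {k: list(v) for k, v in self.candidate.items()},
            "belief_since": dict(self._belief_since),
            "usage_onset": dict(self.usage_onset),
            "last_height": list(self.last_height) if self.last_height else None,
            "log": {
                "actions": [asdict(a) for a in self.log.actions],
                "detections": list(self.log.detections),
                "tap_uses": self.log.tap_uses,
                "shower_uses": self.log.shower_uses,
                "location_changes": self.log.location_changes,
                "context_intervals": [list(x) for x in self.log.context_intervals],
                "health": list(self.log.health),
                "delayed": list(self.log.delayed),
            },
        }

    def load_state(self, d: dict) -> None:
        self.day = d["day"]
        self.now = d["now"]
        self.idx = d["idx"]
        self.finished = d["finished"]
        self.platform.model = ContextModel.from_text(d["model"], extra_vocabulary=EXTRA_VOCABULARY)
        self.platform.state = TimerState.from_dict(d["timer"])
        self.believed = dict(d["believed"])
        self.candidate = {k: (v[0], v[1]) for k, v in d["candidate"].items()}
        self._belief_since = dict(d["belief_since"])
        self.usage_onset = dict(d["usage_onset"])
        self.last_height = tuple(d["last_height"]) if d["last_height"] else None
        lg = d["log"]
        self.log = RunLog(
            day=self.day,
            actions=[Action(**a) for a in lg["actions"]],
            detections=list(lg["detections"]),
            tap_uses=lg["tap_uses"],
            shower_uses=lg["shower_uses"],
            location_changes=lg["location_changes"],
            context_intervals=[tuple(x) for x in lg["context_intervals"]],
            health=list(lg["health"]),
            delayed=list(lg["delayed"]),
        )


def run_day(scenario: Scenario, day: int, seed: int, platform: Optional[Platform] = None):
    """Simulate one day and run the full reasoning pipeline over it.

    Returns (timelines, sheets, run log).  A fresh platform is built unless
    one is supplied (whose timer state is reused across days).
    """
    timelines, events, reads, sheets, fault_log, crashes = scenario.generate_day(day, seed)
    plat = platform or build_platform(scenario)
    runner = DayRunner(plat, events, reads, scenario, day=day, fault_log=fault_log)
    log = runner.run()
    return timelines, sheets, log
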