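"""Service-layer semantics: deployed-service wiring of the built-in specs, the
reminder/escalation ladder against an independently coded state-machine
oracle, channel selection, and the silence / escalation-bound /
personalization invariants."""

import numpy as np
import pytest

from aalsim.context import ContextModel, EntityKind, Triple
from aalsim.rules import parse_ruleset
from aalsim.services import (
    Action,
    ClockRegressionError,
    InvalidThresholdError,
    ReminderPolicy,
    ServiceSpec,
    TimerState,
    builtin_service_specs,
    select_channel,
    service_spec_from_dict,
    step,
)

TAP_RULE = (
    "rule tap_unattended: (sink, lastUser, ?u:Patient)"
    " & (proxSink, hasStatus, silent) & (vibSink, hasStatus, firing)"
    " => (?u, perform, tapOn) & (?u, locatedIn, washroom)"
)


def tap_world(phase="day"):
    m = ContextModel(extra_vocabulary=("lastUser", "hasModality"))
    m.register_entity("washroom", EntityKind.LOCATION)
    m.register_entity("sink", EntityKind.OBJECT)
    m.register_entity("proxSink", EntityKind.SENSOR)
    m.register_entity("vibSink", EntityKind.SENSOR)
    m.register_entity("patient1", EntityKind.PATIENT)
    m.register_entity("caregiver1", EntityKind.CAREGIVER)
    m.register_entity("tapOn", EntityKind.DEVIANCE)
    m.register_entity("tapReminder", EntityKind.ASSISTIVE_SERVICE)
    m.register_entity("speaker1", EntityKind.INTERACTION_DEVICE)
    m.register_entity("phone1", EntityKind.INTERACTION_DEVICE)
    m.register_entity("console", EntityKind.INTERACTION_DEVICE)
    m.assert_fact(Triple("sink", "locatedIn", "washroom"))
    m.assert_fact(Triple("tapOn", "needService", "tapReminder"))
    m.assert_fact(Triple("caregiver1", "monitors", "washroom"))
    m.assert_fact(Triple("patient1", "usesDevice", "speaker1"))
    m.assert_fact(Triple("speaker1", "hasModality", "speaker"))
    m.assert_fact(Triple("caregiver1", "usesDevice", "phone1"))
    m.assert_fact(Triple("phone1", "hasModality", "smartphone"))
    m.assert_fact(Triple("console", "hasModality", "console"))
    m.assert_fact(Triple("proxSink", "hasStatus", "firing"))
    m.assert_fact(Triple("vibSink", "hasStatus", "silent"))
    m.assert_fact(Triple("washroom", "hasPhase", phase))
    return m, parse_ruleset(TAP_RULE)


def set_condition(m, on: bool):
    m.retract_where(subject="proxSink", predicate="hasStatus")
    m.retract_where(subject="vibSink", predicate="hasStatus")
    m.retract_where(subject="sink", predicate="lastUser")
    if on:
        m.assert_fact(Triple("proxSink", "hasStatus", "silent"))
        m.assert_fact(Triple("vibSink", "hasStatus", "firing"))
        m.assert_fact(Triple("sink", "lastUser", "patient1"))
    else:
        m.assert_fact(Triple("proxSink", "hasStatus", "firing"))
        m.assert_fact(Triple("vibSink", "hasStatus", "silent"))


TAP_SPEC = ServiceSpec(
    name="tapReminder", deviance="tapOn", trigger_rule="tap_unattended",
    guard_s=10.0, policy=ReminderPolicy(3, 5.0),
)


def ladder_oracle(schedule, T, guard=10.0, interval=5.0, max_repeats=3, patient_leg=True):
    """Hand-written automaton for one service episode ladder.

    ``schedule`` maps each second to condition on/off.  Returns the list of
    (t, kind) the service must emit when stepped once per second.
    """
    out = []
    onset = None
    sent = 0
    last = None
    escalated = False
    for t in range(T):
        if not schedule[t]:
            onset, sent, last, escalated = None, 0, None, False
            continue
        if onset is None:
            onset, sent, last, escalated = t, 0, None, False
        if t < onset + guard or escalated:
            continue
        due = last is None or t >= last + interval
        if not due:
            continue
        if patient_leg and sent < max_repeats:
            out.append((t, "Reminder"))
            sent += 1
            last = t
        elif not escalated:
            out.append((t, "Notification"))
            escalated = True
            last = t
    return out


class TestBuiltinSpecs:
    def test_four_deployed_services_wiring(self):
        specs = builtin_service_specs()
        assert [s.name for s in specs] == ["wanderingAlert", "showerTooLong", "tapReminder", "fallAlert"]
        wandering = specs[0]
        assert wandering.patient_channel is None  # no interaction with the intended patient
        assert wandering.caregiver_channels == ("caregiver-smartphone", "nursing-console")
        fall = specs[3]
        assert fall.escalation_kind == "Alert"

    def test_invalid_threshold_rejected(self):
        with pytest.raises(InvalidThresholdError):
            builtin_service_specs({"tap_guard_s": -1})
        with pytest.raises(InvalidThresholdError):
            ReminderPolicy(-1, 30.0)

    def test_zero_repeats_escalates_immediately(self):
        m, rules = tap_world()
        spec = ServiceSpec(name="tapReminder", deviance="tapOn", trigger_rule="tap_unattended",
                           guard_s=10.0, policy=ReminderPolicy(0, 5.0))
        set_condition(m, True)
        st = TimerState()
        acts0, _ = step(m, rules, [spec], st, 0.0)   # onset observed, guard pending
        assert acts0 == []
        acts, _ = step(m, rules, [spec], st, 10.0)   # guard elapsed: no reminders, straight to caregivers
        assert [a.kind for a in acts] == ["Notification"]

    def test_fifth_service_loadable_from_config(self):
        d = {"name": "showerNoSoap", "deviance": "noSoap", "trigger_rule": "soap", "guard_s": 120}
        specs = builtin_service_specs() + [service_spec_from_dict(d)]
        assert len(specs) == 5 and specs[4].name == "showerNoSoap"


class TestStep:
    def test_quiescent_model_emits_nothing(self):
        m, rules = tap_world()
        st = TimerState()
        for t in range(0, 100, 10):
            acts, _ = step(m, rules, [TAP_SPEC], st, float(t))
            assert acts == []
        assert st.episodes == {}

    def test_clock_regression_rejected(self):
        m, rules = tap_world()
        st = TimerState()
        step(m, rules, [TAP_SPEC], st, 10.0)
        with pytest.raises(ClockRegressionError):
            step(m, rules, [TAP_SPEC], st, 5.0)

    def test_full_ladder_then_escalation(self):
        m, rules = tap_world()
        set_condition(m, True)
        st = TimerState()
        emitted = []
        for t in range(0, 40):
            acts, _ = step(m, rules, [TAP_SPEC], st, float(t))
            emitted += [(a.t, a.kind, a.recipient, a.channel) for a in acts]
        assert emitted == [
            (10.0, "Reminder", "patient1", "patient-speaker"),
            (15.0, "Reminder", "patient1", "patient-speaker"),
            (20.0, "Reminder", "patient1", "patient-speaker"),
            (25.0, "Notification", "caregiver1", "caregiver-smartphone"),
        ]
        assert len(st.detections) == 1

    @pytest.mark.parametrize("seed", range(12))
    def test_random_schedules_match_state_machine_oracle(self, seed):
        rng = np.random.default_rng(seed)
        T = 200
        # random on/off episodes
        schedule = np.zeros(T, dtype=bool)
        t = 0
        while t < T:
            gap = int(rng.integers(1, 30))
            span = int(rng.integers(1, 40))
            schedule[t + gap:t + gap + span] = True
            t += gap + span
        m, rules = tap_world()
        st = TimerState()
        got = []
        for t in range(T):
            set_condition(m, bool(schedule[t]))
            acts, _ = step(m, rules, [TAP_SPEC], st, float(t))
            got += [(a.t, a.kind) for a in acts]
        assert got == ladder_oracle(schedule, T)

    def test_escalation_bound_per_episode(self):
        m, rules = tap_world()
        set_condition(m, True)
        st = TimerState()
        acts = []
        for t in range(0, 300):
            a, _ = step(m, rules, [TAP_SPEC], st, float(t))
            acts += a
        # one long episode: at most maxRepeats reminders + 1 escalation
        assert len(acts) <= TAP_SPEC.policy.max_repeats + 1

    def test_condition_clear_resets_episode(self):
        m, rules = tap_world()
        st = TimerState()
        set_condition(m, True)
        step(m, rules, [TAP_SPEC], st, 0.0)
        assert ("patient1", "tapReminder") in st.episodes
        set_condition(m, False)
        step(m, rules, [TAP_SPEC], st, 5.0)
        assert st.episodes == {}

    def test_personalization_is_isolated(self):
        # disabling the service for patient2 must not change patient1's actions
        def run(enabled_for):
            m, rules = tap_world()
            m.register_entity("patient2", EntityKind.PATIENT)
            spec = ServiceSpec(name="tapReminder", deviance="tapOn", trigger_rule="tap_unattended",
                               guard_s=10.0, policy=ReminderPolicy(3, 5.0), enabled_for=enabled_for)
            set_condition(m, True)
            st = TimerState()
            acts = []
            for t in range(0, 30):
                a, _ = step(m, rules, [spec], st, float(t))
                acts += a
            return [(a.t, a.kind, a.patient) for a in acts]

        assert run(None) == run(frozenset({"patient1"}))


class TestSelectChannel:
    def test_night_reroutes_to_caregiver_smartphone(self):
        m, rules = tap_world(phase="night")
        set_condition(m, True)
        from aalsim.rules import forward_chain

        saturated, _, _ = forward_chain(m, rules)
        draft = Action(0.0, "Reminder", "tapReminder", "patient1", "", "", "", "e")
        routed = select_channel(saturated, draft, "night")
        assert routed.kind == "Notification"
        assert routed.recipient == "caregiver1"
        assert routed.device == "phone1"
        assert routed.mirrored_to == "console"

    def test_daytime_reminder_uses_room_speaker(self):
        m, rules = tap_world()
        draft = Action(0.0, "Reminder", "tapReminder", "patient1", "", "", "", "e")
        routed = select_channel(m, draft, "day")
        assert routed.channel == "patient-speaker" and routed.device == "speaker1"

    def test_missing_device_drops_action_with_health_entry(self):
        m, rules = tap_world()
        m.retract_fact(Triple("patient1", "usesDevice", "speaker1"))
        set_condition(m, True)
        st = TimerState()
        acts = []
        for t in range(0, 12):
            a, _ = step(m, rules, [TAP_SPEC], st, float(t))
            acts += a
        assert acts == []
        assert any(e["event"] == "action-dropped" for e in st.health_log)
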