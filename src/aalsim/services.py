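"""Assistive services: trigger evaluation, reminders, escalation, routing.

Each deployed service watches the reasoning fixpoint for a patient-attributed
deviance condition (``(patient, perform, <deviance>)``), requires it to
persist for a guard duration, then walks a reminder/escalation ladder:

* up to ``max_repeats`` Reminders to the patient (speaker), one per
  ``interval_s``;
* then a single Notification (or, for falls, an immediate Alert) to the
  caregiver in charge, on their smartphone, mirrored to the nursing console.

At night, or when a service has no patient channel at all (wandering — the
co-resident must not be woken), the patient leg is skipped and the caregiver
is notified directly.  When the condition clears, the episode state resets
and nothing further is emitted: the system stays silent when no issue is
present.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .context import ContextModel, EntityKind, Triple
from .rules import RuleSet, forward_chain

__all__ = [
    "ReminderPolicy",
    "ServiceSpec",
    "Action",
    "Episode",
    "TimerState",
    "ServiceError",
    "InvalidThresholdError",
    "ClockRegressionError",
    "NoDeviceError",
    "builtin_service_specs",
    "service_spec_from_dict",
    "step",
    "select_channel",
    "find_device",
]

PATIENT_SPEAKER = "patient-speaker"
CAREGIVER_SMARTPHONE = "caregiver-smartphone"
NURSING_CONSOLE = "nursing-console"
CHANNELS = {PATIENT_SPEAKER, CAREGIVER_SMARTPHONE, NURSING_CONSOLE}


class ServiceError(ValueError):
    pass


class InvalidThresholdError(ServiceError):
    pass


class ClockRegressionError(ServiceError):
    pass


class NoDeviceError(ServiceError):
    """Recipient has no registered device of the required modality."""


@dataclass(frozen=True)
class ReminderPolicy:
    max_repeats: int = 3
    interval_s: float = 30.0

    def __post_init__(self) -> None:
        if self.max_repeats < 0:
            raise InvalidThresholdError("max_repeats must be >= 0")
        if self.interval_s <= 0:
            raise InvalidThresholdError("interval_s must be > 0")


@dataclass(frozen=True)
class ServiceSpec:
    name: str
    deviance: str                     # entity asserted by the trigger rule
    trigger_rule: str                 # rule id whose head asserts perform/<deviance>
    guard_s: float                    # persistence before the service reacts
    policy: ReminderPolicy = ReminderPolicy()
    patient_channel: Optional[str] = PATIENT_SPEAKER
    caregiver_channels: tuple[str, ...] = (CAREGIVER_SMARTPHONE, NURSING_CONSOLE)
    suppress_patient_at_night: bool = True
    escalation_kind: str = "Notification"   # "Alert" for fall detection
    enabled_for: Optional[frozenset[str]] = None  # None = every patient

    def __post_init__(self) -> None:
        if self.guard_s < 0:
            raise InvalidThresholdError(f"{self.name}: guard_s must be >= 0")
        for ch in self.caregiver_channels:
            if ch not in CHANNELS:
                raise ServiceError(f"{self.name}: unknown channel {ch!r}")
        if self.patient_channel is not None and self.patient_channel not in CHANNELS:
            raise ServiceError(f"{self.name}: unknown channel {self.patient_channel!r}")

    def enabled(self, patient: str) -> bool:
        return self.enabled_for is None or patient in self.enabled_for


@dataclass(frozen=True)
class Action:
    t: float
    kind: str                         # Reminder | Notification | Alert
    service: str
    patient: str                      # the patient the episode concerns
    recipient: str                    # who the action addresses
    channel: str
    device: str
    episode_id: str
    mirrored_to: Optional[str] = None
    message: str = ""


@dataclass
class Episode:
    onset: float
    triggered: bool = False
    reminders_sent: int = 0
    last_action_t: Optional[float] = None
    escalated: bool = False

    def to_dict(self) -> dict:
        return {
            "onset": self.onset,
            "triggered": self.triggered,
            "reminders_sent": self.reminders_sent,
            "last_action_t": self.last_action_t,
            "escalated": self.escalated,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Episode":
        return cls(**d)


@dataclass
class TimerState:
    """Per (patient, service) episode clocks plus run-scoped logs."""

    episodes: dict[tuple[str, str], Episode] = field(default_factory=dict)
    last_now: Optional[float] = None
    detections: list[dict] = field(default_factory=list)   # guard-satisfied deviances
    health_log: list[dict] = field(default_factory=list)   # dropped actions etc.

    def cancel_service(self, service: str) -> None:
        for key in [k for k in self.episodes if k[1] == service]:
            del self.episodes[key]

    def to_dict(self) -> dict:
        return {
            "episodes": [[list(k), ep.to_dict()] for k, ep in sorted(self.episodes.items())],
            "last_now": self.last_now,
            "detections": list(self.detections),
            "health_log": list(self.health_log),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TimerState":
        st = cls()
        st.episodes = {tuple(k): Episode.from_dict(ep) for k, ep in d["episodes"]}
        st.last_now = d["last_now"]
        st.detections = list(d["detections"])
        st.health_log = list(d["health_log"])
        return st


# ---------------------------------------------------------------------------
# built-in specs (deployed-service wiring)

_DEFAULTS = {
    "wandering_guard_s": 60.0,
    "shower_guard_s": 900.0,      # 15 min of continuous shower motion + vibration
    "tap_guard_s": 60.0,          # delay after proximity loses the patient
    "fall_stillness_s": 60.0,     # unchanged height before the alert
    "reminder_interval_s": 30.0,
    "max_repeats": 3,
    "patient_interaction": True,  # deployment-phase flag (phases 1-2: caregivers only)
}


def builtin_service_specs(config: Optional[dict] = None) -> list[ServiceSpec]:
    """The four deployed services: wandering at night, showering too long,
    tap left on, toilet fall detection."""
    cfg = dict(_DEFAULTS)
    if config:
        unknown = set(config) - set(_DEFAULTS)
        if unknown:
            raise ServiceError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(config)
    for key in ("wandering_guard_s", "shower_guard_s", "tap_guard_s", "fall_stillness_s", "reminder_interval_s"):
        if cfg[key] <= 0:
            raise InvalidThresholdError(f"{key} must be > 0")
    if cfg["max_repeats"] < 0:
        raise InvalidThresholdError("max_repeats must be >= 0")
    policy = ReminderPolicy(cfg["max_repeats"], cfg["reminder_interval_s"])
    patient_ch = PATIENT_SPEAKER if cfg["patient_interaction"] else None
    return [
        ServiceSpec(
            name="wanderingAlert",
            deviance="wandering",
            trigger_rule="wandering",
            guard_s=cfg["wandering_guard_s"],
            policy=ReminderPolicy(0, cfg["reminder_interval_s"]),
            patient_channel=None,  # no interaction with the intended patient
        ),
        ServiceSpec(
            name="showerTooLong",
            deviance="longShower",
            trigger_rule="shower_running",
            guard_s=cfg["shower_guard_s"],
            policy=policy,
            patient_channel=patient_ch,
        ),
        ServiceSpec(
            name="tapReminder",
            deviance="tapOn",
            trigger_rule="tap_unattended",
            guard_s=cfg["tap_guard_s"],
            policy=policy,
            patient_channel=patient_ch,
        ),
        ServiceSpec(
            name="fallAlert",
            deviance="toiletFall",
            trigger_rule="toilet_fall",
            guard_s=cfg["fall_stillness_s"],
            policy=ReminderPolicy(0, cfg["reminder_interval_s"]),
            patient_channel=None,
            escalation_kind="Alert",
        ),
    ]


def service_spec_from_dict(d: dict) -> ServiceSpec:
    """Load an additional service spec (e.g. *shower without soap*) from a
    parsed configuration mapping."""
    policy = ReminderPolicy(
        int(d.get("max_repeats", _DEFAULTS["max_repeats"])),
        float(d.get("reminder_interval_s", _DEFAULTS["reminder_interval_s"])),
    )
    return ServiceSpec(
        name=d["name"],
        deviance=d["deviance"],
        trigger_rule=d["trigger_rule"],
        guard_s=float(d["guard_s"]),
        policy=policy,
        patient_channel=d.get("patient_channel", PATIENT_SPEAKER),
        suppress_patient_at_night=bool(d.get("suppress_patient_at_night", True)),
        escalation_kind=d.get("escalation_kind", "Notification"),
        enabled_for=frozenset(d["enabled_for"]) if d.get("enabled_for") else None,
    )


# ---------------------------------------------------------------------------
# routing

def find_device(model: ContextModel, owner: str, modality: str) -> str:
    """Device of the given modality registered to ``owner`` (usesDevice +
    hasModality triples); deterministic (sorted) when several exist."""
    hits = sorted(
        b["?d"]
        for b in model.query((owner, "usesDevice", "?d"))
        if model.holds(Triple(b["?d"], "hasModality", modality))
    )
    if not hits:
        raise NoDeviceError(f"{owner} has no {modality} device")
    return hits[0]


def _is_night(model: ContextModel) -> bool:
    return bool(model.query(("?r", "hasPhase", "night")))


def _caregiver_in_charge(model: ContextModel, patient: str) -> str:
    hits = sorted(b["?c"] for b in model.query(("?c", "inChargeOf", patient)))
    if not hits:
        # no inChargeOf derivation (e.g. the patient's location is unknown):
        # any caregiver on duty takes the notification rather than nobody
        hits = sorted(n for n, k in model.entities.items() if k is EntityKind.CAREGIVER)
    if not hits:
        raise NoDeviceError(f"no caregiver available for {patient}")
    return hits[0]


def select_channel(model: ContextModel, action: Action, phase: str) -> Action:
    """Finalize an action's channel and device.

    Patient-directed actions at night are rerouted to the caregiver channel
    (so co-residents are not disturbed); caregiver actions resolve to the
    smartphone of the caregiver in charge, mirrored to the nursing console.
    ``model`` must be the saturated (post-reasoning) model so that
    ``inChargeOf`` facts are visible.
    """
    if action.kind == "Reminder" and phase == "night":
        action = replace(action, kind="Notification")
    if action.kind == "Reminder":
        device = find_device(model, action.patient, "speaker")
        return replace(action, recipient=action.patient, channel=PATIENT_SPEAKER, device=device)
    caregiver = _caregiver_in_charge(model, action.patient)
    device = find_device(model, caregiver, "smartphone")
    mirror = None
    consoles = sorted(b["?d"] for b in model.query(("?d", "hasModality", "console")))
    if consoles:
        mirror = consoles[0]
    return replace(
        action,
        recipient=caregiver,
        channel=CAREGIVER_SMARTPHONE,
        device=device,
        mirrored_to=mirror,
    )


# ---------------------------------------------------------------------------
# the per-cycle step

def step(
    model: ContextModel,
    rules: RuleSet,
    specs: Sequence[ServiceSpec],
    state: TimerState,
    now: float,
) -> tuple[list[Action], TimerState]:
    """Advance every service's timer logic to ``now``.

    ``model`` holds the current base facts (sensor statuses, phase,
    attribution); the fixpoint is recomputed here, never persisted.  Emitted
    actions have their channel and device resolved; undeliverable actions
    are dropped with a health-log entry instead of raising.
    """
    if state.last_now is not None and now < state.last_now:
        raise ClockRegressionError(f"clock went backwards: {now} < {state.last_now}")
    state.last_now = now

    saturated, derived, _ = forward_chain(model, rules)
    phase = "night" if _is_night(model) else "day"

    active: dict[tuple[str, str], ServiceSpec] = {}
    for spec in sorted(specs, key=lambda s: s.name):
        for b in saturated.query(("?u", "perform", spec.deviance)):
            patient = b["?u"]
            if spec.enabled(patient):
                active[(patient, spec.name)] = spec

    # conditions that cleared: reset their episodes
    for key in [k for k in state.episodes if k not in active]:
        del state.episodes[key]

    actions: list[Action] = []
    for key in sorted(active):
        patient, service = key
        spec = active[key]
        ep = state.episodes.get(key)
        if ep is None:
            ep = state.episodes[key] = Episode(onset=now)
        if now < ep.onset + spec.guard_s:  # same float expression as next_deadline
            continue
        if not ep.triggered:
            ep.triggered = True
            state.detections.append(
                {"t": now, "patient": patient, "service": service, "deviance": spec.deviance, "onset": ep.onset}
            )
        episode_id = f"{patient}:{service}:{ep.onset:.0f}"
        patient_leg = (
            spec.patient_channel is not None
            and spec.policy.max_repeats > 0
            and not (phase == "night" and spec.suppress_patient_at_night)
        )
        due = ep.last_action_t is None or now >= ep.last_action_t + spec.policy.interval_s
        draft = None
        if patient_leg and ep.reminders_sent < spec.policy.max_repeats:
            if due:
                draft = Action(now, "Reminder", service, patient, patient, "", "", episode_id)
        elif not ep.escalated and due:
            draft = Action(now, spec.escalation_kind, service, patient, "", "", "", episode_id)
        if draft is None:
            continue
        try:
            final = select_channel(saturated, draft, phase)
        except NoDeviceError as exc:
            state.health_log.append(
                {"t": now, "event": "action-dropped", "service": service, "patient": patient, "reason": str(exc)}
            )
            # count the attempt so the ladder still advances deterministically
            if draft.kind == "Reminder":
                ep.reminders_sent += 1
            else:
                ep.escalated = True
            ep.last_action_t = now
            continue
        if final.kind == "Reminder":
            ep.reminders_sent += 1
        else:
            ep.escalated = True
        ep.last_action_t = now
        actions.append(final)
    return actions, state


def next_deadline(specs: Sequence[ServiceSpec], state: TimerState) -> Optional[float]:
    """Earliest future instant at which some episode needs re-evaluation."""
    by_name = {s.name: s for s in specs}
    deadlines = []
    for (patient, service), ep in state.episodes.items():
        spec = by_name.get(service)
        if spec is None:
            continue
        if ep.escalated:
            continue
        if ep.last_action_t is None:
            deadlines.append(ep.onset + spec.guard_s)
        else:
            deadlines.append(ep.last_action_t + spec.policy.interval_s)
    return min(deadlines) if deadlines else None
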