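"""Runtime component registration: sensors, devices, assistive services.

On the deployed system, discovery ran over DPWS and components lived in an
OSGi container; here discovery is replaced by explicit ``register`` calls
driven by the scenario script, with identical semantics: a newly registered
component's semantic representation is merged into the context model, bound
to its context (location, object, patient), and participates in the very
next reasoning cycle — no restart, no reconstruction of existing state.

The registry tracks exactly which triples each registration added, so
unregistration removes a component's footprint without disturbing triples
that other components still rely on (a sensor may back several services).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .context import EntityKind, Triple
from .rules import parse_ruleset
from .runtime import Platform
from .services import ServiceSpec

__all__ = [
    "ComponentDescriptor",
    "Binding",
    "RegistryError",
    "DuplicateIdError",
    "DanglingBindingError",
    "UnknownIdError",
    "register",
    "unregister",
]

_SENSOR_CONTACT_MODALITIES = {"pressure", "vibration", "ranging"}  # attachedTo their target


class RegistryError(ValueError):
    pass


class DuplicateIdError(RegistryError):
    pass


class DanglingBindingError(RegistryError):
    pass


class UnknownIdError(RegistryError):
    pass


@dataclass(frozen=True)
class ComponentDescriptor:
    """Intrinsic description of a discovered component."""

    id: str
    cls: str                               # sensor | device | service
    modality: Optional[str] = None         # sensor/device modality
    rule_text: Optional[str] = None        # service: its trigger rule(s)
    spec: Optional[ServiceSpec] = None     # service: timing/escalation spec
    deviance: Optional[str] = None         # service: deviance entity it watches

    def __post_init__(self) -> None:
        if self.cls not in ("sensor", "device", "service"):
            raise RegistryError(f"unknown component class {self.cls!r}")
        if self.cls == "service" and (self.spec is None or self.rule_text is None):
            raise RegistryError(f"service {self.id} needs rule_text and spec")
        if self.cls in ("sensor", "device") and not self.modality:
            raise RegistryError(f"{self.cls} {self.id} needs a modality")


@dataclass(frozen=True)
class Binding:
    """Context attachment established through the configuration tool."""

    target: Optional[str] = None           # sensor: object/location it observes
    owner: Optional[str] = None            # device: the patient/caregiver using it
    sensors: tuple[str, ...] = ()          # service: sensors it uses
    devices: tuple[str, ...] = ()          # service: interaction devices it uses


@dataclass
class _Entry:
    descriptor: ComponentDescriptor
    binding: Binding
    added_triples: list[Triple] = field(default_factory=list)
    added_entities: list[str] = field(default_factory=list)
    rule_ids: list[str] = field(default_factory=list)


def _add(platform: Platform, entry: _Entry, t: Triple) -> None:
    refs = platform.triple_refs
    if t in platform.model:
        refs[t] = refs.get(t, 1) + 1
    else:
        platform.model.assert_fact(t)
        refs[t] = refs.get(t, 0) + 1
    entry.added_triples.append(t)


def _require(platform: Platform, name: str) -> None:
    if name not in platform.model.entities:
        raise DanglingBindingError(f"binding target not registered: {name}")


def register(platform: Platform, descriptor: ComponentDescriptor, binding: Binding) -> Platform:
    """Integrate a component at runtime; effective at the next step()."""
    if descriptor.id in platform.registry:
        raise DuplicateIdError(descriptor.id)
    entry = _Entry(descriptor, binding)
    model = platform.model

    if descriptor.cls == "sensor":
        if binding.target is None:
            raise DanglingBindingError(f"sensor {descriptor.id} has no target")
        _require(platform, binding.target)
        if descriptor.id not in model.entities:
            model.register_entity(descriptor.id, EntityKind.SENSOR)
            entry.added_entities.append(descriptor.id)
        pred = "attachedTo" if descriptor.modality in _SENSOR_CONTACT_MODALITIES else "monitors"
        _add(platform, entry, Triple(descriptor.id, pred, binding.target))
        _add(platform, entry, Triple(descriptor.id, "hasStatus", "silent"))

    elif descriptor.cls == "device":
        if descriptor.id not in model.entities:
            model.register_entity(descriptor.id, EntityKind.INTERACTION_DEVICE)
            entry.added_entities.append(descriptor.id)
        _add(platform, entry, Triple(descriptor.id, "hasModality", descriptor.modality))
        if binding.owner is not None:
            _require(platform, binding.owner)
            _add(platform, entry, Triple(binding.owner, "usesDevice", descriptor.id))

    else:  # service
        for s in binding.sensors:
            _require(platform, s)
        for d in binding.devices:
            _require(platform, d)
        if descriptor.id not in model.entities:
            model.register_entity(descriptor.id, EntityKind.ASSISTIVE_SERVICE)
            entry.added_entities.append(descriptor.id)
        deviance = descriptor.deviance or descriptor.spec.deviance
        if deviance not in model.entities:
            model.register_entity(deviance, EntityKind.DEVIANCE)
            entry.added_entities.append(deviance)
        _add(platform, entry, Triple(deviance, "needService", descriptor.id))
        for s in binding.sensors:
            _add(platform, entry, Triple(descriptor.id, "usesSensor", s))
        for d in binding.devices:
            _add(platform, entry, Triple(descriptor.id, "usesDevice", d))
        for rule in parse_ruleset(descriptor.rule_text):
            platform.ruleset.add(rule)
            entry.rule_ids.append(rule.id)
        platform.specs.append(descriptor.spec)

    platform.registry[descriptor.id] = entry
    return platform


def unregister(platform: Platform, component_id: str) -> Platform:
    """Remove a component: its triples, rules, spec and pending timers."""
    entry = platform.registry.get(component_id)
    if entry is None:
        raise UnknownIdError(component_id)
    model = platform.model
    refs = platform.triple_refs

    for t in entry.added_triples:
        refs[t] = refs.get(t, 1) - 1
        if refs[t] <= 0:
            model.retract_fact(t)
            refs.pop(t, None)
    for rid in entry.rule_ids:
        platform.ruleset.remove(rid)
    if entry.descriptor.cls == "service":
        platform.specs = [s for s in platform.specs if s.name != entry.descriptor.spec.name]
        platform.state.cancel_service(entry.descriptor.spec.name)
    if entry.descriptor.cls == "sensor":
        # a pulled sensor leaves no facts behind: anything still mentioning it goes
        model.retract_where(subject=component_id)
        for t in [t for t in model.facts if t.object == component_id]:
            model.retract_fact(t)
    for name in entry.added_entities:
        still_used = any(t.subject == name or t.object == name for t in model.facts)
        if not still_used:
            model.entities.pop(name, None)
    del platform.registry[component_id]
    return platform
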