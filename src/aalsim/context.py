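"""Typed triple store for the smart-room environment ontology.

The context model is the platform's single source of truth about the
environment: a registry of typed entities (patients, caregivers, locations,
sensors, interaction devices, assistive services, activities, deviances,
plain objects) and a set of (subject, predicate, object) facts over a closed
— but configurable — predicate vocabulary.  It is deliberately *not* an RDF
store: no namespaces, no subsumption, no inverse properties.  Rules (see
:mod:`aalsim.rules`) treat it as a plain fact base.

Literals are restricted to strings, numbers and minute-resolution
time-of-day strings (``"HH:MM"``); entity-valued objects must be registered.
"""

from __future__ import annotations

import enum
import re
from typing import Iterable, Iterator, NamedTuple, Union

__all__ = [
    "EntityKind",
    "Triple",
    "ContextModel",
    "ContextError",
    "EntityKindConflictError",
    "UnknownSubjectError",
    "UnknownPredicateError",
    "DEFAULT_VOCABULARY",
    "diff",
    "is_variable",
]

Literal = Union[str, int, float]

#: Relations used by the deployed platform.  The set is closed by default;
#: pass ``extra_vocabulary`` to ContextModel to extend it (plug & play
#: integration adds relations such as usesSensor at runtime).
DEFAULT_VOCABULARY = frozenset(
    {
        "hasStatus",
        "locatedIn",
        "attachedTo",
        "monitors",
        "ownsBed",
        "perform",
        "needService",
        "isInterestedIn",
        "inChargeOf",
        "usesSensor",
        "usesDevice",
        "hasPhase",
    }
)

_TOKEN_RE = re.compile(r"^\S+$")


class ContextError(ValueError):
    """Base class for context-model violations."""


class EntityKindConflictError(ContextError):
    """An identifier is being re-registered with a different kind."""


class UnknownSubjectError(ContextError):
    """A fact's subject (or entity-valued object) is not registered."""


class UnknownPredicateError(ContextError):
    """A fact's predicate is outside the model vocabulary."""


class EntityKind(enum.Enum):
    PATIENT = "Patient"
    CAREGIVER = "Caregiver"
    LOCATION = "Location"
    SENSOR = "Sensor"
    INTERACTION_DEVICE = "InteractionDevice"
    ASSISTIVE_SERVICE = "AssistiveService"
    ACTIVITY = "Activity"
    DEVIANCE = "Deviance"
    OBJECT = "Object"

    @classmethod
    def from_name(cls, name: str) -> "EntityKind":
        for kind in cls:
            if kind.value == name:
                return kind
        raise ContextError(f"unknown entity kind: {name!r}")


class Triple(NamedTuple):
    """One fact: subject and predicate are identifiers, object may be a literal."""

    subject: str
    predicate: str
    object: Literal

    def __str__(self) -> str:  # matches the line-oriented serialization
        return f"{self.subject} {self.predicate} {_format_term(self.object)}"


def is_variable(term: object) -> bool:
    """Pattern terms starting with ``?`` are variables (``?u`` or ``?u:Patient``)."""
    return isinstance(term, str) and term.startswith("?")


def _format_term(obj: Literal) -> str:
    if isinstance(obj, str):
        return obj
    if isinstance(obj, float) and obj == int(obj):
        return str(int(obj))
    return str(obj)


def _parse_literal(text: str) -> Literal:
    try:
        return int(text)
    except ValueError:
        pass
    try:
        return float(text)
    except ValueError:
        pass
    return text


class ContextModel:
    """Entity registry plus fact set with set semantics.

    Mutating methods return ``self`` so call sites can chain them; use
    :meth:`copy` to snapshot a state before an update (e.g. for :func:`diff`).
    """

    def __init__(self, extra_vocabulary: Iterable[str] = ()) -> None:
        self.entities: dict[str, EntityKind] = {}
        self.vocabulary: frozenset[str] = DEFAULT_VOCABULARY | frozenset(extra_vocabulary)
        self._facts: set[Triple] = set()
        self._by_predicate: dict[str, set[Triple]] = {}

    # -- registry ---------------------------------------------------------

    def register_entity(self, name: str, kind: EntityKind) -> "ContextModel":
        if not name or not _TOKEN_RE.match(name):
            raise ContextError(f"invalid identifier: {name!r}")
        existing = self.entities.get(name)
        if existing is not None and existing is not kind:
            raise EntityKindConflictError(
                f"{name} already registered as {existing.value}, not {kind.value}"
            )
        self.entities[name] = kind
        return self

    def kind_of(self, name: str) -> EntityKind | None:
        return self.entities.get(name)

    # -- facts ------------------------------------------------------------

    @property
    def facts(self) -> frozenset[Triple]:
        return frozenset(self._facts)

    def __len__(self) -> int:
        return len(self._facts)

    def __contains__(self, t: Triple) -> bool:
        return t in self._facts

    def assert_fact(self, t: Triple) -> "ContextModel":
        if t.subject not in self.entities:
            raise UnknownSubjectError(f"unregistered subject: {t.subject}")
        if t.predicate not in self.vocabulary:
            raise UnknownPredicateError(f"predicate not in vocabulary: {t.predicate}")
        if isinstance(t.object, str) and is_variable(t.object):
            raise ContextError("facts must be ground (no variables)")
        self._facts.add(t)
        self._by_predicate.setdefault(t.predicate, set()).add(t)
        return self

    def retract_fact(self, t: Triple) -> "ContextModel":
        self._facts.discard(t)
        bucket = self._by_predicate.get(t.predicate)
        if bucket is not None:
            bucket.discard(t)
        return self

    def retract_where(self, subject=None, predicate=None, object=None) -> "ContextModel":
        """Retract every fact matching the given constant fields (None = any)."""
        doomed = [
            t
            for t in (self._by_predicate.get(predicate, self._facts) if predicate else self._facts)
            if (subject is None or t.subject == subject)
            and (predicate is None or t.predicate == predicate)
            and (object is None or t.object == object)
        ]
        for t in doomed:
            self.retract_fact(t)
        return self

    # -- queries ----------------------------------------------------------

    def query(self, pattern: tuple) -> list[dict[str, Literal]]:
        """Bindings under which ``pattern`` is a fact.

        Pattern terms are constants or ``?``-prefixed variables.  An
        all-constant pattern acts as a membership test: it yields ``[{}]``
        when the fact holds and ``[]`` otherwise.  Repeated variables must
        bind consistently.
        """
        s, p, o = pattern
        candidates = self._by_predicate.get(p, set()) if not is_variable(p) else self._facts
        out: list[dict[str, Literal]] = []
        for t in candidates:
            binding: dict[str, Literal] = {}
            if not _bind(s, t.subject, binding):
                continue
            if not _bind(p, t.predicate, binding):
                continue
            if not _bind(o, t.object, binding):
                continue
            out.append(binding)
        return out

    def holds(self, t: Triple) -> bool:
        return t in self._facts

    # -- copy / equality --------------------------------------------------

    def copy(self) -> "ContextModel":
        m = ContextModel()
        m.vocabulary = self.vocabulary
        m.entities = dict(self.entities)
        m._facts = set(self._facts)
        m._by_predicate = {p: set(b) for p, b in self._by_predicate.items()}
        return m

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ContextModel):
            return NotImplemented
        return self.entities == other.entities and self._facts == other._facts

    def __hash__(self):  # pragma: no cover - models are mutable
        raise TypeError("ContextModel is unhashable")

    # -- serialization ----------------------------------------------------

    def to_text(self) -> str:
        lines = [f"@entity {name} {kind.value}" for name, kind in sorted(self.entities.items())]
        lines.extend(str(t) for t in sorted(self._facts, key=lambda t: (t.subject, t.predicate, str(t.object))))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str, extra_vocabulary: Iterable[str] = ()) -> "ContextModel":
        m = cls(extra_vocabulary=extra_vocabulary)
        for lineno, raw in enumerate(text.splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if parts[0] == "@entity":
                if len(parts) != 3:
                    raise ContextError(f"line {lineno}: malformed @entity line")
                m.register_entity(parts[1], EntityKind.from_name(parts[2]))
            else:
                if len(parts) != 3:
                    raise ContextError(f"line {lineno}: expected 'subject predicate object'")
                m.assert_fact(Triple(parts[0], parts[1], _parse_literal(parts[2])))
        return m

    def __iter__(self) -> Iterator[Triple]:
        return iter(self._facts)

    def __repr__(self) -> str:
        return f"<ContextModel {len(self.entities)} entities, {len(self._facts)} facts>"


def _bind(term, value, binding: dict) -> bool:
    if is_variable(term):
        name = term.split(":", 1)[0]
        if name == "?":  # anonymous
            return True
        if name in binding:
            return binding[name] == value
        binding[name] = value
        return True
    return term == value


def diff(before: ContextModel, after: ContextModel) -> tuple[set[Triple], set[Triple]]:
    """Net fact edits turning ``before`` into ``after``: (added, removed)."""
    added = set(after.facts) - set(before.facts)
    removed = set(before.facts) - set(after.facts)
    return added, removed
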