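"""First-order conjunctive rules and forward-chaining fixpoint computation.

Rules are universally quantified Horn clauses over triple patterns, written
in a small text dialect::

    rule svc: (?u:Patient, perform, ?dv:Deviance)
            & (?dv, needService, ?s:AssistiveService)
           => (?u, isInterestedIn, ?s)

Variables are ``?``-prefixed and may carry an entity-kind guard after a
colon (the guard plays the role of a sorted quantifier, e.g. "for all
patients u").  Negation is deliberately absent: conditions such as "patient
not on the bed" are encoded as positive sensor-status facts (``hasStatus
silent``) maintained by the event layer, which keeps the fixpoint monotone
and order-independent.

Derived facts are never persisted across reasoning cycles; every cycle
recomputes the least fixpoint from the current base facts, so sensor status
flips need no truth maintenance.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence, Union

from .context import (
    ContextModel,
    EntityKind,
    Literal,
    Triple,
    UnknownPredicateError,
)

__all__ = [
    "Term",
    "Var",
    "TriplePattern",
    "Rule",
    "RuleSet",
    "RuleError",
    "RuleParseError",
    "RangeRestrictionError",
    "FixpointCapError",
    "NotDerivedError",
    "Derivation",
    "ProofNode",
    "parse_ruleset",
    "print_ruleset",
    "match",
    "forward_chain",
    "explain",
]


class RuleError(ValueError):
    pass


class RuleParseError(RuleError):
    def __init__(self, message: str, lineno: int | None = None):
        self.lineno = lineno
        super().__init__(f"line {lineno}: {message}" if lineno else message)


class RangeRestrictionError(RuleError):
    """A consequent variable does not occur in the antecedents."""


class FixpointCapError(RuleError):
    """Iteration cap exceeded: almost certainly a configuration bug."""


class NotDerivedError(RuleError):
    """explain() was asked about a fact absent from the derivation trace."""


class Var(NamedTuple):
    name: str                       # without the leading '?'
    kind: Optional[EntityKind]      # sort guard, or None

    def __str__(self) -> str:
        return f"?{self.name}:{self.kind.value}" if self.kind else f"?{self.name}"


Term = Union[str, int, float, Var]


class TriplePattern(NamedTuple):
    subject: Term
    predicate: str                  # always a constant
    object: Term

    def __str__(self) -> str:
        return f"({self.subject}, {self.predicate}, {self.object})"


@dataclass(frozen=True)
class Rule:
    id: str
    antecedents: tuple[TriplePattern, ...]
    consequents: tuple[TriplePattern, ...]

    def __post_init__(self) -> None:
        if not self.antecedents:
            raise RuleError(f"rule {self.id}: empty antecedent list")
        bound = {t.name for pat in self.antecedents for t in pat if isinstance(t, Var)}
        for pat in self.consequents:
            for t in pat:
                if isinstance(t, Var) and t.name not in bound:
                    raise RangeRestrictionError(
                        f"rule {self.id}: consequent variable ?{t.name} not bound in antecedents"
                    )


@dataclass
class RuleSet:
    rules: list[Rule] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.rules]
        if len(ids) != len(set(ids)):
            raise RuleError("duplicate rule ids")

    def __iter__(self):
        return iter(self.rules)

    def __len__(self) -> int:
        return len(self.rules)

    def get(self, rule_id: str) -> Rule:
        for r in self.rules:
            if r.id == rule_id:
                return r
        raise KeyError(rule_id)

    def add(self, rule: Rule) -> None:
        if any(r.id == rule.id for r in self.rules):
            raise RuleError(f"duplicate rule id: {rule.id}")
        self.rules.append(rule)

    def remove(self, rule_id: str) -> None:
        self.rules = [r for r in self.rules if r.id != rule_id]

    def copy(self) -> "RuleSet":
        return RuleSet(list(self.rules))


# ---------------------------------------------------------------------------
# parsing / printing

_RULE_RE = re.compile(r"rule\s+(?P<id>[A-Za-z_][\w-]*)\s*:\s*(?P<body>.*?)=>(?P<head>.*?)(?=\brule\s|\Z)", re.S)
_PAT_RE = re.compile(r"\(\s*([^,()]+?)\s*,\s*([^,()]+?)\s*,\s*([^,()]+?)\s*\)")


def _parse_term(text: str) -> Term:
    text = text.strip()
    if text.startswith("?"):
        name, _, kind = text[1:].partition(":")
        if not name:
            raise RuleParseError(f"bad variable {text!r}")
        return Var(name, EntityKind.from_name(kind) if kind else None)
    try:
        return int(text)
    except ValueError:
        pass
    try:
        return float(text)
    except ValueError:
        pass
    return text


def _parse_conjunction(text: str, what: str, lineno: int) -> tuple[TriplePattern, ...]:
    pats = []
    rest = text
    for m in _PAT_RE.finditer(text):
        s, p, o = (_parse_term(x) for x in m.groups())
        if isinstance(p, Var) or not isinstance(p, str):
            raise RuleParseError(f"{what}: predicate must be a constant identifier", lineno)
        pats.append(TriplePattern(s, p, o))
    stripped = _PAT_RE.sub("", text).replace("&", "").strip()
    if stripped:
        raise RuleParseError(f"{what}: unparsed text {stripped!r}", lineno)
    del rest
    return tuple(pats)


def parse_ruleset(text: str) -> RuleSet:
    """Parse the rule dialect; round-trips through :func:`print_ruleset`."""
    # strip comments, keeping line structure for error reporting
    lines = [ln.split("#", 1)[0] for ln in text.splitlines()]
    clean = "\n".join(lines)
    if clean.strip() and not clean.lstrip().startswith("rule"):
        first_bad = next(i + 1 for i, ln in enumerate(lines) if ln.strip())
        raise RuleParseError("expected 'rule <id>: ...'", first_bad)
    rules = []
    consumed_spans = []
    for m in _RULE_RE.finditer(clean):
        lineno = clean.count("\n", 0, m.start()) + 1
        body = _parse_conjunction(m.group("body"), f"rule {m.group('id')} antecedents", lineno)
        head = _parse_conjunction(m.group("head"), f"rule {m.group('id')} consequents", lineno)
        if not body:
            raise RuleParseError(f"rule {m.group('id')}: empty antecedents", lineno)
        if not head:
            raise RuleParseError(f"rule {m.group('id')}: empty consequents", lineno)
        rules.append(Rule(m.group("id"), body, head))
        consumed_spans.append(m.span())
    leftover = clean
    for a, b in reversed(consumed_spans):
        leftover = leftover[:a] + leftover[b:]
    if leftover.strip():
        raise RuleParseError(f"unparsed text: {leftover.strip()[:40]!r}")
    return RuleSet(rules)


def print_ruleset(ruleset: RuleSet) -> str:
    out = []
    for r in ruleset:
        body = " & ".join(str(p) for p in r.antecedents)
        head = " & ".join(str(p) for p in r.consequents)
        out.append(f"rule {r.id}: {body} => {head}")
    return "\n".join(out) + ("\n" if out else "")


# ---------------------------------------------------------------------------
# matching

def _kind_ok(model: ContextModel, var: Var, value) -> bool:
    if var.kind is None:
        return True
    return isinstance(value, str) and model.kind_of(value) is var.kind


def _subst(term: Term, binding: dict) -> Term:
    if isinstance(term, Var):
        return binding.get(term.name, term)
    return term


def match(model: ContextModel, antecedents: Sequence[TriplePattern]) -> list[dict[str, Literal]]:
    """All substitutions making every antecedent a fact of ``model``.

    Patterns are joined left to right; kind guards filter candidate values
    against the entity registry.  Returned bindings map bare variable names
    (no ``?``) to constants.
    """
    bindings: list[dict[str, Literal]] = [{}]
    for pat in antecedents:
        nxt: list[dict[str, Literal]] = []
        for b in bindings:
            s = _subst(pat.subject, b)
            o = _subst(pat.object, b)
            q = (
                s if not isinstance(s, Var) else f"?{s.name}",
                pat.predicate,
                o if not isinstance(o, Var) else f"?{o.name}",
            )
            for delta in model.query(q):
                merged = dict(b)
                ok = True
                for key, val in delta.items():
                    name = key[1:]  # strip '?'
                    merged[name] = val
                # enforce kind guards for any variable of this pattern
                for term in (pat.subject, pat.object):
                    if isinstance(term, Var) and not _kind_ok(model, term, merged.get(term.name)):
                        ok = False
                        break
                if ok:
                    nxt.append(merged)
        bindings = nxt
        if not bindings:
            return []
    # deduplicate (joins can reach the same substitution along several orders)
    seen, out = set(), []
    for b in bindings:
        key = tuple(sorted(b.items()))
        if key not in seen:
            seen.add(key)
            out.append(b)
    return out


# ---------------------------------------------------------------------------
# forward chaining

class Derivation(NamedTuple):
    fact: Triple
    rule_id: str
    bindings: dict
    premises: tuple[Triple, ...]


def _instantiate(pat: TriplePattern, binding: dict) -> Triple:
    s = _subst(pat.subject, binding)
    p = pat.predicate
    o = _subst(pat.object, binding)
    if isinstance(s, Var) or isinstance(o, Var):  # pragma: no cover - range restriction
        raise RuleError("unbound variable at instantiation")
    return Triple(s, p, o)


def forward_chain(
    model: ContextModel, rules: RuleSet
) -> tuple[ContextModel, set[Triple], list[Derivation]]:
    """Least fixpoint of ``rules`` over ``model`` (naive evaluation).

    Returns the saturated model (the input is not mutated), the set of
    newly derived facts, and a trace recording, for each derived fact, the
    first rule application that produced it.  Purely conjunctive rules make
    the fixpoint independent of rule order; the trace content is
    deterministic up to record order.
    """
    for r in rules:
        for pat in list(r.antecedents) + list(r.consequents):
            if pat.predicate not in model.vocabulary:
                raise UnknownPredicateError(
                    f"rule {r.id}: predicate {pat.predicate!r} not in vocabulary"
                )
    work = model.copy()
    derived: set[Triple] = set()
    trace: list[Derivation] = []
    constants = set(work.entities)
    cap = max(1, len(constants)) ** 2 * max(1, len(work.vocabulary))
    changed = True
    while changed:
        changed = False
        for rule in rules:
            for binding in match(work, rule.antecedents):
                premises = tuple(_instantiate(p, binding) for p in rule.antecedents)
                for cpat in rule.consequents:
                    fact = _instantiate(cpat, binding)
                    if fact not in work:
                        work.assert_fact(fact)
                        derived.add(fact)
                        trace.append(Derivation(fact, rule.id, dict(binding), premises))
                        changed = True
                        if len(derived) > cap:
                            raise FixpointCapError(
                                f"derived more than {cap} facts; non-terminating rule configuration?"
                            )
    return work, derived, trace


# ---------------------------------------------------------------------------
# explanation

@dataclass
class ProofNode:
    """Proof tree grounding a derived fact in base facts (leaves)."""

    fact: Triple
    rule_id: Optional[str] = None          # None for base facts
    bindings: dict = field(default_factory=dict)
    premises: list["ProofNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return self.rule_id is None

    def leaves(self) -> list[Triple]:
        if self.is_leaf:
            return [self.fact]
        out = []
        for p in self.premises:
            out.extend(p.leaves())
        return out


def explain(trace: Iterable[Derivation], fact: Triple) -> ProofNode:
    """Proof tree for ``fact``; base facts yield leaf nodes."""
    by_fact = {}
    for d in trace:
        by_fact.setdefault(d.fact, d)

    def build(f: Triple, seen: frozenset) -> ProofNode:
        d = by_fact.get(f)
        if d is None or f in seen:
            return ProofNode(f)
        return ProofNode(
            f,
            d.rule_id,
            dict(d.bindings),
            [build(p, seen | {f}) for p in d.premises],
        )

    if fact not in by_fact:
        # base facts explain themselves as leaves only when they were premises
        # of something; a fact never seen at all is an error.
        for d in by_fact.values():
            if fact in d.premises:
                return ProofNode(fact)
        raise NotDerivedError(f"fact not in derivation trace: {fact}")
    return build(fact, frozenset())
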