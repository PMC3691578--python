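"""Rule dialect parsing, match semantics, forward-chaining fixpoints and
proof-tree explanations, each checked against independent brute-force
oracles on random instances."""

import itertools

import numpy as np
import pytest

from aalsim.context import ContextModel, EntityKind, Triple
from aalsim.rules import (
    RangeRestrictionError,
    Rule,
    RuleParseError,
    RuleSet,
    TriplePattern,
    Var,
    explain,
    forward_chain,
    match,
    parse_ruleset,
    print_ruleset,
)

SVC_RULE = (
    "rule svc: (?u:Patient, perform, ?dv:Deviance)"
    " & (?dv, needService, ?s:AssistiveService)"
    " => (?u, isInterestedIn, ?s)"
)


def svc_model():
    m = ContextModel()
    m.register_entity("patient1", EntityKind.PATIENT)
    m.register_entity("wandering", EntityKind.DEVIANCE)
    m.register_entity("wanderingAlert", EntityKind.ASSISTIVE_SERVICE)
    m.assert_fact(Triple("patient1", "perform", "wandering"))
    m.assert_fact(Triple("wandering", "needService", "wanderingAlert"))
    return m


class TestParsing:
    def test_service_selection_rule(self):
        rs = parse_ruleset(SVC_RULE)
        assert len(rs) == 1
        rule = rs.get("svc")
        assert len(rule.antecedents) == 2
        assert rule.antecedents[0].subject == Var("u", EntityKind.PATIENT)

    def test_empty_text(self):
        assert len(parse_ruleset("")) == 0
        assert len(parse_ruleset("# only comments\n")) == 0

    def test_range_restriction_violation(self):
        with pytest.raises(RangeRestrictionError):
            parse_ruleset("rule bad: (?u, perform, wandering) => (?u, isInterestedIn, ?s)")

    def test_parse_error_has_line_number(self):
        with pytest.raises(RuleParseError):
            parse_ruleset("this is not a rule")

    def test_print_parse_round_trip(self):
        from aalsim.runtime import default_ruleset

        rs = default_ruleset()
        again = parse_ruleset(print_ruleset(rs))
        assert [r.id for r in again] == [r.id for r in rs]
        assert [r.antecedents for r in again] == [r.antecedents for r in rs]
        assert [r.consequents for r in again] == [r.consequents for r in rs]

    def test_duplicate_rule_ids_rejected(self):
        with pytest.raises(Exception):
            parse_ruleset(SVC_RULE + "\n" + SVC_RULE)


class TestMatch:
    def test_service_selection_binding(self):
        rs = parse_ruleset(SVC_RULE)
        got = match(svc_model(), rs.get("svc").antecedents)
        assert got == [{"u": "patient1", "dv": "wandering", "s": "wanderingAlert"}]

    def test_unsatisfiable_body(self):
        m = svc_model()
        pats = (TriplePattern(Var("x", None), "inChargeOf", Var("y", None)),)
        assert match(m, pats) == []

    def test_kind_guard_filters(self):
        m = svc_model()
        m.register_entity("sleeping", EntityKind.ACTIVITY)
        m.assert_fact(Triple("patient1", "perform", "sleeping"))
        pats = (TriplePattern(Var("u", EntityKind.PATIENT), "perform", Var("dv", EntityKind.DEVIANCE)),)
        assert match(m, pats) == [{"u": "patient1", "dv": "wandering"}]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_substitution_oracle(self, seed):
        rng = np.random.default_rng(seed)
        kinds = list(EntityKind)
        m = ContextModel()
        names = [f"c{i}" for i in range(6)]
        for n in names:
            m.register_entity(n, kinds[int(rng.integers(len(kinds)))])
        preds = ["hasStatus", "locatedIn", "perform"]
        for _ in range(int(rng.integers(20, 200))):
            m.assert_fact(Triple(names[int(rng.integers(6))], preds[int(rng.integers(3))], names[int(rng.integers(6))]))
        # random body of <=3 patterns over vars x,y and constants
        vars_ = [Var("x", None), Var("y", None)]
        body = []
        for _ in range(int(rng.integers(1, 4))):
            s = vars_[int(rng.integers(2))] if rng.random() < 0.6 else names[int(rng.integers(6))]
            o = vars_[int(rng.integers(2))] if rng.random() < 0.6 else names[int(rng.integers(6))]
            body.append(TriplePattern(s, preds[int(rng.integers(3))], o))
        got = {tuple(sorted(b.items())) for b in match(m, body)}
        # oracle: cartesian product over the constant pool, filter
        used = {t.name for pat in body for t in (pat.subject, pat.object) if isinstance(t, Var)}
        expected = set()
        for combo in itertools.product(names, repeat=len(used)):
            sub = dict(zip(sorted(used), combo))
            inst = [
                Triple(
                    sub[p.subject.name] if isinstance(p.subject, Var) else p.subject,
                    p.predicate,
                    sub[p.object.name] if isinstance(p.object, Var) else p.object,
                )
                for p in body
            ]
            if all(t in m for t in inst):
                expected.add(tuple(sorted(sub.items())))
        assert got == expected


def naive_fixpoint_oracle(model, rules):
    """Independent fixpoint: brute-force substitution over all constants,
    re-scanned until stable."""
    work = model.copy()
    names = sorted(work.entities)
    changed = True
    while changed:
        changed = False
        for rule in rules:
            used = sorted({t.name for pat in rule.antecedents for t in (pat.subject, pat.object) if isinstance(t, Var)})
            for combo in itertools.product(names, repeat=len(used)):
                sub = dict(zip(used, combo))

                def ground(term):
                    return sub[term.name] if isinstance(term, Var) else term

                ok = True
                for pat in rule.antecedents:
                    for term in (pat.subject, pat.object):
                        if isinstance(term, Var) and term.kind is not None and work.kind_of(sub[term.name]) is not term.kind:
                            ok = False
                    if not ok or Triple(ground(pat.subject), pat.predicate, ground(pat.object)) not in work:
                        ok = False
                        break
                if not ok:
                    continue
                for pat in rule.consequents:
                    t = Triple(ground(pat.subject), pat.predicate, ground(pat.object))
                    if t not in work:
                        work.assert_fact(t)
                        changed = True
    return work


def random_rule_instance(rng, n_rules=5, n_facts=60, n_entities=8):
    kinds = list(EntityKind)
    m = ContextModel()
    names = [f"c{i}" for i in range(n_entities)]
    for n in names:
        m.register_entity(n, kinds[int(rng.integers(len(kinds)))])
    preds = ["hasStatus", "locatedIn", "perform", "monitors", "inChargeOf"]
    for _ in range(n_facts):
        m.assert_fact(Triple(names[int(rng.integers(n_entities))], preds[int(rng.integers(len(preds)))],
                             names[int(rng.integers(n_entities))]))
    rules = []
    for k in range(n_rules):
        vars_ = [Var("x", None), Var("y", None)]
        body = []
        for _ in range(int(rng.integers(1, 3))):
            s = vars_[int(rng.integers(2))] if rng.random() < 0.7 else names[int(rng.integers(n_entities))]
            o = vars_[int(rng.integers(2))] if rng.random() < 0.7 else names[int(rng.integers(n_entities))]
            body.append(TriplePattern(s, preds[int(rng.integers(len(preds)))], o))
        bound = [t for pat in body for t in (pat.subject, pat.object) if isinstance(t, Var)]
        if not bound:
            bound = [names[0]]
        pick = lambda: bound[int(rng.integers(len(bound)))] if bound and rng.random() < 0.8 else names[int(rng.integers(n_entities))]
        head = TriplePattern(pick(), preds[int(rng.integers(len(preds)))], pick())
        rules.append(Rule(f"r{k}", tuple(body), (head,)))
    return m, RuleSet(rules)


class TestForwardChain:
    def test_night_wandering_derivation(self, night_model):
        model, rules = night_model
        _, derived, _ = forward_chain(model, rules)
        for fact in [
            Triple("patient1", "perform", "wandering"),
            Triple("patient2", "perform", "sleeping"),
            Triple("patient1", "isInterestedIn", "wanderingAlert"),
            Triple("caregiver1", "inChargeOf", "patient1"),
        ]:
            assert fact in derived

    def test_empty_ruleset(self, tiny_model):
        m2, derived, trace = forward_chain(tiny_model, RuleSet([]))
        assert derived == set() and m2 == tiny_model and trace == []

    def test_input_model_not_mutated(self, night_model):
        model, rules = night_model
        before = model.copy()
        forward_chain(model, rules)
        assert model == before

    @pytest.mark.parametrize("seed", range(10))
    def test_fixpoint_equals_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m, rules = random_rule_instance(rng)
        got, derived, _ = forward_chain(m, rules)
        expected = naive_fixpoint_oracle(m, rules)
        assert got.facts == expected.facts
        assert derived == set(expected.facts) - set(m.facts)

    @pytest.mark.parametrize("seed", range(4))
    def test_rule_order_invariance(self, seed):
        rng = np.random.default_rng(50 + seed)
        m, rules = random_rule_instance(rng)
        base, _, _ = forward_chain(m, rules)
        perm = list(rules.rules)
        rng.shuffle(perm)
        other, _, _ = forward_chain(m, RuleSet(perm))
        assert base.facts == other.facts

    def test_monotone_derivation(self, night_model):
        # adding facts can only grow the fixpoint
        model, rules = night_model
        full, derived, _ = forward_chain(model, rules)
        smaller = model.copy()
        smaller.retract_fact(Triple("pressureBed2", "hasStatus", "firing"))
        _, derived_small, _ = forward_chain(smaller, rules)
        assert derived_small <= derived | set()  # no fact appears that the larger model lacks
        assert len(derived_small) <= len(derived)


class TestExplain:
    def test_service_selection_proof(self, night_model):
        model, rules = night_model
        _, _, trace = forward_chain(model, rules)
        node = explain(trace, Triple("patient1", "isInterestedIn", "wanderingAlert"))
        assert node.rule_id == "svc"
        premise_facts = {p.fact for p in node.premises}
        assert Triple("wandering", "needService", "wanderingAlert") in premise_facts
        # every leaf of the proof is a base fact
        assert all(leaf in model for leaf in node.leaves())

    def test_base_fact_is_leaf(self, night_model):
        model, rules = night_model
        _, _, trace = forward_chain(model, rules)
        node = explain(trace, Triple("wandering", "needService", "wanderingAlert"))
        assert node.is_leaf

    def test_not_derived_error(self, night_model):
        from aalsim.rules import NotDerivedError

        model, rules = night_model
        _, _, trace = forward_chain(model, rules)
        with pytest.raises(NotDerivedError):
            explain(trace, Triple("patient2", "perform", "wandering"))

    @pytest.mark.parametrize("seed", range(3))
    def test_every_derived_fact_grounds_in_base_facts(self, seed):
        rng = np.random.default_rng(200 + seed)
        m, rules = random_rule_instance(rng)
        _, derived, trace = forward_chain(m, rules)
        for fact in derived:
            node = explain(trace, fact)
            assert all(leaf in m for leaf in node.leaves())
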