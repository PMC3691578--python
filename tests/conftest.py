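"""Shared fixtures: small context models, random-instance generators and a
session-scoped batch of pipeline days (simulated, reasoned, classified) that
several test modules analyse from different angles."""

from __future__ import annotations

import numpy as np
import pytest

from aalsim.context import ContextModel, EntityKind, Triple
from aalsim.runtime import build_platform, run_day
from aalsim.simulate import default_scenario


@pytest.fixture
def night_model():
    from aalsim.runtime import night_wandering_model

    return night_wandering_model()


@pytest.fixture
def tiny_model():
    m = ContextModel()
    m.register_entity("pressureBed1", EntityKind.SENSOR)
    m.register_entity("pirBedroom", EntityKind.SENSOR)
    m.assert_fact(Triple("pressureBed1", "hasStatus", "silent"))
    m.assert_fact(Triple("pirBedroom", "hasStatus", "firing"))
    return m


def random_model(rng: np.random.Generator, n_entities: int = 10, n_facts: int = 100) -> ContextModel:
    kinds = list(EntityKind)
    m = ContextModel()
    names = [f"e{i}" for i in range(n_entities)]
    for name in names:
        m.register_entity(name, kinds[int(rng.integers(len(kinds)))])
    preds = sorted(m.vocabulary)
    for _ in range(n_facts):
        s = names[int(rng.integers(n_entities))]
        p = preds[int(rng.integers(len(preds)))]
        o = names[int(rng.integers(n_entities))]
        m.assert_fact(Triple(s, p, o))
    return m


@pytest.fixture(scope="session")
def pipeline_days():
    """30 fault-free days of the default scenario through the full stack."""
    sc = default_scenario()
    out = []
    for day in range(30):
        timelines, sheets, log = run_day(sc, day, 4000 + day)
        out.append((timelines, sheets, log))
    return sc, out


@pytest.fixture
def scenario():
    return default_scenario()


@pytest.fixture
def platform(scenario):
    return build_platform(scenario)
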