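"""Shared fixtures.

The abstraction pipeline on the bistable switch is the most expensive shared
artifact, so it is built once per session (modest sampling depth) and reused
by the abstraction unit tests; the acceptance tests build their own at the
full sampling depth.
"""

from __future__ import annotations

import numpy as np
import pytest

from crossscale.abstraction import abstract_model
from crossscale.models import ReactionModel
from crossscale.zoo import make_apoptosis_cascade, make_bistable_switch, make_liver_model

GRID = [0.0, 1.0, 1.5, 2.0]


@pytest.fixture(scope="session")
def bistable():
    return make_bistable_switch()


@pytest.fixture(scope="session")
def apoptosis():
    return make_apoptosis_cascade()


@pytest.fixture(scope="session")
def liver():
    return make_liver_model()


@pytest.fixture(scope="session")
def decay_model():
    return ReactionModel(
        "decay", ["x"], [1.0], parameters={"k": 0.5}, rates={"x": "-k * x"}
    )


@pytest.fixture(scope="session")
def bistable_automaton(bistable):
    """Automaton + report from the default pipeline at reduced depth."""
    automaton, report = abstract_model(bistable, "S", GRID, 20, seed=11)
    return automaton, report
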