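"""Shared fixtures.

The session-scoped ``toy_model`` trains one miniature detector that several
behavioural tests share (proposal quality, labelling, negative controls,
checkpoint round-trips), so the expensive training happens once.
"""

from __future__ import annotations

import numpy as np
import pytest

from dcrnet.data import flip
from dcrnet.detector import CellDetector, DetectorConfig
from dcrnet.experiments import desk_schedule, make_fields, train_desk_model
from dcrnet.synth import FieldSpec, generate_field


@pytest.fixture(scope="session")
def toy_fields():
    """Twelve desk-scale training fields plus their horizontal flips."""
    fields = make_fields(12, 500, prefix="toy")
    return fields + [flip(f, "horizontal") for f in fields]


@pytest.fixture(scope="session")
def toy_model(toy_fields):
    """A miniature detector trained long enough to behave sensibly."""
    model, trace = train_desk_model(toy_fields, seed=11, iterations=220)
    assert np.isfinite(trace[-1]["total"])
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
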