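"""Shared fixtures.

The ten-seed default simulation + screen runs are expensive, so they are
built once per session and reused by the classifier-recovery and
diversity-contrast acceptance tests.
"""

from __future__ import annotations

import pytest

from its_screen.screen import screen_clones
from its_screen.simulate import SimParams, make_reference_unit, simulate_clone_set


@pytest.fixture(scope="session")
def unit():
    return make_reference_unit()


@pytest.fixture(scope="session")
def refs(unit):
    return unit.refs


@pytest.fixture(scope="session")
def default_runs(unit):
    """(dataset, evidences) for SimParams defaults over seeds 1..10.

    Clones whose partition could not be projected (a whole region deleted)
    are excluded from screening; they are vanishingly rare under defaults.
    """
    runs = []
    for seed in range(1, 11):
        ds = simulate_clone_set(SimParams(seed=seed), reference=unit)
        delimited = [c for c in ds.clones if c.partition is not None]
        evidences = screen_clones(delimited, unit.refs)
        runs.append((ds, evidences))
    return runs
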