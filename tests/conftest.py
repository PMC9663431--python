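"""Shared fixtures: hand-built micro-sessions and generated rich sessions."""

import numpy as np
import pytest

from numprod import (
    BehaviorParams,
    PopulationSpec,
    Session,
    TrialRecord,
    generate_session,
)


def make_trial(trial_id, target, produced=None, protocol="dot", condition="standard",
               arrangement="standard", outcome=None, pecks=None, rt=None):
    produced = target if produced is None else produced
    if outcome is None:
        if produced == target:
            outcome = "correct"
        elif produced == target + 1:
            outcome = "error_plus"
        else:
            outcome = "error_minus"
    return TrialRecord(
        trial_id=trial_id,
        target_number=target,
        protocol=protocol,
        condition=condition,
        timing_arrangement=arrangement,
        outcome=outcome,
        produced_count=produced,
        peck_times=pecks or [],
        first_response_rt=rt,
    )


def make_session(trials, units=None, session_id="s0", crow_id="c0", metadata=None):
    units = {
        uid: {tid: np.asarray(ts, dtype=float) for tid, ts in by_trial.items()}
        for uid, by_trial in (units or {}).items()
    }
    s = Session(session_id=session_id, crow_id=crow_id, trials=trials, units=units,
                metadata=metadata or {})
    s.validate()
    return s


@pytest.fixture
def tiny_session():
    """One trial, one unit, three spikes."""
    trials = [make_trial(0, 3, pecks=[2000.0, 2600.0, 3300.0], rt=400.0)]
    units = {"u0": {0: [100.0, 850.0, 1200.0]}}
    return make_session(trials, units)


@pytest.fixture(scope="session")
def rich_session():
    """Balanced 600-trial session, 40 units (16 tuned), realistic noise.

    Session-scoped: several modules analyze the same recording.
    """
    spec = PopulationSpec(n_units=40, tuned_fraction=0.4, peak_gain_range=(10, 25), seed=2)
    return generate_session(spec, BehaviorParams(trials_per_cell=30), seed=2)


@pytest.fixture(scope="session")
def rich(rich_session):
    return rich_session[0]


@pytest.fixture(scope="session")
def rich_truth(rich_session):
    return rich_session[1]
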