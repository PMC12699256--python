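import datetime as dt

import pytest

from peerma.simulate import SimulationConfig, noiseless_config, simulate_dyad
from peerma.types import AssessmentRecord, Construct, Role, Trigger

MONDAY = dt.date(2019, 9, 2)


@pytest.fixture(scope="session")
def fixtures():
    from peerma.fixtures import load_fixtures

    return load_fixtures()


@pytest.fixture(scope="session")
def noiseless_dyad():
    """One dyad with a perfect peer channel and full compliance."""
    config = noiseless_config(n_days=84)
    return simulate_dyad(config, dyad_id="1", seed=11)


def record(
    construct=Construct.HOPE,
    timestamp=dt.datetime(2019, 9, 2, 10, 0),
    value=0.5,
    role=Role.PATIENT,
    complete=True,
    trigger=Trigger.APPLICATION,
    confidence=None,
    comment=None,
    dyad_id="1",
):
    return AssessmentRecord(
        dyad_id=dyad_id,
        role=role,
        construct=construct,
        timestamp=timestamp,
        value_raw=value if complete else None,
        trigger=trigger,
        complete=complete,
        confidence=confidence,
        comment=comment,
    )
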