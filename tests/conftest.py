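import numpy as np
import pytest

from nirsgraph.config import Chromophore, Group, RunConfig
from nirsgraph.session import RecordingSession, default_channel_labels
from nirsgraph.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def run_config() -> RunConfig:
    return RunConfig(seed=0)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact planted cohort: 4 subjects per group, 12 channels, one
    6-channel module — enough structure for graph-level assertions."""
    spec = CohortSpec(
        n_per_group={Group.HC: 4, Group.MCI: 4, Group.AD: 4},
        n_channels=12,
        planted_modules=(tuple(range(6)),),
        seed=11,
    )
    sessions, truth = generate_cohort(spec)
    return spec, sessions, truth


@pytest.fixture()
def noise_session() -> RecordingSession:
    rng = np.random.default_rng(42)
    return RecordingSession(
        subject_id="s01",
        group=Group.HC,
        chromophore=Chromophore.HBO,
        data=rng.standard_normal((4, 2033)),
        fs=8.138,
        channel_labels=default_channel_labels(4),
    )
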