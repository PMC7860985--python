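import numpy as np
import pytest

from cytofp.events import EventMatrix, ExperimentSet


def make_em(events, channels=None, sample_id="s1", replicate_id="0",
            transformed=False, **kwargs):
    events = np.asarray(events, dtype=float)
    if channels is None:
        channels = [f"CH{i}" for i in range(events.shape[1])]
    return EventMatrix(
        sample_id=sample_id,
        replicate_id=replicate_id,
        channels=list(channels),
        events=events,
        transformed=transformed,
        **kwargs,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def simple_csv(tmp_path):
    path = tmp_path / "events.csv"
    path.write_text(
        "FSC-H,SSC-H,FL1-H\n"
        "100.0,200.0,300.0\n"
        "110.0,210.0,310.0\n"
        "120.0,220.0,320.0\n"
    )
    return str(path)


@pytest.fixture
def three_sample_set(rng):
    members = [
        make_em(rng.normal(5.0, 1.0, size=(200, 3)),
                channels=["FSC-H", "SSC-H", "FL1-H"],
                sample_id=f"s{i}", transformed=True)
        for i in range(3)
    ]
    return ExperimentSet(members)
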