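import numpy as np
import pytest

from barkbeat.io_events import BarkBout, BarkEvent


def make_bout(onsets, durations=0.1, **meta):
    """Build a bout from onset times; durations scalar or per-event."""
    if np.isscalar(durations):
        durations = [durations] * len(onsets)
    events = tuple(
        BarkEvent(onset=float(o), offset=float(o + d))
        for o, d in zip(onsets, durations)
    )
    return BarkBout(events=events, **meta)


@pytest.fixture
def worked_bout():
    """The hand-checked example: onsets 0, 1, 2.5, 3 (IOIs 1, 1.5, 0.5)."""
    return make_bout([0.0, 1.0, 2.5, 3.0], durations=0.2, bout_id="worked")


@pytest.fixture
def isochronous_bout():
    """10 barks exactly 0.31 s apart, no jitter."""
    return make_bout([i * 0.31 for i in range(10)], durations=0.12,
                     bout_id="iso", age_class="adult")


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
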