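import numpy as np
import pytest

from actipart.streams import ALPHABET, BehaviorStream

#: printed anchors reused across tests: cohort compositional center and the
#: log-triglycerides coefficient (unit direction + magnitude)
GEOMETRIC_MEAN = np.array([0.0564, 0.5472, 0.2794, 0.0364, 0.0801])
TRIG_DIRECTION = np.array([0.2183, 0.3025, 0.1347, 0.2551, 0.0895])
TRIG_NORM = 0.29

PROFILES = {
    "couch potato": np.array([30, 50, 10, 5, 5], float) / 100,
    "office worker": np.array([5, 70, 10, 5, 10], float) / 100,
    "doorman": np.array([5, 15, 70, 5, 5], float) / 100,
    "active": np.array([5, 40, 30, 5, 20], float) / 100,
}


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def make_stream(labels, epoch_length_s=1.0, days=None, subject_id="s0"):
    labels = list(labels)
    if days is None:
        days = [0] * len(labels)
    return BehaviorStream(
        subject_id=subject_id,
        epoch_length_s=epoch_length_s,
        labels=np.array(labels, dtype=object),
        day_index=np.array(days, dtype=int),
    )


def random_stream(rng, n_epochs, epoch_length_s=1.0, n_days=1, p_nonwear=0.1):
    probs = np.full(len(ALPHABET), (1 - p_nonwear) / (len(ALPHABET) - 1))
    probs[-1] = p_nonwear
    labels = rng.choice(ALPHABET, size=n_epochs, p=probs)
    bounds = np.sort(rng.choice(np.arange(1, n_epochs), size=n_days - 1, replace=False)) if n_days > 1 else []
    days = np.zeros(n_epochs, dtype=int)
    for b in bounds:
        days[b:] += 1
    return make_stream(labels, epoch_length_s=epoch_length_s, days=days)
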