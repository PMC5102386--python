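import numpy as np
import pytest

import trithresh as tt


@pytest.fixture(scope="session")
def clinical():
    return tt.make_clinical_fixture()


@pytest.fixture(scope="session")
def model1_summary():
    """100 replicates of n=1000 for the strongest grid model, shared across
    acceptance and property tests."""
    return tt.run_model(tt.get_model(1), reps=100, n=1000, seed=1234)


@pytest.fixture(scope="session")
def model22_summary():
    """100 replicates of n=1000 for a weak balanced model (mu1=1, sd1=1)."""
    return tt.run_model(tt.get_model(22), reps=100, n=1000, seed=1234)


def random_two_class(rng, n=40, ties=False):
    """Small labelled sample with both classes present; optionally tied scores."""
    labels = np.zeros(n, dtype=int)
    labels[: n // 3 + 1] = 1
    rng.shuffle(labels)
    if ties:
        scores = rng.integers(0, n // 3, size=n).astype(float)
    else:
        scores = rng.normal(labels.astype(float), 1.2)
    return tt.LabeledScores(scores, labels)
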