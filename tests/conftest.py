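import numpy as np
import pytest

from mcieeg.preprocess import EpochSet, preprocess_recordings
from mcieeg.simulate import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """Six subjects per class with both class contrasts planted."""
    spec = CohortSpec(
        n_subjects_per_class=6,
        epochs_per_subject=6,
        complexity_effect=0.8,
        coherence_effect=0.8,
        affected_channels=("T5", "O2"),
        seed=42,
    )
    return spec, generate_cohort(spec)


@pytest.fixture(scope="session")
def tiny_epochs(tiny_cohort) -> EpochSet:
    _, recs = tiny_cohort
    return preprocess_recordings(recs)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def logistic_map(r: float, n: int, x0: float = 0.4) -> np.ndarray:
    x = np.empty(n)
    x[0] = x0
    for i in range(1, n):
        x[i] = r * x[i - 1] * (1 - x[i - 1])
    return x
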