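import numpy as np
import pytest

from riskreclass import Cohort


@pytest.fixture
def toy_cohort() -> Cohort:
    """Ten subjects, four events, risks straddling the 0.20 threshold."""
    risks = np.array([0.05, 0.12, 0.15, 0.25, 0.08, 0.11, 0.14, 0.18, 0.22, 0.30])
    outcomes = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
    return Cohort(subject_id=np.arange(10), risk=risks, outcome=outcomes)


def random_small_cohort(rng: np.random.Generator, n_max: int = 12) -> Cohort:
    """Small random cohort with both classes, for brute-force comparisons."""
    n = int(rng.integers(3, n_max + 1))
    risks = rng.random(n) * 0.9 + 0.01
    outcomes = np.zeros(n, dtype=int)
    n_events = int(rng.integers(1, n))
    outcomes[rng.permutation(n)[:n_events]] = 1
    return Cohort(subject_id=np.arange(n), risk=risks, outcome=outcomes)
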