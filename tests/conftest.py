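import numpy as np
import pytest

from icusurv import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """n=300 cohort without embeddings (fast structural tests)."""
    return generate_cohort(CohortConfig(n_subjects=300, include_embeddings=False, seed=42))


@pytest.fixture(scope="session")
def emb_cohort():
    """n=80 cohort with token/image embeddings."""
    return generate_cohort(CohortConfig(n_subjects=80, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def brute_force_c_index(times, events, risks):
    """Independent O(n^2) pair enumeration of the concordance index.

    A pair (j, i) is comparable when subject j has an event strictly before
    subject i's observed time; it scores 1 if j's risk is strictly higher,
    0.5 on a risk tie.
    """
    times = np.asarray(times, float)
    events = np.asarray(events).astype(bool)
    risks = np.asarray(risks, float)
    num = 0.0
    den = 0
    n = len(times)
    for j in range(n):
        if not events[j]:
            continue
        for i in range(n):
            if times[j] < times[i]:
                den += 1
                if risks[j] > risks[i]:
                    num += 1.0
                elif risks[j] == risks[i]:
                    num += 0.5
    if den == 0:
        raise ValueError("no comparable pair")
    return num / den, num, den
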