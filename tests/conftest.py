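import numpy as np
import pytest

import screenval as sv


@pytest.fixture(scope="session")
def default_scale():
    return sv.default_affective_scale()


@pytest.fixture(scope="session")
def small_cohort():
    """Seeded 300-participant cohort with default generator settings."""
    return sv.sample_cohort(sv.default_sim_config(n_participants=300, seed=42))


@pytest.fixture(scope="session")
def medium_cohort():
    """Seeded 5000-participant cohort for distributional checks."""
    return sv.sample_cohort(sv.default_sim_config(n_participants=5000, seed=7))


def brute_force_auc(scores, labels):
    """Independent pairwise oracle: P(pos > neg) + 0.5 P(pos = neg)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))
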