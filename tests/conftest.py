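import numpy as np
import pandas as pd
import pytest

from pancox import SimulationConfig, simulate_cohort


def brute_force_cindex(entry, exit_, status, scores):
    """Definition-level pair enumeration, independent of the package path."""
    entry = np.asarray(entry, float)
    exit_ = np.asarray(exit_, float)
    status = np.asarray(status, int)
    scores = np.asarray(scores, float)
    conc = 0.0
    ncomp = 0
    n = len(exit_)
    for i in range(n):
        if status[i] != 1:
            continue
        for j in range(n):
            if j == i:
                continue
            if entry[j] < exit_[i] < exit_[j]:
                ncomp += 1
                if scores[i] > scores[j]:
                    conc += 1.0
                elif scores[i] == scores[j]:
                    conc += 0.5
    return conc / ncomp, ncomp


def random_survival(rng, n, with_truncation=True, tie_prob=0.3):
    """A small random left-truncated response for property tests."""
    entry = rng.exponential(2.0, n) if with_truncation else np.zeros(n)
    gap = rng.exponential(6.0, n) + 0.1
    exit_ = entry + gap
    if tie_prob > 0:
        ties = rng.uniform(size=n) < tie_prob
        exit_[ties] = np.ceil(exit_[ties])
        exit_ = np.maximum(exit_, entry + 0.1)
    status = (rng.uniform(size=n) < 0.7).astype(int)
    if status.sum() == 0:
        status[0] = 1
    return pd.DataFrame({"entry": entry, "exit": exit_, "status": status})


@pytest.fixture(scope="session")
def signal_cohort():
    """Two-cancer cohort with real shared signal, full linked tables."""
    cfg = SimulationConfig(
        n_cancers=2, cohort_sizes=(220, 160), n_shared_features=3,
        shared_beta=(0.8, -0.6, 0.0), n_specific_features=1,
        specific_beta=((0.5,), (-0.5,)), entry_mean_days=60.0, seed=42)
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
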