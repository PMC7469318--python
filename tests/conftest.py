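import numpy as np
import pytest

from informdrop import (SimConfig, TrialDataset, dataset_from_records,
                        default_schedule, simulate_trial)


@pytest.fixture(scope="session")
def schedule():
    return default_schedule()


@pytest.fixture(scope="session")
def mcar_trial():
    """Small MCAR trial shared by read-only tests."""
    return simulate_trial(SimConfig(n_per_arm=60, mechanism="mcar", seed=42))


@pytest.fixture(scope="session")
def mcar_dataset(mcar_trial):
    return mcar_trial.dataset


def monotone_scores(d, J=8, value=50.0):
    """Scores available at the first d visits only."""
    sc = np.full(J, np.nan)
    sc[:d] = value
    return sc


@pytest.fixture()
def make_monotone_dataset(schedule):
    """Factory: dataset with prescribed dropout-index counts per arm."""

    def _make(counts_by_arm):
        recs = []
        i = 0
        for arm, counts in counts_by_arm.items():
            for d, c in counts.items():
                for _ in range(c):
                    recs.append((f"s{i}", arm, monotone_scores(d)))
                    i += 1
        return dataset_from_records(recs, schedule)

    return _make
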