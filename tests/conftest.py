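import numpy as np
import pytest

from coxsislasso import (SimulationConfig, SurvivalDataset, simulate_dataset,
                         strong_signal_config)


def random_survival(n, p, seed, censor_frac=0.3):
    """Small unstructured censored dataset for oracle tests."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    time = rng.exponential(size=n) + 1e-3
    event = (rng.uniform(size=n) > censor_frac).astype(int)
    event[:2] = 1  # keep the dataset fittable
    return SurvivalDataset(
        X=X, time=time, event=event,
        feature_ids=[f"G{j:03d}" for j in range(p)],
        sample_ids=[f"S{i:03d}" for i in range(n)],
    )


@pytest.fixture(scope="session")
def small_sim():
    """A modest simulated dataset with known sparse truth (n=120, p=30)."""
    return simulate_dataset(strong_signal_config(
        n=120, p=30, n_active=3, censoring=0.2, seed=42))


@pytest.fixture(scope="session")
def null_sim():
    """Pure-noise survival data (no covariate affects the hazard)."""
    return simulate_dataset(SimulationConfig(
        n=150, p=20, support=(), beta_true=(),
        censoring_rate_target=0.2, seed=7))
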