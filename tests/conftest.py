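import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import shootcs as sc

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def tiny_table() -> sc.SampleTable:
    """Three stands, two species, hand-written activities."""
    df = pd.DataFrame(
        {
            "stand": ["A", "A", "A", "B", "B", "C", "C", "C"],
            "species": ["oak", "oak", "cherry", "oak", "cherry", "oak", "oak", "cherry"],
            "origin": [0, 1, 0, 0, 0, 1, 0, 0],
            "activity": [10.0, 20.0, 15.0, 5.0, 8.0, 100.0, 150.0, 80.0],
            "censored": [False] * 8,
        }
    )
    return sc.SampleTable.from_frame(df, provenance="fixture")


@pytest.fixture(scope="session")
def single_species_table() -> sc.SampleTable:
    """A 20-stand, one-species synthetic survey with known truth (no censoring)."""
    cfg = sc.GeneratorConfig(
        n_stands=20,
        per_stand_n=8,
        species_pool={"Quercus serrata": 1.0},
        origin_prob=0.0,
        truth=sc.HyperParams(mu_bar=5.6, sigma_bar=0.74, sigma_M=1.1),
        seed=42,
    )
    table, _ = sc.generate(cfg)
    return table


@pytest.fixture(scope="session")
def quick_mcmc() -> sc.McmcConfig:
    """Short-chain protocol for fast fits in unit tests."""
    return sc.McmcConfig(chains=2, warmup=1500, sampling=3000, seed=7)


def batch_means_mcse(x: np.ndarray, n_batches: int = 20) -> float:
    """Monte Carlo standard error of a chain mean by the batch-means method."""
    x = np.asarray(x, dtype=float)
    size = x.size // n_batches
    means = x[: size * n_batches].reshape(n_batches, size).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_batches))
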