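"""Shared fixtures: small fast datasets for unit tests, the standard
fixed-seed study dataset for end-to-end checks. Everything is generated
programmatically; seed 7 is the suite's fixed seed."""

from __future__ import annotations

import numpy as np
import pytest

import colbci

SUITE_SEED = 7


@pytest.fixture(scope="session")
def small_spec() -> colbci.SyntheticSpec:
    return colbci.SyntheticSpec(
        n_trials=60,
        n_channels=8,
        duration=2.0,
        informative_channels=(1, 4),
        bands=((8.54, 12.71), (18.92, 23.08)),
        seed=SUITE_SEED,
    )


@pytest.fixture(scope="session")
def small_data(small_spec) -> tuple[colbci.EpochsSet, colbci.SyntheticGroundTruth]:
    return colbci.generate_mi_dataset(small_spec)


@pytest.fixture(scope="session")
def small_model(small_data) -> colbci.COLModel:
    epochs, _ = small_data
    return colbci.train_col(epochs)


@pytest.fixture(scope="session")
def mi200() -> tuple[colbci.EpochsSet, colbci.SyntheticGroundTruth]:
    """The standard study dataset: 200 trials, 32 channels, 5 informative."""
    return colbci.generate_mi_dataset(colbci.SyntheticSpec(seed=SUITE_SEED))


@pytest.fixture(scope="session")
def mi200_model(mi200) -> colbci.COLModel:
    epochs, _ = mi200
    return colbci.train_col(epochs)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(SUITE_SEED)


def random_combiner_instance(
    rng: np.random.Generator, n: int = 60, c: int = 12
) -> tuple[np.ndarray, np.ndarray]:
    """A random decision-matrix-like instance: P in (0,1), binary labels."""
    P = rng.random((n, c))
    y = rng.integers(0, 2, n).astype(float)
    if y.min() == y.max():  # force both classes
        y[0] = 1.0 - y[0]
    return P, y
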