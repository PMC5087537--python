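"""Shared fixtures: all test data is generated at test time."""

import numpy as np
import pytest

from footmotion.classify import MOTIONS, train_bank
from footmotion.pipeline import build_dataset
from footmotion.synthetic import simulate_session


@pytest.fixture(scope="session")
def mixed_session():
    """A small labelled session: 3 steps of each motion, misaligned mounting."""
    motions = [m for m in MOTIONS for _ in range(3)]
    return simulate_session(motions, seed=7, misalignment_deg=(12.0, -6.0))


@pytest.fixture(scope="session")
def small_dataset():
    """Feature matrix + labels from three short simulated wearers."""
    X_all, y_all = [], []
    for u, mis in enumerate([(0.0, 0.0), (15.0, 8.0), (-10.0, 5.0)]):
        motions = [m for m in MOTIONS for _ in range(6)]
        ls = simulate_session(motions, seed=100 + u, misalignment_deg=mis)
        X, y = build_dataset(ls)
        X_all.append(X)
        y_all += y
    return np.vstack(X_all), y_all


@pytest.fixture(scope="session")
def trained_bank(small_dataset):
    X, y = small_dataset
    return train_bank(X, y, backend="svm", seed=0)


@pytest.fixture(scope="session")
def benchmark_corpus():
    """The synthetic benchmark: ten simulated wearers, 20 steps per motion
    each (>= 200 windows per motion in total), varied mounting."""
    rng = np.random.default_rng(2016)
    X_all, y_all = [], []
    for u in range(10):
        motions = [m for m in MOTIONS for _ in range(20)]
        mis = tuple(rng.uniform(-20, 20, 2))
        ls = simulate_session(motions, seed=1000 + u, misalignment_deg=mis)
        X, y = build_dataset(ls)
        X_all.append(X)
        y_all += y
    return np.vstack(X_all), y_all
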