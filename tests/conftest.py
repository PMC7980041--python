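"""Shared fixtures: generated datasets and small trained models.

Session-scoped so expensive artifacts (geometry batches, trained readouts)
are built once and reused across test modules.  All fixtures are seeded;
the suite is deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

from perceptgap.classifiers import (GenericConvClassifier, LocalBagClassifier,
                                    records_to_arrays)
from perceptgap.contour_stimuli import generate_dataset


class MetadataOracle:
    """Reference model that reads labels from record metadata (accuracy 1)."""

    classes_ = np.array([0, 1])

    def fit(self, X, y):
        return self

    def fit_records(self, records):
        return self

    def predict_records(self, records):
        return np.array([r.y for r in records])


class ConstantModel:
    """Always predicts class 0 (chance on balanced sets)."""

    classes_ = np.array([0, 1])

    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.zeros(len(X), dtype=int)

    def predict_proba(self, X):
        return np.tile([0.75, 0.25], (len(X), 1))


@pytest.fixture(scope="session")
def geometry_batch():
    """10^4 records per class, geometry only (no rendering)."""
    records, _ = generate_dataset(20_000, 0.5, seed=101, render_images=False)
    return records


@pytest.fixture(scope="session")
def train_records():
    records, _ = generate_dataset(800, 0.5, seed=11)
    return records


@pytest.fixture(scope="session")
def test_records():
    records, _ = generate_dataset(200, 0.5, seed=12)
    return records


@pytest.fixture(scope="session")
def local_model(train_records):
    X, y = records_to_arrays(train_records)
    return LocalBagClassifier(seed=0).fit(X, y)


@pytest.fixture(scope="session")
def generic_model(train_records):
    X, y = records_to_arrays(train_records)
    return GenericConvClassifier(seed=0).fit(X, y)


@pytest.fixture
def oracle_model():
    return MetadataOracle()


@pytest.fixture
def constant_model():
    return ConstantModel()
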