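"""Shared fixtures: the default synthetic study and small reusable inputs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from comodnet import (
    ExpressionMatrix,
    default_mirna_modules,
    generate_design,
    preprocess_pipeline,
    simulate_expression,
)

DEFAULT_SEED = 42


@pytest.fixture(scope="session")
def design():
    return generate_design(7, seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def default_raw(design):
    """Raw replicate-spot intensity matrix of the default synthetic study."""
    return simulate_expression(
        design, default_mirna_modules(), n_features=500, seed=DEFAULT_SEED
    )


@pytest.fixture(scope="session")
def default_log2(default_raw):
    """Preprocessed (normalized, collapsed, log2) default matrix."""
    return preprocess_pipeline(default_raw)


@pytest.fixture(scope="session")
def default_modules(default_log2):
    """Module partition + soft-power report of the default dataset."""
    from comodnet import coexpression_modules

    return coexpression_modules(default_log2)


def make_log2_matrix(values: np.ndarray, sample_ids=None, feature_ids=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    sample_ids = sample_ids or [f"s{i}" for i in range(values.shape[1])]
    feature_ids = feature_ids or [f"f{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=feature_ids, columns=sample_ids), scale="log2"
    )


@pytest.fixture
def rng():
    return np.random.default_rng(DEFAULT_SEED)
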