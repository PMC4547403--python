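"""Shared fixtures: small synthetic cohorts generated at test time."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import mirmark as mm

settings.register_profile(
    "ci", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """A small but well-powered cohort: 30/10 samples, 4 miRNAs x 5 targets."""
    return mm.CohortConfig(
        n_cancer=30,
        n_normal=10,
        n_mirna=4,
        n_gene=30,
        targets_per_mirna=5,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return mm.generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_edges(small_cohort, small_config):
    _, _, _, truth = small_cohort
    return mm.generate_prediction_db(truth, small_config)


@pytest.fixture()
def expr_matrix():
    """A tiny deterministic 3x4 mRNA matrix."""
    values = pd.DataFrame(
        np.array(
            [
                [1.0, 2.0, 3.0, 4.0],
                [4.0, 3.0, 2.0, 1.0],
                [2.0, 2.5, 3.5, 3.0],
            ]
        ),
        index=["G1", "G2", "G3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return mm.ExpressionMatrix(values=values, feature_kind="mRNA", dataset_id="tiny")


@pytest.fixture(scope="session")
def separable_feature():
    """Factory for a single feature whose classes are widely separated."""

    def make(n_cancer=8, n_normal=4, gap=10.0, seed=0):
        rng = np.random.default_rng(seed)
        x = np.concatenate(
            [rng.normal(gap, 1.0, n_cancer), rng.normal(0.0, 1.0, n_normal)]
        )
        y = np.concatenate([np.ones(n_cancer, dtype=int), np.zeros(n_normal, dtype=int)])
        return x, y

    return make
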