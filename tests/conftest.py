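"""Shared fixtures: small synthetic cohorts generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from vocsig import CohortSpec, FeatureTable, extract_feature_table, generate_cohort
from vocsig.features import MFCC_COLUMNS


@pytest.fixture(scope="session")
def meow_cohort():
    """Study-scale meow cohort: 8 individuals x 15 calls, unit variance scales."""
    spec = CohortSpec(
        n_individuals=8,
        calls_per_individual=15,
        call_type="meow",
        sample_rate=16_000.0,
        seed=101,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def meow_features(meow_cohort):
    """Per-call feature table extracted from the session meow cohort."""
    return extract_feature_table(meow_cohort)


@pytest.fixture(scope="session")
def meow_table(meow_features):
    return FeatureTable(meow_features, group_field="individual_id")


@pytest.fixture(scope="session")
def meow_mfcc_table(meow_features):
    return FeatureTable(meow_features, MFCC_COLUMNS, group_field="individual_id")


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
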