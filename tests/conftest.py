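"""Shared fixtures: small synthetic corpora and clean trace profiles."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from ephysqc.feature_extraction import extract_feature_table
from ephysqc.synthetic_traces import GeneratorProfile, generate_dataset


CLEAN_PROFILE = GeneratorProfile(
    noise_sigma=0.0,
    spike_height_cv=0.05,
    spike_width_cv=0.05,
    baseline_wander=0.0,
)


@pytest.fixture
def clean_profile() -> GeneratorProfile:
    """Noiseless, artefact-free profile with near-identical spikes."""
    return CLEAN_PROFILE


def make_clean_profile(**overrides) -> GeneratorProfile:
    return dataclasses.replace(CLEAN_PROFILE, **overrides)


@pytest.fixture(scope="session")
def small_corpus():
    """22-trace labelled corpus (10 good / 7 intermediate / 5 bad)."""
    return generate_dataset(
        {"good": 10, "intermediate": 7, "bad": 5}, seed=42
    )


@pytest.fixture(scope="session")
def small_features(small_corpus):
    traces, labels, _ = small_corpus
    table = extract_feature_table(traces)
    y = labels.codes(table.index)
    return table, np.asarray(y)
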