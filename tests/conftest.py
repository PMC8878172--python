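import numpy as np
import pandas as pd
import pytest

from pathwaydr import (
    FixtureConfig,
    build_multiomics_profiles,
    compute_cellline_features,
    make_gene_sets,
    make_omics_layers,
    make_response_from_model,
)


@pytest.fixture(scope="session")
def fixture_config():
    return FixtureConfig(seed=11)


@pytest.fixture(scope="session")
def gene_sets(fixture_config):
    return make_gene_sets(fixture_config)


@pytest.fixture(scope="session")
def omics_layers(fixture_config, gene_sets):
    return make_omics_layers(fixture_config, gene_sets)


@pytest.fixture(scope="session")
def profiles(omics_layers, gene_sets):
    return build_multiomics_profiles(omics_layers, gene_sets)


@pytest.fixture(scope="session")
def cellline_features(profiles):
    return compute_cellline_features(profiles)


@pytest.fixture(scope="session")
def response_and_truth(fixture_config, cellline_features):
    return make_response_from_model(fixture_config, cellline_features)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def random_profile_frame(rng, n_pathways=6, n_samples=8, prefix="cl"):
    """Helper for tests that need an arbitrary dense activity matrix."""
    data = rng.normal(size=(n_pathways, n_samples))
    return pd.DataFrame(
        data,
        index=[f"pw{i}" for i in range(n_pathways)],
        columns=[f"{prefix}{j}" for j in range(n_samples)],
    )
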