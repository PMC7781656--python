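import numpy as np
import pandas as pd
import pytest

from soiltrace import AbundanceTable, FeatureKind, SyntheticConfig, ValueKind, generate_study


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study reused by pipeline-level tests."""
    return generate_study(SyntheticConfig(seed=7, n_mice_per_group=6))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_relative(values, sample_ids=None, feature_ids=None, kind=FeatureKind.TAXON):
    values = np.asarray(values, dtype=float)
    sample_ids = sample_ids or [f"s{i}" for i in range(values.shape[0])]
    feature_ids = feature_ids or [f"f{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=sample_ids, columns=feature_ids)
    return AbundanceTable(df, kind, ValueKind.RELATIVE)


def make_counts(values, sample_ids=None, feature_ids=None, kind=FeatureKind.TAXON):
    values = np.asarray(values, dtype=float)
    sample_ids = sample_ids or [f"s{i}" for i in range(values.shape[0])]
    feature_ids = feature_ids or [f"f{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=sample_ids, columns=feature_ids)
    return AbundanceTable(df, kind, ValueKind.COUNT)
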