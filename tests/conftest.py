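import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import microcda as m
from microcda.synth import default_diff_features

settings.register_profile(
    "ci", max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_table():
    """3 samples x 4 features with simple integer counts."""
    df = pd.DataFrame(
        [[5, 0, 3, 2], [1, 4, 0, 6], [2, 2, 2, 2]],
        index=["s1", "s2", "s3"],
        columns=["f1", "f2", "f3", "f4"],
    )
    return m.CountTable(df)


@pytest.fixture
def toy_meta():
    return m.SampleMetadata(
        pd.Series({"s1": "A", "s2": "B", "s3": "A"}, name="group")
    )


@pytest.fixture
def four_sample_meta():
    return m.SampleMetadata(
        pd.Series({"s1": "A", "s2": "A", "s3": "B", "s4": "B"}, name="group")
    )


@pytest.fixture(scope="session")
def signal_dataset():
    """40 samples, 120 features, 10 injected effects at 2 SD."""
    spec = m.SyntheticSpec(
        n_per_group=(20, 20), n_features=120, n_genera=12, seed=11,
        delta_sd=2.0,
    )
    spec = dataclasses.replace(
        spec, diff_features=default_diff_features(spec, 10)
    )
    table, tax, meta, truth = m.generate_dataset(spec)
    return spec, table, tax, meta, truth


@pytest.fixture(scope="session")
def null_dataset():
    spec = m.SyntheticSpec(
        n_per_group=(15, 15), n_features=80, n_genera=10, seed=5, delta_sd=0.0
    )
    table, tax, meta, truth = m.generate_dataset(spec)
    return spec, table, tax, meta, truth


@pytest.fixture(scope="session")
def signal_alr(signal_dataset):
    """Filtered, pseudocounted ALR matrix + labels for the signal dataset."""
    _, table, _, meta, truth = signal_dataset
    ps = m.add_pseudocount(m.prevalence_filter(table, meta))
    ref = m.select_alr_reference(ps)
    alr = m.alr_transform(ps, ref)
    y = meta.labels_for(alr.sample_ids)
    return alr, y, meta, truth
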