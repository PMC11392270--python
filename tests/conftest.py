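import numpy as np
import pandas as pd
import pytest

from ehgpreterm.records_io import (
    Dataset,
    DeliveryMode,
    EHGRecord,
    FeatureTable,
    GroupLabel,
    RecordMetadata,
)
from ehgpreterm.synthetic_data import (
    ClassEffectParams,
    SyntheticConfig,
    generate_dataset,
    write_fixture,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_meta(delivery=40.0, recording=31.0, mode=DeliveryMode.SPONTANEOUS):
    return RecordMetadata(
        gestation_at_recording=recording,
        gestation_at_delivery=delivery,
        delivery_mode=mode,
        dataset=Dataset.SYNTHETIC,
        epoch="later",
    )


def make_record(x3, fs=20.0, record_id="rec", **meta_kw):
    """Build a 3-channel record from one array (replicated) or dict."""
    if isinstance(x3, dict):
        signals = {k: np.asarray(v, dtype=float) for k, v in x3.items()}
    else:
        x = np.asarray(x3, dtype=float)
        signals = {"S1": x.copy(), "S2": x.copy(), "S3": x.copy()}
    return EHGRecord(
        record_id=record_id, signals=signals, fs=fs, meta=make_meta(**meta_kw)
    )


def make_table(n_premature, n_term, n_features=3, seed=0, shift=0.0):
    """Gaussian feature table; premature class mean shifted by `shift`."""
    rng = np.random.default_rng(seed)
    n = n_premature + n_term
    X = rng.standard_normal((n, n_features))
    X[:n_premature] += shift
    ids = [f"P{i:03d}" for i in range(n_premature)] + [
        f"T{i:03d}" for i in range(n_term)
    ]
    cols = [f"f{j}" for j in range(n_features)]
    values = pd.DataFrame(X, index=ids, columns=cols)
    labels = pd.Series([1] * n_premature + [0] * n_term, index=ids)
    return FeatureTable(values=values, labels=labels)


@pytest.fixture(scope="session")
def tiny_collection():
    """5 records per group at 120 s: enough for IO and pipeline checks."""
    config = SyntheticConfig(
        group_sizes={g: 5 for g in GroupLabel},
        duration_s=120.0,
        effects=ClassEffectParams(),
        seed=99,
    )
    return generate_dataset(config)


@pytest.fixture(scope="session")
def fixture_tree(tiny_collection, tmp_path_factory):
    directory = tmp_path_factory.mktemp("records")
    write_fixture(tiny_collection, directory)
    return directory
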