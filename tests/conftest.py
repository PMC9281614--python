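import numpy as np
import pytest

import ecgsqa as e


@pytest.fixture(scope="session")
def default_config():
    return e.ScatteringConfig()


@pytest.fixture(scope="session")
def default_bank(default_config):
    return e.build_filter_bank(default_config)


@pytest.fixture(scope="session")
def clean_segment():
    """One 10-s clean synthetic ECG segment at the working rate."""
    rec = e.synth_ecg(duration_s=10.0, fs=250.0, heart_rate_bpm=60.0, seed=42)
    return e.segment(rec, 10.0, 10.0)[0]


@pytest.fixture(scope="session")
def small_trained_model(default_bank, default_config):
    """A quick Bi-LSTM trained on a small synthetic three-grade set."""
    data = e.build_dataset(40, seed=11)
    feats = e.transform_batch([d.segment for d in data], default_bank, default_config)
    cfg = e.ClassifierConfig.desk(
        max_epochs=40, hidden_units=32, batch_size=64, seed=11, standardize=True
    )
    model = e.train(feats, [d.label for d in data], cfg)
    return model
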