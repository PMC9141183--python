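import numpy as np
import pytest

from emofuse.data_model import (
    WindowedDataset,
    slice_windows,
    trim_to_last_seconds,
)
from emofuse.synthetic import SyntheticConfig, generate


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_recordings():
    """2 subjects x 4 trials x 60 s, default 15-channel montage, seed-fixed."""
    cfg = SyntheticConfig(n_subjects=2, n_trials=4, seed=5)
    recs, labels = generate(cfg)
    return recs, labels


@pytest.fixture(scope="session")
def small_windows(small_recordings) -> WindowedDataset:
    recs, _ = small_recordings
    return WindowedDataset.concatenate(
        [slice_windows(trim_to_last_seconds(r, 40.0), 10.0) for r in recs]
    )
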