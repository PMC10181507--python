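import numpy as np
import pytest

import flamingo_ecg as fe


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise-free five-class beats, 20 per class, full-length windows."""
    return fe.generate_dataset(
        fe.SyntheticConfig(n_per_class=20, noise_sd=0.0, seed=0)
    )


@pytest.fixture(scope="session")
def noisy_dataset():
    """Default-noise five-class beats on a short window, 30 per class."""
    return fe.generate_dataset(
        fe.SyntheticConfig(n_per_class=30, window_length=64, noise_sd=0.1, seed=1)
    )


@pytest.fixture(scope="session")
def scaled_small(noisy_dataset):
    """Scaler fitted on the whole small dataset (for model unit tests)."""
    params = fe.fit_scaler(noisy_dataset)
    return fe.apply_scaler(noisy_dataset, params)


@pytest.fixture
def quadratic_objective():
    return fe.ObjectiveSpec(
        evaluate=lambda x: float((x[0] - 0.5) ** 2),
        lower_bounds=[-2.0],
        upper_bounds=[2.0],
    )
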