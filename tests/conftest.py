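import numpy as np
import pytest

import fishcut as fc


@pytest.fixture(scope="session")
def noiseless_config():
    return fc.ScanConfig(gaussian_noise_sd=0.0, impulse_rate=0.0,
                         vibration_amplitude=0.0)


@pytest.fixture(scope="session")
def small_noiseless_dataset(noiseless_config):
    """50 noiseless synthetic fish shared across feature/extraction tests."""
    return fc.generate_dataset(50, noiseless_config, seed=11)


@pytest.fixture(scope="session")
def small_noisy_dataset():
    """60 synthetic fish at default noise for feature/model tests."""
    return fc.generate_dataset(60, fc.ScanConfig(), seed=13)


@pytest.fixture(scope="session")
def small_noisy_scores(small_noisy_dataset):
    """PC scores + head lengths for the small noisy dataset."""
    ds = small_noisy_dataset
    lines = [fc.extract_demarcation_line(fc.preprocess_cloud(c))
             for c in ds.clouds]
    F = fc.build_feature_matrix(lines, p=60)
    pca = fc.pca_fit(F)
    S = fc.pca_transform(pca, F, n_components=3)
    return S, ds.head_lengths


def rel_err(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return np.abs(a - b) / np.maximum(1e-8, np.abs(a) + np.abs(b))
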