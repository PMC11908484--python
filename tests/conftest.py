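"""Shared fixtures: small synthetic datasets generated at test time."""
import numpy as np
import pytest

from pseudosorter import preprocess, simulate


@pytest.fixture(scope="session")
def two_class_set():
    """Small well-separated 2-class waveform dataset with features.

    Seed 8 draws templates with low cross-correlation (~0.2), so the two
    classes are widely separated at SNR ~10.
    """
    cfg = simulate.SimConfig(n_neurons=2, n_spikes=2000, noise_sigma=2.0,
                             target_snr_range=(10.0, 10.5), seed=8)
    wset, truth = simulate.generate_waveform_dataset(cfg)
    wset = preprocess.normalize_and_gradient(wset)
    return wset, truth


@pytest.fixture(scope="session")
def five_class_set():
    """Mid-size 5-class dataset at moderate SNR."""
    cfg = simulate.SimConfig(n_neurons=5, n_spikes=4000, noise_sigma=2.0,
                             target_snr_range=(6.0, 10.0), seed=1)
    wset, truth = simulate.generate_waveform_dataset(cfg)
    wset = preprocess.normalize_and_gradient(wset)
    return wset, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def gaussian_blobs(n_blobs, n_per_blob, sep=20.0, dim=10, seed=0):
    """Well-separated Gaussian blobs in latent-like space."""
    rng = np.random.default_rng(seed)
    centers = rng.normal(0.0, sep, size=(n_blobs, dim))
    pts = np.concatenate([c + rng.normal(0.0, 1.0, size=(n_per_blob, dim))
                          for c in centers])
    labels = np.repeat(np.arange(n_blobs), n_per_blob)
    return pts, labels
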