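import functools

import numpy as np
import pytest

from leafspec import Spectrum, SyntheticConfig, generate_dataset


def make_spectrum(start=350.0, stop=2500.0, step=1.0, value=0.3,
                  kind="reflectance"):
    wl = start + step * np.arange(int(round((stop - start) / step)) + 1)
    vals = np.full_like(wl, float(value))
    return Spectrum(wl, vals, kind)


def random_reflectance(rng, start=350.0, stop=2500.0, step=1.0,
                       lo=0.05, hi=0.9):
    wl = start + step * np.arange(int(round((stop - start) / step)) + 1)
    return Spectrum(wl, rng.uniform(lo, hi, size=wl.shape), "reflectance")


ZERO_NOISE = dict(noise_sd_reflectance=0.0, noise_sd_fluorescence=0.0,
                  pigment_scatter_sd=0.0, ratio_scatter_sd=0.0)


@functools.lru_cache(maxsize=8)
def cached_dataset(**kwargs):
    return generate_dataset(SyntheticConfig(**kwargs))


@pytest.fixture(scope="session")
def small_dataset():
    """60-sample default-config dataset shared across tests."""
    return cached_dataset(n_samples=60, seed=42)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """20 samples with all noise and scatter switched off."""
    return cached_dataset(n_samples=20, seed=7, **ZERO_NOISE)
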