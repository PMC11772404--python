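import numpy as np
import pandas as pd
import pytest

from aquaspec import (SpectraSet, average_replicates, crop_wavelengths,
                      default_cannabis_config, simulate_spectraset)

#: Canonical seed used throughout the suite.
SEED = 0


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)


@pytest.fixture
def small_set(rng):
    """5 samples x 21 wavelengths of smooth random spectra."""
    wl = np.arange(1300, 1342, 2.0)
    base = 0.5 + 0.002 * (wl - 1300)
    X = base + 0.1 * np.exp(-0.5 * ((wl - 1320) / 8) ** 2) \
        + 0.01 * rng.standard_normal((5, wl.size))
    meta = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(5)],
        "chemovar": ["a", "a", "b", "b", "b"],
        "major_class": ["high_THCA"] * 2 + ["high_CBDA"] * 3,
        "replicate_index": [1, 2, 1, 2, 3],
    })
    return SpectraSet(wl, X, meta)


@pytest.fixture(scope="session")
def default_sim():
    """Default 7-chemovar simulated study (spectra, composition, truth)."""
    return simulate_spectraset(default_cannabis_config(seed=SEED))


@pytest.fixture(scope="session")
def default_spectra(default_sim):
    """Replicate-averaged, cropped spectra of the default design."""
    s, _, _ = default_sim
    return crop_wavelengths(average_replicates(s), 1300, 1600)
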