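import numpy as np
import pandas as pd
import pytest

from lolichemo import SpectraSet, default_study_config, generate


@pytest.fixture(scope="session")
def small_dataset():
    """A 40-sample replicate-level synthetic dataset (fixed seed)."""
    spectra, truth = generate(default_study_config(seed=42, n_samples=40))
    return spectra, truth


@pytest.fixture
def tiny_set():
    """A deterministic 6-sample, 12-point set with a known linear structure."""
    rng = np.random.default_rng(7)
    wl = 1100.0 + 2.0 * np.arange(12)
    matrix = 0.4 + 0.001 * rng.standard_normal((6, 12))
    matrix += np.outer(np.linspace(0, 1, 6), np.exp(-0.5 * ((wl - 1110) / 4.0) ** 2))
    meta = pd.DataFrame(
        {"sample_id": [f"t{i}" for i in range(6)], "conc": np.linspace(10, 60, 6)}
    )
    return SpectraSet(wavelengths=wl, matrix=matrix, meta=meta)
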