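import numpy as np
import pytest

from ramanlda import (
    SyntheticConfig,
    canonical_fingerprint_grid,
    generate_dataset,
)
from ramanlda.synthetic_data import BaselineConfig


@pytest.fixture(scope="session")
def grid():
    return canonical_fingerprint_grid()


@pytest.fixture(scope="session")
def noise_free_set():
    """Deterministic templates-only dataset: 600 spectra, no nuisance terms."""
    sset, truth = generate_dataset(SyntheticConfig.noise_free(seed=1))
    return sset, truth


@pytest.fixture(scope="session")
def default_set_seed42():
    """Calibrated default study design at seed 42 (noise, baselines, outliers)."""
    sset, truth = generate_dataset(SyntheticConfig(seed=42))
    return sset, truth


def small_config(seed: int, **overrides) -> SyntheticConfig:
    """A scaled-down study design for fast end-to-end tests."""
    kwargs = dict(
        n_samples_per_entity=3,
        n_spectra_per_sample=5,
        seed=seed,
        baseline=BaselineConfig(),
        contamination=None,
    )
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)


def index_of(grid, wavenumber: float) -> int:
    return int(np.argmin(np.abs(grid.values - wavenumber)))
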