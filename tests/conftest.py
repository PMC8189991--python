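import numpy as np
import pytest

from protir.spectral_model import WavenumberGrid, default_library
from protir.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def fine_grid():
    """0.5 cm-1 grid over a range wide enough for every library band."""
    return WavenumberGrid.regular(1440.0, 1760.0, 0.5)


@pytest.fixture(scope="session")
def window_grid():
    """The 4 cm-1 analysis grid, 1480-1720 cm-1."""
    return WavenumberGrid.regular(1480.0, 1720.0, 4.0)


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def small_dataset():
    """24-protein noiseless synthetic study (shared; treat as read-only)."""
    cfg = GeneratorConfig(n_proteins=24, seed=7, noise_sigma=0.0,
                          drift_amplitude=0.0, normalize=False)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def noisy_dataset():
    """48-protein study with default noise/drift, preprocessed."""
    cfg = GeneratorConfig(n_proteins=48, seed=11)
    return generate_dataset(cfg)
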