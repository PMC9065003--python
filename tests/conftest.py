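import numpy as np
import pytest

from ramansalt.spectio import Spectrum, SpectrumSet
from ramansalt.synthgen import SynthConfig, generate_dataset


@pytest.fixture
def toy_spectrum() -> Spectrum:
    shift = np.linspace(400.0, 500.0, 101)
    intensity = 10.0 + 0.05 * shift + 5.0 * np.exp(-0.5 * ((shift - 450.0) / 4.0) ** 2)
    return Spectrum(shift, intensity, "toy")


@pytest.fixture
def toy_set() -> SpectrumSet:
    shift = np.array([400.0, 401.0, 402.0, 403.0])
    intensities = np.array([[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0], [2.0, 5.0, 2.0, 5.0]])
    return SpectrumSet(shift, intensities, ("a", "b", "c"))


@pytest.fixture(scope="session")
def small_synth():
    """Small but fully structured synthetic dataset (2 weeks x 4 conc x 10)."""
    cfg = SynthConfig(weeks=(2, 3), n_per_group=10, seed=42)
    sset, truth = generate_dataset(cfg)
    return cfg, sset, truth


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
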