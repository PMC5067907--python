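import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from eemkit import fixtures as fx

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_dataset():
    """30 noiseless molecules over 4 single-bond atom types (H1 C1 N1 O1),
    reference charges generated by the ground-truth set itself."""
    config = fx.FixtureConfig(n_molecules=30, seed=11)
    molecules, charges, truth = fx.make_dataset(config)
    return molecules, charges, truth


@pytest.fixture(scope="session")
def noisy_hetero_dataset():
    """40 molecules over 8 atom types with sigma=0.05 e Gaussian noise on
    the reference charges: the heterogeneous, imperfect-data regime."""
    config = fx.FixtureConfig(
        n_molecules=40,
        atoms_min=5,
        atoms_max=12,
        palette=dict(fx.PALETTE_ORGANIC),
        noise_sigma=0.05,
        seed=21,
    )
    molecules, charges, truth = fx.make_dataset(config)
    return molecules, charges, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
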