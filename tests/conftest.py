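import numpy as np
import pytest

from flairseg.phantom import PhantomSpec, generate_phantom
from flairseg.pipeline import run_synthetic_experiment


@pytest.fixture(scope="session")
def e2e_result():
    """The reference synthetic segmentation experiment, run once per session.

    20 phantoms (64x64x24, 1-2 lesions, mild bias, low noise), 5000 training
    tiles, 30 epochs, 5 held-out test cases. Shared by the end-to-end
    acceptance check and the training-dynamics tests.
    """
    return run_synthetic_experiment(seed=7)


@pytest.fixture()
def clean_phantom():
    """Noise-free, bias-free single-lesion phantom with its exact mask."""
    spec = PhantomSpec(n_lesions=1, noise_sd=0.0, bias_amplitude=1.0, seed=42)
    return generate_phantom(spec)


@pytest.fixture()
def noisy_phantom():
    """Default-condition phantom (noise SD 4, bias amplitude 1.2)."""
    spec = PhantomSpec(seed=13)
    return generate_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
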