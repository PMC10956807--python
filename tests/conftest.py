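import numpy as np
import pytest

from dermafusion.synthetic import LesionSpec, generate_lesion_image


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240321)


@pytest.fixture(scope="session")
def clean_lesion():
    """Noise-free elliptical lesion with ground truth, 128x128."""
    spec = LesionSpec(
        center=(64.0, 64.0),
        axes=(38.0, 30.0),
        lesion_color=(80, 50, 40),
        noise_sigma=0.0,
    )
    image, mask = generate_lesion_image(spec, (128, 128), seed=11)
    return image, mask, spec


@pytest.fixture(scope="session")
def noisy_lesion():
    """Same lesion geometry at noise sigma=10 (8-bit units)."""
    spec = LesionSpec(
        center=(64.0, 64.0),
        axes=(38.0, 30.0),
        lesion_color=(80, 50, 40),
        noise_sigma=10.0,
    )
    image, mask = generate_lesion_image(spec, (128, 128), seed=12)
    return image, mask, spec
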