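import numpy as np
import pytest

from busfusion.phantoms import PhantomParams, generate_phantom


@pytest.fixture(scope="session")
def benign_case():
    return generate_phantom(
        PhantomParams(label="benign", tumor_diameter_mm=10, seed=7)
    )


@pytest.fixture(scope="session")
def malignant_case():
    return generate_phantom(
        PhantomParams(label="malignant", tumor_diameter_mm=15, seed=3)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
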