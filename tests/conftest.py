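import numpy as np
import pytest

from petmrvol.phantom import (
    DwiPhantomSpec,
    PetPhantomSpec,
    generate_dwi_phantom,
    generate_pet_phantom,
)


@pytest.fixture(scope="session")
def pet_phantom():
    """Default noiseless Gaussian PET phantom: (volume, voi, analytic curve)."""
    return generate_pet_phantom(PetPhantomSpec(), 0)


@pytest.fixture(scope="session")
def dwi_phantom_noiseless():
    return generate_dwi_phantom(DwiPhantomSpec(), 0)


@pytest.fixture(scope="session")
def dwi_phantom_snr30():
    spec = DwiPhantomSpec(rician_sigma=450.0 / 30.0)
    return generate_dwi_phantom(spec, 1)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    return 2.0 * np.count_nonzero(a & b) / (np.count_nonzero(a) + np.count_nonzero(b))
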