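import numpy as np
import pytest

from sinoseg.phantoms import LesionSpec, add_lesion, generate_phantom


@pytest.fixture()
def phantom128():
    return generate_phantom(128, "mammography", rng_seed=7)


@pytest.fixture()
def lesion_sample():
    """128px mammography phantom with one centered circular lesion."""
    sample = generate_phantom(128, "mammography", rng_seed=7)
    spec = LesionSpec(
        center_yx=(64.0, 60.0), semi_axes=(7.0, 7.0), contrast=0.35
    )
    return add_lesion(sample, spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
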