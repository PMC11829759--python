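import numpy as np
import pytest

from tailbud.synthetic import EmbryoPhantomSpec, generate_nuclear_stack


@pytest.fixture(scope="session")
def separated_phantom():
    """Noiseless 50-nucleus phantom with well-separated (non-touching) nuclei."""
    spec = EmbryoPhantomSpec(
        n_nuclei=50,
        shape_voxels=(40, 120, 120),
        min_separation_factor=1.4,
        noise_sd=0.0,
        seed=11,
    )
    stack, labels, truth = generate_nuclear_stack(spec)
    return spec, stack, labels, truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)
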