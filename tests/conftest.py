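import numpy as np
import pytest

from scintiseg.data_io import split_by_patient
from scintiseg.phantom import PhantomConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_phantom_config():
    """32-px phantoms with radii scaled to the frame; fast enough for CI."""
    return PhantomConfig(image_size=32, n_patients=4, lesions_per_image=(1, 3),
                         small_radius_px=(1.0, 2.0), large_radius_px=(2.5, 5.0),
                         n_confounders=(0, 2), seed=7)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_phantom_config, tmp_path_factory):
    """A written-out 4-patient dataset with a 3:1 patient split."""
    out = tmp_path_factory.mktemp("phantom_data")
    manifest = generate_dataset(tiny_phantom_config, out)
    return split_by_patient(manifest, 0.75, seed=0)
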