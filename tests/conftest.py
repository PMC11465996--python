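import numpy as np
import pytest

from pamoct import phantom, reconstruct


@pytest.fixture(scope="session")
def fundus_scene():
    """Canonical noise-relevant two-layer scene shared by slow tests."""
    return phantom.build_fundus_scene(seed=0, with_choroid=True)


@pytest.fixture(scope="session")
def retinal_scene():
    return phantom.build_fundus_scene(seed=0, with_choroid=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def clean_enface(scene, modality="pam1064", t=0.0, seed=0):
    """Noise-free normalized en face image of a scene."""
    acq = phantom.AcquisitionConfig(noise_sigma_pam=0.0, seed=seed)
    vol = phantom.simulate_volume(scene, acq, modality, t)
    return reconstruct.normalize(reconstruct.enface(vol))
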