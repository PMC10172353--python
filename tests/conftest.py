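import numpy as np
import pytest

from clonepipe.io import ImageStack


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_stack(voxels, voxel_size=(1.0, 1.0), roles=None, image_id="test"):
    roles = roles if roles is not None else {"genotype_1": 0}
    return ImageStack(voxels=voxels, voxel_size=voxel_size, channel_roles=roles, image_id=image_id)


@pytest.fixture
def tiny_stack():
    """4-plane, 2-channel, 64x64 deterministic integer stack."""
    rng = np.random.default_rng(7)
    vox = rng.integers(0, 255, size=(4, 64, 64, 2), dtype=np.uint8)
    return make_stack(vox, roles={"genotype_1": 0, "nuclear": 1}, image_id="tiny")


def random_blob(rng, shape=(4, 48, 48), n_seeds=3, dilations=6):
    """A random connected-ish 3D blob for partition property tests."""
    from scipy import ndimage as ndi

    vol = np.zeros(shape, dtype=bool)
    for _ in range(n_seeds):
        z = rng.integers(0, shape[0])
        r = rng.integers(8, shape[1] - 8)
        c = rng.integers(8, shape[2] - 8)
        vol[z, r, c] = True
    structure = np.zeros((3, 3, 3), dtype=bool)
    structure[1] = True
    structure[0, 1, 1] = structure[2, 1, 1] = True
    return ndi.binary_dilation(vol, structure=structure, iterations=int(dilations))
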