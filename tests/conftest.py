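import numpy as np
import pytest

from ccbarrel.synthetic import BundleParams, build_bundle


@pytest.fixture
def parallel_hexamer():
    """Noiseless all-parallel hexamer, zero offsets."""
    return build_bundle(BundleParams())


@pytest.fixture
def antiparallel_hexamer():
    """Noiseless antiparallel-alternating hexamer with a 5.6 A Z-shift."""
    params = BundleParams(
        orientation=(1, -1, 1, -1, 1, -1),
        axial_offsets=(2.8, -2.8, 2.8, -2.8, 2.8, -2.8),
    )
    return build_bundle(params)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_rotation(rng):
    """Uniform random rotation matrix."""
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()


def rigid_transform_model(model, R, t):
    """Apply a rigid transform to every chain of an AssemblyModel."""
    from dataclasses import replace

    chains = [(cid, ctype, xyz @ R.T + t) for cid, ctype, xyz in model.chains]
    return replace(model, chains=chains)
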