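import numpy as np
import pytest

from qmrisim import ProtocolParams
from qmrisim.phantoms import Phantom


@pytest.fixture
def single_voxel_phantom():
    """3x3 phantom with one center voxel -> isochromat exactly at r=0."""

    def make(t1=0.5, t2=0.1, pd=1.0, fov=0.25):
        pd_map = np.zeros((3, 3))
        pd_map[1, 1] = pd
        return Phantom(
            pd_map=pd_map,
            t1_map=np.full((3, 3), t1),
            t2_map=np.full((3, 3), t2),
            fov=fov,
        )

    return make


@pytest.fixture
def se_params():
    """Plain spin-echo (etl=1 TSE) protocol parameters for small matrices."""

    def make(n=16, tr=3.0, te=0.008):
        return ProtocolParams(
            name="se_test",
            kind="tse",
            matrix_n=n,
            n_slices=1,
            tr=tr,
            te=te,
            etl=1,
            center_echo=1,
        )

    return make
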