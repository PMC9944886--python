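import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from moadshape.fixtures import make_toy_ligand
from moadshape.gaussian_shape import build_shape
from moadshape.transforms import RigidTransform


@pytest.fixture
def ring6():
    return make_toy_ligand("ring", 6, ligand_id="ring6")


@pytest.fixture
def ring6_shape(ring6):
    return build_shape(ring6.conformers[0])


@pytest.fixture
def tetra_shape():
    return build_shape(make_toy_ligand("tetrahedral", 5).conformers[0])


@pytest.fixture
def chain4_shape():
    return build_shape(make_toy_ligand("linear", 4).conformers[0])


def random_transform(seed: int, max_translation: float = 4.0) -> RigidTransform:
    rng = np.random.default_rng(seed)
    quat = rng.normal(size=4)
    return RigidTransform.from_rotation(
        Rotation.from_quat(quat / np.linalg.norm(quat)),
        rng.uniform(-max_translation, max_translation, size=3),
    )
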