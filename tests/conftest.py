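import numpy as np
import pytest

from emnmr.model import build_backbone
from emnmr.synthetic import make_benchmark


IDEAL_HELIX_DIHEDRALS = (-57.0, -47.0)


@pytest.fixture(scope="session")
def helix21():
    """Ideal 21-residue α-helix."""
    return build_backbone("A" * 21, [IDEAL_HELIX_DIHEDRALS] * 21)


@pytest.fixture(scope="session")
def mono3_case():
    return make_benchmark("mono3", seed=1)


@pytest.fixture(scope="session")
def mono5_case():
    return make_benchmark("mono5", seed=1)


@pytest.fixture(scope="session")
def c3_case():
    return make_benchmark("c3", seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def fitted_helix_axis(ca: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares axis through CA atoms: (center, unit axis, axial extent)."""
    c = ca.mean(axis=0)
    _, _, vt = np.linalg.svd(ca - c)
    axis = vt[0]
    proj = (ca - c) @ axis
    return c, axis, float(proj.max() - proj.min())
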