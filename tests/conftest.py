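import numpy as np
import pytest

from sealerdelta.phantom import PhantomSpec, make_baseline, make_followup
from sealerdelta.transforms import RigidTransform


@pytest.fixture(scope="session")
def coarse_spec():
    """Coarse-mesh phantom used by most geometry tests (fast, ~4k faces)."""
    return PhantomSpec(seed=42, mesh_edge_length=0.3)


@pytest.fixture(scope="session")
def coarse_baseline(coarse_spec):
    return make_baseline(coarse_spec)


@pytest.fixture(scope="session")
def identity_spec():
    """Noise-free phantom at identity placement, for exact-geometry checks."""
    return PhantomSpec(seed=7, mesh_edge_length=0.3, surface_noise_sd=0.0,
                       session_transform=RigidTransform.identity())


@pytest.fixture(scope="session")
def identity_baseline(identity_spec):
    return make_baseline(identity_spec)


@pytest.fixture(scope="session")
def shrink_pair(coarse_baseline):
    """Baseline plus a 30% volume-loss follow-up (noisy, random placements)."""
    followup = make_followup(coarse_baseline, -0.3, time_label="3m", time_index=1)
    return coarse_baseline, followup


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR-based)."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
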