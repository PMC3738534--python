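"""Shared fixtures: ideal quadruplex specs and independent geometry oracles."""

import numpy as np
import pytest

from g4dyn.synthetic_data import LoopBaseSpec, Pose, SyntheticSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def stem_spec():
    """Three-layer stem, no loops, single frame."""
    return SyntheticSpec(n_layers=3, n_frames=1, seed=1)


@pytest.fixture
def looped_spec():
    """Three-layer stem with one adenine stacked on the top layer."""
    return SyntheticSpec(
        n_layers=3,
        loop_bases=(LoopBaseSpec("A", Pose(d_z=3.4, tilt=20.0, offset=1.0),
                                 attach_layer=3),),
        n_frames=1, seed=1)


def random_rotation(rng):
    """Uniform-ish random proper rotation from a normalized quaternion."""
    from scipy.spatial.transform import Rotation
    q = rng.normal(size=4)
    return Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()


def random_unit(rng):
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def kabsch_oracle(mobile, target):
    """Independent brute-force rigid superposition (SVD Kabsch with proper-
    rotation sign correction).  Returns (R, t, rmsd) mapping mobile onto
    target."""
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    H = (mobile - mc).T @ (target - tc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    moved = (mobile - mc) @ R.T + tc
    rmsd = np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1)))
    t = tc - R @ mc
    return R, t, float(rmsd)


def svd_plane_normal(coords):
    """Best-fit plane normal of a point cloud, oriented into the +Z hemisphere."""
    c = coords - coords.mean(axis=0)
    _, _, Vt = np.linalg.svd(c)
    n = Vt[2]
    return n if n[2] >= 0 else -n
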