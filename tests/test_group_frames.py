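"""Axis association: Rodrigues properties, bisectors, quartet/pair frames."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from g4dyn.base_frames import fit_base_frame
from g4dyn.group_frames import (DegenerateAxisError, associate_axes,
                                axis_angle, pair_frame, quartet_frame,
                                rodrigues_matrix)
from g4dyn.reference_bases import get_standard_base
from g4dyn.synthetic_data import build_quartet
from conftest import random_rotation, random_unit, svd_plane_normal


def _angle_deg(a, b):
    return np.degrees(np.arccos(np.clip(abs(np.dot(a, b)), -1, 1)))


def _quartet_frames(bases):
    std = get_standard_base("G")
    return [fit_base_frame(dict(zip(b.atom_names, b.coords)), std) for b in bases]


class TestRodrigues:
    def test_matrix_properties_random_draws(self, rng):
        for _ in range(1000):
            axis = random_unit(rng)
            angle = rng.uniform(-np.pi, np.pi)
            R = rodrigues_matrix(axis, angle)
            assert np.allclose(R @ R.T, np.eye(3), atol=1e-9)
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
            assert np.allclose(R @ axis, axis, atol=1e-9)

    def test_agrees_with_quaternion_oracle(self, rng):
        for _ in range(100):
            axis = random_unit(rng)
            angle = rng.uniform(-np.pi, np.pi)
            expected = Rotation.from_rotvec(axis * angle).as_matrix()
            assert np.allclose(rodrigues_matrix(axis, angle), expected, atol=1e-12)


_component = st.floats(min_value=-1.0, max_value=1.0,
                       allow_nan=False, allow_infinity=False)
_vector = st.tuples(_component, _component, _component).filter(
    lambda v: np.linalg.norm(v) > 1e-3)


@settings(derandomize=True, max_examples=200)
@given(v1=_vector, v2=_vector, angle=st.floats(-np.pi, np.pi))
def test_association_properties_hypothesis(v1, v2, angle):
    """For arbitrary non-degenerate directions: Rodrigues matrices are
    proper rotations fixing their axis, and the association is a bisector."""
    z1 = np.array(v1) / np.linalg.norm(v1)
    z2 = np.array(v2) / np.linalg.norm(v2)
    R = rodrigues_matrix(z1, angle)
    assert np.allclose(R @ R.T, np.eye(3), atol=1e-9)
    assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
    assert np.allclose(R @ z1, z1, atol=1e-9)
    if np.dot(z1, z2) > -1 + 1e-6:
        b = associate_axes(z1, z2)
        a1 = np.arccos(np.clip(np.dot(b, z1), -1, 1))
        a2 = np.arccos(np.clip(np.dot(b, z2), -1, 1))
        assert a1 == pytest.approx(a2, abs=1e-7)


class TestAxisAngle:
    def test_orthogonal_pair(self):
        spec = axis_angle([0, 0, 1], [0, 1, 0])
        assert spec.angle == pytest.approx(np.pi / 2)
        assert np.allclose(spec.axis, [-1, 0, 0])

    def test_parallel_pair_is_identity(self):
        spec = axis_angle([0, 0, 1], [0, 0, 1])
        assert spec.angle == 0.0
        assert np.allclose(spec.matrix, np.eye(3))

    def test_full_angle_rotation_maps_z1_onto_z2(self, rng):
        for _ in range(200):
            z1, z2 = random_unit(rng), random_unit(rng)
            if np.dot(z1, z2) <= -1 + 1e-6:
                continue
            spec = axis_angle(z1, z2)
            assert np.allclose(spec.matrix @ z1, z2, atol=1e-9)

    def test_antiparallel_rejected(self):
        with pytest.raises(DegenerateAxisError):
            axis_angle([0, 0, 1], [0, 0, -1])

    def test_zero_vector_rejected(self):
        with pytest.raises(DegenerateAxisError):
            axis_angle([0, 0, 0], [0, 0, 1])


class TestAssociate:
    def test_orthogonal_bisector(self):
        out = associate_axes([0, 0, 1], [0, 1, 0])
        assert np.allclose(out, [0, np.sqrt(2) / 2, np.sqrt(2) / 2], atol=1e-12)

    def test_identity(self):
        assert np.allclose(associate_axes([0, 0, 1], [0, 0, 1]), [0, 0, 1])

    def test_bisector_makes_equal_angles(self, rng):
        for _ in range(200):
            z1, z2 = random_unit(rng), random_unit(rng)
            if np.dot(z1, z2) <= -1 + 1e-6:
                continue
            b = associate_axes(z1, z2)
            a1 = np.arccos(np.clip(np.dot(b, z1), -1, 1))
            a2 = np.arccos(np.clip(np.dot(b, z2), -1, 1))
            assert a1 == pytest.approx(a2, abs=1e-9)

    def test_near_parallel_equals_normalized_sum(self, rng):
        for _ in range(50):
            z1 = random_unit(rng)
            # perturb by <= 10 degrees
            axis = random_unit(rng)
            z2 = rodrigues_matrix(axis, np.radians(rng.uniform(0, 10))) @ z1
            expected = (z1 + z2) / np.linalg.norm(z1 + z2)
            assert np.allclose(associate_axes(z1, z2), expected, atol=1e-9)


class TestQuartetFrame:
    def test_symmetric_planar_quartet(self):
        bases = build_quartet(radius=5.0, tilt=0.0)
        gf = quartet_frame(_quartet_frames(bases))
        assert np.allclose(gf.z_axis, [0, 0, 1], atol=1e-8)
        assert np.allclose(gf.origin, 0.0, atol=1e-8)

    def test_symmetric_tilts_cancel(self):
        bases = build_quartet(radius=5.0, tilt=5.0)
        gf = quartet_frame(_quartet_frames(bases))
        assert _angle_deg(gf.z_axis, [0, 0, 1]) < 1e-6

    def test_origin_is_mean_of_member_origins(self):
        bases = build_quartet(radius=5.4, tilt=3.0)
        frames = _quartet_frames(bases)
        gf = quartet_frame(frames)
        assert np.allclose(gf.origin, np.mean([f.origin for f in frames], axis=0))

    def test_perturbed_quartet_matches_svd_plane_normal(self, rng):
        # near-planar regime: small per-base rocks and sub-0.1 A jitter; the
        # equal-weight bisector and the atom-weighted SVD plane then agree
        std = get_standard_base("G")
        for _ in range(50):
            bases = build_quartet(radius=5.4, tilt=rng.uniform(0, 3))
            all_coords = []
            frames = []
            for b in bases:
                tilt_axis = random_unit(rng)
                R = rodrigues_matrix(tilt_axis, np.radians(rng.uniform(0, 2.5)))
                c = b.coords.mean(axis=0)
                coords = (b.coords - c) @ R.T + c + rng.normal(scale=0.05, size=3)
                frames.append(fit_base_frame(dict(zip(b.atom_names, coords)), std))
                all_coords.append(coords)
            gf = quartet_frame(frames)
            normal = svd_plane_normal(np.vstack(all_coords))
            assert _angle_deg(gf.z_axis, normal) < 2.0

    def test_pairing_robustness(self, rng):
        for _ in range(20):
            bases = build_quartet(radius=5.4, tilt=rng.uniform(0, 8))
            frames = _quartet_frames(bases)
            seq = quartet_frame(frames, pairing="sequential")
            diag = quartet_frame(frames, pairing="diagonal")
            assert _angle_deg(seq.z_axis, diag.z_axis) < 1.0

    def test_rigid_motion_equivariance(self, rng):
        std = get_standard_base("G")
        bases = build_quartet(radius=5.4, tilt=4.0)
        frames = _quartet_frames(bases)
        gf = quartet_frame(frames)
        R = random_rotation(rng)
        t = rng.normal(scale=8.0, size=3)
        moved = [fit_base_frame(dict(zip(b.atom_names, b.coords @ R.T + t)), std)
                 for b in bases]
        gf2 = quartet_frame(moved)
        assert np.allclose(gf2.origin, R @ gf.origin + t, atol=1e-6)
        assert _angle_deg(gf2.z_axis, R @ gf.z_axis) < 1e-6

    def test_antialigned_members_are_flipped(self):
        bases = build_quartet(radius=5.4, tilt=0.0)
        frames = _quartet_frames(bases)
        # simulate anti-parallel strands: negate two normals
        import dataclasses
        flipped = [frames[0],
                   dataclasses.replace(frames[1], y_axis=-frames[1].y_axis,
                                       z_axis=-frames[1].z_axis),
                   frames[2],
                   dataclasses.replace(frames[3], y_axis=-frames[3].y_axis,
                                       z_axis=-frames[3].z_axis)]
        gf = quartet_frame(flipped)
        assert _angle_deg(gf.z_axis, [0, 0, 1]) < 1e-6

    def test_near_perpendicular_member_rejected(self):
        frames = _quartet_frames(build_quartet(radius=5.4))
        import dataclasses
        bad = dataclasses.replace(frames[1], x_axis=np.array([0.0, 0, 1]),
                                  y_axis=np.array([0.0, 1, 0]),
                                  z_axis=np.array([-1.0, 0, 0]))
        with pytest.raises(DegenerateAxisError):
            quartet_frame([frames[0], bad, frames[2], frames[3]])


class TestPairFrame:
    def test_identical_frames_returned_unchanged(self):
        frames = _quartet_frames(build_quartet(radius=5.4))
        pf = pair_frame([frames[0], frames[0]])
        assert np.allclose(pf.origin, frames[0].origin)
        assert np.allclose(pf.z_axis, frames[0].z_axis)

    def test_parallel_offset_bases(self):
        std = get_standard_base("T")
        f1 = fit_base_frame(dict(zip(std.atom_names, std.coords)), std)
        f2 = fit_base_frame(dict(zip(std.atom_names,
                                     std.coords + [0, 0, 3.4])), std)
        pf = pair_frame([f1, f2])
        assert np.allclose(pf.z_axis, [0, 0, 1], atol=1e-9)
        assert pf.origin[2] == pytest.approx(1.7)

    def test_pair_z_matches_svd_normal(self, rng):
        std_a, std_t = get_standard_base("A"), get_standard_base("T")
        # pseudo Watson-Crick arrangement: two near-coplanar bases side by side
        a_coords = std_a.coords + [4.5, 0, 0.1]
        t_coords = (std_t.coords @ rodrigues_matrix(np.array([1.0, 0, 0]),
                                                    np.radians(5)).T
                    - [4.5, 0, 0])
        fa = fit_base_frame(dict(zip(std_a.atom_names, a_coords)), std_a)
        ft = fit_base_frame(dict(zip(std_t.atom_names, t_coords)), std_t)
        pf = pair_frame([fa, ft])
        normal = svd_plane_normal(np.vstack([a_coords, t_coords]))
        assert _angle_deg(pf.z_axis, normal) < 2.0
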