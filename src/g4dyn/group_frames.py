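"""Composite frames for base pairs and G-quartets by half-angle axis association.

Two base normals Z1, Z2 are merged into one group normal by rotating Z1
half-way toward Z2 about the axis Z1 x Z2 — the geodesic bisector of the two
directions.  A quartet normal is built hierarchically: the four guanines are
split into two pairs, each pair is associated, and the two pair normals are
associated again.  The group center is the arithmetic mean of the member
centers.

Fitted normals of an anti-parallel quadruplex point to both sides of the
quartet plane, so members are first flipped into a common hemisphere (sign of
the dot product against the first member) before any association.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .base_frames import BaseFrame

__all__ = ["GroupFrame", "RotationSpec", "DegenerateAxisError",
           "rodrigues_matrix", "axis_angle", "associate_axes",
           "quartet_frame", "pair_frame"]

_PARALLEL_TOL = 1e-9


class DegenerateAxisError(ValueError):
    """Anti-parallel or near-perpendicular axes whose association is undefined."""


@dataclass(frozen=True)
class RotationSpec:
    """Axis-angle rotation with its matrix realization.

    ``matrix`` is the proper rotation by ``angle`` (radians) about the unit
    vector ``axis``; the axis is its fixed point.
    """

    axis: np.ndarray = field(repr=False)
    angle: float = 0.0
    matrix: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        axis = np.asarray(self.axis, dtype=float)
        object.__setattr__(self, "axis", axis)
        if abs(np.linalg.norm(axis) - 1.0) > 1e-9:
            raise ValueError("rotation axis must be unit length")
        m = rodrigues_matrix(axis, self.angle) if self.matrix is None \
            else np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)


@dataclass(frozen=True)
class GroupFrame:
    """Center and normal of a base group (pair or quartet)."""

    member_count: int
    origin: np.ndarray = field(repr=False)
    z_axis: np.ndarray = field(repr=False)

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        z = np.asarray(self.z_axis, dtype=float)
        object.__setattr__(self, "z_axis", z)
        if self.member_count not in (2, 4):
            raise ValueError("member_count must be 2 or 4")
        if abs(np.linalg.norm(z) - 1.0) > 1e-9:
            raise ValueError("group z_axis must be unit length")


def rodrigues_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Proper rotation matrix for a rotation by ``angle`` about unit ``axis``.

    R = cos(phi) I + sin(phi) [u]_x + (1 - cos(phi)) u u^T
    """
    u = np.asarray(axis, dtype=float)
    c, s = np.cos(angle), np.sin(angle)
    ux, uy, uz = u
    cross = np.array([[0.0, -uz, uy],
                      [uz, 0.0, -ux],
                      [-uy, ux, 0.0]])
    return c * np.eye(3) + s * cross + (1.0 - c) * np.outer(u, u)


def _check_unit(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise DegenerateAxisError(f"{name} is a zero vector")
    if abs(n - 1.0) > 1e-6:
        raise ValueError(f"{name} must be unit length (|v| = {n:.3g})")
    return v / n


def _any_perpendicular(v: np.ndarray) -> np.ndarray:
    """A deterministic unit vector orthogonal to v."""
    helper = np.array([1.0, 0.0, 0.0]) if abs(v[0]) <= 0.9 else np.array([0.0, 1.0, 0.0])
    p = np.cross(v, helper)
    return p / np.linalg.norm(p)


def axis_angle(z1: np.ndarray, z2: np.ndarray) -> RotationSpec:
    """Rotation carrying z1 onto z2: angle from the dot product, axis from the
    cross product, matrix by the Rodrigues formula.

    Anti-parallel inputs are rejected (the axis is undefined); callers dealing
    with unoriented normals must flip signs first.
    """
    z1 = _check_unit(z1, "z1")
    z2 = _check_unit(z2, "z2")
    dot = float(np.clip(np.dot(z1, z2), -1.0, 1.0))
    if dot <= -1.0 + 1e-9:
        raise DegenerateAxisError("anti-parallel axes: rotation axis undefined; flip one input")
    cross = np.cross(z1, z2)
    norm = np.linalg.norm(cross)
    angle = float(np.arccos(dot))
    if norm < _PARALLEL_TOL:
        # Parallel: zero rotation, axis conventionally any unit vector.
        return RotationSpec(axis=_any_perpendicular(z1), angle=0.0, matrix=np.eye(3))
    return RotationSpec(axis=cross / norm, angle=angle)


def associate_axes(z1: np.ndarray, z2: np.ndarray) -> np.ndarray:
    """Geodesic bisector of two unit normals: z1 rotated by half the
    inter-axis angle about z1 x z2.

    The result makes equal angles with both inputs; parallel inputs return z1
    unchanged.
    """
    spec = axis_angle(z1, z2)
    if spec.angle == 0.0:
        return np.array(z1, dtype=float)
    half = rodrigues_matrix(spec.axis, spec.angle / 2.0)
    out = half @ np.asarray(z1, dtype=float)
    return out / np.linalg.norm(out)


def _oriented_normals(frames: Sequence[BaseFrame]) -> list:
    """Member normals flipped into the hemisphere of the first member."""
    z_ref = frames[0].z_axis
    out = []
    for i, f in enumerate(frames):
        d = float(np.dot(f.z_axis, z_ref))
        if abs(d) < 0.1:
            raise DegenerateAxisError(
                f"member {i + 1} is near-perpendicular to member 1 "
                f"(|cos| = {abs(d):.3f} < 0.1): not a stacked base group")
        out.append(f.z_axis if d >= 0 else -f.z_axis)
    return out


def quartet_frame(frames: Sequence[BaseFrame], pairing: str = "sequential") -> GroupFrame:
    """Associate four base frames into a quartet frame.

    The four normals are split into two pairs (``sequential`` = (1,2)(3,4),
    ``diagonal`` = (1,3)(2,4)), each pair is bisected, and the two pair
    normals are bisected again.  The origin is the mean of the four base
    centers.  For near-parallel members the two pairing schemes agree to well
    under a degree.
    """
    frames = list(frames)
    if len(frames) != 4:
        raise ValueError("quartet_frame needs exactly 4 base frames")
    zs = _oriented_normals(frames)
    if pairing == "sequential":
        (a1, a2), (b1, b2) = (0, 1), (2, 3)
    elif pairing == "diagonal":
        (a1, a2), (b1, b2) = (0, 2), (1, 3)
    else:
        raise ValueError(f"unknown pairing scheme {pairing!r}")
    z_a = associate_axes(zs[a1], zs[a2])
    z_b = associate_axes(zs[b1], zs[b2])
    z_q = associate_axes(z_a, z_b)
    origin = np.mean([f.origin for f in frames], axis=0)
    return GroupFrame(member_count=4, origin=origin, z_axis=z_q)


def pair_frame(frames: Sequence[BaseFrame]) -> GroupFrame:
    """Associate two base frames into a pair frame (midpoint center,
    bisector normal)."""
    frames = list(frames)
    if len(frames) != 2:
        raise ValueError("pair_frame needs exactly 2 base frames")
    zs = _oriented_normals(frames)
    z_p = associate_axes(zs[0], zs[1])
    origin = 0.5 * (frames[0].origin + frames[1].origin)
    return GroupFrame(member_count=2, origin=origin, z_axis=z_p)
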