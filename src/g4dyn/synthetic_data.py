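"""Idealized G-quadruplex structures and trajectories with known ground truth.

This generator is the test bed for the whole analysis chain.  It builds
geometrically ideal stacked G-quartet layers (default rise 3.3 Angstrom,
twist 30 degrees, center-to-base radius 5.4 Angstrom — typical quadruplex
stem values), places loop bases at exactly specified poses relative to a
layer, and evolves the structure over frames with per-base rigid-body noise
and an optional two-state Markov switch that toggles one loop base between a
stacked and an alternate pose.

Poses are constructed so the analysis recovers them exactly on noiseless
frames: the loop-base center is displaced from the layer center by d_z along
the bisector of the layer normal and the tilted base normal, plus an
in-plane offset perpendicular to that bisector.  Every stochastic element is
driven by one seeded generator, so a fixed seed reproduces output
bit-for-bit.

The generator emulates pose dynamics only: bases are rigid (fit RMSD ~ 0),
there is no solvent, no backbone connecting loop to stem, and noise is
uncorrelated between frames, unlike real MD where displacements are strongly
autocorrelated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .group_frames import rodrigues_matrix
from .reference_bases import get_standard_base
from .structure_io import Atom, Trajectory

__all__ = ["Pose", "LoopBaseSpec", "MarkovSwitch", "SyntheticSpec",
           "GroundTruth", "PlacedBase", "build_quartet", "build_quadruplex",
           "simulate_trajectory", "synth_hbond_series", "write_pdb",
           "write_ground_truth_tsv", "load_spec"]

_X = np.array([1.0, 0.0, 0.0])
_Z = np.array([0.0, 0.0, 1.0])


@dataclass(frozen=True)
class Pose:
    """Loop-base pose relative to its reference group: Z-distance (Angstrom),
    plane tilt (degrees), in-plane offset (Angstrom)."""

    d_z: float = 3.4
    tilt: float = 0.0
    offset: float = 0.0


@dataclass(frozen=True)
class LoopBaseSpec:
    """One loop base: identity, nominal pose, and the layer it sits against
    (1-based layer index)."""

    base_code: str = "A"
    pose: Pose = Pose()
    attach_layer: int = 1


@dataclass(frozen=True)
class MarkovSwitch:
    """Two-state switch for one loop base (index into ``loop_bases``).

    ``p_leave`` is the per-frame probability of leaving the stacked (nominal)
    pose, ``p_enter`` of returning to it; the stationary stacked probability
    is p_enter / (p_leave + p_enter).
    """

    p_leave: float
    p_enter: float
    alt_pose: Pose
    base_index: int = 0

    def __post_init__(self):
        for p in (self.p_leave, self.p_enter):
            if not (0.0 <= p <= 1.0):
                raise ValueError("Markov probabilities must lie in [0, 1]")

    @property
    def stationary_stacked(self) -> float:
        total = self.p_leave + self.p_enter
        return 1.0 if total == 0 else self.p_enter / total


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parametric description of one synthetic quadruplex trajectory."""

    n_layers: int = 3
    rise: float = 3.3
    twist: float = 30.0
    quartet_radius: float = 5.4
    loop_bases: tuple = ()
    noise_t: float = 0.0        # per-base rigid translation SD, Angstrom
    noise_r: float = 0.0        # per-base rigid rotation SD, degrees
    noise_atom: float = 0.0     # optional per-atom Gaussian SD, Angstrom
    markov: Optional[MarkovSwitch] = None
    n_frames: int = 1
    frame_spacing: float = 5.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "loop_bases", tuple(self.loop_bases))
        if self.rise <= 0:
            raise ValueError("rise must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.markov is not None and self.loop_bases \
                and not (0 <= self.markov.base_index < len(self.loop_bases)):
            raise ValueError("markov.base_index out of range")


@dataclass
class GroundTruth:
    """What the generator actually wrote: per-frame Markov state (1 =
    stacked/nominal), nominal poses, and the analytic stationary stacked
    probability."""

    states: np.ndarray = field(repr=False)
    poses: tuple = ()
    stationary_stacked: Optional[float] = None


@dataclass
class PlacedBase:
    """One placed base: residue metadata plus ring-atom coordinates."""

    base_code: str
    resid: int
    atom_names: tuple
    coords: np.ndarray = field(repr=False)

    @property
    def resname(self) -> str:
        return "D" + self.base_code

    @property
    def center(self) -> np.ndarray:
        return self.coords.mean(axis=0)


def _place_base(code: str, rotation: np.ndarray, translation: np.ndarray,
                resid: int) -> PlacedBase:
    std = get_standard_base(code)
    coords = std.coords @ rotation.T + translation
    return PlacedBase(base_code=code, resid=resid,
                      atom_names=std.atom_names, coords=coords)


def build_quartet(radius: float = 5.4, tilt: float = 0.0,
                  z: float = 0.0, phase: float = 0.0,
                  first_resid: int = 1) -> List[PlacedBase]:
    """Four standard guanines at 90-degree increments about the Z axis.

    Base centers sit at ``radius`` from the axis in the plane at height
    ``z``; ``tilt`` rocks each base about its tangential direction in a
    4-fold symmetric pattern (the quartet normal stays exactly (0, 0, 1));
    ``phase`` rotates the whole quartet about Z (degrees).
    """
    if radius <= 2.0:
        raise ValueError("quartet radius must exceed 2 Angstrom")
    out = []
    for k in range(4):
        theta = np.radians(phase + 90.0 * k)
        radial = np.array([np.cos(theta), np.sin(theta), 0.0])
        tangent = np.array([-np.sin(theta), np.cos(theta), 0.0])
        rot = rodrigues_matrix(tangent, np.radians(tilt)) @ rodrigues_matrix(_Z, theta)
        out.append(_place_base("G", rot, radial * radius + np.array([0, 0, z]),
                               first_resid + k))
    return out


def _loop_placement(spec: SyntheticSpec, loop: LoopBaseSpec, pose: Pose
                    ) -> Tuple[np.ndarray, np.ndarray]:
    """Rotation and translation placing a loop base at an exact pose.

    The base plane is tilted about the X axis; the center is displaced from
    the layer center by d_z along the bisector of layer normal and base
    normal (below the stem when attached to layer 1 of a multi-layer stem,
    above otherwise) plus the in-plane offset along X, which is orthogonal
    to the bisector by construction.
    """
    layer_z = (loop.attach_layer - 1) * spec.rise
    side = -1.0 if (loop.attach_layer == 1 and spec.n_layers > 1) else 1.0
    t = np.radians(pose.tilt)
    rot = rodrigues_matrix(_X, t)
    bisector = rodrigues_matrix(_X, t / 2.0) @ _Z
    center = np.array([0.0, 0.0, layer_z]) \
        + side * pose.d_z * bisector + pose.offset * _X
    return rot, center


def _assemble(spec: SyntheticSpec, poses: Sequence[Pose]) -> List[PlacedBase]:
    bases: List[PlacedBase] = []
    resid = 1
    for layer in range(spec.n_layers):
        bases.extend(build_quartet(spec.quartet_radius, tilt=0.0,
                                   z=layer * spec.rise,
                                   phase=layer * spec.twist,
                                   first_resid=resid))
        resid += 4
    for loop, pose in zip(spec.loop_bases, poses):
        rot, center = _loop_placement(spec, loop, pose)
        bases.append(_place_base(loop.base_code, rot, center, resid))
        resid += 1
    return bases


def _check_clashes(bases: Sequence[PlacedBase]) -> None:
    for i in range(len(bases)):
        for j in range(i + 1, len(bases)):
            d = np.linalg.norm(bases[i].coords[:, None, :]
                               - bases[j].coords[None, :, :], axis=2)
            if d.min() < 1.0:
                raise ValueError(
                    f"construction clash: residues {bases[i].resid} and "
                    f"{bases[j].resid} have atoms {d.min():.2f} Angstrom apart")


def _roster(bases: Sequence[PlacedBase]) -> tuple:
    atoms = []
    for b in bases:
        for name in b.atom_names:
            atoms.append(Atom(name=name, resid=b.resid, resname=b.resname))
    return tuple(atoms)


def _frame_coords(bases: Sequence[PlacedBase]) -> np.ndarray:
    return np.concatenate([b.coords for b in bases], axis=0)


def build_quadruplex(spec: SyntheticSpec) -> Tuple[Trajectory, GroundTruth]:
    """Deterministic single-frame structure at the nominal poses."""
    poses = [lb.pose for lb in spec.loop_bases]
    bases = _assemble(spec, poses)
    _check_clashes(bases)
    traj = Trajectory(atoms=_roster(bases),
                      coords=_frame_coords(bases)[None, :, :],
                      frame_spacing=spec.frame_spacing)
    gt = GroundTruth(states=np.ones(1, dtype=int), poses=tuple(poses),
                     stationary_stacked=None)
    return traj, gt


def simulate_trajectory(spec: SyntheticSpec) -> Tuple[Trajectory, GroundTruth]:
    """Evolve the structure over ``spec.n_frames`` frames.

    Per frame: (1) advance the two-state Markov chain if configured (initial
    state drawn from its stationary distribution) and pick the switching
    base's pose accordingly; (2) apply independent rigid-body noise — a
    random rotation (rotation-vector components N(0, noise_r), applied about
    the base center) and a translation N(0, noise_t) per axis — to every
    base; (3) optionally add per-atom Gaussian noise for fitter stress tests.
    """
    rng = np.random.default_rng(spec.seed)
    nominal = [lb.pose for lb in spec.loop_bases]
    _check_clashes(_assemble(spec, nominal))

    markov = spec.markov
    if markov is not None and not spec.loop_bases:
        raise ValueError("markov switching configured but no loop bases present")
    state = 1
    if markov is not None:
        state = 1 if rng.random() < markov.stationary_stacked else 0

    roster = None
    states = np.ones(spec.n_frames, dtype=int)
    sigma_r = np.radians(spec.noise_r)
    all_frames = []
    for f in range(spec.n_frames):
        if markov is not None:
            if f > 0:
                u = rng.random()
                if state == 1 and u < markov.p_leave:
                    state = 0
                elif state == 0 and u < markov.p_enter:
                    state = 1
            states[f] = state
        poses = list(nominal)
        if markov is not None and state == 0:
            poses[markov.base_index] = markov.alt_pose
        bases = _assemble(spec, poses)
        for b in bases:
            if sigma_r > 0 or spec.noise_t > 0:
                rotvec = rng.normal(0.0, sigma_r, 3) if sigma_r > 0 else np.zeros(3)
                trans = rng.normal(0.0, spec.noise_t, 3) if spec.noise_t > 0 else np.zeros(3)
                angle = np.linalg.norm(rotvec)
                R = rodrigues_matrix(rotvec / angle, angle) if angle > 0 else np.eye(3)
                c = b.center
                b.coords = (b.coords - c) @ R.T + c + trans
            if spec.noise_atom > 0:
                b.coords = b.coords + rng.normal(0.0, spec.noise_atom, b.coords.shape)
        if roster is None:
            roster = _roster(bases)
        all_frames.append(_frame_coords(bases))
    frames = np.stack(all_frames)
    traj = Trajectory(atoms=roster, coords=frames, frame_spacing=spec.frame_spacing)
    gt = GroundTruth(states=states, poses=tuple(nominal),
                     stationary_stacked=None if markov is None
                     else markov.stationary_stacked)
    return traj, gt


def synth_hbond_series(schedule: Sequence[bool],
                       bonded_distance: float = 2.9,
                       broken_distance: float = 4.2,
                       jitter: float = 0.0,
                       d_cut: float = 3.5,
                       frame_spacing: float = 5.0,
                       seed: int = 0) -> Tuple[Trajectory, np.ndarray]:
    """Minimal donor-hydrogen-acceptor trajectory following an on/off schedule.

    The donor (N3 of residue 1) sits at the origin with its hydrogen on the
    +X axis; the acceptor (N1 of residue 2) sits on +X at the bonded or
    broken distance per the schedule, with optional isotropic Gaussian jitter
    on its position.  Returns the trajectory and the ground-truth bonded
    mask.
    """
    mask = np.asarray(schedule, dtype=bool)
    if mask.ndim != 1 or len(mask) == 0:
        raise ValueError("schedule must be a non-empty 1-D boolean sequence")
    if not (bonded_distance < d_cut < broken_distance):
        raise ValueError("distance levels must straddle the cutoff")
    rng = np.random.default_rng(seed)
    atoms = (Atom("N3", 1, "DT"), Atom("H3", 1, "DT"), Atom("N1", 2, "DA"))
    coords = np.zeros((len(mask), 3, 3))
    coords[:, 1, 0] = 1.01  # donor hydrogen along +X
    level = np.where(mask, bonded_distance, broken_distance)
    coords[:, 2, 0] = level
    if jitter > 0:
        coords[:, 2, :] += rng.normal(0.0, jitter, (len(mask), 3))
    traj = Trajectory(atoms=atoms, coords=coords, frame_spacing=frame_spacing)
    return traj, mask


# ---------------------------------------------------------------------------
# Output

_ELEMENTS = {"N": "N", "C": "C", "O": "O", "P": "P", "H": "H", "S": "S"}


def write_pdb(traj: Trajectory, path) -> None:
    """Write a multi-model PDB (fixed-format ATOM records, 3-decimal
    coordinates); byte-identical output for identical input."""
    lines = []
    for f in range(traj.n_frames):
        lines.append(f"MODEL     {f + 1:4d}")
        for i, a in enumerate(traj.atoms):
            x, y, z = traj.coords[f, i]
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            element = _ELEMENTS.get(a.name[0].upper(), a.name[0].upper())
            lines.append(
                f"ATOM  {i + 1:5d} {name:<4s} {a.resname:<3s} {a.chain}"
                f"{a.resid:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
                f"          {element:>2s}")
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_ground_truth_tsv(gt: GroundTruth, path,
                           frame_spacing: float = 5.0) -> None:
    """Sidecar TSV: frame, time, Markov state; poses in a comment header."""
    lines = []
    for i, pose in enumerate(gt.poses):
        lines.append(f"# pose_{i}\td_z={pose.d_z}\ttilt={pose.tilt}\toffset={pose.offset}")
    if gt.stationary_stacked is not None:
        lines.append(f"# stationary_stacked\t{gt.stationary_stacked:.6f}")
    lines.append("frame\ttime_ps\tstate")
    for f, s in enumerate(gt.states):
        lines.append(f"{f + 1}\t{f * frame_spacing:.3f}\t{int(s)}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_spec(path) -> SyntheticSpec:
    """Read a :class:`SyntheticSpec` from a YAML key-value file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    loops = []
    for lb in raw.pop("loop_bases", []):
        pose = Pose(**lb.pop("pose", {}))
        loops.append(LoopBaseSpec(pose=pose, **lb))
    markov = raw.pop("markov", None)
    if markov is not None:
        markov = MarkovSwitch(alt_pose=Pose(**markov.pop("alt_pose", {})), **markov)
    return SyntheticSpec(loop_bases=tuple(loops), markov=markov, **raw)
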