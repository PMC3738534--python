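"""Helpers mapping trajectory residues to fitted base/group frames."""

from __future__ import annotations

from typing import Sequence, Union

from .base_frames import BaseFrame, fit_base_frame
from .group_frames import GroupFrame, pair_frame, quartet_frame
from .reference_bases import base_code_from_residue_name, get_standard_base
from .structure_io import Selection, SelectionError, Trajectory, select

__all__ = ["ring_coords", "residue_base_frame", "frame_for_residues"]

AnyFrame = Union[BaseFrame, GroupFrame]


def ring_coords(traj: Trajectory, frame_idx: int, resid: int) -> dict:
    """Ring heavy-atom coordinates of one residue in one frame, keyed by name."""
    idx = select(traj, Selection([resid]))
    resname = traj.atoms[idx[0]].resname
    std = get_standard_base(base_code_from_residue_name(resname))
    wanted = set(std.atom_names)
    out = {}
    for i in idx:
        name = traj.atoms[i].name.upper()
        if name in wanted:
            out[name] = traj.coords[frame_idx, i]
    return out


def residue_base_frame(traj: Trajectory, frame_idx: int, resid: int) -> BaseFrame:
    """Fit the base of one residue in one frame to its standard reference."""
    idx = select(traj, Selection([resid]))
    resname = traj.atoms[idx[0]].resname
    std = get_standard_base(base_code_from_residue_name(resname))
    return fit_base_frame(ring_coords(traj, frame_idx, resid), std)


def frame_for_residues(traj: Trajectory, frame_idx: int,
                       residues: Sequence[int], pairing: str = "sequential") -> AnyFrame:
    """Base frame (1 residue), pair frame (2) or quartet frame (4)."""
    residues = list(residues)
    frames = [residue_base_frame(traj, frame_idx, r) for r in residues]
    if len(frames) == 1:
        return frames[0]
    if len(frames) == 2:
        return pair_frame(frames)
    if len(frames) == 4:
        return quartet_frame(frames, pairing=pairing)
    raise SelectionError(
        f"a base group must contain 1, 2 or 4 residues, got {len(frames)}")
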