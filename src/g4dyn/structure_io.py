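"""Trajectory container and multi-model PDB input.

A trajectory is a fixed atom roster plus per-frame coordinates.  Multi-model
PDB (``MODEL``/``ENDMDL``) is the baseline on-disk format; a file without
``MODEL`` records is a one-frame trajectory.  Frames are 0-based internally
and reported 1-based in text outputs; coordinates are in Angstrom and frame
spacing in picoseconds (default 5 ps, a common trajectory writing interval).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

__all__ = ["Atom", "Trajectory", "Selection", "StructureError",
           "SelectionError", "read_structure", "select"]

DEFAULT_FRAME_SPACING_PS = 5.0


class StructureError(ValueError):
    """Unreadable or internally inconsistent structure input."""


class SelectionError(ValueError):
    """Selection that resolves to no atoms in the roster."""


@dataclass(frozen=True)
class Atom:
    """One roster entry: atom name, 1-based residue index, residue name, chain."""

    name: str
    resid: int
    resname: str
    chain: str = "A"


@dataclass
class Trajectory:
    """Fixed atom roster with per-frame coordinates.

    Attributes
    ----------
    atoms : tuple of Atom
        The roster, identical for every frame.
    coords : ndarray, shape (n_frames, n_atoms, 3)
        Coordinates in Angstrom.
    frame_spacing : float
        Time between stored frames in ps.
    """

    atoms: tuple
    coords: np.ndarray = field(repr=False)
    frame_spacing: float = DEFAULT_FRAME_SPACING_PS

    def __post_init__(self):
        self.atoms = tuple(self.atoms)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise StructureError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise StructureError("coords second dimension must match the atom roster")
        if self.coords.shape[0] < 1:
            raise StructureError("a trajectory needs at least one frame")
        if not self.frame_spacing > 0:
            raise StructureError("frame_spacing must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def times_ps(self) -> np.ndarray:
        """Frame times in ps (frame 0 at t = 0)."""
        return np.arange(self.n_frames) * self.frame_spacing

    def residue_ids(self) -> list:
        """Distinct residue indices in roster order."""
        seen, out = set(), []
        for a in self.atoms:
            if a.resid not in seen:
                seen.add(a.resid)
                out.append(a.resid)
        return out

    def subset(self, frame_slice: slice) -> "Trajectory":
        """New trajectory restricted to a frame window (same roster)."""
        return Trajectory(self.atoms, self.coords[frame_slice], self.frame_spacing)


@dataclass(frozen=True)
class Selection:
    """Residue indices plus an optional atom-name filter.

    ``residues`` is an ordered list of 1-based residue indices; when
    ``atom_names`` is given only those atoms are kept within each residue.
    Resolution order is residue-major, file order within a residue.
    """

    residues: tuple
    atom_names: Optional[tuple] = None

    def __init__(self, residues: Sequence[int], atom_names: Optional[Sequence[str]] = None):
        object.__setattr__(self, "residues", tuple(int(r) for r in residues))
        object.__setattr__(self, "atom_names",
                           None if atom_names is None else tuple(str(n) for n in atom_names))


def select(traj: Trajectory, spec: Selection) -> list:
    """Resolve a :class:`Selection` to an ordered list of atom indices.

    Deterministic for identical inputs.  Raises :class:`SelectionError` when
    any requested residue matches nothing — silent emptiness is never
    returned.
    """
    wanted = None if spec.atom_names is None else {n.upper() for n in spec.atom_names}
    out = []
    for resid in spec.residues:
        hits = [i for i, a in enumerate(traj.atoms)
                if a.resid == resid and (wanted is None or a.name.upper() in wanted)]
        if not hits:
            raise SelectionError(
                f"selection matched no atoms for residue {resid}"
                + ("" if wanted is None else f" with atom names {sorted(wanted)}"))
        out.extend(hits)
    if not out:
        raise SelectionError("empty selection: no residues requested")
    return out


def read_structure(path, frame_spacing: float = DEFAULT_FRAME_SPACING_PS) -> Trajectory:
    """Read a (multi-model) PDB file into a :class:`Trajectory`.

    Every MODEL becomes one frame; a file without MODEL records yields a
    single frame.  Hydrogens are retained if present.  All models must carry
    the identical atom roster; the first mismatching frame is named in the
    error.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            structure = parser.get_structure(path.stem, str(path))
    except Exception as exc:
        raise StructureError(f"{path}: not parseable as PDB ({exc})") from exc
    models = list(structure)
    if not models:
        raise StructureError(f"{path}: no models / atoms found")

    roster = None
    frames = []
    for m_i, model in enumerate(models):
        names, xyz = [], []
        for chain in model:
            for residue in chain:
                for atom in residue:
                    names.append(Atom(name=atom.get_name(),
                                      resid=residue.id[1],
                                      resname=residue.get_resname().strip(),
                                      chain=chain.id))
                    xyz.append(atom.get_coord())
        if not names:
            raise StructureError(f"{path}: model {m_i + 1} contains no atoms")
        names = tuple(names)
        if roster is None:
            roster = names
        elif names != roster:
            raise StructureError(
                f"{path}: atom roster of model {m_i + 1} differs from model 1 "
                f"({len(names)} vs {len(roster)} atoms or reordered records)")
        frames.append(np.asarray(xyz, dtype=float))

    return Trajectory(atoms=roster, coords=np.stack(frames), frame_spacing=frame_spacing)
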