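"""Trajectory-level summaries: pairwise RMSD, reference RMSD, backbone torsions.

Pairwise RMSD matrices expose the coarse conformational history of a
trajectory (long-lived states show as low-RMSD blocks).  Fitting and
measuring selections are independent, so one can superpose on the rigid
G-stem while measuring loop atoms — the standard way to isolate loop motion
from global tumbling.  Note that per-pair superposed RMSD is not a metric (no
triangle inequality); the matrices are descriptive.

Backbone torsions use the standard nucleic-acid definitions (alpha =
O3'(i-1)-P-O5'-C5', ..., chi via N9/C4 for purines and N1/C2 for
pyrimidines), reported in [0, 360) and binned into the g+ / t / g- rotamer
wells centered at 60, 180 and 300 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .reference_bases import base_code_from_residue_name
from .structure_io import Selection, SelectionError, Trajectory, select

__all__ = ["RMSDMatrix", "TorsionSeries", "pairwise_rmsd",
           "rmsd_to_reference", "torsion_series", "dihedral", "rotamer_label"]

TORSION_DEFS = {
    "alpha":   ((-1, "O3'"), (0, "P"), (0, "O5'"), (0, "C5'")),
    "beta":    ((0, "P"), (0, "O5'"), (0, "C5'"), (0, "C4'")),
    "gamma":   ((0, "O5'"), (0, "C5'"), (0, "C4'"), (0, "C3'")),
    "delta":   ((0, "C5'"), (0, "C4'"), (0, "C3'"), (0, "O3'")),
    "epsilon": ((0, "C4'"), (0, "C3'"), (0, "O3'"), (1, "P")),
    "zeta":    ((0, "C3'"), (0, "O3'"), (1, "P"), (1, "O5'")),
}
_GREEK = {"α": "alpha", "β": "beta", "γ": "gamma", "δ": "delta",
          "ε": "epsilon", "ζ": "zeta", "χ": "chi"}


@dataclass
class RMSDMatrix:
    """Symmetric matrix of superposed RMSD between retained frame pairs."""

    matrix: np.ndarray = field(repr=False)
    frame_indices: np.ndarray = field(repr=False)  # 0-based original frames
    stride: int = 1

    def to_text(self, path) -> None:
        """Plain-text square matrix with 1-based frame header row/column."""
        frames = self.frame_indices + 1
        lines = ["frame\t" + "\t".join(str(f) for f in frames)]
        for i, f in enumerate(frames):
            lines.append(str(f) + "\t" + "\t".join(
                f"{v:.4f}" for v in self.matrix[i]))
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class TorsionSeries:
    """Per-frame torsion angle (degrees, [0, 360)) with rotamer labels."""

    name: str
    residue: int
    angles_deg: np.ndarray = field(repr=False)
    labels: tuple = field(repr=False, default=())

    def to_tsv(self, path, frame_spacing: float = 1.0) -> None:
        lines = ["frame\ttime_ps\tangle_deg\trotamer"]
        for i, (a, lab) in enumerate(zip(self.angles_deg, self.labels)):
            lines.append(f"{i + 1}\t{i * frame_spacing:.3f}\t{a:.3f}\t{lab}")
        Path(path).write_text("\n".join(lines) + "\n")


def dihedral(p1, p2, p3, p4) -> float:
    """IUPAC dihedral of four points, in degrees wrapped to [0, 360)."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2) / np.linalg.norm(b2)
    return float(np.degrees(np.arctan2(y, x)) % 360.0)


def rotamer_label(angle_deg: float) -> str:
    """g+ for [0, 120), t for [120, 240), g- for [240, 360)."""
    a = angle_deg % 360.0
    if a < 120.0:
        return "g+"
    if a < 240.0:
        return "t"
    return "g-"


def _fit_transform(mobile_fit: np.ndarray, target_fit: np.ndarray):
    """Rigid transform (R, mobile centroid, target centroid) superposing
    mobile onto target over the fit atoms."""
    mc, tc = mobile_fit.mean(axis=0), target_fit.mean(axis=0)
    rot, _ = Rotation.align_vectors(target_fit - tc, mobile_fit - mc)
    return rot.as_matrix(), mc, tc


def _superposed_rmsd(mobile: np.ndarray, target: np.ndarray,
                     fit_idx: Sequence[int], calc_idx: Sequence[int]) -> float:
    R, mc, tc = _fit_transform(mobile[fit_idx], target[fit_idx])
    moved = (mobile[calc_idx] - mc) @ R.T + tc
    diff = moved - target[calc_idx]
    return float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))


def pairwise_rmsd(traj: Trajectory, fit_sel: Selection, calc_sel: Selection,
                  stride: int = 1) -> RMSDMatrix:
    """All-against-all superposed RMSD over strided frames.

    Each pair is superposed on ``fit_sel`` (rigid least squares) and measured
    over ``calc_sel``.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    fit_idx = select(traj, fit_sel)
    calc_idx = select(traj, calc_sel)
    frames = np.arange(0, traj.n_frames, stride)
    n = len(frames)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v = _superposed_rmsd(traj.coords[frames[j]], traj.coords[frames[i]],
                                 fit_idx, calc_idx)
            m[i, j] = m[j, i] = v
    return RMSDMatrix(matrix=m, frame_indices=frames, stride=stride)


def rmsd_to_reference(traj: Trajectory, ref_coords: np.ndarray,
                      fit_sel: Selection, calc_sel: Selection) -> np.ndarray:
    """Per-frame RMSD against one reference frame.

    ``ref_coords`` must cover the full atom roster, shape (n_atoms, 3);
    fitting and measuring selections may differ (e.g. fit on the G-stem,
    measure the loop).
    """
    ref = np.asarray(ref_coords, dtype=float)
    if ref.shape != (traj.n_atoms, 3):
        raise ValueError(
            f"reference roster mismatch: expected shape ({traj.n_atoms}, 3), got {ref.shape}")
    fit_idx = select(traj, fit_sel)
    calc_idx = select(traj, calc_sel)
    return np.array([_superposed_rmsd(traj.coords[f], ref, fit_idx, calc_idx)
                     for f in range(traj.n_frames)])


def _atom_index(traj: Trajectory, resid: int, name: str) -> int:
    for i, a in enumerate(traj.atoms):
        if a.resid == resid and a.name.upper() == name.upper():
            return i
    raise SelectionError(f"missing atom {name}@{resid} required for the torsion")


def torsion_series(traj: Trajectory, residue: int, torsion: str) -> TorsionSeries:
    """Backbone or glycosidic torsion of one residue across all frames."""
    key = _GREEK.get(torsion, torsion).lower()
    if key == "chi":
        resname = None
        for a in traj.atoms:
            if a.resid == residue:
                resname = a.resname
                break
        if resname is None:
            raise SelectionError(f"no residue {residue} in trajectory")
        code = base_code_from_residue_name(resname)
        defs = ((0, "O4'"), (0, "C1'"), (0, "N9"), (0, "C4")) if code in ("A", "G") \
            else ((0, "O4'"), (0, "C1'"), (0, "N1"), (0, "C2"))
    elif key in TORSION_DEFS:
        defs = TORSION_DEFS[key]
    else:
        raise ValueError(f"unknown torsion {torsion!r}")
    idx = [_atom_index(traj, residue + off, name) for off, name in defs]
    angles = np.array([dihedral(*(traj.coords[f, i] for i in idx))
                       for f in range(traj.n_frames)])
    labels = tuple(rotamer_label(a) for a in angles)
    return TorsionSeries(name=key, residue=residue, angles_deg=angles, labels=labels)
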