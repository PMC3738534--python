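"""Hydrogen-bond detection, occupancy and lifetime statistics.

A donor-acceptor contact is bonded in a frame when the heavy-atom distance is
at most ``d_cut`` (default 3.5 Angstrom) and the D-H...A angle is within
``a_cut`` (default 30 degrees) of linearity, i.e. D-H...A >= 150 degrees.
With several hydrogens on the donor the bond counts if any of them satisfies
the angle test; when no hydrogen exists in the roster the check degrades to
distance-only and the result is flagged accordingly.

Occupancy is the bonded fraction of frames; the mean lifetime is the average
length of contiguous bonded runs converted to ps by the frame spacing, with
no gap tolerance by default (one broken frame ends a run; ``max_gap`` can
relax this).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import numpy as np

from .structure_io import Selection, SelectionError, Trajectory, select

__all__ = ["HBondSpec", "HBondStats", "hbond_geometry", "hbond_frame",
           "hbond_series", "hbond_stats"]

_COVALENT_DH_MAX = 1.3  # Angstrom: H within this distance of the donor is "on" it


@dataclass(frozen=True)
class HBondSpec:
    """One named donor-acceptor contact.

    ``donor`` and ``acceptor`` are (residue index, atom name) pairs resolving
    to single heavy atoms.  ``hydrogen`` may name explicit hydrogen atoms; by
    default hydrogens covalently attached to the donor are auto-detected from
    the roster (name starting with H, within 1.3 Angstrom in the first
    frame).
    """

    donor: Tuple[int, str]
    acceptor: Tuple[int, str]
    hydrogen: Optional[Tuple[int, str]] = None
    d_cut: float = 3.5
    a_cut: float = 30.0

    def __post_init__(self):
        if not self.d_cut > 0:
            raise ValueError("d_cut must be positive")
        if not (0 < self.a_cut <= 90):
            raise ValueError("a_cut must lie in (0, 90] degrees")

    def label(self) -> str:
        """Table-style name, e.g. ``N6@A19->O4@T6`` style ``donor->acceptor``."""
        return f"{self.donor[1]}@{self.donor[0]}->{self.acceptor[1]}@{self.acceptor[0]}"


@dataclass
class HBondStats:
    """Occupancy and lifetime summary of one contact over a trajectory."""

    occupancy: float
    mean_lifetime_ps: float
    n_events: int
    n_frames: int
    series: np.ndarray = field(repr=False, default=None)  # per-frame 0/1
    distance_only: bool = False

    @property
    def occupancy_pct(self) -> float:
        return 100.0 * self.occupancy

    def to_tsv(self, path, frame_spacing: float = 1.0) -> None:
        lines = ["frame\ttime_ps\tbonded"]
        for i, b in enumerate(self.series):
            lines.append(f"{i + 1}\t{i * frame_spacing:.3f}\t{int(b)}")
        lines += [f"# occupancy_pct\t{self.occupancy_pct:.2f}",
                  f"# mean_lifetime_ps\t{self.mean_lifetime_ps:.2f}",
                  f"# n_events\t{self.n_events}",
                  f"# distance_only\t{int(self.distance_only)}"]
        Path(path).write_text("\n".join(lines) + "\n")


def hbond_geometry(donor: np.ndarray, acceptor: np.ndarray,
                   hydrogens: np.ndarray, d_cut: float, a_cut: float) -> bool:
    """Pure geometric bond test on one frame's coordinates.

    ``hydrogens`` is an (n, 3) array (possibly empty, triggering the
    distance-only fallback).
    """
    donor = np.asarray(donor, dtype=float)
    acceptor = np.asarray(acceptor, dtype=float)
    if np.linalg.norm(donor - acceptor) > d_cut:
        return False
    hydrogens = np.asarray(hydrogens, dtype=float).reshape(-1, 3)
    if len(hydrogens) == 0:
        return True  # distance-only fallback
    for h in hydrogens:
        v1, v2 = donor - h, acceptor - h
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        dha = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        if 180.0 - dha <= a_cut:
            return True
    return False


def _resolve_single(traj: Trajectory, resid: int, name: str) -> int:
    idx = select(traj, Selection([resid], [name]))
    if len(idx) != 1:
        raise SelectionError(
            f"{name}@{resid} is ambiguous: resolves to {len(idx)} atoms")
    return idx[0]


def _resolve_hydrogens(traj: Trajectory, spec: HBondSpec, donor_idx: int) -> list:
    if spec.hydrogen is not None:
        return list(select(traj, Selection([spec.hydrogen[0]], [spec.hydrogen[1]])))
    resid = traj.atoms[donor_idx].resid
    d0 = traj.coords[0, donor_idx]
    out = []
    for i, a in enumerate(traj.atoms):
        if a.resid == resid and a.name.upper().startswith("H"):
            if np.linalg.norm(traj.coords[0, i] - d0) <= _COVALENT_DH_MAX:
                out.append(i)
    return out


def hbond_frame(traj: Trajectory, frame_idx: int, spec: HBondSpec) -> bool:
    """Bond verdict for one frame of a trajectory."""
    d = _resolve_single(traj, *spec.donor)
    a = _resolve_single(traj, *spec.acceptor)
    hs = _resolve_hydrogens(traj, spec, d)
    return hbond_geometry(traj.coords[frame_idx, d], traj.coords[frame_idx, a],
                          traj.coords[frame_idx, hs], spec.d_cut, spec.a_cut)


def hbond_series(traj: Trajectory, spec: HBondSpec) -> Tuple[np.ndarray, bool]:
    """Per-frame bond booleans plus the distance-only flag."""
    d = _resolve_single(traj, *spec.donor)
    a = _resolve_single(traj, *spec.acceptor)
    hs = _resolve_hydrogens(traj, spec, d)
    distance_only = len(hs) == 0
    dist = np.linalg.norm(traj.coords[:, a] - traj.coords[:, d], axis=1)
    bonded = dist <= spec.d_cut
    if not distance_only:
        angle_ok = np.zeros(traj.n_frames, dtype=bool)
        for h in hs:
            v1 = traj.coords[:, d] - traj.coords[:, h]
            v2 = traj.coords[:, a] - traj.coords[:, h]
            cosang = np.sum(v1 * v2, axis=1) / (
                np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1))
            dha = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            angle_ok |= (180.0 - dha) <= spec.a_cut
        bonded &= angle_ok
    return bonded, distance_only


def _run_lengths(mask: np.ndarray) -> list:
    runs, current = [], 0
    for b in mask:
        if b:
            current += 1
        elif current:
            runs.append(current)
            current = 0
    if current:
        runs.append(current)
    return runs


def hbond_stats(traj: Trajectory, spec: HBondSpec,
                start: Optional[int] = None, end: Optional[int] = None,
                max_gap: int = 0) -> HBondStats:
    """Occupancy and mean lifetime of one contact.

    ``start``/``end`` restrict to a 1-based inclusive frame window (the whole
    trajectory by default).  ``max_gap`` > 0 lets runs bridge that many
    consecutive broken frames (bridged frames still count as unbonded for
    occupancy).
    """
    lo = 1 if start is None else int(start)
    hi = traj.n_frames if end is None else int(end)
    if not (1 <= lo <= hi <= traj.n_frames):
        raise ValueError(
            f"frame window [{lo}, {hi}] outside trajectory of {traj.n_frames} frames")
    bonded, distance_only = hbond_series(traj, spec)
    window = bonded[lo - 1:hi]
    occupancy = float(np.mean(window))
    mask = window.copy()
    if max_gap > 0:  # bridge short gaps for lifetime bookkeeping only
        bonded_idx = np.flatnonzero(window)
        for i, j in zip(bonded_idx[:-1], bonded_idx[1:]):
            if 1 < j - i <= max_gap + 1:
                mask[i:j] = True
    runs = _run_lengths(mask)
    n_events = len(runs)
    mean_lifetime = float(np.mean(runs) * traj.frame_spacing) if runs else 0.0
    return HBondStats(occupancy=occupancy, mean_lifetime_ps=mean_lifetime,
                      n_events=n_events, n_frames=len(window),
                      series=window.astype(int), distance_only=distance_only)
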