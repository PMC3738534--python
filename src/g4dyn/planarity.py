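"""Quartet planarity: the RMSD_Z statistic and its trajectory distribution.

A perfectly planar G-quartet has every ring atom in the plane defined by the
quartet center and the associated quartet normal.  RMSD_Z quantifies the
departure from that plane: each ring atom's coordinate, taken relative to the
quartet center, is projected onto the quartet Z axis, and the root mean
square of those projections is the planarity deviation.  The quartet frame is
recomputed in every trajectory frame, so the statistic is invariant under
rigid motion of the whole quartet.

Default normalization pools all atoms into a single RMSD,
sqrt(sum_i sum_j z_ij^2 / sum_i N_i); an alternative averages the four
per-base RMSDs instead (``normalization="per_base"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .group_frames import GroupFrame
from .residue_frames import frame_for_residues, ring_coords
from .structure_io import Selection, Trajectory

__all__ = ["PlanarityResult", "PlanarityHistogram", "rmsd_z",
           "planarity_series", "planarity_distribution"]


@dataclass(frozen=True)
class PlanarityResult:
    """RMSD_Z of one quartet in one frame.

    ``per_base_contrib`` holds each base's summed squared Z-displacement
    (Angstrom^2 * atoms); their total over ``n_atoms_total`` atoms gives the
    pooled mean square.
    """

    rmsd_z: float
    per_base_contrib: tuple
    n_atoms_total: int

    def __post_init__(self):
        if self.rmsd_z < 0:
            raise ValueError("rmsd_z must be non-negative")


@dataclass
class PlanarityHistogram:
    """Normalized probability histogram of per-frame RMSD_Z values."""

    bin_centers: np.ndarray = field(repr=False)
    probability: np.ndarray = field(repr=False)
    mode: float = 0.0      # bin center with the highest probability (peak point)
    mean: float = 0.0
    sd: float = 0.0        # distribution width

    def to_tsv(self, path) -> None:
        lines = ["bin_center_A\tprobability"]
        for c, p in zip(self.bin_centers, self.probability):
            lines.append(f"{c:.5f}\t{p:.6f}")
        lines += [f"# mode_A\t{self.mode:.5f}", f"# mean_A\t{self.mean:.5f}",
                  f"# sd_A\t{self.sd:.5f}"]
        Path(path).write_text("\n".join(lines) + "\n")


def rmsd_z(quartet_coords: Sequence[np.ndarray], frame: GroupFrame,
           normalization: str = "pooled") -> PlanarityResult:
    """Planarity deviation of four bases against their quartet frame.

    Parameters
    ----------
    quartet_coords : sequence of four (n_i, 3) arrays
        Ring heavy-atom coordinates of the four bases the frame was built
        from (9 atoms each for guanines).
    frame : GroupFrame
        Quartet center and normal.
    normalization : {"pooled", "per_base"}
        Pooled (default) divides the total squared displacement by the total
        atom count; per_base averages the four per-base RMSDs.
    """
    if frame.member_count != 4:
        raise ValueError("rmsd_z requires a quartet GroupFrame (member_count 4)")
    bases = [np.asarray(b, dtype=float) for b in quartet_coords]
    if len(bases) != 4:
        raise ValueError(f"expected 4 bases, got {len(bases)}")
    contrib, counts, per_base_rmsd = [], [], []
    for b in bases:
        if b.ndim != 2 or b.shape[1] != 3 or b.shape[0] == 0:
            raise ValueError("each base must be a non-empty (n, 3) coordinate array")
        z = (b - frame.origin) @ frame.z_axis
        contrib.append(float(np.sum(z ** 2)))
        counts.append(b.shape[0])
        per_base_rmsd.append(float(np.sqrt(np.mean(z ** 2))))
    total = int(sum(counts))
    if normalization == "pooled":
        value = float(np.sqrt(sum(contrib) / total))
    elif normalization == "per_base":
        value = float(np.mean(per_base_rmsd))
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return PlanarityResult(rmsd_z=value, per_base_contrib=tuple(contrib),
                           n_atoms_total=total)


def planarity_series(traj: Trajectory, quartet_sel: Selection,
                     normalization: str = "pooled",
                     pairing: str = "sequential") -> np.ndarray:
    """Per-frame RMSD_Z of one quartet selection (4 residues)."""
    residues = list(quartet_sel.residues)
    if len(residues) != 4:
        raise ValueError("quartet selection must name exactly 4 residues")
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        frame = frame_for_residues(traj, f, residues, pairing=pairing)
        coords = [np.array(list(ring_coords(traj, f, r).values())) for r in residues]
        out[f] = rmsd_z(coords, frame, normalization=normalization).rmsd_z
    return out


def planarity_distribution(traj: Trajectory, quartet_sel: Selection,
                           n_bins: int = 50,
                           normalization: str = "pooled") -> PlanarityHistogram:
    """Probability distribution of per-frame RMSD_Z over a trajectory.

    The histogram is normalized to total probability 1; the mode bin is the
    peak of the distribution and the standard deviation its width.
    """
    if traj.n_frames < 2:
        raise ValueError("planarity_distribution needs at least 2 frames")
    values = planarity_series(traj, quartet_sel, normalization=normalization)
    lo, hi = float(values.min()), float(values.max())
    if hi - lo < 1e-12:  # degenerate: all frames identical
        hi = lo + 1e-6
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    prob = counts / counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    return PlanarityHistogram(bin_centers=centers, probability=prob,
                              mode=float(centers[np.argmax(prob)]),
                              mean=float(values.mean()), sd=float(values.std()))
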