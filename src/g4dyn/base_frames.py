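"""Per-base reference frames from least-squares superposition.

Each observed base is fitted to its standard planar reference by a rigid
(rotation + translation, reflection-free) least-squares superposition of the
ring heavy atoms.  The image of the standard origin is the base center and
the images of the standard unit axes are the base triad; the Z axis is then
perpendicular to the base plane by construction.  Only the center and Z axis
feed the group-frame association downstream, but the full triad is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.spatial.transform import Rotation

from .reference_bases import StandardBase

__all__ = ["BaseFrame", "FitError", "fit_base_frame"]


class FitError(ValueError):
    """Missing atoms or degenerate geometry in a base fit."""


@dataclass(frozen=True)
class BaseFrame:
    """Orthonormal right-handed base triad.

    Attributes
    ----------
    origin : ndarray, shape (3,)
        Base center in Angstrom (image of the standard-base origin).
    x_axis, y_axis, z_axis : ndarray, shape (3,)
        Unit axes; ``x_axis x y_axis = z_axis``.
    fit_rmsd : float
        Post-fit ring-atom RMSD in Angstrom.
    """

    origin: np.ndarray = field(repr=False)
    x_axis: np.ndarray = field(repr=False)
    y_axis: np.ndarray = field(repr=False)
    z_axis: np.ndarray = field(repr=False)
    fit_rmsd: float = 0.0

    def __post_init__(self):
        for name in ("origin", "x_axis", "y_axis", "z_axis"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,):
                raise ValueError(f"{name} must be a 3-vector")
            object.__setattr__(self, name, v)
        for name in ("x_axis", "y_axis", "z_axis"):
            if abs(np.linalg.norm(getattr(self, name)) - 1.0) > 1e-9:
                raise ValueError(f"{name} is not unit length")
        if np.linalg.norm(np.cross(self.x_axis, self.y_axis) - self.z_axis) > 1e-8:
            raise ValueError("axes are not right-handed (x cross y != z)")
        if self.fit_rmsd < 0:
            raise ValueError("fit_rmsd must be non-negative")

    @property
    def rotation(self) -> np.ndarray:
        """3x3 matrix whose columns are the triad axes."""
        return np.column_stack([self.x_axis, self.y_axis, self.z_axis])


def fit_base_frame(obs_coords: Mapping[str, np.ndarray], std: StandardBase) -> BaseFrame:
    """Fit a standard base onto observed ring-atom coordinates.

    Parameters
    ----------
    obs_coords : mapping of atom name -> (3,) coordinates
        Must contain every ring atom of ``std``; names are matched after
        upper-casing.  Extra atoms are ignored.
    std : StandardBase
        Reference geometry to superpose.

    Returns
    -------
    BaseFrame
        Origin and axes are the images of the standard origin and unit axes
        under the fitted rigid motion; ``fit_rmsd`` is the residual ring-atom
        RMSD.

    Raises
    ------
    FitError
        When a ring atom is absent or the observed atoms are (near-)collinear,
        which leaves the plane normal undetermined.
    """
    lut = {str(k).upper(): np.asarray(v, dtype=float) for k, v in obs_coords.items()}
    missing = [n for n in std.atom_names if n not in lut]
    if missing:
        raise FitError(f"missing ring atom(s) for base {std.base_code}: {', '.join(missing)}")
    obs = np.array([lut[n] for n in std.atom_names], dtype=float)
    if not np.all(np.isfinite(obs)):
        raise FitError("non-finite coordinates in observed base")

    obs_centroid = obs.mean(axis=0)
    obs_c = obs - obs_centroid
    sv = np.linalg.svd(obs_c, compute_uv=False)
    if sv[1] < 1e-6 * max(sv[0], 1.0):
        raise FitError("degenerate (collinear) base coordinates: plane is undetermined")

    # std.coords is already centered on its origin, so the fitted motion maps
    # the standard origin to the observed centroid.
    rot, rssd = Rotation.align_vectors(obs_c, std.coords)
    R = rot.as_matrix()
    rmsd = float(rssd) / np.sqrt(len(std.atom_names))
    return BaseFrame(origin=obs_centroid,
                     x_axis=R[:, 0], y_axis=R[:, 1], z_axis=R[:, 2],
                     fit_rmsd=rmsd)
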