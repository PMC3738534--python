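"""Standard reference geometries for the four DNA nucleobases.

Each base is stored as an idealized, exactly planar ring-atom geometry in a
standard frame: the base plane is the XY plane and the origin is the centroid
of the ring heavy atoms, which serves as the base center in all downstream
frame fitting.  Coordinates derive from the standard reference frame for
nucleic-acid bases established in the crystallographic literature, translated
so the ring centroid sits at the origin and with residual out-of-plane
components (< 0.002 A in the published tables) zeroed.

Only ring heavy atoms are exposed: nine for purines (N1, C2, N3, C4, C5, C6,
N7, C8, N9) and six for pyrimidines (N1, C2, N3, C4, C5, C6).  Exocyclic
substituents (O6, N2, C7/methyl, ...) are deliberately excluded from the
fitting atom set because they bias the best-fit plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StandardBase", "UnsupportedBaseError", "get_standard_base",
           "PURINE_RING_ATOMS", "PYRIMIDINE_RING_ATOMS", "base_code_from_residue_name"]

PURINE_RING_ATOMS = ("N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9")
PYRIMIDINE_RING_ATOMS = ("N1", "C2", "N3", "C4", "C5", "C6")


class UnsupportedBaseError(ValueError):
    """Raised for base codes outside {A, C, G, T}."""


@dataclass(frozen=True)
class StandardBase:
    """Idealized planar geometry of one nucleobase.

    Attributes
    ----------
    base_code : str
        One of ``A``, ``C``, ``G``, ``T``.
    atom_names : tuple of str
        Ordered ring heavy-atom names.
    coords : ndarray, shape (n_atoms, 3)
        Coordinates in Angstrom; all z components are exactly zero and the
        centroid is exactly the origin.
    """

    base_code: str
    atom_names: tuple
    coords: np.ndarray = field(repr=False)

    def __post_init__(self):
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float))
        self.coords.setflags(write=False)
        if len(self.atom_names) != len(set(self.atom_names)):
            raise ValueError(f"duplicate atom names in standard base {self.base_code}")
        if self.coords.shape != (len(self.atom_names), 3):
            raise ValueError("coords shape does not match atom_names")

    @property
    def is_purine(self) -> bool:
        return self.base_code in ("A", "G")


# Standard-frame ring coordinates (x, y) in Angstrom, prior to centering.
_RAW_RING_XY = {
    "A": {
        "N9": (-1.291, 4.498), "C8": (0.024, 4.897), "N7": (0.877, 3.902),
        "C5": (0.071, 2.771), "C6": (0.369, 1.398), "N1": (-0.668, 0.532),
        "C2": (-1.912, 1.023), "N3": (-2.320, 2.290), "C4": (-1.267, 3.124),
    },
    "G": {
        "N9": (-1.289, 4.551), "C8": (0.023, 4.962), "N7": (0.870, 3.969),
        "C5": (0.071, 2.833), "C6": (0.424, 1.460), "N1": (-0.700, 0.641),
        "C2": (-1.999, 1.087), "N3": (-2.342, 2.364), "C4": (-1.265, 3.177),
    },
    "C": {
        "N1": (-1.285, 4.542), "C2": (-1.472, 3.158), "N3": (-0.391, 2.344),
        "C4": (0.837, 2.868), "C5": (1.056, 4.275), "C6": (-0.023, 5.068),
    },
    "T": {
        "N1": (-1.284, 4.500), "C2": (-1.462, 3.135), "N3": (-0.298, 2.407),
        "C4": (0.994, 2.897), "C5": (1.106, 4.338), "C6": (-0.024, 5.057),
    },
}


def _build(code: str) -> StandardBase:
    names = PURINE_RING_ATOMS if code in ("A", "G") else PYRIMIDINE_RING_ATOMS
    xy = np.array([_RAW_RING_XY[code][n] for n in names], dtype=float)
    xy = xy - xy.mean(axis=0)  # origin = ring centroid
    coords = np.column_stack([xy, np.zeros(len(names))])
    return StandardBase(base_code=code, atom_names=names, coords=coords)


_STANDARD_BASES = {code: _build(code) for code in ("A", "C", "G", "T")}

# Residue-name aliases seen in PDB files (D-prefixed, terminal-suffixed, plain).
_RESNAME_TO_CODE = {}
for _code in ("A", "C", "G", "T"):
    for _alias in (_code, "D" + _code, "D" + _code + "5", "D" + _code + "3",
                   _code + "5", _code + "3"):
        _RESNAME_TO_CODE[_alias] = _code
_RESNAME_TO_CODE.update({"ADE": "A", "CYT": "C", "GUA": "G", "THY": "T"})


def get_standard_base(base_code: str) -> StandardBase:
    """Return the embedded standard geometry for one nucleobase.

    Parameters
    ----------
    base_code : str
        Single-letter code, one of ``A``, ``C``, ``G``, ``T`` (case
        insensitive).

    Raises
    ------
    UnsupportedBaseError
        For uracil, modified bases, or anything else outside the four
        canonical DNA bases.
    """
    code = str(base_code).strip().upper()
    if code not in _STANDARD_BASES:
        raise UnsupportedBaseError(
            f"unsupported base code {base_code!r}: expected one of A, C, G, T")
    return _STANDARD_BASES[code]


def base_code_from_residue_name(resname: str) -> str:
    """Map a PDB residue name (``DG``, ``DT5``, ``ADE``, ...) to its base code.

    Raises :class:`UnsupportedBaseError` when the residue is not a canonical
    DNA nucleotide.
    """
    key = str(resname).strip().upper()
    if key not in _RESNAME_TO_CODE:
        raise UnsupportedBaseError(f"residue name {resname!r} is not a canonical DNA base")
    return _RESNAME_TO_CODE[key]
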