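"""Per-amino-acid properties for the reduced chain model.

Each residue carries a hydrophobic weight ``h`` in [0, 1] (Kyte-Doolittle
hydropathy rescaled onto the unit interval), an integer side-chain charge
``q``, and the geometry of its single side-chain interaction site S: the
Ca-S pseudo-bond length approximates the distance from Ca to the
side-chain heavy-atom centroid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = ["ResidueSpec", "RESIDUE_TABLE", "get_residue"]


@dataclass(frozen=True)
class ResidueSpec:
    """Properties of one amino-acid type in the reduced representation."""

    name: str  #: one-letter code
    h: float  #: hydrophobic weight, dimensionless in [0, 1]
    q: int  #: side-chain charge in {-1, 0, +1}
    s_bond: float  #: Ca-S bond length, Angstrom (> 0)
    s_angle: float = math.radians(110.0)  #: N-Ca-S angle, radians

    def __post_init__(self) -> None:
        if not 0.0 <= self.h <= 1.0:
            raise ValueError(f"hydrophobic weight {self.h} outside [0, 1]")
        if abs(self.q) > 1:
            raise ValueError(f"|charge| > 1 for residue {self.name}")
        if self.s_bond <= 0:
            raise ValueError("side-chain bond length must be positive")


# Kyte-Doolittle hydropathy, rescaled h = (kd + 4.5) / 9.0.
_KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

_CHARGE = {"D": -1, "E": -1, "K": 1, "R": 1}

# Approximate Ca -> side-chain-centroid distances (Angstrom).
_S_BOND = {
    "A": 1.5, "R": 4.1, "N": 2.5, "D": 2.5, "C": 2.1,
    "Q": 3.1, "E": 3.1, "G": 1.0, "H": 3.1, "I": 2.3,
    "L": 2.6, "K": 3.5, "M": 2.9, "F": 3.4, "P": 1.9,
    "S": 1.9, "T": 1.9, "W": 3.9, "Y": 3.8, "V": 2.0,
}

RESIDUE_TABLE: dict[str, ResidueSpec] = {
    aa: ResidueSpec(
        name=aa,
        h=round((_KD[aa] + 4.5) / 9.0, 6),
        q=_CHARGE.get(aa, 0),
        s_bond=_S_BOND[aa],
    )
    for aa in _KD
}


def get_residue(letter: str) -> ResidueSpec:
    """Look up the spec for a one-letter amino-acid code."""
    try:
        return RESIDUE_TABLE[letter.upper()]
    except KeyError:
        raise KeyError(f"unknown amino-acid letter {letter!r}") from None


def with_hydrophobicity(spec: ResidueSpec, h: float) -> ResidueSpec:
    """Return a copy of *spec* with hydrophobic weight overridden."""
    return replace(spec, h=h)
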