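"""Reduced-representation polymer geometry.

Chains are built from an amino-acid sequence; each residue contributes
backbone sites N, H, Ca, C, O plus one side-chain site S.  Cartesian
coordinates are a deterministic function of the internal coordinates
(phi, psi, chi per residue), the peptide rigid-body frame, and fixed
ideal bond lengths/angles.  The receptor chain is anchored at its first
residue; the peptide chain carries a rigid-body frame (rotation +
translation) and lives in a periodic cubic box of side L.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from . import _geom
from ._geom import ACA, AH, ATOMS_PER_RES
from .residues import ResidueSpec, get_residue

__all__ = [
    "ChainTopology",
    "ChainSystem",
    "InternalState",
    "Conformation",
    "NativeReference",
    "build_chain",
    "realize_coordinates",
    "chain_coordinates",
    "minimum_image_distance",
    "make_flipped_reference",
    "mutate",
]

Role = Literal["receptor", "peptide"]

#: heavy-atom slots within a residue (everything except the amide H)
HEAVY_SLOTS = np.array([0, 2, 3, 4, 5])


@dataclass(frozen=True)
class ChainTopology:
    """Sequence-level description of one chain."""

    sequence: tuple[ResidueSpec, ...]
    role: Role
    c_terminal_carboxylate: bool = False
    n_terminal_charge: bool = False

    def __post_init__(self) -> None:
        if len(self.sequence) < 2:
            raise ValueError("chain must have at least 2 residues")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def letters(self) -> str:
        return "".join(r.name for r in self.sequence)

    @property
    def n_atoms(self) -> int:
        return len(self.sequence) * ATOMS_PER_RES

    def s_bonds(self) -> np.ndarray:
        return np.array([r.s_bond for r in self.sequence])

    def s_angles(self) -> np.ndarray:
        return np.array([r.s_angle for r in self.sequence])

    def hydrophobicities(self) -> np.ndarray:
        return np.array([r.h for r in self.sequence])

    def charges(self) -> np.ndarray:
        return np.array([r.q for r in self.sequence], dtype=float)


def build_chain(sequence: str | Sequence[ResidueSpec], role: Role) -> ChainTopology:
    """Resolve a one-letter sequence into a :class:`ChainTopology`.

    Peptides carry a charged C-terminal carboxylate and a charged N
    terminus by default, reflecting the free termini of short ligand
    peptides (PDZ ligands bind through their C terminus).
    """
    if role not in ("receptor", "peptide"):
        raise ValueError(f"unknown chain role {role!r}")
    if len(sequence) == 0:
        raise ValueError("empty sequence")
    specs: list[ResidueSpec] = []
    for pos, item in enumerate(sequence):
        if isinstance(item, ResidueSpec):
            specs.append(item)
            continue
        try:
            specs.append(get_residue(item))
        except KeyError:
            raise ValueError(
                f"unknown residue letter {item!r} at position {pos}"
            ) from None
    is_pep = role == "peptide"
    return ChainTopology(
        sequence=tuple(specs),
        role=role,
        c_terminal_carboxylate=is_pep,
        n_terminal_charge=is_pep,
    )


def mutate(topology: ChainTopology, position: int, new_residue: str) -> ChainTopology:
    """Return a topology with the residue at *position* replaced.

    Only the named residue's spec changes; chain role and terminal
    flags are preserved.
    """
    n = len(topology)
    if not -n <= position < n:
        raise IndexError(f"residue position {position} out of range for length {n}")
    position %= n
    spec = get_residue(new_residue)
    seq = list(topology.sequence)
    seq[position] = spec
    return replace(topology, sequence=tuple(seq))


@dataclass(frozen=True)
class NativeReference:
    """Native bound pose and derived reference data for one complex.

    ``contacts`` lists native inter-chain residue pairs
    (receptor_index, peptide_index); ``flipped_coords`` is the
    half-turn-rotated control pose with terminal Ca positions
    exchanged.
    """

    peptide_coords: np.ndarray  #: (n_pep_atoms, 3) native peptide pose
    restraint_centers: np.ndarray  #: (n_rec_res, 3) native receptor Ca
    contacts: np.ndarray  #: (m, 2) int, (receptor residue, peptide residue)
    flipped_coords: np.ndarray | None = None
    receptor_coords: np.ndarray | None = None  #: (n_rec_atoms, 3), optional

    def __post_init__(self) -> None:
        if self.contacts is not None and len(self.contacts) == 0:
            raise ValueError("native contact list is empty for a bound reference")


@dataclass(frozen=True)
class InternalState:
    """Internal-coordinate state: torsions plus the peptide rigid-body frame."""

    torsions: np.ndarray  #: (n_res, 3)
    frame_rotation: np.ndarray  #: (3, 3)
    frame_translation: np.ndarray  #: (3,)


@dataclass(frozen=True)
class ChainSystem:
    """A receptor-peptide pair in a periodic cubic box."""

    receptor: ChainTopology
    peptide: ChainTopology
    box_side: float = 60.0
    receptor_anchor: np.ndarray = field(
        default_factory=lambda: _geom.canonical_anchor() + 30.0
    )
    native: NativeReference | None = None
    native_state: InternalState | None = None  #: internal coords of the native pose

    def __post_init__(self) -> None:
        if self.box_side <= 0:
            raise ValueError("box side must be positive")

    @property
    def n_res(self) -> int:
        return len(self.receptor) + len(self.peptide)

    @property
    def n_atoms(self) -> int:
        return self.n_res * ATOMS_PER_RES

    @property
    def peptide_atom_slice(self) -> slice:
        start = len(self.receptor) * ATOMS_PER_RES
        return slice(start, start + len(self.peptide) * ATOMS_PER_RES)


@dataclass
class Conformation:
    """Realized Cartesian state of a :class:`ChainSystem`."""

    system: ChainSystem
    torsions: np.ndarray  #: (n_res, 3) phi, psi, chi (radians)
    frame_rotation: np.ndarray  #: (3, 3) peptide rigid-body rotation
    frame_translation: np.ndarray  #: (3,) peptide rigid-body translation (Angstrom)
    coords: np.ndarray  #: (n_atoms, 3) derived atom coordinates

    @property
    def box_side(self) -> float:
        return self.system.box_side

    @property
    def peptide_coords(self) -> np.ndarray:
        return self.coords[self.system.peptide_atom_slice]

    @property
    def receptor_coords(self) -> np.ndarray:
        return self.coords[: len(self.system.receptor) * ATOMS_PER_RES]


def chain_coordinates(
    topology: ChainTopology,
    torsions: np.ndarray,
    anchor: np.ndarray | None = None,
) -> np.ndarray:
    """Realize one chain in isolation (chain-local frame by default)."""
    torsions = np.asarray(torsions, dtype=float)
    if torsions.shape != (len(topology), 3):
        raise ValueError(
            f"torsion array shape {torsions.shape} does not match "
            f"({len(topology)}, 3)"
        )
    if anchor is None:
        anchor = _geom.canonical_anchor()
    coords = np.empty((topology.n_atoms, 3))
    _geom.build_chain(
        np.ascontiguousarray(torsions),
        topology.s_bonds(),
        topology.s_angles(),
        np.ascontiguousarray(anchor, dtype=float),
        coords,
        0,
    )
    return coords


def realize_coordinates(
    system: ChainSystem,
    torsions: np.ndarray,
    frame_rotation: np.ndarray | None = None,
    frame_translation: np.ndarray | None = None,
) -> Conformation:
    """Realize the full system from internal coordinates.

    The receptor is anchored at ``system.receptor_anchor``; the peptide
    is built in its local frame and then rigidly transformed by
    (rotation, translation).  Identical inputs give bitwise-identical
    coordinates.
    """
    torsions = np.asarray(torsions, dtype=float)
    if torsions.shape != (system.n_res, 3):
        raise ValueError(
            f"torsion array shape {torsions.shape} does not match ({system.n_res}, 3)"
        )
    if frame_rotation is None:
        frame_rotation = np.eye(3)
    if frame_translation is None:
        frame_translation = np.zeros(3)
    frame_rotation = np.asarray(frame_rotation, dtype=float)
    frame_translation = np.asarray(frame_translation, dtype=float)

    n_rec = len(system.receptor)
    coords = np.empty((system.n_atoms, 3))
    _geom.build_chain(
        np.ascontiguousarray(torsions[:n_rec]),
        system.receptor.s_bonds(),
        system.receptor.s_angles(),
        np.ascontiguousarray(system.receptor_anchor, dtype=float),
        coords,
        0,
    )
    _geom.build_chain(
        np.ascontiguousarray(torsions[n_rec:]),
        system.peptide.s_bonds(),
        system.peptide.s_angles(),
        _geom.canonical_anchor(),
        coords,
        n_rec,
    )
    pep = system.peptide_atom_slice
    coords[pep] = coords[pep] @ frame_rotation.T + frame_translation
    return Conformation(
        system=system,
        torsions=torsions.copy(),
        frame_rotation=frame_rotation.copy(),
        frame_translation=frame_translation.copy(),
        coords=coords,
    )


def minimum_image_distance(a: np.ndarray, b: np.ndarray, L: float) -> float:
    """Distance between *a* and *b* under cubic periodic boundary conditions."""
    if L <= 0:
        raise ValueError("box side must be positive")
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    d -= L * np.round(d / L)
    return float(np.sqrt((d * d).sum()))


def make_flipped_reference(native_coords: np.ndarray) -> np.ndarray:
    """Rotate a peptide pose by a half turn, exchanging terminal Ca positions.

    The rotation axis passes through the midpoint of the first and last
    Ca and is perpendicular to the first->last Ca vector; among the
    perpendicular directions, the one pointing toward the peptide
    centroid is chosen (an arbitrary perpendicular is used if the
    centroid lies on the terminal axis).  The transform is rigid and is
    its own inverse.
    """
    coords = np.asarray(native_coords, dtype=float)
    n_res = coords.shape[0] // ATOMS_PER_RES
    if n_res < 2:
        raise ValueError("flip needs at least 2 residues")
    ca_first = coords[ACA]
    ca_last = coords[(n_res - 1) * ATOMS_PER_RES + ACA]
    v = ca_last - ca_first
    nv = np.linalg.norm(v)
    if nv < 1e-9:
        raise ValueError("degenerate pose: terminal Ca atoms coincide")
    v /= nv
    mid = 0.5 * (ca_first + ca_last)
    w = coords.mean(axis=0) - mid
    w -= v * (w @ v)
    if np.linalg.norm(w) < 1e-9:
        # centroid on the terminal axis: any perpendicular will do
        trial = np.zeros(3)
        trial[int(np.argmin(np.abs(v)))] = 1.0
        w = trial - v * (trial @ v)
    axis = w / np.linalg.norm(w)
    # rotation by pi about `axis`: R = 2 a a^T - I
    R = 2.0 * np.outer(axis, axis) - np.eye(3)
    return (coords - mid) @ R.T + mid
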