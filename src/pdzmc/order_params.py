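"""Structural order parameters for binding progress and peptide nativeness.

The primary pair of reaction coordinates is Q, the fraction of native
inter-chain residue contacts, and Delta_CM, the distance between model
and native peptide centers of mass (computed over the Ca atoms of the
last 4 peptide residues, i.e. the C-terminal window that anchors in the
binding pocket).  Peptide RMSD to the native pose comes in two
flavors: non-optimized (no superposition, so it reports both location
on the receptor surface and internal conformation) and optimized
(minimized over rigid motions of the peptide, the folding-style
measure).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from ._geom import ACA, ATOMS_PER_RES
from .chain import Conformation, HEAVY_SLOTS, NativeReference

__all__ = [
    "AtomSelection",
    "rmsd_nonopt",
    "rmsd_opt",
    "rmsd_opt_batch",
    "fraction_native_contacts",
    "delta_cm",
    "is_bound",
    "radius_of_gyration",
]

DEFAULT_CONTACT_CUTOFF = 4.5  #: heavy-atom native-contact distance (Angstrom)
DEFAULT_BOUND_RCUT = 6.0  #: bound-state non-optimized RMSD cutoff (Angstrom)


@dataclass(frozen=True)
class AtomSelection:
    """Which peptide atoms enter an RMSD-type measure."""

    mode: Literal["all-heavy", "ca"] = "all-heavy"
    residue_range: tuple[int, int] | None = None  #: half-open, peptide-local

    def atom_indices(self, n_res: int) -> np.ndarray:
        """Flat atom indices into an (n_res * 6, 3) peptide coordinate array."""
        lo, hi = self.residue_range if self.residue_range else (0, n_res)
        if not 0 <= lo < hi <= n_res:
            raise ValueError(f"invalid residue range {self.residue_range}")
        res = np.arange(lo, hi)
        if self.mode == "ca":
            return res * ATOMS_PER_RES + ACA
        if self.mode == "all-heavy":
            return (res[:, None] * ATOMS_PER_RES + HEAVY_SLOTS[None, :]).ravel()
        raise ValueError(f"unknown selection mode {self.mode!r}")


def _select(coords: np.ndarray, selection: AtomSelection | None) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if selection is None:
        selection = AtomSelection()
    n_res = coords.shape[-2] // ATOMS_PER_RES
    return coords[..., selection.atom_indices(n_res), :]


def rmsd_nonopt(
    model: np.ndarray,
    native: np.ndarray,
    selection: AtomSelection | None = None,
    box_side: float | None = None,
) -> float:
    """Non-optimized RMSD: sqrt(sum ||r_i - r_i_nat||^2 / n), no superposition.

    With ``box_side`` given, a single common periodic-image shift (the
    one minimizing the mean displacement) is applied to the whole
    model, so a peptide that wrapped across the box compares against
    the nearest image of the native pose.
    """
    p = _select(model, selection)
    q = _select(native, selection)
    if p.shape != q.shape:
        raise ValueError(f"selection shapes differ: {p.shape} vs {q.shape}")
    d = p - q
    if box_side is not None:
        shift = box_side * np.round(d.mean(axis=0) / box_side)
        d = d - shift
    return float(np.sqrt((d * d).sum() / p.shape[0]))


def rmsd_opt(
    model: np.ndarray,
    native: np.ndarray,
    selection: AtomSelection | None = None,
) -> float:
    """Optimized RMSD: minimized over rigid translations/rotations (Kabsch).

    Always <= the non-optimized value; invariant under rigid motion of
    either input.  For collinear atom sets the optimal rotation is not
    unique; the value returned is still the minimum.
    """
    return float(rmsd_opt_batch(np.asarray(model)[None], native, selection)[0])


def rmsd_opt_batch(
    models: np.ndarray,
    native: np.ndarray,
    selection: AtomSelection | None = None,
) -> np.ndarray:
    """Optimized RMSD of a stack of models (m, n_atoms, 3) against one native."""
    p = _select(models, selection)
    q = _select(native, selection)
    if p.shape[-2:] != q.shape:
        raise ValueError(f"selection shapes differ: {p.shape[-2:]} vs {q.shape}")
    n = q.shape[0]
    if n < 3:
        raise ValueError("optimal superposition needs at least 3 atoms")
    pc = p - p.mean(axis=-2, keepdims=True)
    qc = q - q.mean(axis=0)
    # Kabsch via SVD of the covariance, with the proper-rotation sign fix;
    # the MSD is evaluated from explicit rotated residuals (the
    # singular-value form |P|^2 + |Q|^2 - 2 sum(s) cancels catastrophically
    # for near-identical structures)
    h = np.einsum("mni,nj->mij", pc, qc)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(np.einsum("mij,mjk->mik", u, vt)))
    u_adj = u.copy()
    u_adj[:, :, -1] *= d[:, None]
    rot = np.einsum("mij,mjk->mik", u_adj, vt)  # p @ rot best matches q
    resid = np.einsum("mni,mij->mnj", pc, rot) - qc[None, :, :]
    msd = np.einsum("mni,mni->m", resid, resid) / n
    return np.sqrt(np.maximum(msd, 0.0))


def fraction_native_contacts(
    conf: Conformation,
    native: NativeReference,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> float:
    """Fraction Q of native inter-chain contacts present in a conformation.

    Two residues are in contact if any two heavy atoms, one from each,
    are closer than *cutoff* -- the same rule used to define the native
    list.  Q = 1 at the native reference.  Contact entries are
    (receptor residue, peptide residue), each chain-local.
    """
    if len(native.contacts) == 0:
        raise ValueError("empty native contact list")
    n_rec = len(conf.system.receptor)
    box_side = conf.box_side
    c = conf.coords.reshape(-1, ATOMS_PER_RES, 3)[:, HEAVY_SLOTS, :]
    formed = 0
    for ri, pi in native.contacts:
        d = c[n_rec + pi][None, :, :] - c[ri][:, None, :]
        d = d - box_side * np.round(d / box_side)
        if (np.einsum("abk,abk->ab", d, d) < cutoff * cutoff).any():
            formed += 1
    return formed / len(native.contacts)


def delta_cm(
    peptide_coords: np.ndarray,
    native: NativeReference,
    box_side: float | None = None,
) -> float:
    """Distance between model and native peptide centers of mass (Angstrom).

    Both centers are computed over the Ca atoms of the last 4 peptide
    residues; perturbing earlier residues leaves the value unchanged.
    """
    coords = np.asarray(peptide_coords, dtype=float)
    n_res = coords.shape[0] // ATOMS_PER_RES
    if n_res < 4:
        raise ValueError("Delta_CM needs a peptide of at least 4 residues")
    sel = AtomSelection(mode="ca", residue_range=(n_res - 4, n_res))
    idx = sel.atom_indices(n_res)
    d = coords[idx].mean(axis=0) - native.peptide_coords[idx].mean(axis=0)
    if box_side is not None:
        d = d - box_side * np.round(d / box_side)
    return float(np.linalg.norm(d))


def is_bound(
    peptide_coords: np.ndarray,
    native: NativeReference,
    r_cut: float = DEFAULT_BOUND_RCUT,
    box_side: float | None = None,
) -> bool:
    """Bound-state indicator: non-optimized all-heavy RMSD below *r_cut*.

    The non-optimized measure is used deliberately: a small value means
    the peptide sits at the right surface area *and* in a native-like
    internal conformation.  Default cutoff 6 Angstrom; 9 Angstrom is
    the standard sensitivity alternative.
    """
    if r_cut <= 0:
        raise ValueError("bound-state cutoff must be positive")
    return (
        rmsd_nonopt(peptide_coords, native.peptide_coords, box_side=box_side) < r_cut
    )


def radius_of_gyration(peptide_coords: np.ndarray) -> float:
    """Radius of gyration over peptide Ca atoms (Angstrom)."""
    coords = np.asarray(peptide_coords, dtype=float)
    n_res = coords.shape[0] // ATOMS_PER_RES
    ca = coords[AtomSelection(mode="ca").atom_indices(n_res)]
    d = ca - ca.mean(axis=0)
    return float(np.sqrt((d * d).sum() / ca.shape[0]))
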