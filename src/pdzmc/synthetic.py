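"""Synthetic test systems with known ground truth.

Three kinds of generator live here:

* a toy domain-peptide complex -- a 24-residue receptor folded into a
  beta-hairpin plus one alpha-helix forming a binding groove, and a
  5-residue peptide beta-augmenting the hairpin's free strand edge in
  a docked native pose.  Class I-like and class II-like peptides share
  the receptor and differ only at P(-2): polar (Ser) versus
  hydrophobic (Val), mirroring the Ser/Thr-X-Phi versus Phi-X-Phi
  C-terminal motif distinction.  The extra hydrophobic contacts that
  P(-2) makes with the groove in the class II pattern are the designed
  source of the class contrast.
* an exactly enumerable mini-system (one mobile residue on a discrete
  phi/psi grid) whose Boltzmann distribution is computed by full
  enumeration -- the oracle for sampling correctness.
* closed-form synthetic datasets (two-state binding curves and
  exponential relaxation ensembles) with known parameters, for
  fit-recovery studies.

The receptor reference fold and the docked peptide pose were designed
once by constrained energy minimization of the reduced model and are
frozen here as literal internal-coordinate tables, so every generator
is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from . import _geom
from .chain import (
    ChainSystem,
    ChainTopology,
    InternalState,
    NativeReference,
    build_chain,
    make_flipped_reference,
    mutate,
    realize_coordinates,
)
from .energy import EnergyParams, total_energy
from .order_params import DEFAULT_CONTACT_CUTOFF
from .sampling import Mobility, MoveSet, STSchedule
from .thermo import BindingCurve, two_state_model
from ._geom import ATOMS_PER_RES, ACA
from .chain import HEAVY_SLOTS

__all__ = [
    "ToyComplexSpec",
    "EnumerableSpec",
    "EnumerableSystem",
    "RECEPTOR_SEQUENCE",
    "CLASS_I_PEPTIDE",
    "CLASS_II_PEPTIDE",
    "make_toy_complex",
    "make_enumerable_system",
    "make_two_state_samples",
    "make_relaxation_ensemble",
]

#: 24-residue receptor: beta-hairpin (0-17, turn at 8-9) + helix (19-23).
#: Hydrophobic groove residues: L6/I11 at the P(0) pocket, F12/F13 as a
#: double anchor at the P(-2) pocket; K4 sits near the peptide C-terminal
#: carboxylate.
RECEPTOR_SEQUENCE = "ENNNKNLNNNNIFFNVNNNNANNN"
CLASS_I_PEPTIDE = "KASAV"  #: polar P(-2), hydrophobic P(0)
CLASS_II_PEPTIDE = "KAVAV"  #: hydrophobic P(-2) and P(0)

_NATIVE_TORSIONS = [
    (-2.356194, 1.858880, -2.094395),
    (0.124600, 1.226863, -2.094395),
    (2.267893, 1.113748, -2.094395),
    (-1.591424, 2.924985, -2.094395),
    (-2.326815, 2.302131, -2.094395),
    (-2.555119, 2.794158, -2.094395),
    (-2.069212, 2.433680, -2.094395),
    (-2.538510, 2.388764, -2.094395),
    (0.848127, 0.585560, -2.094395),
    (1.324833, -0.220595, -2.094395),
    (-1.496998, 2.420398, -2.094395),
    (-1.421896, 2.256876, -2.094395),
    (-2.489103, 2.622663, 0.698132),
    (3.099261, -2.878355, -1.221730),
    (-2.373417, 1.715996, -2.094395),
    (-2.140130, -0.556174, -2.094395),
    (0.395826, 1.338838, -2.094395),
    (-2.486980, 2.605192, -2.094395),
    (-0.850753, -0.887886, -2.094395),
    (-0.994838, -0.820305, -2.094395),
    (-0.994838, -0.820305, -2.094395),
    (-0.994838, -0.820305, -2.094395),
    (-0.994838, -0.820305, -2.094395),
    (-0.994838, -0.820305, -2.094395),
    (0.000000, 2.370988, -2.094395),
    (-2.358602, 2.353069, -2.094395),
    (-2.316849, 2.359923, -2.094395),
    (-2.408448, 2.324252, -2.094395),
    (-2.302686, 1.893788, -2.094395),
]

_POSE_ROTATION = [
    (-0.542879786, -0.290280455, 0.788047457),
    (-0.818036785, 0.395070340, -0.418013451),
    (-0.189993042, -0.871582861, -0.451935792),
]

_POSE_TRANSLATION = (-2.625572, 13.036814, -3.584607)


@dataclass(frozen=True)
class ToyComplexSpec:
    """Parameters of the toy domain-peptide generator."""

    pattern: Literal["classI", "classII"] = "classI"
    receptor_size: int = 24
    peptide_length: int = 5
    box_side: float = 60.0
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF
    seed: int = 0
    mutations: tuple = ()  #: (chain, position, new_residue) applied before realization

    def __post_init__(self) -> None:
        if self.peptide_length < 4:
            raise ValueError("peptide needs >= 4 residues (Delta_CM window)")
        if (self.receptor_size, self.peptide_length) != (24, 5):
            raise ValueError(
                "the frozen reference fold is defined for a 24-residue "
                "receptor and a 5-residue peptide"
            )


def _native_contacts(coords: np.ndarray, n_rec: int, n_pep: int, cutoff: float) -> np.ndarray:
    c = coords.reshape(-1, ATOMS_PER_RES, 3)[:, HEAVY_SLOTS, :]
    pairs = []
    for ri in range(n_rec):
        for pi in range(n_pep):
            d = c[n_rec + pi][None, :, :] - c[ri][:, None, :]
            if (np.einsum("abk,abk->ab", d, d) < cutoff * cutoff).any():
                pairs.append((ri, pi))
    return np.array(pairs, dtype=np.int64).reshape(-1, 2)


def make_toy_complex(
    spec: ToyComplexSpec, params: EnergyParams | None = None
) -> ChainSystem:
    """Build a toy complex with its native reference, centered in the box.

    The returned system carries the native bound pose (as both
    Cartesian reference and internal coordinates), receptor restraint
    centers, the native inter-chain contact list under the standard
    heavy-atom rule, and the flipped-peptide control pose.
    """
    params = params or EnergyParams()
    receptor = build_chain(RECEPTOR_SEQUENCE, "receptor")
    pep_seq = {"classI": CLASS_I_PEPTIDE, "classII": CLASS_II_PEPTIDE}[spec.pattern]
    peptide = build_chain(pep_seq, "peptide")
    for chain_name, pos, aa in spec.mutations:
        if chain_name == "receptor":
            receptor = mutate(receptor, pos, aa)
        elif chain_name == "peptide":
            peptide = mutate(peptide, pos, aa)
        else:
            raise ValueError(f"unknown chain {chain_name!r}")

    tors = np.array(_NATIVE_TORSIONS)
    pose_R = np.array(_POSE_ROTATION)
    pose_t = np.array(_POSE_TRANSLATION)

    # realize at the design anchor to find the pose, then recenter in the box
    base = ChainSystem(
        receptor=receptor, peptide=peptide, box_side=spec.box_side,
        receptor_anchor=_geom.canonical_anchor(),
    )
    local = realize_coordinates(base, tors)  # identity frame
    frame_t = pose_t - pose_R @ local.peptide_coords.mean(axis=0)
    draft = realize_coordinates(base, tors, pose_R, frame_t)
    shift = np.full(3, spec.box_side / 2.0) - draft.receptor_coords.mean(axis=0)

    anchor = _geom.canonical_anchor() + shift
    system = ChainSystem(
        receptor=receptor, peptide=peptide, box_side=spec.box_side, receptor_anchor=anchor
    )
    native_state = InternalState(
        torsions=tors, frame_rotation=pose_R, frame_translation=frame_t + shift
    )
    conf = realize_coordinates(
        system, tors, native_state.frame_rotation, native_state.frame_translation
    )

    n_rec, n_pep = len(receptor), len(peptide)
    contacts = _native_contacts(conf.coords, n_rec, n_pep, spec.contact_cutoff)
    if len(contacts) == 0:
        raise RuntimeError("generated native pose has no inter-chain contacts")
    if not (contacts[:, 1] == n_pep - 1).any():
        raise RuntimeError("native contact list does not involve the P(0) residue")
    breakdown = total_energy(conf, params)
    if not np.isfinite(breakdown.E_total) or breakdown.E_ev > 5.0:
        raise RuntimeError(
            f"generated native pose clashes (E_ev = {breakdown.E_ev:.2f})"
        )

    ca = conf.coords.reshape(-1, ATOMS_PER_RES, 3)[:n_rec, ACA].copy()
    native = NativeReference(
        peptide_coords=conf.peptide_coords.copy(),
        restraint_centers=ca,
        contacts=contacts,
        flipped_coords=make_flipped_reference(conf.peptide_coords),
        receptor_coords=conf.receptor_coords.copy(),
    )
    return ChainSystem(
        receptor=receptor, peptide=peptide, box_side=spec.box_side,
        receptor_anchor=anchor, native=native, native_state=native_state,
    )


# ---------------------------------------------------------------------------
# exactly enumerable mini-system

@dataclass(frozen=True)
class EnumerableSpec:
    """One mobile residue on a discrete phi/psi grid; everything else frozen."""

    n_grid: int = 12  #: torsion values per angle (state count n_grid**2)
    box_side: float = 30.0
    separation: float = 5.5  #: receptor-to-peptide offset (Angstrom)

    def __post_init__(self) -> None:
        if self.n_grid ** 2 > 10**6:
            raise ValueError("state count exceeds the enumeration bound")


@dataclass(frozen=True)
class EnumerableSystem:
    """A toy system whose Boltzmann distribution is known exactly."""

    system: ChainSystem
    mobility: Mobility
    move_set: MoveSet
    grid: np.ndarray
    energies: np.ndarray  #: (n_grid, n_grid) total energy per (phi, psi) state
    rmsds: np.ndarray = None  #: per-state non-optimized heavy-atom RMSD to native

    def probabilities(self, T: float) -> np.ndarray:
        """Exact Boltzmann state probabilities at temperature T."""
        w = np.exp(-(self.energies - self.energies.min()) / T)
        return w / w.sum()

    def exact_mean_energy(self, T: float) -> float:
        return float((self.probabilities(T) * self.energies).sum())

    def exact_cv(self, T: float, n_res: int | None = None) -> float:
        """Exact specific heat per residue from the enumerated distribution."""
        p = self.probabilities(T)
        e1 = (p * self.energies).sum()
        e2 = (p * self.energies**2).sum()
        n = n_res if n_res is not None else self.system.n_res
        return float((e2 - e1 * e1) / (n * T * T))

    def exact_bound_probability(self, T: float, r_cut: float = 6.0) -> float:
        return float(self.probabilities(T)[self.rmsds < r_cut].sum())


def make_enumerable_system(spec: EnumerableSpec = EnumerableSpec()) -> EnumerableSystem:
    """Build the enumerable fixture and its exact Boltzmann distribution.

    A 2-residue receptor is frozen next to a 2-residue peptide whose
    second residue's (phi, psi) move on an ``n_grid`` x ``n_grid``
    grid; all other degrees of freedom are frozen.  The exact state
    distribution comes from evaluating the full energy at every grid
    point.
    """
    receptor = build_chain("NL", "receptor")
    peptide = build_chain("AV", "peptide")
    ng = spec.n_grid
    grid = -math.pi + 2.0 * math.pi * (np.arange(ng) + 0.5) / ng

    anchor = _geom.canonical_anchor() + spec.box_side / 2.0
    tors = np.zeros((4, 3))
    tors[:, 0] = math.radians(-120.0)
    tors[:, 1] = math.radians(125.0)
    tors[:, 2] = math.radians(-120.0)
    tors[3, 0] = grid[0]
    tors[3, 1] = grid[0]
    system0 = ChainSystem(
        receptor=receptor, peptide=peptide, box_side=spec.box_side,
        receptor_anchor=anchor,
    )
    # place the peptide beside the receptor, offset perpendicular to the chain
    local = realize_coordinates(system0, tors)
    rec_cm = local.receptor_coords.mean(axis=0)
    frame_t = rec_cm + np.array([0.0, 0.0, spec.separation]) - local.peptide_coords.mean(axis=0)

    # restraint centers pin the receptor (it is immobile anyway)
    conf = realize_coordinates(system0, tors, np.eye(3), frame_t)
    ca = conf.coords.reshape(-1, ATOMS_PER_RES, 3)[:2, ACA].copy()
    native = NativeReference(
        peptide_coords=conf.peptide_coords.copy(),
        restraint_centers=ca,
        contacts=np.array([[1, 1]], dtype=np.int64),
        flipped_coords=make_flipped_reference(conf.peptide_coords),
    )
    system = ChainSystem(
        receptor=receptor, peptide=peptide, box_side=spec.box_side,
        receptor_anchor=anchor, native=native,
        native_state=InternalState(tors, np.eye(3), frame_t),
    )

    from .order_params import rmsd_nonopt

    params = EnergyParams()
    energies = np.empty((ng, ng))
    rmsds = np.empty((ng, ng))
    t = tors.copy()
    for i in range(ng):
        for j in range(ng):
            t[3, 0] = grid[i]
            t[3, 1] = grid[j]
            c = realize_coordinates(system, t, np.eye(3), frame_t)
            energies[i, j] = total_energy(c, params).E_total
            rmsds[i, j] = rmsd_nonopt(
                c.peptide_coords, native.peptide_coords, box_side=spec.box_side
            )

    mobility = Mobility(
        chi_rec=np.empty(0, dtype=np.int64),
        chi_pep=np.empty(0, dtype=np.int64),
        backbone_rec=np.empty((0, 2), dtype=np.int64),
        backbone_pep=np.empty((0, 2), dtype=np.int64),
        pivot=np.array([[3, 0], [3, 1]], dtype=np.int64),
        grid=grid,
    )
    move_set = MoveSet(
        rec_sidechain=0.0, rec_backbone=0.0, pep_sidechain=0.0,
        pep_backbone=0.0, pep_pivot=1.0, translate=0.0, rotate=0.0,
    )
    return EnumerableSystem(
        system=system, mobility=mobility, move_set=move_set,
        grid=grid, energies=energies, rmsds=rmsds,
    )


# ---------------------------------------------------------------------------
# closed-form synthetic datasets

def make_two_state_samples(
    X_U: float,
    X_B: float,
    dE: float,
    Tm: float,
    temperatures: Sequence[float],
    n_per_T: int = 100,
    noise: float = 0.0,
    seed: int = 0,
) -> BindingCurve:
    """Synthetic binding curve drawn around the exact two-state model.

    Per-temperature means are the exact curve plus Gaussian noise of
    standard deviation ``noise / sqrt(n_per_T)``; the stored errors are
    set to that standard deviation (zero-noise curves get zero error).
    """
    if dE < 0:
        raise ValueError("dE must be non-negative")
    t = np.asarray(temperatures, dtype=float)
    if (t <= 0).any():
        raise ValueError("temperatures must be positive")
    rng = np.random.default_rng(seed)
    exact = two_state_model(t, X_U, X_B, dE, Tm)
    sem = noise / math.sqrt(n_per_T)
    means = exact + (rng.normal(size=t.shape) * sem if noise > 0 else 0.0)
    return BindingCurve(
        temperatures=t, means=means, errors=np.full_like(t, sem), observable="two-state",
    )


def make_relaxation_ensemble(
    a: float,
    b: float,
    tau: float,
    noise: float,
    n_runs: int,
    steps: np.ndarray,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Ensemble of noisy realizations of a + b exp(-t/tau).

    Returns (steps, values) with values of shape (n_runs, n_points);
    noise is additive white Gaussian per point and run.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    steps = np.asarray(steps, dtype=float)
    rng = np.random.default_rng(seed)
    curve = a + b * np.exp(-steps / tau)
    values = np.tile(curve, (n_runs, 1))
    if noise > 0:
        values = values + rng.normal(size=(n_runs, len(steps))) * noise
    return steps, values
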