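"""Metropolis Monte Carlo engine: move sets, simulated tempering,
fixed-temperature equilibrium runs, and small-step kinetics ensembles.

Temperatures are in model units with k_B = 1.  One elementary MC step
is one attempted conformational move of any type; in simulated
tempering a temperature-index update is additionally attempted every
``st_interval`` steps and treated as an ordinary MC update.

The receptor receives side-chain rotations and semi-local backbone
moves (8 consecutive phi/psi angles turned in a coordinated way); the
peptide additionally receives pivot, rigid-translation and
rigid-rotation moves.  Kinetics mode turns the global pivot move off
and shrinks the translation step from 5 to 1 Angstrom, so relaxation
proceeds through small-step dynamics only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import _geom, _mc
from ._energy import pack_params, reach_array
from .chain import ChainSystem, Conformation, InternalState, realize_coordinates
from .energy import EnergyParams, _charge_sites
from .order_params import DEFAULT_CONTACT_CUTOFF, rmsd_opt_batch, AtomSelection
from ._geom import ATOMS_PER_RES, ACA

__all__ = [
    "MoveSet",
    "STSchedule",
    "Trajectory",
    "Mobility",
    "metropolis_accept",
    "st_temperature_update",
    "propose_move",
    "estimate_st_weights",
    "run_simulated_tempering",
    "run_fixed_T",
    "run_kinetics_ensemble",
    "run_isolated_peptide",
    "random_peptide_state",
]

ENERGY_COLUMNS = [
    "E_hb_intra", "E_hb_inter", "E_hp", "E_el",
    "E_solv", "E_ev", "E_restraint", "E_total",
]
MOVE_NAMES = [
    "rec_sidechain", "rec_backbone", "pep_sidechain", "pep_backbone",
    "pep_pivot", "translate", "rotate", "st",
]


@dataclass(frozen=True)
class MoveSet:
    """Relative move frequencies and step sizes.

    Frequencies need not sum to one; they are normalized after zeroing
    types the system cannot support (e.g. backbone windows on chains
    with fewer than 8 mobile torsions).
    """

    rec_sidechain: float = 0.20
    rec_backbone: float = 0.20
    pep_sidechain: float = 0.10
    pep_backbone: float = 0.20
    pep_pivot: float = 0.15
    translate: float = 0.10
    rotate: float = 0.05
    translation_step: float = 5.0  #: Angstrom
    rotation_step: float = 0.5  #: radians
    sidechain_step: float = 1.0  #: radians
    backbone_step: float = 0.08  #: radians (small: the window still moves all downstream atoms)
    pivot_enabled: bool = True
    backbone_window: int = 8  #: torsions per semi-local move (fixed)

    def __post_init__(self) -> None:
        freqs = self.frequencies()
        if (freqs < 0).any():
            raise ValueError("move frequencies must be non-negative")
        if freqs.sum() == 0:
            raise ValueError("at least one move type must have positive frequency")
        if self.backbone_window != 8:
            raise ValueError("the semi-local backbone window is fixed at 8 torsions")
        if not self.pivot_enabled and self.pep_pivot > 0:
            raise ValueError("pivot frequency must be 0 when pivot is disabled")

    def frequencies(self) -> np.ndarray:
        return np.array(
            [
                self.rec_sidechain, self.rec_backbone, self.pep_sidechain,
                self.pep_backbone, self.pep_pivot, self.translate, self.rotate,
            ]
        )

    @classmethod
    def kinetics(cls, **overrides) -> "MoveSet":
        """Small-step kinetics move set: pivot off, 1 Angstrom translations."""
        defaults = dict(pep_pivot=0.0, pivot_enabled=False, translation_step=1.0)
        defaults.update(overrides)
        return cls(**defaults)


@dataclass(frozen=True)
class STSchedule:
    """Simulated-tempering temperature ladder with free-energy weights g_k."""

    temperatures: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        object.__setattr__(self, "temperatures", t)
        if (np.diff(t) <= 0).any() or (t <= 0).any():
            raise ValueError("temperatures must be positive and strictly increasing")
        w = self.weights
        w = np.zeros_like(t) if w is None else np.asarray(w, dtype=float)
        if w.shape != t.shape:
            raise ValueError("weights shape must match temperatures")
        object.__setattr__(self, "weights", w)

    @classmethod
    def geometric(cls, t_min: float, t_max: float, k: int = 8) -> "STSchedule":
        """Geometric ladder T_k = T_min (T_max/T_min)^((k-1)/(K-1))."""
        if not 0 < t_min < t_max:
            raise ValueError("need 0 < t_min < t_max")
        i = np.arange(k)
        return cls(temperatures=t_min * (t_max / t_min) ** (i / (k - 1)))

    def __len__(self) -> int:
        return len(self.temperatures)


@dataclass(frozen=True)
class Mobility:
    """Which internal coordinates the sampler may move (global residue ids)."""

    chi_rec: np.ndarray
    chi_pep: np.ndarray
    backbone_rec: np.ndarray  #: (n, 2) rows (residue, 0=phi / 1=psi)
    backbone_pep: np.ndarray
    pivot: np.ndarray  #: (n, 2) peptide torsions addressable by pivot moves
    grid: np.ndarray = field(default_factory=lambda: np.empty(0))  #: discrete torsion values

    @classmethod
    def default(cls, n_rec: int, n_pep: int) -> "Mobility":
        def bb(lo: int, n: int) -> np.ndarray:
            rows = []
            for r in range(lo, lo + n):
                if r != lo:
                    rows.append((r, 0))  # phi of the first residue is undefined
                rows.append((r, 1))
            return np.array(rows, dtype=np.int64)

        pep_bb = bb(n_rec, n_pep) if n_pep else np.empty((0, 2), dtype=np.int64)
        return cls(
            chi_rec=np.arange(n_rec, dtype=np.int64),
            chi_pep=np.arange(n_rec, n_rec + n_pep, dtype=np.int64),
            backbone_rec=bb(0, n_rec) if n_rec else np.empty((0, 2), dtype=np.int64),
            backbone_pep=pep_bb,
            pivot=pep_bb.copy(),
        )


@dataclass
class Trajectory:
    """Time-ordered record of one MC run.

    ``df`` has one row per recorded state: step index, temperature
    index k, temperature, the full energy breakdown, and the order
    parameters.  ``pep_coords`` holds the matching peptide snapshots
    (empty when snapshot storage was disabled).
    """

    df: pd.DataFrame
    meta: dict
    pep_coords: np.ndarray
    min_energy: float
    min_coords: np.ndarray
    state_index: np.ndarray | None = None  #: discrete-grid state ids (enumerable runs)
    visits: np.ndarray | None = None  #: per-grid-state visit counts (every step)

    def __post_init__(self) -> None:
        steps = self.df["step"].to_numpy()
        if (np.diff(steps) <= 0).any():
            raise ValueError("record steps must be strictly increasing")

    @property
    def temperatures(self) -> np.ndarray:
        return np.asarray(self.meta["temperatures"])

    def acceptance_rates(self) -> dict[str, float]:
        att = np.asarray(self.meta["attempted"], dtype=float)
        acc = np.asarray(self.meta["accepted"], dtype=float)
        with np.errstate(invalid="ignore"):
            rates = np.where(att > 0, acc / np.maximum(att, 1), np.nan)
        return dict(zip(MOVE_NAMES, rates))


def metropolis_accept(delta_e: float, T: float, rng: np.random.Generator) -> bool:
    """Metropolis criterion: accept with probability min(1, exp(-dE/T))."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    if not math.isfinite(delta_e):
        return False
    return delta_e <= 0 or rng.random() < math.exp(-delta_e / T)


def st_temperature_update(
    energy: float, k: int, schedule: STSchedule, rng: np.random.Generator
) -> int:
    """One simulated-tempering index update (+-1 neighbor proposal).

    Accepts with min(1, exp[-E (1/T_new - 1/T_old) + g_new - g_old]).
    """
    kn = k + (1 if rng.random() < 0.5 else -1)
    if not 0 <= kn < len(schedule):
        return k
    t = schedule.temperatures
    g = schedule.weights
    x = -energy * (1.0 / t[kn] - 1.0 / t[k]) + g[kn] - g[k]
    if x >= 0 or rng.random() < math.exp(x):
        return kn
    return k


def propose_move(
    rng: np.random.Generator, move_set: MoveSet, n_rec: int, n_pep: int
) -> tuple[str, dict]:
    """Draw one move descriptor with the configured type frequencies.

    Mirrors the compiled engine's proposal distributions; used for
    direct statistical checks of the move generator.
    """
    freqs = move_set.frequencies()
    freqs = freqs / freqs.sum()
    kind = MOVE_NAMES[rng.choice(7, p=freqs)]
    payload: dict = {}
    if kind == "translate":
        payload["delta"] = (2 * rng.random(3) - 1) * move_set.translation_step
    elif kind == "rotate":
        payload["angle"] = (2 * rng.random() - 1) * move_set.rotation_step
    elif kind in ("rec_backbone", "pep_backbone"):
        g = rng.normal(size=8) * move_set.backbone_step
        payload["deltas"] = g - g.mean()
    elif kind in ("rec_sidechain", "pep_sidechain"):
        payload["delta"] = (2 * rng.random() - 1) * move_set.sidechain_step
    return kind, payload


# ---------------------------------------------------------------------------
# engine wrapper

def _adjusted_frequencies(move_set: MoveSet, mob: Mobility) -> np.ndarray:
    f = move_set.frequencies().copy()
    if len(mob.chi_rec) == 0:
        f[0] = 0.0
    if len(mob.backbone_rec) < 8:
        f[1] = 0.0
    if len(mob.chi_pep) == 0:
        f[2] = 0.0
    if len(mob.backbone_pep) < 8:
        f[3] = 0.0
    if len(mob.pivot) == 0:
        f[4] = 0.0
    if f.sum() <= 0:
        raise ValueError("no supported move type has positive frequency")
    return f / f.sum()


def _initial_state(
    system: ChainSystem,
    init: InternalState | Literal["native", "random"],
    rng: np.random.Generator,
    clearance: float = 0.0,
) -> InternalState:
    if isinstance(init, InternalState):
        return init
    if init == "native":
        if system.native_state is None:
            raise ValueError("system has no native internal state; pass one explicitly")
        return system.native_state
    if init == "random":
        return random_peptide_state(system, rng, clearance=clearance)
    raise ValueError(f"unknown init {init!r}")


def random_peptide_state(
    system: ChainSystem,
    rng: np.random.Generator,
    clearance: float = 10.0,
    max_tries: int = 2000,
) -> InternalState:
    """Random peptide conformation and placement away from the receptor.

    The receptor sits at its native internal coordinates; the peptide
    receives uniform random torsions, a uniform random orientation and
    a position such that every peptide atom is at least *clearance*
    from every receptor atom (minimum image).
    """
    if system.native_state is None:
        raise ValueError("receptor native torsions are required for placement")
    n_rec = len(system.receptor)
    tors = system.native_state.torsions.copy()
    L = system.box_side
    rec_heavy = None
    for _ in range(max_tries):
        tors[n_rec:] = rng.uniform(-math.pi, math.pi, size=(len(system.peptide), 3))
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        R = np.array(
            [
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ]
        )
        t = rng.uniform(0.0, L, size=3)
        conf = realize_coordinates(system, tors, R, t)
        if n_rec == 0:
            return InternalState(tors.copy(), R, t)
        if rec_heavy is None:
            rec_heavy = conf.receptor_coords
        d = conf.peptide_coords[:, None, :] - rec_heavy[None, :, :]
        d -= L * np.round(d / L)
        if (np.einsum("ijk,ijk->ij", d, d) >= clearance * clearance).all():
            return InternalState(tors.copy(), R, t)
    raise RuntimeError(
        f"could not place the peptide with {clearance} A clearance "
        f"in a box of side {L} A after {max_tries} tries"
    )


def _pack_system(system: ChainSystem):
    n_rec = len(system.receptor)
    n_pep = len(system.peptide)
    h = np.concatenate(
        [system.receptor.hydrophobicities(), system.peptide.hydrophobicities()]
    )
    sbond = np.concatenate([system.receptor.s_bonds(), system.peptide.s_bonds()])
    sangle = np.concatenate([system.receptor.s_angles(), system.peptide.s_angles()])
    c_atom, c_q, c_res = _charge_sites(system)
    native = system.native
    if native is not None:
        centers = np.ascontiguousarray(native.restraint_centers, dtype=float)
        nat_pep = np.ascontiguousarray(native.peptide_coords, dtype=float)
        contacts = np.ascontiguousarray(native.contacts, dtype=np.int64).reshape(-1, 2).copy()
        contacts[:, 1] += n_rec  # chain-local -> global residue ids
    else:
        centers = np.zeros((0, 3))
        nat_pep = np.zeros((n_pep * ATOMS_PER_RES, 3))
        contacts = np.empty((0, 2), dtype=np.int64)
    return {
        "n_rec": n_rec,
        "n_pep": n_pep,
        "h": h,
        "sbond": sbond,
        "sangle": sangle,
        "anchor": np.ascontiguousarray(system.receptor_anchor, dtype=float),
        "canon": _geom.canonical_anchor(),
        "c_atom": c_atom.astype(np.int64),
        "c_q": c_q.astype(float),
        "c_res": c_res.astype(np.int64),
        "centers": centers,
        "nat_pep": nat_pep,
        "contacts": contacts,
    }


def _run_engine(
    system: ChainSystem,
    params: EnergyParams,
    temps: np.ndarray,
    weights: np.ndarray,
    k0: int,
    st_interval: int,
    n_steps: int,
    seed: int,
    move_set: MoveSet,
    record_every: int,
    init_state: InternalState,
    mobility: Mobility | None,
    store_snapshots: bool,
    contact_cutoff: float,
    mode: str,
) -> Trajectory:
    pk = _pack_system(system)
    n_rec, n_pep = pk["n_rec"], pk["n_pep"]
    mob = mobility if mobility is not None else Mobility.default(n_rec, n_pep)
    freqs = _adjusted_frequencies(move_set, mob)
    cum = np.cumsum(freqs)
    prm, radii = pack_params(params, system.box_side)

    tors = np.ascontiguousarray(init_state.torsions, dtype=float).copy()
    frameR = np.ascontiguousarray(init_state.frame_rotation, dtype=float).copy()
    framet = np.ascontiguousarray(init_state.frame_translation, dtype=float).copy()

    ns = n_steps // record_every + 1
    npa = n_pep * ATOMS_PER_RES
    rec_step = np.zeros(ns, dtype=np.int64)
    rec_k = np.zeros(ns, dtype=np.int64)
    rec_comps = np.zeros((ns, 8))
    rec_q = np.zeros(ns)
    rec_rmsd = np.zeros(ns)
    rec_dcm = np.zeros(ns)
    rec_pep = np.zeros((ns, npa * 3) if store_snapshots else (1, 1))
    rec_state = np.full(ns, -1, dtype=np.int64)
    ng = len(mob.grid)
    n_grid_states = ng ** min(len(mob.pivot), 2) if ng else 0
    visits = np.zeros(max(n_grid_states, 1), dtype=np.int64)
    att = np.zeros(8, dtype=np.int64)
    acc = np.zeros(8, dtype=np.int64)
    min_out = np.zeros(1)
    min_coords = np.zeros(((n_rec + n_pep) * ATOMS_PER_RES, 3))

    k_final = _mc.run_mc(
        n_rec, n_rec + n_pep, pk["h"], pk["sbond"], pk["sangle"], pk["anchor"],
        pk["canon"], pk["c_atom"], pk["c_q"], pk["c_res"], pk["centers"], prm, radii,
        reach_array(pk["sbond"]), pk["nat_pep"], pk["contacts"], contact_cutoff,
        mob.chi_rec, mob.chi_pep, mob.backbone_rec, mob.backbone_pep,
        mob.pivot, np.ascontiguousarray(mob.grid, dtype=float),
        cum, move_set.translation_step, move_set.rotation_step,
        move_set.sidechain_step, move_set.backbone_step,
        np.ascontiguousarray(temps, dtype=float),
        np.ascontiguousarray(weights, dtype=float),
        k0, st_interval, n_steps, record_every, int(store_snapshots),
        int(seed) & 0x7FFFFFFF,
        tors, frameR, framet,
        rec_step, rec_k, rec_comps, rec_q, rec_rmsd, rec_dcm, rec_pep, rec_state,
        visits, att, acc, min_out, min_coords,
    )

    df = pd.DataFrame({"step": rec_step, "k": rec_k, "T": temps[rec_k]})
    for i, col in enumerate(ENERGY_COLUMNS):
        df[col] = rec_comps[:, i]
    df["Q"] = rec_q
    df["rmsd"] = rec_rmsd
    df["dcm"] = rec_dcm
    pep_snap = rec_pep.reshape(ns, npa, 3) if store_snapshots else np.empty((0, npa, 3))
    if store_snapshots and n_pep >= 1:
        nat = pk["nat_pep"]
        if np.any(nat):
            df["rmsd_opt"] = rmsd_opt_batch(pep_snap, nat)
        ca = pep_snap[:, ACA::ATOMS_PER_RES, :]
        dev = ca - ca.mean(axis=1, keepdims=True)
        df["rg"] = np.sqrt(np.einsum("mni,mni->m", dev, dev) / ca.shape[1])

    meta = {
        "mode": mode,
        "seed": int(seed),
        "n_steps": int(n_steps),
        "record_every": int(record_every),
        "temperatures": np.asarray(temps, dtype=float).tolist(),
        "weights": np.asarray(weights, dtype=float).tolist(),
        "st_interval": int(st_interval),
        "k_final": int(k_final),
        "attempted": att.tolist(),
        "accepted": acc.tolist(),
        "contact_cutoff": float(contact_cutoff),
        "final_state": InternalState(tors, frameR, framet),
        "move_set": move_set,
    }
    return Trajectory(
        df=df,
        meta=meta,
        pep_coords=pep_snap,
        min_energy=float(min_out[0]),
        min_coords=min_coords,
        state_index=rec_state if ng else None,
        visits=visits if ng else None,
    )


def run_fixed_T(
    system: ChainSystem,
    params: EnergyParams,
    T: float,
    n_steps: int,
    seed: int,
    move_set: MoveSet | None = None,
    record_every: int = 100,
    init: InternalState | str = "native",
    mobility: Mobility | None = None,
    store_snapshots: bool = True,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> Trajectory:
    """One fixed-temperature equilibrium MC run."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    rng = np.random.default_rng(seed)
    state = _initial_state(system, init, rng)
    return _run_engine(
        system, params, np.array([T]), np.array([0.0]), 0, 0, n_steps,
        seed, move_set or MoveSet(), record_every, state, mobility,
        store_snapshots, contact_cutoff, mode="fixed",
    )


def run_simulated_tempering(
    system: ChainSystem,
    params: EnergyParams,
    schedule: STSchedule,
    n_steps: int,
    seed: int,
    move_set: MoveSet | None = None,
    record_every: int = 100,
    st_interval: int = 10,
    init: InternalState | str = "native",
    mobility: Mobility | None = None,
    store_snapshots: bool = True,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
    k0: int | None = None,
) -> Trajectory:
    """One simulated-tempering run over the schedule's temperature ladder."""
    rng = np.random.default_rng(seed)
    state = _initial_state(system, init, rng)
    if k0 is None:
        k0 = len(schedule) // 2
    return _run_engine(
        system, params, schedule.temperatures, schedule.weights, k0,
        st_interval, n_steps, seed, move_set or MoveSet(), record_every,
        state, mobility, store_snapshots, contact_cutoff, mode="st",
    )


def run_kinetics_ensemble(
    system: ChainSystem,
    params: EnergyParams,
    T: float,
    n_runs: int,
    n_steps: int,
    seed: int,
    move_set: MoveSet | None = None,
    record_every: int = 500,
    clearance: float = 10.0,
    mobility: Mobility | None = None,
    store_snapshots: bool = False,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> list[Trajectory]:
    """Ensemble of independent small-step binding-relaxation runs.

    Each run starts from an independent random peptide conformation
    with every peptide atom at least *clearance* from the receptor,
    and evolves with the kinetics move set (pivot off, 1 Angstrom
    translation steps).
    """
    ms = move_set or MoveSet.kinetics()
    if ms.pivot_enabled or ms.pep_pivot > 0:
        raise ValueError("kinetics runs require the pivot move to be off")
    out = []
    for i in range(n_runs):
        sub = (int(seed) * 1000003 + 7919 * i + 1) % (2**31)
        rng = np.random.default_rng(sub)
        state = random_peptide_state(system, rng, clearance=clearance)
        out.append(
            _run_engine(
                system, params, np.array([T]), np.array([0.0]), 0, 0, n_steps,
                sub, ms, record_every, state, mobility, store_snapshots,
                contact_cutoff, mode="kinetics",
            )
        )
    return out


def run_isolated_peptide(
    peptide,
    params: EnergyParams,
    T: float,
    n_steps: int,
    seed: int,
    box_side: float = 60.0,
    move_set: MoveSet | None = None,
    record_every: int = 100,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> Trajectory:
    """Equilibrium run of a peptide chain alone in the box.

    The reference conformational behavior of the free peptide (e.g.
    its radius of gyration against temperature); RMSD-type columns are
    reported against the initial extended conformation and carry no
    binding meaning here.
    """
    from .chain import ChainTopology

    if isinstance(peptide, ChainSystem):
        peptide = peptide.peptide
    if not isinstance(peptide, ChainTopology):
        raise TypeError("expected a peptide ChainTopology or a ChainSystem")
    n_pep = len(peptide)
    rng = np.random.default_rng(seed)
    tors = np.zeros((n_pep, 3))
    tors[:, 0] = math.radians(-120.0)
    tors[:, 1] = math.radians(125.0)
    tors[:, 2] = math.radians(-120.0)
    # dummy empty receptor: the kernel supports n_rec = 0 directly
    h = peptide.hydrophobicities()
    sbond = peptide.s_bonds()
    sangle = peptide.s_angles()
    atoms, qs, res_idx = [], [], []
    for i, spec in enumerate(peptide.sequence):
        if spec.q != 0:
            atoms.append(i * ATOMS_PER_RES + 5)
            qs.append(float(spec.q))
            res_idx.append(i)
    if peptide.n_terminal_charge:
        atoms.append(0)
        qs.append(1.0)
        res_idx.append(0)
    if peptide.c_terminal_carboxylate:
        atoms.append((n_pep - 1) * ATOMS_PER_RES + 4)
        qs.append(-1.0)
        res_idx.append(n_pep - 1)
    prm, radii = pack_params(params, box_side)
    mob = Mobility.default(0, n_pep)
    ms = move_set or MoveSet()
    freqs = _adjusted_frequencies(ms, mob)
    cum = np.cumsum(freqs)

    frameR = np.eye(3)
    framet = np.full(3, box_side / 2.0)
    ns = n_steps // record_every + 1
    npa = n_pep * ATOMS_PER_RES
    rec_step = np.zeros(ns, dtype=np.int64)
    rec_k = np.zeros(ns, dtype=np.int64)
    rec_comps = np.zeros((ns, 8))
    rec_q = np.zeros(ns)
    rec_rmsd = np.zeros(ns)
    rec_dcm = np.zeros(ns)
    rec_pep = np.zeros((ns, npa * 3))
    rec_state = np.full(ns, -1, dtype=np.int64)
    visits = np.zeros(1, dtype=np.int64)
    att = np.zeros(8, dtype=np.int64)
    acc = np.zeros(8, dtype=np.int64)
    min_out = np.zeros(1)
    min_coords = np.zeros((npa, 3))

    # native reference = the initial extended realization
    init_coords = np.zeros((npa, 3))
    _geom.build_chain(tors, sbond, sangle, _geom.canonical_anchor(), init_coords, 0)
    nat_pep = init_coords @ frameR.T + framet

    _mc.run_mc(
        0, n_pep, h, sbond, sangle, _geom.canonical_anchor(), _geom.canonical_anchor(),
        np.asarray(atoms, dtype=np.int64), np.asarray(qs, dtype=float),
        np.asarray(res_idx, dtype=np.int64), np.zeros((0, 3)), prm, radii,
        reach_array(sbond), nat_pep, np.empty((0, 2), dtype=np.int64), contact_cutoff,
        mob.chi_rec, mob.chi_pep, mob.backbone_rec, mob.backbone_pep,
        mob.pivot, np.empty(0),
        cum, ms.translation_step, ms.rotation_step, ms.sidechain_step, ms.backbone_step,
        np.array([float(T)]), np.array([0.0]), 0, 0, n_steps, record_every, 1,
        int(seed) & 0x7FFFFFFF,
        tors, frameR, framet,
        rec_step, rec_k, rec_comps, rec_q, rec_rmsd, rec_dcm, rec_pep, rec_state,
        visits, att, acc, min_out, min_coords,
    )
    df = pd.DataFrame({"step": rec_step, "k": rec_k, "T": float(T)})
    for i, col in enumerate(ENERGY_COLUMNS):
        df[col] = rec_comps[:, i]
    df["Q"] = rec_q
    df["rmsd"] = rec_rmsd
    df["dcm"] = rec_dcm
    pep_snap = rec_pep.reshape(ns, npa, 3)
    ca = pep_snap[:, ACA::ATOMS_PER_RES, :]
    dev = ca - ca.mean(axis=1, keepdims=True)
    df["rg"] = np.sqrt(np.einsum("mni,mni->m", dev, dev) / ca.shape[1])
    meta = {
        "mode": "isolated",
        "seed": int(seed),
        "n_steps": int(n_steps),
        "record_every": int(record_every),
        "temperatures": [float(T)],
        "weights": [0.0],
        "st_interval": 0,
        "k_final": 0,
        "attempted": att.tolist(),
        "accepted": acc.tolist(),
        "contact_cutoff": float(contact_cutoff),
        "move_set": ms,
    }
    return Trajectory(
        df=df, meta=meta, pep_coords=pep_snap,
        min_energy=float(min_out[0]), min_coords=min_coords,
    )


def estimate_st_weights(
    pilots: Sequence[Trajectory] | Trajectory,
    schedule: STSchedule,
    equilibration: float = 0.2,
) -> STSchedule:
    """Set ST weights by trapezoidal integration of <E> over inverse temperature.

    Uniform temperature occupancy requires g_k = -ln Z_k (up to a
    constant); since d(-ln Z)/d(beta) = <E>, the weights follow from
    the pilot mean energies by the trapezoid rule on the beta grid.
    Pilot data may be per-temperature fixed-T runs or a single ST run
    (conditional means per temperature index are used).
    """
    t = schedule.temperatures
    means = np.full(len(t), np.nan)
    trajs = [pilots] if isinstance(pilots, Trajectory) else list(pilots)
    if len(trajs) == 0:
        raise ValueError("no pilot data")
    for traj in trajs:
        df = traj.df.iloc[int(len(traj.df) * equilibration):]
        for k in range(len(t)):
            sel = df[np.isclose(df["T"], t[k])]
            if len(sel):
                prev = means[k]
                m = float(sel["E_total"].mean())
                means[k] = m if np.isnan(prev) else 0.5 * (prev + m)
    if np.isnan(means).any():
        # fall back to interpolation over visited temperatures
        ok = ~np.isnan(means)
        if ok.sum() < 2:
            raise ValueError("pilot data covers fewer than 2 temperatures")
        means = np.interp(1.0 / t, 1.0 / t[ok][::-1], means[ok][::-1])
    beta = 1.0 / t
    g = np.zeros(len(t))
    for k in range(1, len(t)):
        g[k] = g[k - 1] + 0.5 * (means[k - 1] + means[k]) * (beta[k] - beta[k - 1])
    return replace(schedule, weights=g - g[0])
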