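"""File formats: PDB structures, trajectory tables, run configuration.

PDB reading maps an experimental structure onto the reduced
representation: backbone N/Ca/C/O are taken as-is to extract phi/psi,
the side-chain interaction site is placed at the side-chain heavy-atom
centroid (Cb direction for glycine-like cases), and the amide H is
rebuilt from ideal geometry.  The native reference realized from those
internal coordinates therefore has ideal bond lengths/angles rather
than the crystallographic ones.

Trajectories are versioned, self-describing tab-separated text; a
record-count header makes truncation detectable on read.
"""

from __future__ import annotations

import io as _io
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
import biotite.structure as bst
import biotite.structure.io.pdb as bpdb

from . import _geom
from ._geom import ACA, AC, AH, AN, AO, AS, ATOMS_PER_RES
from .chain import (
    ChainSystem,
    Conformation,
    InternalState,
    NativeReference,
    build_chain,
    make_flipped_reference,
    realize_coordinates,
)
from .energy import EnergyParams
from .order_params import DEFAULT_CONTACT_CUTOFF
from .sampling import MoveSet, Trajectory

__all__ = [
    "read_structure",
    "write_pdb",
    "write_trajectory",
    "read_trajectory",
    "RunConfig",
    "load_config",
    "save_config",
]

TRAJ_FORMAT_VERSION = 1

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def _chain_internal_coords(atoms: bst.AtomArray) -> tuple[str, np.ndarray]:
    """Extract sequence and (phi, psi, chi) torsions from one PDB chain."""
    res_ids = np.unique(atoms.res_id)
    seq = []
    backbone = []  # per residue: N, CA, C positions
    side_centroids = []
    for rid in res_ids:
        res = atoms[atoms.res_id == rid]
        name = res.res_name[0]
        if name not in _THREE_TO_ONE:
            raise ValueError(f"non-standard residue {name} at res_id {rid}")
        seq.append(_THREE_TO_ONE[name])
        bb = {}
        for at in ("N", "CA", "C"):
            hit = res[res.atom_name == at]
            if len(hit) == 0:
                raise ValueError(f"missing backbone atom {at} at res_id {rid}")
            bb[at] = hit.coord[0]
        backbone.append((bb["N"], bb["CA"], bb["C"]))
        side = res[
            ~np.isin(res.atom_name, ("N", "CA", "C", "O", "OXT"))
            & (res.element != "H")
        ]
        if len(side):
            side_centroids.append(side.coord.mean(axis=0))
        else:  # glycine: pseudo-site 1 A from Ca, away from the backbone
            n, ca, c = bb["N"], bb["CA"], bb["C"]
            v = ca - 0.5 * (n + c)
            side_centroids.append(ca + v / np.linalg.norm(v))
    n_res = len(seq)
    tors = np.zeros((n_res, 3))
    for i in range(n_res):
        n, ca, c = backbone[i]
        if i > 0:
            c_prev = backbone[i - 1][2]
            tors[i, 0] = _geom.dihedral(c_prev, n, ca, c)
        if i < n_res - 1:
            n_next = backbone[i + 1][0]
            tors[i, 1] = _geom.dihedral(n, ca, c, n_next)
        else:
            tors[i, 1] = math.radians(125.0)  # terminal psi is arbitrary
        # chi convention: dihedral(C, N, Ca, S)
        tors[i, 2] = _geom.dihedral(c, n, ca, side_centroids[i])
    return "".join(seq), tors


def read_structure(
    path: str | Path,
    receptor_chain: str,
    peptide_chain: str | None = None,
    box_side: float = 60.0,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> ChainSystem:
    """Load receptor (and optionally peptide) chains from a PDB file.

    Only ATOM records are used; altloc A is kept; insertion codes are
    rejected.  When both chains are given, the realized bound pose
    defines the native reference (restraint centers, contact list,
    flipped control).
    """
    pdb = bpdb.PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1, altloc="first")
    atoms = atoms[np.isin(atoms.ins_code, ("", " ")) | (atoms.ins_code == "")]
    if np.any(atoms.ins_code != ""):
        raise ValueError("insertion codes are not supported")
    atoms = atoms[~atoms.hetero]
    available = sorted(set(atoms.chain_id))
    wanted = [receptor_chain] + ([peptide_chain] if peptide_chain else [])
    for cid in wanted:
        if cid not in available:
            raise ValueError(
                f"chain {cid!r} not found; available chains: {available}"
            )

    rec_seq, rec_tors = _chain_internal_coords(atoms[atoms.chain_id == receptor_chain])
    receptor = build_chain(rec_seq, "receptor")
    if peptide_chain is None:
        system = ChainSystem(
            receptor=receptor,
            peptide=build_chain("GG", "peptide"),
            box_side=box_side,
        )
        return system

    pep_seq, pep_tors = _chain_internal_coords(atoms[atoms.chain_id == peptide_chain])
    peptide = build_chain(pep_seq, "peptide")
    tors = np.vstack([rec_tors, pep_tors])

    # realize the receptor at the PDB anchor, recentered in the box later;
    # the peptide frame reproduces its PDB placement via superposition
    rec_atoms = atoms[atoms.chain_id == receptor_chain]
    first = rec_atoms[rec_atoms.res_id == np.min(rec_atoms.res_id)]
    anchor = np.array(
        [
            first[first.atom_name == "N"].coord[0],
            first[first.atom_name == "CA"].coord[0],
            first[first.atom_name == "C"].coord[0],
        ],
        dtype=float,
    )
    base = ChainSystem(
        receptor=receptor, peptide=peptide, box_side=box_side, receptor_anchor=anchor
    )
    local = realize_coordinates(base, tors)
    # superpose the realized peptide backbone onto the PDB peptide backbone
    pep_atoms = atoms[atoms.chain_id == peptide_chain]
    tgt = []
    for rid in np.unique(pep_atoms.res_id):
        res = pep_atoms[pep_atoms.res_id == rid]
        for at in ("N", "CA", "C"):
            tgt.append(res[res.atom_name == at].coord[0])
    tgt = np.asarray(tgt, dtype=float)
    src = local.peptide_coords.reshape(-1, ATOMS_PER_RES, 3)[:, (AN, ACA, AC), :].reshape(-1, 3)
    sc, tc = src.mean(axis=0), tgt.mean(axis=0)
    H = (src - sc).T @ (tgt - tc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = tc - R @ sc

    # recenter the whole complex in the box
    draft = realize_coordinates(base, tors, R, t)
    shift = np.full(3, box_side / 2.0) - draft.receptor_coords.mean(axis=0)
    system = ChainSystem(
        receptor=receptor, peptide=peptide, box_side=box_side,
        receptor_anchor=anchor + shift,
    )
    conf = realize_coordinates(system, tors, R, t + shift)
    from .synthetic import _native_contacts  # standard heavy-atom contact rule

    contacts = _native_contacts(conf.coords, len(receptor), len(peptide), contact_cutoff)
    native = NativeReference(
        peptide_coords=conf.peptide_coords.copy(),
        restraint_centers=conf.coords.reshape(-1, ATOMS_PER_RES, 3)[: len(receptor), ACA].copy(),
        contacts=contacts,
        flipped_coords=make_flipped_reference(conf.peptide_coords),
        receptor_coords=conf.receptor_coords.copy(),
    )
    return ChainSystem(
        receptor=receptor, peptide=peptide, box_side=box_side,
        receptor_anchor=anchor + shift, native=native,
        native_state=InternalState(tors, R, t + shift),
    )


_SLOT_NAMES = ("N", "H", "CA", "C", "O", "CB")


def write_pdb(conf: Conformation, path: str | Path) -> None:
    """Write a snapshot in PDB format (side-chain site as pseudo-atom CB)."""
    system = conf.system
    n_rec = len(system.receptor)
    n_res = system.n_res
    n_atoms = n_res * ATOMS_PER_RES
    arr = bst.AtomArray(n_atoms)
    one_to_three = {v: k for k, v in _THREE_TO_ONE.items()}
    seqs = list(system.receptor.sequence) + list(system.peptide.sequence)
    for res in range(n_res):
        local = res if res < n_rec else res - n_rec
        for slot in range(ATOMS_PER_RES):
            i = res * ATOMS_PER_RES + slot
            arr.chain_id[i] = "R" if res < n_rec else "P"
            arr.res_id[i] = local + 1
            arr.res_name[i] = one_to_three[seqs[res].name]
            arr.atom_name[i] = _SLOT_NAMES[slot]
            arr.element[i] = _SLOT_NAMES[slot][0]
            arr.hetero[i] = False
    arr.coord = conf.coords.astype(np.float32)
    out = bpdb.PDBFile()
    out.set_structure(arr)
    out.write(str(path))


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as self-describing tab-separated text."""
    meta = {
        k: v
        for k, v in traj.meta.items()
        if k not in ("final_state", "move_set")
    }
    meta["format_version"] = TRAJ_FORMAT_VERSION
    meta["n_records"] = int(len(traj.df))
    meta["min_energy"] = float(traj.min_energy)
    with open(path, "w") as fh:
        fh.write(f"# pdzmc trajectory v{TRAJ_FORMAT_VERSION}\n")
        fh.write("# meta " + json.dumps(meta, sort_keys=True) + "\n")
        traj.df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_trajectory(path: str | Path) -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory`.

    Fails loudly on version mismatch or truncation (record count is
    checked against the header), and round-trips all columns to full
    precision.
    """
    with open(path) as fh:
        head = fh.readline()
        if not head.startswith("# pdzmc trajectory v"):
            raise ValueError(f"{path}: not a pdzmc trajectory file")
        version = int(head.rsplit("v", 1)[1])
        if version != TRAJ_FORMAT_VERSION:
            raise ValueError(
                f"{path}: format version {version} != {TRAJ_FORMAT_VERSION}"
            )
        meta_line = fh.readline()
        if not meta_line.startswith("# meta "):
            raise ValueError(f"{path}: missing metadata header")
        meta = json.loads(meta_line[len("# meta "):])
        df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    if len(df) != meta.get("n_records", -1):
        raise ValueError(
            f"{path}: truncated trajectory ({len(df)} of "
            f"{meta.get('n_records')} records)"
        )
    return Trajectory(
        df=df,
        meta=meta,
        pep_coords=np.empty((0, 0, 3)),
        min_energy=float(meta.get("min_energy", np.nan)),
        min_coords=np.empty((0, 3)),
    )


@dataclass
class RunConfig:
    """Complete, serializable description of one simulation run."""

    mode: Literal["st", "fixed", "kinetics", "isolated"] = "fixed"
    pattern: str = "classI"  #: toy-complex pattern (ignored when pdb_path given)
    pdb_path: str | None = None
    receptor_chain: str | None = None
    peptide_chain: str | None = None
    box_side: float = 60.0
    temperature: float = 0.8
    t_min: float = 0.4
    t_max: float = 2.0
    n_temperatures: int = 8
    st_interval: int = 10
    n_steps: int = 100000
    n_runs: int = 1
    record_every: int = 100
    seed: int = 1
    clearance: float = 10.0
    energy: dict = field(default_factory=dict)
    move_set: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("st", "fixed", "kinetics", "isolated"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "kinetics":
            ms = self.resolved_move_set()
            if ms.pivot_enabled or ms.pep_pivot > 0:
                raise ValueError("kinetics mode requires the pivot move off")
            if ms.translation_step != 1.0:
                raise ValueError("kinetics mode requires 1 A translation steps")

    def resolved_params(self) -> EnergyParams:
        return EnergyParams(**self.energy)

    def resolved_move_set(self) -> MoveSet:
        if self.mode == "kinetics":
            return MoveSet.kinetics(**self.move_set)
        return MoveSet(**self.move_set)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)
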