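"""Implicit-solvent effective energy for the reduced chain model.

The total energy is a sum of: directional backbone hydrogen bonding
(intra- and inter-chain), pairwise side-chain hydrophobic attraction,
buriedness-enhanced screened electrostatics, a backbone desolvation
penalty acting on unsatisfied NH/CO groups, soft excluded volume, and
harmonic Ca restraints holding the receptor near its native structure.

Energies are in model units with the Boltzmann constant equal to 1.

The desolvation term penalizes NH/CO groups that participate in no
hydrogen bond *and* whose solvation probe point -- 2.0 Angstrom from H
along the N-H direction (NH groups) or 2.0 Angstrom from O along the
C=O direction (CO groups) -- is occupied by other protein atoms rather
than available to a solvent molecule:

    E_solv = eps_solv * sum_i delta_i * b(p_i)

where delta_i = 1 for unsatisfied groups and b is the degree of
buriedness of the probe point (neighbor count within R_b, saturating
at n_sat).  The same buriedness measure, evaluated at charged sites,
strengthens electrostatic interactions between buried partners by a
factor (1 + gamma * min(b_i, b_j)).

This module is the readable reference implementation; the Monte Carlo
engine uses an equivalent compiled kernel (see ``_energy``), and the
test suite asserts their agreement on random states.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._geom import AC, ACA, AH, AN, AO, AS, ATOMS_PER_RES
from .chain import ChainSystem, Conformation, HEAVY_SLOTS

__all__ = [
    "EnergyParams",
    "EnergyBreakdown",
    "probe_point",
    "hbond_pair_energy",
    "satisfied_groups",
    "buriedness",
    "desolvation_energy",
    "hydrophobic_energy",
    "electrostatic_energy",
    "excluded_volume_energy",
    "restraint_energy",
    "total_energy",
]


@dataclass(frozen=True)
class EnergyParams:
    """All tunable constants of the energy function (model units / Angstrom)."""

    eps_hb: float = 3.2  #: hydrogen-bond strength (depth at ideal geometry)
    eps_hp: float = 3.5  #: hydrophobic contact strength
    eps_el: float = 2.0  #: electrostatic strength
    gamma_el: float = 1.0  #: buriedness enhancement of electrostatics
    eps_solv: float = 2.0  #: desolvation penalty strength
    eps_ev: float = 2.0  #: excluded-volume strength
    k_res: float = 6.0  #: receptor Ca restraint spring constant

    d_probe: float = 2.0  #: probe-point offset from H (NH) or O (CO)
    R_b: float = 4.0  #: buriedness neighbor radius
    n_sat: int = 5  #: neighbor count at which buriedness saturates
    e_sat_frac: float = 0.2  #: a group is H-bonded if some pair < -e_sat_frac*eps_hb

    hb_r0: float = 2.0  #: ideal H...O distance
    hb_sigma: float = 0.35  #: radial Gaussian width
    hb_switch_on: float = 3.0  #: start of the smooth distance cutoff ramp
    hb_cutoff: float = 3.5  #: hydrogen-bond distance cutoff

    r_on: float = 4.0  #: hydrophobic contact ramp: full contact below
    r_off: float = 5.5  #: hydrophobic contact ramp: zero beyond

    el_lambda: float = 5.0  #: electrostatic screening length
    el_switch_on: float = 10.0
    el_cutoff: float = 12.0

    ev_scale: float = 0.85  #: global scaling of summed atomic radii
    ev_radii: tuple[float, ...] = (1.4, 0.0, 1.7, 1.7, 1.4, 1.8)  #: per atom slot

    def __post_init__(self) -> None:
        for name in ("eps_hb", "eps_hp", "eps_el", "eps_solv", "eps_ev", "k_res"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.e_sat_frac <= 0:
            raise ValueError("satisfied-bond threshold must be a negative energy")
        if not self.r_on < self.r_off:
            raise ValueError("hydrophobic ramp needs r_on < r_off")
        if self.R_b <= 0 or self.n_sat < 1:
            raise ValueError("invalid buriedness parameters")

    @property
    def e_sat(self) -> float:
        """Threshold pair energy below which a group counts as H-bonded (< 0)."""
        return -self.e_sat_frac * self.eps_hb


@dataclass(frozen=True)
class EnergyBreakdown:
    """Per-term energies and their total (model units)."""

    E_hb_intra: float
    E_hb_inter: float
    E_hp: float
    E_el: float
    E_solv: float
    E_ev: float
    E_restraint: float
    E_total: float = field(default=np.nan)

    def __post_init__(self) -> None:
        total = (
            self.E_hb_intra + self.E_hb_inter + self.E_hp + self.E_el
            + self.E_solv + self.E_ev + self.E_restraint
        )
        if math.isnan(self.E_total):
            object.__setattr__(self, "E_total", total)
        elif abs(self.E_total - total) > 1e-9 * max(1.0, abs(total)):
            raise ValueError("stored total does not equal the component sum")

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.E_hb_intra, self.E_hb_inter, self.E_hp, self.E_el,
                self.E_solv, self.E_ev, self.E_restraint, self.E_total,
            ]
        )


# ---------------------------------------------------------------------------
# geometry helpers

def _residue_chain_ids(system: ChainSystem) -> np.ndarray:
    return np.repeat([0, 1], [len(system.receptor), len(system.peptide)])


def _backbone_arrays(conf: Conformation):
    c = conf.coords.reshape(-1, ATOMS_PER_RES, 3)
    return c[:, AN], c[:, AH], c[:, ACA], c[:, AC], c[:, AO], c[:, AS]


def _min_image(d: np.ndarray, L: float) -> np.ndarray:
    return d - L * np.round(d / L)


def probe_point(group: tuple[int, str], conf: Conformation, d_probe: float = 2.0) -> np.ndarray:
    """Solvation probe point of a backbone NH or CO group.

    For an NH group the point lies ``d_probe`` beyond H along the N->H
    direction; for a CO group, ``d_probe`` beyond O along the C->O
    direction.
    """
    res, kind = group
    o = res * ATOMS_PER_RES
    if kind == "NH":
        base, tip = conf.coords[o + AN], conf.coords[o + AH]
    elif kind == "CO":
        base, tip = conf.coords[o + AC], conf.coords[o + AO]
    else:
        raise ValueError(f"unknown group kind {kind!r}")
    v = tip - base
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise ValueError("degenerate zero-length bond vector")
    return tip + d_probe * v / n


def _switch(r: np.ndarray, on: float, off: float) -> np.ndarray:
    """Smooth 1 -> 0 cosine ramp between *on* and *off*."""
    r = np.asarray(r, dtype=float)
    s = np.ones_like(r)
    ramp = (r > on) & (r < off)
    s[ramp] = 0.5 * (1.0 + np.cos(np.pi * (r[ramp] - on) / (off - on)))
    s[r >= off] = 0.0
    return s


def hbond_pair_energy(
    donor: int, acceptor: int, conf: Conformation, params: EnergyParams
) -> float:
    """Energy of one NH(donor residue) ... OC(acceptor residue) pairing.

    Directional form: a radial Gaussian centered on the ideal H...O
    distance times squared-cosine alignment factors for N-H...O and
    H...O=C, smoothly switched off at the distance cutoff.  The optimum
    (ideal distance, collinear alignment) equals -eps_hb.
    """
    m = hbond_energy_matrix(conf, params)
    return float(m[donor, acceptor])


def hbond_energy_matrix(conf: Conformation, params: EnergyParams) -> np.ndarray:
    """(n_res, n_res) matrix of donor-NH x acceptor-CO pair energies."""
    N, H, _, C, O, _ = _backbone_arrays(conf)
    L = conf.box_side
    chain = _residue_chain_ids(conf.system)
    n = len(chain)

    hv = O[None, :, :] - H[:, None, :]  # donor i -> acceptor j
    cross = chain[:, None] != chain[None, :]
    hv[cross] = _min_image(hv[cross], L)
    r = np.linalg.norm(hv, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        uhv = hv / r[..., None]
    nh = H - N
    nh /= np.linalg.norm(nh, axis=-1, keepdims=True)
    co = O - C
    co /= np.linalg.norm(co, axis=-1, keepdims=True)
    u1 = np.einsum("ik,ijk->ij", nh, uhv)
    u2 = -np.einsum("jk,ijk->ij", co, uhv)
    ok = (r < params.hb_cutoff) & (r > 1e-9) & (u1 > 0) & (u2 > 0)
    e = np.zeros((n, n))
    radial = np.exp(-((r - params.hb_r0) ** 2) / (2.0 * params.hb_sigma**2))
    sw = _switch(r, params.hb_switch_on, params.hb_cutoff)
    e[ok] = -params.eps_hb * (radial * u1**2 * u2**2 * sw)[ok]
    # covalent neighbors cannot hydrogen bond: own CO and the preceding CO
    idx = np.arange(n)
    same = chain[:, None] == chain[None, :]
    excl = same & (
        (idx[:, None] == idx[None, :]) | (idx[:, None] == idx[None, :] + 1)
    )
    e[excl] = 0.0
    return e


def satisfied_groups(
    conf: Conformation, params: EnergyParams, hb_matrix: np.ndarray | None = None
) -> np.ndarray:
    """(n_res, 2) flags: column 0 = NH satisfied, column 1 = CO satisfied.

    A group is satisfied iff at least one intra- or inter-chain pairing
    has energy below ``params.e_sat``; the desolvation term penalizes
    the complementary (unsatisfied, delta = 1) groups.
    """
    if hb_matrix is None:
        hb_matrix = hbond_energy_matrix(conf, params)
    sat = np.empty((hb_matrix.shape[0], 2), dtype=bool)
    sat[:, 0] = (hb_matrix < params.e_sat).any(axis=1)
    sat[:, 1] = (hb_matrix < params.e_sat).any(axis=0)
    return sat


def buriedness(
    point: np.ndarray,
    conf: Conformation,
    params: EnergyParams,
    exclude_residues: tuple[int, ...] = (),
) -> float:
    """Degree of buriedness of *point*, dimensionless in [0, 1].

    Counts heavy atoms (excluding the listed residues) within ``R_b``
    of the point, divided by ``n_sat`` and clamped to 1.  Zero means the
    point is available to a solvent molecule; one means it is fully
    occupied by other protein atoms.
    """
    coords = conf.coords.reshape(-1, ATOMS_PER_RES, 3)
    mask = np.ones(coords.shape[0], dtype=bool)
    for r in exclude_residues:
        mask[r] = False
    heavy = coords[mask][:, HEAVY_SLOTS, :].reshape(-1, 3)
    d = _min_image(heavy - np.asarray(point), conf.box_side)
    count = int((np.einsum("ij,ij->i", d, d) < params.R_b**2).sum())
    return min(count / params.n_sat, 1.0)


def _group_exclusions(res: int, chain: np.ndarray) -> tuple[int, ...]:
    """Residues whose atoms do not count toward a probe's buriedness.

    The probing group's own residue and its covalent neighbors are
    excluded: their backbone atoms sit within R_b of the probe for
    purely topological reasons, regardless of conformation.
    """
    out = [res]
    if res - 1 >= 0 and chain[res - 1] == chain[res]:
        out.append(res - 1)
    if res + 1 < len(chain) and chain[res + 1] == chain[res]:
        out.append(res + 1)
    return tuple(out)


def desolvation_energy(
    conf: Conformation, params: EnergyParams, sat: np.ndarray | None = None
) -> float:
    """Backbone desolvation penalty, >= 0.

    Sums eps_solv * buriedness(probe) over all unsatisfied NH and CO
    groups; zero when every group is hydrogen bonded or every probe is
    solvent exposed.
    """
    if sat is None:
        sat = satisfied_groups(conf, params)
    chain = _residue_chain_ids(conf.system)
    e = 0.0
    for res in range(len(chain)):
        excl = _group_exclusions(res, chain)
        for col, kind in ((0, "NH"), (1, "CO")):
            if sat[res, col]:
                continue
            p = probe_point((res, kind), conf, params.d_probe)
            e += params.eps_solv * buriedness(p, conf, params, exclude_residues=excl)
    return e


def hydrophobic_energy(conf: Conformation, params: EnergyParams) -> float:
    """Side-chain hydrophobic attraction, <= 0.

    E_hp = -eps_hp * sum_{a<b} h_a h_b C_ab with C_ab a linear contact
    ramp 1 -> 0 between r_on and r_off on the S...S distance; chain
    neighbors (|i-j| <= 1 within a chain) are skipped.
    """
    S = conf.coords.reshape(-1, ATOMS_PER_RES, 3)[:, AS]
    h = np.concatenate(
        [conf.system.receptor.hydrophobicities(), conf.system.peptide.hydrophobicities()]
    )
    chain = _residue_chain_ids(conf.system)
    n = len(h)
    e = 0.0
    for i in range(n):
        if h[i] == 0.0:
            continue
        for j in range(i + 1, n):
            if h[j] == 0.0:
                continue
            if chain[i] == chain[j] and j - i <= 1:
                continue
            d = S[j] - S[i]
            if chain[i] != chain[j]:
                d = _min_image(d, conf.box_side)
            r = float(np.linalg.norm(d))
            if r >= params.r_off:
                continue
            c = 1.0 if r <= params.r_on else (params.r_off - r) / (params.r_off - params.r_on)
            e -= params.eps_hp * h[i] * h[j] * c
    return e


def _charge_sites(system: ChainSystem) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Charged interaction sites: (atom indices, charges, residue indices)."""
    atoms: list[int] = []
    qs: list[float] = []
    res_idx: list[int] = []
    offset = 0
    for topo in (system.receptor, system.peptide):
        n = len(topo)
        for i, spec in enumerate(topo.sequence):
            if spec.q != 0:
                atoms.append((offset + i) * ATOMS_PER_RES + AS)
                qs.append(float(spec.q))
                res_idx.append(offset + i)
        if topo.n_terminal_charge:
            atoms.append(offset * ATOMS_PER_RES + AN)
            qs.append(1.0)
            res_idx.append(offset)
        if topo.c_terminal_carboxylate:
            atoms.append((offset + n - 1) * ATOMS_PER_RES + AO)
            qs.append(-1.0)
            res_idx.append(offset + n - 1)
        offset += n
    return np.array(atoms, dtype=int), np.array(qs), np.array(res_idx, dtype=int)


def electrostatic_energy(conf: Conformation, params: EnergyParams) -> float:
    """Screened Coulomb term over charged sites with buriedness enhancement.

    Each pair is scaled by (1 + gamma * min(b_i, b_j)) where b is the
    buriedness of the charge site, making interactions between buried
    partners effectively stronger than solvent-exposed ones.
    """
    atoms, qs, res_idx = _charge_sites(conf.system)
    if len(atoms) == 0:
        return 0.0
    chain = _residue_chain_ids(conf.system)
    b = np.array(
        [
            buriedness(conf.coords[a], conf, params, exclude_residues=(int(r),))
            for a, r in zip(atoms, res_idx)
        ]
    )
    e = 0.0
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            if res_idx[i] == res_idx[j]:
                continue
            d = conf.coords[atoms[j]] - conf.coords[atoms[i]]
            if chain[res_idx[i]] != chain[res_idx[j]]:
                d = _min_image(d, conf.box_side)
            r = float(np.linalg.norm(d))
            if r >= params.el_cutoff or r < 1e-9:
                continue
            sw = float(_switch(np.array(r), params.el_switch_on, params.el_cutoff))
            e += (
                params.eps_el * qs[i] * qs[j]
                * (1.0 + params.gamma_el * min(b[i], b[j]))
                * math.exp(-r / params.el_lambda) / r * sw
            )
    return e


def excluded_volume_energy(conf: Conformation, params: EnergyParams) -> float:
    """Soft pairwise repulsion between heavy atoms, >= 0.

    Pair potential eps_ev * ((s/r)^12 - 2 (s/r)^6 + 1) for r < s,
    s = ev_scale * (r_a + r_b); zero (and C1-continuous) at r = s.
    Same-residue and chain-neighbor pairs are skipped.
    """
    coords = conf.coords
    chain = _residue_chain_ids(conf.system)
    n_res = len(chain)
    radii = params.ev_radii
    e = 0.0
    for ia in range(coords.shape[0]):
        sa = ia % ATOMS_PER_RES
        if sa == AH:
            continue
        ra = ia // ATOMS_PER_RES
        for ib in range(ia + 1, coords.shape[0]):
            sb = ib % ATOMS_PER_RES
            if sb == AH:
                continue
            rb = ib // ATOMS_PER_RES
            if chain[ra] == chain[rb] and rb - ra <= 1:
                continue
            d = coords[ib] - coords[ia]
            if chain[ra] != chain[rb]:
                d = _min_image(d, conf.box_side)
            s = params.ev_scale * (radii[sa] + radii[sb])
            r2 = float(d @ d)
            if r2 >= s * s:
                continue
            x6 = (s * s / r2) ** 3
            e += params.eps_ev * (x6 * x6 - 2.0 * x6 + 1.0)
    return e


def restraint_energy(conf: Conformation, params: EnergyParams) -> float:
    """Harmonic Ca restraints keeping the receptor near its native pose."""
    native = conf.system.native
    if native is None:
        return 0.0
    n_rec = len(conf.system.receptor)
    ca = conf.coords.reshape(-1, ATOMS_PER_RES, 3)[:n_rec, ACA]
    d = ca - native.restraint_centers
    return float(params.k_res * np.einsum("ij,ij->", d, d))


def total_energy(conf: Conformation, params: EnergyParams) -> EnergyBreakdown:
    """Full energy breakdown of a realized conformation."""
    hb = hbond_energy_matrix(conf, params)
    chain = _residue_chain_ids(conf.system)
    cross = chain[:, None] != chain[None, :]
    e_hb_inter = float(hb[cross].sum())
    e_hb_intra = float(hb.sum() - e_hb_inter)
    sat = satisfied_groups(conf, params, hb_matrix=hb)
    return EnergyBreakdown(
        E_hb_intra=e_hb_intra,
        E_hb_inter=e_hb_inter,
        E_hp=hydrophobic_energy(conf, params),
        E_el=electrostatic_energy(conf, params),
        E_solv=desolvation_energy(conf, params, sat=sat),
        E_ev=excluded_volume_energy(conf, params),
        E_restraint=restraint_energy(conf, params),
    )
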