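"""Compiled energy kernels used by the Monte Carlo engine.

Terms are computed per interaction class -- receptor-receptor (rr),
peptide-peptide (pp) and cross-chain (x) -- so the sampler can reuse
cached class sums when a move touched only one chain.  Cross-chain
distances use the minimum-image convention; intra-chain distances are
plain (chains are kept small relative to the box).

Residue-pair distance prechecks based on per-residue reach bounds
(see :func:`reach_array`) skip atom-pair loops that cannot contribute;
the bound is strict, so results are bitwise identical to the
unscreened sums.  The readable reference implementation lives in
:mod:`pdzmc.energy`; the test suite asserts agreement between the two
on random states.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .energy import EnergyParams

# packed parameter vector layout
P_EPS_HB = 0
P_EPS_HP = 1
P_EPS_EL = 2
P_GAMMA_EL = 3
P_EPS_SOLV = 4
P_EPS_EV = 5
P_K_RES = 6
P_D_PROBE = 7
P_R_B = 8
P_N_SAT = 9
P_E_SAT = 10  # absolute threshold (negative)
P_HB_R0 = 11
P_HB_SIGMA = 12
P_HB_SWITCH = 13
P_HB_CUT = 14
P_R_ON = 15
P_R_OFF = 16
P_EL_LAMBDA = 17
P_EL_SWITCH = 18
P_EL_CUT = 19
P_EV_SCALE = 20
P_L = 21
N_PRM = 22

# heavy atom slots (N, Ca, C, O, S); slot 1 is the amide H
HEAVY = np.array([0, 2, 3, 4, 5], dtype=np.int64)


def pack_params(params: EnergyParams, L: float) -> tuple[np.ndarray, np.ndarray]:
    """Pack an :class:`EnergyParams` into the kernel parameter vector."""
    prm = np.zeros(N_PRM)
    prm[P_EPS_HB] = params.eps_hb
    prm[P_EPS_HP] = params.eps_hp
    prm[P_EPS_EL] = params.eps_el
    prm[P_GAMMA_EL] = params.gamma_el
    prm[P_EPS_SOLV] = params.eps_solv
    prm[P_EPS_EV] = params.eps_ev
    prm[P_K_RES] = params.k_res
    prm[P_D_PROBE] = params.d_probe
    prm[P_R_B] = params.R_b
    prm[P_N_SAT] = float(params.n_sat)
    prm[P_E_SAT] = params.e_sat
    prm[P_HB_R0] = params.hb_r0
    prm[P_HB_SIGMA] = params.hb_sigma
    prm[P_HB_SWITCH] = params.hb_switch_on
    prm[P_HB_CUT] = params.hb_cutoff
    prm[P_R_ON] = params.r_on
    prm[P_R_OFF] = params.r_off
    prm[P_EL_LAMBDA] = params.el_lambda
    prm[P_EL_SWITCH] = params.el_switch_on
    prm[P_EL_CUT] = params.el_cutoff
    prm[P_EV_SCALE] = params.ev_scale
    prm[P_L] = L
    return prm, np.array(params.ev_radii)


def reach_array(s_bonds: np.ndarray) -> np.ndarray:
    """Per-residue bound on the distance of any site from its Ca.

    The farthest sites from Ca are the side-chain site (s_bond), the
    carbonyl O (<= 2.75 A via C) and the amide H (<= 2.47 A via N); a
    small margin keeps the bound strict under floating-point error.
    """
    return np.maximum(s_bonds, 2.80) + 0.1


@njit(cache=True, inline="always")
def _mi1(d, L):
    """Minimum-image correction of one displacement component."""
    while d > 0.5 * L:
        d -= L
    while d < -0.5 * L:
        d += L
    return d


@njit(cache=True, inline="always")
def _ca_d2_plain(coords, i, j):
    dx = coords[j * 6 + 2, 0] - coords[i * 6 + 2, 0]
    dy = coords[j * 6 + 2, 1] - coords[i * 6 + 2, 1]
    dz = coords[j * 6 + 2, 2] - coords[i * 6 + 2, 2]
    return dx * dx + dy * dy + dz * dz


@njit(cache=True, inline="always")
def _ca_d2_mi(coords, i, j, L):
    dx = _mi1(coords[j * 6 + 2, 0] - coords[i * 6 + 2, 0], L)
    dy = _mi1(coords[j * 6 + 2, 1] - coords[i * 6 + 2, 1], L)
    dz = _mi1(coords[j * 6 + 2, 2] - coords[i * 6 + 2, 2], L)
    return dx * dx + dy * dy + dz * dz


@njit(cache=True)
def _hb_pair(coords, di, aj, prm, cross):
    """Energy of the NH(di)...OC(aj) pairing; 0 beyond cutoff/misaligned."""
    L = prm[P_L]
    oN = di * 6
    oH = oN + 1
    oC = aj * 6 + 3
    oO = aj * 6 + 4
    dx = coords[oO, 0] - coords[oH, 0]
    dy = coords[oO, 1] - coords[oH, 1]
    dz = coords[oO, 2] - coords[oH, 2]
    if cross:
        dx = _mi1(dx, L)
        dy = _mi1(dy, L)
        dz = _mi1(dz, L)
    cut = prm[P_HB_CUT]
    r2 = dx * dx + dy * dy + dz * dz
    if r2 >= cut * cut or r2 < 1e-18:
        return 0.0
    r = math.sqrt(r2)
    nhx = coords[oH, 0] - coords[oN, 0]
    nhy = coords[oH, 1] - coords[oN, 1]
    nhz = coords[oH, 2] - coords[oN, 2]
    nnh = math.sqrt(nhx * nhx + nhy * nhy + nhz * nhz)
    u1 = (nhx * dx + nhy * dy + nhz * dz) / (nnh * r)
    if u1 <= 0.0:
        return 0.0
    cox = coords[oO, 0] - coords[oC, 0]
    coy = coords[oO, 1] - coords[oC, 1]
    coz = coords[oO, 2] - coords[oC, 2]
    nco = math.sqrt(cox * cox + coy * coy + coz * coz)
    u2 = -(cox * dx + coy * dy + coz * dz) / (nco * r)
    if u2 <= 0.0:
        return 0.0
    radial = math.exp(-((r - prm[P_HB_R0]) ** 2) / (2.0 * prm[P_HB_SIGMA] ** 2))
    sw = 1.0
    if r > prm[P_HB_SWITCH]:
        sw = 0.5 * (1.0 + math.cos(math.pi * (r - prm[P_HB_SWITCH]) / (cut - prm[P_HB_SWITCH])))
    return -prm[P_EPS_HB] * radial * u1 * u1 * u2 * u2 * sw


@njit(cache=True)
def _probes_for_chain(coords, r0, r1, prm, probes):
    """Fill solvation probe points for residues [r0, r1)."""
    dp = prm[P_D_PROBE]
    for i in range(r0, r1):
        oN = i * 6
        oH = oN + 1
        oC = i * 6 + 3
        oO = i * 6 + 4
        vx = coords[oH, 0] - coords[oN, 0]
        vy = coords[oH, 1] - coords[oN, 1]
        vz = coords[oH, 2] - coords[oN, 2]
        n = math.sqrt(vx * vx + vy * vy + vz * vz)
        probes[i, 0, 0] = coords[oH, 0] + dp * vx / n
        probes[i, 0, 1] = coords[oH, 1] + dp * vy / n
        probes[i, 0, 2] = coords[oH, 2] + dp * vz / n
        vx = coords[oO, 0] - coords[oC, 0]
        vy = coords[oO, 1] - coords[oC, 1]
        vz = coords[oO, 2] - coords[oC, 2]
        n = math.sqrt(vx * vx + vy * vy + vz * vz)
        probes[i, 1, 0] = coords[oO, 0] + dp * vx / n
        probes[i, 1, 1] = coords[oO, 1] + dp * vy / n
        probes[i, 1, 2] = coords[oO, 2] + dp * vz / n


@njit(cache=True)
def intra_terms(coords, r0, r1, h, prm, radii, reach, satmin, burown, probes):
    """All within-chain terms for residues [r0, r1).

    Fills that chain's rows of ``satmin`` (minimum H-bond pair energy
    per NH/CO group), ``burown`` (probe neighbor counts from own-chain
    atoms, chain neighbors i-1..i+1 excluded) and ``probes``.  Returns
    (e_hb, e_hp, e_ev).
    """
    _probes_for_chain(coords, r0, r1, prm, probes)
    for i in range(r0, r1):
        satmin[i, 0] = 1e30
        satmin[i, 1] = 1e30
        burown[i, 0] = 0.0
        burown[i, 1] = 0.0
    hb_cut = prm[P_HB_CUT]
    e_hb = 0.0
    for i in range(r0, r1):
        for j in range(r0, r1):
            if j == i or j == i - 1:
                continue
            lim = reach[i] + reach[j] + hb_cut
            if _ca_d2_plain(coords, i, j) >= lim * lim:
                continue
            e = _hb_pair(coords, i, j, prm, False)
            if e < 0.0:
                e_hb += e
                if e < satmin[i, 0]:
                    satmin[i, 0] = e
                if e < satmin[j, 1]:
                    satmin[j, 1] = e
    e_hp = 0.0
    r_off = prm[P_R_OFF]
    r_on = prm[P_R_ON]
    for i in range(r0, r1):
        if h[i] == 0.0:
            continue
        oi = i * 6 + 5
        for j in range(i + 2, r1):
            if h[j] == 0.0:
                continue
            oj = j * 6 + 5
            dx = coords[oj, 0] - coords[oi, 0]
            dy = coords[oj, 1] - coords[oi, 1]
            dz = coords[oj, 2] - coords[oi, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= r_off * r_off:
                continue
            r = math.sqrt(r2)
            c = 1.0 if r <= r_on else (r_off - r) / (r_off - r_on)
            e_hp -= prm[P_EPS_HP] * h[i] * h[j] * c
    e_ev = 0.0
    scale = prm[P_EV_SCALE]
    ev_max = scale * 2.0 * 1.8  # largest pair sigma (two side-chain sites)
    for i in range(r0, r1):
        for j in range(i + 2, r1):
            lim = reach[i] + reach[j] + ev_max
            if _ca_d2_plain(coords, i, j) >= lim * lim:
                continue
            for a in range(5):
                sa = HEAVY[a]
                oi = i * 6 + sa
                for b in range(5):
                    sb = HEAVY[b]
                    oj = j * 6 + sb
                    s = scale * (radii[sa] + radii[sb])
                    dx = coords[oj, 0] - coords[oi, 0]
                    dy = coords[oj, 1] - coords[oi, 1]
                    dz = coords[oj, 2] - coords[oi, 2]
                    r2 = dx * dx + dy * dy + dz * dz
                    if r2 >= s * s:
                        continue
                    x6 = (s * s / r2) ** 3
                    e_ev += prm[P_EPS_EV] * (x6 * x6 - 2.0 * x6 + 1.0)
    # own-chain probe buriedness (counts, clamped later together with cross)
    rb = prm[P_R_B]
    rb2 = rb * rb
    for i in range(r0, r1):
        for col in range(2):
            px = probes[i, col, 0]
            py = probes[i, col, 1]
            pz = probes[i, col, 2]
            cnt = 0.0
            for k in range(r0, r1):
                if k >= i - 1 and k <= i + 1:
                    continue
                okca = k * 6 + 2
                dx = coords[okca, 0] - px
                dy = coords[okca, 1] - py
                dz = coords[okca, 2] - pz
                lim = reach[k] + rb
                if dx * dx + dy * dy + dz * dz >= lim * lim:
                    continue
                for a in range(5):
                    ok = k * 6 + HEAVY[a]
                    dx = coords[ok, 0] - px
                    dy = coords[ok, 1] - py
                    dz = coords[ok, 2] - pz
                    if dx * dx + dy * dy + dz * dz < rb2:
                        cnt += 1.0
            burown[i, col] = cnt
    return e_hb, e_hp, e_ev


@njit(cache=True)
def cross_terms(coords, n_rec, n_res, h, prm, radii, reach, satx, burx, probes):
    """All cross-chain terms (minimum image).  Returns (e_hb, e_hp, e_ev).

    Fills ``satx`` (min cross H-bond pair energy per group) and ``burx``
    (probe neighbor counts from the *other* chain) for every residue.
    """
    L = prm[P_L]
    for i in range(n_res):
        satx[i, 0] = 1e30
        satx[i, 1] = 1e30
        burx[i, 0] = 0.0
        burx[i, 1] = 0.0
    hb_cut = prm[P_HB_CUT]
    r_off = prm[P_R_OFF]
    r_on = prm[P_R_ON]
    scale = prm[P_EV_SCALE]
    ev_max = scale * 2.0 * 1.8
    # When the box comfortably exceeds every interaction range plus the
    # residue reaches, the periodic image of any contributing atom pair
    # equals the image of its Ca pair, so the shift can be found once
    # per residue pair.  Applying `+ shift` is the same IEEE operation
    # as the per-component subtract loop, so results are bit-identical;
    # small boxes fall back to per-atom minimum image.
    hoist = L >= 48.0
    e_hb = 0.0
    e_hp = 0.0
    e_ev = 0.0
    for i in range(n_rec):
        for j in range(n_rec, n_res):
            if hoist:
                sx = 0.0
                sy = 0.0
                sz = 0.0
                cx = coords[j * 6 + 2, 0] - coords[i * 6 + 2, 0]
                while cx > 0.5 * L:
                    cx -= L
                    sx -= L
                while cx < -0.5 * L:
                    cx += L
                    sx += L
                cy = coords[j * 6 + 2, 1] - coords[i * 6 + 2, 1]
                while cy > 0.5 * L:
                    cy -= L
                    sy -= L
                while cy < -0.5 * L:
                    cy += L
                    sy += L
                cz = coords[j * 6 + 2, 2] - coords[i * 6 + 2, 2]
                while cz > 0.5 * L:
                    cz -= L
                    sz -= L
                while cz < -0.5 * L:
                    cz += L
                    sz += L
                ca2 = cx * cx + cy * cy + cz * cz
            else:
                sx = 0.0
                sy = 0.0
                sz = 0.0
                ca2 = _ca_d2_mi(coords, i, j, L)
            lim_hb = reach[i] + reach[j] + hb_cut
            if ca2 < lim_hb * lim_hb:
                e = _hb_pair(coords, i, j, prm, True)  # receptor donor
                if e < 0.0:
                    e_hb += e
                    if e < satx[i, 0]:
                        satx[i, 0] = e
                    if e < satx[j, 1]:
                        satx[j, 1] = e
                e = _hb_pair(coords, j, i, prm, True)  # peptide donor
                if e < 0.0:
                    e_hb += e
                    if e < satx[j, 0]:
                        satx[j, 0] = e
                    if e < satx[i, 1]:
                        satx[i, 1] = e
            if h[i] != 0.0 and h[j] != 0.0:
                lim_hp = reach[i] + reach[j] + r_off
                if ca2 < lim_hp * lim_hp:
                    oi = i * 6 + 5
                    oj = j * 6 + 5
                    if hoist:
                        dx = coords[oj, 0] - coords[oi, 0] + sx
                        dy = coords[oj, 1] - coords[oi, 1] + sy
                        dz = coords[oj, 2] - coords[oi, 2] + sz
                    else:
                        dx = _mi1(coords[oj, 0] - coords[oi, 0], L)
                        dy = _mi1(coords[oj, 1] - coords[oi, 1], L)
                        dz = _mi1(coords[oj, 2] - coords[oi, 2], L)
                    r2 = dx * dx + dy * dy + dz * dz
                    if r2 < r_off * r_off:
                        r = math.sqrt(r2)
                        c = 1.0 if r <= r_on else (r_off - r) / (r_off - r_on)
                        e_hp -= prm[P_EPS_HP] * h[i] * h[j] * c
            lim_ev = reach[i] + reach[j] + ev_max
            if ca2 < lim_ev * lim_ev:
                for a in range(5):
                    sa = HEAVY[a]
                    oi = i * 6 + sa
                    for b in range(5):
                        sb = HEAVY[b]
                        oj = j * 6 + sb
                        s = scale * (radii[sa] + radii[sb])
                        if hoist:
                            dx = coords[oj, 0] - coords[oi, 0] + sx
                            dy = coords[oj, 1] - coords[oi, 1] + sy
                            dz = coords[oj, 2] - coords[oi, 2] + sz
                        else:
                            dx = _mi1(coords[oj, 0] - coords[oi, 0], L)
                            dy = _mi1(coords[oj, 1] - coords[oi, 1], L)
                            dz = _mi1(coords[oj, 2] - coords[oi, 2], L)
                        r2 = dx * dx + dy * dy + dz * dz
                        if r2 >= s * s:
                            continue
                        x6 = (s * s / r2) ** 3
                        e_ev += prm[P_EPS_EV] * (x6 * x6 - 2.0 * x6 + 1.0)
    # probe buriedness contributions from the other chain
    rb = prm[P_R_B]
    rb2 = rb * rb
    for i in range(n_res):
        if i < n_rec:
            k0, k1 = n_rec, n_res
        else:
            k0, k1 = 0, n_rec
        for col in range(2):
            px = probes[i, col, 0]
            py = probes[i, col, 1]
            pz = probes[i, col, 2]
            cnt = 0.0
            for k in range(k0, k1):
                okca = k * 6 + 2
                if hoist:
                    sx = 0.0
                    sy = 0.0
                    sz = 0.0
                    dx = coords[okca, 0] - px
                    while dx > 0.5 * L:
                        dx -= L
                        sx -= L
                    while dx < -0.5 * L:
                        dx += L
                        sx += L
                    dy = coords[okca, 1] - py
                    while dy > 0.5 * L:
                        dy -= L
                        sy -= L
                    while dy < -0.5 * L:
                        dy += L
                        sy += L
                    dz = coords[okca, 2] - pz
                    while dz > 0.5 * L:
                        dz -= L
                        sz -= L
                    while dz < -0.5 * L:
                        dz += L
                        sz += L
                else:
                    sx = 0.0
                    sy = 0.0
                    sz = 0.0
                    dx = _mi1(coords[okca, 0] - px, L)
                    dy = _mi1(coords[okca, 1] - py, L)
                    dz = _mi1(coords[okca, 2] - pz, L)
                lim = reach[k] + rb
                if dx * dx + dy * dy + dz * dz >= lim * lim:
                    continue
                for a in range(5):
                    ok = k * 6 + HEAVY[a]
                    if hoist:
                        dx = coords[ok, 0] - px + sx
                        dy = coords[ok, 1] - py + sy
                        dz = coords[ok, 2] - pz + sz
                    else:
                        dx = _mi1(coords[ok, 0] - px, L)
                        dy = _mi1(coords[ok, 1] - py, L)
                        dz = _mi1(coords[ok, 2] - pz, L)
                    if dx * dx + dy * dy + dz * dz < rb2:
                        cnt += 1.0
            burx[i, col] = cnt
    return e_hb, e_hp, e_ev


@njit(cache=True)
def solvation_energy(satmin, satx, burown, burx, prm):
    """Assemble E_solv from cached per-group minima and neighbor counts."""
    e_sat = prm[P_E_SAT]
    n_sat = prm[P_N_SAT]
    e = 0.0
    for i in range(satmin.shape[0]):
        for col in range(2):
            if satmin[i, col] < e_sat or satx[i, col] < e_sat:
                continue
            b = (burown[i, col] + burx[i, col]) / n_sat
            if b > 1.0:
                b = 1.0
            e += prm[P_EPS_SOLV] * b
    return e


@njit(cache=True)
def electro_energy(coords, n_rec, n_res, c_atom, c_q, c_res, prm, reach):
    """Buriedness-enhanced screened Coulomb sum over charged sites."""
    nc = c_atom.shape[0]
    if nc == 0:
        return 0.0
    L = prm[P_L]
    rb = prm[P_R_B]
    rb2 = rb * rb
    n_sat = prm[P_N_SAT]
    b = np.empty(nc)
    for s in range(nc):
        px = coords[c_atom[s], 0]
        py = coords[c_atom[s], 1]
        pz = coords[c_atom[s], 2]
        own = c_res[s]
        own_rec = own < n_rec
        cnt = 0.0
        for k in range(n_res):
            if k == own:
                continue
            cross = (k < n_rec) != own_rec
            okca = k * 6 + 2
            dx = coords[okca, 0] - px
            dy = coords[okca, 1] - py
            dz = coords[okca, 2] - pz
            if cross:
                dx = _mi1(dx, L)
                dy = _mi1(dy, L)
                dz = _mi1(dz, L)
            lim = reach[k] + rb
            if dx * dx + dy * dy + dz * dz >= lim * lim:
                continue
            for a in range(5):
                ok = k * 6 + HEAVY[a]
                dx = coords[ok, 0] - px
                dy = coords[ok, 1] - py
                dz = coords[ok, 2] - pz
                if cross:
                    dx = _mi1(dx, L)
                    dy = _mi1(dy, L)
                    dz = _mi1(dz, L)
                if dx * dx + dy * dy + dz * dz < rb2:
                    cnt += 1.0
        bi = cnt / n_sat
        b[s] = 1.0 if bi > 1.0 else bi
    e = 0.0
    cut = prm[P_EL_CUT]
    for i in range(nc):
        for j in range(i + 1, nc):
            if c_res[i] == c_res[j]:
                continue
            dx = coords[c_atom[j], 0] - coords[c_atom[i], 0]
            dy = coords[c_atom[j], 1] - coords[c_atom[i], 1]
            dz = coords[c_atom[j], 2] - coords[c_atom[i], 2]
            if (c_res[i] < n_rec) != (c_res[j] < n_rec):
                dx = _mi1(dx, L)
                dy = _mi1(dy, L)
                dz = _mi1(dz, L)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= cut * cut or r2 < 1e-18:
                continue
            r = math.sqrt(r2)
            sw = 1.0
            if r > prm[P_EL_SWITCH]:
                sw = 0.5 * (1.0 + math.cos(math.pi * (r - prm[P_EL_SWITCH]) / (cut - prm[P_EL_SWITCH])))
            bm = b[i] if b[i] < b[j] else b[j]
            e += (
                prm[P_EPS_EL] * c_q[i] * c_q[j]
                * (1.0 + prm[P_GAMMA_EL] * bm)
                * math.exp(-r / prm[P_EL_LAMBDA]) / r * sw
            )
    return e


@njit(cache=True)
def restraint_energy(coords, centers, prm):
    """Harmonic Ca restraint sum over receptor residues."""
    e = 0.0
    for i in range(centers.shape[0]):
        oca = i * 6 + 2
        dx = coords[oca, 0] - centers[i, 0]
        dy = coords[oca, 1] - centers[i, 1]
        dz = coords[oca, 2] - centers[i, 2]
        e += dx * dx + dy * dy + dz * dz
    return prm[P_K_RES] * e


@njit(cache=True)
def full_components(
    coords, n_rec, n_res, h, c_atom, c_q, c_res, centers, prm, radii, reach,
    satmin, satx, burown, burx, probes, comps,
):
    """Compute the complete energy breakdown from scratch.

    ``comps`` layout: [hb_intra, hb_inter, hp, el, solv, ev, restraint,
    total].  Also returns the three per-class scalar triples used as MC
    caches: (rr, pp, x), each (hb, hp, ev).
    """
    hb_rr, hp_rr, ev_rr = intra_terms(coords, 0, n_rec, h, prm, radii, reach, satmin, burown, probes)
    hb_pp, hp_pp, ev_pp = intra_terms(coords, n_rec, n_res, h, prm, radii, reach, satmin, burown, probes)
    hb_x, hp_x, ev_x = cross_terms(coords, n_rec, n_res, h, prm, radii, reach, satx, burx, probes)
    comps[0] = hb_rr + hb_pp
    comps[1] = hb_x
    comps[2] = hp_rr + hp_pp + hp_x
    comps[3] = electro_energy(coords, n_rec, n_res, c_atom, c_q, c_res, prm, reach)
    comps[4] = solvation_energy(satmin, satx, burown, burx, prm)
    comps[5] = ev_rr + ev_pp + ev_x
    comps[6] = restraint_energy(coords, centers, prm)
    comps[7] = comps[0] + comps[1] + comps[2] + comps[3] + comps[4] + comps[5] + comps[6]
    return hb_rr, hp_rr, ev_rr, hb_pp, hp_pp, ev_pp, hb_x, hp_x, ev_x
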