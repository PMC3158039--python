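"""Compiled Metropolis Monte Carlo loop.

One elementary MC step is one attempted conformational move.  Move
types: receptor side-chain rotation, receptor semi-local backbone
window, peptide side-chain rotation, peptide semi-local backbone
window, peptide pivot, rigid translation, rigid rotation.  In
simulated-tempering mode a temperature-index update is attempted every
``st_every`` steps as an ordinary MC update with acceptance
min(1, exp[-E (1/T_new - 1/T_old) + g_new - g_old]).

Per-move energy evaluation reuses cached class sums (receptor-receptor,
peptide-peptide) for the chain a move did not touch and recomputes
cross-chain terms exactly; the running breakdown therefore equals a
full recomputation at every step (asserted in the tests).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from ._geom import build_chain
from ._energy import (
    HEAVY,
    P_L,
    cross_terms,
    electro_energy,
    full_components,
    intra_terms,
    restraint_energy,
    solvation_energy,
)

# move-type indices (slot 7 counts temperature updates)
M_REC_CHI = 0
M_REC_BB = 1
M_PEP_CHI = 2
M_PEP_BB = 3
M_PEP_PIVOT = 4
M_TRANSLATE = 5
M_ROTATE = 6
M_ST = 7
N_MOVE_TYPES = 7
BB_WINDOW = 8  # torsions turned by one semi-local backbone move


@njit(cache=True, inline="always")
def _wrap_angle(a):
    while a > math.pi:
        a -= 2.0 * math.pi
    while a <= -math.pi:
        a += 2.0 * math.pi
    return a


@njit(cache=True)
def _order_params(coords, n_rec, n_res, nat_pep, contacts, ccut, L):
    """(Q, non-optimized heavy-atom RMSD, Delta_CM) versus the native pose."""
    n_pep = n_res - n_rec
    # fraction of native inter-chain contacts
    q = 0.0
    if contacts.shape[0] > 0:
        formed = 0
        for c in range(contacts.shape[0]):
            ri = contacts[c, 0]
            pi = contacts[c, 1]
            hit = False
            for a in range(5):
                oa = ri * 6 + HEAVY[a]
                for b in range(5):
                    ob = pi * 6 + HEAVY[b]
                    dx = coords[ob, 0] - coords[oa, 0]
                    dx -= L * math.floor(dx / L + 0.5)
                    dy = coords[ob, 1] - coords[oa, 1]
                    dy -= L * math.floor(dy / L + 0.5)
                    dz = coords[ob, 2] - coords[oa, 2]
                    dz -= L * math.floor(dz / L + 0.5)
                    if dx * dx + dy * dy + dz * dz < ccut * ccut:
                        hit = True
                        break
                if hit:
                    break
            if hit:
                formed += 1
        q = formed / contacts.shape[0]
    # non-optimized RMSD over peptide heavy atoms, common periodic image
    mdx = 0.0
    mdy = 0.0
    mdz = 0.0
    n_heavy = n_pep * 5
    for i in range(n_pep):
        for a in range(5):
            o = (n_rec + i) * 6 + HEAVY[a]
            on = i * 6 + HEAVY[a]
            mdx += coords[o, 0] - nat_pep[on, 0]
            mdy += coords[o, 1] - nat_pep[on, 1]
            mdz += coords[o, 2] - nat_pep[on, 2]
    mdx /= n_heavy
    mdy /= n_heavy
    mdz /= n_heavy
    sx = L * math.floor(mdx / L + 0.5)
    sy = L * math.floor(mdy / L + 0.5)
    sz = L * math.floor(mdz / L + 0.5)
    ss = 0.0
    for i in range(n_pep):
        for a in range(5):
            o = (n_rec + i) * 6 + HEAVY[a]
            on = i * 6 + HEAVY[a]
            dx = coords[o, 0] - nat_pep[on, 0] - sx
            dy = coords[o, 1] - nat_pep[on, 1] - sy
            dz = coords[o, 2] - nat_pep[on, 2] - sz
            ss += dx * dx + dy * dy + dz * dz
    rmsd = math.sqrt(ss / n_heavy)
    # center-of-mass distance over Ca of the last 4 peptide residues
    cmx = 0.0
    cmy = 0.0
    cmz = 0.0
    cnx = 0.0
    cny = 0.0
    cnz = 0.0
    for i in range(n_pep - 4, n_pep):
        o = (n_rec + i) * 6 + 2
        on = i * 6 + 2
        cmx += coords[o, 0]
        cmy += coords[o, 1]
        cmz += coords[o, 2]
        cnx += nat_pep[on, 0]
        cny += nat_pep[on, 1]
        cnz += nat_pep[on, 2]
    dx = (cmx - cnx) / 4.0
    dy = (cmy - cny) / 4.0
    dz = (cmz - cnz) / 4.0
    dx -= L * math.floor(dx / L + 0.5)
    dy -= L * math.floor(dy / L + 0.5)
    dz -= L * math.floor(dz / L + 0.5)
    dcm = math.sqrt(dx * dx + dy * dy + dz * dz)
    return q, rmsd, dcm


@njit(cache=True)
def _transform_pep(pep_local, R, t, coords, n_rec):
    for i in range(pep_local.shape[0]):
        x = pep_local[i, 0]
        y = pep_local[i, 1]
        z = pep_local[i, 2]
        o = n_rec * 6 + i
        coords[o, 0] = R[0, 0] * x + R[0, 1] * y + R[0, 2] * z + t[0]
        coords[o, 1] = R[1, 0] * x + R[1, 1] * y + R[1, 2] * z + t[1]
        coords[o, 2] = R[2, 0] * x + R[2, 1] * y + R[2, 2] * z + t[2]


@njit(cache=True)
def run_mc(
    # system
    n_rec, n_res, h, sbond, sangle, anchor_rec, canon_anchor,
    c_atom, c_q, c_res, centers, prm, radii, reach,
    nat_pep, contacts, contact_cut,
    # mobility
    mob_chi_rec, mob_chi_pep, bb_list_rec, bb_list_pep, piv_list, grid,
    # move set
    cum_freq, trans_step, rot_step, chi_step, bb_step,
    # protocol
    temps, weights, k0, st_every, n_steps, record_every, store_pep, seed,
    # state (mutated in place)
    tors, frameR, framet,
    # outputs
    rec_step, rec_k, rec_comps, rec_q, rec_rmsd, rec_dcm, rec_pep, rec_state,
    visits, att, acc, min_out, min_coords,
):
    np.random.seed(seed)
    L = prm[P_L]
    n_pep = n_res - n_rec
    n_atoms = n_res * 6
    npa = n_pep * 6
    grid_n = grid.shape[0]

    coords = np.empty((n_atoms, 3))
    coords_p = np.empty((n_atoms, 3))
    pep_local = np.empty((npa, 3))
    pep_local_p = np.empty((npa, 3))
    tors_p = np.empty_like(tors)
    frameR_p = np.empty((3, 3))
    framet_p = np.empty(3)

    satmin = np.empty((n_res, 2))
    satx = np.empty((n_res, 2))
    burown = np.empty((n_res, 2))
    burx = np.empty((n_res, 2))
    probes = np.empty((n_res, 2, 3))
    satmin_p = np.empty((n_res, 2))
    satx_p = np.empty((n_res, 2))
    burown_p = np.empty((n_res, 2))
    burx_p = np.empty((n_res, 2))
    probes_p = np.empty((n_res, 2, 3))
    comps = np.empty(8)
    comps_p = np.empty(8)

    # initial coordinates
    build_chain(tors[:n_rec], sbond[:n_rec], sangle[:n_rec], anchor_rec, coords, 0)
    pep_tmp = np.empty((npa, 3))
    build_chain(tors[n_rec:], sbond[n_rec:], sangle[n_rec:], canon_anchor, pep_tmp, 0)
    for i in range(npa):
        for d in range(3):
            pep_local[i, d] = pep_tmp[i, d]
    _transform_pep(pep_local, frameR, framet, coords, n_rec)

    (hb_rr, hp_rr, ev_rr, hb_pp, hp_pp, ev_pp, hb_x, hp_x, ev_x) = full_components(
        coords, n_rec, n_res, h, c_atom, c_q, c_res, centers, prm, radii, reach,
        satmin, satx, burown, burx, probes, comps,
    )
    e_el = comps[3]
    e_rest = comps[6]

    k = k0
    min_out[0] = comps[7]
    for i in range(n_atoms):
        for d in range(3):
            min_coords[i, d] = coords[i, d]

    # grid-state bookkeeping for the enumerable fixture
    gidx0 = 0
    gidx1 = 0
    if grid_n > 0:
        r0 = piv_list[0, 0]
        a0 = piv_list[0, 1]
        best = 1e30
        for gg in range(grid_n):
            d = abs(_wrap_angle(tors[r0, a0] - grid[gg]))
            if d < best:
                best = d
                gidx0 = gg
        if piv_list.shape[0] > 1:
            r1 = piv_list[1, 0]
            a1 = piv_list[1, 1]
            best = 1e30
            for gg in range(grid_n):
                d = abs(_wrap_angle(tors[r1, a1] - grid[gg]))
                if d < best:
                    best = d
                    gidx1 = gg

    n_rec_samp = 0

    for step in range(n_steps + 1):
        # record (state at `step` completed conformational updates)
        if step % record_every == 0:
            rec_step[n_rec_samp] = step
            rec_k[n_rec_samp] = k
            for c in range(8):
                rec_comps[n_rec_samp, c] = comps[c]
            q, rmsd, dcm = _order_params(coords, n_rec, n_res, nat_pep, contacts, contact_cut, L)
            rec_q[n_rec_samp] = q
            rec_rmsd[n_rec_samp] = rmsd
            rec_dcm[n_rec_samp] = dcm
            if store_pep == 1:
                for i in range(npa):
                    for d in range(3):
                        rec_pep[n_rec_samp, i * 3 + d] = coords[n_rec * 6 + i, d]
            if grid_n > 0:
                if piv_list.shape[0] > 1:
                    rec_state[n_rec_samp] = gidx0 * grid_n + gidx1
                else:
                    rec_state[n_rec_samp] = gidx0
            n_rec_samp += 1
        if step == n_steps:
            break

        # temperature update (simulated tempering)
        if st_every > 0 and step % st_every == 0:
            att[M_ST] += 1
            dk = 1 if np.random.random() < 0.5 else -1
            kn = k + dk
            if 0 <= kn < temps.shape[0]:
                x = -comps[7] * (1.0 / temps[kn] - 1.0 / temps[k]) + weights[kn] - weights[k]
                if x >= 0.0 or np.random.random() < math.exp(x):
                    k = kn
                    acc[M_ST] += 1

        # draw a conformational move
        u = np.random.random()
        mt = 0
        while mt < N_MOVE_TYPES - 1 and u > cum_freq[mt]:
            mt += 1
        att[mt] += 1

        for i in range(n_res):
            for d in range(3):
                tors_p[i, d] = tors[i, d]
        for a in range(3):
            framet_p[a] = framet[a]
            for b in range(3):
                frameR_p[a, b] = frameR[a, b]

        moved_pep_torsions = False
        moved_rigid = False
        moved_receptor = False
        new_gidx = -1
        piv_dim = -1

        if mt == M_REC_CHI:
            idx = mob_chi_rec[np.random.randint(0, mob_chi_rec.shape[0])]
            tors_p[idx, 2] = _wrap_angle(tors_p[idx, 2] + (2.0 * np.random.random() - 1.0) * chi_step)
            moved_receptor = True
        elif mt == M_REC_BB:
            nmob = bb_list_rec.shape[0]
            start = np.random.randint(0, nmob - BB_WINDOW + 1)
            mean = 0.0
            g8 = np.empty(BB_WINDOW)
            for l in range(BB_WINDOW):
                g8[l] = np.random.normal() * bb_step
                mean += g8[l]
            mean /= BB_WINDOW
            for l in range(BB_WINDOW):
                r = bb_list_rec[start + l, 0]
                a = bb_list_rec[start + l, 1]
                tors_p[r, a] = _wrap_angle(tors_p[r, a] + g8[l] - mean)
            moved_receptor = True
        elif mt == M_PEP_CHI:
            idx = mob_chi_pep[np.random.randint(0, mob_chi_pep.shape[0])]
            tors_p[idx, 2] = _wrap_angle(tors_p[idx, 2] + (2.0 * np.random.random() - 1.0) * chi_step)
            moved_pep_torsions = True
        elif mt == M_PEP_BB:
            nmob = bb_list_pep.shape[0]
            start = np.random.randint(0, nmob - BB_WINDOW + 1)
            mean = 0.0
            g8 = np.empty(BB_WINDOW)
            for l in range(BB_WINDOW):
                g8[l] = np.random.normal() * bb_step
                mean += g8[l]
            mean /= BB_WINDOW
            for l in range(BB_WINDOW):
                r = bb_list_pep[start + l, 0]
                a = bb_list_pep[start + l, 1]
                tors_p[r, a] = _wrap_angle(tors_p[r, a] + g8[l] - mean)
            moved_pep_torsions = True
        elif mt == M_PEP_PIVOT:
            piv_dim = np.random.randint(0, piv_list.shape[0])
            r = piv_list[piv_dim, 0]
            a = piv_list[piv_dim, 1]
            if grid_n > 0:
                new_gidx = np.random.randint(0, grid_n)
                tors_p[r, a] = grid[new_gidx]
            else:
                tors_p[r, a] = _wrap_angle(tors_p[r, a] + (2.0 * np.random.random() - 1.0) * math.pi)
            moved_pep_torsions = True
        elif mt == M_TRANSLATE:
            for d in range(3):
                framet_p[d] += (2.0 * np.random.random() - 1.0) * trans_step
                framet_p[d] -= L * math.floor(framet_p[d] / L)
            moved_rigid = True
        else:  # M_ROTATE
            ax = np.random.normal()
            ay = np.random.normal()
            az = np.random.normal()
            n = math.sqrt(ax * ax + ay * ay + az * az)
            if n < 1e-12:
                ax, ay, az, n = 1.0, 0.0, 0.0, 1.0
            ax /= n
            ay /= n
            az /= n
            ang = (2.0 * np.random.random() - 1.0) * rot_step
            ca = math.cos(ang)
            sa = math.sin(ang)
            # Rodrigues rotation matrix
            Rot = np.empty((3, 3))
            Rot[0, 0] = ca + ax * ax * (1 - ca)
            Rot[0, 1] = ax * ay * (1 - ca) - az * sa
            Rot[0, 2] = ax * az * (1 - ca) + ay * sa
            Rot[1, 0] = ay * ax * (1 - ca) + az * sa
            Rot[1, 1] = ca + ay * ay * (1 - ca)
            Rot[1, 2] = ay * az * (1 - ca) - ax * sa
            Rot[2, 0] = az * ax * (1 - ca) - ay * sa
            Rot[2, 1] = az * ay * (1 - ca) + ax * sa
            Rot[2, 2] = ca + az * az * (1 - ca)
            # rotate about the current peptide centroid
            cx = 0.0
            cy = 0.0
            cz = 0.0
            for i in range(npa):
                cx += coords[n_rec * 6 + i, 0]
                cy += coords[n_rec * 6 + i, 1]
                cz += coords[n_rec * 6 + i, 2]
            cx /= npa
            cy /= npa
            cz /= npa
            for a in range(3):
                for b in range(3):
                    s = 0.0
                    for c in range(3):
                        s += Rot[a, c] * frameR[c, b]
                    frameR_p[a, b] = s
            tx = framet[0] - cx
            ty = framet[1] - cy
            tz = framet[2] - cz
            framet_p[0] = Rot[0, 0] * tx + Rot[0, 1] * ty + Rot[0, 2] * tz + cx
            framet_p[1] = Rot[1, 0] * tx + Rot[1, 1] * ty + Rot[1, 2] * tz + cy
            framet_p[2] = Rot[2, 0] * tx + Rot[2, 1] * ty + Rot[2, 2] * tz + cz
            moved_rigid = True

        # realize proposal coordinates
        for i in range(n_atoms):
            for d in range(3):
                coords_p[i, d] = coords[i, d]
        if moved_receptor:
            build_chain(tors_p[:n_rec], sbond[:n_rec], sangle[:n_rec], anchor_rec, coords_p, 0)
        elif moved_pep_torsions:
            build_chain(tors_p[n_rec:], sbond[n_rec:], sangle[n_rec:], canon_anchor, pep_tmp, 0)
            for i in range(npa):
                for d in range(3):
                    pep_local_p[i, d] = pep_tmp[i, d]
            _transform_pep(pep_local_p, frameR_p, framet_p, coords_p, n_rec)
        else:
            for i in range(npa):
                for d in range(3):
                    pep_local_p[i, d] = pep_local[i, d]
            _transform_pep(pep_local_p, frameR_p, framet_p, coords_p, n_rec)

        # proposal energy: reuse the untouched chain's cached class sums
        for i in range(n_res):
            for c in range(2):
                satmin_p[i, c] = satmin[i, c]
                burown_p[i, c] = burown[i, c]
                for d in range(3):
                    probes_p[i, c, d] = probes[i, c, d]
        if moved_receptor:
            hb_rr_p, hp_rr_p, ev_rr_p = intra_terms(
                coords_p, 0, n_rec, h, prm, radii, reach, satmin_p, burown_p, probes_p
            )
            hb_pp_p, hp_pp_p, ev_pp_p = hb_pp, hp_pp, ev_pp
            e_rest_p = restraint_energy(coords_p, centers, prm)
        else:
            hb_pp_p, hp_pp_p, ev_pp_p = intra_terms(
                coords_p, n_rec, n_res, h, prm, radii, reach, satmin_p, burown_p, probes_p
            )
            hb_rr_p, hp_rr_p, ev_rr_p = hb_rr, hp_rr, ev_rr
            e_rest_p = e_rest
        hb_x_p, hp_x_p, ev_x_p = cross_terms(
            coords_p, n_rec, n_res, h, prm, radii, reach, satx_p, burx_p, probes_p
        )
        e_el_p = electro_energy(coords_p, n_rec, n_res, c_atom, c_q, c_res, prm, reach)
        e_solv_p = solvation_energy(satmin_p, satx_p, burown_p, burx_p, prm)
        comps_p[0] = hb_rr_p + hb_pp_p
        comps_p[1] = hb_x_p
        comps_p[2] = hp_rr_p + hp_pp_p + hp_x_p
        comps_p[3] = e_el_p
        comps_p[4] = e_solv_p
        comps_p[5] = ev_rr_p + ev_pp_p + ev_x_p
        comps_p[6] = e_rest_p
        comps_p[7] = (
            comps_p[0] + comps_p[1] + comps_p[2] + comps_p[3]
            + comps_p[4] + comps_p[5] + comps_p[6]
        )

        d_e = comps_p[7] - comps[7]
        accept = False
        if math.isfinite(d_e):
            if d_e <= 0.0:
                accept = True
            elif np.random.random() < math.exp(-d_e / temps[k]):
                accept = True

        if accept:
            acc[mt] += 1
            for i in range(n_atoms):
                for d in range(3):
                    coords[i, d] = coords_p[i, d]
            for i in range(n_res):
                for d in range(3):
                    tors[i, d] = tors_p[i, d]
            for a in range(3):
                framet[a] = framet_p[a]
                for b in range(3):
                    frameR[a, b] = frameR_p[a, b]
            if moved_pep_torsions or moved_rigid:
                for i in range(npa):
                    for d in range(3):
                        pep_local[i, d] = pep_local_p[i, d]
            for i in range(n_res):
                for c in range(2):
                    satmin[i, c] = satmin_p[i, c]
                    satx[i, c] = satx_p[i, c]
                    burown[i, c] = burown_p[i, c]
                    burx[i, c] = burx_p[i, c]
                    for d in range(3):
                        probes[i, c, d] = probes_p[i, c, d]
            hb_rr, hp_rr, ev_rr = hb_rr_p, hp_rr_p, ev_rr_p
            hb_pp, hp_pp, ev_pp = hb_pp_p, hp_pp_p, ev_pp_p
            hb_x, hp_x, ev_x = hb_x_p, hp_x_p, ev_x_p
            e_el = e_el_p
            e_rest = e_rest_p
            for c in range(8):
                comps[c] = comps_p[c]
            if mt == M_PEP_PIVOT and grid_n > 0:
                if piv_dim == 0:
                    gidx0 = new_gidx
                else:
                    gidx1 = new_gidx
            if comps[7] < min_out[0]:
                min_out[0] = comps[7]
                for i in range(n_atoms):
                    for d in range(3):
                        min_coords[i, d] = coords[i, d]

        if grid_n > 0:
            if piv_list.shape[0] > 1:
                visits[gidx0 * grid_n + gidx1] += 1
            else:
                visits[gidx0] += 1

    return k
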