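"""Numba kernels for internal-to-Cartesian chain construction.

Atom layout: every residue contributes six sites, stored contiguously in
the order N, H, Ca, C, O, S (S = single side-chain interaction site).
Bond lengths and angles are ideal peptide-unit values; omega is fixed at
180 degrees, so the only internal degrees of freedom are (phi, psi, chi).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# atom slots within a residue
AN, AH, ACA, AC, AO, AS = 0, 1, 2, 3, 4, 5
ATOMS_PER_RES = 6

# ideal geometry (Angstrom / radians)
B_N_CA = 1.458
B_CA_C = 1.525
B_C_N = 1.329
B_C_O = 1.229
B_N_H = 1.000
TH_N_CA_C = math.radians(111.0)
TH_CA_C_N = math.radians(116.6)
TH_C_N_CA = math.radians(121.7)
TH_CA_C_O = math.radians(120.5)
TH_C_N_H = math.radians(119.0)
TH_CA_N_H = math.radians(110.0)
OMEGA = math.pi

#: Ca(i)-Ca(i+1) virtual bond length implied by the ideal geometry and
#: omega = 180 (computed once at import from the constants above).
CA_CA_VIRTUAL = 0.0  # set below


@njit(cache=True)
def place_atom(a, b, c, bond, theta, tau):
    """NeRF placement: position D bonded to *c* with given internal coords.

    *bond* = |C-D|, *theta* = angle(B, C, D), *tau* = dihedral(A, B, C, D).
    """
    ab = b - a
    bc = c - b
    nbc = bc / np.sqrt(bc[0] ** 2 + bc[1] ** 2 + bc[2] ** 2)
    n = np.empty(3)
    n[0] = ab[1] * nbc[2] - ab[2] * nbc[1]
    n[1] = ab[2] * nbc[0] - ab[0] * nbc[2]
    n[2] = ab[0] * nbc[1] - ab[1] * nbc[0]
    nn = np.sqrt(n[0] ** 2 + n[1] ** 2 + n[2] ** 2)
    n = n / nn
    m = np.empty(3)
    m[0] = n[1] * nbc[2] - n[2] * nbc[1]
    m[1] = n[2] * nbc[0] - n[0] * nbc[2]
    m[2] = n[0] * nbc[1] - n[1] * nbc[0]
    st = math.sin(theta)
    d = np.empty(3)
    for k in range(3):
        d[k] = (
            -bond * math.cos(theta) * nbc[k]
            + bond * st * math.cos(tau) * m[k]
            + bond * st * math.sin(tau) * n[k]
        )
    return c + d


@njit(cache=True)
def dihedral(p0, p1, p2, p3):
    """Signed dihedral angle (radians) for atoms p0-p1-p2-p3."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.empty(3)
    n1[0] = b0[1] * b1[2] - b0[2] * b1[1]
    n1[1] = b0[2] * b1[0] - b0[0] * b1[2]
    n1[2] = b0[0] * b1[1] - b0[1] * b1[0]
    n2 = np.empty(3)
    n2[0] = b1[1] * b2[2] - b1[2] * b2[1]
    n2[1] = b1[2] * b2[0] - b1[0] * b2[2]
    n2[2] = b1[0] * b2[1] - b1[1] * b2[0]
    m1 = np.empty(3)
    nb1 = np.sqrt(b1[0] ** 2 + b1[1] ** 2 + b1[2] ** 2)
    m1[0] = (n1[1] * n2[2] - n1[2] * n2[1]) / nb1
    m1[1] = (n1[2] * n2[0] - n1[0] * n2[2]) / nb1
    m1[2] = (n1[0] * n2[1] - n1[1] * n2[0]) / nb1
    x = n1[0] * n2[0] + n1[1] * n2[1] + n1[2] * n2[2]
    y = m1[0] * b1[0] + m1[1] * b1[1] + m1[2] * b1[2]
    return math.atan2(y, x)


@njit(cache=True)
def build_chain(tors, s_bond, s_angle, anchor, coords, res0):
    """Realize one chain's Cartesian coordinates from internal coordinates.

    tors : (n_res, 3) phi, psi, chi in radians (phi of residue 0 is unused)
    s_bond, s_angle : (n_res,) side-chain site geometry
    anchor : (3, 3) positions of N, Ca, C of residue 0
    coords : output array, filled at rows [res0*6, (res0+n_res)*6)
    """
    n_res = tors.shape[0]
    if n_res == 0:
        return
    o = res0 * ATOMS_PER_RES
    # residue 0 backbone from the anchor
    for k in range(3):
        coords[o + AN, k] = anchor[0, k]
        coords[o + ACA, k] = anchor[1, k]
        coords[o + AC, k] = anchor[2, k]
    # terminal amide H: dihedral(C, Ca, N, H) = 180 deg
    coords[o + AH] = place_atom(
        coords[o + AC], coords[o + ACA], coords[o + AN], B_N_H, TH_CA_N_H, math.pi
    )
    for i in range(n_res):
        oi = (res0 + i) * ATOMS_PER_RES
        if i > 0:
            op = (res0 + i - 1) * ATOMS_PER_RES
            coords[oi + AN] = place_atom(
                coords[op + AN], coords[op + ACA], coords[op + AC],
                B_C_N, TH_CA_C_N, tors[i - 1, 1],
            )
            coords[oi + ACA] = place_atom(
                coords[op + ACA], coords[op + AC], coords[oi + AN],
                B_N_CA, TH_C_N_CA, OMEGA,
            )
            coords[oi + AC] = place_atom(
                coords[op + AC], coords[oi + AN], coords[oi + ACA],
                B_CA_C, TH_N_CA_C, tors[i, 0],
            )
            # amide H trans to the preceding Ca across the C-N bond
            coords[oi + AH] = place_atom(
                coords[op + ACA], coords[op + AC], coords[oi + AN],
                B_N_H, TH_C_N_H, 0.0,
            )
        # carbonyl O: dihedral(N, Ca, C, O) = psi + 180
        coords[oi + AO] = place_atom(
            coords[oi + AN], coords[oi + ACA], coords[oi + AC],
            B_C_O, TH_CA_C_O, tors[i, 1] + math.pi,
        )
        # side-chain site: cone about the N-Ca bond, dihedral(C, N, Ca, S) = chi
        coords[oi + AS] = place_atom(
            coords[oi + AC], coords[oi + AN], coords[oi + ACA],
            s_bond[i], s_angle[i], tors[i, 2],
        )


def _ca_ca_virtual() -> float:
    tors = np.full((2, 3), math.pi)
    coords = np.zeros((12, 3))
    anchor = np.array(
        [
            [0.0, 0.0, 0.0],
            [B_N_CA, 0.0, 0.0],
            [
                B_N_CA + B_CA_C * math.cos(math.pi - TH_N_CA_C),
                B_CA_C * math.sin(math.pi - TH_N_CA_C),
                0.0,
            ],
        ]
    )
    build_chain(tors, np.ones(2), np.full(2, math.radians(110.0)), anchor, coords, 0)
    d = coords[2] - coords[8]
    return float(np.sqrt((d * d).sum()))


def canonical_anchor() -> np.ndarray:
    """N, Ca, C positions of residue 0 in the chain-local frame."""
    return np.array(
        [
            [0.0, 0.0, 0.0],
            [B_N_CA, 0.0, 0.0],
            [
                B_N_CA + B_CA_C * math.cos(math.pi - TH_N_CA_C),
                B_CA_C * math.sin(math.pi - TH_N_CA_C),
                0.0,
            ],
        ]
    )


CA_CA_VIRTUAL = _ca_ca_virtual()
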