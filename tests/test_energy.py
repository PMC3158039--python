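"""Energy function contracts: hydrogen bonding, desolvation probes and
buriedness, hydrophobic/electrostatic/excluded-volume terms, and
agreement between the reference implementation and the compiled
kernels."""

import math

import numpy as np
import pytest

from pdzmc import _energy as ke
from pdzmc.chain import ChainSystem, NativeReference, build_chain, realize_coordinates
from pdzmc.energy import (
    EnergyBreakdown,
    EnergyParams,
    _charge_sites,
    _group_exclusions,
    _residue_chain_ids,
    buriedness,
    desolvation_energy,
    electrostatic_energy,
    excluded_volume_energy,
    hbond_energy_matrix,
    hbond_pair_energy,
    hydrophobic_energy,
    probe_point,
    restraint_energy,
    satisfied_groups,
    total_energy,
)
from conftest import random_conformation


def _extended(system, where=120.0):
    tors = np.zeros((system.n_res, 3))
    tors[:, 0] = math.radians(-120.0)
    tors[:, 1] = math.radians(130.0)
    tors[:, 2] = math.radians(-120.0)
    return realize_coordinates(system, tors, np.eye(3), np.full(3, where))


@pytest.fixture(scope="module")
def separated():
    """Two extended chains far apart in a huge box (no interactions)."""
    rec = build_chain("ASLVKASLVK", "receptor")
    pep = build_chain("KAVAV", "peptide")
    return _extended(ChainSystem(receptor=rec, peptide=pep, box_side=400.0), 300.0)


def kernel_breakdown(conf, params):
    """Evaluate the compiled energy kernel on a realized conformation."""
    system = conf.system
    n_rec = len(system.receptor)
    n_res = system.n_res
    h = np.concatenate(
        [system.receptor.hydrophobicities(), system.peptide.hydrophobicities()]
    )
    sbond = np.concatenate([system.receptor.s_bonds(), system.peptide.s_bonds()])
    c_atom, c_q, c_res = _charge_sites(system)
    centers = (
        system.native.restraint_centers
        if system.native is not None
        else np.zeros((0, 3))
    )
    prm, radii = ke.pack_params(params, system.box_side)
    satmin = np.zeros((n_res, 2))
    satx = np.zeros((n_res, 2))
    burown = np.zeros((n_res, 2))
    burx = np.zeros((n_res, 2))
    probes = np.zeros((n_res, 2, 3))
    comps = np.zeros(8)
    ke.full_components(
        conf.coords, n_rec, n_res, h, c_atom.astype(np.int64), c_q,
        c_res.astype(np.int64), np.ascontiguousarray(centers, dtype=float),
        prm, radii, ke.reach_array(sbond), satmin, satx, burown, burx, probes, comps,
    )
    return comps


class TestProbePoint:
    def test_nh_probe_2A_beyond_H(self, separated, params):
        conf = separated
        # the printed construction: probe = H + 2.0 * unit(H - N)
        for res in (0, 3, 12):
            o = res * 6
            n, hatom = conf.coords[o], conf.coords[o + 1]
            expect = hatom + 2.0 * (hatom - n) / np.linalg.norm(hatom - n)
            assert np.allclose(probe_point((res, "NH"), conf), expect, atol=1e-12)
            assert np.linalg.norm(probe_point((res, "NH"), conf) - hatom) == pytest.approx(2.0)

    def test_co_probe_2A_beyond_O(self, separated):
        for res in (1, 7):
            o = res * 6
            c, oatom = conf_c, conf_o = separated.coords[o + 3], separated.coords[o + 4]
            expect = oatom + 2.0 * (oatom - c) / np.linalg.norm(oatom - c)
            assert np.allclose(probe_point((res, "CO"), separated), expect, atol=1e-12)

    def test_synthetic_axis_cases(self, separated):
        # N=(0,0,0), H=(1,0,0) -> probe (3,0,0); C=(0,0,0), O=(0,1.23,0) -> (0,3.23,0)
        conf = separated
        coords = conf.coords.copy()
        coords[0] = (0.0, 0.0, 0.0)
        coords[1] = (1.0, 0.0, 0.0)
        coords[3] = (0.0, 0.0, 0.0)
        coords[4] = (0.0, 1.23, 0.0)
        patched = type(conf)(
            system=conf.system, torsions=conf.torsions,
            frame_rotation=conf.frame_rotation,
            frame_translation=conf.frame_translation, coords=coords,
        )
        assert np.allclose(probe_point((0, "NH"), patched), (3.0, 0.0, 0.0), atol=1e-12)
        assert np.allclose(probe_point((0, "CO"), patched), (0.0, 3.23, 0.0), atol=1e-12)


class TestHydrogenBond:
    def test_zero_beyond_cutoff(self, separated, params):
        # donor on one chain, acceptor on the far-away other chain
        assert hbond_pair_energy(0, 12, separated, params) == 0.0

    def test_ideal_geometry_minus_eps(self, separated, params):
        conf = separated
        coords = conf.coords.copy()
        # build an ideal pairing: N-H...O=C collinear, H...O at r0
        coords[0] = (0.0, 0.0, 0.0)  # N of donor residue 0
        coords[1] = (1.0, 0.0, 0.0)  # H
        o = 12 * 6
        coords[o + 4] = (1.0 + params.hb_r0, 0.0, 0.0)  # O of acceptor residue 12
        coords[o + 3] = (2.0 + params.hb_r0 + 1.23, 0.0, 0.0)  # C beyond O... wrong side
        coords[o + 3] = (1.0 + params.hb_r0 + 1.23, 0.0, 0.0)
        # C must be on the far side so that O->H continues the C->O direction
        coords[o + 3] = (1.0 + params.hb_r0 + 1.23, 0.0, 0.0)
        patched = type(conf)(
            system=conf.system, torsions=conf.torsions,
            frame_rotation=conf.frame_rotation,
            frame_translation=conf.frame_translation, coords=coords,
        )
        e = hbond_pair_energy(0, 12, patched, EnergyParams())
        assert e == pytest.approx(-EnergyParams().eps_hb, abs=1e-12)

    def test_helix_interior_satisfied(self, params):
        rec = build_chain("ASLVKASLVKASLVK", "receptor")
        pep = build_chain("KAVAV", "peptide")
        system = ChainSystem(receptor=rec, peptide=pep, box_side=400.0)
        tors = np.zeros((20, 3))
        tors[:15, 0] = math.radians(-57.0)
        tors[:15, 1] = math.radians(-47.0)
        tors[:, 2] = math.radians(-120.0)
        tors[15:, 0] = math.radians(-120.0)
        tors[15:, 1] = math.radians(130.0)
        conf = realize_coordinates(system, tors, np.eye(3), np.full(3, 300.0))
        sat = satisfied_groups(conf, params)
        # interior helix CO (acceptors i=4..10 pair with donors i+4)
        assert sat[4:10, 1].all()
        assert sat[8:11, 0].all()

    def test_extended_isolated_chain_unsatisfied(self, separated, params):
        sat = satisfied_groups(separated, params)
        assert not sat.any()

    def test_single_ideal_pair_satisfies_exactly_those_groups(self, separated, params):
        conf = separated
        coords = conf.coords.copy()
        coords[0] = (0.0, 0.0, 0.0)
        coords[1] = (1.0, 0.0, 0.0)
        o = 12 * 6
        coords[o + 4] = (3.0, 0.0, 0.0)
        coords[o + 3] = (4.23, 0.0, 0.0)
        patched = type(conf)(
            system=conf.system, torsions=conf.torsions,
            frame_rotation=conf.frame_rotation,
            frame_translation=conf.frame_translation, coords=coords,
        )
        sat = satisfied_groups(patched, params)
        assert sat[0, 0] and sat[12, 1]
        assert sat.sum() == 2


class TestBuriednessAndDesolvation:
    def test_isolated_probe_zero(self, separated, params):
        p = probe_point((4, "NH"), separated)
        chain = _residue_chain_ids(separated.system)
        b = buriedness(p, separated, params, exclude_residues=_group_exclusions(4, chain))
        assert b == 0.0

    def test_clamped_at_one_and_half_count(self, separated, params):
        conf = separated
        # count the receptor-core neighborhood of an arbitrary interior point
        pt = conf.coords[6 * 6 + 2]  # a Ca position: many own-chain atoms nearby
        b = buriedness(pt, conf, params)
        assert 0.0 <= b <= 1.0
        # construct exact counts: a point with n_sat/2 neighbors within R_b
        # (place a probe near isolated residue pair and count by hand)
        coords = conf.coords
        target = coords[0] + np.array([50.0, 0, 0])
        dist = np.linalg.norm(
            coords.reshape(-1, 6, 3)[:, (0, 2, 3, 4, 5), :].reshape(-1, 3) - target,
            axis=1,
        )
        count = int((dist < params.R_b).sum())
        assert buriedness(target, conf, params) == pytest.approx(
            min(count / params.n_sat, 1.0)
        )

    def test_desolvation_zero_when_all_satisfied(self, separated, params):
        sat = np.ones((separated.system.n_res, 2), dtype=bool)
        assert desolvation_energy(separated, params, sat=sat) == 0.0

    def test_desolvation_zero_for_exposed_extended_chains(self, separated, params):
        assert desolvation_energy(separated, params) == 0.0

    def test_single_buried_unsatisfied_group_costs_eps_solv(self, toy_class1, params):
        """Hand evaluation: one unsatisfied NH whose probe has >= n_sat
        neighbors contributes exactly eps_solv."""
        st = toy_class1.native_state
        conf = realize_coordinates(toy_class1, st.torsions, st.frame_rotation, st.frame_translation)
        sat = satisfied_groups(conf, params)
        chain = _residue_chain_ids(conf.system)
        # find a buried unsatisfied group and verify the sum term by term
        total = desolvation_energy(conf, params, sat=sat)
        manual = 0.0
        for res in range(conf.system.n_res):
            for col, kind in ((0, "NH"), (1, "CO")):
                if sat[res, col]:
                    continue
                b = buriedness(
                    probe_point((res, kind), conf), conf, params,
                    exclude_residues=_group_exclusions(res, chain),
                )
                manual += params.eps_solv * b
        assert total == pytest.approx(manual, abs=1e-12)
        assert total > 0  # the bound interface buries some unsatisfied groups


class TestHydrophobicAndElectrostatic:
    def test_hp_zero_when_far(self, separated, params):
        # chains far apart: only intra-chain contacts remain; move them apart too
        rec = build_chain("GG", "receptor")  # low-content chain
        pep = build_chain("GG", "peptide")
        conf = _extended(ChainSystem(receptor=rec, peptide=pep, box_side=400.0), 300.0)
        assert hydrophobic_energy(conf, params) == 0.0

    def test_full_contact_minus_eps(self, params):
        rec = build_chain("GIG", "receptor")  # I has h = 1
        pep = build_chain("GGIG", "peptide")
        system = ChainSystem(receptor=rec, peptide=pep, box_side=400.0)
        conf = _extended(system, 300.0)
        coords = conf.coords.copy()
        # place the two unit-weight side-chain sites within r_on, jam the
        # rest of both chains far away from everything
        coords[1 * 6 + 5] = (0.0, 0.0, 0.0)
        coords[(3 + 2) * 6 + 5] = (params.r_on - 1.0, 0.0, 0.0)
        patched = type(conf)(
            system=system, torsions=conf.torsions,
            frame_rotation=conf.frame_rotation,
            frame_translation=conf.frame_translation, coords=coords,
        )
        e = hydrophobic_energy(patched, params)
        # subtract contributions not involving the pair of interest
        coords2 = coords.copy()
        coords2[(3 + 2) * 6 + 5] = (200.0, 0.0, 0.0)
        rest = hydrophobic_energy(
            type(conf)(
                system=system, torsions=conf.torsions,
                frame_rotation=conf.frame_rotation,
                frame_translation=conf.frame_translation, coords=coords2,
            ),
            params,
        )
        assert e - rest == pytest.approx(-params.eps_hp, rel=1e-6)

    def test_el_zero_without_charges(self, params):
        rec = build_chain("ASGT", "receptor")
        pep = build_chain("ASGTA", "peptide")
        pep = type(pep)(sequence=pep.sequence, role="peptide",
                        c_terminal_carboxylate=False, n_terminal_charge=False)
        conf = _extended(ChainSystem(receptor=rec, peptide=pep, box_side=400.0), 300.0)
        assert electrostatic_energy(conf, params) == 0.0

    def test_buriedness_enhancement_ratio(self, params):
        """A fixed +/- pair is stronger by exactly (1 + gamma) when both
        charge sites go from solvent-exposed (b=0) to fully buried (b=1)."""
        rec = build_chain("KGGGGG", "receptor")
        pep = type(build_chain("GDGGG", "peptide"))(
            sequence=build_chain("GDGGG", "peptide").sequence, role="peptide",
            c_terminal_carboxylate=False, n_terminal_charge=False,
        )
        system = ChainSystem(receptor=rec, peptide=pep, box_side=4000.0)
        conf = _extended(system, 2000.0)
        coords = np.full_like(conf.coords, 500.0)
        # scatter everything far apart, then place the two charge sites
        coords += np.arange(coords.shape[0])[:, None] * 37.0
        k_site = 0 * 6 + 5  # receptor K side-chain site
        d_site = (6 + 1) * 6 + 5  # peptide D side-chain site
        r = 5.0
        coords[k_site] = (0.0, 0.0, 0.0)
        coords[d_site] = (r, 0.0, 0.0)
        exposed = type(conf)(
            system=system, torsions=conf.torsions,
            frame_rotation=conf.frame_rotation,
            frame_translation=conf.frame_translation, coords=coords,
        )
        e0 = electrostatic_energy(exposed, params)
        # bury both sites: pack another residue's 5 heavy atoms within R_b
        buried_coords = coords.copy()
        for res, site in ((2, k_site), (6 + 3, d_site)):
            for slot in (0, 2, 3, 4, 5):
                buried_coords[res * 6 + slot] = coords[site] + np.array([0.0, 2.0, 0.1 * slot])
        buried = type(conf)(
            system=system, torsions=conf.torsions,
            frame_rotation=conf.frame_rotation,
            frame_translation=conf.frame_translation, coords=buried_coords,
        )
        e1 = electrostatic_energy(buried, params)
        assert e0 < 0  # attraction
        assert e1 / e0 == pytest.approx(1 + params.gamma_el, rel=1e-9)


class TestTotalEnergy:
    def test_restraint_zero_at_native(self, toy_class1, params):
        st = toy_class1.native_state
        conf = realize_coordinates(toy_class1, st.torsions, st.frame_rotation, st.frame_translation)
        assert restraint_energy(conf, params) == pytest.approx(0.0, abs=1e-16)

    def test_total_is_component_sum(self, toy_class1, params, rng):
        conf = random_conformation(toy_class1, rng)
        bd = total_energy(conf, params)
        parts = (
            bd.E_hb_intra + bd.E_hb_inter + bd.E_hp + bd.E_el
            + bd.E_solv + bd.E_ev + bd.E_restraint
        )
        assert bd.E_total == pytest.approx(parts, abs=1e-9)

    def test_breakdown_rejects_bad_total(self):
        with pytest.raises(ValueError):
            EnergyBreakdown(1, 1, 0, 0, 0, 0, 0, E_total=99.0)

    def test_kernel_matches_reference_on_random_states(self, toy_class1, params, rng):
        """The compiled kernel (the engine's evaluation path) must equal
        the reference implementation term by term."""
        for _ in range(25):
            conf = random_conformation(toy_class1, rng)
            ref = total_energy(conf, params).as_array()
            got = kernel_breakdown(conf, params)
            assert np.allclose(ref, got, atol=1e-9), (ref, got)


class TestEnergyProperties:
    N_RANDOM = 1000

    def test_sign_contracts_on_random_conformations(self, toy_class1, params, rng):
        """E_hp <= 0, E_solv >= 0, E_ev >= 0, E_restraint >= 0 on 1000
        random states (kernel path for speed; kernel == reference is
        asserted separately)."""
        for _ in range(self.N_RANDOM):
            conf = random_conformation(toy_class1, rng)
            comps = kernel_breakdown(conf, params)
            hb_i, hb_x, hp, el, solv, ev, rest, tot = comps
            assert hp <= 0.0
            assert solv >= 0.0
            assert ev >= 0.0
            assert rest >= 0.0
            assert hb_i <= 0.0 and hb_x <= 0.0
            assert np.isfinite(tot)

    def test_rigid_motion_invariance(self, small_system, params, rng):
        tors = rng.uniform(-math.pi, math.pi, (15, 3))
        big = ChainSystem(
            receptor=small_system.receptor, peptide=small_system.peptide, box_side=4000.0
        )
        a = realize_coordinates(big, tors, np.eye(3), np.full(3, 2000.0))
        bd_a = total_energy(a, params)
        # translate + rotate the whole system rigidly
        theta = 0.7
        rot = np.array(
            [
                [math.cos(theta), -math.sin(theta), 0],
                [math.sin(theta), math.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        shifted = a.coords @ rot.T + np.array([11.0, -7.0, 3.0])
        b = type(a)(
            system=big, torsions=a.torsions, frame_rotation=a.frame_rotation,
            frame_translation=a.frame_translation, coords=shifted,
        )
        bd_b = total_energy(b, params)
        assert np.allclose(bd_a.as_array(), bd_b.as_array(), atol=1e-8)

    def test_energy_continuity_in_torsions(self, toy_class1, params):
        st = toy_class1.native_state
        conf = realize_coordinates(toy_class1, st.torsions, st.frame_rotation, st.frame_translation)
        e0 = kernel_breakdown(conf, params)[7]
        tors = st.torsions.copy()
        tors[12, 1] += 1e-6
        conf2 = realize_coordinates(toy_class1, tors, st.frame_rotation, st.frame_translation)
        e1 = kernel_breakdown(conf2, params)[7]
        assert abs(e1 - e0) < 1e-3  # O(1e-5) expected; generous bound
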