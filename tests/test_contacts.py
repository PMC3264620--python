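"""Hydrogen-bond and contact criteria against brute-force distance oracles."""

import numpy as np
import pytest

from abhelix.contacts import (
    contact_map,
    count_alpha_hbs,
    detect_hbonds,
    dual_mode_binding,
    ligand_peptide_hbonds,
    nonpolar_contacts,
    peptide_acceptors,
    peptide_donors,
    residue_ligand_contact,
    backbone_donors,
)
from abhelix.geometry import RigidTransform, sidechain_center_of_geometry
from abhelix.model_io import (
    AtomRecord,
    Frame,
    Topology,
    Trajectory,
    attach_ligand,
    build_peptide,
)
from scipy.spatial.transform import Rotation

from conftest import move_ligand_atom


def brute_force_hbonds(frame, topology, donors, acceptors, cutoff):
    """Independent all-pairs oracle for the HB criterion."""
    out = set()
    for d, h in donors:
        for a in acceptors:
            da, aa = topology.atoms[d], topology.atoms[a]
            if da.segment == aa.segment and da.residue_index == aa.residue_index:
                continue
            dist = float(np.linalg.norm(frame.coords[h] - frame.coords[a]))
            if dist <= cutoff:
                out.add((h, a))
    return out


class TestHBondCriterion:
    @pytest.mark.parametrize("dist,expected", [(2.39, 1), (2.40, 1),
                                               (2.41, 0)])
    def test_cutoff_boundary(self, dist, expected):
        """A bond exists exactly when the acceptor-H distance is <= 2.4 A."""
        atoms = [
            AtomRecord("NZ", "N", 13, "LYS", "peptide",
                       attached_polar_hydrogens=("HZ1",)),
            AtomRecord("HZ1", "H", 13, "LYS", "peptide"),
            AtomRecord("OD1", "O", 14, "ASP", "peptide",
                       is_hb_acceptor=True),
        ]
        topo = Topology(atoms=atoms, sequence="KD", first_index=13)
        frame = Frame(0.0, np.array([
            [-1.0, 0, 0], [0.0, 0, 0], [dist, 0, 0],
        ]))
        bonds = detect_hbonds(frame, topo, [(0, 1)], [2])
        assert len(bonds) == expected

    def test_ideal_helix_backbone_pairs_only_i_i4(self, ideal_helix):
        """Backbone donors/acceptors yield exactly the ten (i, i+4) bonds."""
        topo, frame = ideal_helix
        donors = backbone_donors(topo)
        acceptors = [i for i, a in enumerate(topo.atoms)
                     if a.is_hb_acceptor and a.is_backbone]
        bonds = detect_hbonds(frame, topo, donors, acceptors)
        got = {(b.hydrogen_index, b.acceptor_index) for b in bonds}
        assert got == brute_force_hbonds(frame, topo, donors, acceptors, 2.4)
        pairs = set()
        for b in bonds:
            dres = topo.atoms[b.donor_index].residue_index
            ares = topo.atoms[b.acceptor_index].residue_index
            pairs.add((ares, dres))
        # the caps extend the same geometry: ACE O reaches HN(16) and
        # O(23) reaches the amide cap NH2, giving (12,16) and (23,27)
        expected = {(i, i + 4) for i in range(12, 24)}
        assert pairs == expected

    def test_alpha_hb_region_restriction(self, ideal_helix):
        topo, frame = ideal_helix
        assert count_alpha_hbs(frame, topo, (13, 26)) == 10
        assert count_alpha_hbs(frame, topo, (15, 24)) == 6
        assert count_alpha_hbs(frame, topo, (15, 19)) == 1

    def test_alpha_hb_never_exceeds_six_and_non_increasing(self):
        """Unwinding the helix never raises the middle-region HB count."""
        prev = 7
        for lam in np.linspace(0.0, 1.0, 11):
            phi = -57.0 + lam * (-135.0 + 57.0)
            psi = -47.0 + lam * (135.0 + 47.0)
            topo, fr = build_peptide("HHQKLVFFAEDVGS", 13, phi, psi)
            n = count_alpha_hbs(fr, topo)
            assert 0 <= n <= 6
            assert n <= prev
            prev = n


class TestLigandHBonds:
    def test_detached_ligand_no_bonds(self, helix_with_dec):
        topo, frame = helix_with_dec
        assert ligand_peptide_hbonds(frame, topo) == []

    def test_missing_ligand_fails(self, ideal_helix):
        topo, frame = ideal_helix
        with pytest.raises(ValueError, match="no ligand"):
            ligand_peptide_hbonds(frame, topo)

    def test_constructed_salt_bridge_detected(self, helix_with_dec):
        """A donor H placed 1.9 A from D23 Od1 registers as one bond."""
        topo, frame = helix_with_dec
        od1 = frame.coords[topo.atom_index(23, "OD1")]
        frame2 = move_ligand_atom(topo, frame, "HN3",
                                  od1 + np.array([1.9, 0, 0]))
        frame2 = move_ligand_atom(topo, frame2, "N3",
                                  od1 + np.array([2.9, 0, 0]))
        bonds = ligand_peptide_hbonds(frame2, topo)
        assert len(bonds) == 1
        b = bonds[0]
        assert topo.atoms[b.acceptor_index].atom_name == "OD1"
        assert topo.atoms[b.hydrogen_index].atom_name == "HN3"

    def test_bifurcated_bond_counts_per_pair(self, helix_with_dec):
        """One hydrogen within the cutoff of both D23 carboxylate oxygens
        counts twice (per acceptor pair)."""
        topo, frame = helix_with_dec
        od1 = frame.coords[topo.atom_index(23, "OD1")]
        od2 = frame.coords[topo.atom_index(23, "OD2")]
        mid = (od1 + od2) / 2
        axis = od2 - od1
        normal = np.cross(axis, [0.0, 0.0, 1.0])
        normal /= np.linalg.norm(normal)
        h_pos = mid + 1.5 * normal
        assert np.linalg.norm(h_pos - od1) <= 2.4
        assert np.linalg.norm(h_pos - od2) <= 2.4
        frame2 = move_ligand_atom(topo, frame, "HN3", h_pos)
        frame2 = move_ligand_atom(topo, frame2, "N3", h_pos + [0, 0, 1.0])
        bonds = ligand_peptide_hbonds(frame2, topo)
        names = sorted(topo.atoms[b.acceptor_index].atom_name for b in bonds)
        assert names == ["OD1", "OD2"]


class TestDualModeBinding:
    def test_two_sided_binding_true(self, helix_with_pep, pep_spec):
        """Basic->E22 and H13->acidic bonds in one frame: dual mode."""
        topo, frame = helix_with_pep
        oe2 = frame.coords[topo.atom_index(22, "OE2")]
        frame2 = move_ligand_atom(topo, frame, "HN7",
                                  oe2 + np.array([1.9, 0, 0]))
        hd1 = frame2.coords[topo.atom_index(13, "HD1")]
        frame2 = move_ligand_atom(topo, frame2, "O4",
                                  hd1 + np.array([0, 1.9, 0]))
        bonds = ligand_peptide_hbonds(frame2, topo)
        assert dual_mode_binding(bonds, topo, pep_spec)

    def test_one_sided_binding_false(self, helix_with_pep, pep_spec):
        topo, frame = helix_with_pep
        oe2 = frame.coords[topo.atom_index(22, "OE2")]
        frame2 = move_ligand_atom(topo, frame, "HN7",
                                  oe2 + np.array([1.9, 0, 0]))
        bonds = ligand_peptide_hbonds(frame2, topo)
        assert bonds and not dual_mode_binding(bonds, topo, pep_spec)

    def test_empty_list_false(self, helix_with_pep, pep_spec):
        topo, _ = helix_with_pep
        assert not dual_mode_binding([], topo, pep_spec)

    def test_ligand_without_acidic_groups_always_false(self, helix_with_dec,
                                                       dec_spec):
        topo, frame = helix_with_dec
        od1 = frame.coords[topo.atom_index(23, "OD1")]
        frame2 = move_ligand_atom(topo, frame, "HN3",
                                  od1 + np.array([1.9, 0, 0]))
        bonds = ligand_peptide_hbonds(frame2, topo)
        assert bonds and not dual_mode_binding(bonds, topo, dec_spec)


class TestResidueLigandContacts:
    @pytest.mark.parametrize("dist,expected", [(5.99, True), (6.01, False)])
    def test_cog_cutoff_boundary(self, helix_with_dec, dist, expected):
        # the <=-inclusive boundary itself is exercised with exactly
        # representable coordinates in TestHBondCriterion
        topo, frame = helix_with_dec
        cog = sidechain_center_of_geometry(frame, topo, 18)
        frame2 = move_ligand_atom(topo, frame, "C5",
                                  cog + np.array([dist, 0, 0]))
        assert residue_ligand_contact(frame2, topo, 18, "C5") is expected

    def test_coincident_atom_in_contact(self, helix_with_dec):
        topo, frame = helix_with_dec
        cog = sidechain_center_of_geometry(frame, topo, 20)
        frame2 = move_ligand_atom(topo, frame, "C1", cog)
        assert residue_ligand_contact(frame2, topo, 20, "C1")

    def test_agrees_with_exhaustive_oracle(self, helix_with_dec, dec_spec):
        """Randomly placed ligand: criterion matches direct recomputation
        for every (residue, atom) pair."""
        topo, frame = helix_with_dec
        rng = np.random.default_rng(21)
        coords = frame.coords.copy()
        lig_idx = [topo.atom_index(0, n, "ligand")
                   for n in dec_spec.heavy_atoms]
        center = frame.coords[:20].mean(axis=0)
        coords[lig_idx] = center + rng.normal(0, 6.0,
                                              (len(lig_idx), 3))
        frame2 = Frame(0.0, coords)
        for ri in topo.residue_indices:
            cog = sidechain_center_of_geometry(frame2, topo, ri)
            for n in dec_spec.heavy_atoms:
                direct = np.linalg.norm(
                    cog - frame2.coords[topo.atom_index(0, n, "ligand")]
                ) <= 6.0
                assert residue_ligand_contact(frame2, topo, ri, n) == direct


class TestContactMap:
    def _traj_with_occupancy(self, helix_with_dec, bound_pattern):
        topo, frame = helix_with_dec
        cog18 = sidechain_center_of_geometry(frame, topo, 18)
        frames = []
        for k, bound in enumerate(bound_pattern):
            f = frame
            if bound:
                f = move_ligand_atom(topo, frame, "C5", cog18 + [1.0, 0, 0])
            frames.append(Frame(10.0 * k, f.coords))
        return Trajectory(topo, frames, stride_ps=10.0)

    def test_half_occupancy_gives_half_probability(self, helix_with_dec,
                                                   dec_spec):
        traj = self._traj_with_occupancy(helix_with_dec,
                                         [True, False] * 5)
        cmap = contact_map(traj, dec_spec)
        assert cmap.loc[18, "C5"] == pytest.approx(0.5)
        assert cmap.loc[18, "C9"] == 0.0
        assert ((cmap.values >= 0) & (cmap.values <= 1)).all()

    def test_permanent_contact_gives_one(self, helix_with_dec, dec_spec):
        traj = self._traj_with_occupancy(helix_with_dec, [True] * 4)
        cmap = contact_map(traj, dec_spec)
        assert cmap.loc[18, "C5"] == 1.0
        assert cmap.loc[13, "C5"] == 0.0

    def test_rigid_motion_invariance(self, helix_with_dec, dec_spec):
        traj = self._traj_with_occupancy(helix_with_dec, [True, False, True])
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        tf = RigidTransform(rot, np.array([3.0, -8.0, 1.0]))
        moved = Trajectory(
            traj.topology,
            [Frame(f.time_ps, tf.apply(f.coords)) for f in traj.frames],
            traj.stride_ps,
        )
        a = contact_map(traj, dec_spec)
        b = contact_map(moved, dec_spec)
        assert np.allclose(a.values, b.values)

    def test_rows_and_columns(self, helix_with_dec, dec_spec):
        traj = self._traj_with_occupancy(helix_with_dec, [True])
        cmap = contact_map(traj, dec_spec)
        assert list(cmap.index) == list(range(13, 27))
        assert list(cmap.columns) == list(dec_spec.heavy_atoms)


class TestNonpolarContacts:
    def test_detached_ligand_zero(self, helix_with_dec, dec_spec):
        topo, frame = helix_with_dec
        assert nonpolar_contacts(frame, topo, dec_spec) == 0

    def test_single_constructed_contact(self, helix_with_dec, dec_spec):
        """One ligand atom placed outward 4.9 A off V18 Cg1 touches only
        that carbon."""
        topo, frame = helix_with_dec
        cg1 = frame.coords[topo.atom_index(18, "CG1")]  # V18 sidechain
        heavy = [i for i, a in enumerate(topo.atoms)
                 if a.segment == "peptide" and a.is_heavy]
        center = frame.coords[heavy].mean(axis=0)
        u = (cg1 - center) / np.linalg.norm(cg1 - center)
        pos = cg1 + 4.9 * u
        # premise: exactly one eligible peptide carbon sits within 5 A
        eligible = [i for i, a in enumerate(topo.atoms)
                    if a.segment == "peptide" and a.element == "C"
                    and 17 <= a.residue_index <= 21
                    and not a.is_backbone_carbonyl_carbon]
        near = [i for i in eligible
                if np.linalg.norm(frame.coords[i] - pos) <= 5.0]
        assert near == [topo.atom_index(18, "CG1")]
        frame2 = move_ligand_atom(topo, frame, "C5", pos)
        assert nonpolar_contacts(frame2, topo, dec_spec) == 1

    def test_backbone_carbonyl_excluded(self, helix_with_dec, dec_spec):
        """A ligand atom close only to a backbone C=O carbon counts zero."""
        topo, frame = helix_with_dec
        c19 = frame.coords[topo.atom_index(19, "C")]
        # offset along the carbonyl O direction, away from other carbons
        o19 = frame.coords[topo.atom_index(19, "O")]
        u = (o19 - c19) / np.linalg.norm(o19 - c19)
        frame2 = move_ligand_atom(topo, frame, "C5", c19 + 4.9 * u)
        d_to_c = np.linalg.norm(frame2.coords[
            topo.atom_index(0, "C5", "ligand")] - c19)
        assert d_to_c <= 5.0
        pep_c = [i for i, a in enumerate(topo.atoms)
                 if a.segment == "peptide" and a.element == "C"
                 and 17 <= a.residue_index <= 21
                 and not a.is_backbone_carbonyl_carbon]
        lig = frame2.coords[topo.atom_index(0, "C5", "ligand")]
        n_direct = sum(
            np.linalg.norm(frame2.coords[i] - lig) <= 5.0 for i in pep_c
        )
        assert nonpolar_contacts(frame2, topo, dec_spec) == n_direct

    def test_randomized_frame_matches_oracle(self, helix_with_dec, dec_spec):
        topo, frame = helix_with_dec
        rng = np.random.default_rng(33)
        coords = frame.coords.copy()
        lig_idx = [topo.atom_index(0, n, "ligand")
                   for n in dec_spec.heavy_atoms]
        center = frame.coords[topo.atom_index(19, "CA")]
        coords[lig_idx] = center + rng.normal(0, 4.0, (len(lig_idx), 3))
        frame2 = Frame(0.0, coords)
        count = 0
        for i, a in enumerate(topo.atoms):
            if (a.segment != "peptide" or a.element != "C"
                    or not (17 <= a.residue_index <= 21)
                    or a.is_backbone_carbonyl_carbon):
                continue
            for n in dec_spec.nonpolar_atoms:
                j = topo.atom_index(0, n, "ligand")
                if np.linalg.norm(frame2.coords[i] - frame2.coords[j]) <= 5.0:
                    count += 1
        assert nonpolar_contacts(frame2, topo, dec_spec) == count
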