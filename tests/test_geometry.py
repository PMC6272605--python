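import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import (branched_chain, brute_force_automorphisms,
                      brute_force_min_rmsd, propane_like, square_ring)
from consdock.fixtures import (benzene, decamer_ligand, ethane_heavy,
                               linear_chain_cno)
from consdock.geometry import (HBondContact, detect_clashes, detect_hbonds,
                               enumerate_automorphisms, kabsch_rmsd,
                               pose_rmsd, rmsd_matrix, superpose)
from consdock.pose_model import (Atom, MolecularGraph, Pose, PoseError,
                                 ProteinStructure)


def _rot_z(deg):
    th = np.radians(deg)
    return np.array([[np.cos(th), -np.sin(th), 0],
                     [np.sin(th), np.cos(th), 0], [0, 0, 1]])


class TestAutomorphisms:
    @pytest.mark.parametrize("graph_fn,expected", [
        (benzene, 12),          # dihedral symmetry of the ring
        (ethane_heavy, 2),
        (linear_chain_cno, 1),
        (square_ring, 8),
        (propane_like, 2),
        (branched_chain, 1),
        (decamer_ligand, 1),
    ])
    def test_counts_match_brute_force(self, graph_fn, expected):
        g = graph_fn()
        maps = enumerate_automorphisms(g)
        assert len(maps) == expected
        assert set(maps) == set(brute_force_automorphisms(g))

    def test_identity_first(self):
        maps = enumerate_automorphisms(benzene())
        assert maps[0] == tuple(range(6))

    def test_cap_falls_back_to_identity(self):
        with pytest.warns(UserWarning, match="cap"):
            maps = enumerate_automorphisms(benzene(), limit=5)
        assert maps == [tuple(range(6))]

    def test_disconnected_heavy_graph_rejected(self):
        g = MolecularGraph([Atom("C", [0, 0, 0]), Atom("C", [5, 0, 0])], {})
        with pytest.raises(PoseError, match="connected"):
            enumerate_automorphisms(g)


class TestPoseRmsd:
    def test_identical_poses_zero(self, decamer_pose):
        assert pose_rmsd(decamer_pose, decamer_pose).value == pytest.approx(0.0, abs=1e-12)

    def test_rigid_translation_exact(self, decamer_pose):
        moved = Pose("decamer", decamer_pose.graph.translated([2.0, 0, 0]))
        assert pose_rmsd(decamer_pose, moved).value == pytest.approx(2.0, abs=1e-12)

    def test_benzene_sixty_degree_rotation(self, benzene_pose):
        rotated = Pose("benzene", benzene_pose.graph.transformed(_rot_z(60), np.zeros(3)))
        with_sym = pose_rmsd(benzene_pose, rotated).value
        without = pose_rmsd(benzene_pose, rotated, symmetry=False).value
        assert with_sym == pytest.approx(0.0, abs=1e-9)
        assert without > 1.0

    def test_symmetry_minimum_matches_brute_force(self):
        rng = np.random.default_rng(11)
        for graph_fn in (benzene, square_ring, propane_like, linear_chain_cno):
            base = Pose("m", graph_fn())
            jitter = graph_fn()
            moved = MolecularGraph(
                [Atom(a.element, a.coords + rng.normal(scale=0.4, size=3))
                 for a in jitter.atoms], dict(jitter.bonds))
            other = Pose("m", moved)
            got = pose_rmsd(base, other).value
            assert got == pytest.approx(brute_force_min_rmsd(base, other), abs=1e-9)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_symmetric_and_bounded_by_identity(self, seed):
        rng = np.random.default_rng(seed)
        g = benzene()
        moved = MolecularGraph(
            [Atom(a.element, a.coords + rng.normal(scale=0.8, size=3))
             for a in g.atoms], dict(g.bonds))
        a, b = Pose("m", g), Pose("m", moved)
        d_ab = pose_rmsd(a, b).value
        d_ba = pose_rmsd(b, a).value
        d_id = pose_rmsd(a, b, symmetry=False).value
        d_fit = pose_rmsd(a, b, superpose_first=True).value
        assert d_ab == pytest.approx(d_ba, abs=1e-9)
        assert d_ab <= d_id + 1e-12
        assert d_fit <= d_ab + 1e-9

    def test_atom_reordering_resolved_by_graph_match(self, decamer_pose):
        g = decamer_pose.graph
        order = [3, 0, 5, 1, 9, 2, 8, 4, 7, 6]
        inv = {old: new for new, old in enumerate(order)}
        reordered = MolecularGraph(
            [g.atoms[i] for i in order],
            {(inv[i], inv[j]): o for (i, j), o in g.bonds.items()})
        other = Pose("decamer", reordered)
        assert pose_rmsd(decamer_pose, other).value == pytest.approx(0.0, abs=1e-12)

    def test_element_mismatch_errors(self, benzene_pose, chain_pose):
        chain_pose.compound_id = "benzene"
        with pytest.raises(PoseError, match="element multiset"):
            pose_rmsd(benzene_pose, chain_pose)

    def test_topology_mismatch_errors(self):
        ring = Pose("m", square_ring())
        open_chain = MolecularGraph(
            [Atom("C", [i * 1.5, 0, 0]) for i in range(4)],
            {(0, 1): 1.0, (1, 2): 1.0, (2, 3): 1.0})
        with pytest.raises(PoseError, match="isomorphism"):
            pose_rmsd(ring, Pose("m", open_chain))


class TestRmsdMatrix:
    def test_identical_poses_all_zero(self, decamer_pose):
        poses = [Pose("decamer", decamer_pose.graph, engine_id=f"e{i}",
                      receptor_id="r1") for i in range(4)]
        m = rmsd_matrix(poses)
        np.testing.assert_allclose(m.values, 0.0, atol=1e-12)

    def test_two_poses_translation(self, decamer_pose):
        other = Pose("decamer", decamer_pose.graph.translated([0, 3.0, 0]),
                     engine_id="e2", receptor_id="r1")
        m = rmsd_matrix([decamer_pose, other])
        np.testing.assert_allclose(m.values, [[0, 3], [3, 0]], atol=1e-12)

    def test_planted_displacements_recovered(self):
        base = decamer_ligand()
        shifts = [0.0, 0.7, 1.8, 4.0]   # along one axis: pairwise = |Δ|
        poses = [Pose("c", base.translated([s, 0, 0]), engine_id=f"e{i}",
                      receptor_id="r1") for i, s in enumerate(shifts)]
        m = rmsd_matrix(poses)
        expected = np.abs(np.subtract.outer(shifts, shifts))
        np.testing.assert_allclose(m.values, expected, atol=1e-6)

    def test_error_names_offending_pair(self, benzene_pose):
        other = Pose("benzene", linear_chain_cno(), engine_id="e2",
                     receptor_id="r1")
        with pytest.raises(PoseError, match=r"\(0,1\)"):
            rmsd_matrix([benzene_pose, other])

    def test_mixed_compounds_rejected(self, benzene_pose, chain_pose):
        with pytest.raises(PoseError, match="share compound"):
            rmsd_matrix([benzene_pose, chain_pose])


class TestSuperposition:
    def _manual_kabsch(self, P, Q):
        # SVD Kabsch oracle, written independently of the implementation
        Pc, Qc = P - P.mean(0), Q - Q.mean(0)
        C = Pc.T @ Qc
        U, S, Vt = np.linalg.svd(C)
        d = np.sign(np.linalg.det(U @ Vt))
        D = np.diag([1.0, 1.0, d])
        R = U @ D @ Vt
        return float(np.sqrt(np.mean(np.sum((Qc @ R.T - Pc) ** 2, axis=1))))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_manual_svd(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.normal(size=(12, 3))
        Q = P @ _rot_z(37).T + rng.normal(scale=0.3, size=(12, 3)) + [4, 1, -2]
        assert kabsch_rmsd(P, Q) == pytest.approx(self._manual_kabsch(P, Q), abs=1e-7)

    def test_rigid_motion_removed(self):
        rng = np.random.default_rng(0)
        P = rng.normal(size=(10, 3))
        Q = P @ _rot_z(63).T + [1.0, -2.0, 0.5]
        assert kabsch_rmsd(P, Q) == pytest.approx(0.0, abs=1e-7)
        R, t, _ = superpose(Q, P)
        np.testing.assert_allclose(Q @ R.T + t, P, atol=1e-7)


def _protein(coords, elements=None, labels=None):
    n = len(coords)
    return ProteinStructure(np.asarray(coords, float),
                            elements or ["C"] * n,
                            labels or ["ALA1"] * n)


class TestClashes:
    def test_distant_ligand_no_clash(self, decamer_pose):
        prot = _protein(decamer_pose.graph.heavy_coords() + [50.0, 0, 0])
        assert detect_clashes(decamer_pose.graph, prot) == []

    def test_threshold_arithmetic(self):
        # C/C: 0.75 * (1.7 + 1.7) = 2.55 Å cutoff
        lig = MolecularGraph([Atom("C", [0, 0, 0])], {})
        assert len(detect_clashes(lig, _protein([[1.0, 0, 0]]))) == 1
        assert detect_clashes(lig, _protein([[2.56, 0, 0]])) == []

    def test_planted_overlaps_counted_exactly(self):
        rng = np.random.default_rng(3)
        base = decamer_ligand()
        lig_xyz = base.heavy_coords()
        far = rng.uniform(30, 60, size=(40, 3))
        k = 5
        planted = lig_xyz[:k] + rng.normal(scale=0.05, size=(k, 3))
        prot = _protein(np.vstack([far, planted]))
        clashes = detect_clashes(base, prot)
        # oracle: brute-force all-pairs scan
        expected = 0
        scale, r = 0.75, 1.7
        from consdock.geometry import BONDI_RADII
        for i in base.heavy_indices:
            for p, pc in enumerate(prot.coords):
                cut = scale * (BONDI_RADII.get(base.atoms[i].element, 1.7) + r)
                if np.linalg.norm(base.atoms[i].coords - pc) < cut:
                    expected += 1
        assert len(clashes) == expected >= k

    def test_empty_protein_gives_empty(self, decamer_pose):
        prot = ProteinStructure(np.zeros((0, 3)), [], [])
        assert detect_clashes(decamer_pose.graph, prot) == []


class TestHBonds:
    def _arg_fixture(self, n_dist=2.8):
        """A guanidinium-like N placed n_dist Å from a ligand hydroxyl O,
        near-linear with the O-H bond."""
        lig = MolecularGraph(
            [Atom("O", [0, 0, 0]), Atom("H", [0.96, 0, 0]),
             Atom("C", [-1.4, 0, 0])],
            {(0, 1): 1.0, (0, 2): 1.0})
        prot = _protein([[n_dist, 0.05, 0]], elements=["N"], labels=["ARG169"])
        return lig, prot

    def test_near_linear_contact_found(self):
        lig, prot = self._arg_fixture()
        contacts = detect_hbonds(lig, prot)
        assert len(contacts) == 1
        c = contacts[0]
        assert c.residue == "ARG169" and c.ligand_is_donor
        assert c.distance == pytest.approx(2.8, abs=0.01)
        assert c.angle > 150

    def test_beyond_cutoff_no_contact(self):
        lig, prot = self._arg_fixture(n_dist=5.0)
        assert detect_hbonds(lig, prot) == []

    def test_bent_donor_geometry_rejected(self):
        lig = MolecularGraph(
            [Atom("O", [0, 0, 0]), Atom("H", [0.96, 0, 0]),
             Atom("C", [-1.4, 0, 0])],
            {(0, 1): 1.0, (0, 2): 1.0})
        # acceptor behind the donor: D-H...A angle far below 120°
        prot = _protein([[-2.0, 2.0, 0]], elements=["N"], labels=["ARG169"])
        assert detect_hbonds(lig, prot) == []

    def test_residue_filter_semantics(self):
        lig = MolecularGraph([Atom("O", [0, 0, 0]), Atom("C", [-1.4, 0, 0])],
                             {(0, 1): 1.0})
        prot = _protein([[2.9, 0, 0]], elements=["O"], labels=["THR248"])
        assert detect_hbonds(lig, prot, residues={"T248"})
        assert detect_hbonds(lig, prot, residues={"THR248"})
        # filter to a residue that exists elsewhere in the structure
        prot2 = ProteinStructure(
            np.array([[2.9, 0, 0], [40.0, 0, 0]]), ["O", "N"],
            ["THR248", "ARG169"])
        assert detect_hbonds(lig, prot2, residues={"R169"}) == []

    def test_unknown_residue_label_errors(self):
        lig, prot = self._arg_fixture()
        with pytest.raises(PoseError, match="unknown residue"):
            detect_hbonds(lig, prot, residues={"Z999"})
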