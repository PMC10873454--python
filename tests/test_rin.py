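import numpy as np
import pytest

from xynrin.rin import (InteractionConfig, IType, aromatic_centroids, build_rin,
                        detect_hbonds, detect_ionic, detect_pication, detect_pipi,
                        detect_ssbonds, detect_vdw, DETECTORS)
from xynrin.structio import Structure
from xynrin.synthetic import make_random_structure, random_rotation

from conftest import make_residue
from oracles import edge_set, oracle_edge_set


def two_residue_structure(res_a, res_b):
    return Structure("toy", [res_a, res_b])


def gly_pair(no_distance):
    """Backbone N of residue 5 placed `no_distance` from backbone O of residue 1."""
    a = make_residue("A", 1, "GLY", [
        ("N", "N", (-8, 0, 0)), ("CA", "C", (-7, 0, 1)),
        ("C", "C", (-6, 0, 0)), ("O", "O", (0, 0, 0))])
    b = make_residue("A", 5, "GLY", [
        ("N", "N", (no_distance, 0, 0)), ("CA", "C", (no_distance + 1.2, 0, 1)),
        ("C", "C", (no_distance + 2.4, 0, 0)), ("O", "O", (no_distance + 3.6, 0, 0.4))])
    return two_residue_structure(a, b)


class TestHbonds:
    def test_contact_below_cutoff(self):
        edges = detect_hbonds(gly_pair(2.9))
        assert len(edges) == 1
        assert edges[0].itype is IType.HBOND
        assert edges[0].distance == pytest.approx(2.9)

    def test_contact_beyond_cutoff(self):
        assert detect_hbonds(gly_pair(3.6)) == []

    def test_planted_helix_contacts_match_brute_force(self):
        # residues with k planted N...O contacts; oracle defines the truth
        st = make_random_structure(40, seed=3, box_size=30.0)
        assert edge_set(detect_hbonds(st)) == oracle_edge_set(st, "HBOND")

    def test_sequence_neighbors_excluded(self):
        a = make_residue("A", 1, "GLY", [("N", "N", (0, 0, 0)), ("CA", "C", (1, 0, 0)),
                                         ("C", "C", (2, 0, 0)), ("O", "O", (3, 0, 0))])
        b = make_residue("A", 2, "GLY", [("N", "N", (3, 0, 2.0)), ("CA", "C", (4, 0, 2)),
                                         ("C", "C", (5, 0, 2)), ("O", "O", (6, 0, 2))])
        assert detect_hbonds(two_residue_structure(a, b)) == []


class TestVdw:
    def test_carbon_pair_inside_threshold(self):
        a = make_residue("A", 1, "ALA", [("CA", "C", (0, 0, -1.5)), ("CB", "C", (0, 0, 0))])
        b = make_residue("A", 5, "ALA", [("CA", "C", (3.8, 0, 1.5)), ("CB", "C", (3.8, 0, 0))])
        edges = detect_vdw(two_residue_structure(a, b))
        assert len(edges) == 1  # 3.8 <= 1.7 + 1.7 + 0.5
        assert edges[0].distance == pytest.approx(3.8)

    def test_carbon_pair_outside_threshold(self):
        a = make_residue("A", 1, "ALA", [("CB", "C", (0, 0, 0))])
        b = make_residue("A", 5, "ALA", [("CB", "C", (3.95, 0, 0))])
        assert detect_vdw(two_residue_structure(a, b)) == []

    def test_unknown_element_errors(self):
        a = make_residue("A", 1, "ALA", [("CB", "X", (0, 0, 0))])
        b = make_residue("A", 5, "ALA", [("CB", "C", (3.0, 0, 0))])
        with pytest.raises(ValueError, match="unknown element"):
            detect_vdw(two_residue_structure(a, b))

    def test_grid_equals_brute_force(self):
        st = make_random_structure(50, seed=11, box_size=30.0)
        assert edge_set(detect_vdw(st)) == oracle_edge_set(st, "VDW")


class TestSsbonds:
    def test_typical_disulfide(self):
        a = make_residue("A", 1, "CYS", [("CB", "C", (0, 0, -1.8)), ("SG", "S", (0, 0, 0))])
        b = make_residue("A", 5, "CYS", [("CB", "C", (2.05, 0, 1.8)), ("SG", "S", (2.05, 0, 0))])
        edges = detect_ssbonds(two_residue_structure(a, b))
        assert len(edges) == 1
        assert edges[0].distance == pytest.approx(2.05)

    def test_stretched_pair_rejected(self):
        a = make_residue("A", 1, "CYS", [("SG", "S", (0, 0, 0))])
        b = make_residue("A", 5, "CYS", [("SG", "S", (2.6, 0, 0))])
        assert detect_ssbonds(two_residue_structure(a, b)) == []

    def test_three_cysteines_one_qualifying_pair(self):
        a = make_residue("A", 1, "CYS", [("SG", "S", (0, 0, 0))])
        b = make_residue("A", 5, "CYS", [("SG", "S", (2.1, 0, 0))])
        c = make_residue("A", 9, "CYS", [("SG", "S", (20, 0, 0))])
        edges = detect_ssbonds(Structure("t", [a, b, c]))
        assert len(edges) == 1
        assert {edges[0].residue_a[1], edges[0].residue_b[1]} == {1, 5}


class TestIonic:
    def asp(self, x):
        return make_residue("A", 1, "ASP", [
            ("CB", "C", (x - 2.5, 0, 0)), ("CG", "C", (x - 1.25, 0, 0)),
            ("OD1", "O", (x - 1.8, 1.1, 0)), ("OD2", "O", (x, 0, 0))])

    def test_salt_bridge(self):
        lys = make_residue("A", 5, "LYS", [("NZ", "N", (3.5, 0, 0)),
                                           ("CE", "C", (4.9, 0, 0))])
        # second residue placed mid-chain so termini rules do not fire
        far = make_residue("A", 9, "GLY", [("CA", "C", (50, 50, 50))])
        edges = detect_ionic(Structure("t", [self.asp(0), lys, far]))
        assert len(edges) == 1
        assert edges[0].distance == pytest.approx(3.5)

    def test_like_charges_rejected(self):
        glu = make_residue("A", 5, "GLU", [("OE1", "O", (3.5, 0, 0)),
                                           ("OE2", "O", (4.5, 1, 0))])
        far = make_residue("A", 9, "GLY", [("CA", "C", (50, 50, 50))])
        assert detect_ionic(Structure("t", [self.asp(0), glu, far])) == []

    def test_planted_bridges_vs_decoys(self):
        st = make_random_structure(50, seed=21, box_size=30.0)
        assert edge_set(detect_ionic(st)) == oracle_edge_set(st, "IONIC")


class TestAromatic:
    def test_idealized_ring_centroid_at_origin(self):
        ring = []
        for i, n in enumerate(("CG", "CD1", "CE1", "CZ", "CE2", "CD2")):
            ang = np.radians(60 * i)
            ring.append((n, "C", (1.39 * np.cos(ang), 1.39 * np.sin(ang), 0.0)))
        phe = make_residue("A", 1, "PHE", ring)
        cents = aromatic_centroids(phe)
        assert len(cents) == 1
        np.testing.assert_allclose(cents[0][1], [0, 0, 0], atol=1e-6)

    def test_trp_has_two_centroids(self):
        from xynrin.synthetic import RANDOM_TEMPLATES
        trp = make_residue("A", 1, "TRP", RANDOM_TEMPLATES["TRP"])
        assert len(aromatic_centroids(trp)) == 2

    def test_incomplete_ring_skipped_with_warning(self, caplog):
        phe = make_residue("A", 1, "PHE", [("CG", "C", (0, 0, 0)),
                                           ("CD1", "C", (1, 0, 0))])
        with caplog.at_level("WARNING"):
            assert aromatic_centroids(phe) == []
        assert "missing ring atom" in caplog.text


def hexagon(center, names=("CG", "CD1", "CE1", "CZ", "CE2", "CD2")):
    out = []
    for i, n in enumerate(names):
        ang = np.radians(60 * i)
        out.append((n, "C", (center[0] + 1.39 * np.cos(ang),
                             center[1] + 1.39 * np.sin(ang), center[2])))
    return out


class TestPipi:
    def test_stacked_phe_pair(self):
        a = make_residue("A", 1, "PHE", hexagon((0, 0, 0)))
        b = make_residue("A", 5, "PHE", hexagon((0, 0, 5.0)))
        edges = detect_pipi(two_residue_structure(a, b))
        assert len(edges) == 1
        assert edges[0].pair_label == "F-F"
        assert edges[0].distance == pytest.approx(5.0)

    def test_beyond_cutoff(self):
        a = make_residue("A", 1, "PHE", hexagon((0, 0, 0)))
        b = make_residue("A", 5, "PHE", hexagon((0, 0, 6.6)))
        assert detect_pipi(two_residue_structure(a, b)) == []

    def test_pair_label_census(self):
        residues = [make_residue("A", 1, "PHE", hexagon((0, 0, 0)))]
        # 3 F-F partners and one F-Y partner around the first ring
        for k, (num, off) in enumerate([(5, (6, 0, 0)), (9, (-6, 0, 0)), (13, (0, 6, 0))]):
            residues.append(make_residue("A", num, "PHE", hexagon(off)))
        residues.append(make_residue("A", 17, "TYR", hexagon((0, -6, 0))))
        _, summary = build_rin(Structure("t", residues))
        assert summary.pipi_pairs["F-F"] == 3
        assert summary.pipi_pairs["F-Y"] == 1


class TestPication:
    def test_lys_over_phe_ring(self):
        phe = make_residue("A", 1, "PHE", hexagon((0, 0, 0)))
        lys = make_residue("A", 5, "LYS", [("NZ", "N", (0, 0, 4.2)),
                                           ("CE", "C", (0, 0, 5.7))])
        edges = detect_pication(two_residue_structure(phe, lys))
        assert len(edges) == 1
        assert edges[0].distance == pytest.approx(4.2)

    def test_beyond_cutoff(self):
        phe = make_residue("A", 1, "PHE", hexagon((0, 0, 0)))
        lys = make_residue("A", 5, "LYS", [("NZ", "N", (0, 0, 5.2))])
        assert detect_pication(two_residue_structure(phe, lys)) == []

    def test_mixed_cation_geometries(self):
        st = make_random_structure(50, seed=31, box_size=30.0)
        assert edge_set(detect_pication(st)) == oracle_edge_set(st, "PICATION")


class TestBuildRin:
    def test_one_edge_of_each_type(self, six_type_fixture):
        st, truth = six_type_fixture
        edges, summary = build_rin(st)
        assert edge_set(edges) == edge_set(truth.edges)
        for itype in IType:
            assert summary.per_type[itype.value] >= 1

    def test_empty_structure_has_missing_ratio(self):
        a = make_residue("A", 1, "ALA", [("CB", "C", (0, 0, 0))])
        b = make_residue("A", 5, "ALA", [("CB", "C", (20, 0, 0))])
        _, summary = build_rin(two_residue_structure(a, b))
        assert summary.n_edges == 0
        assert summary.edge_node_ratio is None

    def test_determinism(self, random_structure):
        e1, _ = build_rin(random_structure)
        e2, _ = build_rin(random_structure)
        assert e1 == e2

    def test_census_consistency(self, random_structure):
        edges, summary = build_rin(random_structure)
        assert summary.n_edges == sum(summary.per_type.values())
        assert sum(summary.pipi_pairs.values()) == summary.per_type["PIPI"]
        assert summary.n_nodes <= 2 * summary.n_edges


class TestProperties:
    @pytest.mark.parametrize("seed", range(25))
    def test_oracle_equivalence_all_detectors(self, seed):
        st = make_random_structure(50, seed=seed, box_size=30.0)
        for itype in IType:
            got = edge_set(DETECTORS[itype](st, InteractionConfig()))
            assert got == oracle_edge_set(st, itype.value), itype

    @pytest.mark.parametrize("seed", range(5))
    def test_rigid_motion_invariance(self, seed, rng):
        st = make_random_structure(40, seed=seed, box_size=28.0)
        edges_ref, _ = build_rin(st)

        rot = random_rotation(rng)
        trans = rng.uniform(-30, 30, size=3)
        moved = st.transformed(rot, trans)
        edges_moved, _ = build_rin(moved)
        ref = {(e.pair_key, e.itype) for e in edges_ref}
        got = {(e.pair_key, e.itype) for e in edges_moved}
        assert ref == got
        d_ref = sorted(e.distance for e in edges_ref)
        d_got = sorted(e.distance for e in edges_moved)
        np.testing.assert_allclose(d_ref, d_got, atol=1e-6)

    def test_symmetry_under_residue_reversal(self, random_structure):
        st = random_structure
        reversed_st = Structure(st.id, list(reversed(st.residues)))
        e1, _ = build_rin(st)
        e2, _ = build_rin(reversed_st)
        assert edge_set(e1) == edge_set(e2)
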