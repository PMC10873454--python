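import numpy as np
import pytest

from xynrin.diffres import (SubstitutionSet, classify_columns,
                            count_differential_columns, design_mutants,
                            find_enriched_regions, mutable_positions,
                            split_termini)
from xynrin.structio import Alignment, Structure
from xynrin.synthetic import make_msa_fixture, random_rotation

from conftest import make_residue


def toy_alignment(ref, members, ids=None):
    ids = ids or ["REF", "QUERY"] + [f"M{i}" for i in range(1, len(members))]
    return Alignment(ids, [ref] + members)


class TestClassifyColumns:
    def test_group_a_when_all_members_differ(self):
        # ref Q at column 1; every cluster member carries E
        aln = toy_alignment("Q", ["E", "E", "E", "E", "E"])
        recs = classify_columns(aln, "REF", "QUERY",
                                ["QUERY", "M1", "M2", "M3", "M4"])
        assert len(recs) == 1
        assert recs[0].group == "A"
        assert recs[0].n_cluster_diff == 5

    def test_group_b_when_subset_differs(self):
        aln = toy_alignment("Q", ["E", "Q", "Q", "E", "E"])
        recs = classify_columns(aln, "REF", "QUERY",
                                ["QUERY", "M1", "M2", "M3", "M4"])
        assert recs[0].group == "B"
        assert recs[0].n_cluster_diff == 3

    def test_identical_column_yields_no_record(self):
        aln = toy_alignment("Q", ["Q", "Q", "Q", "Q", "Q"])
        assert classify_columns(aln, "REF", "QUERY",
                                ["QUERY", "M1", "M2", "M3", "M4"]) == []

    def test_query_must_be_cluster_member(self):
        aln = toy_alignment("Q", ["E", "E"])
        with pytest.raises(ValueError, match="member"):
            classify_columns(aln, "REF", "QUERY", ["M1"])

    def test_unknown_id_errors(self):
        aln = toy_alignment("Q", ["E"])
        with pytest.raises(KeyError):
            classify_columns(aln, "REF", "NOPE", ["NOPE"])

    def test_gap_in_member_counts_as_differing(self):
        aln = toy_alignment("Q", ["E", "-", "Q"])
        recs = classify_columns(aln, "REF", "QUERY", ["QUERY", "M1", "M2"])
        assert recs[0].n_cluster_diff == 2
        assert recs[0].group == "B"

    def test_gap_in_query_has_no_mutable_position(self):
        aln = toy_alignment("QA", ["-A", "EA"])
        recs = classify_columns(aln, "REF", "QUERY", ["QUERY", "M1"])
        assert recs[0].query_position is None

    def test_partition_property_on_random_alignments(self, rng):
        """A and B columns partition the set of differential columns."""
        for seed in range(10):
            aln, truth, meta = make_msa_fixture(
                n_cluster=5, length=60, n_groupA=6, n_groupB=7, seed=seed)
            recs = classify_columns(aln, meta["ref_id"], meta["query_id"],
                                    meta["cluster_ids"])
            ref_row, q_row = aln.row(meta["ref_id"]), aln.row(meta["query_id"])
            diff_cols = {i + 1 for i in range(aln.length) if ref_row[i] != q_row[i]}
            assert {r.column_index for r in recs} == diff_cols
            assert all(r.group in "AB" for r in recs)


class TestDesignMutants:
    @pytest.fixture
    def fixture(self):
        aln, truth, meta = make_msa_fixture(
            n_cluster=5, length=50, n_groupA=4, n_groupB=3, seed=42)
        recs = classify_columns(aln, meta["ref_id"], meta["query_id"],
                                meta["cluster_ids"])
        query_seq = aln.row(meta["query_id"]).replace("-", "")
        ref_row = aln.row(meta["ref_id"])
        return aln, recs, query_seq, ref_row

    def test_all_selection_matches_ref_at_every_differential_column(self, fixture):
        aln, recs, query_seq, ref_row = fixture
        sel = SubstitutionSet("all", frozenset(mutable_positions(recs)))
        (_, mutant), = design_mutants(query_seq, recs, [sel])
        assert len(mutant) == len(query_seq)
        for r in recs:
            assert mutant[r.query_position - 1] == r.ref_residue

    def test_empty_selection_is_identity(self, fixture):
        _, recs, query_seq, _ = fixture
        (_, mutant), = design_mutants(query_seq, recs,
                                      [SubstitutionSet("id", frozenset())])
        assert mutant == query_seq

    def test_group_a_only_touches_a_positions(self, fixture):
        _, recs, query_seq, _ = fixture
        a_pos = set(mutable_positions(recs, "A"))
        b_pos = set(mutable_positions(recs, "B"))
        assert len(a_pos) == 4 and len(b_pos) == 3
        (_, mutant), = design_mutants(query_seq, recs,
                                      [SubstitutionSet("gA", frozenset(a_pos))])
        changed = {i + 1 for i, (x, y) in enumerate(zip(query_seq, mutant)) if x != y}
        assert changed == a_pos

    def test_position_outside_classified_set_errors(self, fixture):
        _, recs, query_seq, _ = fixture
        classified = set(mutable_positions(recs))
        bad = next(p for p in range(1, len(query_seq) + 1) if p not in classified)
        with pytest.raises(ValueError, match=str(bad)):
            design_mutants(query_seq, recs, [SubstitutionSet("bad", frozenset({bad}))])

    def test_idempotence_and_composition(self, fixture):
        _, recs, query_seq, _ = fixture
        a_pos = frozenset(mutable_positions(recs, "A"))
        b_pos = frozenset(mutable_positions(recs, "B"))
        all_pos = frozenset(mutable_positions(recs))
        (_, m_a), = design_mutants(query_seq, recs, [SubstitutionSet("a", a_pos)])
        # idempotence: applying the same set to its own output is a no-op
        (_, m_a_twice), = design_mutants(m_a, recs, [SubstitutionSet("a", a_pos)])
        assert m_a_twice == m_a
        # composition: groupA then groupB equals all positions at once
        (_, m_ab), = design_mutants(m_a, recs, [SubstitutionSet("b", b_pos)])
        (_, m_all), = design_mutants(query_seq, recs, [SubstitutionSet("all", all_pos)])
        assert m_ab == m_all


class TestSplitTermini:
    def test_even_count(self):
        assert split_termini([3, 10, 40, 200]) == ([3, 10], [40, 200])

    def test_odd_count_ceil_rule(self):
        assert split_termini([5, 6, 7]) == ([5, 6], [7])

    def test_midpoint_policy(self):
        assert split_termini([10, 290], "midpoint", midpoint=150) == ([10], [290])

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            split_termini([])


def grid_structure(coords, res_name="ALA"):
    residues = []
    for i, c in enumerate(coords):
        c = np.asarray(c, float)
        residues.append(make_residue("A", i + 1, res_name, [
            ("CA", "C", tuple(c + [0, 0, 1.5])), ("CB", "C", tuple(c))]))
    return Structure("grid", residues)


class TestEnrichedRegions:
    def test_two_planted_clusters(self):
        c1 = [(0, 0, 0), (4, 0, 0), (0, 4, 0), (4, 4, 0)]
        c2 = [(50, 0, 0), (54, 0, 0), (50, 4, 0), (54, 4, 0)]
        st = grid_structure(c1 + c2)
        regions = find_enriched_regions(st, list(range(1, 9)), 10.0, 3)
        assert len(regions) == 2
        assert all(len(r.members) == 4 for r in regions)

    def test_scattered_residues_give_no_region(self):
        coords = [(0, 0, 0), (20, 0, 0), (40, 0, 0), (60, 0, 0)]
        st = grid_structure(coords)
        assert find_enriched_regions(st, [1, 2, 3, 4], 10.0, 2) == []

    def test_matches_adjacency_matrix_oracle(self, rng):
        import networkx as nx
        coords = rng.uniform(0, 40, size=(25, 3))
        st = grid_structure(coords)
        regions = find_enriched_regions(st, list(range(1, 26)), 10.0, 1)
        # oracle: connected components on the explicit adjacency graph
        g = nx.Graph()
        g.add_nodes_from(range(25))
        for i in range(25):
            for j in range(i + 1, 25):
                if np.linalg.norm(coords[i] - coords[j]) <= 10.0:
                    g.add_edge(i, j)
        oracle = {frozenset(c) for c in nx.connected_components(g)}
        got = {frozenset(m[1] - 1 for m in r.members) for r in regions}
        assert got == oracle

    def test_invariant_under_rigid_motion_and_permutation(self, rng):
        coords = rng.uniform(0, 30, size=(12, 3))
        st = grid_structure(coords)
        ref = find_enriched_regions(st, list(range(1, 13)), 10.0, 2)
        moved = st.transformed(random_rotation(rng), rng.uniform(-20, 20, 3))
        perm = list(rng.permutation(range(1, 13)))
        got = find_enriched_regions(moved, perm, 10.0, 2)
        as_sets = lambda rs: {frozenset(m[1] for m in r.members) for r in rs}
        assert as_sets(ref) == as_sets(got)

    def test_unmappable_position_errors(self):
        st = grid_structure([(0, 0, 0)])
        with pytest.raises(ValueError, match="outside"):
            find_enriched_regions(st, [5], 10.0, 1)


class TestDifferentialCount:
    def test_pairwise_count(self):
        aln = Alignment(["a", "b"], ["MKVQ-A", "MRVQEA"])
        assert count_differential_columns(aln, "a", "b") == 2
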