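import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lretpath as lp
from lretpath.molecular_graph import Edge, TransferGraph
from lretpath.pathway_scoring import (
    DecayParameters,
    KindParameters,
    NO_PATH,
    edge_decay,
    edge_weight,
)
from lretpath import synthetic_data as syn

PARAMS = DecayParameters()


class TestEdgeDecay:
    def test_covalent_distance_free(self):
        # B = 0 makes the covalent factor independent of bond length
        for r in (1.0, 1.5, 2.0):
            q = edge_decay(Edge(1, 2, "covalent", r), PARAMS)
            assert q == pytest.approx(0.6)
            assert math.log(q) == pytest.approx(-0.5108, abs=1e-4)

    def test_hbond_at_reference_distance(self):
        q = edge_decay(Edge(1, 2, "hbond", 2.8), PARAMS)
        assert q == pytest.approx(0.36)

    def test_space_direct_evaluation(self):
        q = edge_decay(Edge(1, 2, "space", 3.4), PARAMS)
        assert q == pytest.approx(0.6 * math.exp(-1.7 * 2.0), rel=1e-12)
        assert math.log(q) == pytest.approx(-3.911, abs=1e-3)

    def test_clamp_below_reference(self):
        # shorter than R must not beat the contact value A
        q = edge_decay(Edge(1, 2, "hbond", 2.0), PARAMS)
        assert q == pytest.approx(0.36)
        assert edge_weight(Edge(1, 2, "hbond", 2.0), PARAMS) >= 0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            KindParameters(A=1.5, B=0, R=0)
        with pytest.raises(ValueError):
            KindParameters(A=0.5, B=-1, R=0)

    @given(r=st.floats(0.5, 10.0), kind=st.sampled_from(["covalent", "hbond", "space"]))
    @settings(max_examples=50, deadline=None)
    def test_decay_in_unit_interval(self, r, kind):
        q = edge_decay(Edge(1, 2, kind, r), PARAMS)
        assert 0 < q <= PARAMS.for_kind(kind).A


class TestBestPath:
    def test_linear_chain_closed_form(self, chain10):
        structure, truth = chain10
        graph = lp.build_transfer_graph(structure)
        result = lp.best_path(graph, truth["donor_serial"], truth["acceptor_serial"])
        assert result.ln_k == pytest.approx(truth["expected_ln_k"], rel=1e-12)
        assert result.atom_count == 11
        assert result.kind_counts == {"covalent": 10}

    def test_identity_path(self, chain10):
        structure, _ = chain10
        graph = lp.build_transfer_graph(structure)
        r = lp.best_path(graph, 1, 1)
        assert r.ln_k == 0.0 and r.atom_count == 1 and r.edge_decays == ()

    def test_unreachable_returns_sentinel(self):
        g = syn.make_random_graph(5, 0.0, seed=0)
        r = lp.best_path(g, 1, 5)
        assert r is NO_PATH or not r.found
        assert r.ln_k == float("-inf")

    def test_unknown_node_raises(self, chain10):
        structure, _ = chain10
        graph = lp.build_transfer_graph(structure)
        with pytest.raises(KeyError):
            lp.best_path(graph, 1, 999)

    def test_additivity_of_ln_k(self, chain10):
        structure, truth = chain10
        graph = lp.build_transfer_graph(structure)
        r = lp.best_path(graph, truth["donor_serial"], truth["acceptor_serial"])
        assert r.ln_k == pytest.approx(sum(math.log(q) for q in r.edge_decays), rel=1e-12)

    def test_symmetry(self):
        for seed in range(10):
            g = syn.make_random_graph(10, 0.35, seed=seed)
            fwd = lp.best_path(g, 1, 10)
            rev = lp.best_path(g, 10, 1)
            assert fwd.ln_k == pytest.approx(rev.ln_k) or (
                not fwd.found and not rev.found
            )

    def test_adding_edge_never_hurts(self):
        g = syn.make_random_graph(8, 0.3, seed=3)
        before = lp.best_path(g, 1, 8).ln_k
        g.add_edge(Edge(1, 8, "hbond", 2.8))
        after = lp.best_path(g, 1, 8).ln_k
        assert after >= before

    def test_longer_jump_never_helps(self):
        def graph_with(r):
            g = TransferGraph(extra_nodes=[1, 2, 3])
            g.add_edge(Edge(1, 2, "covalent", 1.5))
            g.add_edge(Edge(2, 3, "space", r))
            return g

        short = lp.best_path(graph_with(3.0), 1, 3).ln_k
        long = lp.best_path(graph_with(4.5), 1, 3).ln_k
        assert long < short

    def test_networkx_agrees_on_optimal_weight(self):
        """Independent check: total -ln q matches networkx Dijkstra."""
        import networkx as nx

        for seed in range(20):
            g = syn.make_random_graph(12, 0.3, seed=100 + seed)
            nxg = g.to_networkx(PARAMS)
            ours = lp.best_path(g, 1, 12)
            try:
                weight = nx.dijkstra_path_length(nxg, 1, 12)
            except nx.NetworkXNoPath:
                assert not ours.found
                continue
            assert -ours.ln_k == pytest.approx(weight, rel=1e-9)


class TestBruteForceOracle:
    def test_triangle_prefers_two_light_edges(self):
        g = TransferGraph(extra_nodes=[1, 2, 3])
        g.add_edge(Edge(1, 3, "space", 5.5))       # heavy direct edge
        g.add_edge(Edge(1, 2, "covalent", 1.5))
        g.add_edge(Edge(2, 3, "covalent", 1.5))
        r = lp.brute_force_best_path(g, 1, 3)
        assert r.atoms == (1, 2, 3)
        assert r.ln_k == pytest.approx(2 * math.log(0.6), rel=1e-12)

    def test_single_edge(self):
        g = TransferGraph(extra_nodes=[1, 2])
        g.add_edge(Edge(1, 2, "hbond", 2.8))
        r = lp.brute_force_best_path(g, 1, 2)
        assert r.atoms == (1, 2)
        assert r.ln_k == pytest.approx(math.log(0.36), rel=1e-12)

    def test_disconnected_sentinel(self):
        g = TransferGraph(extra_nodes=[1, 2])
        assert not lp.brute_force_best_path(g, 1, 2).found

    def test_node_guard(self):
        g = TransferGraph(extra_nodes=range(1, 16))
        with pytest.raises(ValueError):
            lp.brute_force_best_path(g, 1, 15)

    def test_oracle_equivalence_sample(self):
        """Dijkstra equals exhaustive enumeration, path and score."""
        for seed in range(40):
            g = syn.make_random_graph(10, 0.35, seed=seed)
            a = lp.best_path(g, 1, 10)
            b = lp.brute_force_best_path(g, 1, 10)
            assert a.ln_k == b.ln_k
            assert a.atoms == b.atoms


class TestRanking:
    def test_mini_protein_ranking(self, mini_protein_pdb):
        s = lp.read_pdb(mini_protein_pdb)
        graph = lp.build_transfer_graph(s)
        ranking = lp.rank_residues(s, graph)
        assert len(ranking) == 2
        kinds = {r.residue_id[2]: r for r in ranking}
        assert kinds["TYR"].acceptor_atom == "OH"
        assert kinds["TRP"].acceptor_atom == "NE1"
        ln_ks = [r.path.ln_k for r in ranking]
        assert ln_ks == sorted(ln_ks, reverse=True)
        assert all(r.path.found for r in ranking)

    def test_forbid_fe_his_changes_or_keeps_score(self, mini_protein_pdb):
        s = lp.read_pdb(mini_protein_pdb)
        graph = lp.build_transfer_graph(s)
        free = lp.rank_residues(s, graph)
        forbidden = lp.rank_residues(s, graph, forbid_fe_his=True)
        for a, b in zip(free, forbidden):
            assert b.path.ln_k <= a.path.ln_k  # removing an edge cannot help
            assert not any(
                e.is_fe_his_link and b.path.uses_edge(e.atom_i, e.atom_j)
                for e in graph.edges
            )

    def test_no_iron_raises(self, chain10):
        structure, _ = chain10
        graph = lp.build_transfer_graph(structure)
        with pytest.raises(ValueError, match="no heme iron"):
            lp.rank_residues(structure, graph)

    def test_missing_acceptor_atom_skipped_with_warning(self):
        atoms = [
            lp.Atom(serial=1, name="FE", element="Fe", residue_name="HEM",
                    residue_number=100, chain_id="A", position=np.zeros(3), is_het=True),
            lp.Atom(serial=2, name="CB", element="C", residue_name="TYR",
                    residue_number=5, chain_id="A", position=np.array([3.0, 0, 0])),
            lp.Atom(serial=3, name="OH", element="O", residue_name="TYR",
                    residue_number=6, chain_id="A", position=np.array([5.5, 0, 0])),
        ]
        s = lp.Structure(atoms=atoms)
        graph = lp.build_transfer_graph(s)
        with pytest.warns(UserWarning, match="lacks acceptor atom"):
            ranking = lp.rank_residues(s, graph)
        assert len(ranking) == 1
        assert ranking.rows[0].residue_id[1] == 6


class TestSelectCandidates:
    def make_ranking(self, values):
        from lretpath.pathway_scoring import PathResult, RankingRow, ResidueRanking

        rows = []
        for i, v in enumerate(values):
            path = PathResult(atoms=(1, 2), edge_decays=(math.exp(v),), edge_kinds=("covalent",), ln_k=v)
            rows.append(RankingRow(("A", i + 1, "TYR"), "OH", path))
        return ResidueRanking(rows=rows)

    def test_cutoff_selects_top_rows(self):
        ranking = self.make_ranking([-10, -12, -13, -15])
        selected = lp.select_candidates(ranking, -12.86)
        assert [r.path.ln_k for r in selected] == [-10, -12]

    def test_cutoff_below_all(self):
        ranking = self.make_ranking([-10, -12])
        assert len(lp.select_candidates(ranking, -99)) == 2

    def test_cutoff_above_all(self):
        ranking = self.make_ranking([-10, -12])
        assert lp.select_candidates(ranking, -5) == []
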