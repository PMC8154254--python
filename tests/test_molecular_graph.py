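import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lretpath as lp
from lretpath.molecular_graph import Edge, HBondCriteria


def atom(serial, name, element, resname="ALA", resnum=1, chain="A", pos=(0, 0, 0), **kw):
    return lp.Atom(
        serial=serial, name=name, element=element, residue_name=resname,
        residue_number=resnum, chain_id=chain, position=np.asarray(pos, float), **kw
    )


def edge_set(edges):
    return {frozenset((e.atom_i, e.atom_j)) for e in edges}


class TestCovalentPerception:
    def test_alanine_template(self):
        s = lp.Structure(atoms=[
            atom(1, "N", "N", pos=(0, 0, 0)),
            atom(2, "CA", "C", pos=(1.45, 0, 0)),
            atom(3, "C", "C", pos=(2.0, 1.3, 0)),
            atom(4, "O", "O", pos=(3.2, 1.4, 0)),
            atom(5, "CB", "C", pos=(1.9, -1.0, 1.0)),
        ])
        edges = lp.perceive_covalent_bonds(s)
        assert edge_set(edges) == {
            frozenset((1, 2)), frozenset((2, 3)), frozenset((3, 4)), frozenset((2, 5)),
        }

    def test_peptide_bond_between_consecutive_residues(self):
        s = lp.Structure(atoms=[
            atom(1, "C", "C", resnum=1, pos=(0, 0, 0)),
            atom(2, "N", "N", resnum=2, pos=(1.33, 0, 0)),
        ])
        edges = lp.perceive_covalent_bonds(s)
        assert edge_set(edges) == {frozenset((1, 2))}

    def test_no_peptide_bond_across_chain_break(self):
        s = lp.Structure(atoms=[
            atom(1, "C", "C", resnum=1, pos=(0, 0, 0)),
            atom(2, "N", "N", resnum=2, pos=(4.0, 0, 0)),  # too far
        ])
        assert lp.perceive_covalent_bonds(s) == []

    def test_fe_his_link_added_and_flagged(self, mini_protein_pdb):
        s = lp.read_pdb(mini_protein_pdb)
        edges = lp.perceive_covalent_bonds(s)
        links = [e for e in edges if e.is_fe_his_link]
        assert len(links) == 1
        fe = lp.resolve_atom(s, {"name": "FE"})
        ne2 = lp.resolve_atom(s, {"name": "NE2", "residue_name": "HIS"})
        assert {links[0].atom_i, links[0].atom_j} == {fe.serial, ne2.serial}
        assert links[0].r_ij == pytest.approx(2.1, abs=0.01)

    def test_heme_without_his_warns(self):
        s = lp.Structure(atoms=[
            atom(1, "FE", "Fe", resname="HEM", pos=(0, 0, 0), is_het=True),
            atom(2, "NA", "N", resname="HEM", pos=(2.0, 0, 0), is_het=True),
        ])
        with pytest.warns(UserWarning, match="no proximal histidine"):
            edges = lp.perceive_covalent_bonds(s)
        assert not any(e.is_fe_his_link for e in edges)

    def test_unknown_residue_distance_fallback(self):
        s = lp.Structure(atoms=[
            atom(1, "C1", "C", resname="LIG", pos=(0, 0, 0), is_het=True),
            atom(2, "C2", "C", resname="LIG", pos=(1.5, 0, 0), is_het=True),
            atom(3, "C3", "C", resname="LIG", pos=(5.0, 0, 0), is_het=True),
        ])
        with pytest.warns(UserWarning, match="no connectivity template"):
            edges = lp.perceive_covalent_bonds(s)
        assert edge_set(edges) == {frozenset((1, 2))}

    def test_disulfide_by_distance_rule(self):
        s = lp.Structure(atoms=[
            atom(1, "SG", "S", resname="CYS", resnum=1, pos=(0, 0, 0)),
            atom(2, "SG", "S", resname="CYS", resnum=10, pos=(2.05, 0, 0)),
        ])
        edges = lp.perceive_covalent_bonds(s)
        assert edge_set(edges) == {frozenset((1, 2))}


class TestHBondDetection:
    def water_dimer(self, ha=1.9, angle=170.0):
        """Donor water (O1, H) aimed at acceptor oxygen O2."""
        d = np.zeros(3)
        h = np.array([0.96, 0.0, 0.0])
        theta = math.radians(180.0 - angle)
        a = h + ha * np.array([math.cos(theta), math.sin(theta), 0.0])
        return lp.Structure(atoms=[
            atom(1, "O", "O", resname="HOH", resnum=1, pos=d, is_het=True, is_water=True),
            atom(2, "H1", "H", resname="HOH", resnum=1, pos=h, is_het=True, is_water=True),
            atom(3, "O", "O", resname="HOH", resnum=2, pos=a, is_het=True, is_water=True),
        ])

    def test_ideal_dimer_detected(self):
        edges = lp.detect_hbond_edges(self.water_dimer(1.9, 170.0))
        assert len(edges) == 1
        e = edges[0]
        assert e.kind == "hbond"
        assert {e.atom_i, e.atom_j} == {1, 3}
        # r_ij is the heavy-atom donor-acceptor separation, not H···A
        assert e.r_ij > 1.9

    def test_distance_failure(self):
        assert lp.detect_hbond_edges(self.water_dimer(2.6, 170.0)) == []

    def test_angle_failure(self):
        assert lp.detect_hbond_edges(self.water_dimer(1.9, 120.0)) == []

    def test_heavy_atom_fallback_without_hydrogens(self):
        s = lp.Structure(atoms=[
            atom(1, "O", "O", resname="HOH", resnum=1, pos=(0, 0, 0), is_water=True),
            atom(2, "O", "O", resname="HOH", resnum=2, pos=(2.8, 0, 0), is_water=True),
        ])
        edges = lp.detect_hbond_edges(s)
        assert len(edges) == 1
        assert edges[0].r_ij == pytest.approx(2.8)

    def test_fallback_excludes_covalent_neighbors(self):
        # carboxylate O-C-O: the two oxygens are 1-3 connected, not H-bonded
        s = lp.Structure(atoms=[
            atom(1, "OE1", "O", resname="GLU", pos=(1.1, 1.1, 0)),
            atom(2, "CD", "C", resname="GLU", pos=(0, 0, 0)),
            atom(3, "OE2", "O", resname="GLU", pos=(1.1, -1.1, 0)),
        ])
        assert lp.detect_hbond_edges(s) == []


class TestBuildTransferGraph:
    def two_atoms(self, r):
        return lp.Structure(atoms=[
            atom(1, "CA", "C", resnum=1, pos=(0, 0, 0)),
            atom(2, "CA", "C", resnum=5, pos=(r, 0, 0)),
        ])

    def test_space_edge_inside_cutoff(self):
        g = lp.build_transfer_graph(self.two_atoms(5.0), space_cutoff=6.0)
        assert g.kind_counts() == {"covalent": 0, "hbond": 0, "space": 1}

    def test_no_edge_beyond_cutoff(self):
        g = lp.build_transfer_graph(self.two_atoms(5.0), space_cutoff=4.0)
        assert g.edges == []

    def test_covalent_precedence_over_space(self):
        g = lp.build_transfer_graph(self.two_atoms(1.5), space_cutoff=6.0)
        assert g.kind_counts() == {"covalent": 1, "hbond": 0, "space": 0}

    def test_edge_kind_partition(self, mini_protein_pdb):
        s = lp.read_pdb(mini_protein_pdb)
        cov = lp.perceive_covalent_bonds(s)
        hb = lp.detect_hbond_edges(s, covalent=cov)
        g = lp.build_transfer_graph(s, covalent=cov, hbond=hb, space_cutoff=6.0)
        counts = g.kind_counts()
        assert counts["covalent"] == len(cov)
        assert sum(counts.values()) == len(g.edges)
        assert len({e.key for e in g.edges}) == len(g.edges)

    def test_graph_is_undirected(self, mini_protein_pdb):
        s = lp.read_pdb(mini_protein_pdb)
        g = lp.build_transfer_graph(s)
        for e in g.edges:
            assert dict(g.neighbors(e.atom_i))[e.atom_j] is e
            assert dict(g.neighbors(e.atom_j))[e.atom_i] is e

    @given(small=st.floats(3.0, 5.0), extra=st.floats(0.1, 3.0))
    @settings(max_examples=25, deadline=None)
    def test_cutoff_monotonicity(self, small, extra):
        """Enlarging the space cutoff never removes an edge."""
        s = lp.Structure(atoms=[
            atom(1, "CA", "C", resnum=1, pos=(0, 0, 0)),
            atom(2, "CA", "C", resnum=5, pos=(3.1, 0, 0)),
            atom(3, "CA", "C", resnum=9, pos=(0, 4.4, 0)),
        ])
        g_small = lp.build_transfer_graph(s, space_cutoff=small)
        g_big = lp.build_transfer_graph(s, space_cutoff=small + extra)
        assert {e.key for e in g_small.edges} <= {e.key for e in g_big.edges}

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            HBondCriteria(max_ha_distance=-1)
        with pytest.raises(ValueError):
            HBondCriteria(min_dha_angle=270)

    def test_edge_validation(self):
        with pytest.raises(ValueError):
            Edge(1, 1, "covalent", 1.0)
        with pytest.raises(ValueError):
            Edge(1, 2, "covalent", -1.0)
        with pytest.raises(ValueError):
            Edge(1, 2, "warp", 1.0)
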