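"""Covalent and hydrogen-bond perception; assembly of the typed atom graph.

The transfer graph has atoms as nodes and three edge kinds — covalent bond,
hydrogen bond, through-space contact — each carrying the interatomic
distance used by the exponential decay law. Each atom pair carries at most
one edge, with precedence covalent > hbond > space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import gemmi
import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Atom, Structure

__all__ = [
    "Edge",
    "TransferGraph",
    "HBondCriteria",
    "perceive_covalent_bonds",
    "detect_hbond_edges",
    "build_transfer_graph",
    "RESIDUE_TEMPLATES",
]

EDGE_KINDS = ("covalent", "hbond", "space")

#: extra slack on the sum of covalent radii for the distance fallback rule, Å
COVALENT_TOLERANCE = 0.45
#: maximum Fe-NE2 separation treated as the proximal-His coordination bond, Å
FE_HIS_CUTOFF = 3.0
PEPTIDE_CUTOFF = 2.0


@dataclass(frozen=True)
class Edge:
    """An undirected typed contact between two atoms (referenced by serial)."""

    atom_i: int
    atom_j: int
    kind: str
    r_ij: float
    is_fe_his_link: bool = False

    def __post_init__(self) -> None:
        if self.atom_i == self.atom_j:
            raise ValueError("self-edge")
        if not (self.r_ij > 0 and np.isfinite(self.r_ij)):
            raise ValueError(f"edge distance must be finite and positive, got {self.r_ij}")
        if self.kind not in EDGE_KINDS:
            raise ValueError(f"unknown edge kind {self.kind!r}")

    @property
    def key(self) -> frozenset[int]:
        return frozenset((self.atom_i, self.atom_j))


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond definition.

    ``max_ha_distance`` (Å) bounds the hydrogen···acceptor separation and
    ``min_dha_angle`` (degrees) the donor-H···acceptor angle at the
    hydrogen. When the donor carries no hydrogen (crystal structures,
    united-atom topologies), ``heavy_atom_fallback_distance`` bounds the
    donor···acceptor heavy-atom separation instead.
    """

    max_ha_distance: float = 2.5
    min_dha_angle: float = 135.0
    heavy_atom_fallback_distance: float = 3.5

    def __post_init__(self) -> None:
        if self.max_ha_distance <= 0 or self.heavy_atom_fallback_distance <= 0:
            raise ValueError("hydrogen-bond distances must be positive")
        if not 0 < self.min_dha_angle <= 180:
            raise ValueError("angle must be in (0, 180]")


class TransferGraph:
    """Undirected typed atom graph over which pathways are scored."""

    def __init__(
        self,
        edges: Iterable[Edge] = (),
        atoms: Iterable[Atom] | None = None,
        extra_nodes: Iterable[int] = (),
        provenance: str = "",
    ) -> None:
        self.atoms: dict[int, Atom] = {a.serial: a for a in atoms} if atoms else {}
        self.provenance = provenance
        self._edges: dict[frozenset[int], Edge] = {}
        self._adjacency: dict[int, dict[int, Edge]] = {}
        for node in self.atoms:
            self._adjacency.setdefault(node, {})
        for node in extra_nodes:
            self._adjacency.setdefault(node, {})
        for edge in edges:
            self.add_edge(edge)

    def add_edge(self, edge: Edge) -> None:
        if edge.key in self._edges:
            raise ValueError(f"duplicate edge {set(edge.key)}")
        self._edges[edge.key] = edge
        self._adjacency.setdefault(edge.atom_i, {})[edge.atom_j] = edge
        self._adjacency.setdefault(edge.atom_j, {})[edge.atom_i] = edge

    @property
    def nodes(self) -> list[int]:
        return list(self._adjacency)

    @property
    def edges(self) -> list[Edge]:
        return list(self._edges.values())

    def __contains__(self, node: int) -> bool:
        return node in self._adjacency

    def has_edge(self, i: int, j: int) -> bool:
        return frozenset((i, j)) in self._edges

    def get_edge(self, i: int, j: int) -> Edge:
        return self._edges[frozenset((i, j))]

    def neighbors(self, node: int) -> Iterator[tuple[int, Edge]]:
        yield from self._adjacency.get(node, {}).items()

    def kind_counts(self) -> dict[str, int]:
        out = {k: 0 for k in EDGE_KINDS}
        for e in self._edges.values():
            out[e.kind] += 1
        return out

    def to_networkx(self, params=None) -> nx.Graph:
        """Export to networkx; with decay parameters, adds -ln(q) weights."""
        g = nx.Graph()
        g.add_nodes_from(self._adjacency)
        for e in self._edges.values():
            attrs = {"kind": e.kind, "r_ij": e.r_ij}
            if params is not None:
                from .pathway_scoring import edge_decay

                attrs["weight"] = -float(np.log(edge_decay(e, params)))
            g.add_edge(e.atom_i, e.atom_j, **attrs)
        return g

    def write_edge_list(self, dest: str | Path) -> None:
        lines = ["atom_i\tatom_j\tkind\tr_ij"]
        for e in sorted(self._edges.values(), key=lambda e: (min(e.atom_i, e.atom_j), max(e.atom_i, e.atom_j))):
            i, j = sorted((e.atom_i, e.atom_j))
            lines.append(f"{i}\t{j}\t{e.kind}\t{e.r_ij:.4f}")
        Path(dest).write_text("\n".join(lines) + "\n")


# --- residue connectivity templates ---------------------------------------

_BACKBONE = [("N", "CA"), ("CA", "C"), ("C", "O"), ("C", "OXT")]

_SIDE_CHAINS: dict[str, list[tuple[str, str]]] = {
    "ALA": [("CA", "CB")],
    "ARG": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "NE"), ("NE", "CZ"),
            ("CZ", "NH1"), ("CZ", "NH2")],
    "ASN": [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "ND2")],
    "ASP": [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")],
    "CYS": [("CA", "CB"), ("CB", "SG")],
    "GLN": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "NE2")],
    "GLU": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "OE2")],
    "GLY": [],
    "HIS": [("CA", "CB"), ("CB", "CG"), ("CG", "ND1"), ("CG", "CD2"), ("ND1", "CE1"),
            ("CD2", "NE2"), ("CE1", "NE2")],
    "ILE": [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2"), ("CG1", "CD1")],
    "LEU": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2")],
    "LYS": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "CE"), ("CE", "NZ")],
    "MET": [("CA", "CB"), ("CB", "CG"), ("CG", "SD"), ("SD", "CE")],
    "PHE": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"), ("CD1", "CE1"),
            ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ")],
    "PRO": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "N")],
    "SER": [("CA", "CB"), ("CB", "OG")],
    "THR": [("CA", "CB"), ("CB", "OG1"), ("CB", "CG2")],
    "TRP": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"), ("CD1", "NE1"),
            ("NE1", "CE2"), ("CD2", "CE2"), ("CD2", "CE3"), ("CE3", "CZ3"),
            ("CZ3", "CH2"), ("CH2", "CZ2"), ("CZ2", "CE2")],
    "TYR": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"), ("CD1", "CE1"),
            ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ"), ("CZ", "OH")],
    "VAL": [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2")],
}

# heme b (protoporphyrin IX + Fe): four pyrrole rings A-D joined by methine
# carbons, two vinyls (rings B, C), four methyls, two propionates (rings A, D)
_HEM_BONDS: list[tuple[str, str]] = [
    ("FE", "NA"), ("FE", "NB"), ("FE", "NC"), ("FE", "ND"),
    ("NA", "C1A"), ("C1A", "C2A"), ("C2A", "C3A"), ("C3A", "C4A"), ("C4A", "NA"),
    ("NB", "C1B"), ("C1B", "C2B"), ("C2B", "C3B"), ("C3B", "C4B"), ("C4B", "NB"),
    ("NC", "C1C"), ("C1C", "C2C"), ("C2C", "C3C"), ("C3C", "C4C"), ("C4C", "NC"),
    ("ND", "C1D"), ("C1D", "C2D"), ("C2D", "C3D"), ("C3D", "C4D"), ("C4D", "ND"),
    ("C1A", "CHA"), ("CHA", "C4D"),
    ("C4A", "CHB"), ("CHB", "C1B"),
    ("C4B", "CHC"), ("CHC", "C1C"),
    ("C4C", "CHD"), ("CHD", "C1D"),
    ("C3A", "CMA"), ("C2B", "CMB"), ("C2C", "CMC"), ("C2D", "CMD"),
    ("C3B", "CAB"), ("CAB", "CBB"),
    ("C3C", "CAC"), ("CAC", "CBC"),
    ("C2A", "CAA"), ("CAA", "CBA"), ("CBA", "CGA"), ("CGA", "O1A"), ("CGA", "O2A"),
    ("C3D", "CAD"), ("CAD", "CBD"), ("CBD", "CGD"), ("CGD", "O1D"), ("CGD", "O2D"),
]

RESIDUE_TEMPLATES: dict[str, list[tuple[str, str]]] = {
    **{name: _BACKBONE + pairs for name, pairs in _SIDE_CHAINS.items()},
    "HEM": _HEM_BONDS,
    "HOH": [("O", "H1"), ("O", "H2"), ("OW", "HW1"), ("OW", "HW2")],
}


def _covalent_radius(element: str) -> float:
    r = gemmi.Element(element).covalent_r
    return r if r > 0 else 0.77


def _distance_rule_pairs(atoms: list[Atom]) -> list[tuple[Atom, Atom, float]]:
    """All pairs bonded by r <= r_cov_i + r_cov_j + tolerance."""
    out = []
    for i, a in enumerate(atoms):
        for b in atoms[i + 1 :]:
            r = float(np.linalg.norm(a.position - b.position))
            if 0 < r <= _covalent_radius(a.element) + _covalent_radius(b.element) + COVALENT_TOLERANCE:
                out.append((a, b, r))
    return out


def _residue_groups(structure: Structure) -> list[list[Atom]]:
    groups: list[list[Atom]] = []
    key = None
    for atom in structure.atoms:
        k = atom.residue_id
        if k != key:
            groups.append([])
            key = k
        groups[-1].append(atom)
    return groups


def perceive_covalent_bonds(structure: Structure) -> list[Edge]:
    """Build the covalent edge set of a single-model structure.

    Intra-residue connectivity comes from templates for the standard amino
    acids, heme and water; atoms a template does not know (hydrogens, altloc
    leftovers, unknown residues) fall back to the covalent-radius distance
    rule. Peptide bonds connect consecutive residues of a chain; the heme
    iron is linked to the proximal histidine NE2 when within
    ``FE_HIS_CUTOFF`` — the coordination bond the decay model treats as
    covalent (and can exclude as artificial during path search).
    """
    edges: dict[frozenset[int], Edge] = {}

    def add(a: Atom, b: Atom, r: float | None = None, fe_his: bool = False) -> None:
        key = frozenset((a.serial, b.serial))
        if key in edges:
            return
        if r is None:
            r = float(np.linalg.norm(a.position - b.position))
        if r <= 0:
            return
        edges[key] = Edge(a.serial, b.serial, "covalent", r, is_fe_his_link=fe_his)

    groups = _residue_groups(structure)
    warned: set[str] = set()
    for group in groups:
        resname = group[0].residue_name
        template = RESIDUE_TEMPLATES.get(resname)
        if template is None:
            if resname not in warned and not group[0].is_water:
                warnings.warn(
                    f"no connectivity template for residue {resname}; using distance rule",
                    stacklevel=2,
                )
                warned.add(resname)
            for a, b, r in _distance_rule_pairs(group):
                add(a, b, r)
            continue
        by_name = {a.name: a for a in group}
        templated: set[str] = set()
        for n1, n2 in template:
            if n1 in by_name and n2 in by_name:
                add(by_name[n1], by_name[n2])
                templated.update((n1, n2))
        template_names = {n for pair in template for n in pair}
        leftovers = [a for a in group if a.name not in template_names]
        if leftovers:
            for a, b, r in _distance_rule_pairs(group):
                if a in leftovers or b in leftovers:
                    add(a, b, r)

    # peptide bonds between consecutive residues of the same chain
    for g1, g2 in zip(groups, groups[1:]):
        if g1[0].chain_id != g2[0].chain_id:
            continue
        c = next((a for a in g1 if a.name == "C"), None)
        n = next((a for a in g2 if a.name == "N"), None)
        if c is not None and n is not None:
            r = float(np.linalg.norm(c.position - n.position))
            if r <= PEPTIDE_CUTOFF:
                add(c, n, r)

    # inter-residue distance fallback (disulfides, ligands, metal contacts)
    atoms = structure.atoms
    coords = structure.coordinates
    max_reach = 2 * max((_covalent_radius(a.element) for a in atoms), default=0.77)
    tree = cKDTree(coords)
    for i, j in tree.query_pairs(max_reach + COVALENT_TOLERANCE):
        a, b = atoms[i], atoms[j]
        if a.residue_id == b.residue_id:
            continue
        if a.element == "H" or b.element == "H":
            continue  # inter-residue H contacts are hydrogen bonds, not covalent
        r = float(np.linalg.norm(coords[i] - coords[j]))
        if r <= _covalent_radius(a.element) + _covalent_radius(b.element) + COVALENT_TOLERANCE:
            add(a, b, r)

    # heme iron to proximal histidine
    irons = [a for a in atoms if a.residue_name == "HEM" and a.element.upper() == "FE"]
    if irons:
        ne2s = [a for a in atoms if a.residue_name == "HIS" and a.name == "NE2"]
        linked = False
        for fe in irons:
            best = None
            for ne2 in ne2s:
                r = float(np.linalg.norm(fe.position - ne2.position))
                if r <= FE_HIS_CUTOFF and (best is None or r < best[1]):
                    best = (ne2, r)
            if best is not None:
                # the flag must survive even if the distance fallback saw the pair first
                edges.pop(frozenset((fe.serial, best[0].serial)), None)
                add(fe, best[0], best[1], fe_his=True)
                linked = True
        if not linked:
            warnings.warn(
                "heme present but no proximal histidine NE2 within "
                f"{FE_HIS_CUTOFF} Å; no Fe-His link added",
                stacklevel=2,
            )
    return list(edges.values())


# --- hydrogen bonds --------------------------------------------------------

def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c at vertex b, degrees."""
    v1 = a - b
    v2 = c - b
    cosang = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _covalent_within_two(adj: dict[int, set[int]], i: int, j: int) -> bool:
    if j in adj.get(i, ()):
        return True
    return any(j in adj.get(k, ()) for k in adj.get(i, ()))


def detect_hbond_edges(
    structure: Structure,
    criteria: HBondCriteria = HBondCriteria(),
    covalent: list[Edge] | None = None,
) -> list[Edge]:
    """Find hydrogen-bond edges under the geometric criteria.

    In a structure that contains hydrogens, donors are N/O atoms with an
    attached hydrogen and the hydrogen-based criterion applies (H···A
    distance plus D-H···A angle). In a hydrogen-free structure (crystal
    coordinates) any N/O may donate and the heavy-atom distance fallback
    applies, excluding pairs already joined by a covalent path of length
    ≤ 2. Either way the edge carries the donor-acceptor heavy-atom
    distance, the separation the decay law is parameterized on.
    """
    if covalent is None:
        covalent = perceive_covalent_bonds(structure)
    adj: dict[int, set[int]] = {}
    for e in covalent:
        adj.setdefault(e.atom_i, set()).add(e.atom_j)
        adj.setdefault(e.atom_j, set()).add(e.atom_i)

    by_serial = {a.serial: a for a in structure.atoms}
    polar = [a for a in structure.atoms if a.element in ("N", "O")]
    if not polar:
        return []
    hydrogens = {a.serial: a for a in structure.atoms if a.element == "H"}

    polar_pos = np.array([a.position for a in polar])
    tree = cKDTree(polar_pos)
    found: dict[frozenset[int], Edge] = {}

    use_fallback = not hydrogens
    for donor in polar:
        attached_h = [
            hydrogens[s] for s in adj.get(donor.serial, ()) if s in hydrogens
        ]
        if attached_h:
            for h in attached_h:
                for idx in tree.query_ball_point(h.position, criteria.max_ha_distance):
                    acc = polar[idx]
                    if acc.serial == donor.serial:
                        continue
                    ha = float(np.linalg.norm(h.position - acc.position))
                    if ha >= criteria.max_ha_distance:
                        continue
                    if _angle_deg(donor.position, h.position, acc.position) <= criteria.min_dha_angle:
                        continue
                    key = frozenset((donor.serial, acc.serial))
                    if key in found:
                        continue
                    r_da = float(np.linalg.norm(donor.position - acc.position))
                    found[key] = Edge(donor.serial, acc.serial, "hbond", r_da)
        elif use_fallback:
            for idx in tree.query_ball_point(
                donor.position, criteria.heavy_atom_fallback_distance
            ):
                acc = polar[idx]
                if acc.serial == donor.serial:
                    continue
                r_da = float(np.linalg.norm(donor.position - acc.position))
                if r_da >= criteria.heavy_atom_fallback_distance:
                    continue
                if _covalent_within_two(adj, donor.serial, acc.serial):
                    continue
                key = frozenset((donor.serial, acc.serial))
                if key not in found:
                    found[key] = Edge(donor.serial, acc.serial, "hbond", r_da)
    # never shadow a covalent contact
    for e in covalent:
        found.pop(e.key, None)
    return list(found.values())


def build_transfer_graph(
    structure: Structure,
    covalent: list[Edge] | None = None,
    hbond: list[Edge] | None = None,
    space_cutoff: float = 6.0,
    provenance: str | None = None,
) -> TransferGraph:
    """Assemble the full typed graph including through-space contacts.

    Every atom pair within ``space_cutoff`` that carries neither a covalent
    nor a hydrogen-bond edge gets one space edge; precedence is
    covalent > hbond > space, so each pair holds exactly one edge.
    """
    if space_cutoff <= 0:
        raise ValueError("space_cutoff must be positive")
    if covalent is None:
        covalent = perceive_covalent_bonds(structure)
    if hbond is None:
        hbond = detect_hbond_edges(structure, covalent=covalent)

    graph = TransferGraph(
        atoms=structure.atoms,
        provenance=provenance
        or f"{structure.identifier or 'structure'}|space_cutoff={space_cutoff}",
    )
    taken: set[frozenset[int]] = set()
    for e in covalent:
        graph.add_edge(e)
        taken.add(e.key)
    for e in hbond:
        if e.key not in taken:
            graph.add_edge(e)
            taken.add(e.key)

    atoms = structure.atoms
    coords = structure.coordinates
    tree = cKDTree(coords)
    for i, j in sorted(tree.query_pairs(space_cutoff)):
        key = frozenset((atoms[i].serial, atoms[j].serial))
        if key in taken:
            continue
        r = float(np.linalg.norm(coords[i] - coords[j]))
        if r > 0:
            graph.add_edge(Edge(atoms[i].serial, atoms[j].serial, "space", r))
            taken.add(key)
    return graph
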