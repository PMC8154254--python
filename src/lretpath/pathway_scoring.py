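"""Exponential decay-factor scoring and max-product pathway search.

Electronic coupling between a donor and an acceptor falls off
multiplicatively along a chain of covalent bonds, hydrogen bonds, and
through-space jumps. Each edge carries a decay factor

    q = A * exp(-B * (r - R))

with per-kind parameters A (dimensionless prefactor), B (1/Å) and R (Å).
A pathway's strength is the product of its edge decays, reported as
ln(k) = Σ ln(q); more negative means weaker coupling. The optimal pathway
maximizes the product, equivalently minimizes Σ -ln(q), so Dijkstra's
algorithm over nonnegative edge weights finds it exactly.
"""

from __future__ import annotations

import heapq
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .molecular_graph import Edge, TransferGraph
from .structure_io import Atom, Structure, resolve_atom

__all__ = [
    "DecayParameters",
    "PathResult",
    "RankingRow",
    "ResidueRanking",
    "NO_PATH",
    "edge_decay",
    "edge_weight",
    "best_path",
    "brute_force_best_path",
    "rank_residues",
    "select_candidates",
]

BRUTE_FORCE_NODE_GUARD = 14


@dataclass(frozen=True)
class KindParameters:
    """(A, B, R) of the decay law for one edge kind."""

    A: float
    B: float
    R: float

    def __post_init__(self) -> None:
        if not 0 < self.A <= 1:
            raise ValueError(f"prefactor A must be in (0, 1], got {self.A}")
        if self.B < 0 or self.R < 0:
            raise ValueError("B and R must be nonnegative")


@dataclass(frozen=True)
class DecayParameters:
    """Per-edge-kind parameters of the tunneling decay law.

    Defaults are the classic pathways-model values: a distance-independent
    factor of 0.6 per covalent bond; hydrogen bonds referenced to a 2.8 Å
    heavy-atom separation; through-space jumps referenced to 1.4 Å with the
    same 1.7 Å⁻¹ exponent.
    """

    covalent: KindParameters = field(default_factory=lambda: KindParameters(0.6, 0.0, 0.0))
    hbond: KindParameters = field(default_factory=lambda: KindParameters(0.36, 1.7, 2.8))
    space: KindParameters = field(default_factory=lambda: KindParameters(0.6, 1.7, 1.4))

    def for_kind(self, kind: str) -> KindParameters:
        try:
            return getattr(self, kind)
        except AttributeError:
            raise KeyError(f"no decay parameters for edge kind {kind!r}") from None

    @classmethod
    def from_dict(cls, d: dict) -> "DecayParameters":
        kinds = {}
        for kind in ("covalent", "hbond", "space"):
            if kind in d:
                v = d[kind]
                kinds[kind] = KindParameters(float(v["A"]), float(v["B"]), float(v["R"]))
        return cls(**kinds)


def edge_decay(edge: Edge, params: DecayParameters = DecayParameters()) -> float:
    """Decay factor q of one edge, clamped to its kind's prefactor A.

    The clamp keeps q ≤ A for r below the reference distance R, so
    -ln(q) ≥ 0 (the Dijkstra precondition) and no jump ever scores better
    than its own contact limit.
    """
    if not np.isfinite(edge.r_ij):
        raise ValueError(f"non-finite edge distance {edge.r_ij}")
    p = params.for_kind(edge.kind)
    return float(min(p.A * math.exp(-p.B * (edge.r_ij - p.R)), p.A))


def edge_weight(edge: Edge, params: DecayParameters = DecayParameters()) -> float:
    """Nonnegative Dijkstra weight -ln(q)."""
    return -math.log(edge_decay(edge, params))


@dataclass(frozen=True)
class PathResult:
    """One optimal pathway: atom chain, per-edge decays, total ln(k)."""

    atoms: tuple[int, ...]
    edge_decays: tuple[float, ...]
    edge_kinds: tuple[str, ...]
    ln_k: float

    @property
    def found(self) -> bool:
        return math.isfinite(self.ln_k)

    @property
    def atom_count(self) -> int:
        return len(self.atoms)

    @property
    def kind_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for k in self.edge_kinds:
            out[k] = out.get(k, 0) + 1
        return out

    def uses_edge(self, i: int, j: int) -> bool:
        pairs = set(zip(self.atoms, self.atoms[1:]))
        return (i, j) in pairs or (j, i) in pairs


NO_PATH = PathResult(atoms=(), edge_decays=(), edge_kinds=(), ln_k=float("-inf"))


def _result_from_chain(graph: TransferGraph, chain: tuple[int, ...], params: DecayParameters) -> PathResult:
    decays, kinds = [], []
    for i, j in zip(chain, chain[1:]):
        e = graph.get_edge(i, j)
        decays.append(edge_decay(e, params))
        kinds.append(e.kind)
    ln_k = float(sum(math.log(q) for q in decays))
    return PathResult(atoms=chain, edge_decays=tuple(decays), edge_kinds=tuple(kinds), ln_k=ln_k)


def _edge_allowed(edge: Edge, forbid_fe_his: bool) -> bool:
    return not (forbid_fe_his and edge.is_fe_his_link)


def best_path(
    graph: TransferGraph,
    donor: int | Atom,
    acceptor: int | Atom,
    params: DecayParameters = DecayParameters(),
    forbid_fe_his: bool = False,
) -> PathResult:
    """Pathway maximizing the product of decay factors (Dijkstra search).

    Ties on total weight are broken by fewer atoms, then by lexicographic
    atom serials, so output is deterministic. With ``forbid_fe_his`` the
    iron-histidine coordination edge is removed before the search. An
    unreachable acceptor yields the ``NO_PATH`` sentinel (ln_k = -inf).
    """
    donor = donor.serial if isinstance(donor, Atom) else donor
    acceptor = acceptor.serial if isinstance(acceptor, Atom) else acceptor
    if donor not in graph or acceptor not in graph:
        raise KeyError("donor and acceptor must be graph nodes")
    if donor == acceptor:
        return PathResult(atoms=(donor,), edge_decays=(), edge_kinds=(), ln_k=0.0)

    # priority = (total -ln q, edge count, serial chain): the secondary keys
    # implement the documented tie-break and are preserved under extension
    heap: list[tuple[float, int, tuple[int, ...]]] = [(0.0, 0, (donor,))]
    settled: set[int] = set()
    while heap:
        dist, nedges, chain = heapq.heappop(heap)
        node = chain[-1]
        if node in settled:
            continue
        settled.add(node)
        if node == acceptor:
            return _result_from_chain(graph, chain, params)
        for nbr, edge in graph.neighbors(node):
            if nbr in settled or not _edge_allowed(edge, forbid_fe_his):
                continue
            heapq.heappush(
                heap, (dist + edge_weight(edge, params), nedges + 1, chain + (nbr,))
            )
    return NO_PATH


def brute_force_best_path(
    graph: TransferGraph,
    donor: int | Atom,
    acceptor: int | Atom,
    params: DecayParameters = DecayParameters(),
    forbid_fe_his: bool = False,
) -> PathResult:
    """Exhaustive max-product search over all simple paths (testing oracle).

    Same tie-breaking as :func:`best_path`; guarded to graphs of at most
    ``BRUTE_FORCE_NODE_GUARD`` nodes.
    """
    n = len(graph.nodes)
    if n > BRUTE_FORCE_NODE_GUARD:
        raise ValueError(f"graph has {n} nodes; brute force limited to {BRUTE_FORCE_NODE_GUARD}")
    donor = donor.serial if isinstance(donor, Atom) else donor
    acceptor = acceptor.serial if isinstance(acceptor, Atom) else acceptor
    if donor not in graph or acceptor not in graph:
        raise KeyError("donor and acceptor must be graph nodes")
    if donor == acceptor:
        return PathResult(atoms=(donor,), edge_decays=(), edge_kinds=(), ln_k=0.0)

    best: tuple[float, int, tuple[int, ...]] | None = None

    def extend(chain: tuple[int, ...], weight: float) -> None:
        nonlocal best
        node = chain[-1]
        if node == acceptor:
            key = (weight, len(chain) - 1, chain)
            if best is None or key < best:
                best = key
            return
        for nbr, edge in graph.neighbors(node):
            if nbr in chain or not _edge_allowed(edge, forbid_fe_his):
                continue
            extend(chain + (nbr,), weight + edge_weight(edge, params))

    extend((donor,), 0.0)
    if best is None:
        return NO_PATH
    return _result_from_chain(graph, best[2], params)


ACCEPTOR_ATOMS = {"TYR": "OH", "TRP": "NE1"}


@dataclass(frozen=True)
class RankingRow:
    residue_id: tuple[str, int, str]  # (chain, residue number, residue name)
    acceptor_atom: str
    path: PathResult
    uses_fe_his_link: bool = False


@dataclass
class ResidueRanking:
    """Per-residue optimal pathways, sorted by descending ln(k)."""

    rows: list[RankingRow]

    def __post_init__(self) -> None:
        self.rows = sorted(
            self.rows, key=lambda r: (-r.path.ln_k, r.residue_id[0], r.residue_id[1])
        )

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def residues(self) -> list[tuple[str, int, str]]:
        return [r.residue_id for r in self.rows]


def _fe_his_edges(graph: TransferGraph) -> list[Edge]:
    return [e for e in graph.edges if e.is_fe_his_link]


def rank_residues(
    structure: Structure,
    graph: TransferGraph,
    params: DecayParameters = DecayParameters(),
    donor=None,
    forbid_fe_his: bool = False,
) -> ResidueRanking:
    """Score every tyrosine (acceptor OH) and tryptophan (acceptor NE1).

    The search runs the inverse route, from the heme iron out to each
    candidate's radical-bearing atom; the undirected graph makes the score
    direction-independent. Rows whose optimal path traverses the
    iron-histidine link are flagged so that treatment can be compared.
    """
    if donor is None:
        irons = [
            a for a in structure.atoms
            if a.residue_name == "HEM" and a.element.upper() == "FE"
        ]
        if not irons:
            raise ValueError("no heme iron (HEM/FE) found; supply donor explicitly")
        donor_atom = irons[0]
    else:
        donor_atom = resolve_atom(structure, donor)

    fe_his = _fe_his_edges(graph)
    rows: list[RankingRow] = []
    seen: set[tuple[str, int, str]] = set()
    for atom in structure.atoms:
        resname = atom.residue_name
        if resname not in ACCEPTOR_ATOMS or atom.residue_id in seen:
            continue
        seen.add(atom.residue_id)
        chain_id, resnum, _ = atom.residue_id
        target_name = ACCEPTOR_ATOMS[resname]
        acceptors = structure.find_atoms(
            name=target_name, residue_number=resnum, chain_id=chain_id, residue_name=resname
        )
        if not acceptors:
            warnings.warn(
                f"{resname} {chain_id}{resnum} lacks acceptor atom {target_name}; skipped",
                stacklevel=2,
            )
            continue
        path = best_path(graph, donor_atom, acceptors[0], params, forbid_fe_his=forbid_fe_his)
        uses_link = any(path.uses_edge(e.atom_i, e.atom_j) for e in fe_his)
        rows.append(
            RankingRow(
                residue_id=atom.residue_id,
                acceptor_atom=target_name,
                path=path,
                uses_fe_his_link=uses_link,
            )
        )
    if not rows:
        raise ValueError("structure contains no scorable Tyr or Trp residues")
    return ResidueRanking(rows=rows)


def select_candidates(ranking: ResidueRanking, cutoff_ln_k: float) -> list[RankingRow]:
    """Rows at or above the ln(k) cutoff, in ranking order.

    Mirrors the selection step where scores of known radical sites in
    related peroxidases set the threshold for mutagenesis targets.
    """
    if not ranking.rows:
        raise ValueError("ranking is empty")
    return [r for r in ranking.rows if r.path.ln_k >= cutoff_ln_k]
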